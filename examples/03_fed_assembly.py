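"""Assemble a filtered expression data (FED) table from per-cell measurements.

Three worms are imaged for three neurons; one cell identification is flagged
as incorrect in the exclusion table, so that worm drops out of the joint
table (it lacks a complete response vector) but its remaining cells stay
available for marginal analyses.
"""

import tempfile
from pathlib import Path

from wormcode import ExclusionTable, apply_exclusion, merge_worms, read_fed, write_fed
from wormcode.fed import CellMeasurement

READOUTS = ("ASI", "ADF", "NSM")
values = {("w1", "ASI"): 812.0, ("w1", "ADF"): 432.5, ("w1", "NSM"): 210.0,
          ("w2", "ASI"): 655.0, ("w2", "ADF"): 388.0, ("w2", "NSM"): 175.5,
          ("w3", "ASI"): 940.0, ("w3", "ADF"): 501.0, ("w3", "NSM"): 260.0}
ms = [CellMeasurement(batch="b1", worm=w, genotype="N2", condition="2.0e9",
                      cell=c, value=v) for (w, c), v in values.items()]

x = ExclusionTable({w: {"ASI": 0, "ADF": 1 if w == "w2" else 0, "NSM": 0}
                    for w in ("w1", "w2", "w3")}, READOUTS)
kept = apply_exclusion(ms, x)
print(f"{len(ms)} measurements, {len(ms) - len(kept)} removed by the exclusion table")

merged = merge_worms(kept, READOUTS)
print(f"joint table: {len(merged.records)} complete worms "
      f"({', '.join(r.worm for r in merged.records)})")
print(f"side table:  {len(merged.side)} measurements from incomplete worms "
      f"({', '.join(sorted({m.worm for m in merged.side}))})")

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "FED_merged.dat"
    write_fed(merged.records, path, READOUTS)
    back, _ = read_fed(path)
    print(f"roundtrip through {path.name}: {'exact' if back == list(merged.records) else 'LOSSY'}")
    print()
    print(path.read_text().rstrip())
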