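"""Filtered expression data (FED) tables: loading, exclusion filtering, merging.

The imaging pipeline produces one background-subtracted integrated intensity
per (worm, neuron).  These per-cell measurements are screened against a
manually curated exclusion table (a binary flag per worm and cell marking
mis-identified neurons), and the surviving values are merged into one row per
worm — the response vector g — provided the worm has a positive value for
every configured readout.  Worms missing any readout are dropped from the
joint table but kept in a per-cell side table so marginal-only analyses can
still use them.

FED files are tab-delimited UTF-8 with a mandatory header line
``batch worm genotype condition <readout...>`` and full-precision decimal
values, so a write/read roundtrip is exact.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "CellMeasurement", "ExclusionTable", "WormRecord", "MergeResult",
    "FedFormatError", "load_measurements", "apply_exclusion", "merge_worms",
    "write_fed", "read_fed",
]

MEASUREMENT_HEADER = ("worm", "cell", "value")


class FedFormatError(ValueError):
    """Raised when an expression or exclusion file violates the documented format."""


@dataclass(frozen=True)
class CellMeasurement:
    """One background-subtracted integrated fluorescence value for one neuron."""

    batch: str
    worm: str
    genotype: str
    condition: str
    cell: str
    value: float


@dataclass(frozen=True)
class WormRecord:
    """One worm's complete response vector, ordered as the configured readouts."""

    batch: str
    worm: str
    genotype: str
    condition: str
    g: tuple

    def __post_init__(self):
        object.__setattr__(self, "g", tuple(float(v) for v in self.g))


@dataclass(frozen=True)
class MergeResult:
    """Joint records (complete worms) plus the per-cell side table of the rest."""

    records: tuple
    side: tuple

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


class ExclusionTable:
    """Binary table flagging mis-identified cells: 0 = correct, 1 = incorrect."""

    def __init__(self, flags: dict[str, dict[str, int]], readouts: Sequence[str]):
        self.readouts = tuple(readouts)
        self.flags = {}
        for worm, row in flags.items():
            if set(row) != set(self.readouts):
                raise FedFormatError(
                    f"exclusion row for worm {worm!r} has cells {sorted(row)}, "
                    f"expected {sorted(self.readouts)}")
            for cell, v in row.items():
                if v not in (0, 1):
                    raise FedFormatError(
                        f"exclusion flag for ({worm!r}, {cell!r}) is {v!r}, must be 0 or 1")
            self.flags[str(worm)] = {c: int(v) for c, v in row.items()}

    def flag(self, worm: str, cell: str) -> int:
        try:
            return self.flags[str(worm)][cell]
        except KeyError:
            raise KeyError(f"no exclusion flag for worm {worm!r}, cell {cell!r}") from None

    @classmethod
    def read_csv(cls, path) -> "ExclusionTable":
        """Read an exclusion CSV: first column worm label, one column per readout."""
        path = Path(path)
        with path.open(newline="") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise FedFormatError(f"{path}: empty exclusion file") from None
            readouts = [h.strip() for h in header[1:]]
            if not readouts:
                raise FedFormatError(f"{path}: exclusion header must name readout columns")
            flags: dict = {}
            for ln, row in enumerate(reader, start=2):
                if not row or not any(s.strip() for s in row):
                    continue
                worm = row[0].strip()
                if len(row) != len(readouts) + 1:
                    raise FedFormatError(f"{path}:{ln}: expected {len(readouts) + 1} "
                                         f"columns, got {len(row)}")
                try:
                    flags[worm] = {c: int(v) for c, v in zip(readouts, row[1:])}
                except ValueError:
                    raise FedFormatError(f"{path}:{ln}: non-integer exclusion flag") from None
        return cls(flags, readouts)


def load_measurements(paths: Sequence, annotation: dict) -> list[CellMeasurement]:
    """Read per-cell expression files into CellMeasurements.

    Each file is tab-delimited with header ``worm\\tcell\\tvalue``; the
    ``annotation`` mapping supplies the experiment-level metadata and must
    contain ``batch``, ``genotype`` and ``condition`` (either one value for
    all files, or a per-file mapping keyed by path).
    """
    per_file = bool(annotation) and all(isinstance(v, dict) for v in annotation.values())
    out: list[CellMeasurement] = []
    for path in paths:
        path = Path(path)
        if per_file:
            try:
                meta = annotation[str(path)]
            except KeyError:
                raise FedFormatError(f"no annotation entry for {path}") from None
        else:
            meta = annotation
        for key in ("batch", "genotype", "condition"):
            if key not in meta:
                raise FedFormatError(f"annotation for {path} lacks {key!r}")
        with path.open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if tuple(h.strip() for h in header) != MEASUREMENT_HEADER:
                raise FedFormatError(
                    f"{path}:1: expected header {list(MEASUREMENT_HEADER)}, got {header}")
            for ln, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise FedFormatError(f"{path}:{ln}: expected 3 columns, got {len(parts)}")
                worm, cell, raw = (s.strip() for s in parts)
                try:
                    value = float(raw)
                except ValueError:
                    raise FedFormatError(
                        f"{path}:{ln}: non-numeric expression value {raw!r}") from None
                if not value == value or value in (float("inf"), float("-inf")):
                    raise FedFormatError(f"{path}:{ln}: non-finite expression value {raw!r}")
                out.append(CellMeasurement(batch=str(meta["batch"]), worm=worm,
                                           genotype=str(meta["genotype"]),
                                           condition=str(meta["condition"]),
                                           cell=cell, value=value))
    return out


def apply_exclusion(ms: Sequence[CellMeasurement],
                    x: ExclusionTable) -> list[CellMeasurement]:
    """Drop measurements whose exclusion flag is 1; order otherwise preserved.

    Every (worm, cell) in ``ms`` must be covered by the table — a worm that
    was imaged but never curated is an error, not a silent pass-through.
    """
    out = []
    for m in ms:
        if x.flag(m.worm, m.cell) == 0:
            out.append(m)
    return out


def merge_worms(ms: Sequence[CellMeasurement],
                readouts: Sequence[str]) -> MergeResult:
    """Combine per-cell measurements into one row (WormRecord) per complete worm.

    A worm enters the joint table only if it has a strictly positive value
    for every readout; zero fluorescence marks a missing/failed quantification
    and negative values (possible after background subtraction) are likewise
    treated as missing (and logged).  Incomplete worms' valid measurements are
    returned in the ``side`` table for marginal-only analyses.  Output is
    sorted by (batch, worm).
    """
    readouts = tuple(readouts)
    by_worm: dict = {}
    meta: dict = {}
    for m in ms:
        if m.cell not in readouts:
            raise ValueError(f"measurement cell {m.cell!r} not in configured "
                             f"readouts {list(readouts)}")
        key = (m.batch, m.worm)
        cellmap = by_worm.setdefault(key, {})
        if m.cell in cellmap:
            raise ValueError(f"duplicate measurement for worm {m.worm!r} "
                             f"(batch {m.batch!r}), cell {m.cell!r}")
        cellmap[m.cell] = m
        meta.setdefault(key, (m.genotype, m.condition))

    records, side = [], []
    for key in sorted(by_worm):
        batch, worm = key
        genotype, condition = meta[key]
        cellmap = by_worm[key]
        usable = {}
        for cell, m in cellmap.items():
            if m.value > 0:
                usable[cell] = m
            elif m.value < 0:
                logger.warning("negative value %g for worm %r cell %r treated as missing",
                               m.value, worm, cell)
        if all(c in usable for c in readouts):
            records.append(WormRecord(batch=batch, worm=worm, genotype=genotype,
                                      condition=condition,
                                      g=tuple(usable[c].value for c in readouts)))
        else:
            side.extend(usable[c] for c in readouts if c in usable)
    return MergeResult(records=tuple(records), side=tuple(side))


_FED_META = ("batch", "worm", "genotype", "condition")


def write_fed(records: Sequence[WormRecord], path, readouts: Sequence[str]) -> Path:
    """Write WormRecords as a tab-delimited FED file with full-precision values."""
    path = Path(path)
    readouts = tuple(readouts)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_FED_META + readouts) + "\n")
        for r in records:
            if len(r.g) != len(readouts):
                raise ValueError(f"record {r.worm!r} has {len(r.g)} readouts, "
                                 f"expected {len(readouts)}")
            vals = "\t".join(repr(v) for v in r.g)
            fh.write(f"{r.batch}\t{r.worm}\t{r.genotype}\t{r.condition}\t{vals}\n")
    return path


def read_fed(path) -> tuple[list[WormRecord], tuple]:
    """Read a FED file; returns (records, readout names)."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:4]) != _FED_META:
            raise FedFormatError(f"{path}:1: FED header must start with {list(_FED_META)}")
        readouts = tuple(header[4:])
        if not readouts:
            raise FedFormatError(f"{path}:1: FED header names no readout columns")
        records = []
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4 + len(readouts):
                raise FedFormatError(f"{path}:{ln}: expected {4 + len(readouts)} columns")
            try:
                g = tuple(float(v) for v in parts[4:])
            except ValueError:
                raise FedFormatError(f"{path}:{ln}: non-numeric expression value") from None
            records.append(WormRecord(batch=parts[0], worm=parts[1], genotype=parts[2],
                                      condition=parts[3], g=g))
    return records, readouts
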