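"""Worked arithmetic for preparing the six-level bacterial food series.

An overnight OP50 culture is measured by a 10-fold-diluted OD600 reading,
concentrated to the 1.12e10 cells/mL working stock (OD600 56), and serially
diluted down to complete food deprivation.
"""

from wormcode import assay

reading = 0.28
od = assay.undiluted_od(reading, 10)
vol = assay.resuspension_volume(450, od, 56)
print(f"10-fold dilution reads OD600 {reading} -> culture OD600 {od:.1f}")
print(f"resuspend the 450 mL pellet in {vol:.2f} mL to reach the OD600 56 stock")
print()

series = assay.food_level_series()
factors = assay.dilution_factors(series)
print("cells/mL      OD600    dilution from previous")
for c, od6, f in zip(series.concentrations, series.od600, factors):
    ftxt = "  NA (plain buffer)" if f is None else f"{f:6.2f}"
    print(f"{c:10.3g}  {od6:7.3f}  {ftxt}")
print()
print("Each row is one food level of the broad-range dietary-restriction "
      "design;\nthe dilution factor turns the previous concentration into this one.")
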