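"""Bacterial food-level arithmetic for the broad-range dietary-restriction design.

Food abundance is set by seeding plates with E. coli OP50 at one of six
concentrations spanning ad libitum (1.12e10 cells/mL) down to complete
deprivation (plain S basal).  Concentrations are prepared by serial dilution
of a working stock whose density is set spectrophotometrically, using the
convention that one OD600 unit corresponds to 2e8 cells/mL.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FoodLevelSeries", "CELLS_PER_OD", "undiluted_od", "resuspension_volume",
           "od_from_cells", "dilution_factors", "food_level_series"]

#: OD600-to-concentration conversion: 1.12e10 cells/mL == OD600 56.
CELLS_PER_OD = 2.0e8

#: The six food concentrations (cells/mL) of the broad-range DR series.
FOOD_CONCENTRATIONS = (1.12e10, 2.00e9, 6.32e8, 6.32e7, 2.00e7, 0.0)


@dataclass(frozen=True)
class FoodLevelSeries:
    """A decreasing series of bacterial densities with their OD600 equivalents."""

    concentrations: tuple
    cells_per_od: float = CELLS_PER_OD

    def __post_init__(self):
        c = tuple(float(v) for v in self.concentrations)
        if any(a <= b for a, b in zip(c, c[1:])):
            raise ValueError("concentrations must be strictly decreasing")
        object.__setattr__(self, "concentrations", c)

    @property
    def od600(self) -> tuple:
        return tuple(od_from_cells(c, self.cells_per_od) for c in self.concentrations)


def undiluted_od(reading: float, dilution_factor: float) -> float:
    """OD600 of the original culture from the reading of a diluted sample."""
    if reading < 0:
        raise ValueError("OD reading cannot be negative")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    return reading * dilution_factor


def resuspension_volume(culture_volume: float, measured_od: float,
                        target_od: float) -> float:
    """Volume (mL) in which to resuspend a pelleted culture to hit a target OD600.

    Conserves total cells: volume x OD is constant, so a 450 mL culture at
    OD 2.8 resuspended for OD 56 needs 450 * 2.8 / 56 = 22.50 mL.
    """
    if culture_volume <= 0 or measured_od <= 0:
        raise ValueError("culture volume and measured OD must be positive")
    if target_od <= 0:
        raise ValueError("target OD must be positive")
    return culture_volume * measured_od / target_od


def od_from_cells(cells_per_ml: float, cells_per_od: float = CELLS_PER_OD) -> float:
    """OD600 equivalent of a bacterial concentration (linear conversion)."""
    if cells_per_ml < 0:
        raise ValueError("concentration cannot be negative")
    return cells_per_ml / cells_per_od


def dilution_factors(series: FoodLevelSeries) -> list:
    """Step dilution factor from each concentration to the next lower one.

    ``factor_i = concentration_{i-1} / concentration_i`` for i >= 1; the
    working stock itself has no predecessor (factor 0 by convention) and a
    zero concentration (plain buffer) has no factor (None).
    """
    c = series.concentrations
    out = [0.0]
    for prev, cur in zip(c, c[1:]):
        out.append(None if cur == 0 else prev / cur)
    return out


def food_level_series() -> FoodLevelSeries:
    """The standard six-level broad-range DR series, zero (plain buffer) included."""
    return FoodLevelSeries(concentrations=FOOD_CONCENTRATIONS)
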