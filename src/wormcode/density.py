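"""Grid-binned kernel density estimates of conditional expression distributions.

Expression responses g (one vector per worm) are summarized per environmental
condition f as a probability vector over a shared hypercubic grid: GS bins per
readout dimension spanning the pooled minimum-to-maximum range of the data.
The Gaussian kernel density estimate is evaluated at the bin centers and
renormalized to sum to one, yielding the conditional distribution p(g|f) that
downstream information-theoretic routines consume.

Group labels 1..5 support leave-one-fifth-out resampling: a density estimated
"for group g" uses the 80% of the data remaining after removing fold g, which
is how estimator variability due to sample size is probed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from wormcode.fed import WormRecord

__all__ = [
    "GridSpec", "ConditionalDensity", "pooled_grid", "assign_groups",
    "estimate_density", "density_filename", "write_density", "read_density",
]


@dataclass(frozen=True)
class GridSpec:
    """Hypercubic evaluation grid: ``gs`` bins per dimension over [lo, hi].

    Bins are half-open ``[edge_i, edge_{i+1})`` with the final bin closed at
    ``hi``; linear bin indices are row-major in readout order.  The total
    number of bins is ``M = gs ** dims``.
    """

    gs: int
    lo: tuple
    hi: tuple

    def __post_init__(self):
        if self.gs < 2:
            raise ValueError("need at least 2 bins per dimension")
        lo = tuple(float(v) for v in np.atleast_1d(self.lo))
        hi = tuple(float(v) for v in np.atleast_1d(self.hi))
        if len(lo) != len(hi):
            raise ValueError("lo and hi must have the same length")
        for a, b in zip(lo, hi):
            if not a < b:
                raise ValueError(f"degenerate range [{a}, {b}]: lo must be < hi")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def dims(self) -> int:
        return len(self.lo)

    @property
    def n_bins(self) -> int:
        return self.gs ** self.dims

    @property
    def shape(self) -> tuple:
        return (self.gs,) * self.dims

    def edges(self, dim: int) -> np.ndarray:
        return np.linspace(self.lo[dim], self.hi[dim], self.gs + 1)

    def centers(self, dim: int) -> np.ndarray:
        e = self.edges(dim)
        return 0.5 * (e[:-1] + e[1:])

    def grid_points(self) -> np.ndarray:
        """All M bin centers as an (M, dims) array, row-major order."""
        axes = [self.centers(d) for d in range(self.dims)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.reshape(-1) for m in mesh], axis=1)

    def bin_widths(self) -> np.ndarray:
        return (np.asarray(self.hi) - np.asarray(self.lo)) / self.gs

    def to_dict(self) -> dict:
        return {"gs": self.gs, "lo": list(self.lo), "hi": list(self.hi)}

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(gs=int(d["gs"]), lo=tuple(d["lo"]), hi=tuple(d["hi"]))


@dataclass(frozen=True)
class ConditionalDensity:
    """Binned estimate of p(g|f) for one (genotype, condition, group)."""

    grid: GridSpec
    condition: str
    genotype: str
    group: int
    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (self.grid.n_bins,):
            raise ValueError(f"expected {self.grid.n_bins} bin probabilities, got {p.shape}")
        if np.any(p < 0) or not np.all(np.isfinite(p)):
            raise ValueError("bin probabilities must be finite and non-negative")
        s = p.sum()
        if s <= 0:
            raise ValueError("density has zero total mass")
        object.__setattr__(self, "p", p / s)


def pooled_grid(records: Sequence[WormRecord], gs: int) -> GridSpec:
    """Shared grid spanning the per-readout min/max over *all* supplied records.

    Densities that will be compared (across conditions or genotypes) must be
    estimated on one common grid, so the range is pooled over everything
    entering the comparison.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to define a grid range")
    G = np.asarray([r.g for r in records], dtype=float)
    lo = G.min(axis=0)
    hi = G.max(axis=0)
    const = np.nonzero(~(lo < hi))[0]
    if const.size:
        raise ValueError(f"readout dimension(s) {const.tolist()} are constant; "
                         "cannot define a grid range")
    return GridSpec(gs=gs, lo=tuple(lo), hi=tuple(hi))


def assign_groups(records: Sequence[WormRecord], k: int = 5,
                  seed: int = 0) -> np.ndarray:
    """Partition records into ``k`` disjoint folds, stratified by (genotype, condition).

    Returns an integer label in ``1..k`` per record.  Within each
    (genotype, condition) cell the fold sizes differ by at most one, so the
    complement of any fold holds ~(k-1)/k of each cell.  Deterministic for a
    given seed.
    """
    n = len(records)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=int)
    cells: dict = {}
    for i, r in enumerate(records):
        cells.setdefault((r.genotype, r.condition), []).append(i)
    for key in sorted(cells):
        idx = np.array(cells[key])
        rng.shuffle(idx)
        # round-robin over shuffled order: sizes within the cell differ by <= 1;
        # the fold order is itself permuted so leftovers spread across folds
        fold_order = rng.permutation(k)
        for j, i in enumerate(idx):
            labels[i] = 1 + int(fold_order[j % k])
    return labels


class _BandwidthKDE(stats.gaussian_kde):
    """Gaussian KDE with a selectable bandwidth factor.

    ``normal_scale`` uses the multivariate normal-reference rule
    H = (4/(d+2))^(2/(d+4)) n^(-2/(d+4)) * Sigma_hat (full sample covariance),
    the same normal-scale family the standard multivariate KDE selectors
    default to; ``scott`` uses Scott's factor n^(-1/(d+4)).
    """

    def __init__(self, dataset, rule: str = "normal_scale"):
        self._rule = rule
        super().__init__(dataset)

    def covariance_factor(self):
        d, n = self.dataset.shape
        if self._rule == "scott":
            return n ** (-1.0 / (d + 4))
        if self._rule == "normal_scale":
            return (4.0 / (d + 2)) ** (1.0 / (d + 4)) * n ** (-1.0 / (d + 4))
        raise ValueError(f"unknown bandwidth rule {self._rule!r}")


def _kde_on_grid(G: np.ndarray, grid: GridSpec, bandwidth: str) -> np.ndarray:
    """Evaluate a Gaussian KDE of the rows of G at all bin centers."""
    pts = grid.grid_points()
    n, d = G.shape
    if n == 1 or np.linalg.matrix_rank(np.cov(G.T).reshape(d, d)) < d:
        # degenerate sample: isotropic kernel of one bin width per dimension
        h = grid.bin_widths()
        z = (pts[:, None, :] - G[None, :, :]) / h[None, None, :]
        dens = np.exp(-0.5 * (z ** 2).sum(axis=2)).sum(axis=1)
    else:
        kde = _BandwidthKDE(G.T, rule=bandwidth)
        dens = kde(pts.T)
    total = dens.sum()
    if total <= 0:
        raise ValueError("all probability mass fell outside the grid")
    return dens / total


def estimate_density(records: Sequence[WormRecord], grid: GridSpec, *,
                     bandwidth: str = "normal_scale", group: int = 0,
                     k: int = 5, frac: float = 1.0, seed: int = 0,
                     min_records: int | None = None) -> ConditionalDensity:
    """Grid-binned conditional density for one (genotype, condition) subset.

    Parameters
    ----------
    records
        Complete WormRecords belonging to a single (genotype, condition).
    grid
        Shared evaluation grid (from :func:`pooled_grid`).
    bandwidth
        ``"normal_scale"`` (default) or ``"scott"``.
    group
        0 uses all records; 1..k uses the (k-1)/k complement of fold
        ``group`` under the seeded partition of :func:`assign_groups`.
    frac
        After group selection, keep this fraction of the remaining records
        (uniform without replacement, seeded).  Used for jack-knife
        sample-size extrapolation.
    min_records
        Minimum sample size; defaults to dims + 2.  Pass 1 to relax (tests).
    """
    conditions = {r.condition for r in records}
    genotypes = {r.genotype for r in records}
    if len(conditions) != 1 or len(genotypes) != 1:
        raise ValueError("records must belong to a single (genotype, condition); "
                         f"got genotypes={sorted(genotypes)} conditions={sorted(conditions)}")
    condition = next(iter(conditions))
    genotype = next(iter(genotypes))
    if not 0 <= group <= k:
        raise ValueError(f"group must be in 0..{k}")
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")

    selected = list(records)
    if group > 0:
        labels = assign_groups(selected, k=k, seed=seed)
        selected = [r for r, lab in zip(selected, labels) if lab != group]
    if frac < 1.0:
        rng = np.random.default_rng(seed + 1)
        m = max(1, int(round(frac * len(selected))))
        idx = rng.choice(len(selected), size=m, replace=False)
        selected = [selected[i] for i in sorted(idx)]

    need = (grid.dims + 2) if min_records is None else min_records
    if len(selected) < need:
        raise ValueError(f"too few records ({len(selected)} < {need}) for condition "
                         f"{condition!r}, group {group}")
    G = np.asarray([r.g for r in selected], dtype=float)
    if G.shape[1] != grid.dims:
        raise ValueError(f"records have {G.shape[1]} readouts but grid has {grid.dims}")
    p = _kde_on_grid(G, grid, bandwidth)
    return ConditionalDensity(grid=grid, condition=condition, genotype=genotype,
                              group=group, p=p)


def density_filename(label: str, genotype: str, condition: str, gs: int,
                     group: int) -> str:
    """Canonical density file name ``<label>_<GT>_<food>_GS<GS>_group<group>.dat``."""
    return f"{label}_{genotype}_{condition}_GS{gs}_group{group}.dat"


def write_density(d: ConditionalDensity, folder, label: str) -> Path:
    """Write a density as a single-column text file plus a grid sidecar JSON."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    path = folder / density_filename(label, d.genotype, d.condition, d.grid.gs, d.group)
    np.savetxt(path, d.p, fmt="%.17g")
    sidecar = path.with_suffix(".json")
    meta = {"grid": d.grid.to_dict(), "condition": d.condition,
            "genotype": d.genotype, "group": d.group}
    sidecar.write_text(json.dumps(meta, indent=1))
    return path


def read_density(path) -> ConditionalDensity:
    path = Path(path)
    p = np.loadtxt(path, ndmin=1)
    meta = json.loads(path.with_suffix(".json").read_text())
    grid = GridSpec.from_dict(meta["grid"])
    return ConditionalDensity(grid=grid, condition=meta["condition"],
                              genotype=meta["genotype"], group=int(meta["group"]),
                              p=p)
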