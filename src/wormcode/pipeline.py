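"""End-to-end convenience wrappers: worm records in, information estimates out.

These helpers wire the module chain together for the common case of one
genotype measured across several food conditions: pool a grid over every
record entering the comparison, estimate one conditional density per
condition, stack them into a discrete channel and compute capacity or the
full information decomposition.  They are also the ``statistic`` callables
handed to the uncertainty machinery.
"""

from __future__ import annotations

from typing import Sequence

from wormcode.density import GridSpec, estimate_density, pooled_grid
from wormcode.fed import WormRecord
from wormcode.infotheory import (CapacityResult, DiscreteChannel,
                                 InfoDecomposition, channel_capacity,
                                 channel_from_densities, decompose)

__all__ = ["channel_from_records", "capacity_from_records", "decompose_records"]


def channel_from_records(records: Sequence[WormRecord], gs: int, *,
                         grid: GridSpec | None = None,
                         bandwidth: str = "normal_scale", group: int = 0,
                         seed: int = 0, frac: float = 1.0) -> DiscreteChannel:
    """Estimate p(g|f) for every condition present and stack into a channel.

    Conditions are ordered by first appearance in ``records``.  A shared
    ``grid`` may be supplied to keep several channels commensurable (e.g.
    across genotypes); otherwise one is pooled from ``records``.
    """
    records = list(records)
    if grid is None:
        grid = pooled_grid(records, gs)
    conditions: list = []
    for r in records:
        if r.condition not in conditions:
            conditions.append(r.condition)
    if len(conditions) < 2:
        raise ValueError("need records from at least 2 conditions to form a channel")
    densities = []
    for cond in conditions:
        sub = [r for r in records if r.condition == cond]
        densities.append(estimate_density(sub, grid, bandwidth=bandwidth,
                                          group=group, seed=seed, frac=frac))
    return channel_from_densities(densities)


def capacity_from_records(records: Sequence[WormRecord], gs: int, *,
                          grid: GridSpec | None = None,
                          bandwidth: str = "normal_scale", group: int = 0,
                          seed: int = 0, frac: float = 1.0,
                          tol: float = 1e-8) -> CapacityResult:
    """Channel capacity (bits) of the expression code estimated from records."""
    ch = channel_from_records(records, gs, grid=grid, bandwidth=bandwidth,
                              group=group, seed=seed, frac=frac)
    return channel_capacity(ch, tol=tol)


def decompose_records(records: Sequence[WormRecord], gs: int, *,
                      grid: GridSpec | None = None,
                      bandwidth: str = "normal_scale", group: int = 0,
                      seed: int = 0, frac: float = 1.0,
                      tol: float = 1e-8) -> InfoDecomposition:
    """Joint/marginal/shuffle information breakdown estimated from records."""
    ch = channel_from_records(records, gs, grid=grid, bandwidth=bandwidth,
                              group=group, seed=seed, frac=frac)
    return decompose(ch, tol=tol)
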