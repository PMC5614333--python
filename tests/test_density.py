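"""Grid construction, fold assignment and grid-binned KDE against analytic oracles."""

import numpy as np
import pytest
from scipy.stats import norm

from wormcode.density import (ConditionalDensity, GridSpec, assign_groups,
                              density_filename, estimate_density, pooled_grid,
                              read_density, write_density)
from conftest import make_records


def analytic_binned_normal(grid):
    """Standard bivariate normal mass per bin from Phi differences, grid-renormalized."""
    per_dim = []
    for d in range(grid.dims):
        e = grid.edges(d)
        per_dim.append(norm.cdf(e[1:]) - norm.cdf(e[:-1]))
    q = np.multiply.outer(*per_dim).reshape(-1)
    return q / q.sum()


class TestGridSpec:
    def test_range_and_bin_count_from_values(self):
        recs = make_records(np.array([[1.0], [5.0], [3.0]]))
        grid = pooled_grid(recs, gs=4)
        assert grid.lo == (1.0,) and grid.hi == (5.0,)
        assert grid.n_bins == 4
        np.testing.assert_allclose(grid.edges(0), [1, 2, 3, 4, 5])

    def test_pooled_range_covers_union_of_conditions(self):
        recs = make_records(np.array([[1.0], [2.0]]), condition="a") + \
            make_records(np.array([[5.0], [9.0]]), condition="b")
        grid = pooled_grid(recs, gs=10)
        assert grid.lo == (1.0,) and grid.hi == (9.0,)

    def test_total_bins_is_gs_to_the_dims(self):
        recs = make_records(np.random.default_rng(0).uniform(1, 2, size=(5, 3)))
        assert pooled_grid(recs, gs=30).n_bins == 27_000

    def test_constant_readout_is_an_error(self):
        recs = make_records(np.array([[1.0, 2.0], [1.0, 3.0]]))
        with pytest.raises(ValueError, match="constant"):
            pooled_grid(recs, gs=5)

    def test_row_major_linearization_of_centers(self):
        grid = GridSpec(gs=2, lo=(0.0, 10.0), hi=(2.0, 14.0))
        np.testing.assert_allclose(
            grid.grid_points(),
            [[0.5, 11], [0.5, 13], [1.5, 11], [1.5, 13]])


class TestAssignGroups:
    def test_even_split_sizes(self):
        recs = make_records(np.arange(10, dtype=float)[:, None])
        labels = assign_groups(recs, k=5, seed=0)
        assert sorted(np.bincount(labels)[1:]) == [2, 2, 2, 2, 2]

    def test_same_seed_same_partition(self):
        recs = make_records(np.arange(23, dtype=float)[:, None])
        np.testing.assert_array_equal(assign_groups(recs, seed=7),
                                      assign_groups(recs, seed=7))

    def test_any_four_fold_union_is_eighty_percent(self):
        recs = make_records(np.arange(50, dtype=float)[:, None])
        labels = assign_groups(recs, k=5, seed=3)
        for g in range(1, 6):
            assert abs(np.sum(labels != g) - 40) <= 1

    def test_stratified_within_condition_cells(self):
        recs = make_records(np.arange(20, dtype=float)[:, None], condition="a") + \
            make_records(np.arange(30, dtype=float)[:, None], condition="b")
        labels = assign_groups(recs, k=5, seed=1)
        for cond, size in (("a", 20), ("b", 30)):
            cell = labels[[i for i, r in enumerate(recs) if r.condition == cond]]
            counts = np.bincount(cell, minlength=6)[1:]
            assert counts.max() - counts.min() <= 1 and counts.sum() == size

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            assign_groups(make_records(np.ones((3, 1)) * [[1], [2], [3]]), k=5)


class TestEstimateDensity:
    def test_single_record_mass_near_the_point_and_normalized(self):
        grid = GridSpec(gs=20, lo=(0.0,), hi=(10.0,))
        recs = make_records(np.array([[4.2]]))
        d = estimate_density(recs, grid, min_records=1)
        assert d.p.sum() == pytest.approx(1.0, abs=1e-12)
        centers = grid.grid_points()[:, 0]
        # bin width is the fallback kernel width; ~all mass within 4 widths
        assert d.p[np.abs(centers - 4.2) < 2.0].sum() > 0.99

    def test_bivariate_normal_matches_analytic_binning(self, rng):
        draws = rng.multivariate_normal([0, 0], np.eye(2), size=2000)
        grid = GridSpec(gs=30, lo=(-4.0, -4.0), hi=(4.0, 4.0))
        d = estimate_density(make_records(draws), grid)
        tv = 0.5 * np.abs(d.p - analytic_binned_normal(grid)).sum()
        assert tv < 0.05

    def test_group_selection_uses_exactly_the_80pc_complement(self):
        vals = np.random.default_rng(5).lognormal(7, 0.3, size=(60, 1))
        recs = make_records(vals)
        grid = GridSpec(gs=15, lo=(vals.min(),), hi=(vals.max(),))
        labels = assign_groups(recs, k=5, seed=11)
        manual = [r for r, lab in zip(recs, labels) if lab != 3]
        assert len(manual) == 48  # 80% of 60
        d_group = estimate_density(recs, grid, group=3, seed=11)
        d_manual = estimate_density(manual, grid, seed=11)
        np.testing.assert_allclose(d_group.p, d_manual.p)

    def test_frac_subsamples_after_group_selection(self):
        vals = np.random.default_rng(6).lognormal(7, 0.3, size=(40, 1))
        recs = make_records(vals)
        grid = GridSpec(gs=10, lo=(vals.min(),), hi=(vals.max(),))
        d1 = estimate_density(recs, grid, frac=0.5, seed=2)
        d2 = estimate_density(recs, grid, frac=0.5, seed=2)
        np.testing.assert_array_equal(d1.p, d2.p)  # seeded, reproducible

    def test_too_few_records_names_the_condition(self):
        grid = GridSpec(gs=5, lo=(0.0, 0.0), hi=(1.0, 1.0))
        recs = make_records(np.array([[0.5, 0.5], [0.6, 0.4]]), condition="2.0e7")
        with pytest.raises(ValueError, match="2.0e7"):
            estimate_density(recs, grid)

    def test_mixed_conditions_rejected(self):
        recs = make_records(np.ones((3, 1)) + np.arange(3)[:, None], condition="a") + \
            make_records(np.ones((3, 1)), condition="b")
        grid = GridSpec(gs=5, lo=(0.0,), hi=(4.0,))
        with pytest.raises(ValueError, match="single"):
            estimate_density(recs, grid)

    @pytest.mark.parametrize("gs", [5, 12])
    def test_every_density_sums_to_one(self, rng, gs):
        vals = rng.lognormal(7, 0.4, size=(50, 2))
        recs = make_records(vals)
        grid = pooled_grid(recs, gs=gs)
        d = estimate_density(recs, grid)
        assert abs(d.p.sum() - 1.0) < 1e-9


class TestDensityFiles:
    def test_filename_convention(self):
        assert density_filename("PDF", "GT123", "2.0e9", 30, 3) == \
            "PDF_GT123_2.0e9_GS30_group3.dat"

    def test_write_read_roundtrip(self, tmp_path, rng):
        vals = rng.lognormal(7, 0.3, size=(30, 2))
        recs = make_records(vals, condition="6.3e8")
        grid = pooled_grid(recs, gs=8)
        d = estimate_density(recs, grid)
        path = write_density(d, tmp_path, "PDF")
        assert path.name == "PDF_N2_6.3e8_GS8_group0.dat"
        back = read_density(path)
        assert back.grid == grid and back.condition == "6.3e8"
        np.testing.assert_allclose(back.p, d.p, rtol=1e-15)

    def test_density_validates_simplex(self):
        grid = GridSpec(gs=4, lo=(0.0,), hi=(1.0,))
        with pytest.raises(ValueError):
            ConditionalDensity(grid=grid, condition="a", genotype="N2", group=0,
                               p=np.array([0.5, -0.1, 0.4, 0.2]))
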