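"""Density calibration: moving windows, classes, thresholds, block bootstrap."""

import numpy as np
import pytest

from burnhab.density import (
    DensityCurve,
    block_bootstrap_density,
    class_summaries,
    classify,
    moving_window_density,
    percent_nests,
    quantile_type8,
    suggest_thresholds,
)


class TestMovingWindow:
    def test_uniform_usage_gives_flat_curve(self, rng):
        ref = rng.random(2000)
        nests = rng.random(300)  # same distribution: no selection
        curve = moving_window_density(nests, ref, total_area_ha=1000.0,
                                      window_frac=0.2, step_frac=0.05)
        expected = 300 / 1000.0
        assert np.all(np.abs(curve.densities - expected) < 3 * expected / np.sqrt(60))

    def test_top_decile_hand_construction(self):
        ref = np.linspace(0.0, 0.99, 100)
        nests = np.full(12, 0.95)  # all above the 90th percentile reference HSI
        curve = moving_window_density(nests, ref, total_area_ha=500.0,
                                      window_frac=0.1, step_frac=0.1)
        assert len(curve.densities) == 10
        np.testing.assert_allclose(curve.densities[:-1], 0.0)
        assert curve.densities[-1] == pytest.approx(12 / (0.1 * 500.0))

    def test_area_scale_equivariance(self, rng):
        ref, nests = rng.random(500), rng.random(50)
        c1 = moving_window_density(nests, ref, 100.0)
        c2 = moving_window_density(nests, ref, 200.0)
        np.testing.assert_allclose(c2.densities, c1.densities / 2.0)

    def test_disjoint_windows_partition_all_nests(self, rng):
        """With step == window the windows tile the HSI axis, so window
        densities integrate back to the total nest count."""
        ref, nests = rng.random(1000), rng.random(137)
        area = 800.0
        curve = moving_window_density(nests, ref, area, window_frac=0.1, step_frac=0.1)
        total = (curve.densities * 0.1 * area).sum()
        assert total == pytest.approx(len(nests))

    def test_invalid_fractions_rejected(self, rng):
        with pytest.raises(ValueError):
            moving_window_density([0.5], rng.random(10), 10.0, window_frac=1.5)
        with pytest.raises(ValueError):
            moving_window_density([0.5], rng.random(10), 10.0, step_frac=0.5)


class TestClassify:
    @pytest.mark.parametrize("hsi, expected", [
        (0.10, 0), (0.34, 1), (0.59, 1), (0.60, 2), (0.99, 2),
    ])
    def test_boundaries_lower_inclusive(self, hsi, expected):
        assert classify(hsi, (0.34, 0.60)) == expected

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            classify(0.5, (0.6, 0.3))


class TestClassSummaries:
    def test_equal_densities_equal_percents(self, rng):
        ref = np.r_[np.full(100, 0.1), np.full(100, 0.5), np.full(100, 0.9)]
        nests = np.r_[np.full(5, 0.1), np.full(5, 0.5), np.full(5, 0.9)]
        s = class_summaries(nests, ref, (0.3, 0.7), 300.0)
        np.testing.assert_allclose(s.percent_nests, 100 / 3, atol=1e-9)

    def test_conservation_invariants(self, rng):
        ref, nests = rng.random(400), rng.random(60)
        area = 1234.5
        s = class_summaries(nests, ref, (0.3, 0.7), area)
        assert s.area_ha.sum() == pytest.approx(area)
        assert (s.density * s.area_ha).sum() == pytest.approx(len(nests))
        # percent invariant to total area
        s2 = class_summaries(nests, ref, (0.3, 0.7), 10 * area)
        np.testing.assert_allclose(s.percent_nests, s2.percent_nests)

    def test_empty_reference_class_flagged(self, rng):
        ref = rng.uniform(0.5, 1.0, 100)  # nothing below t1
        with pytest.warns(UserWarning, match="low"):
            s = class_summaries(rng.uniform(0.5, 1.0, 10), ref, (0.3, 0.7), 100.0)
        assert np.isnan(s.density[0]) and s.area_ha[0] == 0.0

    def test_percent_nests_helper(self):
        np.testing.assert_allclose(percent_nests([0.0, 0.14, 0.73]),
                                   [0.0, 100 * 0.14 / 0.87, 100 * 0.73 / 0.87])


class TestSuggestThresholds:
    def test_step_curve_recovers_jump_locations(self):
        mids = np.linspace(0.05, 0.95, 19)
        dens = np.where(mids < 0.3, 0.1, np.where(mids < 0.7, 0.5, 1.5))
        curve = DensityCurve(mids=mids, densities=dens, window_frac=0.1, step_frac=0.05)
        t1, t2 = suggest_thresholds(curve)
        assert 0.25 < t1 < 0.35
        assert 0.65 < t2 < 0.75

    def test_flat_curve_tertiles_with_warning(self):
        curve = DensityCurve(mids=np.linspace(0.1, 0.9, 9), densities=np.full(9, 0.4),
                             window_frac=0.1, step_frac=0.1)
        with pytest.warns(UserWarning, match="flat"):
            t1, t2 = suggest_thresholds(curve)
        assert t1 == pytest.approx(np.quantile(curve.mids, 1 / 3))
        assert t2 == pytest.approx(np.quantile(curve.mids, 2 / 3))


class TestTypeEightQuantile:
    def test_hand_computed_plotting_positions(self):
        x = np.arange(1, 10)  # {1..9}
        # h = (n + 1/3) p + 1/3; at p=0.5, h=5 -> the 5th order statistic
        assert quantile_type8(x, 0.5) == pytest.approx(5.0)
        # at p=0.25, h = 9.3333*0.25 + 0.3333 = 2.6667 -> 2 + 0.6667*(3-2)
        assert quantile_type8(x, 0.25) == pytest.approx(8 / 3)
        assert quantile_type8(x, 0.975) == pytest.approx(9.0)  # clipped at max


class TestBlockBootstrap:
    def test_single_cell_degenerate(self, rng):
        nests = rng.random(5)
        ref = rng.random(50)
        with pytest.warns(UserWarning, match="single"):
            s = block_bootstrap_density(nests, ["c0"] * 5, ref, ["c0"] * 50,
                                        (0.3, 0.7), 100.0, n_boot=10, seed=0)
        np.testing.assert_allclose(s.density_ci[:, 0], s.density)
        np.testing.assert_allclose(s.density_ci[:, 1], s.density)

    def test_reproducible_and_brackets_point(self, rng):
        n_cells = 40
        nest_cells = rng.integers(0, n_cells, 60).astype(str)
        ref_cells = rng.integers(0, n_cells, 400).astype(str)
        nests, ref = rng.random(60), rng.random(400)
        kw = dict(thresholds=(0.33, 0.66), total_area_ha=500.0, n_boot=300, seed=7)
        s1 = block_bootstrap_density(nests, nest_cells, ref, ref_cells, **kw)
        s2 = block_bootstrap_density(nests, nest_cells, ref, ref_cells, **kw)
        np.testing.assert_array_equal(s1.density_ci, s2.density_ci)
        assert (s1.density_ci[:, 0] <= s1.density + 1e-9).all()
        assert (s1.density_ci[:, 1] >= s1.density - 1e-9).all()

    def test_homogeneous_coverage(self, rng):
        """Cells are exchangeable and usage is uniform: the 95% block-bootstrap
        CI for each class density should cover the truth at roughly nominal
        rate over replicate data sets."""
        hits = trials = 0
        area = 300.0
        for rep in range(30):
            r = np.random.default_rng(rep)
            n_cells = 25
            ref = r.random(250)
            ref_cells = np.repeat(np.arange(n_cells), 10).astype(str)
            nests = r.random(50)
            nest_cells = r.integers(0, n_cells, 50).astype(str)
            s = block_bootstrap_density(nests, nest_cells, ref, ref_cells,
                                        (1 / 3, 2 / 3), area, n_boot=300, seed=rep)
            truth = 50 / area  # uniform usage: same density in every class
            for c in range(3):
                trials += 1
                hits += s.density_ci[c, 0] <= truth <= s.density_ci[c, 1]
        assert hits / trials > 0.80
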