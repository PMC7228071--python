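"""Weighted logistic regression, AICc subset selection, VIF."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from burnhab import wlr


def _dummy_fit(covs, aicc_value, k=None):
    names = ["Intercept"] + list(covs)
    return wlr.WLRFit(
        covariates=tuple(covs), params=pd.Series(0.0, index=names),
        bse=pd.Series(1.0, index=names), llf=0.0, k=k or len(names),
        aicc=aicc_value, n_obs=100,
    )


class TestWeights:
    def test_printed_sample_sizes(self):
        w = wlr.make_weights(33, 134)
        assert w.w1 == 1.0
        assert w.w0 == pytest.approx(33 / 134)
        assert w.w0 == pytest.approx(0.24627, abs=1e-5)

    def test_balanced_and_identity(self):
        assert wlr.make_weights(50, 50).w0 == 1.0
        with pytest.raises(ValueError):
            wlr.make_weights(0, 10)

    @given(n1=st.integers(1, 500), n0=st.integers(1, 500))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_weighted_prevalence_exactly_half(self, n1, n0):
        y = np.r_[np.ones(n1), np.zeros(n0)]
        w = wlr.observation_weights(y)
        assert (w * y).sum() / w.sum() == pytest.approx(0.5, abs=1e-12)
        assert (w * (1 - y)).sum() == pytest.approx(n1)  # weighted zeros sum to n1

    def test_intercept_only_fitted_probability_is_half(self, rng):
        df = pd.DataFrame({"y": np.r_[np.ones(30), np.zeros(170)]})
        fit = wlr.fit_wlr(df, ())
        p = 1 / (1 + np.exp(-fit.params["Intercept"]))
        assert p == pytest.approx(0.5, abs=1e-8)


class TestPooledWeights:
    def test_larger_location_scaled_down(self):
        w = np.r_[np.full(66, 1.0), np.full(94, 1.0)]
        loc = np.r_[["A"] * 66, ["B"] * 94]
        out, scalars = wlr.make_pooled_weights(w, loc)
        assert scalars["B"] == pytest.approx(66 / 94)
        assert out[loc == "A"].sum() == pytest.approx(out[loc == "B"].sum())
        assert out.sum() == pytest.approx(2 * 66)  # twice the smaller sum

    def test_equal_sums_identity(self):
        w = np.ones(20)
        loc = np.r_[["A"] * 10, ["B"] * 10]
        out, scalars = wlr.make_pooled_weights(w, loc)
        np.testing.assert_array_equal(out, w)
        assert set(scalars.values()) == {1.0}

    def test_single_location_warns_identity(self, caplog):
        with caplog.at_level("WARNING"):
            out, _ = wlr.make_pooled_weights(np.ones(5), np.array(["A"] * 5))
        np.testing.assert_array_equal(out, np.ones(5))
        assert "single location" in caplog.text


class TestFit:
    def test_parameter_recovery_large_n(self, rng):
        n = 4000
        x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
        eta = -0.3 + 0.8 * x1 - 0.5 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        fit = wlr.fit_wlr(df, ("x1", "x2"), np.ones(n))
        assert abs(fit.params["x1"] - 0.8) < 2 * fit.bse["x1"]
        assert abs(fit.params["x2"] + 0.5) < 2 * fit.bse["x2"]

    def test_separation_flagged_and_excluded(self, rng):
        x = np.r_[rng.uniform(1, 2, 20), rng.uniform(-2, -1, 20)]
        df = pd.DataFrame({"y": (x > 0).astype(float), "x": x})
        fit = wlr.fit_wlr(df, ("x",))
        assert fit.separated
        ranking = wlr.rank_models([fit, wlr.fit_wlr(df, ())])
        assert ranking.n_excluded == 1
        assert ranking.best.covariates == ()

    def test_singular_design_rejected(self, rng):
        x = rng.standard_normal(50)
        df = pd.DataFrame({"y": (rng.random(50) < 0.5).astype(float),
                           "x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="singular"):
            wlr.fit_wlr(df, ("x", "x2"))


class TestAICc:
    def test_formula_arithmetic(self):
        assert wlr.aicc(-50.0, 3, 100) == pytest.approx(106 + 24 / 96)

    def test_limit_is_aic(self):
        assert wlr.aicc(-10.0, 1, 10**9) == pytest.approx(20 + 2, abs=1e-6)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            wlr.aicc(-10.0, 5, 6)


class TestEnumeration:
    @pytest.mark.parametrize("p, n_nests, expected", [
        (10, 33, 386),  # cap ceil(33/10) = 4
        (10, 47, 638),  # cap 5
        (6, 80, 64),    # cap >= p: all subsets
        (0, 10, 1),     # intercept-only
    ])
    def test_printed_candidate_counts(self, p, n_nests, expected):
        covs = [f"c{i}" for i in range(p)]
        assert len(wlr.enumerate_candidates(covs, n_nests=n_nests)) == expected

    @given(p=st.integers(1, 12), cap=st.integers(0, 12))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_count_matches_binomial_sum(self, p, cap):
        covs = [f"c{i}" for i in range(p)]
        got = len(wlr.enumerate_candidates(covs, cap=cap))
        assert got == sum(math.comb(p, k) for k in range(min(cap, p) + 1))

    def test_order_size_major_lexicographic(self):
        subs = wlr.enumerate_candidates(["a", "b", "c"], cap=2)
        assert subs == [(), ("a",), ("b",), ("c",), ("a", "b"), ("a", "c"), ("b", "c")]


class TestRanking:
    def test_single_model_weight_one(self):
        r = wlr.rank_models([_dummy_fit(["a"], 100.0)])
        assert r.akaike_weights[0] == 1.0
        assert r.delta_aicc[0] == 0.0

    def test_equal_aicc_split_and_delta_two(self):
        r = wlr.rank_models([_dummy_fit(["a"], 100.0), _dummy_fit(["b"], 100.0)])
        np.testing.assert_allclose(r.akaike_weights, [0.5, 0.5])
        r2 = wlr.rank_models([_dummy_fit(["a"], 100.0), _dummy_fit(["b"], 102.0)])
        expected = np.array([1.0, np.exp(-1.0)])
        np.testing.assert_allclose(r2.akaike_weights, expected / expected.sum(), atol=1e-12)
        assert r2.akaike_weights[0] == pytest.approx(0.731, abs=1e-3)

    def test_weights_sum_to_one(self, rng):
        fits = [_dummy_fit([f"c{i}"], 100 + 10 * rng.random()) for i in range(20)]
        r = wlr.rank_models(fits)
        assert r.akaike_weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (r.delta_aicc >= 0).all()


class TestPooledCandidates:
    def _rankings(self):
        toolbox = wlr.rank_models([
            _dummy_fit(["LocBrnOpn", "LandBrnOpn", "TreeDens", "PIPO_pct"], 80.4),
            _dummy_fit(["LocBrnOpn", "LandBrnOpn", "LandPIPO", "TreeDens"], 80.9),
            _dummy_fit(["LocBrnOpn", "LandBrnOpn", "TreeDens"], 81.2),
            _dummy_fit(["LandBrnOpn", "TreeDens", "PIPO_pct"], 81.8),
            _dummy_fit([], 94.4),
        ])
        canyon = wlr.rank_models([
            _dummy_fit(["LandBrnOpn", "TreeDens"], 123.1),
            _dummy_fit(["LandBrnOpn", "TreeDens", "PIPO_pct"], 124.2),
            _dummy_fit(["LocBrnOpn", "LandBrnOpn", "TreeDens"], 124.4),
            _dummy_fit(["LandBrnOpn", "TreeDens", "PIPO"], 125.1),  # delta exactly 2.0
            _dummy_fit([], 132.4),
        ])
        return [toolbox, canyon]

    def test_inclusive_union_gives_six_covariates_and_64_subsets(self):
        covs = wlr.pooled_candidate_covariates(self._rankings(), delta=2.0)
        assert set(covs) == {"LocBrnOpn", "LandBrnOpn", "TreeDens",
                             "PIPO_pct", "LandPIPO", "PIPO"}
        assert len(wlr.enumerate_candidates(covs, n_nests=80)) == 64

    def test_exclusive_threshold_would_drop_boundary_model(self):
        covs = wlr.pooled_candidate_covariates(self._rankings(), delta=1.999)
        assert "PIPO" not in covs and len(covs) == 5

    def test_disjoint_singletons_union(self):
        r1 = wlr.rank_models([_dummy_fit(["a"], 10.0)])
        r2 = wlr.rank_models([_dummy_fit(["b"], 10.0)])
        assert wlr.pooled_candidate_covariates([r1, r2]) == ["a", "b"]


class TestVIF:
    def test_orthogonal_covariates_unit_vif(self):
        n = 64
        t = np.arange(n)
        df = pd.DataFrame({"a": np.cos(2 * np.pi * t / n), "b": np.sin(2 * np.pi * t / n)})
        v = wlr.vif(df, ["a", "b"])
        np.testing.assert_allclose(v, 1.0, atol=1e-10)

    def test_known_r_squared(self):
        n = 200
        rng = np.random.default_rng(5)
        z1 = rng.standard_normal(n)
        z1 = (z1 - z1.mean()) / np.linalg.norm(z1 - z1.mean())
        e = rng.standard_normal(n)
        e = e - e.mean() - (e @ z1) * z1
        e /= np.linalg.norm(e)
        r2 = 0.61
        df = pd.DataFrame({"x1": z1, "x2": np.sqrt(r2) * z1 + np.sqrt(1 - r2) * e})
        v = wlr.vif(df, ["x1", "x2"])
        assert v["x2"] == pytest.approx(1 / (1 - 0.61), abs=1e-6)
        assert v["x2"] == pytest.approx(2.564, abs=1e-3)

    def test_duplicate_covariate_flagged_infinite(self, rng):
        x = rng.standard_normal(50)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(50)})
        v = wlr.vif(df, ["a", "b", "c"])
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_requires_two_covariates(self, rng):
        with pytest.raises(ValueError):
            wlr.vif(pd.DataFrame({"a": rng.standard_normal(10)}), ["a"])
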