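"""Statistical engine: rank tests, ROC, sweeps and logistic models."""

import numpy as np
import pandas as pd
import pytest

from aneukit.exceptions import SeparationError
from aneukit.stats import (
    LogisticModel,
    ThresholdSweepResult,
    fit_logistic,
    group_comparison,
    mann_whitney_u,
    normalize_predictors,
    published_model,
    roc,
    select_polynomial_order,
    significance_stars,
    spearman,
    threshold_sweep,
)
from aneukit.synthetic import DomeSpec, make_dome_mesh, make_sweep_cohort_maps


class TestMannWhitney:
    def test_exact_enumeration_oracle(self):
        """{1,2,3} vs {4,5,6}: U = 0, exact two-tailed p = 2/C(6,3) = 0.1."""
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_degenerate_all_equal(self):
        u, p = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_vs_asymptotic_agreement(self):
        """|p_exact − p_asymptotic| < 0.01 for tie-free n = 10/10 samples."""
        from scipy import stats as sps

        rng = np.random.default_rng(21)
        for _ in range(20):
            x, y = rng.normal(size=10), rng.normal(0.4, 1.0, size=10)
            _, p_mine = mann_whitney_u(x, y)  # exact branch (n ≤ 20)
            p_asym = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(p_mine - p_asym) < 0.01


class TestSpearman:
    def test_monotone_perfect(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(6), np.arange(6.0))

    def test_stars_convention(self):
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == ""


class TestRoc:
    def test_complete_separation(self):
        res = roc([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert 2.0 < res.threshold < 3.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_auc_equals_pairwise_concordance(self):
        """AUC matches brute-force pairwise concordance (ties ½) on 100 sets."""
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = rng.integers(8, 30)
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            conc = np.mean(
                (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
            )
            assert roc(scores, labels).auc == pytest.approx(conc, abs=1e-12)

    def test_cross_check_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        scores = rng.normal(size=200)
        labels = (rng.random(200) < 0.4).astype(int)
        assert roc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=10_000)
        labels = rng.integers(0, 2, size=10_000)
        assert roc(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1.0, 2.0], [1, 1])


class TestNormalization:
    def test_starred_mean_is_one(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        starred, means = normalize_predictors(df, ["a", "b"])
        assert starred["a*"].mean() == pytest.approx(1.0, abs=1e-12)
        assert np.all(starred["b*"] == 1.0)
        assert means == {"a": 2.0, "b": 5.0}

    def test_stored_means_apply_to_new_data(self):
        train = pd.DataFrame({"a": [1.0, 3.0]})
        _, means = normalize_predictors(train, ["a"])
        new = pd.DataFrame({"a": [4.0]})
        starred, _ = normalize_predictors(new, ["a"], means=means)
        assert starred["a*"].iloc[0] == pytest.approx(2.0)  # 4 / train mean 2

    def test_nonpositive_mean_rejected(self):
        df = pd.DataFrame({"a": [-1.0, -2.0]})
        with pytest.raises(ValueError):
            normalize_predictors(df, ["a"])


class TestLogistic:
    def test_null_slope_small(self):
        rng = np.random.default_rng(13)
        n = 400
        df = pd.DataFrame(
            {"x": rng.lognormal(size=n), "ruptured": rng.integers(0, 2, n)}
        )
        model = fit_logistic(df, {"x": 1})
        assert abs(model.coef_[1]) < 0.5

    def test_separation_raises(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
                           "ruptured": [0, 0, 0, 1, 1, 1]})
        with pytest.raises(SeparationError):
            with pytest.warns(UserWarning):  # EPV < 5 on the toy data
                fit_logistic(df, {"x": 1})

    def test_epv_warning(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(
            {"x": rng.lognormal(size=12), "ruptured": [0, 1] * 6}
        )
        with pytest.warns(UserWarning, match="events per variable"):
            fit_logistic(df, {"x": 2})

    def test_model_roundtrip_through_file(self, tmp_path):
        rng = np.random.default_rng(15)
        n = 300
        x = rng.lognormal(size=n)
        p = 1 / (1 + np.exp(-(x - 1.0)))
        df = pd.DataFrame({"x": x, "ruptured": (rng.random(n) < p).astype(int)})
        model = fit_logistic(df, {"x": 2})
        path = tmp_path / "model.txt"
        model.save(path)
        back = LogisticModel.load(path)
        np.testing.assert_allclose(back.coef_, model.coef_)
        np.testing.assert_allclose(
            back.predict_proba(df), model.predict_proba(df), rtol=1e-12
        )

    def test_sklearn_style_params(self):
        model = LogisticModel(["a", "b"], {"a": 2, "b": 1})
        params = model.get_params()
        assert params["orders"] == {"a": 2, "b": 1}


class TestOrderSelection:
    def test_quadratic_boundary_selects_high_order(self):
        """Data separable in x² (not in x) needs an even polynomial."""
        rng = np.random.default_rng(16)
        n = 400
        x = rng.lognormal(sigma=0.6, size=n)
        eta = 4.0 - 8.0 * (x - 1.2) ** 2  # band around x = 1.2 ruptures
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame({"x": x, "ruptured": y})
        assert select_polynomial_order(df, "x", max_order=3) >= 2

    def test_monotone_logit_mostly_selects_linear(self):
        """A linear logit keeps order 1 in most replicates at n = 200."""
        rng = np.random.default_rng(17)
        wins = 0
        n_seeds = 20
        for _ in range(n_seeds):
            x = rng.lognormal(sigma=0.5, size=200)
            y = (rng.random(200) < 1 / (1 + np.exp(-(2.0 * (x - 1.0))))).astype(int)
            df = pd.DataFrame({"x": x, "ruptured": y})
            try:
                wins += select_polynomial_order(df, "x", max_order=3) == 1
            except SeparationError:
                pass
        assert wins >= 0.7 * n_seeds

    def test_max_order_one(self):
        rng = np.random.default_rng(18)
        df = pd.DataFrame(
            {"x": rng.lognormal(size=100), "ruptured": rng.integers(0, 2, 100)}
        )
        assert select_polynomial_order(df, "x", max_order=1) == 1


class TestPublishedModels:
    def test_worked_example_model_one(self):
        """All-ones starred inputs: exponent 1.373, odds 3.947, p 0.798."""
        m = published_model("maxWSSG-NSI-AR")
        ones = pd.DataFrame({"maxWSSG*": [1.0], "NSI*": [1.0], "AR*": [1.0]})
        assert m.decision_function(ones)[0] == pytest.approx(1.373, abs=1e-9)
        assert m.predict_odds(ones)[0] == pytest.approx(3.947, abs=1e-3)
        assert m.predict_proba(ones)[0] == pytest.approx(0.798, abs=1e-3)

    def test_worked_example_model_two(self):
        m = published_model("AHG-NSI-AR")
        ones = pd.DataFrame({"AHG*": [1.0], "NSI*": [1.0], "AR*": [1.0]})
        assert m.decision_function(ones)[0] == pytest.approx(1.646, abs=1e-9)
        assert m.predict_proba(ones)[0] == pytest.approx(0.838, abs=1e-3)

    def test_monotone_in_nsi(self):
        m = published_model("maxWSSG-NSI-AR")
        hi = pd.DataFrame({"maxWSSG*": [1.0], "NSI*": [1.0], "AR*": [1.0]})
        lo = pd.DataFrame({"maxWSSG*": [1.0], "NSI*": [1e-6], "AR*": [1.0]})
        assert m.predict_proba(lo)[0] < m.predict_proba(hi)[0]

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            published_model("nope")

    def test_probability_stays_in_unit_interval(self):
        m = published_model("maxWSSG-NSI-AR")
        rng = np.random.default_rng(19)
        df = pd.DataFrame(
            {
                "maxWSSG*": rng.lognormal(sigma=0.5, size=500),
                "NSI*": rng.lognormal(sigma=0.3, size=500),
                "AR*": rng.lognormal(sigma=0.3, size=500),
            }
        )
        p = m.predict_proba(df)
        assert np.all((p > 0) & (p < 1))


@pytest.fixture(scope="module")
def sweep_mesh():
    mesh, _ = make_dome_mesh(DomeSpec(cap_radius=2e-3, mesh_edge_length=3e-4, seed=0))
    return mesh


class TestThresholdSweep:
    def test_single_grid_point_reduces_to_one_test(self, sweep_mesh):
        labels = np.array([1] * 6 + [0] * 6)
        maps = make_sweep_cohort_maps(sweep_mesh, labels, seed=1)
        t0 = 5e4
        res = threshold_sweep(
            sweep_mesh, maps, labels, "above", grid=np.array([t0])
        )
        areas = np.array(
            [
                sweep_mesh.face_areas[m[sweep_mesh.faces].mean(axis=1) > t0].sum()
                for m in maps
            ]
        )
        _, p_direct = mann_whitney_u(areas[labels == 1], areas[labels == 0])
        assert res.p_area[0] == pytest.approx(p_direct)
        assert res.optimal_threshold == t0

    def test_out_of_range_grid_degenerate(self, sweep_mesh):
        labels = np.array([1] * 4 + [0] * 4)
        maps = make_sweep_cohort_maps(sweep_mesh, labels, seed=2)
        hi = max(m.max() for m in maps) * 10
        with pytest.warns(UserWarning, match="degenerate"):
            res = threshold_sweep(
                sweep_mesh, maps, labels, "above", grid=np.array([hi, hi * 2])
            )
        assert np.all(res.p_area == 1.0)

    def test_planted_band_recovered(self, sweep_mesh):
        band = (4e4, 6e4)
        labels = np.array([1] * 20 + [0] * 20)
        for seed in range(5):
            maps = make_sweep_cohort_maps(sweep_mesh, labels, band=band, seed=seed)
            res = threshold_sweep(sweep_mesh, maps, labels, "above", n_grid=200)
            assert band[0] <= res.optimal_threshold <= band[1]
            assert res.min_p < 0.05

    def test_result_frame_layout(self, sweep_mesh):
        labels = np.array([1] * 4 + [0] * 4)
        maps = make_sweep_cohort_maps(sweep_mesh, labels, seed=3)
        res = threshold_sweep(sweep_mesh, maps, labels, "above", n_grid=50)
        df = res.to_frame()
        assert list(df.columns) == ["threshold", "p_area", "p_ratio"]
        assert len(df) == 50
        assert isinstance(res, ThresholdSweepResult)


class TestGroupComparison:
    def test_stars_and_layout(self):
        rng = np.random.default_rng(23)
        df = pd.DataFrame(
            {
                "shifted": np.concatenate([rng.normal(3, 1, 20), rng.normal(0, 1, 20)]),
                "same": rng.normal(size=40),
                "ruptured": [1] * 20 + [0] * 20,
            }
        )
        table = group_comparison(df)
        row = table.set_index("parameter")
        assert row.loc["shifted", "stars"] == "**"
        assert row.loc["same", "p_value"] > 0.05
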