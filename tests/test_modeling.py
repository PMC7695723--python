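import numpy as np
import pandas as pd
import pytest

from dce_response import (
    CohortSpec,
    ModelSpec,
    bootstrap_auc_ci,
    compare_auc,
    cv_auc,
    fit_logistic,
    generate_cohort,
    lr_test,
    optimize_model,
)
from dce_response.modeling import FoldPredictions, _auc_rows

from conftest import pair_count_auc


def _binary_table(n00, n01, n10, n11):
    """Table with binary predictor x and outcome pcr with given counts
    n_xy (x then y)."""
    x = [0] * (n00 + n01) + [1] * (n10 + n11)
    y = [0] * n00 + [1] * n01 + [0] * n10 + [1] * n11
    return pd.DataFrame({"x": x, "pcr": y})


class TestFitLogistic:
    def test_single_binary_predictor_recovers_log_odds_ratio(self):
        tab = _binary_table(30, 10, 12, 28)
        fit = fit_logistic(tab, ["x"])
        odds_ratio = (28 * 30) / (12 * 10)
        assert fit.params[1] == pytest.approx(np.log(odds_ratio), abs=1e-5)
        assert fit.params[0] == pytest.approx(np.log(10 / 30), abs=1e-5)
        assert fit.converged and not fit.separation and not fit.rank_deficient

    def test_null_effect_coefficients_near_zero(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(
            {"x": rng.normal(size=5000), "pcr": rng.integers(0, 2, 5000)}
        )
        fit = fit_logistic(tab, ["x"])
        assert abs(fit.params[1]) < 0.1

    def test_duplicated_column_flags_rank_deficiency(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({"x": rng.normal(size=100)})
        tab["x2"] = tab["x"]
        tab["pcr"] = (tab["x"] + rng.normal(size=100) > 0).astype(int)
        fit = fit_logistic(tab, ["x", "x2"])
        assert fit.rank_deficient

    def test_complete_separation_flagged(self):
        tab = pd.DataFrame({"x": np.arange(20.0), "pcr": (np.arange(20) >= 10).astype(int)})
        fit = fit_logistic(tab, ["x"])
        assert fit.separation

    def test_missing_values_rejected(self):
        tab = pd.DataFrame({"x": [1.0, np.nan], "pcr": [0, 1]})
        with pytest.raises(ValueError, match="missing"):
            fit_logistic(tab, ["x"])


class TestLrTest:
    def test_dropping_redundant_duplicate_gives_p_one(self):
        rng = np.random.default_rng(2)
        tab = pd.DataFrame({"x": rng.normal(size=200)})
        tab["x2"] = tab["x"]
        tab["pcr"] = (tab["x"] + rng.normal(size=200) > 0).astype(int)
        assert lr_test(tab, ["x", "x2"], "x2") == pytest.approx(1.0, abs=1e-4)

    def test_non_nested_rejected(self):
        tab = _binary_table(10, 10, 10, 10)
        with pytest.raises(ValueError, match="nested"):
            lr_test(tab, ["x"], "y")

    def test_null_p_values_approximately_uniform(self):
        """Under H0 (tested variable independent of outcome) LR p-values
        are U(0,1); checked with a KS test over 200 simulations."""
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            tab = pd.DataFrame(
                {
                    "x": rng.normal(size=120),
                    "z": rng.normal(size=120),
                    "pcr": rng.integers(0, 2, 120),
                }
            )
            pvals.append(lr_test(tab, ["x", "z"], "z"))
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 1e-3

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        y = (x * 1.5 + rng.normal(size=300) > 0).astype(int)
        tab = pd.DataFrame({"x": x, "pcr": y})
        assert lr_test(tab, ["x"], "x") < 1e-6


class TestCvAuc:
    def test_pooled_auc_equals_pair_counting_oracle(self):
        """Out-of-fold pooled AUC must equal brute-force concordant-pair
        counting on the same scores — fixed tiny table, 2 folds."""
        tab = pd.DataFrame(
            {
                "x": [0.1, 0.9, 0.3, 0.8, 0.2, 0.7, 0.4, 0.6],
                "pcr": [0, 1, 0, 1, 0, 1, 0, 1],
            }
        )
        auc, preds = cv_auc(tab, ["x"], repeats=3, folds=2, seed=5)
        oracle = np.mean(
            [pair_count_auc(s, preds.labels) for s in preds.scores]
        )
        assert auc == pytest.approx(oracle, abs=1e-12)

    def test_perfect_separator_scores_one(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.uniform(0, 0.4, 40), rng.uniform(0.6, 1.0, 40)])
        tab = pd.DataFrame({"x": x, "pcr": np.repeat([0, 1], 40)})
        auc, _ = cv_auc(tab, ["x"], repeats=2, folds=5, seed=7)
        assert auc == pytest.approx(1.0)

    def test_pure_noise_near_half(self):
        rng = np.random.default_rng(8)
        tab = pd.DataFrame(
            {"x": rng.normal(size=2000), "pcr": rng.integers(0, 2, 2000)}
        )
        auc, _ = cv_auc(tab, ["x"], repeats=3, folds=5, seed=9)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_too_small_minority_class_rejected(self):
        tab = pd.DataFrame({"x": np.arange(10.0), "pcr": [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]})
        with pytest.raises(ValueError, match="minority class"):
            cv_auc(tab, ["x"], repeats=1, folds=5)


def test_auc_rows_matches_pair_counting_on_random_instances():
    """The vectorized rank-based AUC (ties counted half) agrees with the
    all-pairs oracle on every random small instance, including ties."""
    rng = np.random.default_rng(10)
    for _ in range(30):
        n = rng.integers(4, 15)
        scores = rng.integers(0, 4, n).astype(float)  # heavy ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            continue
        got = _auc_rows(scores[None, :], labels[None, :])[0]
        assert got == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)


class TestBootstrapCi:
    def _preds(self, scores, labels):
        return FoldPredictions(
            scores=np.asarray(scores, dtype=float)[None, :],
            labels=np.asarray(labels, dtype=int),
        )

    def test_degenerate_perfect_classifier_collapses_at_one(self):
        preds = self._preds(
            np.concatenate([np.zeros(10), np.ones(10)]), np.repeat([0, 1], 10)
        )
        lo, hi = bootstrap_auc_ci(preds, n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_availability_rule(self):
        rng = np.random.default_rng(11)
        scores = rng.uniform(size=30)
        ok = self._preds(scores, np.array([1] * 10 + [0] * 20))
        assert bootstrap_auc_ci(ok, n_boot=100, seed=0) is not None
        few = self._preds(scores, np.array([1] * 4 + [0] * 26))
        assert bootstrap_auc_ci(few, n_boot=100, seed=0) is None

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(12)
        labels = np.array([1] * 40 + [0] * 60)
        scores = np.where(labels == 1, rng.normal(1, 1, 100), rng.normal(0, 1, 100))
        preds = self._preds(scores, labels)
        lo, hi = bootstrap_auc_ci(preds, n_boot=500, seed=3)
        auc = pair_count_auc(scores, labels)
        assert lo <= auc <= hi


class TestCompareAuc:
    def _paired(self, n=200, gap=0.0, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        good = np.where(labels == 1, rng.normal(1.2 + gap, 1, n), rng.normal(0, 1, n))
        base = np.where(labels == 1, rng.normal(1.2, 1, n), rng.normal(0, 1, n))
        a = FoldPredictions(scores=good[None, :], labels=labels)
        b = FoldPredictions(scores=base[None, :], labels=labels)
        return a, b

    def test_self_comparison_p_is_one(self):
        a, _ = self._paired()
        assert compare_auc(a, a, n_boot=500, seed=1) == 1.0

    def test_unpaired_inputs_rejected(self):
        a, _ = self._paired(n=100)
        b, _ = self._paired(n=60)
        with pytest.raises(ValueError, match="paired"):
            compare_auc(a, b)

    def test_true_gap_detected(self):
        a, b = self._paired(n=500, gap=1.6, seed=2)
        assert compare_auc(a, b, n_boot=1000, seed=3) < 0.05

    def test_null_p_not_extreme(self):
        # identical generating process: p should rarely be tiny
        ps = []
        for s in range(10):
            a, b = self._paired(n=300, gap=0.0, seed=100 + s)
            ps.append(compare_auc(a, b, n_boot=400, seed=s))
        assert np.mean(np.array(ps) < 0.05) <= 0.2


class TestOptimizeModel:
    def _cohort(self, effects, n=400, seed=0):
        return generate_cohort(CohortSpec(n=n, seed=seed, feature_effects=effects))

    def test_single_signal_variable_selected(self):
        tab = self._cohort({"ftv_pct_t3": 2.0}, n=600, seed=20)
        spec = ModelSpec(
            candidate_variables=("ftv_t0", "ftv_pct_t1", "ftv_pct_t2", "ftv_pct_t3"),
            include_subtype_covariate=False,
            cv_repeats=5,
            seed=21,
        )
        res = optimize_model(spec, tab)
        assert "ftv_pct_t3" in res.selected_variables
        assert res.search == "exhaustive"
        assert res.cv_auc > 0.7

    def test_all_noise_selection_stays_at_permutation_null(self):
        """Selecting over pure-noise candidates must not manufacture
        signal: the optimized CV-AUC stays inside the band spanned by
        outcome-permuted reruns (no leakage optimism)."""
        tab = self._cohort({}, n=300, seed=22)
        cands = ("ftv_t0", "ftv_pct_t1", "ftv_pct_t2", "ftv_pct_t3")
        spec = ModelSpec(
            candidate_variables=cands,
            include_subtype_covariate=False,
            cv_repeats=3,
            seed=23,
        )
        observed = optimize_model(spec, tab).cv_auc
        perm_aucs = []
        rng = np.random.default_rng(24)
        for k in range(4):
            shuffled = tab.copy()
            shuffled["pcr"] = rng.permutation(shuffled["pcr"].to_numpy())
            perm_spec = ModelSpec(
                candidate_variables=cands,
                include_subtype_covariate=False,
                cv_repeats=3,
                seed=25 + k,
            )
            perm_aucs.append(optimize_model(perm_spec, shuffled).cv_auc)
        assert observed <= max(perm_aucs) + 0.03
        assert abs(observed - 0.5) < 0.1

    def test_deterministic_given_seed(self):
        tab = self._cohort({"bpe_pct_t2": 1.5}, n=200, seed=26)
        spec = ModelSpec(
            candidate_variables=("bpe_t0", "bpe_pct_t1", "bpe_pct_t2", "bpe_pct_t3"),
            include_subtype_covariate=False,
            cv_repeats=3,
            seed=27,
        )
        r1 = optimize_model(spec, tab)
        r2 = optimize_model(spec, tab)
        assert r1.selected_variables == r2.selected_variables
        assert r1.cv_auc == r2.cv_auc
        assert np.array_equal(r1.fold_predictions.scores, r2.fold_predictions.scores)

    def test_small_stratum_rejected_with_message(self):
        tab = self._cohort({}, n=40, seed=28)
        tab = tab[tab["subtype"] == "HR-/HER2+"]
        spec = ModelSpec(
            candidate_variables=("ftv_t0",),
            stratum="HR-/HER2+",
            cv_repeats=2,
        )
        with pytest.raises(ValueError, match="minority class|no patients"):
            optimize_model(spec, tab)

    def test_subtype_covariate_forced_in_full_cohort(self):
        tab = self._cohort({"ftv_pct_t3": 1.0}, n=300, seed=29)
        spec = ModelSpec(
            candidate_variables=("ftv_t0", "ftv_pct_t3"),
            stratum="full",
            cv_repeats=2,
            seed=30,
        )
        res = optimize_model(spec, tab)
        assert len(res.forced_covariates) == 3  # 4 subtypes, reference-coded
        assert all(c.startswith("subtype_") for c in res.forced_covariates)
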