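import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dce_response import (
    CohortSpec,
    build_cohort,
    compare_cohorts,
    generate_cohort,
    percent_change,
    records_from_cohort,
)
from dce_response.cohort import _fisher_rxc_montecarlo


class TestPercentChange:
    @pytest.mark.parametrize(
        "baseline,later,expected",
        [(10.0, 5.0, -50.0), (2.0, 2.0, 0.0), (4.0, 6.0, 50.0)],
    )
    def test_examples(self, baseline, later, expected):
        assert percent_change(baseline, later) == pytest.approx(expected)

    def test_zero_or_missing_baseline_is_missing(self):
        assert math.isnan(percent_change(0.0, 5.0))
        assert math.isnan(percent_change(float("nan"), 5.0))
        assert math.isnan(percent_change(3.0, float("nan")))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        b=st.floats(min_value=1e-3, max_value=1e6),
        k=st.floats(min_value=0.0, max_value=100.0),
    )
    def test_multiplicative_identity(self, b, k):
        # percent_change(b, b*k) = 100 (k - 1) exactly, for any baseline
        assert percent_change(b, b * k) == pytest.approx(100.0 * (k - 1.0), abs=1e-6)


def _records(patients):
    """Helper building a long record table; patients is a dict
    pid -> {(feat, tp): value} with defaults filled in."""
    rows = []
    for pid, overrides in patients.items():
        for tp in ("T0", "T1", "T2", "T3"):
            if overrides.get(("drop", tp)):
                continue
            row = {"patient_id": pid, "timepoint": tp}
            for feat, col in [("ftv", "ftv_cm3"), ("ld", "ld_cm"), ("sph", "sph"), ("bpe", "bpe_pct")]:
                row[col] = overrides.get((feat, tp), 2.0)
            rows.append(row)
    return pd.DataFrame(rows)


def _clinical(pids, pcr=0):
    return pd.DataFrame(
        {
            "patient_id": list(pids),
            "hr_status": "+",
            "her2_status": "-",
            "pcr": pcr,
        }
    )


class TestBuildCohort:
    def test_missing_bpe_excludes_one_patient(self):
        recs = _records(
            {f"P{i}": {} for i in range(4)}
            | {"P4": {("bpe", "T2"): float("nan")}}
        )
        cohort = build_cohort(recs, _clinical([f"P{i}" for i in range(5)]))
        assert cohort.n_included == 4
        assert cohort.exclusion_counts["bpe_undefined"] == 1
        excl = cohort.data[~cohort.data["included"]]
        assert list(excl["patient_id"]) == ["P4"]

    def test_all_complete_nothing_excluded(self):
        recs = _records({f"P{i}": {} for i in range(5)})
        cohort = build_cohort(recs, _clinical([f"P{i}" for i in range(5)]))
        assert cohort.n_included == 5
        assert sum(cohort.exclusion_counts.values()) == 0

    def test_exclusion_precedence_and_accounting(self):
        recs = _records(
            {
                "A": {},
                "B": {("drop", "T1"): True},  # missing exam
                "C": {("sph", "T3"): float("nan")},
                "D": {("ftv", "T0"): 0.0},  # zero baseline -> pct missing
                "E": {("drop", "T2"): True, ("sph", "T0"): float("nan")},
            }
        )
        clin = _clinical(list("ABCDE"))
        clin.loc[clin.patient_id == "A", "pcr"] = np.nan
        cohort = build_cohort(recs, clin)
        reasons = dict(zip(cohort.data.patient_id, cohort.data.exclusion_reason))
        assert reasons["A"] == "missing_outcome"
        assert reasons["B"] == "missing_exam"
        assert reasons["C"] == "sph_undefined"
        assert reasons["D"] == "missing_feature"
        assert reasons["E"] == "missing_exam"  # precedence: exam > feature
        assert cohort.n_included + sum(cohort.exclusion_counts.values()) == 5

    def test_duplicate_records_rejected(self):
        recs = _records({"P0": {}})
        dup = pd.concat([recs, recs.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            build_cohort(dup, _clinical(["P0"]))

    def test_variables_equal_hand_computed_percent_changes(self):
        recs = _records(
            {
                "P0": {
                    ("ftv", "T0"): 10.0,
                    ("ftv", "T1"): 5.0,
                    ("ftv", "T2"): 2.0,
                    ("ftv", "T3"): 1.0,
                    ("bpe", "T0"): 40.0,
                    ("bpe", "T3"): 30.0,
                }
            }
        )
        cohort = build_cohort(recs, _clinical(["P0"]))
        row = cohort.included_data.iloc[0]
        assert row["ftv_t0"] == 10.0
        assert row["ftv_pct_t1"] == pytest.approx(-50.0)
        assert row["ftv_pct_t2"] == pytest.approx(-80.0)
        assert row["ftv_pct_t3"] == pytest.approx(-90.0)
        assert row["bpe_pct_t3"] == pytest.approx(-25.0)

    def test_generator_roundtrip_preserves_variables(self):
        """Splitting a generated cohort into records + clinical and
        rebuilding it must reproduce the generator's variables."""
        tab = generate_cohort(CohortSpec(n=40, seed=13))
        recs, clin = records_from_cohort(tab)
        cohort = build_cohort(recs, clin)
        assert cohort.n_included == 40
        merged = cohort.included_data.set_index("patient_id")
        orig = tab.set_index("patient_id")
        for var in ("ftv_pct_t3", "sph_t0", "bpe_pct_t1", "ld_pct_t2"):
            assert np.allclose(merged[var], orig.loc[merged.index, var])

    def test_accounting_identity_under_random_missingness(self):
        tab = generate_cohort(CohortSpec(n=150, missing_rate=0.05, seed=5))
        recs, clin = records_from_cohort(tab)
        cohort = build_cohort(recs, clin)
        assert cohort.n_included + sum(cohort.exclusion_counts.values()) == 150
        assert (
            (~cohort.data["included"]).sum() == sum(cohort.exclusion_counts.values())
        )


def _enumerate_fisher_2x2(table) -> float:
    """Exhaustive hypergeometric two-sided Fisher p for a 2x2 table."""
    from math import comb

    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / denom

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
        if prob(x) <= p_obs + 1e-12
    )


class TestCompareCohorts:
    def test_table_compared_with_itself(self):
        tab = generate_cohort(CohortSpec(n=120, seed=2)).assign(age=50.0)
        tab["age"] = np.random.default_rng(0).normal(50, 8, len(tab))
        p = compare_cohorts(tab, tab)
        assert p["age"] > 0.99
        assert p["subtype"] == pytest.approx(1.0, abs=0.01)
        assert p["treatment_arm"] == 1.0

    def test_disjoint_age_distributions(self):
        a = generate_cohort(CohortSpec(n=100, seed=3)).assign(age=30.0)
        b = generate_cohort(CohortSpec(n=100, seed=4)).assign(age=70.0)
        a["age"] += np.arange(100) * 0.01
        b["age"] += np.arange(100) * 0.01
        p = compare_cohorts(a, b)
        assert p["age"] < 1e-10

    def test_fisher_2x2_matches_enumeration_oracle(self):
        a = pd.DataFrame({"treatment_arm": ["experimental"] * 30 + ["control"] * 10})
        b = pd.DataFrame({"treatment_arm": ["experimental"] * 18 + ["control"] * 22})
        p = compare_cohorts(
            a, b, continuous=(), categorical=("treatment_arm",)
        )["treatment_arm"]
        table = [[10, 30], [22, 18]]
        assert p == pytest.approx(_enumerate_fisher_2x2(table), abs=1e-9)

    def test_rxc_montecarlo_calibrates_against_scipy_on_2x2(self):
        # the Monte-Carlo path should approximate the exact 2x2 answer
        table = np.array([[12, 28], [25, 15]])
        from scipy.stats import fisher_exact

        p_mc = _fisher_rxc_montecarlo(table, n_sim=40000, seed=1)
        assert p_mc == pytest.approx(fisher_exact(table)[1], abs=0.02)

    def test_absent_characteristic_skipped_with_warning(self):
        a = pd.DataFrame({"age": [1.0, 2.0, 3.0]})
        b = pd.DataFrame({"other": [1, 2, 3]})
        with pytest.warns(UserWarning, match="skipped"):
            p = compare_cohorts(a, b, continuous=("age",), categorical=())
        assert p == {}
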