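"""Longitudinal feature tables, model variables and exclusion accounting.

Each patient contributes four serial MRI exams (T0 pre-treatment, T1
early-, T2 mid-, T3 post-treatment), each measured for four features:
functional tumor volume (FTV, cm³), longest diameter (LD, cm, a
radiologist-reported input), sphericity (SPH, unitless) and contralateral
background parenchymal enhancement (BPE, %).  The modeling variables are
each feature's baseline value plus its percent change from baseline at
T1, T2 and T3 — 16 variables in all.  Analysis is restricted to patients
with all four features available at all timepoints; everyone else is
excluded with a single first-applicable reason, and the accounting
(included + per-reason exclusions = input patients) is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import FEATURES, SUBTYPES, TIMEPOINTS, VARIABLES, variable_name

__all__ = [
    "percent_change",
    "CohortTable",
    "build_cohort",
    "records_from_cohort",
    "compare_cohorts",
    "EXCLUSION_REASONS",
]

FEATURE_COLUMNS = {"ftv": "ftv_cm3", "ld": "ld_cm", "sph": "sph", "bpe": "bpe_pct"}

#: first-applicable exclusion precedence
EXCLUSION_REASONS = (
    "missing_outcome",
    "missing_exam",
    "sph_undefined",
    "bpe_undefined",
    "missing_feature",
)


def percent_change(baseline: float, later: float) -> float:
    """Percent change from baseline: ``(later - baseline)/baseline * 100``.

    Missing (NaN) when either input is missing or the baseline is zero —
    a zero-baseline trend is undefined, mirroring the exclusion of
    incomplete data rather than raising.
    """
    if baseline is None or later is None:
        return float("nan")
    baseline = float(baseline)
    later = float(later)
    if not np.isfinite(baseline) or not np.isfinite(later) or baseline == 0:
        return float("nan")
    return (later - baseline) / baseline * 100.0


@dataclass
class CohortTable:
    """Assembled per-patient analysis table with exclusion accounting.

    ``data`` holds one row per patient: clinical fields, the 16 model
    variables, ``included`` and ``exclusion_reason``.  ``included_data``
    is the analysis subset (all 16 variables non-missing by
    construction).
    """

    data: pd.DataFrame
    exclusion_counts: dict[str, int] = field(default_factory=dict)

    @property
    def included_data(self) -> pd.DataFrame:
        return self.data[self.data["included"]].reset_index(drop=True)

    @property
    def n_included(self) -> int:
        return int(self.data["included"].sum())


def build_cohort(records: pd.DataFrame, clinical: pd.DataFrame) -> CohortTable:
    """Assemble the analysis table from long feature records and clinical data.

    ``records`` needs columns patient_id, timepoint, ftv_cm3, ld_cm, sph,
    bpe_pct (values may be NaN); ``clinical`` needs patient_id, pcr and
    the subtype fields (hr_status/her2_status or subtype).  Patients are
    excluded with the first applicable reason in precedence order:
    missing outcome, missing exam (absent timepoint row), undefined SPH,
    undefined/QC-excluded BPE, then any other missing feature value.
    """
    if records.duplicated(subset=["patient_id", "timepoint"]).any():
        dupes = records[records.duplicated(subset=["patient_id", "timepoint"])]
        raise ValueError(
            f"duplicate (patient, timepoint) records: {dupes['patient_id'].tolist()}"
        )
    clin = clinical.set_index("patient_id")
    missing_clin = set(records["patient_id"]) - set(clin.index)
    if missing_clin:
        raise ValueError(f"clinical data missing for patients: {sorted(missing_clin)}")
    if "subtype" not in clin.columns:
        clin = clin.assign(
            subtype="HR"
            + clin["hr_status"].astype(str)
            + "/HER2"
            + clin["her2_status"].astype(str)
        )

    rows = []
    counts = {r: 0 for r in EXCLUSION_REASONS}
    for pid, grp in records.groupby("patient_id", sort=True):
        grp = grp.set_index("timepoint")
        c = clin.loc[pid]
        row: dict = {
            "patient_id": pid,
            "subtype": c["subtype"],
            "pcr": c["pcr"],
            "treatment_arm": c.get("treatment_arm", ""),
        }
        for extra in ("age", "hr_status", "her2_status"):
            if extra in clin.columns:
                row[extra] = c[extra]

        reason = None
        if pd.isna(c["pcr"]):
            reason = "missing_outcome"
        elif any(tp not in grp.index for tp in TIMEPOINTS):
            reason = "missing_exam"

        values: dict[str, float] = {}
        for feat in FEATURES:
            col = FEATURE_COLUMNS[feat]
            for tp in TIMEPOINTS:
                v = grp.loc[tp, col] if tp in grp.index else float("nan")
                values[(feat, tp)] = float(v) if pd.notna(v) else float("nan")
        for feat in FEATURES:
            row[variable_name(feat, "T0")] = values[(feat, "T0")]
            for tp in TIMEPOINTS[1:]:
                row[variable_name(feat, tp)] = percent_change(
                    values[(feat, "T0")], values[(feat, tp)]
                )
        if reason is None:
            if any(np.isnan(values[("sph", tp)]) for tp in TIMEPOINTS):
                reason = "sph_undefined"
            elif any(np.isnan(values[("bpe", tp)]) for tp in TIMEPOINTS):
                reason = "bpe_undefined"
            elif any(not np.isfinite(row[v]) for v in VARIABLES):
                reason = "missing_feature"

        row["included"] = reason is None
        row["exclusion_reason"] = reason or ""
        if reason:
            counts[reason] += 1
        rows.append(row)

    data = pd.DataFrame(rows)
    data["pcr"] = pd.to_numeric(data["pcr"], errors="coerce")
    return CohortTable(data=data, exclusion_counts=counts)


def records_from_cohort(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a generated wide cohort table into long feature records and a
    clinical table, the inputs :func:`build_cohort` consumes."""
    recs = []
    for _, r in cohort.iterrows():
        for tp in TIMEPOINTS:
            recs.append(
                {
                    "patient_id": r["patient_id"],
                    "timepoint": tp,
                    "ftv_cm3": r[f"ftv_{tp}"],
                    "ld_cm": r[f"ld_{tp}"],
                    "sph": r[f"sph_{tp}"],
                    "bpe_pct": r[f"bpe_{tp}"],
                }
            )
    clinical_cols = [
        c
        for c in ("patient_id", "subtype", "hr_status", "her2_status", "pcr", "treatment_arm", "age")
        if c in cohort.columns
    ]
    return pd.DataFrame(recs), cohort[clinical_cols].copy()


def _fisher_rxc_montecarlo(
    table: np.ndarray, n_sim: int = 20000, seed: int = 0
) -> float:
    """Monte-Carlo Fisher exact test for an R×C contingency table.

    Simulates tables with the observed margins (via permutation of the
    category labels) and compares hypergeometric table probabilities,
    the standard simulated-p-value construction for tables too large to
    enumerate.
    """
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))

    def log_prob(t: np.ndarray) -> float:
        from scipy.special import gammaln

        return float(
            gammaln(t.sum(axis=1) + 1).sum()
            + gammaln(t.sum(axis=0) + 1).sum()
            - gammaln(t.sum() + 1)
            - gammaln(t + 1).sum()
        )

    obs = log_prob(table)
    hits = 0
    for _ in range(n_sim):
        perm = rng.permutation(cols)
        sim = np.zeros_like(table)
        np.add.at(sim, (rows, perm), 1)
        if log_prob(sim) <= obs + 1e-9:
            hits += 1
    return (hits + 1) / (n_sim + 1)


def compare_cohorts(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    continuous: tuple[str, ...] = ("age",),
    categorical: tuple[str, ...] = ("race", "subtype", "menopausal_status", "treatment_arm"),
    seed: int = 0,
) -> dict[str, float]:
    """Baseline-characteristic comparison between two cohorts.

    Wilcoxon rank-sum for continuous characteristics, Fisher's exact
    test for categorical ones (exact 2×2 via the hypergeometric
    distribution; seeded Monte-Carlo for larger tables).  A
    characteristic absent from either table is skipped with a warning.
    """
    if table_a.empty or table_b.empty:
        raise ValueError("both cohort tables must be non-empty")
    out: dict[str, float] = {}
    for col in continuous:
        if col not in table_a.columns or col not in table_b.columns:
            warnings.warn(f"characteristic {col!r} absent; comparison skipped")
            continue
        a = table_a[col].dropna().to_numpy()
        b = table_b[col].dropna().to_numpy()
        out[col] = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    for col in categorical:
        if col not in table_a.columns or col not in table_b.columns:
            warnings.warn(f"characteristic {col!r} absent; comparison skipped")
            continue
        levels = sorted(set(table_a[col].dropna()) | set(table_b[col].dropna()))
        ct = np.array(
            [
                [(table_a[col] == lv).sum() for lv in levels],
                [(table_b[col] == lv).sum() for lv in levels],
            ]
        )
        ct = ct[:, ct.sum(axis=0) > 0]
        if ct.shape[1] < 2:
            out[col] = 1.0
        elif ct.shape[1] == 2:
            out[col] = float(stats.fisher_exact(ct)[1])
        else:
            out[col] = _fisher_rxc_montecarlo(ct, seed=seed)
    return out
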