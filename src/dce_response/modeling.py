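"""Logistic-regression pCR prediction with cross-validated AUC model
selection, bootstrap confidence intervals and ROC comparisons.

The analysis fits ordinary (maximum-likelihood) logistic regressions of
the binary pathologic-complete-response outcome on subsets of the 16
longitudinal MRI variables.  Predictive performance is the area under
the ROC curve of pooled out-of-fold predictions under repeated
stratified k-fold cross-validation (default 100 repeats of 5 folds),
averaged over repeats.  "Optimized" models are the candidate subsets
with the highest cross-validated AUC — exhaustively enumerated for a
single feature's four variables, greedy-forward for the combined
16-variable search — with selection and evaluation sharing the same
folds within each repeat so no test fold leaks into selection.  CIs of
the cross-validated AUC come from 1,000 patient-level bootstrap
resamples of out-of-fold scores; paired AUC differences are tested with
a 2,000-replicate two-sided bootstrap.  Per-variable p-values are
likelihood-ratio chi-squared tests of nested models.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LogitFit",
    "FoldPredictions",
    "ModelSpec",
    "ModelResult",
    "fit_logistic",
    "cv_auc",
    "optimize_model",
    "bootstrap_auc_ci",
    "compare_auc",
    "lr_test",
]

MIN_CLASS_FOR_CI = 5  # bootstrap CI "unavailable" below this minority count


# --------------------------------------------------------------------------
# plain logistic fits and LR tests
# --------------------------------------------------------------------------


@dataclass
class LogitFit:
    variables: tuple[str, ...]
    params: np.ndarray  # intercept first
    llf: float
    converged: bool
    separation: bool
    rank_deficient: bool


def _design(table: pd.DataFrame, variables) -> tuple[np.ndarray, np.ndarray]:
    X = table[list(variables)].to_numpy(dtype=float)
    y = table["pcr"].to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("design matrix or outcome contains missing values")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    return X, y


def fit_logistic(table: pd.DataFrame, variables) -> LogitFit:
    """Maximum-likelihood logistic fit of pCR on the given variables.

    Non-convergence, (quasi-)complete separation and rank deficiency are
    flagged on the result, never silently accepted.  Rank-deficient
    designs (e.g. duplicated columns) are fitted with a gradient method,
    which still attains the maximum likelihood even though individual
    coefficients are not identified.
    """
    variables = tuple(variables)
    X, y = _design(table, variables)
    Xc = sm.add_constant(X, has_constant="add")
    rank_deficient = np.linalg.matrix_rank(Xc) < Xc.shape[1]
    method = "bfgs" if rank_deficient else "newton"
    model = sm.Logit(y, Xc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method=method, disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            res = model.fit(method="bfgs", disp=0, maxiter=500)
        p = res.predict()
    eps = 1e-8
    # (quasi-)complete separation: the likelihood is driven to its
    # supremum (llf -> 0) or every fitted probability is at a boundary
    separation = bool(
        len(p) > 0
        and (res.llf > -1e-3 or np.all((p < eps) | (p > 1 - eps)))
    )
    return LogitFit(
        variables=variables,
        params=np.asarray(res.params),
        llf=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation,
        rank_deficient=bool(rank_deficient),
    )


def lr_test(table: pd.DataFrame, variables_full, variable_dropped: str) -> float:
    """Likelihood-ratio chi-squared test of nested logistic models with
    and without one variable; returns the p-value (df = 1)."""
    variables_full = tuple(variables_full)
    if variable_dropped not in variables_full:
        raise ValueError(
            f"{variable_dropped!r} is not in the full model — models not nested"
        )
    reduced = tuple(v for v in variables_full if v != variable_dropped)
    llf_full = fit_logistic(table, variables_full).llf
    llf_red = fit_logistic(table, reduced).llf
    stat = max(0.0, 2.0 * (llf_full - llf_red))
    return float(stats.chi2.sf(stat, df=1))


# --------------------------------------------------------------------------
# cross-validated AUC
# --------------------------------------------------------------------------


@dataclass
class FoldPredictions:
    """Out-of-fold predicted probabilities per CV repeat.

    ``scores`` has shape (repeats, n); row r holds each patient's
    predicted probability when held out in repeat r.  ``aggregated``
    averages over repeats — the patient-level score used for bootstrap
    CIs and paired comparisons.
    """

    scores: np.ndarray
    labels: np.ndarray
    patient_ids: np.ndarray | None = None

    @property
    def aggregated(self) -> np.ndarray:
        return self.scores.mean(axis=0)

    @property
    def per_repeat_auc(self) -> np.ndarray:
        return np.array(
            [roc_auc_score(self.labels, s) for s in self.scores]
        )


def _make_folds(y: np.ndarray, repeats: int, folds: int, seed: int):
    """Outcome-stratified fold assignments, one list of (train, test)
    splits per repeat.  Stratification guarantees both classes per fold
    whenever each class has at least ``folds`` members."""
    n_min = int(min((y == 1).sum(), (y == 0).sum()))
    if n_min < folds:
        raise ValueError(
            f"minority class has {n_min} patients, fewer than {folds} folds"
        )
    rng = np.random.SeedSequence(seed)
    out = []
    for child in rng.spawn(repeats):
        rs = int(child.generate_state(1)[0] % (2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        out.append(list(skf.split(np.zeros(len(y)), y)))
    return out


def _oof_scores(X: np.ndarray, y: np.ndarray, folds_per_repeat) -> np.ndarray:
    """(repeats, n) out-of-fold probabilities from unpenalized logistic
    fits on each training fold."""
    scores = np.empty((len(folds_per_repeat), len(y)))
    for r, splits in enumerate(folds_per_repeat):
        for train, test in splits:
            clf = LogisticRegression(penalty=None, max_iter=2000, solver="lbfgs")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(X[train], y[train])
            scores[r, test] = clf.predict_proba(X[test])[:, 1]
    return scores


def cv_auc(
    table: pd.DataFrame,
    variables,
    repeats: int = 100,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, FoldPredictions]:
    """Mean cross-validated AUC under repeated stratified k-fold CV.

    Per repeat, the AUC is computed on the pooled out-of-fold predicted
    probabilities; the result is the mean over repeats.
    """
    X, y = _design(table, variables)
    folds_per_repeat = _make_folds(y, repeats, folds, seed)
    scores = _oof_scores(X, y, folds_per_repeat)
    preds = FoldPredictions(
        scores=scores,
        labels=y.astype(int),
        patient_ids=table["patient_id"].to_numpy()
        if "patient_id" in table.columns
        else None,
    )
    return float(preds.per_repeat_auc.mean()), preds


# --------------------------------------------------------------------------
# model optimization
# --------------------------------------------------------------------------


@dataclass
class ModelSpec:
    candidate_variables: tuple[str, ...]
    stratum: str = "full"
    include_subtype_covariate: bool | None = None
    cv_repeats: int = 100
    cv_folds: int = 5
    selection_strategy: str = "auto"  # auto | exhaustive | forward
    seed: int = 0

    def __post_init__(self) -> None:
        self.candidate_variables = tuple(self.candidate_variables)
        if not self.candidate_variables:
            raise ValueError("candidate set must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.selection_strategy not in ("auto", "exhaustive", "forward"):
            raise ValueError("selection_strategy must be auto|exhaustive|forward")
        if self.include_subtype_covariate is None:
            self.include_subtype_covariate = self.stratum == "full"


@dataclass
class ModelResult:
    selected_variables: tuple[str, ...]
    cv_auc: float
    auc_ci: tuple[float, float] | None
    per_variable_p: dict[str, float]
    fold_predictions: FoldPredictions
    n_patients: int
    forced_covariates: tuple[str, ...] = ()
    search: str = "exhaustive"


def _subtype_dummies(table: pd.DataFrame) -> pd.DataFrame:
    """Reference-coded subtype indicator columns appended to the table."""
    dummies = pd.get_dummies(table["subtype"], prefix="subtype", drop_first=True)
    dummies.columns = [c.replace("/", "_").replace("+", "p").replace("-", "n") for c in dummies.columns]
    return pd.concat([table.reset_index(drop=True), dummies.reset_index(drop=True).astype(float)], axis=1)


def optimize_model(spec: ModelSpec, table: pd.DataFrame) -> ModelResult:
    """Select the candidate subset with the highest cross-validated AUC.

    The search is exhaustive over non-empty subsets when there are at
    most 8 candidates (a single feature's 4 variables → 15 subsets) and
    greedy forward selection with a no-improvement stop otherwise.  All
    subsets are scored on the same per-repeat folds, so selection and
    evaluation cannot leak across folds; ties break toward fewer
    variables, then lexicographically.  For the full cohort, subtype
    enters every model as a forced categorical covariate.
    """
    if spec.stratum != "full":
        table = table[table["subtype"] == spec.stratum]
    table = table.reset_index(drop=True)
    if table.empty:
        raise ValueError(f"stratum {spec.stratum!r} has no patients")

    forced: tuple[str, ...] = ()
    if spec.include_subtype_covariate and "subtype" in table.columns:
        table = _subtype_dummies(table)
        forced = tuple(c for c in table.columns if c.startswith("subtype_"))

    y = table["pcr"].to_numpy(dtype=float)
    n_min = int(min((y == 1).sum(), (y == 0).sum()))
    if n_min < spec.cv_folds:
        raise ValueError(
            f"stratum {spec.stratum!r}: minority class has {n_min} patients, "
            f"fewer than {spec.cv_folds} folds"
        )
    folds_per_repeat = _make_folds(y, spec.cv_repeats, spec.cv_folds, spec.seed)

    cache: dict[tuple[str, ...], tuple[float, np.ndarray]] = {}

    def score(subset: tuple[str, ...]) -> float:
        key = tuple(sorted(subset))
        if key not in cache:
            X = table[list(forced) + list(key)].to_numpy(dtype=float)
            scores = _oof_scores(X, y, folds_per_repeat)
            aucs = [roc_auc_score(y, s) for s in scores]
            cache[key] = (float(np.mean(aucs)), scores)
        return cache[key][0]

    candidates = spec.candidate_variables
    strategy = spec.selection_strategy
    if strategy == "auto":
        strategy = "exhaustive" if len(candidates) <= 8 else "forward"

    def better(a: tuple[str, ...], b: tuple[str, ...] | None) -> bool:
        if b is None:
            return True
        sa, sb = score(a), score(b)
        if sa != sb:
            return sa > sb
        if len(a) != len(b):
            return len(a) < len(b)
        return tuple(sorted(a)) < tuple(sorted(b))

    best: tuple[str, ...] | None = None
    if strategy == "exhaustive":
        for r in range(1, len(candidates) + 1):
            for subset in itertools.combinations(candidates, r):
                if better(subset, best):
                    best = subset
    else:  # greedy forward with no-improvement stop
        current: tuple[str, ...] = ()
        current_score = -np.inf
        remaining = list(candidates)
        while remaining:
            step_best = None
            for v in remaining:
                trial = current + (v,)
                if step_best is None or better(trial, step_best):
                    step_best = trial
            if step_best is None or score(step_best) <= current_score:
                break
            current = step_best
            current_score = score(step_best)
            remaining.remove(step_best[-1])
        best = current if current else (candidates[0],)

    best_key = tuple(sorted(best))
    best_auc, best_scores = cache[best_key]
    preds = FoldPredictions(
        scores=best_scores,
        labels=y.astype(int),
        patient_ids=table["patient_id"].to_numpy()
        if "patient_id" in table.columns
        else None,
    )
    ci = bootstrap_auc_ci(preds, seed=spec.seed + 1)
    model_vars = tuple(forced) + best_key
    per_p = {v: lr_test(table, model_vars, v) for v in best_key}
    return ModelResult(
        selected_variables=best_key,
        cv_auc=best_auc,
        auc_ci=ci,
        per_variable_p=per_p,
        fold_predictions=preds,
        n_patients=len(table),
        forced_covariates=forced,
        search=strategy,
    )


# --------------------------------------------------------------------------
# bootstrap CI and paired AUC comparison
# --------------------------------------------------------------------------


def _auc_rows(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise rank-based AUC (ties counted half) for matrices of
    resampled (score, label) pairs; NaN where a row has one class."""
    ranks = stats.rankdata(scores, axis=1)
    npos = labels.sum(axis=1)
    n = scores.shape[1]
    nneg = n - npos
    with np.errstate(invalid="ignore", divide="ignore"):
        auc = (np.where(labels, ranks, 0.0).sum(axis=1) - npos * (npos + 1) / 2.0) / (
            npos * nneg
        )
    auc[(npos == 0) | (nneg == 0)] = np.nan
    return auc


def bootstrap_auc_ci(
    fold_predictions: FoldPredictions,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float] | None:
    """Percentile bootstrap CI of the cross-validated AUC.

    Resamples patients (their aggregated out-of-fold score with their
    label) with replacement and recomputes the AUC per resample.
    Returns None — the CI is unavailable — when either outcome class has
    fewer than 5 patients, formalizing 'the number of outcomes was too
    small' for a reliable interval.
    """
    s = fold_predictions.aggregated
    y = fold_predictions.labels
    if len(s) == 0:
        raise ValueError("no predictions to bootstrap")
    if min(int(y.sum()), int((1 - y).sum())) < MIN_CLASS_FOR_CI:
        return None
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(s), size=(n_boot, len(s)))
    aucs = _auc_rows(s[idx], y[idx])
    aucs = aucs[np.isfinite(aucs)]
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def compare_auc(
    fold_predictions_a: FoldPredictions,
    fold_predictions_b: FoldPredictions,
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """Two-sided paired bootstrap test of the AUC difference.

    Both prediction sets must cover the same patients in the same order
    (the paired design).  Patients are resampled jointly; the p-value is
    the two-sided tail probability of a zero difference under the
    bootstrap distribution of the paired AUC difference.
    """
    ya, yb = fold_predictions_a.labels, fold_predictions_b.labels
    if len(ya) != len(yb) or not np.array_equal(ya, yb):
        raise ValueError("paired comparison requires identical patients/labels")
    pa = fold_predictions_a.patient_ids
    pb = fold_predictions_b.patient_ids
    if pa is not None and pb is not None and not np.array_equal(pa, pb):
        raise ValueError("paired comparison requires identical patients")
    sa, sb = fold_predictions_a.aggregated, fold_predictions_b.aggregated
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(ya), size=(n_boot, len(ya)))
    lab = ya[idx]
    d = _auc_rows(sa[idx], lab) - _auc_rows(sb[idx], lab)
    d = d[np.isfinite(d)]
    if len(d) == 0:
        return 1.0
    p_lo = (np.sum(d <= 0) + 1) / (len(d) + 1)
    p_hi = (np.sum(d >= 0) + 1) / (len(d) + 1)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))
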