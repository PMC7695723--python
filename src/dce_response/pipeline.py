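"""End-to-end orchestration: exam feature extraction and cohort modeling.

`run_extract` walks a directory of NIfTI DCE exams (three phases per
exam plus a JSON sidecar with spacing, laterality, VOI bounds and the
radiologist longest diameter), computes enhancement maps, FTV,
sphericity and contralateral BPE for each, and writes one feature row
per (patient, timepoint).  A corrupted exam is logged and skipped; the
run continues.

`run_model` assembles the analysis cohort from feature and clinical
CSVs and fits the optimized single-feature and combined models in the
full cohort and per HR/HER2 subtype, writing a results JSON, a
Table-2-shaped CSV of AUCs, and the per-patient out-of-fold scores that
every reported CI and p-value derives from.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._axes import contralateral
from .bpe import classify_fgt, compute_bpe, segment_breast
from .cohort import build_cohort
from .enhancement import DceSeries, compute_enhancement
from .ftv import VOI, FtvThresholds, compute_ftv
from .modeling import ModelSpec, compare_auc, optimize_model
from .phantom import FEATURES, SUBTYPES, variable_name
from .sphericity import compute_sphericity

__all__ = ["PipelineConfig", "run_extract", "run_model", "write_report"]

log = logging.getLogger("dce_response")

MODEL_TYPES = ("FTV only", "BPE only", "SPH only", "LD only", "Combined")
MODEL_FEATURES = {"FTV only": ("ftv",), "BPE only": ("bpe",), "SPH only": ("sph",), "LD only": ("ld",), "Combined": FEATURES}


@dataclass
class PipelineConfig:
    """Run configuration; all analysis defaults live here, not in code."""

    series_dir: str = ""
    clinical_csv: str = ""
    features_csv: str = ""
    out_dir: str = "out"
    pe_threshold: float = 70.0
    ser_threshold: float = 0.0
    threshold_overrides: dict[str, float] = field(default_factory=dict)
    bpe_n_slices: int = 5
    chest_wall_fraction: float = 0.85
    fcm_clusters: int = 2
    fcm_fuzziness: float = 2.0
    sph_min_voxels: int = 10
    cv_repeats: int = 100
    cv_folds: int = 5
    n_boot_ci: int = 1000
    n_boot_compare: int = 2000
    selection_strategy: str = "auto"
    exhaustive: bool = False
    strata: tuple[str, ...] = ("full",) + SUBTYPES
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        cfg.strata = tuple(cfg.strata)
        return cfg


def _load_exam(meta_path: Path) -> tuple[DceSeries, dict]:
    import nibabel as nib

    meta = json.loads(meta_path.read_text())
    stem = meta_path.name[: -len("_meta.json")]
    vols = {}
    for phase in ("s0", "s1", "s2"):
        p = meta_path.parent / f"{stem}_{phase}.nii.gz"
        if not p.exists():
            p = meta_path.parent / f"{stem}_{phase}.nii"
        vols[phase] = np.asarray(nib.load(p).dataobj, dtype=float)
    series = DceSeries(
        s0=vols["s0"],
        s1=vols["s1"],
        s2=vols["s2"],
        spacing=tuple(meta["spacing_mm"]),
        laterality_of_tumor=meta["laterality_of_tumor"],
        timepoint_label=meta["timepoint"],
        patient_id=meta["patient_id"],
    )
    return series, meta


def extract_exam_features(
    series: DceSeries, meta: dict, config: PipelineConfig
) -> dict:
    """All four features of one exam: FTV and SPH inside the VOI, BPE in
    the contralateral breast, LD passed through from the sidecar."""
    maps = compute_enhancement(series)
    pe_min = config.threshold_overrides.get(series.patient_id, config.pe_threshold)
    voi = VOI(bounds=tuple(tuple(b) for b in meta["voi_bounds"]))
    ftv_cm3, tumor = compute_ftv(
        maps, voi, series.spacing, FtvThresholds(pe_min=pe_min, ser_min=config.ser_threshold)
    )
    sph_res = compute_sphericity(tumor, min_voxels=config.sph_min_voxels)

    side = contralateral(series.laterality_of_tumor)
    breast = segment_breast(series, side, config.chest_wall_fraction)
    if breast.empty or breast.qc_flags:
        bpe_val, bpe_defined = float("nan"), False
        qc = sorted(breast.qc_flags)
    else:
        fgt3d, _ = classify_fgt(
            series, breast, seed=config.seed, c=config.fcm_clusters, m=config.fcm_fuzziness
        )
        bpe_res = compute_bpe(maps, breast, fgt3d, config.bpe_n_slices)
        bpe_val, bpe_defined = bpe_res.bpe_pct, bpe_res.defined
        qc = []
    return {
        "patient_id": series.patient_id,
        "timepoint": series.timepoint_label,
        "ftv_cm3": ftv_cm3,
        "ld_cm": meta.get("ld_cm", float("nan")),
        "sph": sph_res.sph if sph_res.defined else float("nan"),
        "bpe_pct": bpe_val if bpe_defined else float("nan"),
        "qc_flags": ";".join(qc),
    }


def run_extract(config: PipelineConfig) -> pd.DataFrame:
    """Extract features for every exam under ``config.series_dir``.

    Unreadable exams are recorded as errors and skipped; the run
    continues and exits cleanly as long as at least the directory was
    readable.  Writes ``features.csv`` (and an error log) to the output
    directory.
    """
    series_dir = Path(config.series_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metas = sorted(series_dir.glob("*_meta.json"))
    if not metas:
        log.warning("no exams found in %s", series_dir)
    rows, errors = [], []
    for meta_path in metas:
        try:
            series, meta = _load_exam(meta_path)
            rows.append(extract_exam_features(series, meta, config))
        except Exception as exc:  # per-exam failure: record, continue
            log.error("exam %s failed: %s", meta_path.name, exc)
            errors.append({"exam": meta_path.name, "error": str(exc)})
    features = pd.DataFrame(
        rows,
        columns=["patient_id", "timepoint", "ftv_cm3", "ld_cm", "sph", "bpe_pct", "qc_flags"],
    )
    features.to_csv(out_dir / "features.csv", index=False)
    if errors:
        pd.DataFrame(errors).to_csv(out_dir / "extract_errors.csv", index=False)
    return features


def run_model(config: PipelineConfig) -> dict:
    """Optimized single-feature and combined models per stratum.

    For each stratum × model type: selected variables, cross-validated
    AUC, bootstrap CI, per-variable LR p-values, and the paired
    bootstrap p-value of Combined versus the best single feature.  A
    stratum too small to cross-validate is reported as unavailable and
    the run continues.
    """
    features = pd.read_csv(config.features_csv)
    clinical = pd.read_csv(config.clinical_csv)
    cohort = build_cohort(features, clinical)
    table = cohort.included_data
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    strategy = "exhaustive" if config.exhaustive else config.selection_strategy
    results: dict = {
        "n_input": len(cohort.data),
        "n_included": cohort.n_included,
        "exclusion_counts": cohort.exclusion_counts,
        "strata": {},
    }
    scores_rows = []
    for si, stratum in enumerate(config.strata):
        stratum_res: dict = {}
        fold_preds = {}
        for mi, model_type in enumerate(MODEL_TYPES):
            feats = MODEL_FEATURES[model_type]
            candidates = tuple(
                variable_name(f, t) for f in feats for t in ("T0", "T1", "T2", "T3")
            )
            spec = ModelSpec(
                candidate_variables=candidates,
                stratum=stratum,
                cv_repeats=config.cv_repeats,
                cv_folds=config.cv_folds,
                selection_strategy=strategy if model_type == "Combined" else "auto",
                seed=config.seed + 1000 * si + mi,
            )
            try:
                res = optimize_model(spec, table)
            except ValueError as exc:
                stratum_res[model_type] = {"available": False, "reason": str(exc)}
                continue
            fold_preds[model_type] = res.fold_predictions
            stratum_res[model_type] = {
                "available": True,
                "selected_variables": list(res.selected_variables),
                "cv_auc": res.cv_auc,
                "auc_ci": list(res.auc_ci) if res.auc_ci else None,
                "per_variable_p": res.per_variable_p,
                "n_patients": res.n_patients,
            }
            agg = res.fold_predictions.aggregated
            for pid, scr, lab in zip(
                res.fold_predictions.patient_ids, agg, res.fold_predictions.labels
            ):
                scores_rows.append(
                    {
                        "stratum": stratum,
                        "model": model_type,
                        "patient_id": pid,
                        "oof_score": scr,
                        "pcr": int(lab),
                    }
                )
        singles = [
            m
            for m in MODEL_TYPES[:-1]
            if stratum_res.get(m, {}).get("available")
        ]
        if singles and stratum_res.get("Combined", {}).get("available"):
            best_single = max(singles, key=lambda m: stratum_res[m]["cv_auc"])
            p = compare_auc(
                fold_preds["Combined"],
                fold_preds[best_single],
                n_boot=config.n_boot_compare,
                seed=config.seed + 7919 + si,
            )
            stratum_res["combined_vs_best_single"] = {
                "best_single": best_single,
                "p_value": p,
            }
        results["strata"][stratum] = stratum_res

    (out_dir / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    pd.DataFrame(scores_rows).to_csv(out_dir / "oof_scores.csv", index=False)
    write_report(results, out_dir / "auc_table.csv")
    return results


def write_report(results: dict, path: str | Path) -> pd.DataFrame:
    """Render the per-stratum AUC table (models as rows, strata as
    columns, 'AUC (lo, hi)' cells) to CSV."""
    strata = list(results["strata"])
    rows = []
    for model_type in MODEL_TYPES:
        row = {"model_type": model_type}
        for stratum in strata:
            cell = results["strata"][stratum].get(model_type, {})
            if not cell.get("available"):
                row[stratum] = "n/a"
            elif cell["auc_ci"]:
                row[stratum] = (
                    f"{cell['cv_auc']:.2f} ({cell['auc_ci'][0]:.2f}, {cell['auc_ci'][1]:.2f})"
                )
            else:
                row[stratum] = f"{cell['cv_auc']:.2f} (CI not available)"
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
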