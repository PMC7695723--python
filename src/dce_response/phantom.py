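"""Synthetic DCE-MRI phantoms and synthetic longitudinal cohorts.

Two generators stand in for trial data:

* :func:`generate_dce_exam` builds a digital breast phantom — fat and
  fibroglandular tissue inside two half-ellipsoid breast envelopes
  attached to a chest-wall slab, plus an enhancing tumor of controllable
  shape and kinetics — and renders the three DCE phases from exact
  class-wise percent enhancement (PE) and signal enhancement ratio (SER),
  so every downstream feature (FTV, sphericity, BPE, longest diameter)
  has an analytic ground truth.

* :func:`generate_cohort` draws a longitudinal cohort with the
  statistical structure the response analysis assumes: HR/HER2 subtype
  mix, subtype-specific pathologic-complete-response (pCR) rates,
  log-normal feature baselines and pCR-conditional percent-change
  trajectories at the three on-treatment timepoints.

The signal model is piecewise constant per tissue class with additive
Gaussian noise: ``S1 = S0 (1 + PE/100)`` and ``S2 = S0 + (S1 - S0)/SER``,
with ground truth recorded before noise is added.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from ._axes import AX_AP, AX_LR, AX_SI, lateral_slice
from .enhancement import DceSeries, compute_enhancement
from .ftv import VOI, FtvThresholds, TumorMask
from .sphericity import compute_sphericity

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "TrajectoryModel",
    "LABELS",
    "generate_dce_exam",
    "generate_longitudinal_exams",
    "generate_cohort",
    "summarize_pcr_rates",
    "write_exam",
    "SUBTYPES",
    "FEATURES",
    "VARIABLES",
    "variable_name",
]

#: integer codes of the voxel label map
LABELS = {"background": 0, "fat": 1, "fgt": 2, "tumor": 3, "chest": 4}

SUBTYPES = ("HR+/HER2-", "HR+/HER2+", "HR-/HER2+", "HR-/HER2-")
FEATURES = ("ftv", "ld", "sph", "bpe")
TIMEPOINTS = ("T0", "T1", "T2", "T3")

#: subtype mix of the analysis cohort this generator emulates
DEFAULT_SUBTYPE_PROBS = (162 / 384, 60 / 384, 30 / 384, 132 / 384)
#: subtype-specific pCR probabilities (24/162, 19/60, 20/30, 51/132)
DEFAULT_PCR_RATES = (24 / 162, 19 / 60, 20 / 30, 51 / 132)


def variable_name(feature: str, timepoint: str) -> str:
    """Model-variable name: baseline ``<feat>_t0`` or percent change
    ``<feat>_pct_t{1,2,3}``."""
    if timepoint == "T0":
        return f"{feature}_t0"
    return f"{feature}_pct_t{timepoint[-1]}"


#: the 16 model variables (4 features × {baseline, %ΔT1, %ΔT2, %ΔT3})
VARIABLES = tuple(variable_name(f, t) for f in FEATURES for t in TIMEPOINTS)


# --------------------------------------------------------------------------
# image phantom
# --------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Parameters of one synthetic DCE exam.

    Geometry is derived from the grid: two breast envelopes (flat face at
    the chest-wall plane), a fat-intensity chest slab behind them sized so
    that the default posterior cutoff of the breast segmenter lands at the
    chest wall, and a central fibroglandular blob per breast (optionally
    with scattered islands).  The tumor sits in ``breast_side``.
    """

    grid_shape: tuple[int, int, int] = (56, 64, 64)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    breast_side: str = "left"
    tumor_center: tuple[float, float, float] | None = None  # mm, (si, ap, lr)
    tumor_shape: str = "sphere"  # sphere | ellipsoid | shell
    tumor_radius_mm: float | tuple[float, float, float] = 10.0
    tumor_pe_pct: float = 130.0
    tumor_ser: float = 1.2
    fgt_fraction: float = 0.2
    fgt_pe_pct: float = 30.0
    fgt_ser: float = 0.8
    fat_pe_pct: float = 5.0
    fat_ser: float = 0.8
    fgt_islands: int = 0
    noise_sd: float = 0.0
    s0_level: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape axes must be >= 8 voxels")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.breast_side not in ("left", "right"):
            raise ValueError("breast_side must be 'left' or 'right'")
        if self.tumor_shape not in ("sphere", "ellipsoid", "shell"):
            raise ValueError("tumor_shape must be sphere, ellipsoid or shell")
        if self.tumor_ser == 0:
            raise ValueError("tumor_ser must be nonzero")
        if not (0.0 <= self.fgt_fraction <= 1.0):
            raise ValueError("fgt_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.s0_level <= 0:
            raise ValueError("s0_level must be > 0")

    @property
    def tumor_radii_mm(self) -> tuple[float, float, float]:
        r = self.tumor_radius_mm
        if np.isscalar(r):
            return (float(r),) * 3
        return tuple(float(x) for x in r)


@dataclass
class PhantomTruth:
    """Ground truth recorded before noise, enabling exact oracles."""

    true_ftv_cm3: float
    true_sph: float
    true_bpe_pct: float
    true_ld_cm: float
    voxel_labels: np.ndarray
    voi_bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


def _breast_geometry(spec: PhantomSpec):
    """Breast envelope parameters in voxel units.

    The chest slab thickness is ``by * (1/f - 1)`` with ``f = 0.85`` so
    that a posterior cutoff keeping the anterior 85% of the foreground's
    anteroposterior extent cuts exactly at the chest-wall plane.
    """
    nz, ny, nx = (
        spec.grid_shape[AX_SI],
        spec.grid_shape[AX_AP],
        spec.grid_shape[AX_LR],
    )
    by = 0.60 * ny  # breast depth (AP semi-axis), voxels
    slab = max(2, int(round(by * (1.0 / 0.85 - 1.0))))
    y_cw = ny - slab  # chest-wall plane (AP index)
    az = 0.40 * nz
    ax = 0.23 * nx
    zc = 0.5 * (nz - 1)
    centers = {"right": 0.26 * (nx - 1), "left": 0.74 * (nx - 1)}
    return az, by, ax, zc, y_cw, centers, slab


def _ellipsoid_mask(shape, center, radii_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii_vox))
    return q <= 1.0


def _build_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    shape = spec.grid_shape
    az, by, ax, zc, y_cw, centers, slab = _breast_geometry(spec)
    labels = np.zeros(shape, dtype=np.uint8)

    # chest slab spanning the full posterior face behind the chest wall
    idx = [slice(None)] * 3
    idx[AX_AP] = slice(int(y_cw), shape[AX_AP])
    labels[tuple(idx)] = LABELS["chest"]

    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    for side, cx in centers.items():
        env = (
            ((zz - zc) / az) ** 2
            + ((yy - y_cw) / by) ** 2
            + ((xx - cx) / ax) ** 2
        ) <= 1.0
        env &= yy < y_cw
        labels[env] = LABELS["fat"]

        if spec.fgt_fraction > 0:
            f = spec.fgt_fraction ** (1.0 / 3.0)
            blob = _ellipsoid_mask(
                shape,
                (zc, y_cw - 0.45 * by, cx),
                (max(f * az, 1.0), max(f * by / 2.0, 1.0), max(f * ax, 1.0)),
            )
            labels[blob & env] = LABELS["fgt"]
            for _ in range(spec.fgt_islands):
                oz = rng.uniform(-0.5, 0.5) * az
                oy = -rng.uniform(0.2, 0.8) * by
                ox = rng.uniform(-0.5, 0.5) * ax
                isl = _ellipsoid_mask(
                    shape,
                    (zc + oz, y_cw + oy, cx + ox),
                    (2.0, 2.0, 2.0),
                )
                labels[isl & env] = LABELS["fgt"]
    return labels


def _tumor_mask(spec: PhantomSpec, labels: np.ndarray) -> np.ndarray:
    shape = spec.grid_shape
    az, by, ax, zc, y_cw, centers, _ = _breast_geometry(spec)
    if spec.tumor_center is None:
        cx = centers[spec.breast_side]
        center_vox = (zc, y_cw - 0.5 * by, cx)
    else:
        center_vox = tuple(
            c / s for c, s in zip(spec.tumor_center, spec.spacing)
        )
    radii_vox = tuple(
        r / s for r, s in zip(spec.tumor_radii_mm, spec.spacing)
    )
    if spec.tumor_shape == "sphere":
        radii_vox = (radii_vox[0],) * 3
    tumor = _ellipsoid_mask(shape, center_vox, radii_vox)
    if spec.tumor_shape == "shell":
        inner = _ellipsoid_mask(
            shape, center_vox, tuple(0.6 * r for r in radii_vox)
        )
        tumor &= ~inner
    if not tumor.any():
        raise ValueError("tumor mask is empty — radius too small for the grid")
    breastish = np.isin(labels, [LABELS["fat"], LABELS["fgt"]])
    if not breastish[tumor].all():
        raise ValueError("tumor extends outside the breast envelope")
    return tumor


def _max_caliper_mm(mask: np.ndarray, spacing) -> float:
    """Longest diameter of a voxel mask: max pairwise distance between
    voxel centers (convex hull vertices), in mm."""
    pts = np.argwhere(mask).astype(float) * np.asarray(spacing)
    if len(pts) == 1:
        return float(np.max(spacing))
    if len(pts) <= 4:
        hull_pts = pts
    else:
        try:
            hull_pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (coplanar) masks
            hull_pts = pts
    d2 = np.sum(
        (hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2, axis=-1
    )
    return float(np.sqrt(d2.max()))


def _voi_bounds(tumor: np.ndarray, pad: int = 3):
    bounds = []
    for ax_i in range(3):
        other = tuple(a for a in range(3) if a != ax_i)
        any_ax = np.any(tumor, axis=other)
        lo = int(np.argmax(any_ax))
        hi = int(len(any_ax) - np.argmax(any_ax[::-1]))
        bounds.append(
            (max(0, lo - pad), min(tumor.shape[ax_i], hi + pad))
        )
    return tuple(bounds)


def generate_dce_exam(
    spec: PhantomSpec, timepoint_label: str = "T0", patient_id: str = "phantom"
) -> tuple[DceSeries, PhantomTruth]:
    """Render one three-phase DCE exam plus its ground truth.

    Noise-free phantoms make downstream feature extraction exactly
    checkable: FTV equals the voxel count of threshold-passing tumor
    voxels times the voxel volume, and BPE equals the generative FGT PE.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _build_labels(spec, rng)
    tumor = _tumor_mask(spec, labels)
    labels[tumor] = LABELS["tumor"]

    s0_by_class = {
        "background": 0.0,
        "fat": spec.s0_level,
        "chest": spec.s0_level,
        "fgt": 0.5 * spec.s0_level,
        "tumor": 0.6 * spec.s0_level,
    }
    pe_by_class = {
        "background": 0.0,
        "fat": spec.fat_pe_pct,
        "chest": spec.fat_pe_pct,
        "fgt": spec.fgt_pe_pct,
        "tumor": spec.tumor_pe_pct,
    }
    ser_by_class = {
        "background": 1.0,
        "fat": spec.fat_ser,
        "chest": spec.fat_ser,
        "fgt": spec.fgt_ser,
        "tumor": spec.tumor_ser,
    }
    s0 = np.zeros(spec.grid_shape)
    s1 = np.zeros(spec.grid_shape)
    s2 = np.zeros(spec.grid_shape)
    for name, code in LABELS.items():
        sel = labels == code
        base = s0_by_class[name]
        early = base * (1.0 + pe_by_class[name] / 100.0)
        late = base + (early - base) / ser_by_class[name]
        s0[sel], s1[sel], s2[sel] = base, early, late

    # ground truth before noise
    thresholds = FtvThresholds()
    passing = tumor & (pe_by_class["tumor"] >= thresholds.pe_min) & (
        ser_by_class["tumor"] >= thresholds.ser_min
    )
    voxvol_cm3 = float(np.prod(spec.spacing)) / 1000.0
    true_ftv = float(passing.sum()) * voxvol_cm3
    sph_res = compute_sphericity(TumorMask(mask=tumor, spacing=spec.spacing))
    truth = PhantomTruth(
        true_ftv_cm3=true_ftv,
        true_sph=sph_res.sph if sph_res.defined else float("nan"),
        true_bpe_pct=float(spec.fgt_pe_pct),
        true_ld_cm=_max_caliper_mm(tumor, spec.spacing) / 10.0,
        voxel_labels=labels,
        voi_bounds=_voi_bounds(tumor),
    )

    if spec.noise_sd > 0:
        s0 = s0 + rng.normal(0.0, spec.noise_sd, spec.grid_shape)
        s1 = s1 + rng.normal(0.0, spec.noise_sd, spec.grid_shape)
        s2 = s2 + rng.normal(0.0, spec.noise_sd, spec.grid_shape)
        s0, s1, s2 = (np.clip(v, 0.0, None) for v in (s0, s1, s2))

    series = DceSeries(
        s0=s0,
        s1=s1,
        s2=s2,
        spacing=spec.spacing,
        laterality_of_tumor=spec.breast_side,
        timepoint_label=timepoint_label,
        patient_id=patient_id,
    )
    return series, truth


def generate_longitudinal_exams(
    spec: PhantomSpec,
    patient_id: str = "phantom",
    radius_factors: tuple[float, ...] = (1.0, 0.8, 0.55, 0.35),
    pe_factors: tuple[float, ...] = (1.0, 0.95, 0.9, 0.85),
) -> list[tuple[DceSeries, PhantomTruth]]:
    """Four serial exams of one patient with a shrinking, de-enhancing
    tumor — a longitudinal response in miniature."""
    exams = []
    radii = np.atleast_1d(spec.tumor_radius_mm).astype(float)
    for tp, rf, pf in zip(TIMEPOINTS, radius_factors, pe_factors):
        tp_spec = replace(
            spec,
            tumor_radius_mm=tuple(radii * rf) if radii.size > 1 else float(radii[0] * rf),
            tumor_pe_pct=spec.tumor_pe_pct * pf,
            seed=spec.seed + TIMEPOINTS.index(tp),
        )
        exams.append(generate_dce_exam(tp_spec, tp, patient_id))
    return exams


# --------------------------------------------------------------------------
# cohort generator
# --------------------------------------------------------------------------


@dataclass
class TrajectoryModel:
    """Generative model of feature baselines and on-treatment changes.

    Baselines are log-normal (sphericity: clipped normal, being bounded
    in (0, 1]); pCR patients' mean percent changes at T1–T3 are more
    negative than non-pCR patients' (monotone shrinkage).  Percent
    changes get Gaussian noise built from a shared per-patient response
    latent plus feature-specific noise (``response_correlation`` sets
    the shared share), so the four features are correlated the way
    serial response measurements are and combining them is informative
    but not perfectly separating; clipped at −100%.
    """

    baseline_log_mean: dict[str, float] = field(
        default_factory=lambda: {
            "ftv": float(np.log(10.0)),  # cm^3
            "ld": float(np.log(3.5)),  # cm
            "bpe": float(np.log(25.0)),  # %
        }
    )
    baseline_log_sd: dict[str, float] = field(
        default_factory=lambda: {"ftv": 0.8, "ld": 0.35, "bpe": 0.5}
    )
    sph_mean: float = 0.7
    sph_sd: float = 0.08
    mean_pct_change: dict[tuple[str, bool], tuple[float, float, float]] = field(
        default_factory=lambda: {
            ("ftv", False): (-30.0, -55.0, -70.0),
            ("ftv", True): (-45.0, -75.0, -88.0),
            ("ld", False): (-15.0, -30.0, -40.0),
            ("ld", True): (-25.0, -45.0, -58.0),
            ("sph", False): (-5.0, -10.0, -12.0),
            ("sph", True): (-9.0, -15.0, -19.0),
            ("bpe", False): (-10.0, -20.0, -25.0),
            ("bpe", True): (-16.0, -28.0, -35.0),
        }
    )
    pct_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"ftv": 20.0, "ld": 15.0, "sph": 10.0, "bpe": 15.0}
    )
    response_correlation: float = 0.6


@dataclass
class CohortSpec:
    """Parameters of a synthetic longitudinal cohort."""

    n: int = 384
    subtype_probs: tuple[float, float, float, float] = DEFAULT_SUBTYPE_PROBS
    pcr_rate_by_subtype: tuple[float, float, float, float] = DEFAULT_PCR_RATES
    feature_effects: dict[str, float] | None = None
    trajectory_model: TrajectoryModel = field(default_factory=TrajectoryModel)
    missing_rate: float = 0.0
    experimental_arm_prob: float = 303 / 384
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size n must be > 0")
        if abs(sum(self.subtype_probs) - 1.0) > 1e-9:
            raise ValueError("subtype_probs must sum to 1")
        for p in (*self.subtype_probs, *self.pcr_rate_by_subtype):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.feature_effects is not None:
            unknown = set(self.feature_effects) - set(VARIABLES)
            if unknown:
                raise ValueError(f"unknown feature_effects variables: {unknown}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")


def _draw_trajectories(
    tm: TrajectoryModel, pcr: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-feature (n, 4) matrices of raw values at T0–T3."""
    n = len(pcr)
    rho = tm.response_correlation
    if not (0.0 <= rho <= 1.0):
        raise ValueError("response_correlation must lie in [0, 1]")
    latent = rng.normal(0.0, 1.0, (n, 3))  # shared response course
    out: dict[str, np.ndarray] = {}
    for feat in FEATURES:
        if feat == "sph":
            base = np.clip(rng.normal(tm.sph_mean, tm.sph_sd, n), 0.05, 1.0)
        else:
            base = rng.lognormal(
                tm.baseline_log_mean[feat], tm.baseline_log_sd[feat], n
            )
        vals = np.empty((n, 4))
        vals[:, 0] = base
        means_pcr = np.asarray(tm.mean_pct_change[(feat, True)])
        means_non = np.asarray(tm.mean_pct_change[(feat, False)])
        mean_pct = np.where(pcr[:, None], means_pcr, means_non)
        noise = rho * latent + np.sqrt(1.0 - rho**2) * rng.normal(0.0, 1.0, (n, 3))
        pct = mean_pct + tm.pct_noise_sd[feat] * noise
        pct = np.clip(pct, -100.0, None)
        vals[:, 1:] = base[:, None] * (1.0 + pct / 100.0)
        if feat == "sph":
            vals = np.clip(vals, 0.0, 1.0)
        out[feat] = vals
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort as a long feature table plus clinical data.

    Returns a wide per-patient DataFrame with patient_id, subtype,
    hr/her2 status, treatment arm, pCR, the raw feature values at the
    four timepoints (columns ``<feat>_T0`` … ``<feat>_T3``) and the 16
    derived model variables.

    Two outcome mechanisms are supported: by default pCR is drawn from
    the subtype-specific rates and trajectories are pCR-conditional;
    when ``feature_effects`` is given, trajectories are drawn from the
    pooled (non-pCR) model and pCR is drawn from a logistic model on
    the standardized named variables, so variable-selection behavior can
    be planted exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    subtype_idx = rng.choice(4, size=n, p=np.asarray(spec.subtype_probs))
    rates = np.asarray(spec.pcr_rate_by_subtype)

    if spec.feature_effects is None:
        pcr = rng.random(n) < rates[subtype_idx]
        feats = _draw_trajectories(spec.trajectory_model, pcr, rng)
    else:
        # features first (no pCR conditioning), then outcome from a
        # logistic model on standardized variables
        feats = _draw_trajectories(
            spec.trajectory_model, np.zeros(n, dtype=bool), rng
        )
        variables = _derive_variables(feats)
        base_rate = float(np.dot(spec.subtype_probs, rates))
        logit = np.full(n, np.log(base_rate / (1.0 - base_rate)))
        for var, beta in spec.feature_effects.items():
            z = variables[var]
            sd = z.std()
            zz = (z - z.mean()) / (sd if sd > 0 else 1.0)
            logit = logit + beta * zz
        pcr = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    variables = _derive_variables(feats)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "subtype": [SUBTYPES[k] for k in subtype_idx],
            "hr_status": ["+" if SUBTYPES[k].startswith("HR+") else "-" for k in subtype_idx],
            "her2_status": ["+" if "HER2+" in SUBTYPES[k] else "-" for k in subtype_idx],
            "treatment_arm": np.where(
                rng.random(n) < spec.experimental_arm_prob, "experimental", "control"
            ),
            "pcr": pcr.astype(int),
        }
    )
    for feat in FEATURES:
        for j, tp in enumerate(TIMEPOINTS):
            df[f"{feat}_{tp}"] = feats[feat][:, j]
    for var, vals in variables.items():
        df[var] = vals

    if spec.missing_rate > 0:
        raw_cols = [f"{f}_{t}" for f in FEATURES for t in TIMEPOINTS]
        drop = rng.random((n, len(raw_cols))) < spec.missing_rate
        for j, col in enumerate(raw_cols):
            df.loc[drop[:, j], col] = np.nan
        # re-derive variables with the missingness applied
        for feat in FEATURES:
            base = df[f"{feat}_T0"].to_numpy()
            for tp in TIMEPOINTS[1:]:
                later = df[f"{feat}_{tp}"].to_numpy()
                with np.errstate(divide="ignore", invalid="ignore"):
                    pct = (later - base) / base * 100.0
                pct[(base == 0) | ~np.isfinite(pct)] = np.nan
                df[variable_name(feat, tp)] = pct
            df[variable_name(feat, "T0")] = base
    return df


def _derive_variables(feats: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for feat, vals in feats.items():
        base = vals[:, 0]
        out[variable_name(feat, "T0")] = base
        for j, tp in enumerate(TIMEPOINTS[1:], start=1):
            with np.errstate(divide="ignore", invalid="ignore"):
                pct = (vals[:, j] - base) / base * 100.0
            pct = np.where(base == 0, np.nan, pct)
            out[variable_name(feat, tp)] = pct
    return out


def summarize_pcr_rates(table: pd.DataFrame) -> dict[str, tuple[int, int, float]]:
    """Per-subtype and overall (n, n_pCR, pCR %) of a cohort table."""
    out: dict[str, tuple[int, int, float]] = {}
    for sub in SUBTYPES:
        sel = table[table["subtype"] == sub]
        k, m = int(sel["pcr"].sum()), len(sel)
        out[sub] = (m, k, 100.0 * k / m if m else float("nan"))
    k, m = int(table["pcr"].sum()), len(table)
    out["full"] = (m, k, 100.0 * k / m if m else float("nan"))
    return out


# --------------------------------------------------------------------------
# file output
# --------------------------------------------------------------------------


def write_exam(
    series: DceSeries, truth: PhantomTruth, out_dir: str | Path
) -> Path:
    """Write one exam as three NIfTI volumes plus a JSON sidecar.

    The sidecar carries spacing, laterality, the VOI bounds and the
    scalar ground truth (including the longest-diameter surrogate that
    stands in for the radiologist measurement).
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{series.patient_id}_{series.timepoint_label}"
    affine = np.diag([*series.spacing, 1.0])
    for phase, vol in (("s0", series.s0), ("s1", series.s1), ("s2", series.s2)):
        nib.save(
            nib.Nifti1Image(vol.astype(np.float32), affine),
            out_dir / f"{stem}_{phase}.nii.gz",
        )
    sidecar = {
        "patient_id": series.patient_id,
        "timepoint": series.timepoint_label,
        "spacing_mm": list(series.spacing),
        "laterality_of_tumor": series.laterality_of_tumor,
        "voi_bounds": [list(b) for b in truth.voi_bounds],
        "ld_cm": truth.true_ld_cm,
        "truth": {
            "ftv_cm3": truth.true_ftv_cm3,
            "sph": truth.true_sph,
            "bpe_pct": truth.true_bpe_pct,
            "ld_cm": truth.true_ld_cm,
        },
    }
    path = out_dir / f"{stem}_meta.json"
    path.write_text(json.dumps(sidecar, indent=2))
    return path
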