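"""Contralateral background parenchymal enhancement (BPE).

BPE is the mean percent enhancement of fibroglandular tissue (FGT) in
the breast opposite the tumor, a fully automated measurement with three
stages:

1. breast segmentation — histogram thresholding of the pre-contrast
   volume, morphological closing, largest connected component on the
   requested side, and a posterior cutoff removing the chest wall;
2. FGT classification — fuzzy c-means clustering of pre-contrast
   intensities inside the breast mask (two clusters; under the
   fat-suppressed convention the lower-intensity cluster is FGT by
   default, configurable via ``polarity``);
3. averaging — mean PE of FGT voxels over five contiguous axial slices
   geometrically centered along the superior–inferior extent of the
   breast, characterizing tissue in the center of the breast.

The segmentation stage is a functional stand-in for a published breast
segmentation method whose details are not reproduced here; quality
flags (insufficient fat suppression, coil inhomogeneity) are simple
intensity heuristics that mark exams for exclusion, mimicking the
exclusion categories of a reading-room QC step rather than replicating
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from ._axes import AX_AP, AX_LR, AX_SI, contralateral, lateral_slice
from .enhancement import DceSeries, EnhancementMaps

__all__ = [
    "BreastMask",
    "FgtMembership",
    "BpeResult",
    "segment_breast",
    "fuzzy_cmeans",
    "classify_fgt",
    "compute_bpe",
]

QC_FAT_SUPPRESSION = "insufficient_fat_suppression"
QC_COIL = "coil_inhomogeneity"
QC_SEGMENTATION = "segmentation_failure"


@dataclass
class BreastMask:
    mask: np.ndarray
    side: str
    axial_axis: int = AX_SI
    qc_flags: set[str] = field(default_factory=set)

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class FgtMembership:
    """Fuzzy c-means result for a 1-D intensity sample.

    ``membership`` is the degree of belonging to the FGT cluster for each
    sample, ``centroids`` are sorted ascending, and ``hard_mask`` applies
    the membership cut.  Memberships across all clusters sum to 1 per
    sample; only the FGT cluster's column is kept.
    """

    membership: np.ndarray
    centroids: np.ndarray
    hard_mask: np.ndarray
    fgt_cluster: int
    n_iter: int = 0


@dataclass
class BpeResult:
    bpe_pct: float
    n_slices_used: int
    slice_indices: list[int]
    defined: bool


def _foreground_threshold(s0: np.ndarray) -> float:
    """Automatic tissue/air threshold on the pre-contrast volume.

    Multi-Otsu with three classes and the lowest cut is used so that
    partially suppressed parenchyma (darker than fat but brighter than
    air) stays in the foreground; plain Otsu is the fallback for nearly
    two-valued data.
    """
    try:
        return float(threshold_multiotsu(s0, classes=3)[0])
    except ValueError:
        return float(threshold_otsu(s0))


def segment_breast(
    series: DceSeries,
    side: str,
    chest_wall_fraction: float = 0.85,
) -> BreastMask:
    """Segment the breast on the requested (contralateral) side.

    The BPE contract is strictly contralateral: asking for the tumor
    side raises.  An empty result is not an exception — the mask comes
    back empty with the ``segmentation_failure`` flag set, and the exam
    is excluded downstream.
    """
    if side == series.laterality_of_tumor:
        raise ValueError(
            "BPE is measured in the contralateral breast; "
            f"tumor is on the {side} side"
        )
    if side != contralateral(series.laterality_of_tumor):
        raise ValueError(f"unknown side {side!r}")
    if not (0.0 < chest_wall_fraction <= 1.0):
        raise ValueError("chest_wall_fraction must be in (0, 1]")

    s0 = series.s0
    flags: set[str] = set()
    if float(s0.max()) <= 0:
        return BreastMask(np.zeros(s0.shape, bool), side, AX_SI, {QC_SEGMENTATION})

    fg = s0 > _foreground_threshold(s0)
    fg = ndimage.binary_closing(fg, structure=np.ones((3, 3, 3)))

    half = np.zeros(s0.shape, dtype=bool)
    idx = [slice(None)] * 3
    idx[AX_LR] = lateral_slice(side, s0.shape[AX_LR])
    half[tuple(idx)] = True
    fg &= half

    labels, n_comp = ndimage.label(fg)
    if n_comp == 0:
        return BreastMask(np.zeros(s0.shape, bool), side, AX_SI, {QC_SEGMENTATION})
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n_comp + 1))
    comp = labels == (1 + int(np.argmax(sizes)))

    # posterior cutoff: keep the anterior chest_wall_fraction of the
    # anteroposterior extent of the component (chest wall is posterior)
    ap_any = np.any(comp, axis=tuple(a for a in range(3) if a != AX_AP))
    front = int(np.argmax(ap_any))
    back = int(len(ap_any) - np.argmax(ap_any[::-1]))  # exclusive
    cut = front + int(round(chest_wall_fraction * (back - front)))
    keep = np.zeros(s0.shape, dtype=bool)
    idx = [slice(None)] * 3
    idx[AX_AP] = slice(0, cut)
    keep[tuple(idx)] = True
    mask = comp & keep

    if not mask.any():
        flags.add(QC_SEGMENTATION)
    else:
        flags |= _qc_flags(s0, mask)
    return BreastMask(mask=mask, side=side, axial_axis=AX_SI, qc_flags=flags)


def _qc_flags(
    s0: np.ndarray,
    mask: np.ndarray,
    fat_suppression_ratio: float = 1.15,
    coil_edge_ratio: float = 1.8,
) -> set[str]:
    """Heuristic image-quality flags on the segmented breast.

    * insufficient fat suppression — the bright (fat) and dark (FGT)
      intensity modes inside the breast are nearly indistinguishable,
      so clustering cannot be trusted (p80/p20 below a ratio);
    * coil inhomogeneity — the rind of the breast is much brighter than
      its core (edge/center mean ratio above a ratio), the appearance
      of surface-coil shading.
    """
    flags: set[str] = set()
    vals = s0[mask]
    p20, p80 = np.percentile(vals, [20, 80])
    if p20 > 0 and p80 / p20 < fat_suppression_ratio:
        flags.add(QC_FAT_SUPPRESSION)
    core = ndimage.binary_erosion(mask, iterations=3)
    rind = mask & ~core
    if core.any() and rind.any():
        core_mean = float(s0[core].mean())
        if core_mean > 0 and float(s0[rind].mean()) / core_mean > coil_edge_ratio:
            flags.add(QC_COIL)
    return flags


def fuzzy_cmeans(
    values: np.ndarray,
    c: int = 2,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    polarity: str = "low",
    membership_cut: float = 0.5,
) -> FgtMembership:
    """Fuzzy c-means (Bezdek) clustering of a 1-D intensity sample.

    Iterates the standard coupled updates — memberships
    ``u_ij ∝ d_ij^(-2/(m-1))`` normalized per sample, centroids as
    ``u^m``-weighted means — until the largest centroid shift falls
    below ``tol``.  Deterministic for a given seed (random initial
    centroids drawn from the distinct sample values).

    ``polarity`` picks which cluster is called fibroglandular tissue:
    ``"low"`` (fat-suppressed convention, FGT darker than fat on the
    pre-contrast image) or ``"high"``.
    """
    values = np.asarray(values, dtype=float).ravel()
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError("fuzziness m must be > 1")
    distinct = np.unique(values)
    if distinct.size < c:
        raise ValueError(
            f"need at least {c} distinct values for {c}-cluster fuzzy c-means"
        )
    rng = np.random.default_rng(seed)
    centroids = np.sort(rng.choice(distinct, size=c, replace=False))

    n_iter = 0
    u = np.empty((values.size, c))
    for n_iter in range(1, max_iter + 1):
        d = np.abs(values[:, None] - centroids[None, :])
        exact = d < 1e-300
        any_exact = exact.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = d ** (-2.0 / (m - 1.0))
            u = w / w.sum(axis=1, keepdims=True)
        # samples sitting exactly on a centroid get full membership there
        if any_exact.any():
            u[any_exact] = exact[any_exact] / exact[any_exact].sum(
                axis=1, keepdims=True
            )
        um = u**m
        new_centroids = (um * values[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = float(np.max(np.abs(new_centroids - centroids)))
        centroids = new_centroids
        if shift < tol:
            break

    order = np.argsort(centroids)
    centroids = centroids[order]
    u = u[:, order]
    fgt_cluster = 0 if polarity == "low" else c - 1
    membership = u[:, fgt_cluster]
    return FgtMembership(
        membership=membership,
        centroids=centroids,
        hard_mask=membership >= membership_cut,
        fgt_cluster=fgt_cluster,
        n_iter=n_iter,
    )


def classify_fgt(
    series: DceSeries,
    breast: BreastMask,
    seed: int = 0,
    polarity: str = "low",
    **fcm_kwargs,
) -> tuple[np.ndarray, FgtMembership]:
    """Fuzzy c-means FGT classification inside a breast mask.

    Clusters the pre-contrast intensities of breast voxels and scatters
    the hard FGT assignment back into a 3-D mask.
    """
    if breast.empty:
        raise ValueError("cannot classify FGT in an empty breast mask")
    fgt = fuzzy_cmeans(
        series.s0[breast.mask], seed=seed, polarity=polarity, **fcm_kwargs
    )
    fgt3d = np.zeros(series.shape, dtype=bool)
    fgt3d[breast.mask] = fgt.hard_mask
    return fgt3d, fgt


def compute_bpe(
    maps: EnhancementMaps,
    breast: BreastMask,
    fgt_mask: np.ndarray,
    n_slices: int = 5,
) -> BpeResult:
    """Mean PE of FGT voxels over centered axial slices.

    The slice stack is the ``n_slices`` contiguous axial slices centered
    at the geometric midpoint of the breast mask's superior–inferior
    extent (ties toward inferior, i.e. the higher slice index); if the
    breast spans fewer slices, all of them are used.  An undefined
    result (no valid FGT voxels in the stack) is a value, not an error;
    such exams are excluded downstream.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    ax = breast.axial_axis
    if breast.empty or not fgt_mask.any():
        return BpeResult(float("nan"), 0, [], False)

    si_any = np.any(breast.mask, axis=tuple(a for a in range(3) if a != ax))
    lo = int(np.argmax(si_any))
    hi = int(len(si_any) - np.argmax(si_any[::-1]))  # exclusive
    extent = hi - lo
    if extent <= n_slices:
        start, stop = lo, hi
    else:
        center = -(-(lo + hi - 1) // 2)  # ceil midpoint -> inferior on ties
        start = center - (n_slices - 1) // 2
        stop = start + n_slices
        if start < lo:
            start, stop = lo, lo + n_slices
        if stop > hi:
            start, stop = hi - n_slices, hi

    stack = np.zeros(breast.mask.shape, dtype=bool)
    idx = [slice(None)] * 3
    idx[ax] = slice(start, stop)
    stack[tuple(idx)] = True

    sel = stack & breast.mask & fgt_mask & maps.valid
    if not sel.any():
        return BpeResult(float("nan"), stop - start, list(range(start, stop)), False)
    return BpeResult(
        bpe_pct=float(maps.pe[sel].mean()),
        n_slices_used=stop - start,
        slice_indices=list(range(start, stop)),
        defined=True,
    )
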