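"""Functional tumor volume (FTV) from enhancement maps.

FTV is the volume of tissue inside a radiologist-defined volume of
interest whose kinetics look tumor-like: early percent enhancement at or
above a threshold (default 70%) and a non-negative signal enhancement
ratio.  It is computed by summing the volumes of threshold-passing voxels
— pure thresholding, no connectivity filtering or hole-filling, so the
mask is exactly the threshold set.  Thresholds adjusted at baseline for a
patient are kept fixed across that patient's later exams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enhancement import EnhancementMaps

__all__ = ["VOI", "FtvThresholds", "TumorMask", "compute_ftv"]


@dataclass
class VOI:
    """Volume of interest: either per-axis half-open index bounds or an
    explicit boolean mask in the exam's voxel frame."""

    bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.bounds is None) == (self.mask is None):
            raise ValueError("provide exactly one of bounds or mask")

    def to_mask(self, shape: tuple[int, ...]) -> np.ndarray:
        if self.mask is not None:
            if self.mask.shape != tuple(shape):
                raise ValueError("VOI mask shape does not match the exam grid")
            if not self.mask.any():
                raise ValueError("VOI is empty")
            return self.mask.astype(bool)
        out = np.zeros(shape, dtype=bool)
        idx = []
        for ax, (lo, hi) in enumerate(self.bounds):
            if not (0 <= lo < hi <= shape[ax]):
                raise ValueError(
                    f"VOI bounds {lo, hi} fall outside the grid on axis {ax}"
                )
            idx.append(slice(lo, hi))
        out[tuple(idx)] = True
        return out


@dataclass(frozen=True)
class FtvThresholds:
    """Kinetic thresholds defining FTV membership (inclusive comparisons)."""

    pe_min: float = 70.0
    ser_min: float = 0.0

    def __post_init__(self) -> None:
        if self.pe_min <= 0:
            raise ValueError("pe_min must be > 0")


@dataclass
class TumorMask:
    mask: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing)) / 1000.0


def compute_ftv(
    maps: EnhancementMaps,
    voi: VOI,
    spacing: tuple[float, float, float],
    thresholds: FtvThresholds = FtvThresholds(),
) -> tuple[float, TumorMask]:
    """Sum voxel volumes with ``PE >= pe_min`` and ``SER >= ser_min``
    inside the VOI.

    Returns the FTV in cm³ together with the boolean tumor mask; an empty
    mask (FTV = 0) is a legal result, e.g. after complete response.
    """
    voi_mask = voi.to_mask(maps.pe.shape)
    with np.errstate(invalid="ignore"):
        passing = (
            voi_mask
            & maps.valid
            & (maps.pe >= thresholds.pe_min)
            & (maps.ser >= thresholds.ser_min)
        )
    tumor = TumorMask(mask=passing, spacing=tuple(float(s) for s in spacing))
    return tumor.volume_cm3, tumor
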