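"""Voxelwise enhancement-kinetics maps from a three-phase DCE-MRI series.

A breast DCE exam here consists of three aligned T1-weighted volumes: the
pre-contrast acquisition ``S0``, an early post-contrast phase ``S1``
(~2.5 min after injection) and a late phase ``S2`` (~7.5 min).  Two
semi-quantitative kinetic maps are derived voxel by voxel:

* percent enhancement  ``PE = (S1 - S0) / S0 * 100``  — how strongly a
  voxel takes up contrast early;
* signal enhancement ratio  ``SER = (S1 - S0) / (S2 - S0)``  — the shape
  of the uptake curve (SER > 1: washout, typical of tumor; SER < 1:
  persistent enhancement, typical of normal parenchyma).

Maps are computed over the whole volume; restriction to a tumor VOI or to
the contralateral breast happens downstream so that the tumor-volume and
background-enhancement measurements share one map computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DceSeries",
    "EnhancementMaps",
    "compute_pe",
    "compute_ser",
    "compute_enhancement",
    "DEFAULT_SER_CAP",
]

#: SER assigned where the late phase returned to baseline while the early
#: phase enhanced (washout limit; the exact value never affects FTV
#: membership because only the sign of SER is thresholded).
DEFAULT_SER_CAP = 10.0

TIMEPOINTS = ("T0", "T1", "T2", "T3")


@dataclass
class DceSeries:
    """One exam's three aligned signal-intensity volumes plus metadata."""

    s0: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    spacing: tuple[float, float, float]
    laterality_of_tumor: str = "left"
    timepoint_label: str = "T0"
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.s0 = np.asarray(self.s0, dtype=float)
        self.s1 = np.asarray(self.s1, dtype=float)
        self.s2 = np.asarray(self.s2, dtype=float)
        if not (self.s0.shape == self.s1.shape == self.s2.shape):
            raise ValueError("S0, S1 and S2 must have identical shapes")
        if self.s0.ndim != 3:
            raise ValueError("DCE volumes must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        if self.laterality_of_tumor not in ("left", "right"):
            raise ValueError("laterality_of_tumor must be 'left' or 'right'")
        if self.timepoint_label not in TIMEPOINTS:
            raise ValueError(f"timepoint_label must be one of {TIMEPOINTS}")
        for name, vol in (("s0", self.s0), ("s1", self.s1), ("s2", self.s2)):
            if np.any(vol < 0):
                raise ValueError(f"{name} contains negative intensities")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.s0.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class EnhancementMaps:
    """PE (%) and SER maps with a validity mask.

    ``valid`` marks voxels whose pre-contrast signal exceeds the noise
    floor; PE and SER are finite wherever ``valid`` is true.
    """

    pe: np.ndarray
    ser: np.ndarray
    valid: np.ndarray
    noise_floor: float = 0.0
    ser_cap: float = DEFAULT_SER_CAP

    def __post_init__(self) -> None:
        if not (self.pe.shape == self.ser.shape == self.valid.shape):
            raise ValueError("pe, ser and valid must share one shape")
        if not np.all(np.isfinite(self.pe[self.valid])):
            raise ValueError("pe must be finite on valid voxels")
        if not np.all(np.isfinite(self.ser[self.valid])):
            raise ValueError("ser must be finite on valid voxels")


def _resolve_noise_floor(series: DceSeries, noise_floor: float | None) -> float:
    if noise_floor is None:
        # relative floor: anything below one part in 10^6 of the brightest
        # pre-contrast voxel counts as air/noise
        return 1e-6 * float(series.s0.max()) if series.s0.size else 0.0
    if noise_floor < 0:
        raise ValueError("noise_floor must be >= 0")
    return float(noise_floor)


def compute_pe(
    series: DceSeries, noise_floor: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Percent-enhancement map ``(S1 - S0)/S0 * 100`` with validity mask.

    Voxels with ``S0 <= noise_floor`` (air, background) are invalid and
    their PE is set to NaN; downstream consumers must honour the mask.
    """
    floor = _resolve_noise_floor(series, noise_floor)
    valid = series.s0 > floor
    pe = np.full(series.shape, np.nan)
    np.divide(series.s1 - series.s0, series.s0, out=pe, where=valid)
    pe[valid] *= 100.0
    return pe, valid


def compute_ser(
    series: DceSeries,
    noise_floor: float | None = None,
    ser_cap: float = DEFAULT_SER_CAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Signal-enhancement-ratio map ``(S1 - S0)/(S2 - S0)``.

    The ratio is made a total function: where the late-phase difference is
    within the noise floor of zero but the early phase did enhance, SER is
    set to ``ser_cap`` (plateau/washout limit, keeping SER >= 0); where
    both differences vanish SER is 0.  Validity mirrors the PE mask
    (``S0`` above the noise floor).
    """
    if ser_cap <= 0:
        raise ValueError("ser_cap must be > 0")
    floor = _resolve_noise_floor(series, noise_floor)
    valid = series.s0 > floor
    early = series.s1 - series.s0
    late = series.s2 - series.s0
    denom_ok = np.abs(late) > floor

    ser = np.zeros(series.shape)
    np.divide(early, late, out=ser, where=denom_ok)
    ser[~denom_ok & (early > floor)] = ser_cap
    ser[~valid] = np.nan
    return ser, valid


def compute_enhancement(
    series: DceSeries,
    noise_floor: float | None = None,
    ser_cap: float = DEFAULT_SER_CAP,
) -> EnhancementMaps:
    """Convenience wrapper computing both kinetic maps at once."""
    floor = _resolve_noise_floor(series, noise_floor)
    pe, valid = compute_pe(series, floor)
    ser, _ = compute_ser(series, floor, ser_cap)
    return EnhancementMaps(pe=pe, ser=ser, valid=valid, noise_floor=floor, ser_cap=ser_cap)
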