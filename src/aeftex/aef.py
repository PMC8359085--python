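"""Arterial enhancement fraction (AEF) mapping from three-phase CT.

The AEF of a voxel is the ratio of its arterial-phase enhancement to its
portal-phase enhancement,

    AEF = (CTa - CTu) / (CTp - CTu),

where CTu, CTa and CTp are the unenhanced, arterial-phase and portal-phase
CT numbers in Hounsfield units. In liver imaging the AEF approximates the
arterial share of tissue perfusion: hepatocellular carcinoma progressively
recruits arterial supply ("arterialization"), so lesions stand out as
high-AEF regions against the portal-dominated parenchyma.

Voxels whose portal enhancement does not exceed a small guard ``epsilon``
have an ill-conditioned denominator and are flagged invalid rather than
zero-filled; downstream statistics must exclude them.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiphaseVolume",
    "AEFMap",
    "align_phases",
    "compute_aef_map",
    "DEFAULT_EPSILON_HU",
    "DEFAULT_CLIP_RANGE",
]

#: Denominator guard in HU: voxels with CTp - CTu <= epsilon are invalid.
DEFAULT_EPSILON_HU: float = 1.0

#: Physical plausibility window for AEF values (unitless).
DEFAULT_CLIP_RANGE: tuple[float, float] = (0.0, 4.0)


@dataclass(frozen=True)
class MultiphaseVolume:
    """Co-registered unenhanced / arterial / portal CT grids in HU.

    Arrays are indexed (plane, row, col); ``voxel_size`` is the matching
    (plane-thickness, row-spacing, col-spacing) in millimetres.
    """

    ctu: np.ndarray
    cta: np.ndarray
    ctp: np.ndarray
    voxel_size: tuple[float, float, float] = (3.0, 0.8, 0.8)

    def __post_init__(self) -> None:
        if not (self.ctu.shape == self.cta.shape == self.ctp.shape):
            raise ValueError(
                "phase grids must share one shape, got "
                f"{self.ctu.shape}, {self.cta.shape}, {self.ctp.shape}"
            )
        if self.ctu.ndim != 3:
            raise ValueError("phase grids must be 3-D (plane, row, col)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.ctu.shape


@dataclass(frozen=True)
class AEFMap:
    """Per-voxel AEF values with a validity mask.

    ``valid`` is False exactly where the portal enhancement CTp - CTu is
    at or below ``epsilon``; there ``values`` is NaN. Valid values are
    clipped into ``clip_range``.
    """

    values: np.ndarray
    valid: np.ndarray
    epsilon: float = DEFAULT_EPSILON_HU
    clip_range: tuple[float, float] = DEFAULT_CLIP_RANGE

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must share a shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def _overlap_msd(fixed: np.ndarray, moving: np.ndarray, shift: tuple[int, int, int]) -> float:
    """Mean squared difference between ``fixed`` and ``moving`` translated by
    ``shift``, evaluated on the overlapping region only."""
    f_sl, m_sl = [], []
    for n, s in zip(fixed.shape, shift):
        lo_f, hi_f = max(0, s), n + min(0, s)
        if hi_f <= lo_f:
            return np.inf
        f_sl.append(slice(lo_f, hi_f))
        m_sl.append(slice(lo_f - s, hi_f - s))
    diff = fixed[tuple(f_sl)].astype(float) - moving[tuple(m_sl)].astype(float)
    return float(np.mean(diff * diff))


def _best_shift(fixed: np.ndarray, moving: np.ndarray, max_shift: int) -> tuple[int, int, int]:
    best, best_msd = (0, 0, 0), np.inf
    window = range(-max_shift, max_shift + 1)
    for shift in itertools.product(window, window, window):
        msd = _overlap_msd(fixed, moving, shift)
        # strict < keeps the lexicographically-first minimiser, which for a
        # symmetric scan ordering prefers the smaller-magnitude shift
        if msd < best_msd - 1e-12 or (
            abs(msd - best_msd) <= 1e-12
            and sum(abs(s) for s in shift) < sum(abs(s) for s in best)
        ):
            best, best_msd = shift, msd
    return best


def align_phases(mv: MultiphaseVolume, max_shift: int = 3) -> MultiphaseVolume:
    """Rigidly align the arterial and portal grids to the unenhanced grid.

    Exhaustive search over integer voxel translations within
    ``[-max_shift, max_shift]`` per axis, minimising the mean squared
    intensity difference on the overlap; the winning translation is applied
    circularly. A deformable method would be needed for real breathing
    motion; an integer rigid shift is sufficient for the rigid phantoms this
    package simulates.

    Warns when a best shift lies on the search-window boundary (the true
    displacement may exceed the window).
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    if max_shift == 0:
        return mv
    aligned = {}
    for name, grid in (("cta", mv.cta), ("ctp", mv.ctp)):
        shift = _best_shift(mv.ctu, grid, max_shift)
        if any(abs(s) == max_shift for s in shift):
            warnings.warn(
                f"best {name} shift {shift} lies on the +/-{max_shift} search "
                "boundary; enlarge max_shift",
                stacklevel=2,
            )
        aligned[name] = np.roll(grid, shift, axis=(0, 1, 2))
    return MultiphaseVolume(mv.ctu, aligned["cta"], aligned["ctp"], mv.voxel_size)


def compute_aef_map(
    mv: MultiphaseVolume,
    epsilon: float = DEFAULT_EPSILON_HU,
    clip_range: tuple[float, float] = DEFAULT_CLIP_RANGE,
) -> AEFMap:
    """Compute the per-voxel AEF map (CTa-CTu)/(CTp-CTu).

    Voxels with portal enhancement <= ``epsilon`` HU are invalid (NaN);
    valid values are clipped into ``clip_range``.
    """
    lo, hi = clip_range
    if not lo < hi:
        raise ValueError(f"clip_range must be increasing, got {clip_range}")
    num = mv.cta.astype(float) - mv.ctu.astype(float)
    den = mv.ctp.astype(float) - mv.ctu.astype(float)
    valid = den > epsilon
    values = np.full(mv.shape, np.nan)
    np.divide(num, den, out=values, where=valid)
    values[valid] = np.clip(values[valid], lo, hi)
    return AEFMap(values=values, valid=valid, epsilon=epsilon, clip_range=clip_range)


def aef_values_in_roi(aef: AEFMap, mask: np.ndarray) -> np.ndarray:
    """Valid AEF values inside a boolean ROI mask (flattened).

    Raises ``ValueError`` when the ROI contains no valid voxel, because every
    downstream statistic would be undefined.
    """
    if mask.shape != aef.shape:
        raise ValueError("ROI mask shape does not match the AEF map")
    sel = mask & aef.valid
    if not sel.any():
        raise ValueError("no valid AEF voxels in ROI")
    return aef.values[sel]
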