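"""The 32 AEF texture features of a lesion ROI.

The lesion ROI is defined on its largest axial plane, mirroring manual
delineation practice; texture is therefore computed in 2-D on that plane.
Four feature families are produced:

* intensity-based statistics (IBS, 11 features) on the raw AEF values;
* intensity-histogram features (IBH, 5) on a uniform-bin histogram;
* grey-level co-occurrence matrix features (GLCM, 6; Haralick);
* grey-level run-length matrix features (GLRLM, 10; Galloway and
  extensions).

Matrix features use a uniform min-max quantization of the ROI's valid AEF
values into ``n_gray_levels`` levels, four 2-D directions at unit distance,
symmetric GLCMs, and per-direction averaging. HaralickCorrelation follows
the ITK convention in which the centring/normalisation terms are the mean
and variance of the *marginal probability vector entries*; this produces the
large (~1e6) magnitudes characteristic of that implementation, unlike the
[-1, 1]-normalised Correlation.

Invalid AEF voxels (non-positive portal enhancement) are excluded: they
break run-length runs and contribute no co-occurrence pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .aef import AEFMap

__all__ = [
    "ROIMask",
    "TextureConfig",
    "GLCMatrix",
    "GLRLMatrix",
    "FeatureVector",
    "FEATURE_NAMES",
    "largest_axial_plane",
    "tumor_area",
    "quantize",
    "intensity_features",
    "glcm",
    "glcm_features",
    "glrlm",
    "glrlm_features",
    "extract_features",
]

IBS_NAMES = (
    "MinIntensity",
    "MaxIntensity",
    "MedianIntensity",
    "MeanValue",
    "StdDeviation",
    "Variance",
    "VolumeCount",
    "VoxelValueSum",
    "Range",
    "MeanDeviation",
    "RelativeDeviation",
)
IBH_NAMES = ("Skewness", "Kurtosis", "Uniformity", "Energy", "Entropy")
GLCM_NAMES = (
    "Inertia",
    "Correlation",
    "InverseDifferenceMoment",
    "ClusterShade",
    "ClusterProminence",
    "HaralickCorrelation",
)
GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GreyLevelNonuniformity",
    "RunLengthNonuniformity",
    "LowGreyLevelRunEmphasis",
    "HighGreyLevelRunEmphasis",
    "ShortRunLowGreyLevelEmphasis",
    "ShortRunHighGreyLevelEmphasis",
    "LongRunLowGreyLevelEmphasis",
    "LongRunHighGreyLevelEmphasis",
)

#: The frozen catalogue of 32 feature names, in reporting order.
FEATURE_NAMES: tuple[str, ...] = IBS_NAMES + IBH_NAMES + GLCM_NAMES + GLRLM_NAMES
assert len(FEATURE_NAMES) == 32

#: 2-D offsets (drow, dcol) for 0, 90, 45 and 135 degrees.
DEFAULT_DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class ROIMask:
    """Boolean lesion mask on the (plane, row, col) grid."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (3.0, 0.8, 0.8)

    def __post_init__(self) -> None:
        if self.mask.ndim != 3:
            raise ValueError("ROI mask must be 3-D")
        if not self.mask.any():
            raise ValueError("ROI mask has no marked voxels")


@dataclass(frozen=True)
class TextureConfig:
    """Discretization and neighbourhood settings for texture features.

    ``n_hist_bins`` (default 256) drives Uniformity/Entropy;
    ``n_gray_levels`` (default 64) drives Energy and the GLCM/GLRLM
    features. The defaults match the magnitudes seen on clinical AEF
    texture reports (Entropy around 6-7 bits, HighGreyLevelRunEmphasis of
    order levels squared).
    """

    n_hist_bins: int = 256
    n_gray_levels: int = 64
    glcm_distance: int = 1
    directions: tuple[tuple[int, int], ...] = DEFAULT_DIRECTIONS
    symmetric_glcm: bool = True

    def __post_init__(self) -> None:
        if self.n_hist_bins < 2:
            raise ValueError("n_hist_bins must be >= 2")
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be >= 2")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")
        for d in self.directions:
            if d not in ((0, 1), (1, 0), (1, 1), (1, -1)):
                raise ValueError(f"unsupported direction {d}")


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized grey-level co-occurrence matrix for one direction."""

    p: np.ndarray
    direction: tuple[int, int]

    def __post_init__(self) -> None:
        if abs(float(self.p.sum()) - 1.0) > 1e-12:
            raise ValueError("GLCM must sum to 1")
        if (self.p < 0).any():
            raise ValueError("GLCM entries must be non-negative")


@dataclass(frozen=True)
class GLRLMatrix:
    """Run-count matrix r[level, run_length] for one direction."""

    r: np.ndarray
    direction: tuple[int, int]

    @property
    def n_runs(self) -> int:
        return int(self.r.sum())


@dataclass(frozen=True)
class FeatureVector:
    """The 32 named texture features for one lesion."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(FEATURE_NAMES)
            raise ValueError(
                f"feature vector must carry exactly the 32 frozen names "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES])


def largest_axial_plane(roi: ROIMask) -> int:
    """Index of the axial plane with the most marked pixels (ties -> lowest)."""
    counts = roi.mask.sum(axis=(1, 2))
    if counts.max() == 0:
        raise ValueError("ROI mask is empty")
    return int(np.argmax(counts))


def tumor_area(roi: ROIMask, plane: int) -> float:
    """In-plane tumor area in cm^2: pixel count x pixel size."""
    count = int(roi.mask[plane].sum())
    if count == 0:
        raise ValueError(f"plane {plane} contains no ROI pixels")
    _, dy, dx = roi.voxel_size
    return count * dy * dx / 100.0


def quantize(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Uniform min-max quantization into integer levels 1..n_levels.

    A constant input maps entirely to level 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to quantize")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    vmin, vmax = float(values.min()), float(values.max())
    if vmax <= vmin:
        return np.ones(values.shape, dtype=np.int64)
    lev = np.floor((values - vmin) / (vmax - vmin) * n_levels).astype(np.int64) + 1
    return np.clip(lev, 1, n_levels)


def _hist_probs(values: np.ndarray, n_bins: int) -> np.ndarray:
    vmin, vmax = float(values.min()), float(values.max())
    if vmax <= vmin:
        return np.array([1.0])
    counts, _ = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    return counts / counts.sum()


def intensity_features(values: np.ndarray, config: TextureConfig) -> dict[str, float]:
    """The 11 IBS + 5 IBH features of the ROI's valid AEF values.

    Moments use the population (n-denominator) convention. Degenerate
    conventions: a constant or single-pixel sample has Skewness = Kurtosis
    = 0, Entropy 0 and Uniformity 1; a zero-mean sample has
    RelativeDeviation 0 by convention (it is sd/mean otherwise).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no valid values in ROI")
    constant = x.max() == x.min()
    # a constant ROI gets exact degenerate values, not round-off residue
    mean = float(x[0]) if constant else float(x.mean())
    sd = 0.0 if constant else float(x.std())
    out: dict[str, float] = {
        "MinIntensity": float(x.min()),
        "MaxIntensity": float(x.max()),
        "MedianIntensity": float(np.median(x)),
        "MeanValue": mean,
        "StdDeviation": sd,
        "Variance": sd * sd,
        "VolumeCount": float(x.size),
        "VoxelValueSum": float(x.sum()),
        "Range": float(x.max() - x.min()),
        "MeanDeviation": float(np.abs(x - mean).mean()),
        "RelativeDeviation": sd / mean if mean != 0 else 0.0,
    }
    if sd <= 1e-12 * max(1.0, abs(mean)):  # constant up to round-off
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    p_hist = _hist_probs(x, config.n_hist_bins)
    p_hist = p_hist[p_hist > 0]
    p_gl = _hist_probs(x, config.n_gray_levels)
    out.update(
        {
            "Skewness": skew,
            "Kurtosis": kurt,
            "Uniformity": float(np.sum(p_hist**2)),
            "Energy": float(np.sum(p_gl**2)),
            "Entropy": float(-np.sum(p_hist * np.log2(p_hist))),
        }
    )
    return out


def glcm(
    levels: np.ndarray, roi2d: np.ndarray, config: TextureConfig
) -> list[GLCMatrix]:
    """Per-direction co-occurrence matrices of a quantized 2-D plane.

    ``levels`` holds integer levels 1..Ng; pixels outside ``roi2d`` (or
    invalid) contribute no pairs. Matrices are symmetrized (when configured)
    and normalized to unit sum. Directions with no valid pair are dropped;
    if none remains an error is raised.
    """
    ng = config.n_gray_levels
    d = config.glcm_distance
    out: list[GLCMatrix] = []
    nr, nc = levels.shape
    for dr, dc in config.directions:
        sr, sc = dr * d, dc * d
        r0 = slice(max(0, -sr), min(nr, nr - sr))
        c0 = slice(max(0, -sc), min(nc, nc - sc))
        a = levels[r0, c0]
        b = levels[max(0, sr) : nr + min(0, sr), max(0, sc) : nc + min(0, sc)]
        ma = roi2d[r0, c0]
        mb = roi2d[max(0, sr) : nr + min(0, sr), max(0, sc) : nc + min(0, sc)]
        sel = ma & mb
        if not sel.any():
            continue
        counts = np.zeros((ng, ng), dtype=float)
        np.add.at(counts, (a[sel] - 1, b[sel] - 1), 1.0)
        if config.symmetric_glcm:
            counts = counts + counts.T
        out.append(GLCMatrix(p=counts / counts.sum(), direction=(dr, dc)))
    if not out:
        raise ValueError("no valid co-occurrence pairs in any direction")
    return out


def glcm_features(matrices: list[GLCMatrix]) -> dict[str, float]:
    """Haralick GLCM features, averaged over directions.

    On a constant plane (all mass at one diagonal cell) the level marginals
    have zero variance; Correlation and HaralickCorrelation are then defined
    as 1.
    """
    if not matrices:
        raise ValueError("need at least one GLCM")
    acc = {name: 0.0 for name in GLCM_NAMES}
    for m in matrices:
        p = m.p
        ng = p.shape[0]
        i = np.arange(1, ng + 1)[:, None]
        j = np.arange(1, ng + 1)[None, :]
        pi = p.sum(axis=1)
        pj = p.sum(axis=0)
        lv = np.arange(1, ng + 1)
        mu_i = float(np.sum(lv * pi))
        mu_j = float(np.sum(lv * pj))
        var_i = float(np.sum((lv - mu_i) ** 2 * pi))
        var_j = float(np.sum((lv - mu_j) ** 2 * pj))
        inertia = float(np.sum((i - j) ** 2 * p))
        idm = float(np.sum(p / (1.0 + (i - j) ** 2)))
        shade = float(np.sum((i + j - mu_i - mu_j) ** 3 * p))
        prom = float(np.sum((i + j - mu_i - mu_j) ** 4 * p))
        sum_ij = float(np.sum(i * j * p))
        if var_i <= 0 or var_j <= 0:
            corr = 1.0
            hcorr = 1.0
        else:
            corr = (sum_ij - mu_i * mu_j) / math.sqrt(var_i * var_j)
            # ITK-style: centre/normalise by the mean and variance of the
            # marginal-probability vector entries, not of the level values
            mm = float(pi.mean())
            mv = float(pi.var())
            hcorr = (sum_ij - mm * mm) / mv if mv > 0 else 1.0
        acc["Inertia"] += inertia
        acc["Correlation"] += corr
        acc["InverseDifferenceMoment"] += idm
        acc["ClusterShade"] += shade
        acc["ClusterProminence"] += prom
        acc["HaralickCorrelation"] += hcorr
    n = len(matrices)
    return {k: v / n for k, v in acc.items()}


def _direction_lines(levels: np.ndarray, roi2d: np.ndarray, direction: tuple[int, int]):
    """Yield (level, in_roi) sequences along each line of a direction."""
    if direction == (0, 1):
        for r in range(levels.shape[0]):
            yield levels[r, :], roi2d[r, :]
    elif direction == (1, 0):
        for c in range(levels.shape[1]):
            yield levels[:, c], roi2d[:, c]
    elif direction == (1, 1):
        nr, nc = levels.shape
        for off in range(-(nr - 1), nc):
            yield np.diagonal(levels, off), np.diagonal(roi2d, off)
    elif direction == (1, -1):
        fl, fm = np.fliplr(levels), np.fliplr(roi2d)
        nr, nc = levels.shape
        for off in range(-(nr - 1), nc):
            yield np.diagonal(fl, off), np.diagonal(fm, off)
    else:  # pragma: no cover - guarded by TextureConfig
        raise ValueError(f"unsupported direction {direction}")


def glrlm(
    levels: np.ndarray, roi2d: np.ndarray, config: TextureConfig
) -> list[GLRLMatrix]:
    """Per-direction run-length matrices of a quantized 2-D plane.

    A run is a maximal sequence of in-ROI pixels sharing one level along a
    direction; out-of-ROI pixels break runs. Each direction conserves
    pixels: sum over the matrix of count x run-length equals the ROI pixel
    count.
    """
    ng = config.n_gray_levels
    lmax = max(levels.shape)
    out: list[GLRLMatrix] = []
    for direction in config.directions:
        r = np.zeros((ng, lmax), dtype=np.int64)
        for line_levels, line_roi in _direction_lines(levels, roi2d, direction):
            run_level, run_len = None, 0
            for lev, inside in zip(line_levels, line_roi):
                if inside and lev == run_level:
                    run_len += 1
                else:
                    if run_len:
                        r[run_level - 1, run_len - 1] += 1
                    run_level, run_len = (int(lev), 1) if inside else (None, 0)
            if run_len:
                r[run_level - 1, run_len - 1] += 1
        out.append(GLRLMatrix(r=r, direction=direction))
    return out


def glrlm_features(matrices: list[GLRLMatrix]) -> dict[str, float]:
    """The ten classical run-length statistics, averaged over directions."""
    mats = [m for m in matrices if m.n_runs > 0]
    if not mats:
        raise ValueError("need at least one run")
    acc = {name: 0.0 for name in GLRLM_NAMES}
    for m in mats:
        r = m.r.astype(float)
        nr = r.sum()
        g = np.arange(1, r.shape[0] + 1)[:, None].astype(float)
        l = np.arange(1, r.shape[1] + 1)[None, :].astype(float)
        rg = r.sum(axis=1)  # per grey level
        rl = r.sum(axis=0)  # per run length
        acc["ShortRunEmphasis"] += float((r / l**2).sum() / nr)
        acc["LongRunEmphasis"] += float((r * l**2).sum() / nr)
        acc["GreyLevelNonuniformity"] += float((rg**2).sum() / nr)
        acc["RunLengthNonuniformity"] += float((rl**2).sum() / nr)
        acc["LowGreyLevelRunEmphasis"] += float((r / g**2).sum() / nr)
        acc["HighGreyLevelRunEmphasis"] += float((r * g**2).sum() / nr)
        acc["ShortRunLowGreyLevelEmphasis"] += float((r / (g**2 * l**2)).sum() / nr)
        acc["ShortRunHighGreyLevelEmphasis"] += float((r * g**2 / l**2).sum() / nr)
        acc["LongRunLowGreyLevelEmphasis"] += float((r * l**2 / g**2).sum() / nr)
        acc["LongRunHighGreyLevelEmphasis"] += float((r * g**2 * l**2).sum() / nr)
    n = len(mats)
    return {k: v / n for k, v in acc.items()}


def extract_features(
    aef: AEFMap, roi: ROIMask, config: TextureConfig | None = None
) -> FeatureVector:
    """Compute the 32-feature vector of one lesion.

    Selects the ROI's largest axial plane, restricts to valid AEF pixels
    there, computes IBS/IBH features on the raw values and GLCM/GLRLM
    features on the quantized plane.
    """
    config = config or TextureConfig()
    if roi.mask.shape != aef.shape:
        raise ValueError("ROI mask shape does not match the AEF map")
    plane = largest_axial_plane(roi)
    roi2d = roi.mask[plane] & aef.valid[plane]
    if not roi2d.any():
        raise ValueError(f"no valid AEF voxels in ROI (plane {plane})")
    plane_vals = aef.values[plane]
    vals = plane_vals[roi2d]

    feats = intensity_features(vals, config)

    levels = np.ones(roi2d.shape, dtype=np.int64)
    lev_in = quantize(vals, config.n_gray_levels)
    levels[roi2d] = lev_in
    try:
        feats.update(glcm_features(glcm(levels, roi2d, config)))
    except ValueError:
        # isolated pixels: no co-occurrence pairs; fall back to the
        # degenerate (homogeneous) conventions
        feats.update(
            {
                "Inertia": 0.0,
                "Correlation": 1.0,
                "InverseDifferenceMoment": 1.0,
                "ClusterShade": 0.0,
                "ClusterProminence": 0.0,
                "HaralickCorrelation": 1.0,
            }
        )
    feats.update(glrlm_features(glrlm(levels, roi2d, config)))
    return FeatureVector(values={name: float(feats[name]) for name in FEATURE_NAMES})
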