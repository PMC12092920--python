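"""Global mammographic radiomic features (GMRFs).

34 features per image: 17 texture/intensity quantities, each computed under
two ROI schemes —

* ``SQ_<Quantity>``: the quantity on the largest square inscribed in the
  breast mask;
* ``ROI_Std_<Quantity>_all``: the quantity per lattice block covering the
  breast, summarised as the standard deviation across blocks.

The 17 quantities are 15 gray-level co-occurrence matrix (GLCM) statistics
(Haralick's 13 classics plus cluster shade and cluster prominence), the
neighbourhood gray-tone difference matrix (NGTDM) coarseness, and the
first-order intensity range. Per-case features are the arithmetic mean of
the four views (LCC, RCC, LMLO, RMLO).

GLCMs are accumulated at distance 1 over the four standard directions
(0, 45, 90, 135 degrees), symmetrised and normalised to sum 1; regions are
min-max quantised (default 64 levels) beforehand, which makes every
GLCM/NGTDM quantity invariant to global intensity shifts. All entropies use
log base 2 with 0*log(0) = 0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import graycomatrix

from .errors import DegenerateROIError
from .images import BreastMask, GrayImage
from .roi import lattice_blocks, largest_inscribed_square

logger = logging.getLogger(__name__)

GLCM_QUANTITIES = (
    "Energy",
    "Contrast",
    "Correlation",
    "Variance",
    "Inverse_difference_moment",
    "Sum_average",
    "Sum_variance",
    "Sum_entropy",
    "Entropy",
    "Difference_variance",
    "Difference_entropy",
    "Info_measure_correlation_1",
    "Info_measure_correlation_2",
    "Cluster_shade",
    "Cluster_prominence",
)
NGTDM_QUANTITIES = ("Coarseness",)
FOS_QUANTITIES = ("Range",)
QUANTITIES = GLCM_QUANTITIES + NGTDM_QUANTITIES + FOS_QUANTITIES

#: the stable 34-name roster, SQ half first, then the lattice (ROI) half
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"SQ_{q}" for q in QUANTITIES] + [f"ROI_Std_{q}_all" for q in QUANTITIES]
)

PLANTED_FEATURES = ("SQ_Cluster_prominence", "ROI_Std_Range_all")
"""The two features the synthetic generator plants a class signal in."""


@dataclass(frozen=True)
class RadiomicsConfig:
    """Knobs of the feature extractor.

    levels: gray levels for GLCM/NGTDM quantisation.
    distance: GLCM pixel-pair offset length.
    block_size / min_coverage: lattice tiling (see :mod:`mammodiff.roi`).
    roi_std_ddof: 1 for the sample SD across lattice blocks (default),
        0 for the population SD.
    """

    levels: int = 64
    distance: int = 1
    block_size: int = 214
    min_coverage: float = 0.5
    roi_std_ddof: int = 1


@dataclass
class GLCM:
    """Normalised, symmetrised co-occurrence matrix over ``levels`` gray levels."""

    matrix: np.ndarray
    levels: int
    distance: int = 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)


@dataclass
class NGTDM:
    """Per-level difference sums ``s`` and pixel counts ``n`` (levels 1..L)."""

    s: np.ndarray
    n: np.ndarray
    levels: int


def quantize(raster: np.ndarray, levels: int = 64) -> np.ndarray:
    """Linear min-max binning of a region's intensities into {1..levels}.

    Bin width is ``(max - min + 1) / levels`` so that an 8-bit full-range
    region with 64 levels gets exactly 4 intensity units per level; a
    constant region maps entirely to level 1.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    raster = np.asarray(raster)
    if raster.size == 0:
        raise ValueError("empty region")
    lo = raster.min()
    hi = raster.max()
    if hi == lo:
        return np.ones(raster.shape, dtype=np.int64)
    q = ((raster.astype(np.float64) - lo) * levels) // (float(hi) - float(lo) + 1.0)
    return q.astype(np.int64) + 1


def compute_glcm(
    q: np.ndarray,
    levels: int,
    distance: int = 1,
    symmetric: bool = True,
) -> GLCM:
    """Co-occurrence matrix at the 4 standard directions, summed and normalised.

    ``q`` is a quantised raster with values in {1..levels}. Pair counts are
    accumulated over all in-raster pixel pairs for offsets at ``distance``
    along 0, 45, 90 and 135 degrees, symmetrised, and normalised to sum 1.
    """
    q = np.asarray(q)
    if q.size < 2:
        raise DegenerateROIError("raster too small for any co-occurring pair")
    counts = graycomatrix(
        (q - 1).astype(np.uint8),
        distances=[distance],
        angles=[0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=levels,
        symmetric=symmetric,
        normed=False,
    )
    total = counts[:, :, 0, :].sum(axis=-1).astype(np.float64)
    s = total.sum()
    if s == 0:
        raise DegenerateROIError("no co-occurring pair at the requested distance")
    return GLCM(matrix=total / s, levels=levels, distance=distance)


def _entropy2(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0*log(0)=0 convention."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def haralick_features(g: GLCM) -> dict[str, float]:
    """The 15 GLCM quantities of :data:`GLCM_QUANTITIES`.

    Gray levels are indexed 1..L. Cluster shade and prominence are the
    third and fourth central co-moments sum((i + j - mu_x - mu_y)^k p(i,j));
    the correlation of a zero-variance GLCM is defined as 0, and the two
    information measures of correlation fall back to 0 when their
    denominators vanish.
    """
    p = g.matrix
    if abs(p.sum() - 1.0) > 1e-8 or (p < 0).any():
        raise ValueError("haralick_features expects a normalised GLCM")
    L = g.levels
    i = np.arange(1, L + 1, dtype=np.float64)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)

    ii = i[:, None]
    jj = i[None, :]
    diff = np.abs(ii - jj)

    # distributions of i+j (support 2..2L) and |i-j| (support 0..L-1)
    p_sum = np.zeros(2 * L + 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    p_diff = np.zeros(L)
    np.add.at(p_diff, diff.astype(int).ravel(), p.ravel())
    k_sum = np.arange(2 * L + 1, dtype=np.float64)
    k_diff = np.arange(L, dtype=np.float64)

    energy = float((p**2).sum())
    contrast = float((diff**2 * p).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        correlation = 0.0
    variance = float((((ii - mu_x) ** 2) * p).sum())
    idm = float((p / (1.0 + diff**2)).sum())
    sum_average = float(k_sum @ p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2) @ p_sum)
    sum_entropy = _entropy2(p_sum)
    entropy = _entropy2(p.ravel())
    diff_mean = float(k_diff @ p_diff)
    diff_variance = float(((k_diff - diff_mean) ** 2) @ p_diff)
    diff_entropy = _entropy2(p_diff)

    hx = _entropy2(px)
    hy = _entropy2(py)
    pxy = np.outer(px, py)
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    hxy2 = _entropy2(pxy.ravel())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    centred = ii + jj - mu_x - mu_y
    cluster_shade = float((centred**3 * p).sum())
    cluster_prominence = float((centred**4 * p).sum())

    return {
        "Energy": energy,
        "Contrast": contrast,
        "Correlation": correlation,
        "Variance": variance,
        "Inverse_difference_moment": idm,
        "Sum_average": sum_average,
        "Sum_variance": sum_variance,
        "Sum_entropy": sum_entropy,
        "Entropy": entropy,
        "Difference_variance": diff_variance,
        "Difference_entropy": diff_entropy,
        "Info_measure_correlation_1": imc1,
        "Info_measure_correlation_2": imc2,
        "Cluster_shade": cluster_shade,
        "Cluster_prominence": cluster_prominence,
    }


def compute_ngtdm(q: np.ndarray, levels: int) -> NGTDM:
    """Neighbourhood gray-tone difference matrix over interior pixels.

    For every pixel whose 3x3 neighbourhood lies fully inside the raster,
    the absolute difference between its level and the mean of its 8
    neighbours is accumulated into ``s`` at that pixel's level; ``n``
    counts interior pixels per level.
    """
    q = np.asarray(q, dtype=np.float64)
    if q.shape[0] < 3 or q.shape[1] < 3:
        raise DegenerateROIError("raster admits no interior pixel for a 3x3 neighbourhood")
    # mean of the 8 neighbours = (3x3 box sum - centre) / 8
    box = ndimage.uniform_filter(q, size=3, mode="constant") * 9.0
    nbr_mean = (box - q) / 8.0
    interior = np.s_[1:-1, 1:-1]
    lvl = q[interior].astype(np.int64).ravel()
    dev = np.abs(q[interior] - nbr_mean[interior]).ravel()
    s = np.bincount(lvl, weights=dev, minlength=levels + 1)[1:]
    n = np.bincount(lvl, minlength=levels + 1)[1:]
    return NGTDM(s=s, n=n.astype(np.int64), levels=levels)


NGTDM_EPS = 1e-6


def ngtdm_features(q: np.ndarray, levels: int) -> dict[str, float]:
    """NGTDM-derived quantities; currently coarseness = 1 / (eps + sum p_i s_i)."""
    m = compute_ngtdm(q, levels)
    total = m.n.sum()
    p_i = m.n / total
    return {"Coarseness": float(1.0 / (NGTDM_EPS + p_i @ m.s))}


def fos_range(raster: np.ndarray) -> float:
    """First-order range: max - min of the raw (unquantised) intensities."""
    raster = np.asarray(raster)
    if raster.size == 0:
        raise ValueError("empty region")
    return float(raster.max() - raster.min())


def region_quantities(raster: np.ndarray, config: RadiomicsConfig) -> dict[str, float]:
    """All 17 quantities for one rectangular region of raw intensities."""
    q = quantize(raster, config.levels)
    out = haralick_features(compute_glcm(q, config.levels, config.distance))
    out.update(ngtdm_features(q, config.levels))
    out["Range"] = fos_range(raster)
    return out


def extract_image_features(
    img: GrayImage,
    mask: BreastMask,
    config: RadiomicsConfig = RadiomicsConfig(),
) -> pd.Series:
    """The 34-feature vector for one preprocessed (flipped, cropped) image.

    SQ half: each quantity once on the largest inscribed square. ROI half:
    each quantity per qualifying lattice block, summarised as the SD across
    blocks (0 with a warning when only one block qualifies).
    """
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    sq = largest_inscribed_square(mask)
    sq_vals = region_quantities(img.pixels[sq.slices()], config)

    blocks = lattice_blocks(mask, config.block_size, config.min_coverage)
    per_block = np.array(
        [list(region_quantities(img.pixels[b.slices()], config).values()) for b in blocks]
    )
    if len(blocks) < 2:
        logger.warning("single lattice block: all ROI_Std features set to 0")
        roi_std = np.zeros(len(QUANTITIES))
    else:
        roi_std = per_block.std(axis=0, ddof=config.roi_std_ddof)

    values = [sq_vals[q] for q in QUANTITIES] + list(roi_std)
    vec = pd.Series(values, index=list(FEATURE_NAMES), dtype=np.float64)
    if not np.isfinite(vec.to_numpy()).all():
        raise ValueError("non-finite feature value extracted")
    return vec


def case_features(vectors: list[pd.Series], case_id: str | None = None) -> pd.Series:
    """Per-case features: the coordinate-wise mean of exactly 4 view vectors."""
    if len(vectors) != 4:
        raise ValueError(f"a case has exactly 4 view images, got {len(vectors)}")
    names = list(vectors[0].index)
    for v in vectors[1:]:
        if list(v.index) != names:
            raise ValueError("feature name sets differ across views")
    out = pd.concat(vectors, axis=1).mean(axis=1)
    out.name = case_id
    return out


@dataclass
class ZScoreParams:
    """Column means/SDs of a fitted z-score transform (for held-out projection)."""

    mean: pd.Series
    std: pd.Series
    constant_columns: list[str] = field(default_factory=list)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = (table - self.mean) / self.std.replace(0.0, 1.0)
        out[self.constant_columns] = 0.0
        return out


def zscore_table(table: pd.DataFrame) -> tuple[pd.DataFrame, ZScoreParams]:
    """Standardise each feature column to mean 0, sample SD 1 across cases.

    Zero-variance columns become all zeros (with a warning). Returns the
    normalised table and the fitted transform parameters.
    """
    if len(table) < 2:
        raise ValueError("z-scoring needs at least 2 cases")
    mean = table.mean(axis=0)
    std = table.std(axis=0, ddof=1)
    constant = list(table.columns[std == 0.0])
    if constant:
        logger.warning("zscore_table: %d constant feature column(s) set to 0", len(constant))
    params = ZScoreParams(mean=mean, std=std, constant_columns=constant)
    return params.transform(table), params
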