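"""3D textural descriptors of a gray-level image inside a tumor mask.

Twenty-eight features in three families:

* gradient (5): mean, variance, skewness, kurtosis and nonzero fraction of
  the 3D gradient magnitude (central differences in physical spacing) over
  in-mask voxels;
* co-occurrence matrix (12): Haralick-family statistics (energy, entropy,
  contrast, homogeneity, correlation, dissimilarity, sum average, sum
  entropy, difference entropy, autocorrelation, cluster shade, cluster
  prominence) of the symmetrized, normalized GLCM accumulated over the 13
  unique 3D direction offsets at distance 1, averaged over directions;
* run-length matrix (11): Galloway-family statistics (SRE, LRE, GLN, RLN,
  RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE) per direction, averaged.

Intensities are quantized to ``levels`` equal-width bins over the in-mask
range, making every feature invariant under affine intensity shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "QuantizedImage",
    "DIRECTIONS_3D",
    "quantize",
    "glcm_matrix",
    "rlm_matrix",
    "glcm_features",
    "rlm_features",
    "gradient_features",
    "compute_texture",
    "GRADIENT_FEATURES",
    "GLCM_FEATURES",
    "RLM_FEATURES",
]

#: the 13 unique direction offsets of the 26-neighborhood (one per +/- pair)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0) or (dz == 0 and (dy, dx) > (0, 0))
)

GRADIENT_FEATURES = (
    "gradient_mean", "gradient_variance", "gradient_skewness",
    "gradient_kurtosis", "gradient_nonzero_fraction",
)
GLCM_FEATURES = (
    "cm_energy", "cm_entropy", "cm_contrast", "cm_homogeneity",
    "cm_correlation", "cm_dissimilarity", "cm_sum_average", "cm_sum_entropy",
    "cm_difference_entropy", "cm_autocorrelation", "cm_cluster_shade",
    "cm_cluster_prominence",
)
RLM_FEATURES = (
    "rlm_sre", "rlm_lre", "rlm_gln", "rlm_rln", "rlm_rp",
    "rlm_lgre", "rlm_hgre", "rlm_srlge", "rlm_srhge", "rlm_lrlge", "rlm_lrhge",
)


@dataclass(frozen=True)
class QuantizedImage:
    """Gray levels binned to [1..levels] inside the mask, 0 outside."""

    levels: int
    quantized: np.ndarray
    intensity_min: float
    intensity_max: float


def quantize(image: np.ndarray, mask: np.ndarray, levels: int = 16) -> QuantizedImage:
    """Equal-width quantization over the in-mask intensity range."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    vals = image[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    lo, hi = float(vals.min()), float(vals.max())
    q = np.zeros(image.shape, dtype=np.int64)
    if hi == lo:
        q[mask] = 1
    else:
        bins = np.clip(
            np.floor((image - lo) / (hi - lo) * levels).astype(np.int64) + 1,
            1, levels,
        )
        q[mask] = bins[mask]
    return QuantizedImage(levels=levels, quantized=q, intensity_min=lo,
                          intensity_max=hi)


def _shifted_views(arr: np.ndarray, offset):
    """Pair of views (a, b) with b displaced by ``offset`` from a."""
    slices_a, slices_b = [], []
    for d, size in zip(offset, arr.shape):
        if d >= 0:
            slices_a.append(slice(0, size - d))
            slices_b.append(slice(d, size))
        else:
            slices_a.append(slice(-d, size))
            slices_b.append(slice(0, size + d))
    return arr[tuple(slices_a)], arr[tuple(slices_b)]


def glcm_matrix(qimg: QuantizedImage, offset) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix for one offset.

    Counts pairs (voxel, voxel + offset) with both members in the mask;
    symmetrization adds the transposed counts, normalization divides by the
    total so the matrix is a probability distribution.
    """
    g = qimg.levels
    a, b = _shifted_views(qimg.quantized, offset)
    valid = (a > 0) & (b > 0)
    av, bv = a[valid] - 1, b[valid] - 1
    counts = np.bincount(av * g + bv, minlength=g * g).reshape(g, g).astype(float)
    counts = counts + counts.T
    total = counts.sum()
    return counts / total if total > 0 else counts


def rlm_matrix(qimg: QuantizedImage, offset) -> np.ndarray:
    """Gray-level run-length matrix for one direction.

    Entry (i, j) counts maximal runs of j+1 consecutive voxels of level
    i+1 along the direction, where a run is bounded by the mask or by a
    level change. Runs are found by walking forward from run-start voxels.
    """
    q = qimg.quantized
    g = qimg.levels
    longest = int(max(q.shape)) * 2  # diagonal runs can exceed one axis
    rlm = np.zeros((g, longest), dtype=float)
    offset = np.asarray(offset, dtype=int)

    # a voxel starts a run when its predecessor (voxel - offset) is outside
    # the array, outside the mask, or a different level
    vox, pred = _shifted_views(q, tuple(-offset))
    sl_vox = []
    for d, size in zip(-offset, q.shape):
        sl_vox.append(slice(0, size - d) if d >= 0 else slice(-d, size))
    inner = np.zeros(q.shape, dtype=bool)
    inner[tuple(sl_vox)] = (vox == pred) & (pred > 0)
    starts = (q > 0) & ~inner

    shape = np.asarray(q.shape)
    for z, y, x in np.argwhere(starts):
        level = q[z, y, x]
        length = 1
        pos = np.array([z, y, x]) + offset
        while np.all(pos >= 0) and np.all(pos < shape) and q[tuple(pos)] == level:
            length += 1
            pos += offset
        rlm[level - 1, length - 1] += 1
    # trim trailing all-zero run-length columns (keep at least one)
    last = max(int(np.nonzero(rlm.sum(axis=0))[0].max()) + 1, 1) if rlm.any() else 1
    return rlm[:, :last]


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """Haralick-family statistics of one normalized GLCM."""
    g = p.shape[0]
    i = np.arange(1, g + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    eps = 1e-12
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    sd_i = float(np.sqrt((((ii - mu_i) ** 2) * p).sum()))
    sd_j = float(np.sqrt((((jj - mu_j) ** 2) * p).sum()))

    # sum (k = i + j) and difference (k = |i - j|) distributions
    psum = np.zeros(2 * g - 1)
    pdiff = np.zeros(g)
    for a in range(g):
        for b in range(g):
            psum[a + b] += p[a, b]
            pdiff[abs(a - b)] += p[a, b]
    ksum = np.arange(2, 2 * g + 1, dtype=float)

    if sd_i * sd_j > 0:
        correlation = float((((ii - mu_i) * (jj - mu_j) * p).sum()) / (sd_i * sd_j))
    else:
        correlation = 1.0
    return {
        "cm_energy": float((p**2).sum()),
        "cm_entropy": float(-(p[p > eps] * np.log2(p[p > eps])).sum()),
        "cm_contrast": float(((ii - jj) ** 2 * p).sum()),
        "cm_homogeneity": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "cm_correlation": correlation,
        "cm_dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "cm_sum_average": float((ksum * psum).sum()),
        "cm_sum_entropy": float(
            -(psum[psum > eps] * np.log2(psum[psum > eps])).sum()
        ),
        "cm_difference_entropy": float(
            -(pdiff[pdiff > eps] * np.log2(pdiff[pdiff > eps])).sum()
        ),
        "cm_autocorrelation": float((ii * jj * p).sum()),
        "cm_cluster_shade": float(((ii + jj - mu_i - mu_j) ** 3 * p).sum()),
        "cm_cluster_prominence": float(((ii + jj - mu_i - mu_j) ** 4 * p).sum()),
    }


def rlm_features(rlm: np.ndarray, n_voxels: int) -> dict[str, float]:
    """Galloway-family statistics of one run-length matrix."""
    nr = rlm.sum()
    if nr == 0:
        return {k: 0.0 for k in RLM_FEATURES}
    g, lmax = rlm.shape
    i = np.arange(1, g + 1, dtype=float)[:, None]      # gray level
    j = np.arange(1, lmax + 1, dtype=float)[None, :]   # run length
    return {
        "rlm_sre": float((rlm / j**2).sum() / nr),
        "rlm_lre": float((rlm * j**2).sum() / nr),
        "rlm_gln": float((rlm.sum(axis=1) ** 2).sum() / nr),
        "rlm_rln": float((rlm.sum(axis=0) ** 2).sum() / nr),
        "rlm_rp": float(nr / n_voxels),
        "rlm_lgre": float((rlm / i**2).sum() / nr),
        "rlm_hgre": float((rlm * i**2).sum() / nr),
        "rlm_srlge": float((rlm / (i**2 * j**2)).sum() / nr),
        "rlm_srhge": float((rlm * i**2 / j**2).sum() / nr),
        "rlm_lrlge": float((rlm * j**2 / i**2).sum() / nr),
        "rlm_lrhge": float((rlm * i**2 * j**2).sum() / nr),
    }


def gradient_features(
    image: np.ndarray, mask: np.ndarray, spacing=(1.0, 1.0, 1.0)
) -> dict[str, float]:
    """Moments of the 3D gradient magnitude over in-mask voxels."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    grads = np.gradient(image, *spacing)
    mag = np.sqrt(sum(g**2 for g in grads))[mask]
    if mag.size == 0:
        raise ValueError("empty mask")
    var = float(mag.var())
    if var > 0:
        skew = float(stats.skew(mag))
        kurt = float(stats.kurtosis(mag))
    else:
        skew, kurt = 0.0, 0.0
    return {
        "gradient_mean": float(mag.mean()),
        "gradient_variance": var,
        "gradient_skewness": skew,
        "gradient_kurtosis": kurt,
        "gradient_nonzero_fraction": float((mag > 0).mean()),
    }


def compute_texture(
    image: np.ndarray,
    mask,
    levels: int = 16,
    spacing=None,
) -> dict[str, float]:
    """All 28 texture features of an intensity image inside a mask.

    ``mask`` may be a boolean array or a :class:`gbmprog.geometry.VoxelMask`
    (its whole-tumor region and spacing are used). GLCM and RLM features are
    averaged over the 13 unique 3D directions.
    """
    from .geometry import VoxelMask

    if isinstance(mask, VoxelMask):
        if spacing is None:
            spacing = mask.spacing
        mask = mask.tumor
    mask = np.asarray(mask, dtype=bool)
    spacing = tuple(spacing) if spacing is not None else (1.0, 1.0, 1.0)
    image = np.asarray(image, dtype=float)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")

    qimg = quantize(image, mask, levels=levels)
    n_voxels = int(mask.sum())

    cm_acc: dict[str, float] = {k: 0.0 for k in GLCM_FEATURES}
    rlm_acc: dict[str, float] = {k: 0.0 for k in RLM_FEATURES}
    for offset in DIRECTIONS_3D:
        for k, v in glcm_features(glcm_matrix(qimg, offset)).items():
            cm_acc[k] += v
        for k, v in rlm_features(rlm_matrix(qimg, offset), n_voxels).items():
            rlm_acc[k] += v
    nd = float(len(DIRECTIONS_3D))
    out = gradient_features(image, mask, spacing)
    out.update({k: v / nd for k, v in cm_acc.items()})
    out.update({k: v / nd for k, v in rlm_acc.items()})
    return out
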