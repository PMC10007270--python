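"""Six image feature descriptors concatenated into a 159-dim vector.

The blocks, in concatenation order:

=================  ======  =====================================================
block              length  summary
=================  ======  =====================================================
color_structure        32  windowed HSV color-presence histogram (8 hue x 2 sat
                           x 2 value bins; 8x8 window, stride 1)
edge_histogram         80  4x4 grid of sub-images, 5-orientation edge histogram
                           from 2x2 pixel blocks
region_shape           35  angular radial transform magnitudes |F(n,m)|,
                           n in {0,1,2}, m in {0..11}, DC-normalized, DC dropped
glcm                    6  gray-level co-occurrence statistics at offset (0,+1)
rgb_mean                3  foreground channel means
column_layout           3  mean foreground luminance of left/middle/right thirds
=================  ======  =====================================================

Histogram-type blocks are count-normalized so they sum to 1 whenever any
color/edge is present.  All blocks except the edge histogram restrict to
foreground (mask) pixels; the edge histogram runs on the whole crop, where
the seed/background boundary itself is the dominant shape cue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

from .imagedata import SeedCrop, crop_seed, load_image, remove_background

__all__ = [
    "BLOCK_INDEX",
    "FEATURE_LENGTH",
    "FeatureVector",
    "GLCMFeatures",
    "color_structure",
    "edge_histogram",
    "region_shape",
    "glcm_features",
    "cooccurrence_stats",
    "rgb_means",
    "column_layout",
    "extract_all",
    "extract_features_table",
    "feature_column_names",
    "save_features_csv",
    "load_features_csv",
]

BLOCK_INDEX: dict[str, tuple[int, int]] = {
    "color_structure": (0, 32),
    "edge_histogram": (32, 80),
    "region_shape": (112, 35),
    "glcm": (147, 6),
    "rgb_mean": (153, 3),
    "column_layout": (156, 3),
}
FEATURE_LENGTH = 159

LUMA = np.array([0.299, 0.587, 0.114])


def _luminance(image: np.ndarray) -> np.ndarray:
    return image.astype(np.float64) @ LUMA


@dataclass(frozen=True)
class FeatureVector:
    """The ordered concatenation of all descriptor blocks."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != (FEATURE_LENGTH,):
            raise ValueError(f"feature vector must have length {FEATURE_LENGTH}")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature vector contains NaN/Inf")
        object.__setattr__(self, "values", values)

    def block(self, name: str) -> np.ndarray:
        off, length = BLOCK_INDEX[name]
        return self.values[off:off + length]


@dataclass(frozen=True)
class GLCMFeatures:
    contrast: float
    dissimilarity: float
    homogeneity: float
    energy: float
    correlation: float
    angular_second_moment: float

    def as_array(self) -> np.ndarray:
        return np.array([
            self.contrast, self.dissimilarity, self.homogeneity,
            self.energy, self.correlation, self.angular_second_moment,
        ])


# ---------------------------------------------------------------------------
# color structure
# ---------------------------------------------------------------------------

CS_WINDOW = 8


def _hsv_bins(image: np.ndarray) -> np.ndarray:
    """Quantize each pixel to one of 32 HSV bins (8 hue x 2 sat x 2 value)."""
    hsv = rgb2hsv(image)
    h = np.minimum((hsv[..., 0] * 8).astype(np.int64), 7)
    s = (hsv[..., 1] >= 0.5).astype(np.int64)
    v = (hsv[..., 2] >= 0.5).astype(np.int64)
    return h * 4 + s * 2 + v


def _box_sums(arr: np.ndarray, size: int) -> np.ndarray:
    """Sums over all size x size windows (stride 1) via an integral image."""
    ii = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=np.float64)
    ii[1:, 1:] = arr.cumsum(axis=0).cumsum(axis=1)
    return (ii[size:, size:] - ii[:-size, size:]
            - ii[size:, :-size] + ii[:-size, :-size])


def color_structure(crop: SeedCrop) -> np.ndarray:
    """Windowed color-presence histogram over 32 HSV bins.

    An 8x8 structuring window slides with stride 1; each window contributes
    one presence count to every bin represented among its foreground
    pixels (a window spanning several colors counts toward each of them).
    The accumulated counts are normalized to sum to 1, so a uniformly
    colored seed puts all mass in a single bin.  Crops smaller than the
    window are padded by edge replication.
    """
    image, mask = crop.image, crop.mask
    if image.shape[0] < CS_WINDOW or image.shape[1] < CS_WINDOW:
        warnings.warn("crop smaller than the 8x8 window; padding by edge replication")
        pr = max(CS_WINDOW - image.shape[0], 0)
        pc = max(CS_WINDOW - image.shape[1], 0)
        image = np.pad(image, ((0, pr), (0, pc), (0, 0)), mode="edge")
        mask = np.pad(mask, ((0, pr), (0, pc)), mode="edge")
    bins = _hsv_bins(image)
    fg_windows = _box_sums(mask.astype(np.float64), CS_WINDOW) > 0.5
    hist = np.zeros(32)
    if not fg_windows.any():
        return hist
    for b in range(32):
        present = _box_sums(((bins == b) & mask).astype(np.float64), CS_WINDOW) > 0.5
        hist[b] = np.count_nonzero(present & fg_windows)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# edge histogram
# ---------------------------------------------------------------------------

EH_THRESHOLD = 11.0
SQRT2 = np.sqrt(2.0)
# 2x2 block filters: vertical, horizontal, 45deg, 135deg, non-directional
EH_FILTERS = np.array([
    [1.0, -1.0, 1.0, -1.0],
    [1.0, 1.0, -1.0, -1.0],
    [SQRT2, 0.0, 0.0, -SQRT2],
    [0.0, SQRT2, -SQRT2, 0.0],
    [2.0, -2.0, -2.0, 2.0],
])


def edge_histogram(crop: SeedCrop, threshold: float = EH_THRESHOLD) -> np.ndarray:
    """Five-orientation local edge histogram over a 4x4 sub-image grid.

    Each sub-image is tiled into non-overlapping 2x2 pixel blocks; a block
    is classified by its strongest filter response when that response
    exceeds ``threshold`` (on the 0-255 intensity scale).  The 16 per-sub-
    image 5-bin histograms are concatenated (row-major sub-images, then
    edge type) and normalized by the total number of counted blocks.
    """
    gray = _luminance(crop.image)
    h, w = gray.shape
    rb = [h * k // 4 for k in range(5)]
    cb = [w * k // 4 for k in range(5)]
    hist = np.zeros((16, 5))
    for si in range(4):
        for sj in range(4):
            sub = gray[rb[si]:rb[si + 1], cb[sj]:cb[sj + 1]]
            bh, bw = sub.shape[0] // 2, sub.shape[1] // 2
            if bh == 0 or bw == 0:
                continue
            blocks = (
                sub[:bh * 2, :bw * 2]
                .reshape(bh, 2, bw, 2)
                .transpose(0, 2, 1, 3)
                .reshape(-1, 4)
            )
            resp = np.abs(blocks @ EH_FILTERS.T)  # (nblocks, 5)
            strongest = resp.argmax(axis=1)
            counted = resp.max(axis=1) > threshold
            for t in range(5):
                hist[si * 4 + sj, t] = np.count_nonzero(counted & (strongest == t))
    total = hist.sum()
    if total > 0:
        hist /= total
    return hist.ravel()


# ---------------------------------------------------------------------------
# region shape (angular radial transform)
# ---------------------------------------------------------------------------

ART_N = 3
ART_M = 12


def region_shape(mask: np.ndarray) -> np.ndarray:
    """ART coefficient magnitudes of the mask, scaled into the unit disk.

    The basis is V_nm(rho, theta) = A_m(theta) R_n(rho) with A_m = e^{j m
    theta} / (2 pi), R_0 = 1, R_n = 2 cos(pi n rho); coefficients are pixel
    sums of conj(V) over the mask mapped so its centroid sits at the origin
    and its farthest pixel at radius 1.  Magnitudes are divided by |F(0,0)|
    and the (identically 1) normalized DC entry is dropped, leaving 35
    translation-, rotation- and scale-invariant values.
    """
    mask = np.asarray(mask, dtype=bool)
    if int(mask.sum()) < 16:
        raise ValueError("degenerate-shape: mask has fewer than 16 pixels")
    ys, xs = np.nonzero(mask)
    y = ys - ys.mean()
    x = xs - xs.mean()
    r = np.hypot(x, y)
    rmax = r.max()
    if rmax == 0:
        raise ValueError("degenerate-shape: zero radius")
    rho = r / rmax
    theta = np.arctan2(y, x)
    coeffs = np.empty((ART_N, ART_M), dtype=np.complex128)
    for n in range(ART_N):
        radial = np.ones_like(rho) if n == 0 else 2.0 * np.cos(np.pi * n * rho)
        for m in range(ART_M):
            angular = np.exp(-1j * m * theta) / (2.0 * np.pi)
            coeffs[n, m] = np.sum(radial * angular)
    mags = np.abs(coeffs)
    mags /= mags[0, 0]
    return np.concatenate([mags[0, 1:], mags[1], mags[2]])


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _quantize(values: np.ndarray, levels: int) -> np.ndarray:
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.zeros(values.shape, dtype=np.int64)
    q = np.floor(levels * (values - vmin) / (vmax - vmin)).astype(np.int64)
    return np.minimum(q, levels - 1)


def cooccurrence_stats(gray: np.ndarray, mask: np.ndarray,
                       levels: int = 8) -> GLCMFeatures:
    """Co-occurrence statistics of a quantized gray image at offset (0,+1).

    The foreground grayscale is min-max quantized to ``levels`` bins;
    horizontally adjacent foreground pairs are accumulated symmetrically
    and normalized to a probability matrix P.  Energy is reported as
    sum(P^2) (no square root), so it coincides with the angular second
    moment; correlation falls back to 0 when either marginal std is 0.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    gray = np.asarray(gray, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    q = np.full(gray.shape, -1, dtype=np.int64)
    q[mask] = _quantize(gray[mask], levels)
    left, right = q[:, :-1], q[:, 1:]
    ok = (left >= 0) & (right >= 0)
    if np.count_nonzero(ok) < 2:
        raise ValueError("fewer than 2 co-occurring foreground pairs")
    P = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(P, (left[ok], right[ok]), 1.0)
    P = P + P.T  # symmetrize
    P /= P.sum()
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    diff = i - j
    contrast = float((P * diff**2).sum())
    dissimilarity = float((P * np.abs(diff)).sum())
    homogeneity = float((P / (1.0 + diff**2)).sum())
    energy = float((P**2).sum())
    pi = P.sum(axis=1)
    mu = (np.arange(levels) * pi).sum()
    var = ((np.arange(levels) - mu) ** 2 * pi).sum()
    if var > 0:
        correlation = float((P * (i - mu) * (j - mu)).sum() / var)
    else:
        correlation = 0.0
    return GLCMFeatures(contrast, dissimilarity, homogeneity, energy,
                        correlation, energy)


def glcm_features(crop: SeedCrop, levels: int = 8) -> GLCMFeatures:
    """Co-occurrence statistics of the crop's foreground luminance."""
    return cooccurrence_stats(_luminance(crop.image), crop.mask, levels)


# ---------------------------------------------------------------------------
# simple foreground statistics
# ---------------------------------------------------------------------------

def rgb_means(crop: SeedCrop) -> np.ndarray:
    """Mean of each channel over foreground pixels, in [0, 255]."""
    return crop.image[crop.mask].mean(axis=0).astype(np.float64)


def column_layout(crop: SeedCrop) -> np.ndarray:
    """Mean foreground luminance of the left/middle/right column thirds.

    Widths follow the floor rule (w//3, w//3, remainder); a third with no
    foreground contributes 0.
    """
    lum = _luminance(crop.image)
    w = crop.image.shape[1]
    t = w // 3
    bounds = [(0, t), (t, 2 * t), (2 * t, w)]
    out = np.zeros(3)
    for k, (c0, c1) in enumerate(bounds):
        m = crop.mask[:, c0:c1]
        if m.any():
            out[k] = lum[:, c0:c1][m].mean()
    return out


# ---------------------------------------------------------------------------
# full vector and batch extraction
# ---------------------------------------------------------------------------

def extract_all(crop: SeedCrop) -> FeatureVector:
    """All six descriptor blocks concatenated in BLOCK_INDEX order."""
    parts = {
        "color_structure": color_structure(crop),
        "edge_histogram": edge_histogram(crop),
        "region_shape": region_shape(crop.mask),
        "glcm": glcm_features(crop).as_array(),
        "rgb_mean": rgb_means(crop),
        "column_layout": column_layout(crop),
    }
    values = np.empty(FEATURE_LENGTH)
    for name, (off, length) in BLOCK_INDEX.items():
        block = np.asarray(parts[name], dtype=np.float64)
        if block.shape != (length,):
            raise ValueError(f"{name} block has wrong length {block.shape}")
        values[off:off + length] = block
    return FeatureVector(values)


def feature_column_names() -> list[str]:
    names = []
    for name, (_, length) in BLOCK_INDEX.items():
        names.extend(f"{name}_{k}" for k in range(length))
    return names


def extract_features_table(
    manifest: pd.DataFrame,
    data_dir,
    bg_threshold: float = 40.0,
    margin: int = 2,
) -> pd.DataFrame:
    """Segment, crop and featurize every manifest row.

    Returns a table with sample_id, the 159 feature columns named
    ``<block>_<k>``, variety, harvest_year and split.
    """
    data_dir = Path(data_dir)
    rows = []
    for rec in manifest.itertuples(index=False):
        image = load_image(data_dir / rec.image_path)
        mask = remove_background(image, threshold=bg_threshold)
        crop = crop_seed(image, mask, margin=margin)
        rows.append(extract_all(crop).values)
    table = pd.DataFrame(np.array(rows), columns=feature_column_names())
    table.insert(0, "sample_id", manifest["sample_id"].to_numpy())
    table["variety"] = manifest["variety"].to_numpy()
    table["harvest_year"] = manifest["harvest_year"].to_numpy()
    table["split"] = manifest["split"].to_numpy()
    return table


def save_features_csv(table: pd.DataFrame, path) -> None:
    """Full-precision serialization: floats survive a round trip bit-exactly."""
    table.to_csv(path, index=False, float_format="%.17g")


def load_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    df["harvest_year"] = df["harvest_year"].astype(int)
    return df
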