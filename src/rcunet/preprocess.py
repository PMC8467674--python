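"""Preprocessing: bicubic resize to the model extent, CLAHE contrast
equalization, and the flip-based training-set doubling.

The resize is the classic cubic-convolution interpolation: every output
value is a weighted sum of a 4x4 neighborhood of source pixels (16
coefficients), with the Catmull-Rom kernel parameter a = -0.5 and
edge-replicated borders. CLAHE equalizes histograms per tile with a clip
limit and blends neighboring tile mappings bilinearly; with a single tile
and no clipping it reduces exactly to global histogram equalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

CUBIC_A = -0.5  # Catmull-Rom cubic-convolution kernel parameter


def cubic_kernel(s: np.ndarray, a: float = CUBIC_A) -> np.ndarray:
    """1-D cubic convolution kernel; the 16 bicubic coefficients are outer
    products of these weights, and they sum to 1 for any sub-pixel offset."""
    s = np.abs(np.asarray(s, dtype=np.float64))
    out = np.zeros_like(s)
    near = s <= 1
    out[near] = (a + 2) * s[near] ** 3 - (a + 3) * s[near] ** 2 + 1
    far = (s > 1) & (s < 2)
    out[far] = a * s[far] ** 3 - 5 * a * s[far] ** 2 + 8 * a * s[far] - 4 * a
    return out


def _resize_matrix(n_src: int, n_dst: int) -> np.ndarray:
    """(n_dst, n_src) weight matrix of 1-D cubic interpolation with
    edge-replicated borders; rows hold the 4 kernel taps."""
    scale = n_src / n_dst
    dst = np.arange(n_dst, dtype=np.float64)
    src = (dst + 0.5) * scale - 0.5
    base = np.floor(src).astype(int)
    t = src - base
    mat = np.zeros((n_dst, n_src))
    for k in range(-1, 3):
        w = cubic_kernel(t - k)
        idx = np.clip(base + k, 0, n_src - 1)
        np.add.at(mat, (dst.astype(int), idx), w)
    return mat


def bicubic_resize(img: np.ndarray,
                   target_extent: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Resize a grayscale image by separable cubic convolution.

    Each output pixel is the 16-coefficient weighted sum over its 4x4
    source neighborhood; output is clamped to [0, 1].
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    th, tw = target_extent
    if th <= 0 or tw <= 0:
        raise ValueError("target extent must be positive")
    wr = _resize_matrix(img.shape[0], th)
    wc = _resize_matrix(img.shape[1], tw)
    return np.clip(wr @ img @ wc.T, 0.0, 1.0)


def nearest_resize(mask: np.ndarray,
                   target_extent: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Nearest-neighbor resize for masks; preserves strict binarity."""
    mask = np.asarray(mask)
    th, tw = target_extent
    sy = mask.shape[0] / th
    sx = mask.shape[1] / tw
    rows = np.clip(np.floor((np.arange(th) + 0.5) * sy), 0,
                   mask.shape[0] - 1).astype(int)
    cols = np.clip(np.floor((np.arange(tw) + 0.5) * sx), 0,
                   mask.shape[1] - 1).astype(int)
    return mask[np.ix_(rows, cols)]


@dataclass(frozen=True)
class ClaheParams:
    clip_limit: float = 2.0       # multiples of the uniform bin count
    tile_grid: tuple[int, int] = (8, 8)
    nbins: int = 256

    def validate(self) -> None:
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be > 0")
        if min(self.tile_grid) < 1:
            raise ValueError("tile counts must be >= 1")


def _tile_mapping(binned: np.ndarray, clip_limit: float, nbins: int) -> np.ndarray:
    """Equalization lookup table (nbins -> [0,1]) for one tile."""
    npix = binned.size
    hist = np.bincount(binned.ravel(), minlength=nbins).astype(np.float64)
    limit = clip_limit * npix / nbins
    if np.isfinite(limit):
        excess = np.maximum(hist - limit, 0.0).sum()
        hist = np.minimum(hist, limit) + excess / nbins
    cdf = np.cumsum(hist)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    if cdf[-1] == cdf_min:  # constant tile: identity mapping
        return np.arange(nbins, dtype=np.float64) / (nbins - 1)
    return np.clip((cdf - cdf_min) / (cdf[-1] - cdf_min), 0.0, 1.0)


def clahe(img: np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0,1] image."""
    params = params or ClaheParams()
    params.validate()
    img = np.asarray(img, dtype=np.float64)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image intensities must lie in [0, 1]")
    if img.max() == img.min():
        logger.info("CLAHE skipped: constant image returned unchanged")
        return img.copy()

    nbins = params.nbins
    binned = np.minimum((img * nbins).astype(int), nbins - 1)
    h, w = img.shape
    tr = min(params.tile_grid[0], h)
    tc = min(params.tile_grid[1], w)
    row_edges = np.linspace(0, h, tr + 1).astype(int)
    col_edges = np.linspace(0, w, tc + 1).astype(int)

    maps = np.empty((tr, tc, nbins))
    for i in range(tr):
        for j in range(tc):
            tile = binned[row_edges[i]:row_edges[i + 1],
                          col_edges[j]:col_edges[j + 1]]
            maps[i, j] = _tile_mapping(tile, params.clip_limit, nbins)

    # bilinear blend of the four surrounding tile mappings per pixel
    centers_y = (row_edges[:-1] + row_edges[1:]) / 2.0
    centers_x = (col_edges[:-1] + col_edges[1:]) / 2.0

    def _coords(pos, centers):
        i1 = np.searchsorted(centers, pos)
        i0 = np.clip(i1 - 1, 0, len(centers) - 1)
        i1 = np.clip(i1, 0, len(centers) - 1)
        span = centers[i1] - centers[i0]
        frac = np.where(span > 0, (pos - centers[i0]) / np.where(span > 0,
                                                                 span, 1.0), 0.0)
        return i0, i1, np.clip(frac, 0.0, 1.0)

    ry0, ry1, fy = _coords(np.arange(h, dtype=np.float64), centers_y)
    cx0, cx1, fx = _coords(np.arange(w, dtype=np.float64), centers_x)

    fy = fy[:, None]
    fx = fx[None, :]
    out = ((1 - fy) * (1 - fx) * maps[ry0[:, None], cx0[None, :], binned]
           + (1 - fy) * fx * maps[ry0[:, None], cx1[None, :], binned]
           + fy * (1 - fx) * maps[ry1[:, None], cx0[None, :], binned]
           + fy * fx * maps[ry1[:, None], cx1[None, :], binned])
    return np.clip(out, 0.0, 1.0)


def hflip(arr: np.ndarray) -> np.ndarray:
    return arr[:, ::-1].copy()


def augment_double(pairs, transform=hflip):
    """Double a training set: originals plus one transformed copy of each,
    with the identical transform applied to image and mask."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cannot augment an empty dataset")
    return pairs + [(transform(img), transform(mask)) for img, mask in pairs]


def crop(img: np.ndarray, box: tuple[int, int, int, int]) -> np.ndarray:
    """Rectangular crop (x0, y0, x1, y1), exclusive upper bounds; used to
    strip manually annotated interference regions (scanner UI, captions)."""
    x0, y0, x1, y1 = box
    if not (0 <= x0 < x1 <= img.shape[1] and 0 <= y0 < y1 <= img.shape[0]):
        raise ValueError(f"crop box {box} outside image {img.shape}")
    return img[y0:y1, x0:x1]


def preprocess_pair(img: np.ndarray, mask: np.ndarray,
                    target_extent: tuple[int, int] = (256, 256),
                    clahe_params: ClaheParams | None = None):
    """Resize (bicubic image / nearest mask) then CLAHE-equalize the image."""
    out_img = clahe(bicubic_resize(img, target_extent), clahe_params)
    out_mask = nearest_resize(np.asarray(mask).astype(bool), target_extent)
    return out_img, out_mask
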