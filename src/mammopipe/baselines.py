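"""Comparator enhancers: HE, CLAHE, and BBHE.

All three operate on 8-bit-scale images quantized to 256 bins and are
intensity-monotone.  HE remaps through floor(cdf * 255).  CLAHE equalizes
clipped tile histograms and blends the tile mappings bilinearly; with one
tile and an infinite clip limit it degenerates to HE.  BBHE splits the
histogram at the mean and equalizes each side onto its own span with a
mid-bin CDF, which preserves the mean of symmetric histograms; a side whose
sub-histogram is constant is left unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np

from .imgio import validate_image

__all__ = ["hist_equalize", "clahe", "bbhe"]


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 255).astype(np.intp)


def _he_lut(counts: np.ndarray) -> np.ndarray:
    cdf = np.cumsum(counts) / max(int(counts.sum()), 1)
    return np.floor(cdf * 255.0)


def hist_equalize(img: np.ndarray) -> np.ndarray:
    """Cumulative-histogram remap over 256 bins onto [0, 255]."""
    img = validate_image(img).astype(np.float64)
    q = _quantize(img)
    counts = np.bincount(q.ravel(), minlength=256)
    return _he_lut(counts)[q].astype(np.float64)


def clahe(
    img: np.ndarray, clip_limit: float = 2.0, tiles: tuple[int, int] = (8, 8)
) -> np.ndarray:
    """Tile-wise clipped-histogram equalization with bilinear blending.

    ``clip_limit`` is a multiple of the tile's mean bin height (np.inf
    disables clipping); clipped excess is redistributed uniformly.
    """
    img = validate_image(img).astype(np.float64)
    if clip_limit <= 0:
        raise ValueError("clip_limit must be > 0")
    t_rows, t_cols = tiles
    h, w = img.shape
    if t_rows < 1 or t_cols < 1:
        raise ValueError("tiles must be >= (1, 1)")
    if t_rows > h or t_cols > w:
        raise ValueError(f"tile grid {tiles} larger than image {img.shape}")
    q = _quantize(img)

    row_edges = np.linspace(0, h, t_rows + 1).round().astype(int)
    col_edges = np.linspace(0, w, t_cols + 1).round().astype(int)
    luts = np.empty((t_rows, t_cols, 256))
    centers_r = np.empty(t_rows)
    centers_c = np.empty(t_cols)
    for i in range(t_rows):
        centers_r[i] = 0.5 * (row_edges[i] + row_edges[i + 1]) - 0.5
        for j in range(t_cols):
            centers_c[j] = 0.5 * (col_edges[j] + col_edges[j + 1]) - 0.5
            tile = q[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            counts = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
            if np.isfinite(clip_limit):
                ceiling = clip_limit * tile.size / 256.0
                excess = np.sum(np.maximum(counts - ceiling, 0.0))
                counts = np.minimum(counts, ceiling) + excess / 256.0
            luts[i, j] = _he_lut(counts)

    # bilinear blend of the four surrounding tile mappings
    rr = np.arange(h, dtype=np.float64)
    cc = np.arange(w, dtype=np.float64)
    i1 = np.clip(np.searchsorted(centers_r, rr), 0, t_rows - 1)
    i0 = np.clip(i1 - 1, 0, t_rows - 1)
    j1 = np.clip(np.searchsorted(centers_c, cc), 0, t_cols - 1)
    j0 = np.clip(j1 - 1, 0, t_cols - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        wr = np.where(
            i1 == i0, 0.0, (rr - centers_r[i0]) / np.where(i1 == i0, 1.0, centers_r[i1] - centers_r[i0])
        )
        wc = np.where(
            j1 == j0, 0.0, (cc - centers_c[j0]) / np.where(j1 == j0, 1.0, centers_c[j1] - centers_c[j0])
        )
    wr = np.clip(wr, 0.0, 1.0)[:, None]
    wc = np.clip(wc, 0.0, 1.0)[None, :]

    i0g, i1g = i0[:, None], i1[:, None]
    j0g, j1g = j0[None, :], j1[None, :]
    v00 = luts[np.broadcast_to(i0g, q.shape), np.broadcast_to(j0g, q.shape), q]
    v01 = luts[np.broadcast_to(i0g, q.shape), np.broadcast_to(j1g, q.shape), q]
    v10 = luts[np.broadcast_to(i1g, q.shape), np.broadcast_to(j0g, q.shape), q]
    v11 = luts[np.broadcast_to(i1g, q.shape), np.broadcast_to(j1g, q.shape), q]
    return (1 - wr) * ((1 - wc) * v00 + wc * v01) + wr * ((1 - wc) * v10 + wc * v11)


def _side_map(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Mid-bin CDF equalization of one histogram side onto [lo, hi]."""
    bins, counts = np.unique(values, return_counts=True)
    if bins.size <= 1:
        return values.astype(np.float64)  # constant side: identity
    n = counts.sum()
    cum = np.cumsum(counts)
    c_mid = (cum - 0.5 * counts) / n
    lut = lo + (hi - lo) * c_mid
    return lut[np.searchsorted(bins, values)]


def bbhe(img: np.ndarray) -> np.ndarray:
    """Brightness-preserving bi-histogram equalization.

    Splits at the mean mu, equalizing values <= mu onto [min, mu] and
    values > mu onto [mu, max] with mid-bin CDFs (the classic two-sided
    remap anchored at the image extremes, which preserves the mean of
    symmetric histograms).
    """
    img = validate_image(img).astype(np.float64)
    q = _quantize(img).astype(np.float64)
    lo, hi = q.min(), q.max()
    if lo == hi:
        warnings.warn("constant image: BBHE is the identity")
        return img.copy()
    mu = q.mean()
    lower = q <= mu
    out = np.empty_like(q)
    out[lower] = _side_map(q[lower], lo, mu)
    out[~lower] = _side_map(q[~lower], mu, hi)
    return out
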