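"""PCA fusion of the three channels into one well-contrasted gray image.

The channels are moved to luminance/chrominance (full-range BT.601 YCbCr)
space, the 3x3 covariance over pixels is eigendecomposed, and the per-pixel
projections onto the eigenvectors are combined with eigenvalue-proportional
weights w_i = lambda_i / sum(lambda).  The result is rescaled to [0, 255].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imgio import ImageRGB, rescale_to_8bit

__all__ = ["EigenDecomposition", "to_ycbcr", "pca_gray", "luminance"]

# full-range BT.601: Y = 0.299 R + 0.587 G + 0.114 B
_KR, _KG, _KB = 0.299, 0.587, 0.114


@dataclass(frozen=True)
class EigenDecomposition:
    """Eigenvalues sorted descending with sign-fixed orthonormal eigenvectors."""

    eigenvalues: np.ndarray   # shape (3,), lambda1 >= lambda2 >= lambda3 >= 0
    eigenvectors: np.ndarray  # shape (3, 3), column i pairs with eigenvalue i

    def __post_init__(self) -> None:
        lam = np.asarray(self.eigenvalues, dtype=np.float64)
        if lam.shape != (3,) or np.any(np.diff(lam) > 1e-12) or lam[-1] < -1e-9:
            raise ValueError(f"eigenvalues must be descending and non-negative: {lam}")
        vec = np.asarray(self.eigenvectors, dtype=np.float64)
        gram = vec.T @ vec
        if not np.allclose(gram, np.eye(3), atol=1e-8):
            raise ValueError("eigenvectors must be orthonormal to 1e-8")

    @property
    def weights(self) -> np.ndarray:
        """Eigenvalue-proportional combination weights (sum to 1)."""
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros(3)
        return self.eigenvalues / total


def to_ycbcr(img: ImageRGB) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full-range BT.601 transform; Cb/Cr offset by 128 and clipped to [0, 255]."""
    img = img.validate()
    r, g, b = (plane.astype(np.float64) for plane in img)
    y = _KR * r + _KG * g + _KB * b
    cb = 128.0 + (b - y) * (0.5 / (1.0 - _KB))
    cr = 128.0 + (r - y) * (0.5 / (1.0 - _KR))
    return (
        np.clip(y, 0.0, 255.0),
        np.clip(cb, 0.0, 255.0),
        np.clip(cr, 0.0, 255.0),
    )


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Orient each eigenvector so its largest-magnitude component is positive.

    Magnitude ties break toward the earliest component, making the map
    deterministic (eigenvectors are otherwise defined only up to sign).
    """
    out = vectors.copy()
    for i in range(out.shape[1]):
        v = out[:, i]
        idx = int(np.argmax(np.abs(v)))  # argmax takes the first index on ties
        if v[idx] < 0:
            out[:, i] = -v
    return out


def eigendecompose(cov: np.ndarray) -> EigenDecomposition:
    """Symmetric 3x3 eigendecomposition, sorted descending, signs fixed."""
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    return EigenDecomposition(lam, _fix_signs(vec[:, order]))


def pca_gray(img: ImageRGB) -> np.ndarray:
    """Fuse three planes into one gray plane by eigenvalue-weighted projection."""
    img = img.validate()
    h, w = img.shape
    if h * w < 2:
        raise ValueError("need at least 2 pixels to estimate the covariance")
    y, cb, cr = to_ycbcr(img)
    data = np.stack([y.ravel(), cb.ravel(), cr.ravel()])  # (3, n)
    centered = data - data.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / data.shape[1]           # 1/n normalization
    eig = eigendecompose(cov)
    if eig.eigenvalues.sum() <= 1e-12:
        warnings.warn("all-constant image: degenerate covariance, returning zeros")
        return np.zeros((h, w))
    projections = eig.eigenvectors.T @ centered           # (3, n)
    gray = (eig.weights[:, None] * projections).sum(axis=0)
    return rescale_to_8bit(gray.reshape(h, w))


def luminance(img: ImageRGB) -> np.ndarray:
    """BT.601 luma plane (baseline gray reduction)."""
    return to_ycbcr(img)[0]
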