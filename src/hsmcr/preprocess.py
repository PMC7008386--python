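"""Spectral-window truncation, AsLS baseline correction, SG smoothing.

The baseline corrector is asymmetric least squares (AsLS): iteratively
reweighted Whittaker smoothing where residuals above the running
baseline get weight ``p`` and residuals below get ``1 - p``, so with
p << 0.5 the smooth curve hugs the lower envelope of the spectrum.  Each
inner step solves the penalized weighted least-squares problem

    z = argmin  sum_i w_i (y_i - z_i)^2  +  lam * sum_i (D2 z)_i^2

exactly via a banded Cholesky solve (the second-difference operator D2
acts on the index grid; the axis is uniform after truncation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from hsmcr.io_cube import SpectralImage

__all__ = [
    "AsLSParams",
    "truncate_range",
    "asls_baseline",
    "correct_image",
    "savgol_smooth",
]


@dataclass(frozen=True)
class AsLSParams:
    """AsLS parameters: smoothness ``lam``, asymmetry ``p``."""

    lam: float = 1e5
    p: float = 1e-3
    max_iter: int = 10
    tol: float = 0.0  # extra weight-change tolerance; 0 = exact stability

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if not (0 < self.p < 1):
            raise ValueError("p must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def truncate_range(image: SpectralImage, lo: float, hi: float) -> SpectralImage:
    """Retain exactly the channels with lo <= wavenumber <= hi."""
    if lo >= hi:
        raise ValueError(f"lo must be < hi, got lo={lo}, hi={hi}")
    keep = (image.axis >= lo) & (image.axis <= hi)
    if not keep.any():
        raise ValueError(
            f"window [{lo}, {hi}] does not overlap axis "
            f"[{image.axis[0]:g}, {image.axis[-1]:g}]"
        )
    meta = dict(image.meta)
    meta["window"] = (float(lo), float(hi))
    return SpectralImage(
        cube=image.cube[:, :, keep].copy(),
        axis=image.axis[keep].copy(),
        mask=image.mask.copy(),
        meta=meta,
    )


def _penalty_banded(n: int, lam: float) -> np.ndarray:
    """Upper-banded form of lam * D2.T @ D2 for solveh_banded (3 bands)."""
    ab = np.zeros((3, n))
    # diagonal of D2'D2 for n >= 5: [1, 5, 6, ..., 6, 5, 1]
    d = np.full(n, 6.0)
    d[0] = d[-1] = 1.0
    if n > 1:
        d[1] = d[-2] = 5.0
    # first off-diagonal: [-2, -4, ..., -4, -2]
    o1 = np.full(n - 1, -4.0)
    o1[0] = o1[-1] = -2.0
    o2 = np.full(n - 2, 1.0)
    ab[2, :] = lam * d
    ab[1, 1:] = lam * o1
    ab[0, 2:] = lam * o2
    return ab


def _whittaker_solve(y: np.ndarray, w: np.ndarray, ab_penalty: np.ndarray) -> np.ndarray:
    ab = ab_penalty.copy()
    ab[2, :] += w
    return solveh_banded(ab, w * y, lower=False)


def asls_baseline(y: np.ndarray, params: AsLSParams = AsLSParams()) -> np.ndarray:
    """Estimate the AsLS baseline of one spectrum.

    Iterates weighted Whittaker solves with weights p above / 1-p below
    the current baseline until the weight vector is stable (or
    ``max_iter``).  The corrected spectrum is ``y - asls_baseline(y)``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 4:
        raise ValueError("y must be a 1-D spectrum with at least 4 channels")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in input spectrum")
    n = y.size
    ab_penalty = _penalty_banded(n, params.lam)
    w = np.ones(n)
    z = y
    for _ in range(params.max_iter):
        z = _whittaker_solve(y, w, ab_penalty)
        w_new = np.where(y > z, params.p, 1.0 - params.p)
        if np.max(np.abs(w_new - w)) <= params.tol:
            break
        w = w_new
    return z


def correct_image(image: SpectralImage, params: AsLSParams = AsLSParams()) -> SpectralImage:
    """Apply AsLS pixelwise to valid pixels; invalid pixels untouched.

    Negative corrected absorbances are kept — non-negativity is a model
    constraint, enforced later in the factorization, not here.
    """
    out = image.copy()
    n = image.n_channels
    if n < 4:
        raise ValueError("image must have at least 4 channels for AsLS")
    ab_penalty = _penalty_banded(n, params.lam)
    rows, cols = image.shape
    for r in range(rows):
        for c in range(cols):
            if not image.mask[r, c]:
                continue
            y = image.cube[r, c]
            try:
                w = np.ones(n)
                z = y
                for _ in range(params.max_iter):
                    z = _whittaker_solve(y, w, ab_penalty)
                    w_new = np.where(y > z, params.p, 1.0 - params.p)
                    if np.max(np.abs(w_new - w)) <= params.tol:
                        break
                    w = w_new
            except Exception as exc:  # re-raise with pixel coordinates
                raise RuntimeError(f"AsLS failed at pixel ({r}, {c}): {exc}") from exc
            out.cube[r, c] = y - z
    out.meta["asls"] = {"lam": params.lam, "p": params.p, "max_iter": params.max_iter}
    return out


def savgol_smooth(y: np.ndarray, window: int = 15, degree: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing with the conventional point-spectrum
    defaults (15-point window, quadratic)."""
    y = np.asarray(y, dtype=float)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if degree >= window:
        raise ValueError(f"degree ({degree}) must be < window ({window})")
    if y.size < window:
        raise ValueError(f"input length {y.size} shorter than window {window}")
    return savgol_filter(y, window_length=window, polyorder=degree)
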