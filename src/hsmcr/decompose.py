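"""Rank estimation, SIMPLISMA initial estimates, and constrained MCR-ALS.

The factorization alternates exact non-negative least-squares updates of
the concentration matrix C (per multiset row) and the pure-spectra
matrix S^T (per channel), with optional correspondence-of-species
zeroing of C blocks for components declared absent in an image, and a
compensated unit-2-norm normalization of the S^T rows every iteration.
Because each half-update is an exact constrained minimizer and the
normalization leaves the product C.S^T unchanged, the lack-of-fit trace
is non-increasing.

All NNLS subproblems in one half-update share a single design matrix,
so they are solved jointly by block principal pivoting with passive-set
grouping (:func:`nnls_multi`) rather than one scipy call per row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.optimize import linear_sum_assignment

from hsmcr.multiset import Multiset

__all__ = [
    "MCRModel",
    "Constraints",
    "nnls_multi",
    "svd_scree",
    "select_rank",
    "simplisma_init",
    "mcr_als_fit",
    "lack_of_fit",
    "estimate_presence",
    "match_components",
    "save_model",
    "load_model",
]


@dataclass
class Constraints:
    """Constraint switches for the ALS optimization."""

    nonneg_C: bool = True
    nonneg_S: bool = True
    normalize_S: bool = True
    correspondence: np.ndarray | None = None  # (n_images, k) presence matrix

    def __post_init__(self) -> None:
        if self.correspondence is not None:
            self.correspondence = np.asarray(self.correspondence, dtype=bool)


@dataclass
class MCRModel:
    """Fitted bilinear model D ~= C @ S_t."""

    C: np.ndarray
    S_t: np.ndarray
    presence: np.ndarray | None
    lof_trace: list[float]
    n_iter: int
    converged: bool
    init_indices: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.S_t.shape[0]

    @property
    def lof(self) -> float:
        return self.lof_trace[-1]


# ---------------------------------------------------------------------------
# Multi-RHS NNLS (shared design matrix), block principal pivoting


def nnls_multi(A: np.ndarray, B: np.ndarray, max_iter: int | None = None, tol: float = 1e-10) -> np.ndarray:
    """Solve min ||A x - b||_2 s.t. x >= 0 for every column b of B.

    All problems share the design matrix ``A`` (m x k), so passive sets
    are tracked per column and columns with identical passive sets are
    solved in one batched normal-equations solve.  Infeasibilities are
    exchanged by block principal pivoting with Murty's single-exchange
    safeguard against cycling.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    squeeze = B.ndim == 1
    if squeeze:
        B = B[:, None]
    if B.shape[0] != A.shape[0]:
        raise ValueError("B row count must equal A row count")
    m, k = A.shape
    n = B.shape[1]
    if max_iter is None:
        max_iter = 5 * k + 20
    AtA = A.T @ A
    AtB = A.T @ B
    scale = max(float(np.abs(AtA).max()), 1.0)
    tol = tol * scale

    P = np.ones((k, n), dtype=bool)  # passive (free) variables
    X = np.zeros((k, n))
    alpha = np.full(n, 3, dtype=int)
    ninf_prev = np.full(n, k + 1, dtype=int)
    active_cols = np.arange(n)

    for _ in range(max_iter):
        _solve_groups(AtA, AtB, P, X, active_cols)
        Y = AtA @ X - AtB  # gradient; dual feasibility needs Y >= 0 on active set
        V = (P & (X < -tol)) | (~P & (Y < -tol))
        ninf = V.sum(axis=0)
        active_cols = np.flatnonzero(ninf > 0)
        if active_cols.size == 0:
            break
        for j in active_cols:
            if ninf[j] < ninf_prev[j]:
                ninf_prev[j] = ninf[j]
                alpha[j] = 3
                P[:, j] ^= V[:, j]
            elif alpha[j] > 0:
                alpha[j] -= 1
                P[:, j] ^= V[:, j]
            else:  # Murty: flip only the highest-index infeasible variable
                i = np.flatnonzero(V[:, j]).max()
                P[i, j] = ~P[i, j]
    np.maximum(X, 0.0, out=X)
    return X[:, 0] if squeeze else X


def _solve_groups(AtA: np.ndarray, AtB: np.ndarray, P: np.ndarray, X: np.ndarray, cols: np.ndarray) -> None:
    """Solve the passive-set normal equations for the given columns,
    grouping columns with identical passive sets."""
    k = AtA.shape[0]
    if cols.size == 0:
        return
    codes = np.zeros(cols.size, dtype=np.int64)
    for i in range(k):
        codes |= P[i, cols].astype(np.int64) << i
    for code in np.unique(codes):
        group = cols[codes == code]
        passive = np.flatnonzero((code >> np.arange(k)) & 1)
        X[:, group] = 0.0
        if passive.size == 0:
            continue
        sub = AtA[np.ix_(passive, passive)]
        rhs = AtB[np.ix_(passive, group)]
        try:
            sol = np.linalg.solve(sub, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(sub, rhs, rcond=None)[0]
        X[np.ix_(passive, group)] = sol


# ---------------------------------------------------------------------------
# Rank estimation


def svd_scree(multiset: Multiset | np.ndarray) -> np.ndarray:
    """Singular values of the augmented data matrix, descending."""
    data = multiset.data if isinstance(multiset, Multiset) else np.asarray(multiset, dtype=float)
    if data.size == 0:
        raise ValueError("empty multiset")
    return np.linalg.svd(data, compute_uv=False)


def select_rank(
    sv: np.ndarray,
    noise_sd: float | None = None,
    method: str = "gap",
    k: int | None = None,
    matrix_shape: tuple[int, int] | None = None,
) -> int:
    """Pick the number of components from a scree of singular values.

    ``gap`` maximizes sv[i-1]/sv[i] over the first half of the scree;
    ``noise_floor`` counts values above the expected top noise singular
    value ``noise_sd * (sqrt(m) + sqrt(n))`` (requires ``matrix_shape``);
    ``manual`` passes ``k`` through.
    """
    sv = np.asarray(sv, dtype=float)
    if np.any(sv < 0) or np.any(np.diff(sv) > 1e-9 * max(sv[0], 1.0)):
        raise ValueError("singular values must be non-negative and descending")
    if method == "manual":
        if k is None:
            raise ValueError("manual method requires k")
        return int(k)
    if method == "gap":
        if sv.size < 2:
            raise ValueError("gap method needs at least 2 singular values")
        upper = max(1, int(np.ceil(sv.size / 2)))
        ratios = np.full(upper, -np.inf)
        for i in range(1, upper + 1):
            lo = sv[i]
            ratios[i - 1] = np.inf if lo == 0 else sv[i - 1] / lo
        return int(np.argmax(ratios)) + 1
    if method == "noise_floor":
        if noise_sd is None or matrix_shape is None:
            raise ValueError("noise_floor method requires noise_sd and matrix_shape")
        m, n = matrix_shape
        floor = noise_sd * (np.sqrt(m) + np.sqrt(n))
        return int(np.sum(sv > floor))
    raise ValueError(f"unknown method {method!r}; choose gap, noise_floor or manual")


# ---------------------------------------------------------------------------
# SIMPLISMA


def simplisma_init(
    multiset: Multiset | np.ndarray, k: int, alpha_pct: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Purest-row initial spectra estimates.

    Purity of row i is sigma_i / (mu_i + alpha) with alpha a fraction of
    the largest row mean; successive selections are down-weighted by the
    determinant of the correlation-around-origin submatrix of already
    selected rows, so near-duplicates of earlier picks score ~0.

    Returns (S0, indices): the k selected spectra clipped at zero and
    scaled to unit 2-norm, and their row indices.
    """
    data = multiset.data if isinstance(multiset, Multiset) else np.asarray(multiset, dtype=float)
    n, m = data.shape
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    mu = data.mean(axis=1)
    sigma = data.std(axis=1)
    alpha = alpha_pct / 100.0 * max(mu.max(), 1e-300)
    purity1 = sigma / (mu + alpha)
    length = np.sqrt(mu**2 + (sigma + alpha) ** 2)
    Z = data / length[:, None]

    rank = np.linalg.matrix_rank(data) if min(n, m) <= 512 else None
    if rank is not None and k > rank:
        warnings.warn(f"requested k={k} exceeds numerical rank {rank}", stacklevel=2)

    selected: list[int] = []
    for _ in range(k):
        if not selected:
            weights = np.ones(n)
        else:
            Zs = Z[selected]  # (q, m)
            q = len(selected)
            Css = (Zs @ Zs.T) / m  # (q, q)
            ci = (Z @ Zs.T) / m  # (n, q)
            cii = np.einsum("ij,ij->i", Z, Z) / m  # (n,)
            mats = np.empty((n, q + 1, q + 1))
            mats[:, 0, 0] = cii
            mats[:, 0, 1:] = ci
            mats[:, 1:, 0] = ci
            mats[:, 1:, 1:] = Css
            weights = np.linalg.det(mats)
        score = weights * purity1
        score[selected] = -np.inf
        selected.append(int(np.argmax(score)))
    S0 = np.clip(data[selected], 0.0, None).astype(float)
    norms = np.linalg.norm(S0, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    S0 = S0 / norms
    return S0, np.asarray(selected)


# ---------------------------------------------------------------------------
# Lack of fit and the ALS loop


def lack_of_fit(D: np.ndarray, C: np.ndarray, S_t: np.ndarray) -> float:
    """Percent unexplained signal: 100 * sqrt(sum(E^2) / sum(D^2))."""
    D = np.asarray(D, dtype=float)
    denom = float(np.sum(D * D))
    if denom == 0:
        raise ValueError("lack of fit undefined for an all-zero data matrix")
    E = D - np.asarray(C) @ np.asarray(S_t)
    return 100.0 * float(np.sqrt(np.sum(E * E) / denom))


def _expand_presence(multiset: Multiset, presence: np.ndarray) -> np.ndarray:
    """Per-row boolean (rows x k) from per-image presence."""
    rows = multiset.n_rows
    k = presence.shape[1]
    out = np.ones((rows, k), dtype=bool)
    for i, image_id in enumerate(multiset.image_ids):
        start, end = multiset.blocks[image_id]
        out[start:end] = presence[i]
    return out


def _update_C(
    D: np.ndarray, S_t: np.ndarray, nonneg: bool, row_presence: np.ndarray | None
) -> np.ndarray:
    rows, k = D.shape[0], S_t.shape[0]
    C = np.zeros((rows, k))
    if row_presence is None:
        patterns = [np.ones(k, dtype=bool)]
        groups = [np.arange(rows)]
    else:
        uniq, inverse = np.unique(row_presence, axis=0, return_inverse=True)
        patterns = [u.astype(bool) for u in uniq]
        groups = [np.flatnonzero(inverse == g) for g in range(len(uniq))]
    for pat, rows_g in zip(patterns, groups):
        if not pat.any() or rows_g.size == 0:
            continue
        A = S_t[pat].T  # (channels, k_present)
        B = D[rows_g].T  # (channels, n_rows_g)
        if nonneg:
            sol = nnls_multi(A, B)
        else:
            sol = np.linalg.lstsq(A, B, rcond=None)[0]
        C[np.ix_(rows_g, np.flatnonzero(pat))] = sol.T
    return C


def _update_S(D: np.ndarray, C: np.ndarray, nonneg: bool, S_prev: np.ndarray) -> np.ndarray:
    k = C.shape[1]
    live = np.linalg.norm(C, axis=0) > 0
    S_t = S_prev.copy()
    if not live.any():
        return S_t
    A = C[:, live]
    if nonneg:
        sol = nnls_multi(A, D)  # (k_live, channels)
    else:
        sol = np.linalg.lstsq(A, D, rcond=None)[0]
    S_t[live] = sol
    return S_t


def mcr_als_fit(
    multiset: Multiset,
    S0: np.ndarray,
    constraints: Constraints = Constraints(),
    tol: float = 0.1,
    max_iter: int = 50,
) -> MCRModel:
    """Constrained alternating least squares on the augmented matrix.

    Per iteration: exact (NN)LS update of C against the current S^T with
    correspondence-absent components excluded from each block's design;
    exact (NN)LS update of S^T against the new C; compensated unit-norm
    rescaling of the S^T rows; LOF appended.  Stops when the relative
    LOF change drops below ``tol`` percent of the previous LOF, or at
    ``max_iter``.
    """
    D = multiset.data
    S_t = np.asarray(S0, dtype=float).copy()
    if S_t.ndim != 2:
        raise ValueError("S0 must be 2-D (k x channels)")
    k, channels = S_t.shape
    if channels != multiset.n_channels:
        raise ValueError(f"S0 channel count {channels} != multiset channels {multiset.n_channels}")
    if k > channels:
        raise ValueError(f"k={k} exceeds channel count {channels}")
    zero_rows = np.flatnonzero(np.linalg.norm(S_t, axis=1) == 0)
    if zero_rows.size:
        raise ValueError(f"S0 contains zero row(s) at indices {zero_rows.tolist()}")

    presence = None
    row_presence = None
    if constraints.correspondence is not None:
        presence = np.asarray(constraints.correspondence, dtype=bool)
        n_images = len(multiset.blocks)
        if presence.shape != (n_images, k):
            raise ValueError(
                f"correspondence shape {presence.shape} != ({n_images}, {k})"
            )
        row_presence = _expand_presence(multiset, presence)

    lof_trace: list[float] = []
    converged = False
    n_iter = 0
    C = np.zeros((D.shape[0], k))
    for n_iter in range(1, max_iter + 1):
        C = _update_C(D, S_t, constraints.nonneg_C, row_presence)
        S_t = _update_S(D, C, constraints.nonneg_S, S_t)
        if constraints.normalize_S:
            norms = np.linalg.norm(S_t, axis=1)
            nz = norms > 0
            S_t[nz] /= norms[nz, None]
            C[:, nz] *= norms[nz]
        lof_trace.append(lack_of_fit(D, C, S_t))
        if len(lof_trace) >= 2:
            prev, cur = lof_trace[-2], lof_trace[-1]
            if prev <= 1e-12 or abs(prev - cur) / prev * 100.0 < tol:
                converged = True
                break
        elif lof_trace[-1] <= 1e-12:
            converged = True
            break
    return MCRModel(
        C=C,
        S_t=S_t,
        presence=presence,
        lof_trace=lof_trace,
        n_iter=n_iter,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Presence estimation and component matching


def estimate_presence(
    model: MCRModel, multiset: Multiset, rel_threshold: float = 0.01
) -> np.ndarray:
    """Automate the map-inspection step that flags absent components.

    A component counts as present in an image when its mean
    concentration over that image's block reaches ``rel_threshold``
    times the largest per-image mean of that component.  Every image is
    guaranteed at least one present component.
    """
    ids = multiset.image_ids
    k = model.k
    means = np.zeros((len(ids), k))
    for i, image_id in enumerate(ids):
        start, end = multiset.blocks[image_id]
        means[i] = model.C[start:end].mean(axis=0)
    col_max = means.max(axis=0)
    col_max[col_max == 0] = 1.0
    presence = means >= rel_threshold * col_max
    for i in range(len(ids)):
        if not presence[i].any():
            presence[i, int(np.argmax(means[i]))] = True
    return presence


def match_components(
    estimated: MCRModel | np.ndarray, truth_spectra: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one matching of estimated to true spectra.

    Returns (perm, corrs): ``perm[j]`` is the estimated component
    assigned to true component ``j``; ``corrs[j]`` the Pearson
    correlation of that pair.  Assignment maximizes total correlation
    (Hungarian algorithm) and is deterministic.
    """
    S_est = estimated.S_t if isinstance(estimated, MCRModel) else np.asarray(estimated, dtype=float)
    S_true = np.asarray(truth_spectra, dtype=float)
    if S_est.shape[0] != S_true.shape[0]:
        raise ValueError(f"component count mismatch: {S_est.shape[0]} vs {S_true.shape[0]}")
    k = S_true.shape[0]
    corr = np.zeros((k, k))
    for j in range(k):
        for i in range(k):
            corr[j, i] = _pearson(S_true[j], S_est[i])
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return perm, corr[np.arange(k), perm]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# Model I/O


def save_model(model: MCRModel, path: str) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("C", data=model.C)
        fh.create_dataset("S_t", data=model.S_t)
        fh.create_dataset("lof_trace", data=np.asarray(model.lof_trace))
        if model.presence is not None:
            fh.create_dataset("presence", data=model.presence)
        fh.attrs["n_iter"] = model.n_iter
        fh.attrs["converged"] = model.converged


def load_model(path: str) -> MCRModel:
    with h5py.File(path, "r") as fh:
        return MCRModel(
            C=fh["C"][()],
            S_t=fh["S_t"][()],
            presence=fh["presence"][()].astype(bool) if "presence" in fh else None,
            lof_trace=list(fh["lof_trace"][()]),
            n_iter=int(fh.attrs["n_iter"]),
            converged=bool(fh.attrs["converged"]),
        )
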