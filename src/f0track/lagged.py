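"""Lagged (convolutional) regression designs and their normal equations.

Both the forward encoding model and the backward decoder are ridge
regressions on time-lagged copies of a small set of series (stimulus
features or EEG channels).  The design matrix for ``T`` lags of ``q``
series has ``q*T`` columns; rows are restricted to time samples where
every lag is in bounds (no zero padding).

For long recordings materializing the design is wasteful, so the Gram
matrix ``X.T @ X`` and cross products ``X.T @ Y`` are computed exactly
from the raw series: the first rows of the series-pair blocks come from
small matrix products over shifted slices and the remaining entries
follow a sliding-window recursion along the diagonals.  The result is bit-for-bit the same sums
as the explicit design (verified in the test suite), at a cost linear in
the recording length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LagGrid:
    """Uniform grid of time lags, in milliseconds, at sampling rate ``fs``.

    The sign convention: a lag tau > 0 means the response sample at time
    ``t`` is explained by the driving series at ``t - tau`` (the driver
    precedes the response); negative lags are anticausal.
    """

    lag_min_ms: float
    lag_max_ms: float
    fs: float

    def __post_init__(self) -> None:
        if self.lag_max_ms <= self.lag_min_ms:
            raise ValueError("lag_max_ms must exceed lag_min_ms")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_lags(self) -> int:
        return int(round((self.lag_max_ms - self.lag_min_ms) * self.fs / 1000.0)) + 1

    @property
    def lags_samples(self) -> np.ndarray:
        start = int(round(self.lag_min_ms * self.fs / 1000.0))
        return start + np.arange(self.n_lags)

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags_samples * 1000.0 / self.fs


FORWARD_LAGS = LagGrid(-250.0, 499.0, 1000.0)   # 750 lags
BACKWARD_LAGS = LagGrid(-5.0, 49.0, 1000.0)     # 55 lags


def _valid_bounds(n: int, lags: np.ndarray) -> tuple[int, int]:
    """First and last response sample index with all lags in bounds."""
    t_start = max(int(lags.max()), 0)
    t_end = min(n - 1, n - 1 + int(lags.min()))
    if t_end < t_start:
        raise ValueError(
            f"recording of {n} samples is shorter than the lag span "
            f"({lags.min()}..{lags.max()} samples)"
        )
    return t_start, t_end


def valid_slice(n: int, lags: np.ndarray) -> slice:
    t_start, t_end = _valid_bounds(n, lags)
    return slice(t_start, t_end + 1)


def build_lagged_design(Z: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Explicit lagged design matrix (series-major column order).

    Column ``c * T + i`` holds series ``c`` delayed by ``lags[i]``
    samples.  Rows run over the valid samples only.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] < Z.shape[1]:
        raise ValueError("Z must be (n_samples, n_series)")
    n, q = Z.shape
    lags = np.asarray(lags, dtype=int)
    T = lags.size
    t_start, t_end = _valid_bounds(n, lags)
    n_valid = t_end - t_start + 1
    X = np.empty((n_valid, q * T))
    for c in range(q):
        for i, tau in enumerate(lags):
            X[:, c * T + i] = Z[t_start - tau : t_end + 1 - tau, c]
    return X


def _first_rows(Z: np.ndarray, u0: int, u1: int, T: int) -> np.ndarray:
    """First rows of all Gram blocks at once.

    Returns R with ``R[j, c1, c2] = sum_u Z[u, c1] * Z[u - j, c2]`` for
    ``u`` in [u0, u1] — one small matrix product per shift.
    """
    A = Z[u0 : u1 + 1]
    q = Z.shape[1]
    R = np.empty((T, q, q))
    for j in range(T):
        R[j] = A.T @ Z[u0 - j : u1 + 1 - j]
    return R


def lagged_gram(Z: np.ndarray, lags: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact ``X.T @ X`` of the lagged design, without materializing X.

    Returns the Gram matrix and the number of valid rows.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n, q = Z.shape
    lags = np.asarray(lags, dtype=int)
    T = lags.size
    t_start, t_end = _valid_bounds(n, lags)
    n_valid = t_end - t_start + 1
    tau0 = int(lags[0])
    u0, u1 = t_start - tau0, t_end - tau0

    G = np.empty((q * T, q * T))
    idx = np.arange(T - 1)
    R = _first_rows(Z, u0, u1, T)
    for c1 in range(q):
        a = Z[:, c1]
        for c2 in range(q):
            b = Z[:, c2]
            block = np.empty((T, T))
            block[0, :] = R[:, c1, c2]
            # fill upper diagonals d = j - i >= 0 by the shift recursion
            for d in range(T - 1):
                i_arr = idx[: T - 1 - d]
                s = u0 - 1 - i_arr
                e = u1 - i_arr
                delta = a[s] * b[s - d] - a[e] * b[e - d]
                block[i_arr + 1, i_arr + 1 + d] = block[0, d] + np.cumsum(delta)
            G[c1 * T : (c1 + 1) * T, c2 * T : (c2 + 1) * T] = block
    # sub-diagonal entries of block (c1, c2) are the upper-diagonal
    # entries of block (c2, c1), by symmetry of the full Gram
    low = np.tril_indices(T, k=-1)
    for c1 in range(q):
        for c2 in range(q):
            blk = G[c1 * T : (c1 + 1) * T, c2 * T : (c2 + 1) * T]
            blk_t = G[c2 * T : (c2 + 1) * T, c1 * T : (c1 + 1) * T]
            blk[low] = blk_t.T[low]
    return G, n_valid


def lagged_cross(Z: np.ndarray, lags: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Exact ``X.T @ Y`` with Y given over the full recording (n, m)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, q = Z.shape
    if Y.shape[0] != n:
        raise ValueError("Z and Y must cover the same samples")
    lags = np.asarray(lags, dtype=int)
    T = lags.size
    t_start, t_end = _valid_bounds(n, lags)
    n_valid = t_end - t_start + 1
    tau0 = int(lags[0])
    u0 = t_start - tau0

    C = np.empty((q * T, Y.shape[1]))
    Yv = Y[t_start : t_end + 1]
    for i in range(T):
        # column block for lag index i across all series at once
        C[i::T, :] = Z[u0 - i : u0 - i + n_valid].T @ Yv
    return C


def mean_eigenvalue(G: np.ndarray, n_valid: int) -> float:
    """Mean eigenvalue of the design covariance, trace(X'X / n) / p."""
    p = G.shape[0]
    return float(np.trace(G)) / (n_valid * p)


def solve_ridge(
    G: np.ndarray,
    C: np.ndarray,
    n_valid: int,
    lambda_ns: np.ndarray | list[float] | float,
) -> tuple[np.ndarray, float]:
    """Solve (X'X + lambda_n * e_m * I) B = X'Y for one or many lambda_n.

    Returns coefficients of shape (n_lambda, p, m) (squeezed to (p, m)
    for a scalar lambda_n) and the mean eigenvalue e_m.
    """
    scalar = np.isscalar(lambda_ns)
    lam = np.atleast_1d(np.asarray(lambda_ns, dtype=float))
    if lam.size == 0:
        raise ValueError("empty lambda grid")
    if np.any(lam < 0):
        raise ValueError("lambda_n must be nonnegative")
    em = mean_eigenvalue(G, n_valid)
    w, V = np.linalg.eigh(G)
    VtC = V.T @ C
    out = np.empty((lam.size, G.shape[0], C.shape[1]))
    for k, ln in enumerate(lam):
        denom = w + ln * em
        # guard exact singularity at lambda 0
        denom = np.where(np.abs(denom) < 1e-12 * max(w.max(), 1.0), np.inf, denom)
        out[k] = V @ (VtC / denom[:, None])
    if scalar:
        return out[0], em
    return out, em


def standardize(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Zero-mean, unit-sd standardization (sd of zero left untouched)."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd
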