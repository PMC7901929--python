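"""Reference linear RSA estimator by orthogonal subspace projection.

HRV is projected onto the column space of a time-delay embedding of the
respiration; the retained variance fraction Px = (yr'yr)/(y'y) quantifies the
linearly respiration-driven part of the HRV.  The projection matrix is
conceptually P = Q (Q'Q)^-1 Q', but the projection is computed with a
least-squares factorization rather than the explicit inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import UniformSignal

__all__ = ["Subspace", "build_embedding", "project"]


@dataclass
class Subspace:
    """Time-delay embedding of respiration: row n holds [x(n-1), ..., x(n-L)].

    Rows are aligned with HRV indices L .. N-1, so every regressor is a
    strictly past respiration sample.
    """

    Q: np.ndarray
    L: int
    lag_set: list[int]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.Q)):
            raise ValueError("embedding contains non-finite entries")


def build_embedding(resp: UniformSignal | np.ndarray, L: int) -> Subspace:
    """Embed the respiration with lags 1..L.

    Parameters
    ----------
    resp : UniformSignal or ndarray
        Respiration samples.
    L : int
        Embedding order; must satisfy 1 <= L <= len(resp) - 1 so at least one
        usable row remains (L = len-1 yields a single row).
    """
    x = resp.samples if isinstance(resp, UniformSignal) else np.asarray(resp, float)
    n = len(x)
    if not isinstance(L, (int, np.integer)) or L < 1:
        raise ValueError("L must be a positive integer")
    if L >= n:
        raise ValueError(f"L={L} too large for a series of length {n}")
    # column j (0-based) holds lag j+1: x[L-1-j : n-1-j]
    Q = np.column_stack([x[L - 1 - j : n - 1 - j] for j in range(L)])
    return Subspace(Q=Q, L=int(L), lag_set=list(range(1, L + 1)))


def project(sub: Subspace, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Orthogonal projection of y onto the embedding's column space.

    Both y and the columns of Q are mean-centered first, so Px is a variance
    (not raw power) fraction.  Rank-deficient embeddings (e.g. a constant
    respiration) fall back to the minimum-norm least-squares solution and are
    flagged.

    Returns
    -------
    yr : ndarray
        Projection of centered y, re-offset by the mean of y.
    px : float
        Variance fraction (yr_c'yr_c)/(y_c'y_c), in [0, 1].
    rank_deficient : bool
        True when Q (centered) had column rank < L.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (sub.Q.shape[0],):
        raise ValueError("length of y must equal rows of Q")
    y_mean = y.mean()
    yc = y - y_mean
    ss_y = float(yc @ yc)
    if ss_y == 0.0:
        raise ValueError("y is constant; Px is undefined")
    Qc = sub.Q - sub.Q.mean(axis=0)
    beta, _, rank, _ = np.linalg.lstsq(Qc, yc)
    yr_c = Qc @ beta
    # projection guarantees px in [0, 1]; clip only roundoff overshoot
    px = float(np.clip(float(yr_c @ yr_c) / ss_y, 0.0, 1.0))
    return yr_c + y_mean, px, rank < sub.Q.shape[1]
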