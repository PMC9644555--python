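"""Signed adjacency and topological overlap from a correlation matrix.

The signed soft-threshold transform A_ij = ((1 + r_ij)/2)^beta keeps
positive and negative correlations distinguishable (r = -1 maps to 0,
r = +1 to 1) instead of folding them together as |r| would.  The
topological overlap matrix (TOM) then rewards pairs that share neighbours,

    TOM_ij = (sum_{u != i,j} A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij),

damping spurious one-off links; 1 - TOM is the dissimilarity fed to
hierarchical clustering.

beta defaults to 2: compositional basis correlations are weaker and
sparser than gene-expression correlations, so the conventional expression
default of 12 would annihilate the network.  A scale-free-fit diagnostic
is provided for choosing beta, but it is never auto-picked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TomMatrices",
    "signed_adjacency",
    "tom_similarity",
    "tom_dissimilarity",
    "build_tom",
    "scale_free_fit",
]


@dataclass
class TomMatrices:
    """Adjacency, TOM, dissimilarity and connectivity for one condition."""

    adjacency: np.ndarray
    beta: float
    tom: np.ndarray
    dissim: np.ndarray
    connectivity: np.ndarray

    def __post_init__(self) -> None:
        for name in ("adjacency", "tom", "dissim"):
            m = getattr(self, name)
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError(f"{name} must be symmetric")
        if np.any((self.tom < -1e-12) | (self.tom > 1 + 1e-12)):
            raise ValueError("TOM entries must lie in [0, 1]")
        if not np.allclose(self.dissim, 1.0 - self.tom):
            raise ValueError("dissim must equal 1 - TOM exactly")


def signed_adjacency(r: np.ndarray, beta: float = 2.0, clip_negative_r: bool = False) -> np.ndarray:
    """Signed soft-threshold adjacency A_ij = ((1 + r_ij)/2)^beta, unit diagonal.

    ``clip_negative_r`` zeroes negative correlations before the transform,
    for the reading of "focus on positive correlations" in which negatives
    are discarded outright rather than down-weighted.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    r = np.asarray(r, dtype=float)
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if np.any(np.abs(r) > 1 + 1e-10):
        raise ValueError("|r| must be <= 1")
    if clip_negative_r:
        r = np.maximum(r, 0.0)
    a = ((1.0 + np.clip(r, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def tom_similarity(a: np.ndarray) -> np.ndarray:
    """Topological overlap of a symmetric adjacency in [0, 1], unit diagonal.

    Matrix form: sum_{u != i,j} A_iu A_uj = (A @ A)_ij - A_ii A_ij - A_ij A_jj
    = (A @ A)_ij - 2 A_ij for unit-diagonal A.  A fully isolated pair
    (k_i = k_j = 0, A_ij = 0) gets TOM_ij = 0 by the guard.
    """
    a = np.asarray(a, dtype=float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.any((a < -1e-12) | (a > 1 + 1e-12)):
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0):
        raise ValueError("adjacency must have unit diagonal")
    k = a.sum(axis=0) - 1.0  # connectivity excludes the diagonal
    shared = a @ a - 2.0 * a  # sum over common neighbours u != i, j
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 1e-12, numer / denom, 0.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    np.fill_diagonal(tom, 1.0)
    tom = (tom + tom.T) / 2.0  # symmetrize fp noise
    return tom


def tom_dissimilarity(tom: np.ndarray) -> np.ndarray:
    """Elementwise 1 - TOM; zero diagonal."""
    return 1.0 - np.asarray(tom, dtype=float)


def build_tom(r: np.ndarray, beta: float = 2.0, clip_negative_r: bool = False) -> TomMatrices:
    """Correlation matrix -> (adjacency, TOM, dissimilarity, connectivity)."""
    a = signed_adjacency(r, beta=beta, clip_negative_r=clip_negative_r)
    tom = tom_similarity(a)
    return TomMatrices(
        adjacency=a,
        beta=float(beta),
        tom=tom,
        dissim=tom_dissimilarity(tom),
        connectivity=a.sum(axis=0) - 1.0,
    )


def scale_free_fit(a: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log degree-distribution fit (scale-free diagnostic).

    Provided to help users judge a beta choice; the pipeline never uses it
    to pick beta automatically.
    """
    k = np.asarray(a).sum(axis=0) - 1.0
    k = k[k > 0]
    if k.size < 2:
        return 0.0
    hist, edges = np.histogram(k, bins=min(n_bins, max(2, k.size // 2)))
    centers = (edges[:-1] + edges[1:]) / 2.0
    keep = hist > 0
    if keep.sum() < 2:
        return 0.0
    x = np.log10(centers[keep])
    y = np.log10(hist[keep] / hist.sum())
    resid = y - np.poly1d(np.polyfit(x, y, 1))(x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
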