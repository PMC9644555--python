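"""SparCC basis correlations for compositional count data.

Relative-abundance (compositional) data make naive correlations between
taxa spurious: the unit-sum constraint induces negative bias everywhere.
SparCC instead estimates correlations between latent *basis* (absolute)
log-abundances from the pairwise log-ratio variances

    t_ij = Var_s( log(x_si / x_sj) ) = w_i + w_j - 2 r_ij sqrt(w_i w_j),

where w_i is the basis variance of taxon i.  Under the sparsity
approximation (sum_j r_ij ~ 0) the basis variances have a closed-form
linear solve, after which r_ij follows directly.  Strongly correlated
pairs violate the sparsity assumption, so the strongest pair is removed
from the system and the solve repeated, a few rounds deep.

Statistical significance comes from an empirical permutation null: each
taxon's counts are independently shuffled across samples, destroying all
taxa-taxa association while preserving marginals, and the observed |r| is
compared to the null |r| distribution.  Benjamini-Hochberg adjustment is
applied to the upper-triangle p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CorrelationEstimate",
    "estimate_fractions",
    "basis_correlations",
    "sparcc",
    "bootstrap_pvalues",
    "bh_adjust",
    "estimate_correlations",
]


@dataclass
class CorrelationEstimate:
    """SparCC correlation matrix with bootstrap p-values and BH q-values.

    Attributes
    ----------
    r : (p, p) ndarray
        Symmetric basis-correlation estimate, unit diagonal, entries in [-1, 1].
    p : (p, p) ndarray
        Two-sided permutation p-values in (0, 1]; diagonal set to 1.
    q : (p, p) ndarray
        BH-adjusted p-values (adjustment over the p*(p-1)/2 upper-triangle
        tests, mirrored).
    n_bootstraps : int
    seed : int | None
    basis_variances : (p,) ndarray
        Estimated basis variances w_i (diagnostic).
    taxa : list[str] | None
        Optional taxon identifiers aligned with the matrix axes.
    """

    r: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_bootstraps: int
    seed: int | None
    basis_variances: np.ndarray
    taxa: list[str] | None = None

    def __post_init__(self) -> None:
        for name in ("r", "p", "q"):
            m = getattr(self, name)
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError(f"{name} matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0):
            raise ValueError("r must have unit diagonal")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("|r| must be <= 1")
        if np.any(self.q + 1e-12 < self.p):
            raise ValueError("q must dominate p elementwise")

    def edge_table(self):
        """Long-format upper-triangle edge table (taxon_a, taxon_b, r, p, q)."""
        import pandas as pd

        n = self.r.shape[0]
        names = self.taxa if self.taxa is not None else [str(i) for i in range(n)]
        iu, ju = np.triu_indices(n, k=1)
        return pd.DataFrame(
            {
                "taxon_a": [names[i] for i in iu],
                "taxon_b": [names[j] for j in ju],
                "r": self.r[iu, ju],
                "p": self.p[iu, ju],
                "q": self.q[iu, ju],
            }
        )


def estimate_fractions(counts, seed: int | None = None) -> np.ndarray:
    """Posterior-mean relative abundances under a uniform Dirichlet prior.

    fractions[s, i] = (counts[s, i] + 1) / (sum_j counts[s, j] + p_taxa);
    every row sums to one.  ``seed`` is accepted for interface symmetry with
    the stochastic Dirichlet draws used inside :func:`sparcc`; the
    posterior mean itself is deterministic.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D samples x taxa matrix")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        bad = np.nonzero(totals <= 0)[0]
        raise ValueError(
            f"samples with zero total counts (indices {bad.tolist()}); "
            "depth-filter the profile first"
        )
    p = counts.shape[1]
    return (counts + 1.0) / (totals + p)[:, None]


def _dirichlet_fractions(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Dirichlet(counts + 1) draw of fractions per sample."""
    g = rng.standard_gamma(counts + 1.0)
    return g / g.sum(axis=1, keepdims=True)


def _logratio_variances(log_fractions: np.ndarray) -> np.ndarray:
    """Matrix T of pairwise log-ratio variances, Var(log x_i - log x_j)."""
    v = np.var(log_fractions, axis=0, ddof=1)
    c = np.cov(log_fractions, rowvar=False, ddof=1)
    t = v[:, None] + v[None, :] - 2.0 * c
    np.fill_diagonal(t, 0.0)
    # numerical: variance of a difference cannot be negative
    np.clip(t, 0.0, None, out=t)
    return t


def _solve_basis(t_mat: np.ndarray, excluded: list[tuple[int, int]]):
    """Closed-form basis-variance solve under the sparsity approximation.

    Row sums of t_ij give the linear system M w = t_rowsum with
    M = ones + diag(p - 2); excluded pairs are removed from both sides.
    """
    p = t_mat.shape[0]
    m = np.ones((p, p)) + np.diag(np.full(p, p - 2.0))
    t = t_mat.sum(axis=1)
    for i, j in excluded:
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        t[i] -= t_mat[i, j]
        t[j] -= t_mat[i, j]
    try:
        omega = np.linalg.solve(m, t)
    except np.linalg.LinAlgError:
        omega = np.linalg.lstsq(m, t, rcond=None)[0]
    if np.any(omega <= 0):
        pos = omega[omega > 0]
        if pos.size == 0:
            raise ValueError("all basis variances non-positive; degenerate input")
        floor = pos.min()
        warnings.warn(
            "negative basis variance estimate floored to smallest positive value",
            RuntimeWarning,
            stacklevel=3,
        )
        omega = np.where(omega <= 0, floor, omega)
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    r = (omega[:, None] + omega[None, :] - t_mat) / denom
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r, omega


def basis_correlations(
    fractions,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
):
    """Single-shot SparCC core on one fraction matrix.

    Solves the basis system, then iteratively excludes the strongest
    remaining |r| pair while it exceeds ``exclusion_threshold``, up to
    ``max_exclusion_rounds`` rounds.

    Returns
    -------
    (r, basis_variances)
    """
    fractions = np.asarray(fractions, dtype=float)
    n, p = fractions.shape
    if p < 4:
        raise ValueError("SparCC needs at least 4 taxa (basis variances unidentifiable)")
    if n < 3:
        raise ValueError("SparCC needs at least 3 samples")
    logf = np.log(fractions)
    t_mat = _logratio_variances(logf)
    excluded: list[tuple[int, int]] = []
    r, omega = _solve_basis(t_mat, excluded)
    mask = np.ones((p, p), dtype=bool)
    np.fill_diagonal(mask, False)
    for _ in range(max_exclusion_rounds):
        absr = np.where(mask, np.abs(r), -np.inf)
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] <= exclusion_threshold:
            break
        excluded.append((int(i), int(j)))
        mask[i, j] = mask[j, i] = False
        r, omega = _solve_basis(t_mat, excluded)
    return r, omega


def sparcc(
    counts,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
    inner_iterations: int = 20,
    seed: int | None = None,
):
    """SparCC correlation estimate averaged over Dirichlet resampled fractions.

    For each of ``inner_iterations`` iterations the fractions are drawn from
    per-sample Dirichlet(counts + 1) posteriors and the basis correlations
    re-solved; the estimates are averaged.  ``inner_iterations=0`` uses the
    deterministic posterior-mean fractions once.

    Returns
    -------
    (r, basis_variances)
    """
    counts = np.asarray(counts, dtype=float)
    if inner_iterations <= 0:
        return basis_correlations(
            estimate_fractions(counts), exclusion_threshold, max_exclusion_rounds
        )
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("samples with zero total counts; depth-filter first")
    r_acc = None
    w_acc = None
    for _ in range(inner_iterations):
        frac = _dirichlet_fractions(counts, rng)
        r, w = basis_correlations(frac, exclusion_threshold, max_exclusion_rounds)
        r_acc = r if r_acc is None else r_acc + r
        w_acc = w if w_acc is None else w_acc + w
    r = r_acc / inner_iterations
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r, w_acc / inner_iterations


def bootstrap_pvalues(
    counts,
    B: int = 1000,
    seed: int | None = None,
    r_obs: np.ndarray | None = None,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
    inner_iterations: int = 20,
) -> np.ndarray:
    """Two-sided empirical p-values from a per-taxon permutation null.

    Each null replicate permutes every taxon column of ``counts``
    independently across samples (association destroyed, marginals kept),
    recomputes SparCC, and records |r|.  The add-one estimator

        p_ij = (1 + #{b : |r_b,ij| >= |r_obs,ij|}) / (B + 1)

    keeps p strictly positive.  Deterministic given ``seed``.
    """
    counts = np.asarray(counts, dtype=float)
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    if r_obs is None:
        r_obs, _ = sparcc(
            counts,
            exclusion_threshold,
            max_exclusion_rounds,
            inner_iterations,
            seed=rng.integers(2**31),
        )
    n, p = counts.shape
    abs_obs = np.abs(r_obs)
    exceed = np.zeros((p, p), dtype=np.int64)
    cols = np.arange(p)
    for _ in range(B):
        idx = rng.random((n, p)).argsort(axis=0)  # independent permutation per column
        perm = counts[idx, cols]
        r_b, _ = sparcc(
            perm,
            exclusion_threshold,
            max_exclusion_rounds,
            inner_iterations,
            seed=rng.integers(2**31),
        )
        exceed += np.abs(r_b) >= abs_obs
    pvals = (1.0 + exceed) / (B + 1.0)
    pvals = np.minimum(pvals, pvals.T)  # symmetrize (counts already symmetric up to fp)
    np.fill_diagonal(pvals, 1.0)
    return pvals


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for a flat vector.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector; flatten matrices first")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bh_adjust_matrix(p_matrix: np.ndarray) -> np.ndarray:
    """BH adjustment over the upper triangle of a symmetric p matrix, mirrored."""
    p_matrix = np.asarray(p_matrix, dtype=float)
    n = p_matrix.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    q_flat = bh_adjust(p_matrix[iu, ju])
    q = np.ones((n, n))
    q[iu, ju] = q_flat
    q[ju, iu] = q_flat
    return q


def estimate_correlations(
    counts,
    B: int = 1000,
    seed: int | None = None,
    taxa: list[str] | None = None,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
    inner_iterations: int = 20,
) -> CorrelationEstimate:
    """Full correlation stage: SparCC r, permutation p, BH q."""
    counts = np.asarray(counts, dtype=float)
    rng = np.random.default_rng(seed)
    r, w = sparcc(
        counts,
        exclusion_threshold,
        max_exclusion_rounds,
        inner_iterations,
        seed=rng.integers(2**31),
    )
    pvals = bootstrap_pvalues(
        counts,
        B=B,
        seed=rng.integers(2**31),
        r_obs=r,
        exclusion_threshold=exclusion_threshold,
        max_exclusion_rounds=max_exclusion_rounds,
        inner_iterations=inner_iterations,
    )
    q = bh_adjust_matrix(pvals)
    # BH never lowers a p-value, but guard fp noise at the boundary
    q = np.maximum(q, pvals)
    return CorrelationEstimate(
        r=r,
        p=pvals,
        q=q,
        n_bootstraps=B,
        seed=seed,
        basis_variances=w,
        taxa=taxa,
    )
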