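"""Compositional correlation inference with permutation significance.

Implements the sparse compositional correlation procedure from first
principles: per-sample fractions are resampled from a Dirichlet posterior,
pairwise log-ratio variances t_ij = Var log(x_i / x_j) are reduced to basis
variances under the sparsity assumption sum_{j != i} rho_ij ~ 0, and the
strongest pairs are iteratively excluded from the linear system before
re-solving.  Significance is assessed by permuting each taxon's counts
across samples and recomputing the correlation estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("nitrilink")

_OMEGA_FLOOR = 1e-6


class SparccInputError(ValueError):
    pass


@dataclass(frozen=True)
class BasisEstimate:
    """Basis variances and correlations from one variation matrix."""

    omega: np.ndarray          # basis variances, >= 0 after clamping
    rho: np.ndarray            # correlation matrix, clamped to [-1, 1]
    excluded_pairs: tuple      # ((i, j), ...) in exclusion order


@dataclass(frozen=True)
class AssociationNetwork:
    """Symmetric correlation estimates with permutation p-values."""

    taxa: tuple
    rho: pd.DataFrame
    pvalues: pd.DataFrame

    def edges(self) -> pd.DataFrame:
        """Edge list with canonical pair order (taxon_a < taxon_b)."""
        rows = []
        taxa = sorted(self.taxa)
        for i, a in enumerate(taxa):
            for b in taxa[i + 1 :]:
                rows.append(
                    (a, b, self.rho.loc[a, b], self.pvalues.loc[a, b])
                )
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p"])


def _as_matrix(counts) -> np.ndarray:
    x = np.asarray(
        counts.to_numpy() if hasattr(counts, "to_numpy") else counts,
        dtype=float,
    )
    if x.ndim != 2:
        raise SparccInputError("counts must be a 2-D samples-by-taxa table")
    if (x < 0).any():
        raise SparccInputError("counts must be non-negative")
    if (x.sum(axis=1) <= 0).any():
        raise SparccInputError("every sample must have a positive total")
    return x


def estimate_fractions(counts, n_draws: int = 20, seed: int = 0) -> np.ndarray:
    """Posterior fraction draws: Dirichlet(counts + 1) per sample.

    Returns an array of shape (n_draws, n_samples, n_taxa); each sample's
    fractions sum to one within floating tolerance.
    """
    x = _as_matrix(counts)
    rng = np.random.default_rng(seed)
    draws = rng.standard_gamma(x + 1.0, size=(n_draws,) + x.shape)
    draws /= draws.sum(axis=2, keepdims=True)
    return draws


def logratio_variance_matrix(fractions) -> np.ndarray:
    """Variation matrix t_ij = sample variance (ddof=1) of log(x_i/x_j)."""
    f = np.asarray(
        fractions.to_numpy() if hasattr(fractions, "to_numpy") else fractions,
        dtype=float,
    )
    if f.shape[0] < 2:
        raise SparccInputError("need at least 2 samples")
    if (f <= 0).any():
        raise SparccInputError("fractions must be strictly positive")
    logs = np.log(f)
    cov = np.cov(logs, rowvar=False, ddof=1)
    var = np.diag(cov)
    t = var[:, None] + var[None, :] - 2.0 * cov
    np.maximum(t, 0.0, out=t)
    np.fill_diagonal(t, 0.0)
    return t


def basis_correlations(
    t: np.ndarray,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
) -> BasisEstimate:
    """Solve for basis variances and correlations with strong-pair exclusion.

    Under the sparsity assumption the row sums t_i = sum_j t_ij satisfy the
    linear system t_i = |P_i| * omega_i + sum_{j in P_i} omega_j, where P_i
    is the set of unexcluded partners of taxon i (initially all others).
    After each solve, the unexcluded pair with the largest |rho| above
    ``exclusion_threshold`` is removed from the system and it is re-solved,
    up to ``max_exclusions`` rounds.  Negative basis variances are clamped
    to a small floor with a warning.
    """
    t = np.asarray(t, dtype=float)
    d = t.shape[0]
    if d < 4:
        raise SparccInputError(
            "need at least 4 taxa for the sparse approximation; report raw "
            "log-ratio variances instead"
        )
    # M = diag(|P_i|) + adjacency of unexcluded pairs
    m = np.ones((d, d)) + np.diag(np.full(d, d - 2.0))
    t_sums = t.sum(axis=1)
    active = ~np.eye(d, dtype=bool)
    excluded = []

    def solve():
        omega = np.linalg.solve(m, t_sums)
        if (omega < 0).any():
            # routine at small sample sizes; clamped to keep rho defined
            log.debug(
                "clamping %d negative basis variance(s)", int((omega < 0).sum())
            )
            omega = np.maximum(omega, _OMEGA_FLOOR)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        rho = (omega[:, None] + omega[None, :] - t) / denom
        np.clip(rho, -1.0, 1.0, out=rho)
        np.fill_diagonal(rho, 1.0)
        return omega, rho

    omega, rho = solve()
    for _ in range(max_exclusions):
        masked = np.where(active, np.abs(rho), -np.inf)
        np.fill_diagonal(masked, -np.inf)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        # never isolate a taxon: it would make the system singular
        if m[i, i] <= 2.0 or m[j, j] <= 2.0:
            break
        active[i, j] = active[j, i] = False
        m[i, j] = m[j, i] = 0.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        t_sums[i] -= t[i, j]
        t_sums[j] -= t[i, j]
        excluded.append((int(min(i, j)), int(max(i, j))))
        omega, rho = solve()
    return BasisEstimate(omega, rho, tuple(excluded))


def sparcc(
    counts,
    n_draws: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Correlation estimate: mean basis correlation over fraction draws."""
    draws = estimate_fractions(counts, n_draws=n_draws, seed=seed)
    acc = None
    for f in draws:
        t = logratio_variance_matrix(f)
        est = basis_correlations(
            t,
            exclusion_threshold=exclusion_threshold,
            max_exclusions=max_exclusions,
        )
        acc = est.rho if acc is None else acc + est.rho
    return acc / len(draws)


def permutation_pvalues(
    counts,
    rho_obs: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
) -> np.ndarray:
    """Two-sided permutation p-values with the add-one estimator.

    Each permutation independently shuffles every taxon's counts across
    samples and recomputes the correlation with a single fraction draw;
    p_ij = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm), so p is never 0.
    """
    if n_perm < 1:
        raise SparccInputError("n_perm must be >= 1")
    x = _as_matrix(counts)
    rng = np.random.default_rng(seed)
    abs_obs = np.abs(np.asarray(rho_obs))
    exceed = np.zeros_like(abs_obs)
    for _ in range(n_perm):
        perm = np.empty_like(x)
        for j in range(x.shape[1]):
            perm[:, j] = x[rng.permutation(x.shape[0]), j]
        rho_perm = sparcc(
            perm,
            n_draws=1,
            exclusion_threshold=exclusion_threshold,
            max_exclusions=max_exclusions,
            seed=rng.integers(2**63),
        )
        exceed += np.abs(rho_perm) >= abs_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    np.fill_diagonal(p, 1.0 / (1.0 + n_perm))
    return p


def build_network(
    counts: pd.DataFrame,
    n_draws: int = 20,
    n_perm: int = 100,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
    seed: int = 0,
) -> AssociationNetwork:
    """Full network construction for one sample set.

    All-zero taxon columns are dropped (with a logged list) before the
    correlation step, mirroring per-period analyses where a taxon may be
    absent from one period entirely.
    """
    present = counts.columns[(counts > 0).any(axis=0)]
    absent = sorted(set(counts.columns) - set(present))
    if absent:
        log.warning("dropping %d all-zero taxa: %s", len(absent), absent)
    sub = counts.loc[:, present]
    rho = sparcc(
        sub,
        n_draws=n_draws,
        exclusion_threshold=exclusion_threshold,
        max_exclusions=max_exclusions,
        seed=seed,
    )
    pvals = permutation_pvalues(
        sub,
        rho,
        n_perm=n_perm,
        seed=seed + 1,
        exclusion_threshold=exclusion_threshold,
        max_exclusions=max_exclusions,
    )
    taxa = tuple(present)
    return AssociationNetwork(
        taxa,
        pd.DataFrame(rho, index=taxa, columns=taxa),
        pd.DataFrame(pvals, index=taxa, columns=taxa),
    )
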