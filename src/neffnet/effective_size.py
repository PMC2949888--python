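"""Effective sample sizes for doubly dependent data matrices.

For a doubly standardized matrix X (p genes × n experiments), the
sample gene–gene and experiment–experiment correlation matrices are

    Σ̂ = X X' / n,    Δ̂ = X' X / p.

The *total correlation* of a correlation matrix C of size k is the mean
squared off-diagonal entry over all unordered pairs, each normalized by
the corresponding diagonal product:

    c² = Σ_{j<j'} (C_jj'² / C_jj C_j'j') / C(k, 2),

and the effective sample size deflates the nominal count by it:

    k_eff = k / (1 + (k − 1) c²).

With independent columns c²=0 and k_eff=k; with perfectly redundant
columns c²=1 and k_eff=1. On an exactly doubly standardized matrix the
empirical moments of Σ̂ and Δ̂ are tied together (Efron's theorem), which
forces

    α̂² = [p(1 + ĉ²(n−1)) − n] / [n(p−1)]

and hence p̂_eff = n̂_eff: gene-side and experiment-side effective sizes
are a single number describing the whole matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix


@dataclass
class EffectiveSizeSummary:
    """Correlation matrices and effective-size scalars for one matrix."""

    sigma_hat: np.ndarray | None  # p×p gene-gene correlations (None if not materialized)
    delta_hat: np.ndarray         # n×n experiment-experiment correlations
    alpha_sq: float               # total gene correlation α̂²
    c_sq: float                   # total experiment correlation ĉ²
    p_eff: float
    n_eff: float


def _require_standardized(X: ExpressionMatrix) -> None:
    if not X.standardized:
        raise ValueError(
            "expression matrix is not doubly standardized; run "
            "neffnet.double_standardize first"
        )


def sample_correlations(X: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Σ̂ = XX'/n and Δ̂ = X'X/p for a doubly standardized matrix.

    Symmetry is enforced by (M + M')/2 to kill floating-point asymmetry.
    """
    _require_standardized(X)
    M = X.values
    p, n = M.shape
    sigma = M @ M.T / n
    delta = M.T @ M / p
    sigma = (sigma + sigma.T) / 2.0
    delta = (delta + delta.T) / 2.0
    return sigma, delta


def total_correlation_sq(C: np.ndarray) -> float:
    """Mean squared off-diagonal correlation over all unordered pairs.

    Each squared off-diagonal entry is normalized by the product of the
    corresponding diagonal entries, so near-unit diagonals from a
    finite-tolerance standardization do not bias the estimate.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {C.shape}")
    k = C.shape[0]
    if k < 2:
        raise ValueError("total correlation needs a matrix of size >= 2 (no pairs otherwise)")
    d = np.diag(C)
    norm = np.outer(d, d)
    R2 = C * C / norm
    iu = np.triu_indices(k, 1)
    return float(R2[iu].mean())


def effective_n(C: np.ndarray) -> float:
    """Effective number of experiments n/(1 + (n−1)ĉ²) from an
    experiment correlation matrix."""
    n = C.shape[0]
    c2 = total_correlation_sq(C)
    return n / (1.0 + (n - 1) * c2)


def effective_p(C: np.ndarray) -> float:
    """Effective number of genes p/(1 + (p−1)α̂²) from a gene
    correlation matrix."""
    return effective_n(C)


def alpha_sq_from_c_sq(c_sq: float, p: int, n: int) -> float:
    """Total gene correlation implied by the total experiment correlation
    on exactly doubly standardized data (Efron's theorem)."""
    return (p * (1.0 + c_sq * (n - 1)) - n) / (n * (p - 1))


def gene_total_correlation_sq(X: ExpressionMatrix, block_size: int = 1024) -> float:
    """α̂² computed blockwise from X without materializing the p×p Σ̂.

    Equivalent to ``total_correlation_sq(sigma_hat)`` to floating-point
    accuracy; memory is O(block_size · p).
    """
    _require_standardized(X)
    M = X.values
    p, n = M.shape
    if p < 2:
        raise ValueError("need at least 2 genes")
    d = (M * M).sum(axis=1) / n  # diag of Σ̂
    total = 0.0
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        S = M[start:stop] @ M.T / n  # (b × p) block of rows of Σ̂
        R2 = S * S / np.outer(d[start:stop], d)
        # strict upper triangle contribution of this row block
        cols = np.arange(p)[None, :]
        rows = np.arange(start, stop)[:, None]
        total += float(R2[cols > rows].sum())
    n_pairs = p * (p - 1) // 2
    return total / n_pairs


def effective_size_summary(
    X: ExpressionMatrix, materialize_sigma: bool = True
) -> EffectiveSizeSummary:
    """Full effective-size readout for a doubly standardized matrix.

    With ``materialize_sigma=False`` the p×p gene correlation matrix is
    never built; α̂² is computed blockwise from X.
    """
    sigma: np.ndarray | None
    if materialize_sigma:
        sigma, delta = sample_correlations(X)
        alpha_sq = total_correlation_sq(sigma)
    else:
        _require_standardized(X)
        M = X.values
        delta = M.T @ M / X.n_genes
        delta = (delta + delta.T) / 2.0
        sigma = None
        alpha_sq = gene_total_correlation_sq(X)
    c_sq = total_correlation_sq(delta)
    p, n = X.values.shape
    return EffectiveSizeSummary(
        sigma_hat=sigma,
        delta_hat=delta,
        alpha_sq=alpha_sq,
        c_sq=c_sq,
        p_eff=p / (1.0 + (p - 1) * alpha_sq),
        n_eff=n / (1.0 + (n - 1) * c_sq),
    )


@dataclass
class EfronIdentityReport:
    alpha_sq_direct: float
    alpha_sq_from_c: float
    p_eff: float
    n_eff: float
    max_discrepancy: float  # max(|α̂²_direct − α̂²_implied|, |p̂_eff − n̂_eff|)


def efron_identity_report(X: ExpressionMatrix) -> EfronIdentityReport:
    """Check the moment identity tying the gene side to the experiment side.

    Computes α̂² both directly from Σ̂ and from ĉ² via the identity that
    holds on exactly doubly standardized data, along with the two
    effective sizes. A large ``max_discrepancy`` flags a matrix that is
    not (well enough) doubly standardized.
    """
    summ = effective_size_summary(X, materialize_sigma=True)
    p, n = X.values.shape
    alpha_implied = alpha_sq_from_c_sq(summ.c_sq, p, n)
    return EfronIdentityReport(
        alpha_sq_direct=summ.alpha_sq,
        alpha_sq_from_c=alpha_implied,
        p_eff=summ.p_eff,
        n_eff=summ.n_eff,
        max_discrepancy=max(
            abs(summ.alpha_sq - alpha_implied), abs(summ.p_eff - summ.n_eff)
        ),
    )
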