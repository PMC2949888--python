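"""Dependency diagnostics for experiments in a compendium.

Experiments drawn from the same project (one lab, one study design)
tend to be correlated, which shows up as structure in the leading
eigenvector of the experiment correlation matrix and as significantly
correlated experiment pairs. Pair significance uses the Fisher
transform of Δ̂ entries with the *effective* number of genes p̂_eff as
the sample size — using the nominal gene count wildly overstates
significance because genes are themselves heavily correlated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .effective_size import (
    alpha_sq_from_c_sq,
    sample_correlations,
    total_correlation_sq,
)
from .io import CompendiumMetadata, ExpressionMatrix
from .trni import bh_select, fisher_z

logger = logging.getLogger(__name__)


@dataclass
class EigenSummary:
    """Leading eigenpair of the experiment correlation matrix."""

    v1: np.ndarray        # unit vector, one component per experiment
    lambda1: float
    experiment_ids: list[str] | None = None


def leading_eigenvector(
    delta_hat: np.ndarray, experiment_ids: list[str] | None = None
) -> EigenSummary:
    """Leading eigenvector of a symmetric correlation matrix.

    Sign convention: the largest-magnitude component is made positive.
    If the top eigenvalue is degenerate (gap < 1e-10) a warning is
    emitted and the tie-break makes the highest-index nonzero component
    positive instead, for determinism.
    """
    C = np.asarray(delta_hat, dtype=float)
    C = (C + C.T) / 2.0
    w, V = np.linalg.eigh(C)
    lam = float(w[-1])
    v = V[:, -1].copy()
    degenerate = C.shape[0] > 1 and (w[-1] - w[-2]) < 1e-10
    if degenerate:
        warnings.warn(
            f"leading eigenvalue is degenerate (gap {w[-1] - w[-2]:.2e}); "
            "eigenvector is not unique",
            stacklevel=2,
        )
        nz = np.nonzero(np.abs(v) > 1e-12)[0]
        pivot = nz[-1] if len(nz) else 0
    else:
        pivot = int(np.argmax(np.abs(v)))
    if v[pivot] < 0:
        v = -v
    return EigenSummary(v1=v, lambda1=lam, experiment_ids=experiment_ids)


def block_permutation_test(
    values, blocks, n_perm: int = 5000, seed: int | None = None
) -> tuple[float, float]:
    """Permutation test for block structure in per-experiment values.

    The statistic is the between-block sum of squares
    Σ_b m_b (mean_b − grand mean)²; large values mean the per-experiment
    quantities (typically components of the leading eigenvector) cluster
    by block (project). The p-value uses the (1 + #{permuted ≥ observed})
    / (n_perm + 1) convention, so it is never exactly zero.
    """
    values = np.asarray(values, dtype=float)
    blocks = np.asarray(blocks)
    if values.shape != blocks.shape:
        raise ValueError("values and blocks must have the same length")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("seed is required (the test is stochastic)")
    uniq, inv = np.unique(blocks, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 blocks")
    counts = np.bincount(inv).astype(float)

    def statistic(v: np.ndarray) -> float:
        grand = v.mean()
        sums = np.bincount(inv, weights=v)
        means = sums / counts
        return float((counts * (means - grand) ** 2).sum())

    obs = statistic(values)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if statistic(rng.permutation(values)) >= obs:
            hits += 1
    return obs, (1 + hits) / (n_perm + 1)


def correlated_experiment_pairs(X: ExpressionMatrix, q: float = 0.1) -> pd.DataFrame:
    """Significantly correlated experiment pairs at BH-FDR level q.

    Fisher-transforms each off-diagonal of Δ̂ and tests it against
    N(0, (p̂_eff − 3)⁻¹), where p̂_eff is the effective number of genes;
    BH step-up over all C(n,2) unordered pairs. Returns a table with
    columns exp_i, exp_j, r, z, p, significant.
    """
    sigma, delta = sample_correlations(X)
    p, n = X.values.shape
    # p̂_eff from the gene side; on doubly standardized data this equals
    # n̂_eff by the moment identity, but it is computed directly here.
    alpha_sq = total_correlation_sq(sigma)
    p_eff = p / (1.0 + (p - 1) * alpha_sq)
    if p_eff <= 3:
        raise ValueError(
            f"p_eff = {p_eff:.3g} <= 3: the Fisher-z null variance "
            "(p_eff - 3)^-1 is undefined"
        )
    iu = np.triu_indices(n, 1)
    d = np.diag(delta)
    r = delta[iu] / np.sqrt(d[iu[0]] * d[iu[1]])
    z = fisher_z(r)
    pvals = 2.0 * stats.norm.sf(np.abs(z) * np.sqrt(p_eff - 3.0))
    reject, _ = bh_select(pvals, q)
    ids = np.asarray(X.experiment_ids)
    return pd.DataFrame(
        {
            "exp_i": ids[iu[0]],
            "exp_j": ids[iu[1]],
            "r": r,
            "z": z,
            "p": pvals,
            "significant": reject,
        }
    )


def project_fcp(
    pairs: pd.DataFrame, meta: CompendiumMetadata, min_size: int = 4
) -> pd.DataFrame:
    """Fraction of correlated pairs (FCP) within each project.

    For each project with at least ``min_size`` experiments, FCP is the
    number of significant within-project pairs divided by C(m, 2).
    Undersized projects are omitted (logged).
    """
    proj = meta.table["project_id"].astype(str)
    rows = []
    for project, members in proj.groupby(proj).groups.items():
        m = len(members)
        if m < min_size:
            logger.info("project %s has %d experiment(s) < min_size=%d; omitted", project, m, min_size)
            continue
        members = set(members)
        within = pairs[pairs["exp_i"].isin(members) & pairs["exp_j"].isin(members)]
        n_pairs = m * (m - 1) // 2
        rows.append(
            {
                "project_id": project,
                "n_experiments": m,
                "n_significant": int(within["significant"].sum()),
                "fcp": float(within["significant"].sum()) / n_pairs,
            }
        )
    return pd.DataFrame(rows, columns=["project_id", "n_experiments", "n_significant", "fcp"])


def group_v1_by_factor(
    eigs: EigenSummary,
    meta: CompendiumMetadata,
    factor: str,
    grouping: dict[str, str] | None = None,
) -> dict[str, list[float]]:
    """Partition leading-eigenvector components by a condition factor.

    ``grouping`` maps factor states to group labels (so that e.g.
    late-log, stationary and biofilm growth phases can be pooled);
    unmapped states go to ``"other"`` with a warning. Without a grouping
    each state is its own group.
    """
    if eigs.experiment_ids is None:
        raise ValueError("EigenSummary lacks experiment ids; pass them to leading_eigenvector")
    if factor not in meta.table.columns or factor == "project_id":
        raise KeyError(
            f"factor {factor!r} not in metadata; available factors: {meta.factor_names}"
        )
    out: dict[str, list[float]] = {}
    warned = set()
    states = meta.table[factor].astype(str)
    for comp, exp in zip(eigs.v1, eigs.experiment_ids):
        state = str(states.loc[exp])
        if grouping is None:
            group = state
        elif state in grouping:
            group = grouping[state]
        else:
            group = "other"
            if state not in warned:
                warnings.warn(f"state {state!r} not in grouping; assigned to 'other'", stacklevel=2)
                warned.add(state)
        out.setdefault(group, []).append(float(comp))
    return out
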