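"""Correlation relevance-network inference with effective-sample-size
adjusted significance.

The pipeline: doubly standardize the matrix, form gene–gene correlations
Σ̂ = XX'/n, Fisher-transform them, compute two-sided p-values against
N(0, (n_eff − 3)⁻¹) — substituting the effective number of experiments
for the nominal one so that dependency among experiments does not
deflate the null variance — and select edges by Benjamini–Hochberg
step-up FDR control. Only pairs involving at least one transcription
factor are reported as putative regulatory interactions.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


def fisher_z(r):
    """Fisher transform z = ½ log((1+r)/(1−r)), elementwise.

    |r| ≥ 1 maps to ±inf with a warning (downstream p-value 0).
    """
    r = np.asarray(r, dtype=float)
    out = np.empty_like(r)
    interior = np.abs(r) < 1
    if not np.all(interior):
        warnings.warn("correlation(s) with |r| >= 1 mapped to +/-inf", stacklevel=2)
    out[interior] = np.arctanh(r[interior])
    out[~interior] = np.sign(r[~interior]) * np.inf
    return out if out.ndim else float(out)


def edge_pvalue(z, n_used: float):
    """Two-sided p-value of a Fisher z under the null N(0, (n_used − 3)⁻¹).

    ``n_used`` may be the nominal sample size, the effective sample size,
    or any externally supplied value > 3.
    """
    if n_used <= 3:
        raise ValueError(
            f"sample size {n_used} <= 3: null variance (n-3)^-1 is undefined"
        )
    z = np.asarray(z, dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(z) * np.sqrt(n_used - 3.0))
    return p if p.ndim else float(p)


def bh_select(pvals, q: float) -> tuple[np.ndarray, int]:
    """Benjamini–Hochberg step-up selection.

    Orders the m p-values ascending, finds the largest k with
    p_(k) ≤ qk/m, and rejects every test with p ≤ p_(k). Returns the
    reject flags in the original order and k (0 if nothing is rejected).
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.ndim != 1:
        raise ValueError("pvals must be 1-D")
    m = len(pvals)
    if m == 0:
        return np.zeros(0, dtype=bool), 0
    if not (0 <= q <= 1):
        raise ValueError(f"q must be in [0, 1], got {q}")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pvals, kind="stable")
    sorted_p = pvals[order]
    thresholds = q * np.arange(1, m + 1) / m
    below = np.nonzero(sorted_p <= thresholds)[0]
    if len(below) == 0:
        return np.zeros(m, dtype=bool), 0
    k_star = int(below[-1]) + 1
    return pvals <= sorted_p[k_star - 1], k_star


def _resolve_n_used(n_mode, X_std: ExpressionMatrix) -> tuple[float, float, float]:
    """Return (n_used, n_eff, c_sq) given the n_mode switch."""
    from .effective_size import total_correlation_sq

    p, n = X_std.values.shape
    delta = X_std.values.T @ X_std.values / p
    delta = (delta + delta.T) / 2.0
    c_sq = total_correlation_sq(delta)
    n_eff = n / (1.0 + (n - 1) * c_sq)
    if n_mode == "neff":
        n_used = n_eff
    elif n_mode == "nominal":
        n_used = float(n)
    else:
        n_used = float(n_mode)
    return n_used, n_eff, c_sq


def infer_network(
    X: ExpressionMatrix,
    tf_ids,
    q: float = 0.1,
    n_mode="neff",
    bh_universe: str = "all_pairs",
    tol: float = 0.01,
    max_iter: int = 100,
) -> tuple[pd.DataFrame, dict]:
    """Infer a TF–gene relevance network at BH-FDR level ``q``.

    Parameters
    ----------
    X
        Expression matrix; doubly standardized first if not already.
    tf_ids
        Regulator gene ids (must all be in the matrix).
    n_mode
        ``"neff"`` (default) tests against N(0, (n̂_eff−3)⁻¹);
        ``"nominal"`` uses the raw experiment count; a number uses that
        value directly (for sensitivity analyses).
    bh_universe
        ``"all_pairs"`` runs BH over every unordered gene pair and then
        reports only TF-involving pairs (the FDR threshold is set on the
        full gene–gene matrix); ``"tf_pairs"`` runs BH over TF-involving
        pairs only.

    Returns
    -------
    (EdgeTable, summary)
        EdgeTable: one row per TF-involving unordered pair with columns
        tf_id, gene_id, r, z, p, passed, rank (ascending p, ties broken
        by |z| descending then ids). Summary records n, p, n_eff, n_used,
        m, q, k_star, bh_universe.
    """
    from .standardize import double_standardize

    tf_ids = list(dict.fromkeys(tf_ids))  # stable-dedupe
    if not tf_ids:
        raise ValueError("tf_ids is empty")
    missing = [t for t in tf_ids if t not in set(X.gene_ids)]
    if missing:
        raise KeyError(f"TF id(s) not in expression matrix: {missing}")

    if not X.standardized:
        X, _ = double_standardize(X, tol=tol, max_iter=max_iter)
    p, n = X.values.shape
    n_used, n_eff, c_sq = _resolve_n_used(n_mode, X)
    if n_used <= 3:
        raise ValueError(f"resolved sample size {n_used:.3g} <= 3; cannot test")

    sigma = X.values @ X.values.T / n
    sigma = (sigma + sigma.T) / 2.0
    d = np.sqrt(np.diag(sigma))
    iu, ju = np.triu_indices(p, 1)
    r_all = sigma[iu, ju] / (d[iu] * d[ju])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z_all = fisher_z(r_all)
    p_all = edge_pvalue(z_all, n_used)

    tf_set = set(tf_ids)
    is_tf = np.asarray([g in tf_set for g in X.gene_ids])
    tf_pair = is_tf[iu] | is_tf[ju]

    if bh_universe == "all_pairs":
        reject_all, k_star = bh_select(p_all, q)
        m = len(p_all)
        passed = reject_all[tf_pair]
    elif bh_universe == "tf_pairs":
        reject_tf, k_star = bh_select(p_all[tf_pair], q)
        m = int(tf_pair.sum())
        passed = reject_tf
    else:
        raise ValueError(f"unknown bh_universe {bh_universe!r}")

    genes = np.asarray(X.gene_ids)
    gi, gj = genes[iu[tf_pair]], genes[ju[tf_pair]]
    ti, tj = is_tf[iu[tf_pair]], is_tf[ju[tf_pair]]
    # put the TF in the tf_id column; TF-TF pairs ordered lexicographically
    both = ti & tj
    swap = (~ti & tj) | (both & (gj < gi))
    tf_col = np.where(swap, gj, gi)
    gene_col = np.where(swap, gi, gj)

    table = pd.DataFrame(
        {
            "tf_id": tf_col,
            "gene_id": gene_col,
            "r": r_all[tf_pair],
            "z": z_all[tf_pair],
            "p": p_all[tf_pair],
            "passed": passed,
        }
    )
    table = table.sort_values(
        by=["p", "z", "tf_id", "gene_id"],
        ascending=[True, True, True, True],
        key=lambda col: -col.abs() if col.name == "z" else col,
        kind="stable",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)

    summary = {
        "n": n,
        "p": p,
        "c_sq": c_sq,
        "n_eff": n_eff,
        "n_used": n_used,
        "n_mode": str(n_mode),
        "m": m,
        "q": q,
        "k_star": k_star,
        "n_edges": int(table["passed"].sum()),
        "bh_universe": bh_universe,
    }
    logger.info(
        "inferred network: n_eff=%.2f, m=%d tests, %d edge(s) at q=%g",
        n_eff, m, summary["n_edges"], q,
    )
    return table, summary
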