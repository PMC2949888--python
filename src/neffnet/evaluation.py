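"""Gold-standard evaluation: precision–sensitivity curves, AUC10, and
nominal-vs-empirical FDR calibration.

Predictions are scored only inside the gold standard's TF × gene
universe (pairs whose members the truth set knows nothing about are
dropped before scoring), and matching is undirected. "Empirical FDR" at
a nominal BH level is the false discovery proportion 1 − precision of
the selected edge set. DFI (difference from ideal) summarizes a
calibration curve as the area of |empirical − nominal| over the nominal
grid: 0 for perfect calibration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, GoldStandard

logger = logging.getLogger(__name__)


@dataclass
class PRCurve:
    """Precision–sensitivity points along a ranked edge list."""

    points: np.ndarray  # (k, 2) array of (sensitivity, precision)
    n_gold: int
    n_scored: int = 0
    n_dropped: int = 0


@dataclass
class CalibrationCurve:
    """Nominal vs empirical FDR over a grid, with its DFI summary."""

    nominal: np.ndarray
    empirical: np.ndarray  # NaN where no edges were selected
    dfi: float = field(init=False)

    def __post_init__(self) -> None:
        self.nominal = np.asarray(self.nominal, dtype=float)
        self.empirical = np.asarray(self.empirical, dtype=float)
        ok = np.isfinite(self.empirical)
        if ok.sum() < 2:
            self.dfi = float("nan")
        else:
            x = self.nominal[ok]
            y = np.abs(self.empirical[ok] - x)
            self.dfi = float(np.trapezoid(y, x))


def _gold_sets(gold: GoldStandard):
    universe = gold.gene_universe
    true_pairs = gold.undirected_edges()
    return universe, true_pairs


def pr_curve(ranked_pairs, gold: GoldStandard) -> PRCurve:
    """Walk a ranked list of (tf, gene) pairs against a gold standard.

    Pairs outside the gold TF × gene universe (neither orientation has a
    TF in ``gold.tf_ids`` with both members known to the gold standard)
    are dropped before scoring (count logged). At each prefix,
    precision = TP/(TP+FP) and sensitivity = TP/n_gold, with gold edges
    matched as undirected pairs.
    """
    if not gold.edges:
        raise ValueError("gold standard has no edges")
    universe, true_pairs = _gold_sets(gold)
    tf_ids = gold.tf_ids

    pts = []
    tp = fp = dropped = 0
    for a, b in ranked_pairs:
        evaluable = (
            a in universe
            and b in universe
            and (a in tf_ids or b in tf_ids)
            and a != b
        )
        if not evaluable:
            dropped += 1
            continue
        if frozenset((a, b)) in true_pairs:
            tp += 1
        else:
            fp += 1
        pts.append((tp / len(true_pairs), tp / (tp + fp)))
    if dropped:
        logger.info("pr_curve: dropped %d pair(s) outside the gold universe", dropped)
    return PRCurve(
        points=np.asarray(pts, dtype=float).reshape(-1, 2),
        n_gold=len(true_pairs),
        n_scored=tp + fp,
        n_dropped=dropped,
    )


def auc10(curve: PRCurve) -> float:
    """Area under the precision-vs-sensitivity curve above 10% precision.

    Ties in sensitivity collapse to their maximum precision; the curve
    is anchored at (0, first precision); integration is trapezoidal over
    sensitivity of max(precision − 0.10, 0).
    """
    if curve.points.size == 0:
        raise ValueError("empty curve")
    sens = curve.points[:, 0]
    prec = curve.points[:, 1]
    # collapse tied sensitivities to max precision
    s_vals, inverse = np.unique(sens, return_inverse=True)
    p_max = np.zeros_like(s_vals)
    np.maximum.at(p_max, inverse, prec)
    s = np.concatenate(([0.0], s_vals))
    p = np.concatenate(([p_max[0]], p_max))
    y = np.clip(p - 0.10, 0.0, None)
    return float(np.trapezoid(y, s))


def ranked_tf_pairs(edge_table) -> list[tuple[str, str]]:
    """(tf, gene) pairs of an EdgeTable in rank order."""
    t = edge_table.sort_values("rank")
    return list(zip(t["tf_id"], t["gene_id"]))


def auc10_for_matrix(
    X: ExpressionMatrix, gold: GoldStandard, tf_ids, n_mode="neff"
) -> float:
    """AUC10 of the full correlation ranking of a matrix against a gold
    standard (convenience wrapper used by leave-one-out analyses)."""
    from .trni import infer_network

    table, _ = infer_network(X, tf_ids, q=1.0, n_mode=n_mode)
    return auc10(pr_curve(ranked_tf_pairs(table), gold))


def fdr_calibration(
    X: ExpressionMatrix,
    gold: GoldStandard,
    tf_ids,
    n_modes=("neff", "nominal"),
    q_grid=None,
    bh_universe: str = "all_pairs",
) -> dict:
    """Nominal-vs-empirical FDR curves for several sample-size choices.

    For each ``n_mode`` the network is inferred once (p-values depend on
    the mode, not on q); at each nominal level q on the grid the BH
    threshold is applied, selected edges are restricted to the gold
    universe, and the empirical FDR is the false discovery proportion
    1 − precision. Levels at which no edge is selected (or none is
    evaluable) are recorded as missing and excluded from DFI with a
    warning.
    """
    from .trni import bh_select, infer_network

    if q_grid is None:
        q_grid = np.arange(0.1, 0.91, 0.1)
    q_grid = np.asarray(q_grid, dtype=float)
    if np.any((q_grid <= 0) | (q_grid >= 1)):
        raise ValueError("q_grid values must lie in (0, 1)")

    universe, true_pairs = _gold_sets(gold)
    tf_set = gold.tf_ids
    out = {}
    for mode in n_modes:
        table, summary = infer_network(
            X, tf_ids, q=1.0, n_mode=mode, bh_universe="tf_pairs"
        )
        # Selection threshold may come from the full pair universe; recompute
        # the pvalue vector accordingly per q using the requested universe.
        if bh_universe == "all_pairs":
            # rebuild all-pairs p-values at this mode once
            full_table, _ = infer_network(X, X.gene_ids, q=1.0, n_mode=mode,
                                          bh_universe="tf_pairs")
            p_for_bh = full_table["p"].to_numpy()
        else:
            p_for_bh = table["p"].to_numpy()

        evaluable = (
            table["tf_id"].isin(tf_set)
            & table["tf_id"].isin(universe)
            & table["gene_id"].isin(universe)
        ).to_numpy()
        is_true = np.array(
            [frozenset((a, b)) in true_pairs for a, b in zip(table["tf_id"], table["gene_id"])]
        )

        empirical = np.full(len(q_grid), np.nan)
        sorted_p = np.sort(p_for_bh)
        m = len(sorted_p)
        for k, q in enumerate(q_grid):
            below = np.nonzero(sorted_p <= q * np.arange(1, m + 1) / m)[0]
            if len(below) == 0:
                warnings.warn(f"no edges selected at q={q:g}; point recorded as missing",
                              stacklevel=2)
                continue
            thresh = sorted_p[below[-1]]
            sel = (table["p"].to_numpy() <= thresh) & evaluable
            n_sel = int(sel.sum())
            if n_sel == 0:
                warnings.warn(f"no evaluable edges at q={q:g}; point recorded as missing",
                              stacklevel=2)
                continue
            empirical[k] = 1.0 - is_true[sel].sum() / n_sel
        out[str(mode)] = CalibrationCurve(nominal=q_grid.copy(), empirical=empirical)
    return out
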