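"""Experiment-subset selection and marginal-contribution analysis.

Because dependent experiments inflate the total correlation c², the
effective sample size n_eff of a subset can exceed that of the full
compendium. This module implements a greedy search that adds, at each
step, the experiment maximizing n_eff of the growing subset; random and
cluster-based subset selection for comparison; and leave-one-out deltas
quantifying what each project or experiment contributes to n_eff (and,
given a gold standard, to network-inference accuracy).

Subset n_eff is evaluated on the principal submatrix of the
full-compendium Δ̂ without re-standardizing each subset, which keeps a
greedy step O(n) per candidate via an incremental update of the sum of
squared correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .effective_size import total_correlation_sq
from .io import CompendiumMetadata, ExpressionMatrix, GoldStandard

logger = logging.getLogger(__name__)


@dataclass
class SubsetTrace:
    """Greedy-addition trace: ids in the order added and n_eff after each."""

    order: list[str]
    n_eff_path: list[float]
    peak_size: int = field(init=False)
    peak_n_eff: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.order) != len(self.n_eff_path):
            raise ValueError("order and n_eff_path must have equal length")
        k = int(np.argmax(self.n_eff_path))
        self.peak_size = k + 1
        self.peak_n_eff = float(self.n_eff_path[k])


def _normalized_sq(delta: np.ndarray) -> np.ndarray:
    d = np.diag(delta)
    return delta * delta / np.outer(d, d)


def _neff_from_ssq(k: int, ssq: float) -> float:
    """n_eff of a k-subset whose pairwise squared correlations sum to ssq.

    A singleton has no pairs; its effective size is taken as 1.
    """
    if k <= 1:
        return 1.0
    c2 = ssq / (k * (k - 1) / 2)
    return k / (1.0 + (k - 1) * c2)


def greedy_neff(
    delta_hat: np.ndarray,
    seed_ids="auto",
    ids: list[str] | None = None,
) -> SubsetTrace:
    """Greedy search for experiment subsets maximizing n_eff.

    Starting from a seed subset ("auto" picks the pair with the smallest
    squared correlation, which maximizes the 2-sample n_eff), each step
    appends the candidate experiment that maximizes n_eff of the
    enlarged subset, breaking ties toward the lowest index, until every
    experiment is included. The n_eff path is evaluated on principal
    submatrices of ``delta_hat``.
    """
    delta = np.asarray(delta_hat, dtype=float)
    n = delta.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    index_of = {e: i for i, e in enumerate(ids)}
    R2 = _normalized_sq(delta)

    if isinstance(seed_ids, str) and seed_ids == "auto":
        iu = np.triu_indices(n, 1)
        flat = R2[iu]
        k = int(np.argmin(flat))  # argmin returns first (lexicographically lowest pair)
        seed_idx = [int(iu[0][k]), int(iu[1][k])]
    else:
        seed_idx = [index_of[e] for e in seed_ids]
        if len(seed_idx) < 2:
            raise ValueError("seed subset must have at least 2 experiments")

    selected: list[int] = []
    order: list[str] = []
    path: list[float] = []
    ssq = 0.0
    in_set = np.zeros(n, dtype=bool)

    def add(j: int) -> None:
        nonlocal ssq
        if selected:
            ssq += float(R2[j, selected].sum())
        selected.append(j)
        in_set[j] = True
        order.append(ids[j])
        path.append(_neff_from_ssq(len(selected), ssq))

    for j in seed_idx:
        add(j)

    while len(selected) < n:
        candidates = np.nonzero(~in_set)[0]
        # incremental: ssq gain of candidate c is sum of R2[c, selected]
        gains = R2[np.ix_(candidates, selected)].sum(axis=1)
        k = len(selected) + 1
        neffs = np.array([_neff_from_ssq(k, ssq + g) for g in gains])
        best = candidates[int(np.argmax(neffs))]  # argmax -> first max -> lowest index
        add(int(best))

    return SubsetTrace(order=order, n_eff_path=path)


def subset_neff(delta_hat: np.ndarray, idx) -> float:
    """n_eff of a principal submatrix of Δ̂ (recomputation reference)."""
    sub = np.asarray(delta_hat)[np.ix_(idx, idx)]
    if sub.shape[0] <= 1:
        return 1.0
    n = sub.shape[0]
    return n / (1.0 + (n - 1) * total_correlation_sq(sub))


def random_subsets(ids, size: int, n_draws: int, seed: int) -> list[list[str]]:
    """Uniform subsets of a given size, without replacement, seeded."""
    ids = list(ids)
    if size > len(ids):
        raise ValueError(f"size {size} > number of experiments {len(ids)}")
    rng = np.random.default_rng(seed)
    return [
        [ids[i] for i in rng.choice(len(ids), size=size, replace=False)]
        for _ in range(n_draws)
    ]


def cluster_select(
    delta_hat: np.ndarray,
    s: int,
    seed: int | None = None,
    ids: list[str] | None = None,
) -> list[str]:
    """One representative experiment from each of s correlation clusters.

    Experiments are clustered by average-linkage hierarchical clustering
    on distance 1 − correlation, the tree is cut at ``s`` clusters, and
    each cluster contributes its medoid (the member with the highest
    mean correlation to the other members; ties to the lowest index).
    ``seed`` is accepted for interface symmetry; the procedure is
    deterministic.
    """
    delta = np.asarray(delta_hat, dtype=float)
    n = delta.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    if not 1 <= s <= n:
        raise ValueError(f"s must be in [1, {n}], got {s}")
    if s == n:
        return list(ids)
    d = np.diag(delta)
    corr = delta / np.sqrt(np.outer(d, d))
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=s, criterion="maxclust")
    reps: list[int] = []
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        if len(members) == 1:
            reps.append(int(members[0]))
            continue
        sub = corr[np.ix_(members, members)]
        mean_corr = (sub.sum(axis=1) - np.diag(sub)) / (len(members) - 1)
        best = mean_corr.max()
        reps.append(int(members[mean_corr >= best - 1e-15].min()))
    return [ids[i] for i in sorted(reps)]


def leave_one_out(
    X: ExpressionMatrix,
    meta: CompendiumMetadata | None,
    level: str = "project",
    gold: GoldStandard | None = None,
    tf_ids=None,
    q: float = 0.1,
    min_remaining: int = 4,
) -> pd.DataFrame:
    """Leave-one-out deltas of n_eff (and optionally AUC10) per unit.

    For each project (``level="project"``, requires metadata) or
    experiment (``level="experiment"``), removes the unit's columns,
    recomputes n_eff on the corresponding Δ̂ submatrix and reports
    delta_n_eff = n_eff(without) − n_eff(full). With a gold standard and
    TF list, the column-subset matrix is re-standardized, a network
    inferred, and delta_auc10 reported the same way. Units whose removal
    leaves fewer than ``min_remaining`` experiments are skipped with a
    warning.
    """
    from .evaluation import auc10_for_matrix

    if not X.standardized:
        raise ValueError("leave_one_out expects a doubly standardized matrix")
    if gold is not None and not tf_ids:
        raise ValueError("tf_ids required when a gold standard is provided")

    p, n = X.values.shape
    delta = X.values.T @ X.values / p
    delta = (delta + delta.T) / 2.0
    full_neff = subset_neff(delta, list(range(n)))
    full_auc = (
        auc10_for_matrix(X, gold, tf_ids) if gold is not None else None
    )

    if level == "project":
        if meta is None:
            raise ValueError("metadata required for project-level leave-one-out")
        projects = meta.project_of(X.experiment_ids)
        units: list[tuple[str, list[int]]] = []
        for proj in dict.fromkeys(projects):
            units.append((proj, [i for i, pr in enumerate(projects) if pr == proj]))
    elif level == "experiment":
        units = [(e, [i]) for i, e in enumerate(X.experiment_ids)]
    else:
        raise ValueError(f"level must be 'project' or 'experiment', got {level!r}")

    rows = []
    for unit, drop_idx in units:
        keep = [i for i in range(n) if i not in set(drop_idx)]
        if len(keep) < min_remaining:
            warnings.warn(
                f"removing {unit!r} leaves {len(keep)} experiment(s) < "
                f"{min_remaining}; skipped",
                stacklevel=2,
            )
            continue
        row = {
            "unit": unit,
            "n_removed": len(drop_idx),
            "delta_n_eff": subset_neff(delta, keep) - full_neff,
        }
        if gold is not None:
            sub = X.subset_experiments([X.experiment_ids[i] for i in keep])
            sub.standardized = False  # column subset must be re-standardized
            row["delta_auc10"] = auc10_for_matrix(sub, gold, tf_ids) - full_auc
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["full_n_eff"] = full_neff
    if full_auc is not None:
        out.attrs["full_auc10"] = full_auc
    return out
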