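"""Tabular I/O for expression compendia, metadata, gold standards and
replicate maps.

All files are plain TSV (tab-delimited, UTF-8, ``#`` comment lines
skipped). Expression matrices are genes in rows × experiments in
columns, with a header row of experiment ids and a first column of gene
ids (the first header cell is ignored). Identifiers are opaque strings.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Gene × experiment expression matrix.

    Parameters
    ----------
    values
        Real matrix, genes in rows, experiments in columns. Log-scale
        intensities as loaded; standardized units after
        :func:`neffnet.standardize.double_standardize`.
    gene_ids, experiment_ids
        Ordered unique identifiers for rows / columns.
    standardized
        Whether the matrix has been doubly standardized.
    """

    values: np.ndarray
    gene_ids: list[str]
    experiment_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.experiment_ids = list(self.experiment_ids)
        p, n = self.values.shape
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} rows")
        if len(self.experiment_ids) != n:
            raise ValueError(f"{len(self.experiment_ids)} experiment ids for {n} columns")
        for name, ids in (("gene", self.gene_ids), ("experiment", self.experiment_ids)):
            dup = _duplicates(ids)
            if dup:
                raise ValueError(f"duplicate {name} id(s): {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing/non-finite value at gene {self.gene_ids[i]!r}, "
                f"experiment {self.experiment_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.values.shape[1]

    def subset_experiments(self, keep: list[str]) -> "ExpressionMatrix":
        """Column subset, preserving the given order of experiment ids."""
        idx = [self.experiment_ids.index(e) for e in keep]
        return replace(
            self,
            values=self.values[:, idx].copy(),
            experiment_ids=list(keep),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.experiment_ids)


@dataclass
class CompendiumMetadata:
    """Per-experiment annotations: project membership and condition factors.

    ``table`` is indexed by experiment id with a mandatory ``project_id``
    column; every other column is a free-form condition factor
    (e.g. ``media_type``, ``growth_phase``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "project_id" not in self.table.columns:
            raise ValueError("metadata needs a 'project_id' column")
        if self.table["project_id"].astype(str).str.len().eq(0).any():
            raise ValueError("empty project id in metadata")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate experiment id(s) in metadata: {dup}")

    @property
    def experiment_ids(self) -> list[str]:
        return list(self.table.index)

    def project_of(self, experiment_ids: list[str]) -> list[str]:
        missing = [e for e in experiment_ids if e not in self.table.index]
        if missing:
            raise KeyError(f"experiments missing from metadata: {missing}")
        return self.table.loc[experiment_ids, "project_id"].astype(str).tolist()

    @property
    def factor_names(self) -> list[str]:
        return [c for c in self.table.columns if c != "project_id"]


@dataclass
class GoldStandard:
    """Known regulatory interactions: directed (tf, gene) pairs.

    ``genes`` is the set of genes over which the truth is considered
    known (the evaluation universe). For curated databases this is left
    ``None`` and defaults to the genes that appear in the edge list —
    absence of an edge outside that set says nothing. A synthetic
    generator, which knows the truth for every gene, sets it to the full
    gene list so that unplanted pairs count as genuine negatives.
    """

    edges: set[tuple[str, str]]
    tf_ids: set[str] = field(default_factory=set)
    genes: set[str] | None = None

    def __post_init__(self) -> None:
        self.edges = set(self.edges)
        self.tf_ids = set(self.tf_ids) | {tf for tf, _ in self.edges}
        if self.genes is not None:
            self.genes = set(self.genes)

    @property
    def gene_universe(self) -> set[str]:
        """Genes evaluable against this gold standard."""
        base = self.tf_ids | {g for _, g in self.edges}
        return base if self.genes is None else base | self.genes

    def undirected_edges(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in self.edges}


ReplicateMap = dict  # experiment_id -> list of replicate column ids


def _duplicates(ids) -> set:
    seen, dup = set(), set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_expression_matrix(path, transpose: bool = False) -> ExpressionMatrix:
    """Load a genes × experiments TSV into an :class:`ExpressionMatrix`.

    ``transpose`` flips the loaded table for experiments-in-rows exports.
    Raises on duplicate ids, missing values and non-numeric cells,
    naming the offending row/column.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if transpose:
        df = df.T
    gene_ids = [str(g) for g in df.index]
    experiment_ids = [str(c) for c in df.columns]
    try:
        values = df.astype(float).to_numpy()
    except ValueError:
        for gid, row in zip(gene_ids, df.itertuples(index=False)):
            for cid, cell in zip(experiment_ids, row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at gene {gid!r}, experiment {cid!r}: {cell!r}"
                    ) from None
        raise
    X = ExpressionMatrix(values, gene_ids, experiment_ids, standardized=False)
    logger.info("loaded expression matrix: p=%d genes, n=%d experiments", X.n_genes, X.n_experiments)
    return X


def write_expression_matrix(X: ExpressionMatrix, path) -> None:
    X.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_metadata(path) -> CompendiumMetadata:
    """Load experiment metadata (experiment_id, project_id, factor columns)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("metadata needs at least experiment_id and project_id columns")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return CompendiumMetadata(df)


def read_gold_standard(path, genes) -> GoldStandard:
    """Load a TF→gene edge list and intersect it with a gene universe.

    Extra columns are ignored; duplicate edges collapse to one; edges
    whose TF or target is absent from ``genes`` are dropped (count
    logged).
    """
    genes = set(genes)
    edges: set[tuple[str, str]] = set()
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected >=2 tab-separated columns")
            n_rows += 1
            edges.add((parts[0], parts[1]))
    if n_rows == 0:
        raise ValueError(f"empty gold standard file: {path}")
    kept = {(tf, g) for tf, g in edges if tf in genes and g in genes}
    dropped = len(edges) - len(kept)
    if dropped:
        logger.info("gold standard: dropped %d edge(s) with unmapped ids", dropped)
    return GoldStandard(edges=kept)


def write_gold_standard(gold: GoldStandard, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tf, g in sorted(gold.edges):
            fh.write(f"{tf}\t{g}\n")


def read_replicate_map(path) -> ReplicateMap:
    """Load experiment_id → replicate column id pairs (one pair per line)."""
    reps: ReplicateMap = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            exp, arr = line.split("\t")[:2]
            reps.setdefault(exp, []).append(arr)
    return reps


def select_cta_replicates(X_all: ExpressionMatrix, reps: ReplicateMap) -> ExpressionMatrix:
    """Collapse replicate arrays to the closest-to-average (CTA) replicate.

    For each experiment the replicate whose profile has the highest
    Pearson correlation with the arithmetic mean of that experiment's
    replicate profiles is kept; ties break to the lowest column index in
    ``X_all``. Replicate columns must be disjoint across experiments.
    """
    col_index = {c: i for i, c in enumerate(X_all.experiment_ids)}
    seen: set[str] = set()
    chosen_cols: list[int] = []
    exp_ids: list[str] = []
    for exp, arrays in reps.items():
        if not arrays:
            raise ValueError(f"experiment {exp!r} has no replicates listed")
        overlap = seen & set(arrays)
        if overlap:
            raise ValueError(f"replicate column(s) {sorted(overlap)} assigned to multiple experiments")
        seen.update(arrays)
        missing = [a for a in arrays if a not in col_index]
        if missing:
            raise KeyError(f"replicate column(s) not in matrix: {missing}")
        idx = [col_index[a] for a in arrays]
        block = X_all.values[:, idx]
        if len(idx) == 1:
            best = idx[0]
        else:
            mean_profile = block.mean(axis=1)
            mc = mean_profile - mean_profile.mean()
            bc = block - block.mean(axis=0, keepdims=True)
            denom = np.sqrt((bc**2).sum(axis=0) * (mc**2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = (bc * mc[:, None]).sum(axis=0) / denom
            corr = np.where(np.isfinite(corr), corr, -np.inf)
            # argmax with lowest-column-index tie break (idx order = column order
            # only if arrays listed in order; use explicit min over best set)
            best_corr = corr.max()
            candidates = [idx[k] for k in range(len(idx)) if corr[k] >= best_corr - 1e-15]
            best = min(candidates)
        chosen_cols.append(best)
        exp_ids.append(exp)
    return ExpressionMatrix(
        X_all.values[:, chosen_cols].copy(),
        X_all.gene_ids,
        exp_ids,
        standardized=X_all.standardized,
    )
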