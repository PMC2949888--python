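"""Matrix-normal compendium generator with planted regulatory networks.

Expression compendia are emulated as draws from a matrix normal
distribution X ~ N_{p,n}(0, Σ ⊗ Δ): Σ encodes gene–gene correlation,
Δ experiment–experiment correlation, and the Kronecker form makes the
two separable. Samples are produced as X = A Z Bᵀ with A Aᵀ = Σ,
B Bᵀ = Δ (Cholesky factors) and Z i.i.d. standard normal.

Structure options for either side:

- ``identity()`` — independent units;
- ``exchangeable(rho)`` — every pair correlated at rho (a single shared
  latent factor);
- ``blocks(sizes, rho)`` — within-block correlation rho, blocks
  independent; on the experiment side blocks play the role of projects
  and block labels are emitted as metadata.

``planted_network_sample`` additionally plants TF→target structure on
the gene side: each target row is β·(its TF row) + σ·noise, giving a
population TF–target correlation β/√(β² + σ²); the planted pairs form
the gold standard.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .io import CompendiumMetadata, ExpressionMatrix, GoldStandard

import pandas as pd


@dataclass(frozen=True)
class CorrStructure:
    """Correlation structure: 'identity', 'exchangeable' or 'blocks'."""

    kind: str
    rho: float = 0.0
    sizes: tuple[int, ...] = ()

    def matrix(self, size: int) -> np.ndarray:
        if self.kind == "identity":
            return np.eye(size)
        if self.kind == "exchangeable":
            C = np.full((size, size), self.rho)
            np.fill_diagonal(C, 1.0)
            return C
        if self.kind == "blocks":
            if sum(self.sizes) != size:
                raise ValueError(f"block sizes {self.sizes} do not sum to {size}")
            C = np.eye(size)
            start = 0
            for b in self.sizes:
                C[start : start + b, start : start + b] = self.rho
                start += b
            np.fill_diagonal(C, 1.0)
            return C
        raise ValueError(f"unknown structure kind {self.kind!r}")

    def labels(self, size: int) -> list[str]:
        """Project labels: one per block, or a single project otherwise."""
        if self.kind == "blocks":
            out = []
            for k, b in enumerate(self.sizes, 1):
                out.extend([f"P{k:02d}"] * b)
            return out
        return ["P01"] * size

    def validate(self) -> None:
        if self.kind in ("exchangeable", "blocks") and not 0 <= self.rho < 1:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")


def identity() -> CorrStructure:
    return CorrStructure("identity")


def exchangeable(rho: float) -> CorrStructure:
    return CorrStructure("exchangeable", rho=rho)


def blocks(sizes, rho: float) -> CorrStructure:
    return CorrStructure("blocks", rho=rho, sizes=tuple(int(s) for s in sizes))


@dataclass
class GeneratorSpec:
    p: int
    n: int
    sigma_spec: CorrStructure
    delta_spec: CorrStructure
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _factor(C: np.ndarray, name: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} correlation structure is not positive definite") from exc


def matrix_normal_sample(
    spec: GeneratorSpec,
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray, CompendiumMetadata]:
    """Draw X ~ N_{p,n}(0, Σ ⊗ Δ).

    Returns the matrix, the true Σ and Δ, and per-experiment metadata
    (project labels from the block structure of Δ).
    """
    spec.sigma_spec.validate()
    spec.delta_spec.validate()
    sigma = spec.sigma_spec.matrix(spec.p)
    delta = spec.delta_spec.matrix(spec.n)
    rng = np.random.default_rng(spec.seed)
    Z = rng.standard_normal((spec.p, spec.n))
    X = Z if spec.sigma_spec.kind == "identity" else _factor(sigma, "gene") @ Z
    if spec.delta_spec.kind != "identity":
        X = X @ _factor(delta, "experiment").T
    gene_ids = [f"g{i:05d}" for i in range(spec.p)]
    exp_ids = [f"e{j:04d}" for j in range(spec.n)]
    meta = CompendiumMetadata(
        pd.DataFrame({"project_id": spec.delta_spec.labels(spec.n)}, index=exp_ids)
    )
    return ExpressionMatrix(X, gene_ids, exp_ids), sigma, delta, meta


def planted_network_sample(
    n_tf: int,
    targets_per_tf: int,
    p_background: int,
    beta: float = 1.0,
    sigma_noise: float = 1.0,
    n: int = 60,
    delta_spec: CorrStructure | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, GoldStandard, CompendiumMetadata]:
    """Compendium with a planted TF→target network.

    TF rows are i.i.d. standard normal across experiments; each of a
    TF's targets is β·(TF row) + σ·(fresh noise); background rows are
    independent noise. All rows are then mixed across experiments by the
    Cholesky factor of Δ, so experiment dependency and regulatory signal
    coexist. The gold standard is exactly the planted (tf, target)
    pairs.
    """
    if delta_spec is None:
        delta_spec = identity()
    delta_spec.validate()
    p = n_tf * (1 + targets_per_tf) + p_background
    if p < 2:
        raise ValueError("need at least 2 genes")
    if beta == 0 and sigma_noise == 0:
        raise ValueError("beta=0 with sigma_noise=0 would give constant target rows")

    rng = np.random.default_rng(seed)
    tf_rows = rng.standard_normal((n_tf, n))
    blocks_ = [tf_rows]
    gene_ids = [f"tf{t:03d}" for t in range(n_tf)]
    edges = set()
    for t in range(n_tf):
        noise = rng.standard_normal((targets_per_tf, n))
        blocks_.append(beta * tf_rows[t][None, :] + sigma_noise * noise)
        for u in range(targets_per_tf):
            gid = f"tg{t:03d}_{u:02d}"
            gene_ids.append(gid)
            edges.add((f"tf{t:03d}", gid))
    if p_background:
        blocks_.append(rng.standard_normal((p_background, n)))
        gene_ids.extend(f"bg{i:05d}" for i in range(p_background))
    X = np.vstack(blocks_)
    if delta_spec.kind != "identity":
        X = X @ _factor(delta_spec.matrix(n), "experiment").T
    exp_ids = [f"e{j:04d}" for j in range(n)]
    meta = CompendiumMetadata(
        pd.DataFrame({"project_id": delta_spec.labels(n)}, index=exp_ids)
    )
    gold = GoldStandard(
        edges=edges,
        tf_ids={f"tf{t:03d}" for t in range(n_tf)},
        genes=set(gene_ids),  # truth is known for every gene in the generator
    )
    return ExpressionMatrix(X, gene_ids, exp_ids), gold, meta
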