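"""Double standardization: iterate until rows and columns simultaneously
have mean 0 and variance 1 (to tolerance).

Each iteration demeans columns, then rows, then scales columns, then
rows. Variances use the population convention (divide by the count, not
count−1) so that on converged data ``X X'/n`` and ``X' X/p`` have unit
diagonals — the identity the effective-sample-size algebra relies on.
The loop stops when the largest absolute entrywise change between
consecutive iterations falls below ``tol``. Because the final operation
is row scaling, row variances are exact at return while column moments
are only within the convergence tolerance of their targets.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-12


def _check_variance(M: np.ndarray, X: ExpressionMatrix) -> None:
    row_sd = M.std(axis=1)
    col_sd = M.std(axis=0)
    if np.any(row_sd < _EPS):
        i = int(np.argmin(row_sd))
        raise ValueError(f"zero-variance row: gene {X.gene_ids[i]!r}")
    if np.any(col_sd < _EPS):
        j = int(np.argmin(col_sd))
        raise ValueError(f"zero-variance column: experiment {X.experiment_ids[j]!r}")


def double_standardize(
    X: ExpressionMatrix, tol: float = 0.01, max_iter: int = 100
) -> tuple[ExpressionMatrix, int]:
    """Doubly standardize an expression matrix.

    Parameters
    ----------
    X
        Matrix with p ≥ 2 genes and n ≥ 2 experiments and no
        zero-variance row or column.
    tol
        Convergence threshold on the max absolute entrywise change
        between consecutive iterations (default 0.01).
    max_iter
        Iteration cap (default 100); exceeding it raises with the last
        delta.

    Returns
    -------
    (ExpressionMatrix, int)
        The standardized matrix (``standardized=True``) and the number
        of iterations run.
    """
    p, n = X.values.shape
    if p < 2 or n < 2:
        raise ValueError(f"need at least 2 rows and 2 columns, got {p}x{n}")
    M = X.values.astype(float, copy=True)
    _check_variance(M, X)

    last_delta = np.inf
    for it in range(1, max_iter + 1):
        prev = M.copy()
        M -= M.mean(axis=0, keepdims=True)   # demean columns
        M -= M.mean(axis=1, keepdims=True)   # demean rows
        _check_variance(M, X)
        M /= M.std(axis=0, keepdims=True)    # scale columns (population sd)
        M /= M.std(axis=1, keepdims=True)    # scale rows
        last_delta = float(np.abs(M - prev).max())
        if last_delta < tol:
            logger.info("double standardization converged in %d iteration(s)", it)
            return replace(X, values=M, standardized=True), it
    raise RuntimeError(
        f"double standardization did not converge in {max_iter} iterations "
        f"(last max-abs change {last_delta:.3g} >= tol {tol:g})"
    )
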