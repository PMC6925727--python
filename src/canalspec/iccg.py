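"""Incomplete-Cholesky-preconditioned conjugate gradients.

The incomplete factor keeps the sparsity pattern of A: entries l_ij are
computed by the complete Cholesky formula wherever a_ij != 0 and dropped
otherwise, A = L L^T + R with R the residual of the dropped fill-in.  On a
dense matrix every entry is "in pattern", so the factorization is complete
and PCG converges in one iteration; on sparse matrices this is classical
IC(0).  Breakdown (non-positive pivot) falls back to a diagonally shifted
factorization, logging the shift.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp

from .errors import ConditioningError, SolverError

log = logging.getLogger(__name__)


def incomplete_cholesky(A: np.ndarray, shift: float = 0.0) -> np.ndarray:
    """Lower factor L with the sparsity of tril(A); dense in, dense out.

    Entries outside the pattern of A are forced to zero (IC(0)); if the
    pattern is full this is the exact Cholesky factor.  Raises
    ``ConditioningError`` on a non-positive pivot (callers may retry with a
    diagonal ``shift``).
    """
    A = np.asarray(A, dtype=np.float64)
    n = len(A)
    if A.shape != (n, n):
        raise ValueError("A must be square")
    pattern = A != 0.0
    L = np.zeros_like(A)
    diag = np.diag(A) + shift
    for j in range(n):
        pivot = diag[j] - L[j, :j] @ L[j, :j]
        if pivot <= 0.0:
            raise ConditioningError(f"non-positive pivot {pivot:g} at column {j}")
        L[j, j] = np.sqrt(pivot)
        if j + 1 < n:
            col = (A[j + 1 :, j] - L[j + 1 :, :j] @ L[j, :j]) / L[j, j]
            L[j + 1 :, j] = np.where(pattern[j + 1 :, j], col, 0.0)
    return L


def ic_preconditioner(A: np.ndarray):
    """Factor A (with automatic diagonal-shift fallback) and return a solver
    for M z = r with M = L L^T, applied as the two triangular systems."""
    from scipy.linalg import solve_triangular

    shift = 0.0
    mean_diag = float(np.mean(np.diag(A)))
    for attempt in range(16):
        try:
            L = incomplete_cholesky(A, shift=shift)
            break
        except ConditioningError:
            shift = max(10.0 * shift, 1e-8 * mean_diag) if shift else 1e-8 * mean_diag
            log.warning("incomplete Cholesky breakdown; retrying with shift %g", shift)
    else:
        raise ConditioningError("incomplete Cholesky failed even with diagonal shift")
    if shift:
        log.info("incomplete Cholesky used diagonal shift %g", shift)

    def solve(r: np.ndarray) -> np.ndarray:
        y = solve_triangular(L, r, lower=True)
        return solve_triangular(L.T, y, lower=False)

    return solve


def pcg(
    A,
    b: np.ndarray,
    M_solve=None,
    tol: float = 1e-10,
    maxiter: int | None = None,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Conjugate gradients with optional preconditioner; returns (x, iters).

    Terminates when ||A x - b|| <= tol * ||b||.
    """
    b = np.asarray(b, dtype=np.float64)
    n = len(b)
    matvec = (lambda v: A @ v) if not callable(A) else A
    x = np.zeros(n) if x0 is None else x0.copy()
    r = b - matvec(x)
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return x, 0
    z = M_solve(r) if M_solve else r
    p = z.copy()
    rz = r @ z
    maxiter = maxiter or 10 * n
    for it in range(1, maxiter + 1):
        Ap = matvec(p)
        denom = p @ Ap
        if denom <= 0:
            raise SolverError("matrix is not positive definite in pcg")
        alpha = rz / denom
        x += alpha * p
        r -= alpha * Ap
        if np.linalg.norm(r) <= tol * bnorm:
            return x, it
        z = M_solve(r) if M_solve else r
        rz_new = r @ z
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise SolverError(
        f"pcg failed to reach tol={tol:g} in {maxiter} iterations "
        f"(residual {np.linalg.norm(r) / bnorm:g})"
    )


def iccg_solve(
    A,
    b: np.ndarray,
    drop_pattern: str = "sparsity-of-A",
    tol: float = 1e-10,
    maxiter: int | None = None,
    return_info: bool = False,
):
    """Solve SPD ``A x = b`` by incomplete-Cholesky-preconditioned CG.

    ``drop_pattern="sparsity-of-A"`` keeps the pattern of A in the factor
    (the only supported strategy; dense A therefore factors completely).
    """
    if drop_pattern not in ("sparsity-of-A", "level-0"):
        raise ValueError(f"unsupported drop_pattern {drop_pattern!r}")
    if sp.issparse(A):
        A = A.toarray()
    A = np.asarray(A, dtype=np.float64)
    M_solve = ic_preconditioner(A)
    x, iters = pcg(A, b, M_solve=M_solve, tol=tol, maxiter=maxiter)
    return (x, iters) if return_info else x
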