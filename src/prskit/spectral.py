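"""Spectral diagnostics on compressed LD matrices.

The store never materializes the dense matrix: matrix-vector products with
R = I + U + Uᵀ use the stored upper-triangular CSR directly (in quantized
form, dequantization folds into a single scale division after the integer
product).  Extremal eigenvalues come from ARPACK (scipy's ``eigsh``) on a
:class:`scipy.sparse.linalg.LinearOperator` view:

* λmax from a largest-magnitude Lanczos run (for a correlation matrix with
  unit diagonal, λmax >= 1, so the largest-magnitude eigenvalue is λmax
  whenever the matrix is anywhere close to PSD);
* λmin from the *shifted* operator R - λmax·I, whose largest-magnitude
  eigenvalue is λmin - λmax, avoiding shift-invert factorizations of
  possibly indefinite matrices.

The smallest eigenvalue drives the numerical stability of
summary-statistics regression: a strongly negative λmin lets the penalized
least-squares objective run away along the corresponding eigenvector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse.linalg as spla

from .ld_store import LDStore

__all__ = [
    "SpectralReport",
    "ld_linear_operator",
    "ld_matvec",
    "extremal_eigenvalues",
    "per_block_min_eigenvalues",
]

_DEFAULT_TOL = 1e-6


@dataclass
class SpectralReport:
    lambda_min: float
    lambda_max: float
    tolerance: float
    iterations: int
    per_block_lambda_min: Optional[list[float]] = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "lambda_min": self.lambda_min,
            "lambda_max": self.lambda_max,
            "tolerance": self.tolerance,
            "iterations": self.iterations,
        }
        if self.per_block_lambda_min is not None:
            out["per_block_lambda_min"] = list(self.per_block_lambda_min)
        out.update(self.extras)
        return out


def ld_linear_operator(ld: LDStore) -> spla.LinearOperator:
    """R = I + U + Uᵀ as a LinearOperator over the compressed store."""
    M = ld.n_variants
    U = ld.upper_csr(dtype=np.float64)
    inv_s = 1.0 / ld.spec.scale if ld.is_quantized else 1.0
    UT = U.T.tocsr()

    def matvec(v):
        v = np.asarray(v, dtype=np.float64).ravel()
        if len(v) != M:
            raise ValueError(f"vector length {len(v)} != {M} variants")
        if not np.all(np.isfinite(v)):
            raise ValueError("vector contains non-finite entries")
        return v + inv_s * (U @ v) + inv_s * (UT @ v)

    return spla.LinearOperator((M, M), matvec=matvec, rmatvec=matvec,
                               dtype=np.float64)


def ld_matvec(ld: LDStore, v: np.ndarray) -> np.ndarray:
    """(I + U + Uᵀ) v without materializing the dense matrix."""
    v = np.asarray(v, dtype=np.float64)
    if v.ravel().shape[0] != ld.n_variants:
        raise ValueError(f"vector length {v.size} != {ld.n_variants} variants")
    return ld_linear_operator(ld) @ v


class SpectralConvergenceError(RuntimeError):
    """Eigenvalue iteration failed; carries any partial estimates."""

    def __init__(self, message: str, partial: Optional[dict] = None):
        super().__init__(message)
        self.partial = partial or {}


def _deterministic_v0(M: int) -> np.ndarray:
    rng = np.random.default_rng(20240601)
    return rng.standard_normal(M)


def extremal_eigenvalues(ld: LDStore, tol: float = _DEFAULT_TOL,
                         maxiter: Optional[int] = None) -> SpectralReport:
    """Estimate λmin and λmax of the LD matrix via shifted Lanczos."""
    M = ld.n_variants
    if M < 1:
        raise ValueError("empty store")
    if M == 1:
        return SpectralReport(1.0, 1.0, tol, 0)
    if M == 2:
        # closed form 1 +/- |r|
        _, row = ld.row_neighbors(0)
        r = abs(float(row[0])) if len(row) else 0.0
        return SpectralReport(1.0 - r, 1.0 + r, tol, 0)

    A = ld_linear_operator(ld)
    v0 = _deterministic_v0(M)
    maxiter = maxiter or max(10 * M, 1000)
    try:
        lmax = float(spla.eigsh(A, k=1, which="LM", tol=tol, v0=v0,
                                maxiter=maxiter,
                                return_eigenvectors=False)[0])
        shifted = spla.LinearOperator(
            (M, M), matvec=lambda v: A @ v - lmax * np.asarray(v).ravel(),
            dtype=np.float64)
        lmin = lmax + float(spla.eigsh(shifted, k=1, which="LM", tol=tol,
                                       v0=v0, maxiter=maxiter,
                                       return_eigenvectors=False)[0])
    except spla.ArpackNoConvergence as exc:
        raise SpectralConvergenceError(
            f"eigenvalue iteration did not converge within {maxiter} "
            "iterations",
            partial={"eigenvalues": getattr(exc, "eigenvalues", None)},
        ) from exc
    except spla.ArpackError as exc:
        # degenerate spectra (e.g. a pure identity matrix makes the shifted
        # operator vanish) break the Lanczos recurrence; fall back to a
        # dense decomposition when that is feasible
        if M > 4096:
            raise SpectralConvergenceError(
                f"eigenvalue iteration failed: {exc}") from exc
        w = np.linalg.eigvalsh(ld.to_dense())
        lmin, lmax = float(w[0]), float(w[-1])
    return SpectralReport(min(lmin, lmax), max(lmin, lmax), tol, maxiter)


def per_block_min_eigenvalues(ld: LDStore,
                              blocks: Sequence[tuple[int, int]],
                              tol: float = _DEFAULT_TOL) -> list[float]:
    """λmin of each diagonal sub-matrix defined by half-open blocks.

    For a block-masked store the whole-matrix spectrum is the
    concatenation of the per-block spectra, so the minimum over this list
    equals the global λmin.  A block boundary that cuts through a stored
    row run indicates the blocks do not match the mask the store was
    built with.
    """
    M = ld.n_variants
    blocks = sorted(tuple(b) for b in blocks)
    covered = 0
    for lo, hi in blocks:
        if lo != covered or hi <= lo:
            raise ValueError("blocks must tile the variant range")
        covered = hi
    if covered != M:
        raise ValueError("blocks must cover all variants")

    counts = np.diff(ld.indptr)
    out = []
    for lo, hi in blocks:
        ends = np.arange(lo, hi) + counts[lo:hi]
        if np.any(ends > hi - 1):
            raise ValueError(
                f"stored rows cross the block boundary at [{lo}, {hi})")
        sub = _dense_block(ld, lo, hi)
        out.append(float(np.linalg.eigvalsh(sub)[0]) if hi - lo <= 1024
                   else _iterative_lambda_min(sub, tol))
    return out


def _dense_block(ld: LDStore, lo: int, hi: int) -> np.ndarray:
    n = hi - lo
    sub = np.eye(n)
    for i in range(lo, hi):
        start, vals = ld.row_neighbors(i)
        if len(vals):
            cols = np.arange(start, start + len(vals)) - lo
            sub[i - lo, cols] = vals
            sub[cols, i - lo] = vals
    return sub


def _iterative_lambda_min(A: np.ndarray, tol: float) -> float:
    lmax = float(spla.eigsh(A, k=1, which="LA", tol=tol,
                            return_eigenvectors=False)[0])
    shifted = A - lmax * np.eye(A.shape[0])
    return lmax + float(spla.eigsh(shifted, k=1, which="LM", tol=tol,
                                   return_eigenvectors=False)[0])
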