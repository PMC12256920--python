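"""Hyperparameter tuning from summary statistics alone.

Validation data are synthesized with the PUMAS sampling scheme: given
full-sample marginal effects ``bhat`` on N individuals and the LD matrix
R, training-subset effects for a fraction ``p`` of the samples are drawn
from::

    bhat_train ~ Normal( bhat, (1/(N p) - 1/N) R )

and the complementary validation effects follow from the exact linear
identity::

    bhat_val = bhat / (1 - p) - p * bhat_train / (1 - p),

so that ``p * bhat_train + (1-p) * bhat_val == bhat`` for every variant
and draw.  Sampling a multivariate normal against a chromosome-wide LD
matrix is intractable, so the matrix is partitioned into contiguous
sub-blocks (at most ``max_block_size`` variants; LD-block boundaries are
respected when the store carries them) and each block is sampled
independently via eigendecomposition, clipping negative eigenvalues at
zero for the factorization.

The candidate proportion-of-causal-variants grid is 20 points log10-spaced
from 10/M to 0.2.  Models along the grid are fitted *pathwise*: π
ascending, each fit warm-started from the previous solution, which reduces
the total number of epochs relative to independent cold starts.  Model
selection maximizes the validation pseudo-R²::

    pseudo_R²(η) = (ηᵀ bhat_val)² / (ηᵀ R̃ η),

the squared correlation between the PRS and the phenotype in the
noiseless standardized limit.  The winning π is then refitted on the
original (unsplit) summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import cavi
from .cavi import (CaviWorkspace, NumericalInstabilityError, PenaltySpec,
                   PRSModel, SumstatsTable, fit)
from .ld_store import LDStore

__all__ = [
    "SplitSpec",
    "GridSpec",
    "pumas_split",
    "default_grid",
    "pathwise_grid_search",
    "pseudo_r2",
    "refit_selected",
    "lambda_grid_search",
    "GridSearchResult",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation summary-statistics split configuration."""

    p_train: float = 0.8
    max_block_size: int = 500
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.p_train < 1.0):
            raise ValueError("p_train must lie in (0, 1)")
        if self.max_block_size < 2:
            raise ValueError("max_block_size must be at least 2")


def _sampling_blocks(ld: LDStore, max_block_size: int) -> list[tuple[int, int]]:
    """Contiguous sampling blocks of bounded size.

    When the store was built with a block mask, LD-block boundaries are
    respected (blocks larger than the cap are split); otherwise plain
    contiguous chunks are used.
    """
    M = ld.n_variants
    base = ld.attrs.get("blocks") or [(0, M)]
    out: list[tuple[int, int]] = []
    for lo, hi in (tuple(b) for b in base):
        n = hi - lo
        n_parts = max(1, int(np.ceil(n / max_block_size)))
        cuts = np.linspace(lo, hi, n_parts + 1).astype(int)
        out.extend(zip(cuts[:-1], cuts[1:]))
    return [b for b in out if b[1] > b[0]]


def pumas_split(sumstats: SumstatsTable, ld: LDStore,
                spec: SplitSpec = SplitSpec()) -> tuple[SumstatsTable,
                                                        SumstatsTable]:
    """Sample complementary train/validation marginal effects.

    Effective sample sizes ``N * p`` and ``N * (1-p)`` are recorded in the
    returned tables.  Reproducible under a fixed seed.
    """
    beta, n, include, _ = cavi.harmonize(sumstats, ld)
    p = spec.p_train
    scale_factors = 1.0 / (n * p) - 1.0 / n
    if np.any(scale_factors[include] <= 0):
        raise ValueError("p_train leaves a non-positive sampling variance")

    rng = np.random.default_rng(spec.seed)
    beta_train = beta.copy()
    for lo, hi in _sampling_blocks(ld, spec.max_block_size):
        sub = np.arange(lo, hi)
        R = _dense_block(ld, lo, hi)
        # PSD repair: the factorization needs non-negative eigenvalues
        w, V = np.linalg.eigh(R)
        w = np.clip(w, 0.0, None)
        # per-variant sampling s.d. factor (n may vary across variants)
        sd = np.sqrt(scale_factors[sub])
        z = rng.standard_normal(len(sub))
        noise = V @ (np.sqrt(w) * z)
        beta_train[sub] = beta[sub] + sd * noise
    beta_val = beta / (1.0 - p) - (p / (1.0 - p)) * beta_train

    # map back to the caller's sumstats rows (aligned to LD order here)
    meta = ld.metadata
    base = {
        "rsid": meta["rsid"].to_numpy(),
        "a1": meta["a1"].to_numpy(),
        "a2": meta["a2"].to_numpy(),
    }
    import pandas as pd

    def table(b, n_eff):
        t = pd.DataFrame(base)
        t["beta"] = b
        t["n"] = n_eff
        t["se"] = 1.0 / np.sqrt(n_eff)
        t["z"] = b * np.sqrt(n_eff)
        t["chr"] = meta["chr"].to_numpy()
        t["pos"] = meta["pos"].to_numpy()
        return SumstatsTable(t.loc[include].reset_index(drop=True))

    return table(beta_train, n * p), table(beta_val, n * (1.0 - p))


def _dense_block(ld: LDStore, lo: int, hi: int) -> np.ndarray:
    n = hi - lo
    R = np.eye(n)
    for i in range(lo, hi):
        start, vals = ld.row_neighbors(i)
        if len(vals):
            stop = min(start + len(vals), hi)
            if stop > start:
                cols = np.arange(start, stop) - lo
                v = np.asarray(vals[: stop - start], dtype=np.float64)
                R[i - lo, cols] = v
                R[cols, i - lo] = v
    return R


# ----------------------------------------------------------------------
# Grids
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Candidate values for the proportion of causal variants π."""

    values: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if len(v) == 0 or np.any(np.diff(v) <= 0):
            raise ValueError("grid values must be strictly increasing")
        if np.any((v <= 0) | (v >= 1)):
            raise ValueError("grid values must lie in (0, 1)")

    def __len__(self):
        return len(self.values)


def default_grid(M: int, n_points: int = 20, hi: float = 0.2) -> GridSpec:
    """The default π grid: ``n_points`` log10-spaced values in [10/M, hi]."""
    lo = 10.0 / M
    if lo >= hi:
        raise ValueError(f"M={M} too small for a non-degenerate grid "
                         f"(10/M must be below {hi})")
    values = np.logspace(np.log10(lo), np.log10(hi), n_points)
    values[0], values[-1] = lo, hi  # exact endpoints
    return GridSpec(tuple(values))


# ----------------------------------------------------------------------
# Scoring and search
# ----------------------------------------------------------------------

def pseudo_r2(eta: np.ndarray, validation: SumstatsTable,
              ld: LDStore) -> float:
    """Validation accuracy from summary statistics alone.

    ``(ηᵀ bhat_val)² / (ηᵀ R̃ η)``, with the quadratic form floored at a
    small ε.  Zero by convention when η vanishes.
    """
    eta = np.asarray(eta, dtype=np.float64)
    if not np.any(eta):
        return 0.0
    beta_val, _, include, _ = cavi.harmonize(validation, ld)
    num = float(eta @ beta_val) ** 2
    U = ld.upper_csr(dtype=np.float64)
    inv_s = 1.0 / ld.spec.scale if ld.is_quantized else 1.0
    quad = float(eta @ eta + 2.0 * inv_s * (eta @ (U @ eta)))
    return num / max(quad, 1e-12)


@dataclass
class GridSearchResult:
    selected_pi: float
    scores: list
    models: list
    total_epochs: int
    failed: list = field(default_factory=list)

    @property
    def best_model(self) -> PRSModel:
        return self.models[int(np.nanargmax(self.scores))]


def pathwise_grid_search(train: SumstatsTable, validation: SumstatsTable,
                         ld: LDStore, grid: GridSpec,
                         penalty: Optional[PenaltySpec] = None, *,
                         warm_start: bool = True, mode: str = "triangular",
                         precision: str = "float64", tol: float = 1e-5,
                         max_iter: int = 1000) -> GridSearchResult:
    """Fit frozen-π models along the grid and select by pseudo-R².

    With ``warm_start`` (the pathwise algorithm) each fit is initialized
    from the previous grid point's full variational state — inclusion
    probabilities, conditional means/variances, and the remaining
    hyperparameters.  Ties in the validation score go to the smaller π
    (the sparser model).  Grid points whose fit diverges are marked
    failed and excluded from selection.
    """
    ws = CaviWorkspace(train, ld, penalty, precision)
    scores: list = []
    models: list = []
    failed: list = []
    total_epochs = 0
    prev_state = None
    for pi in grid.values:
        try:
            model = fit(train, ld, penalty, mode=mode, precision=precision,
                        tol=tol, max_iter=max_iter, fixed_pi=float(pi),
                        init_state=prev_state if warm_start else None,
                        workspace=ws)
        except NumericalInstabilityError:
            failed.append(float(pi))
            scores.append(np.nan)
            models.append(None)
            prev_state = None
            continue
        total_epochs += model.n_epochs
        scores.append(pseudo_r2(model.eta, validation, ld))
        models.append(model)
        if warm_start:
            prev_state = ws.state.copy()
            prev_state.elbo_trace = []
    if all(m is None for m in models):
        raise NumericalInstabilityError("every grid point diverged")

    arr = np.asarray(scores, dtype=np.float64)
    arr[np.isnan(arr)] = -np.inf
    # ties -> smallest pi: argmax returns the first maximizer (ascending grid)
    best = int(np.argmax(arr))
    return GridSearchResult(selected_pi=float(grid.values[best]),
                            scores=scores, models=models,
                            total_epochs=total_epochs, failed=failed)


def refit_selected(sumstats: SumstatsTable, ld: LDStore, selected_pi: float,
                   penalty: Optional[PenaltySpec] = None, *,
                   mode: str = "triangular", precision: str = "float64",
                   tol: float = 1e-5, max_iter: int = 1000) -> PRSModel:
    """Final fit on the original (unsplit) sumstats with π frozen."""
    return fit(sumstats, ld, penalty, mode=mode, precision=precision,
               tol=tol, max_iter=max_iter, fixed_pi=float(selected_pi))


def lambda_grid_search(sumstats: SumstatsTable, ld: LDStore,
                       validation: SumstatsTable,
                       multipliers: Sequence[float] = cavi.DEFAULT_LAMBDA_MULTIPLIERS,
                       *, lambda_min: Optional[float] = None,
                       mode: str = "triangular",
                       precision: str = "float64",
                       tol: float = 1e-5, max_iter: int = 1000):
    """Tune the λmin penalty over multiples of |λmin| on validation data.

    Diverging grid points (typically multiplier 0 on a badly non-PSD
    matrix) are excluded; ties go to the smallest multiplier.
    """
    from . import spectral

    if lambda_min is None:
        lambda_min = spectral.extremal_eigenvalues(ld).lambda_min
    base = abs(min(lambda_min, 0.0))
    results = []
    for mult in multipliers:
        lam = float(mult) * base
        pen = PenaltySpec.global_penalty(lam) if lam > 0 else PenaltySpec.none()
        try:
            model = fit(sumstats, ld, pen, mode=mode, precision=precision,
                        tol=tol, max_iter=max_iter)
        except NumericalInstabilityError:
            results.append((float(mult), lam, np.nan, None))
            continue
        score = pseudo_r2(model.eta, validation, ld)
        results.append((float(mult), lam, score, model))
    usable = [r for r in results if r[3] is not None]
    if not usable:
        raise NumericalInstabilityError("every penalty level diverged")
    best = max(usable, key=lambda r: (r[2], -r[0]))
    return {
        "selected_multiplier": best[0],
        "selected_lambda": best[1],
        "lambda_min": float(lambda_min),
        "scores": [(m, lam, s) for m, lam, s, _ in results],
        "model": best[3],
    }
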