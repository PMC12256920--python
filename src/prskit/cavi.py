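"""Coordinate-ascent variational inference for summary-statistics PRS.

Model
-----
Phenotype and genotypes are standardized, so the marginal GWAS effect for
variant j is ``bhat_j = x_jᵀy / N`` and the in-sample mean squared error of
any candidate effect vector β obeys::

    MSE(β) = 1 - 2 bhatᵀβ + βᵀRβ  >= 0,

with R the in-sample LD matrix.  Effects carry a spike-and-slab prior:
with probability π, β_j ~ Normal(0, σ_β²); otherwise β_j = 0.  The
posterior is approximated by a fully factorized variational family whose
per-variant parameters are an inclusion probability γ_j, a conditional
(slab) mean μ_j, and conditional variance s_j²; the posterior mean is
η_j = γ_j μ_j.  Coordinate ascent on the evidence lower bound (ELBO)
yields closed-form updates::

    s_j²   = σ_ε² / (N(1+λ_j) + σ_ε²/σ_β²)
    μ_j    = (N s_j² / σ_ε²) (bhat_j - q_j),   q_j = Σ_{k≠j} R_jk η_k
    γ_j    = logistic( log(π/(1-π)) + ½ log(s_j²/σ_β²) + μ_j²/(2 s_j²) )

interleaved with variational-EM updates of (π, σ_β², σ_ε²).

λmin penalty
------------
When the approximate LD matrix is not positive semi-definite, the
quadratic form can go negative and the optimization runs away along the
offending eigenvector.  Replacing R with R + λI (λ = |λmin| or a tuned
multiple) restores a well-posed objective; the penalty enters the updates
only through the diagonal term (the (1+λ) factor above) and acts as extra
shrinkage.  λ may vary over genomic blocks.

Execution modes
---------------
*symmetric*: rows hold all neighbors; optional chunked execution updates
contiguous chunks against a shared q (a deterministic emulation of
parallel threads — cross-chunk information is one epoch stale, and an
instability heuristic drops the chunk count when staleness causes
oscillations).  *triangular*: only the stored upper-triangular rows are
touched; during the ascending sweep each update broadcasts forward only,
and a single sparse matrix-vector product with U reconciles q at the end
of the epoch.  Both modes run eagerly dequantized or dequantize-on-the-fly
(DQF), in float64 or float32.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .ld_store import LDStore

__all__ = [
    "SumstatsTable",
    "VariationalState",
    "PenaltySpec",
    "PRSModel",
    "NumericalInstabilityError",
    "standardize_sumstats",
    "posterior_variance",
    "coordinate_update",
    "epoch_symmetric",
    "epoch_triangular",
    "expected_mse",
    "m_step",
    "fit",
    "CaviWorkspace",
]

_SIGMA_E2_FLOOR = 1e-6
_ETA_SQ_DIVERGENCE = 100.0  # Ση² beyond any plausible heritability => runaway


class NumericalInstabilityError(RuntimeError):
    """Raised when inference diverges even under serial execution.

    Usually indicates a badly conditioned (non-PSD) LD matrix; consider
    refitting with a λmin penalty (``PenaltySpec.global_penalty``)."""


# ----------------------------------------------------------------------
# Summary statistics
# ----------------------------------------------------------------------

@dataclass
class SumstatsTable:
    """Per-variant marginal GWAS effects on the standardized scale."""

    table: pd.DataFrame

    REQUIRED = ("rsid", "a1", "a2", "beta", "n")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sumstats table missing columns: {missing}")
        if not np.all(np.isfinite(self.table["beta"])):
            raise ValueError("non-finite standardized effects")
        if np.any(self.table["n"] <= 1):
            raise ValueError("sample sizes must exceed 1")

    @property
    def beta(self) -> np.ndarray:
        return self.table["beta"].to_numpy(dtype=np.float64)

    @property
    def n(self) -> np.ndarray:
        return self.table["n"].to_numpy(dtype=np.float64)

    def __len__(self) -> int:
        return len(self.table)

    def with_beta(self, beta: np.ndarray) -> "SumstatsTable":
        out = self.table.copy()
        out["beta"] = beta
        out["z"] = beta * np.sqrt(self.n)
        return SumstatsTable(out)


_COLUMN_ALIASES = {
    "rsid": ("rsid", "snp", "id", "variant_id"),
    "chr": ("chr", "chrom", "chromosome"),
    "pos": ("pos", "bp", "position"),
    "a1": ("a1", "effect_allele", "allele1"),
    "a2": ("a2", "other_allele", "allele2"),
    "beta_raw": ("beta", "effect", "b"),
    "se": ("se", "standard_error"),
    "z": ("z", "zscore", "z_score"),
    "n": ("n", "n_samples", "sample_size"),
    "maf": ("maf", "eaf", "freq", "allele_frequency"),
}


def standardize_sumstats(raw: pd.DataFrame) -> SumstatsTable:
    """Normalize a raw GWAS table to standardized marginal effects.

    Accepts either (beta, se) or Z plus a per-variant sample size N and
    produces ``beta = Z / sqrt(N)`` — the marginal effect one obtains when
    both genotype and phenotype are standardized.
    """
    cols = {c.lower(): c for c in raw.columns}

    def pick(key, required=True):
        for alias in _COLUMN_ALIASES[key]:
            if alias in cols:
                return raw[cols[alias]]
        if required:
            raise ValueError(f"cannot locate a '{key}' column in sumstats")
        return None

    rsid = pick("rsid").astype(str)
    n = pd.to_numeric(pick("n"), errors="coerce")
    if n.isna().any():
        raise ValueError("missing or non-numeric sample sizes")
    z = pick("z", required=False)
    if z is None:
        beta_raw = pick("beta_raw", required=False)
        se = pick("se", required=False)
        if beta_raw is None or se is None:
            raise ValueError("sumstats need either a Z column or beta + se")
        z = pd.to_numeric(beta_raw) / pd.to_numeric(se)
    z = pd.to_numeric(z)
    beta = z / np.sqrt(n)

    out = pd.DataFrame({
        "rsid": rsid.to_numpy(),
        "a1": pick("a1").astype(str).str.upper().to_numpy(),
        "a2": pick("a2").astype(str).str.upper().to_numpy(),
        "beta": beta.to_numpy(dtype=np.float64),
        "se": 1.0 / np.sqrt(n.to_numpy(dtype=np.float64)),
        "z": z.to_numpy(dtype=np.float64),
        "n": n.to_numpy(dtype=np.float64),
    })
    for opt in ("chr", "pos", "maf"):
        col = pick(opt, required=False)
        if col is not None:
            out[opt] = col.to_numpy()
    return SumstatsTable(out)


# ----------------------------------------------------------------------
# Penalty specification
# ----------------------------------------------------------------------

DEFAULT_LAMBDA_MULTIPLIERS = (0.0, 0.01, 0.1, 1.0, 2.0)


@dataclass
class PenaltySpec:
    """How the λmin stability penalty is applied.

    ``none``: λ = 0 everywhere.  ``global``: a single λ = |λmin| added
    chromosome-wide.  ``per_block``: one λ per genomic block (variants in
    ill-conditioned regions are penalized more).  ``grid``: candidate
    multiples of |λmin| to be tuned on validation data.
    """

    mode: str = "none"
    value: Optional[float] = None
    block_values: Optional[Sequence[float]] = None
    blocks: Optional[Sequence[tuple[int, int]]] = None
    multipliers: Sequence[float] = DEFAULT_LAMBDA_MULTIPLIERS

    def __post_init__(self):
        if self.mode not in ("none", "global", "per_block", "grid"):
            raise ValueError(f"unknown penalty mode: {self.mode!r}")
        if self.value is not None and self.value < 0:
            raise ValueError("penalty values must be non-negative")
        if self.block_values is not None and any(v < 0 for v in self.block_values):
            raise ValueError("penalty values must be non-negative")

    @classmethod
    def none(cls) -> "PenaltySpec":
        return cls(mode="none")

    @classmethod
    def global_penalty(cls, value: float) -> "PenaltySpec":
        return cls(mode="global", value=float(value))

    @classmethod
    def per_block(cls, blocks, values) -> "PenaltySpec":
        return cls(mode="per_block", blocks=list(blocks),
                   block_values=list(values))

    def resolve(self, ld: LDStore) -> "PenaltySpec":
        """Fill in λ values from the spectrum of ``ld`` when absent.

        Negative eigenvalues map to their absolute value; a PSD matrix
        (λmin >= 0) needs no penalty, so λ resolves to 0.
        """
        from . import spectral

        if self.mode == "none":
            return self
        if self.mode == "global":
            if self.value is not None:
                return self
            lam_min = spectral.extremal_eigenvalues(ld).lambda_min
            return PenaltySpec(mode="global", value=max(0.0, -lam_min))
        if self.mode == "per_block":
            blocks = self.blocks
            if blocks is None:
                blocks = [tuple(b) for b in (ld.attrs.get("blocks") or [])]
                if not blocks:
                    raise ValueError("per-block penalty requires block "
                                     "boundaries")
            values = self.block_values
            if values is None:
                mins = spectral.per_block_min_eigenvalues(ld, blocks)
                values = [max(0.0, -v) for v in mins]
            return PenaltySpec(mode="per_block", blocks=list(blocks),
                               block_values=list(values))
        raise ValueError("grid penalties are resolved by the tuning search")

    def lambda_vector(self, M: int) -> np.ndarray:
        if self.mode == "none":
            return np.zeros(M)
        if self.mode == "global":
            if self.value is None:
                raise ValueError("global penalty not resolved")
            return np.full(M, float(self.value))
        if self.mode == "per_block":
            if self.blocks is None or self.block_values is None:
                raise ValueError("per-block penalty not resolved")
            lam = np.zeros(M)
            for (lo, hi), v in zip(self.blocks, self.block_values):
                lam[lo:hi] = v
            return lam
        raise ValueError("grid penalties are resolved by the tuning search")


# ----------------------------------------------------------------------
# Variational state
# ----------------------------------------------------------------------

@dataclass
class VariationalState:
    gamma: np.ndarray
    mu: np.ndarray
    s2: np.ndarray
    eta: np.ndarray
    q: np.ndarray
    pi: float
    sigma_b2: float
    sigma_e2: float
    elbo_trace: list = field(default_factory=list)

    @classmethod
    def initial(cls, M: int, pi: float = 0.01, sigma_b2: Optional[float] = None,
                sigma_e2: float = 0.9, dtype=np.float64) -> "VariationalState":
        if sigma_b2 is None:
            sigma_b2 = max((1.0 - sigma_e2) / max(pi * M, 1.0), 1e-9)
        z = np.zeros(M, dtype=dtype)
        return cls(gamma=np.full(M, pi, dtype=dtype), mu=z.copy(),
                   s2=np.full(M, sigma_b2, dtype=dtype), eta=z.copy(),
                   q=z.copy(), pi=float(pi), sigma_b2=float(sigma_b2),
                   sigma_e2=float(sigma_e2))

    def var_beta(self) -> np.ndarray:
        """Var_q(β_j) = γ_j(μ_j² + s_j²) − η_j² (non-negative by algebra)."""
        return self.gamma * (self.mu ** 2 + self.s2) - self.eta ** 2

    def copy(self) -> "VariationalState":
        return VariationalState(
            gamma=self.gamma.copy(), mu=self.mu.copy(), s2=self.s2.copy(),
            eta=self.eta.copy(), q=self.q.copy(), pi=self.pi,
            sigma_b2=self.sigma_b2, sigma_e2=self.sigma_e2,
            elbo_trace=list(self.elbo_trace))


def posterior_variance(n, sigma_e2, sigma_b2, lambda_min=0.0):
    """Conditional slab variance s² = σ_ε² / (N(1+λ) + σ_ε²/σ_β²)."""
    n = np.asarray(n, dtype=np.float64)
    lam = np.asarray(lambda_min, dtype=np.float64)
    return sigma_e2 / (n * (1.0 + lam) + sigma_e2 / sigma_b2)


# ----------------------------------------------------------------------
# Workspace: harmonized data + prepared CSR views
# ----------------------------------------------------------------------

def harmonize(sumstats: SumstatsTable, ld: LDStore):
    """Align summary statistics to the LD store's variant order.

    Variants are matched on rsID; effect alleles are aligned to the LD
    metadata (a swapped allele pair flips the effect sign, any other
    mismatch drops the variant).  LD variants with no usable summary
    statistic are retained with a zero effect but excluded from the
    coordinate updates, preserving the store's contiguous row structure.

    Returns ``(beta, n, include, report)`` aligned to the LD order.
    """
    M = ld.n_variants
    meta = ld.metadata
    ss = sumstats.table.set_index("rsid")
    ss = ss[~ss.index.duplicated(keep="first")]

    beta = np.zeros(M)
    n = np.full(M, float(np.median(sumstats.n)))
    include = np.zeros(M, dtype=bool)
    n_flipped = n_mismatched = n_absent = 0
    ld_a1 = meta["a1"].astype(str).str.upper().to_numpy()
    ld_a2 = meta["a2"].astype(str).str.upper().to_numpy()
    rsids = meta["rsid"].astype(str).to_numpy()
    for i, rsid in enumerate(rsids):
        if rsid not in ss.index:
            n_absent += 1
            continue
        row = ss.loc[rsid]
        a1, a2 = str(row["a1"]).upper(), str(row["a2"]).upper()
        if (a1, a2) == (ld_a1[i], ld_a2[i]):
            sign = 1.0
        elif (a1, a2) == (ld_a2[i], ld_a1[i]):
            sign = -1.0
            n_flipped += 1
        else:
            n_mismatched += 1
            continue
        beta[i] = sign * float(row["beta"])
        n[i] = float(row["n"])
        include[i] = True

    if not include.any():
        raise ValueError("no variants shared between sumstats and LD store")
    report = {"n_matched": int(include.sum()), "n_flipped": n_flipped,
              "n_mismatched_dropped": n_mismatched,
              "n_absent_in_sumstats": n_absent}
    return beta, n, include, report


class CaviWorkspace:
    """Prepared inference context binding LD, sumstats, and penalty.

    Holds the CSR views the sweep kernels consume.  When the store is
    quantized and was opened lazily, the integer data are kept as-is and
    ``inv_s`` performs dequantize-on-the-fly inside the kernels.
    """

    def __init__(self, sumstats: SumstatsTable, ld: LDStore,
                 penalty: Optional[PenaltySpec] = None,
                 precision: str = "float64"):
        self.ld = ld
        self.precision = precision
        self.dtype = np.float64 if precision == "float64" else np.float32
        M = ld.n_variants

        beta, n, include, self.harmonization = harmonize(sumstats, ld)
        self.bhat = beta.astype(self.dtype)
        self.n_per_variant = n.astype(self.dtype)
        self.include = include
        self.n_eff = float(np.median(n[include]))

        penalty = (penalty or PenaltySpec.none())
        if penalty.mode == "grid":
            raise ValueError("grid penalties must be tuned via "
                             "tuning.lambda_grid_search")
        self.penalty = penalty.resolve(ld)
        self.lam = self.penalty.lambda_vector(M).astype(self.dtype)

        # CSR views.  U: upper-triangular store; S: symmetric off-diagonal.
        U = ld.upper_csr()
        if ld.is_quantized:
            self.inv_s = self.dtype(1.0 / ld.spec.scale)
        else:
            self.inv_s = self.dtype(1.0)
            U = U.astype(self.dtype)
        self.U = U
        S = (U + U.T).tocsr()
        self.S = S
        self._u_view = (U.indptr.astype(np.int64), U.indices.astype(np.int64),
                        U.data)
        self._s_view = (S.indptr.astype(np.int64), S.indices.astype(np.int64),
                        S.data)
        self.state = VariationalState.initial(M, dtype=self.dtype)

    # -- helpers -------------------------------------------------------
    @property
    def M(self) -> int:
        return self.ld.n_variants

    def set_state(self, state: VariationalState) -> None:
        self.state = state
        self.state.gamma = state.gamma.astype(self.dtype)
        self.state.mu = state.mu.astype(self.dtype)
        self.state.s2 = state.s2.astype(self.dtype)
        self.state.eta = state.eta.astype(self.dtype)
        self.refresh_q()

    def refresh_q(self) -> None:
        """Recompute q = (R - I) η from scratch."""
        eta = self.state.eta
        q = float(self.inv_s) * (self.U @ eta + self.U.T @ eta)
        self.state.q = q.astype(self.dtype)

    def quad_form(self, v: np.ndarray) -> float:
        """vᵀ R̃ v through the triangular view."""
        v = np.asarray(v, dtype=np.float64)
        return float(v @ v + 2.0 * float(self.inv_s) * (v @ (self.U @ v)))

    # -- spec operations ----------------------------------------------
    def expected_mse(self) -> float:
        """E_q ||y − Xβ||² / N evaluated under the penalized objective.

        Returns N (1 − 2 bhatᵀη + ηᵀR̃η + Σ λ_j η_j² + Σ (1+λ_j) Var_q β_j).
        Negative values are reported, not raised: they feed the
        instability heuristic.
        """
        st = self.state
        eta = st.eta.astype(np.float64)
        lam = self.lam.astype(np.float64)
        var = st.var_beta().astype(np.float64)
        val = (1.0 - 2.0 * float(self.bhat.astype(np.float64) @ eta)
               + self.quad_form(eta) + float(lam @ (eta ** 2))
               + float((1.0 + lam) @ var))
        return self.n_eff * val

    def elbo(self) -> float:
        st = self.state
        mse = self.expected_mse()
        N = self.n_eff
        fit_term = -0.5 * N * math.log(2.0 * math.pi * st.sigma_e2) \
            - mse / (2.0 * st.sigma_e2)
        g = np.clip(st.gamma[self.include].astype(np.float64), 1e-15,
                    1.0 - 1e-15)
        mu = st.mu[self.include].astype(np.float64)
        s2 = st.s2[self.include].astype(np.float64)
        pi = min(max(st.pi, 1e-15), 1.0 - 1e-15)
        kl_bernoulli = np.sum(g * np.log(g / pi)
                              + (1.0 - g) * np.log((1.0 - g) / (1.0 - pi)))
        kl_gauss = np.sum(g * (0.5 * np.log(st.sigma_b2 / s2)
                               + (s2 + mu ** 2) / (2.0 * st.sigma_b2) - 0.5))
        return float(fit_term - kl_bernoulli - kl_gauss)

    def epoch_symmetric(self, n_chunks: int = 1) -> None:
        """One full pass over all variants using symmetric row access.

        With ``n_chunks == 1`` this is the exact serial reference sweep.
        With more chunks, each chunk is updated against the epoch-start q
        of the other chunks (within-chunk broadcasts still apply), after
        which q is reconciled exactly — a deterministic emulation of
        shared-q concurrent updates and their staleness.
        """
        st = self.state
        indptr, indices, data = self._s_view
        M = self.M
        if n_chunks <= 1:
            _kernels.sweep_range(indptr, indices, data, self.inv_s,
                                 self.bhat, self.n_per_variant, self.include,
                                 st.q, st.gamma, st.mu, st.eta, st.s2,
                                 self.lam, self.dtype(st.pi),
                                 self.dtype(st.sigma_b2),
                                 self.dtype(st.sigma_e2), 0, M, 0, M)
            return
        bounds = np.linspace(0, M, n_chunks + 1).astype(np.int64)
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            _kernels.sweep_range(indptr, indices, data, self.inv_s,
                                 self.bhat, self.n_per_variant, self.include,
                                 st.q, st.gamma, st.mu, st.eta, st.s2,
                                 self.lam, self.dtype(st.pi),
                                 self.dtype(st.sigma_b2),
                                 self.dtype(st.sigma_e2),
                                 int(lo), int(hi), int(lo), int(hi))
        self.refresh_q()

    def epoch_triangular(self) -> None:
        """One pass touching only the stored upper-triangular rows.

        Variants are updated in strictly ascending order; each update
        broadcasts its change forward (to higher indices) through its
        stored row, which is exactly the information the serial symmetric
        sweep would have available.  The backward half of the propagation
        is deferred: after the sweep, one sparse product with U adds
        Σ_{k>j} R_jk Δη_k to every q_j.
        """
        st = self.state
        eta0 = st.eta.copy()
        indptr, indices, data = self._u_view
        M = self.M
        _kernels.sweep_range(indptr, indices, data, self.inv_s,
                             self.bhat, self.n_per_variant, self.include,
                             st.q, st.gamma, st.mu, st.eta, st.s2,
                             self.lam, self.dtype(st.pi),
                             self.dtype(st.sigma_b2),
                             self.dtype(st.sigma_e2), 0, M, 0, M)
        delta = st.eta - eta0
        st.q += (float(self.inv_s) * (self.U @ delta)).astype(self.dtype)

    def m_step(self, frozen: Sequence[str] = ()) -> None:
        """Variational-EM hyperparameter updates (any may be frozen)."""
        st = self.state
        inc = self.include
        M_inc = int(inc.sum())
        g = st.gamma[inc].astype(np.float64)
        if "pi" not in frozen:
            pi = float(np.sum(g)) / M_inc
            st.pi = float(np.clip(pi, 1.0 / M_inc, 1.0 - 1.0 / M_inc))
        if "sigma_b2" not in frozen:
            denom = float(np.sum(g))
            if denom <= 0:
                raise ValueError("all inclusion probabilities are zero; "
                                 "cannot update the slab variance")
            mu = st.mu[inc].astype(np.float64)
            s2 = st.s2[inc].astype(np.float64)
            st.sigma_b2 = float(np.sum(g * (mu ** 2 + s2)) / denom)
        if "sigma_e2" not in frozen:
            st.sigma_e2 = float(np.clip(self.expected_mse() / self.n_eff,
                                        _SIGMA_E2_FLOOR, 1.0))


def coordinate_update(j: int, ws: CaviWorkspace) -> float:
    """Reference (pure python) update of a single coordinate.

    Mirrors the kernel math exactly; used as the oracle for kernel
    equivalence.  Returns the change in η_j, which is broadcast into
    neighbors' q through the symmetric rows.
    """
    st = ws.state
    if not ws.include[j]:
        return 0.0
    nj = float(ws.n_per_variant[j])
    lam_j = float(ws.lam[j])
    s2_j = st.sigma_e2 / (nj * (1.0 + lam_j) + st.sigma_e2 / st.sigma_b2)
    mu_j = (nj * s2_j / st.sigma_e2) * (float(ws.bhat[j]) - float(st.q[j]))
    logit = math.log(st.pi / (1.0 - st.pi)) \
        + 0.5 * math.log(s2_j / st.sigma_b2) + mu_j ** 2 / (2.0 * s2_j)
    if logit > 30.0:
        gamma_j = 1.0
    elif logit < -30.0:
        gamma_j = math.exp(logit)
    else:
        gamma_j = 1.0 / (1.0 + math.exp(-logit))
    eta_new = gamma_j * mu_j
    d = eta_new - float(st.eta[j])
    st.s2[j] = s2_j
    st.mu[j] = mu_j
    st.gamma[j] = gamma_j
    st.eta[j] = eta_new
    if d != 0.0:
        S = ws.S
        lo, hi = S.indptr[j], S.indptr[j + 1]
        cols = S.indices[lo:hi]
        st.q[cols] += (S.data[lo:hi] * float(ws.inv_s) * d).astype(ws.dtype)
    return d


# module-level aliases matching the operation names
def epoch_symmetric(ws: CaviWorkspace, n_chunks: int = 1) -> VariationalState:
    ws.epoch_symmetric(n_chunks)
    return ws.state


def epoch_triangular(ws: CaviWorkspace) -> VariationalState:
    ws.epoch_triangular()
    return ws.state


def expected_mse(ws: CaviWorkspace) -> float:
    return ws.expected_mse()


def m_step(ws: CaviWorkspace, frozen: Sequence[str] = ()) -> tuple:
    ws.m_step(frozen)
    st = ws.state
    return st.pi, st.sigma_b2, st.sigma_e2


# ----------------------------------------------------------------------
# Fit driver
# ----------------------------------------------------------------------

@dataclass
class PRSModel:
    """Fitted posterior summary for one LD region / chromosome."""

    eta: np.ndarray            # posterior mean effects, standardized scale
    gamma: np.ndarray          # posterior inclusion probabilities
    mu: np.ndarray
    s2: np.ndarray
    pi: float
    sigma_b2: float
    sigma_e2: float
    elbo_trace: list
    converged: bool
    n_epochs: int
    metadata: pd.DataFrame
    stability_log: list = field(default_factory=list)
    harmonization: dict = field(default_factory=dict)
    mode: str = "triangular"
    precision: str = "float64"

    @property
    def h2(self) -> float:
        """Heritability under the standardized-phenotype convention."""
        return 1.0 - self.sigma_e2

    def per_allele_beta(self) -> np.ndarray:
        """Posterior mean effects per copy of allele 1."""
        maf = self.metadata["maf"].to_numpy(dtype=np.float64)
        sd = np.sqrt(np.maximum(2.0 * maf * (1.0 - maf), 1e-12))
        return self.eta / sd

    def to_fit_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "CHR": self.metadata["chr"].to_numpy(),
            "SNP": self.metadata["rsid"].to_numpy(),
            "POS": self.metadata["pos"].to_numpy(),
            "A1": self.metadata["a1"].to_numpy(),
            "A2": self.metadata["a2"].to_numpy(),
            "PIP": np.asarray(self.gamma, dtype=np.float64),
            "BETA": self.per_allele_beta(),
        })

    def report(self) -> dict:
        return {
            "pi": self.pi, "sigma_b2": self.sigma_b2,
            "sigma_e2": self.sigma_e2, "h2": self.h2,
            "converged": self.converged, "n_epochs": self.n_epochs,
            "elbo_trace": [float(e) for e in self.elbo_trace],
            "stability_log": self.stability_log,
            "harmonization": self.harmonization,
            "mode": self.mode, "precision": self.precision,
        }


def fit(sumstats: SumstatsTable, ld: LDStore,
        penalty: Optional[PenaltySpec] = None, *,
        mode: str = "triangular", n_chunks: int = 1,
        precision: str = "float64", tol: float = 1e-5,
        max_iter: int = 1000, fixed_pi: Optional[float] = None,
        fixed_sigma_b2: Optional[float] = None,
        fixed_sigma_e2: Optional[float] = None,
        init_state: Optional[VariationalState] = None,
        workspace: Optional[CaviWorkspace] = None) -> PRSModel:
    """Run variational EM to convergence.

    Alternates coordinate-ascent epochs with hyperparameter updates until
    the relative ELBO change stays below ``tol`` for two consecutive
    iterations (or ``max_iter`` is hit).  On detected instability (ELBO
    drop beyond slack, negative expected MSE, non-finite or exploding
    parameters) with chunked execution, the last stable state is restored
    and the chunk count decremented before resuming; instability that
    persists at serial execution raises
    :class:`NumericalInstabilityError` advising a λmin penalty.
    """
    if mode not in ("symmetric", "triangular"):
        raise ValueError(f"unknown LD mode: {mode!r}")
    ws = workspace or CaviWorkspace(sumstats, ld, penalty, precision)

    frozen = []
    if fixed_pi is not None:
        frozen.append("pi")
    if fixed_sigma_b2 is not None:
        frozen.append("sigma_b2")
    if fixed_sigma_e2 is not None:
        frozen.append("sigma_e2")

    if init_state is not None:
        ws.set_state(init_state.copy())
    else:
        pi0 = fixed_pi if fixed_pi is not None else 0.05
        ws.state = VariationalState.initial(
            ws.M, pi=pi0,
            sigma_b2=fixed_sigma_b2, sigma_e2=fixed_sigma_e2 or 0.9,
            dtype=ws.dtype)
    st = ws.state
    if fixed_pi is not None:
        st.pi = float(fixed_pi)
    if fixed_sigma_b2 is not None:
        st.sigma_b2 = float(fixed_sigma_b2)
    if fixed_sigma_e2 is not None:
        st.sigma_e2 = float(fixed_sigma_e2)

    stability_log: list = []
    elbo_prev = -np.inf
    stable_snapshot = ws.state.copy()
    elbo_stable = -np.inf
    n_below_tol = 0
    converged = False
    epoch = 0
    while epoch < max_iter:
        epoch += 1
        if mode == "triangular":
            ws.epoch_triangular()
        else:
            ws.epoch_symmetric(n_chunks)
        ws.m_step(frozen)
        st = ws.state
        mse = ws.expected_mse()
        elbo = ws.elbo()
        st.elbo_trace.append(elbo)

        eta_sq = float(np.sum(st.eta.astype(np.float64) ** 2))
        slack = 1e-6 * max(1.0, abs(elbo_prev))
        unstable = (
            not np.isfinite(elbo)
            or not np.isfinite(eta_sq)
            or mse < 0.0
            or eta_sq > _ETA_SQ_DIVERGENCE
            or (np.isfinite(elbo_prev) and elbo < elbo_prev - max(slack, 1e-3 * max(1.0, abs(elbo_prev))))
        )
        if unstable:
            if n_chunks > 1:
                n_chunks -= 1
                stability_log.append({
                    "epoch": epoch, "event": "instability",
                    "action": f"reduced chunk concurrency to {n_chunks}",
                    "elbo": float(elbo), "expected_mse": float(mse),
                })
                ws.set_state(stable_snapshot.copy())
                # keep the snapshot's ELBO as the reference so a renewed
                # divergence is caught on the very next epoch
                elbo_prev = elbo_stable
                n_below_tol = 0
                continue
            raise NumericalInstabilityError(
                "inference diverged under serial execution "
                f"(expected MSE = {mse:.3g}, Ση² = {eta_sq:.3g}); the LD "
                "matrix is likely not positive semi-definite — consider "
                "refitting with a λmin penalty")

        stable_snapshot = ws.state.copy()
        elbo_stable = elbo
        if np.isfinite(elbo_prev):
            rel = abs(elbo - elbo_prev) / max(abs(elbo_prev), 1.0)
            n_below_tol = n_below_tol + 1 if rel < tol else 0
            if n_below_tol >= 2:
                converged = True
                break
        elbo_prev = elbo

    st = ws.state
    return PRSModel(
        eta=np.asarray(st.eta, dtype=np.float64).copy(),
        gamma=np.asarray(st.gamma, dtype=np.float64).copy(),
        mu=np.asarray(st.mu, dtype=np.float64).copy(),
        s2=np.asarray(st.s2, dtype=np.float64).copy(),
        pi=st.pi, sigma_b2=st.sigma_b2, sigma_e2=st.sigma_e2,
        elbo_trace=list(st.elbo_trace), converged=converged,
        n_epochs=epoch, metadata=ld.metadata,
        stability_log=stability_log, harmonization=ws.harmonization,
        mode=mode, precision=precision)
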