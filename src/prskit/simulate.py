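"""Synthetic genotype / phenotype / GWAS fixture generator.

Nothing here emulates real demography; the generator produces the
simplest data that exercise block versus banded LD structure and the
spike-and-slab generative model the inference assumes:

* **Genotypes** — per haplotype, a latent Gaussian with block-wise
  first-order autoregressive correlation (corr(z_i, z_j) = ρ^|i−j| inside
  a block, 0 across blocks) is thresholded at the MAF-matched quantile;
  a dosage is the sum of two independent haplotypes.  Centimorgan
  positions place each block in its own tight cM cluster with wide gaps
  in between, so a windowed mask reproduces the block structure.
* **Phenotype** — each variant is causal with probability π, causal
  effects are Normal(0, h²/(π·M)) on the standardized scale, and the
  environmental noise is scaled so the realized genetic variance share
  matches h².
* **GWAS** — marginal effects on standardized data: ``bhat_j = x_jᵀy/N``
  with SE = 1/√N and Z = bhat·√N, the convention the inference engine
  expects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cavi import SumstatsTable
from .ld_estimate import GenotypePanel

__all__ = [
    "SimulationConfig",
    "StudyData",
    "simulate_genotypes",
    "simulate_phenotype",
    "marginal_gwas",
    "simulate_study",
]

_ALLELE_PAIRS = [("A", "G"), ("C", "A"), ("G", "T"), ("T", "C")]


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 1000
    n_variants: int = 200
    block_size: int = 50
    rho: float = 0.7          # within-block AR(1) correlation decay
    maf_low: float = 0.05
    maf_high: float = 0.5
    missing_rate: float = 0.0
    pi: float = 0.05          # causal fraction
    h2: float = 0.5           # heritability
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.h2 < 1.0):
            raise ValueError("h2 must lie in [0, 1)")
        if not (0.0 < self.pi <= 1.0):
            raise ValueError("pi must lie in (0, 1]")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")

    def block_intervals(self) -> list[tuple[int, int]]:
        edges = list(range(0, self.n_variants, self.block_size))
        edges.append(self.n_variants)
        return [(lo, hi) for lo, hi in zip(edges[:-1], edges[1:]) if hi > lo]


def _haplotype_block(rng, n, width, rho, thresholds) -> np.ndarray:
    """One block of allele indicators: latent AR(1) Gaussians
    (z_i = ρ z_{i-1} + sqrt(1-ρ²) ε_i) thresholded at the MAF quantile."""
    eps = rng.standard_normal((n, width)).astype(np.float32)
    innov = np.float32(np.sqrt(1.0 - rho ** 2))
    z = eps[:, 0].copy()
    out = np.empty((n, width), dtype=np.uint8)
    out[:, 0] = z > thresholds[0]
    for j in range(1, width):
        z = np.float32(rho) * z + innov * eps[:, j]
        out[:, j] = z > thresholds[j]
    return out


def simulate_genotypes(config: SimulationConfig) -> GenotypePanel:
    """Draw a correlated dosage panel; reproducible under a fixed seed.

    Generated block by block in single precision to keep the memory
    footprint proportional to one block, not the whole panel.
    """
    rng = np.random.default_rng(config.seed)
    n, M = config.n_samples, config.n_variants
    maf = rng.uniform(config.maf_low, config.maf_high, size=M)
    # allele indicator: latent gaussian above the (1 - maf) quantile
    thresholds = norm.ppf(1.0 - maf).astype(np.float32)
    dosages = np.empty((n, M), dtype=np.float32)
    for lo, hi in config.block_intervals():
        h1 = _haplotype_block(rng, n, hi - lo, config.rho, thresholds[lo:hi])
        h2 = _haplotype_block(rng, n, hi - lo, config.rho, thresholds[lo:hi])
        dosages[:, lo:hi] = h1 + h2
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    # cM positions: tight clusters per block, 10 cM gaps between blocks
    cm = np.empty(M)
    for b, (lo, hi) in enumerate(config.block_intervals()):
        cm[lo:hi] = b * 10.0 + np.arange(hi - lo) * 0.01
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(M)]
    variants = pd.DataFrame({
        "chr": np.ones(M, dtype=np.int64),
        "rsid": [f"rs{i}" for i in range(M)],
        "cm": cm,
        "pos": (cm * 1e5).astype(np.int64) + 1,
        "a1": [a for a, _ in alleles],
        "a2": [b for _, b in alleles],
    })
    return GenotypePanel(dosages=dosages, variants=variants)


def _standardized(dosages: np.ndarray) -> np.ndarray:
    """Column-standardized copy, in single precision to bound memory."""
    X = np.asarray(dosages, dtype=np.float32).copy()
    if np.isnan(X).any():
        means = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), means, X).astype(np.float32)
    mu = X.mean(axis=0, dtype=np.float64)
    sd = X.std(axis=0, dtype=np.float64)
    sd[sd == 0] = 1.0
    X -= mu.astype(np.float32)
    X /= sd.astype(np.float32)
    return X


def simulate_phenotype(panel: GenotypePanel, pi: float, h2: float,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Spike-and-slab phenotype; returns (phenotype, true standardized β).

    The noise variance is matched to the *realized* genetic variance so
    that Var(Xβ)/Var(y) ≈ h² in every draw.  If no causal variant is
    drawn, the causal set is redrawn once before giving up.
    """
    if not (0.0 <= h2 < 1.0):
        raise ValueError("h2 must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    M = panel.n_variants
    X = _standardized(panel.dosages)

    beta = np.zeros(M)
    if h2 > 0:
        causal = rng.random(M) < pi
        if not causal.any():
            causal = rng.random(M) < pi
        if not causal.any():
            raise ValueError("no causal variants drawn; increase pi or M")
        beta[causal] = rng.normal(0.0, np.sqrt(h2 / (pi * M)),
                                  size=int(causal.sum()))
    g = (X @ beta.astype(np.float32)).astype(np.float64)
    var_g = float(np.var(g))
    if h2 > 0 and var_g > 0:
        noise_sd = np.sqrt(var_g * (1.0 - h2) / h2)
    else:
        noise_sd = 1.0
    y = g + rng.normal(0.0, noise_sd, size=panel.n_samples)
    return y, beta


def marginal_gwas(panel: GenotypePanel, phenotype: np.ndarray,
                  n_override: Optional[int] = None) -> SumstatsTable:
    """Single-variant association scan on standardized data.

    Zero-variance variants are excluded (their correlation with the
    phenotype is undefined).
    """
    y = np.asarray(phenotype, dtype=np.float64)
    y = (y - y.mean()) / y.std()
    N = len(y)
    sd = np.nanstd(panel.dosages, axis=0)
    keep = sd > 0
    X = _standardized(panel.dosages[:, keep])
    bhat = (X.T @ y.astype(np.float32)).astype(np.float64) / N
    n = float(n_override or N)
    v = panel.variants.loc[keep].reset_index(drop=True)
    table = pd.DataFrame({
        "rsid": v["rsid"].to_numpy(),
        "chr": v["chr"].to_numpy(),
        "pos": v["pos"].to_numpy(),
        "a1": v["a1"].to_numpy(),
        "a2": v["a2"].to_numpy(),
        "beta": bhat,
        "se": np.full(len(bhat), 1.0 / np.sqrt(n)),
        "z": bhat * np.sqrt(n),
        "n": np.full(len(bhat), n),
    })
    return SumstatsTable(table)


# ----------------------------------------------------------------------
# Streaming study generator
# ----------------------------------------------------------------------

@dataclass
class StudyData:
    """One simulated GWAS study: sumstats, LD store, truth, test panel."""

    sumstats: "SumstatsTable"
    ld: object                      # LDStore
    beta_true: np.ndarray           # standardized causal effects
    test_panel: GenotypePanel
    y_test: np.ndarray
    h2_realized: float


def _variant_map(config: SimulationConfig, maf: np.ndarray) -> pd.DataFrame:
    M = config.n_variants
    cm = np.empty(M)
    for b, (lo, hi) in enumerate(config.block_intervals()):
        cm[lo:hi] = b * 10.0 + np.arange(hi - lo) * 0.01
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(M)]
    return pd.DataFrame({
        "chr": np.ones(M, dtype=np.int64),
        "rsid": [f"rs{i}" for i in range(M)],
        "cm": cm,
        "pos": (cm * 1e5).astype(np.int64) + 1,
        "a1": [a for a, _ in alleles],
        "a2": [b for _, b in alleles],
        "maf": np.minimum(maf, 1.0 - maf),
    })


def simulate_study(config: SimulationConfig, n_test: int = 2000,
                   qspec=None) -> StudyData:
    """Simulate a full GWAS study block by block, without ever holding the
    training genotype matrix in memory.

    For each LD block the training haplotypes are generated from a
    dedicated child seed, so the block can be re-generated cheaply: the
    first pass accumulates the genetic value Xβ and the in-sample LD
    (a Gram matrix per block), and a second pass — after the phenotype
    noise is fixed — computes the marginal GWAS effects against the
    complete phenotype.  A held-out test panel with the same allele
    frequencies and causal effects is returned for out-of-sample scoring.

    Peak memory is proportional to one block (N x block_size), which
    keeps study-scale replicates (e.g., N = 50,000) tractable.
    """
    from .ld_store import LDStore, QuantizationSpec, quantize

    qspec = qspec or QuantizationSpec("int8")
    rng = np.random.default_rng(config.seed)
    n, M = config.n_samples, config.n_variants
    maf = rng.uniform(config.maf_low, config.maf_high, size=M)
    thresholds = norm.ppf(1.0 - maf).astype(np.float32)
    blocks = config.block_intervals()
    seeds = np.random.SeedSequence(config.seed).spawn(2 * len(blocks) + 1)
    block_seeds = seeds[: len(blocks)]
    test_seeds = seeds[len(blocks): 2 * len(blocks)]
    pheno_rng = np.random.default_rng(seeds[-1])

    # causal architecture
    beta = np.zeros(M)
    if config.h2 > 0:
        causal = pheno_rng.random(M) < config.pi
        if not causal.any():
            causal = pheno_rng.random(M) < config.pi
        if not causal.any():
            raise ValueError("no causal variants drawn; increase pi or M")
        beta[causal] = pheno_rng.normal(
            0.0, np.sqrt(config.h2 / (config.pi * M)),
            size=int(causal.sum()))
    beta32 = beta.astype(np.float32)

    def train_block(b: int, lo: int, hi: int) -> np.ndarray:
        """Standardized training genotypes for block b (regenerable)."""
        brng = np.random.default_rng(block_seeds[b])
        h1 = _haplotype_block(brng, n, hi - lo, config.rho, thresholds[lo:hi])
        h2_ = _haplotype_block(brng, n, hi - lo, config.rho, thresholds[lo:hi])
        X = (h1 + h2_).astype(np.float32)
        if config.missing_rate > 0:
            miss = brng.random(X.shape) < config.missing_rate
            # mean imputation inside the generator mirrors the default
            # LD-estimation policy
            X[miss] = np.nan
            col_mean = np.nanmean(X, axis=0)
            X = np.where(np.isnan(X), col_mean, X).astype(np.float32)
        mu = X.mean(axis=0, dtype=np.float64).astype(np.float32)
        sd = X.std(axis=0, dtype=np.float64)
        sd[sd == 0] = 1.0
        X -= mu
        X /= sd.astype(np.float32)
        return X

    # pass 1: genetic values + per-block LD
    g = np.zeros(n, dtype=np.float64)
    emp_maf = np.empty(M)
    ld_rows = []
    indptr = np.zeros(M + 1, dtype=np.int64)
    for b, (lo, hi) in enumerate(blocks):
        X = train_block(b, lo, hi)
        g += (X @ beta32[lo:hi]).astype(np.float64)
        C = np.clip((X.T @ X).astype(np.float64) / n, -1.0, 1.0)
        emp_maf[lo:hi] = np.minimum(maf[lo:hi], 1.0 - maf[lo:hi])
        for i in range(lo, hi):
            run = C[i - lo, i - lo + 1:]
            ld_rows.append(run)
            indptr[i + 1] = indptr[i] + len(run)

    var_g = float(np.var(g))
    if config.h2 > 0 and var_g > 0:
        noise_sd = np.sqrt(var_g * (1.0 - config.h2) / config.h2)
    else:
        noise_sd = 1.0
    y = g + pheno_rng.normal(0.0, noise_sd, size=n)
    h2_realized = var_g / float(np.var(y))
    y_std = ((y - y.mean()) / y.std()).astype(np.float32)

    # pass 2: marginal effects against the full phenotype
    bhat = np.empty(M)
    for b, (lo, hi) in enumerate(blocks):
        X = train_block(b, lo, hi)
        bhat[lo:hi] = (X.T @ y_std).astype(np.float64) / n

    data = np.concatenate(ld_rows) if ld_rows else np.empty(0)
    if qspec.is_integer:
        data = quantize(data, qspec)
    else:
        data = data.astype(qspec.numpy_dtype)
    variants = _variant_map(config, maf)
    metadata = variants.rename(columns={})[
        ["rsid", "chr", "pos", "cm", "a1", "a2", "maf"]].copy()
    metadata["ldscore"] = 1.0
    ld = LDStore(data=data, indptr=indptr, metadata=metadata, spec=qspec,
                 attrs={
                     "estimator": "block",
                     "estimator_params": {"n_blocks": len(blocks)},
                     "blocks": [list(b) for b in blocks],
                     "missing_policy": "mean_impute",
                     "sample_size": n,
                     "ancestry": "synthetic",
                 })

    table = pd.DataFrame({
        "rsid": metadata["rsid"].to_numpy(),
        "chr": metadata["chr"].to_numpy(),
        "pos": metadata["pos"].to_numpy(),
        "a1": metadata["a1"].to_numpy(),
        "a2": metadata["a2"].to_numpy(),
        "beta": bhat,
        "se": np.full(M, 1.0 / np.sqrt(n)),
        "z": bhat * np.sqrt(n),
        "n": np.full(M, float(n)),
    })
    sumstats = SumstatsTable(table)

    # held-out test panel: same frequencies and effects, fresh samples
    test_dosages = np.empty((n_test, M), dtype=np.float32)
    g_test = np.zeros(n_test, dtype=np.float64)
    for b, (lo, hi) in enumerate(blocks):
        trng = np.random.default_rng(test_seeds[b])
        h1 = _haplotype_block(trng, n_test, hi - lo, config.rho,
                              thresholds[lo:hi])
        h2_ = _haplotype_block(trng, n_test, hi - lo, config.rho,
                               thresholds[lo:hi])
        Xb = (h1 + h2_).astype(np.float32)
        test_dosages[:, lo:hi] = Xb
        mu = Xb.mean(axis=0, dtype=np.float64).astype(np.float32)
        sd = Xb.std(axis=0, dtype=np.float64)
        sd[sd == 0] = 1.0
        g_test += ((Xb - mu) / sd.astype(np.float32)
                   @ beta32[lo:hi]).astype(np.float64)
    var_gt = float(np.var(g_test))
    noise_sd_t = (np.sqrt(var_gt * (1.0 - config.h2) / config.h2)
                  if config.h2 > 0 and var_gt > 0 else 1.0)
    y_test = g_test + pheno_rng.normal(0.0, noise_sd_t, size=n_test)
    test_panel = GenotypePanel(dosages=test_dosages,
                               variants=variants.drop(columns=["maf"]))
    return StudyData(sumstats=sumstats, ld=ld, beta_true=beta,
                     test_panel=test_panel, y_test=y_test,
                     h2_realized=h2_realized)
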