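# Methods

## Model

`prskit` fits a sparse Bayesian multiple-regression model to GWAS summary
statistics. With genotypes X (N samples × M variants) and phenotype y both
standardized column-wise, the marginal GWAS effect for variant j is
β̂_j = x_jᵀy/N and the in-sample mean squared error of a candidate joint
effect vector β satisfies

    MSE(β) = 1 − 2 β̂ᵀβ + βᵀRβ ≥ 0,

where R is the in-sample LD (correlation) matrix. Joint effects carry a
spike-and-slab prior: β_j = 0 with probability 1−π, and
β_j ~ N(0, σ_β²) with probability π. Inference uses coordinate-ascent
variational inference (CAVI) with a fully factorized posterior family; the
per-variant parameters are the posterior inclusion probability γ_j, the
conditional slab mean μ_j, and conditional variance s_j². Writing
η_j = γ_j μ_j for the posterior mean and q_j = Σ_{k≠j} R_jk η_k for the
LD-weighted neighbor sum, the closed-form updates are

    s_j² = σ_ε² / (N_j (1+λ_j) + σ_ε²/σ_β²)
    μ_j  = (N_j s_j² / σ_ε²) (β̂_j − q_j)
    γ_j  = logistic( log(π/(1−π)) + ½ log(s_j²/σ_β²) + μ_j²/(2 s_j²) )

with λ_j ≥ 0 an optional stability penalty (below). Hyperparameters are
updated by variational EM: π = Σγ/M (clipped to [1/M, 1−1/M]),
σ_β² = Σγ(μ²+s²)/Σγ, and σ_ε² = E_q[MSE]/N clipped to (10⁻⁶, 1]. Under
the standardized-phenotype convention the SNP heritability is reported as
h² = 1 − σ_ε². For M = 1 the factorized family is exact, and the test
suite verifies the reconstructed μ/γ forms against the true single-variant
posterior by numerical integration.

The penalized expected MSE used in the ELBO and the σ_ε² update is

    N (1 − 2 β̂ᵀη + ηᵀR̃η + λ·ηᵀη + Σ_j (1+λ_j) Var_q(β_j)),

i.e. the exact expectation of ‖y − Xβ‖²/σ-free form under the variational
density with R̃ replaced by R̃ + λI. The λ·ηᵀη term is retained (it falls
out of E_q[βᵀ(R̃+λI)β]) so that the serial coordinate updates provably
ascend the same objective the monitor evaluates; dropping it leaves the
parameter updates unchanged but breaks ELBO monotonicity diagnostics under
a penalty.

## LD storage

The LD matrix is symmetric with unit diagonal, so only the strictly
upper-triangular part is stored. Sparsity masks (windowed/banded by
centimorgan distance, or block-diagonal from an LD-block file) make each
row's retained columns a contiguous run immediately right of the diagonal,
so a CSR layout needs no column-index array: a single long `data` array
plus an `indptr` array of length M+1. Interior zeros inside a run are
stored explicitly; scattered sparsity is out of scope.

Entries are held as float64/float32 or scale-quantized to int16/int8 with
s = 2^(b−1) − 1 (127, 32767): q = round(r·s) with round-half-to-even,
r ≈ q/s. The worst-case round-trip error is 1/(2s) — ≈0.0039 for int8,
≈1.5×10⁻⁵ for int16 — and the step sizes are ≈0.008 and ≈0.00003. float16
is deliberately not offered (no portable encoding guarantee across
platforms). On disk the store is a Zarr hierarchy (`matrix/{data,indptr}`,
`metadata/{rsid,chr,pos,cm,a1,a2,maf,ldscore}`) with ~1 MB chunks,
Zstandard compression, and root attributes recording dtype, scale,
estimator kind and parameters, missing-data policy, sample size, and
ancestry. Zarr format 2 is used for its stable variable-width string
encoding.

LD estimation supports two missing-data policies. Mean imputation
completes each variant with its observed mean and computes all
correlations from the same completed matrix, so block-diagonal masks yield
Gram matrices that are PSD up to quantization error. Pairwise-complete
estimation (the plink 1.9 convention) drops samples missing at either
variant, estimating each entry on a different subset; a regression test
reproduces the resulting indefiniteness on a crafted toy. Variant filters
follow common practice: MAC ≥ 20 by default, optional MAF floor, optional
removal of strand-ambiguous (A/T, C/G) variants.

## Spectral diagnostics and the λmin penalty

A `LinearOperator` view computes (I + U + Uᵀ)v directly on the compressed
store (integer data are descaled inside the product, so quantized stores
never need materializing). λmax comes from ARPACK's largest-magnitude
Lanczos iteration; λmin from the shifted operator R − λmax·I, avoiding
factorization of indefinite matrices. The starting vector is fixed
(seeded) so reports are reproducible; default tolerance 1e-6, iteration
cap 10·M. Degenerate spectra that break the Lanczos recurrence (e.g. exact
identity matrices) fall back to a dense decomposition below M = 4096.

When λmin(R̃) < 0 the quadratic form can go negative and coordinate ascent
runs away along the offending eigenvector. The remedy replaces R̃ with
R̃ + |λmin|I, which only changes the diagonal term in the updates (the
(1+λ) factor in s_j²) and acts as extra shrinkage. The penalty may be a
single chromosome-wide value, one value per genomic block (λ of the
block's diagonal submatrix; for block-masked stores the concatenated block
spectra equal the full spectrum), or a grid of multiples
{0, 0.01, 0.1, 1, 2}·|λmin| tuned on validation data.

## Execution modes

*Symmetric* mode walks all variants in ascending order against full
(two-sided) rows, broadcasting each Δη to all neighbors — the classic
right-hand update scheme. *Triangular* (low-memory) mode touches only the
stored upper-triangular rows: during the ascending sweep each update
broadcasts forward only (exactly the information the serial scheme would
have), and one sparse product with U afterwards adds the missing backward
contributions to q. The two modes agree to float tolerance at the end of
every epoch, which the suite asserts directly. *Dequantize-on-the-fly*
keeps the integers in memory and folds 1/s into the kernels.

Chunked execution emulates parallel coordinate ascent: the variant range
is split into chunks that are updated against the epoch-start q of the
other chunks (within-chunk broadcasts still apply), after which q is
reconciled exactly. This is a deterministic model of shared-q threads with
one-epoch staleness; it reproduces the known pathology of parallel
coordinate methods (oscillation when the variants/chunks ratio is small).
The fit driver monitors the ELBO, the expected MSE, and Ση² each epoch; on
instability (ELBO drop beyond slack, negative expected MSE, non-finite or
exploding parameters) it restores the last stable state and decrements the
chunk count, falling back to fully serial execution before declaring a
hard failure that advises the λmin penalty. The inner sweeps are numba
kernels specialized per dtype (float64, float32, int8/int16 + scale);
float32 execution stores all parameter state in single precision.

## Hyperparameter tuning

Validation data are synthesized from the summary statistics themselves:
given β̂ on N samples, training-subset effects for a fraction p are drawn
per contiguous block (≤ 500 variants, respecting LD-block boundaries when
present) as β̂_train ~ N(β̂, (1/(Np) − 1/N) R̃_block) via eigendecomposition
with negative eigenvalues clipped at zero, and validation effects follow
from the exact identity β̂_val = (β̂ − p·β̂_train)/(1−p), so
p·β̂_train + (1−p)·β̂_val = β̂ holds for every variant and draw. Effective
sample sizes Np and N(1−p) are recorded; p defaults to 0.8.

The candidate π grid is 20 log10-spaced points from 10/M to 0.2. The
pathwise search fits frozen-π models in ascending π, warm-starting each
fit from the previous grid point's full variational state (γ, μ, s², η
and the free hyperparameters — carrying everything was the design choice;
carrying only (γ, μ) is the noted alternative). Models are scored by the
validation pseudo-R²,

    (ηᵀ β̂_val)² / (ηᵀ R̃ η),

the squared PRS–phenotype correlation in the noiseless standardized limit;
the suite checks it against realized R² on simulated individual-level
validation data. Ties select the smaller π. The winner is refitted on the
original, unsplit summary statistics with π frozen. In simulations the
pseudo-R² profile is typically flat (differences ~1e-4) for π at or above
the truth, so selection resolves to the sparse end of the plateau — a
known property of this metric, relevant when interpreting selected values.

## Evaluation

Scoring is the dosage-weighted sum of per-allele effects
(standardized-scale η divided by √(2·maf·(1−maf))), with allele-flip sign
handling and mean-dosage imputation for missing calls. Accuracy is
incremental R²: R² of an OLS fit of the phenotype on PRS + covariates
minus the covariates-only R², phenotypes kept on their original scale.
Phenotype outliers beyond 3 SD of the mean are removed in a single pass
(the mean/SD are not re-estimated after removal).

## Synthetic data

The generator emulates the generative model the inference assumes, not
human demography. Haplotypes are latent Gaussians with block-wise AR(1)
correlation ρ^|i−j| (ρ = 0.7 by default), thresholded at the quantile of a
MAF drawn uniformly from [0.05, 0.5]; dosages are sums of two independent
haplotypes, which attenuates the latent correlation (adjacent dosage r ≈
0.5–0.7 at ρ = 0.9). Blocks sit in tight centimorgan clusters separated by
10 cM so windowed masks reproduce the block structure. Phenotypes follow
the spike-and-slab model with causal fraction π and effects
N(0, h²/(πM)); noise is scaled to the realized genetic variance so
Var(Xβ)/Var(y) matches h² per draw. Marginal GWAS effects are x_jᵀy/N with
SE 1/√N on standardized data.

Because real LD has long-range structure, allele-frequency–dependent
architecture, and cross-block leakage that this model lacks, passing tests
demonstrate correctness of the algorithms under their own assumptions, not
field performance on biobank data.

Two generator APIs exist: a panel-materializing one
(`simulate_genotypes` / `simulate_phenotype` / `marginal_gwas`) for
moderate sizes, and a streaming one (`simulate_study`) that generates each
block from its own child seed, accumulates the genetic value and per-block
Gram LD in a first pass, fixes the phenotype noise, and recomputes blocks
in a second pass for the marginal scan — peak memory stays proportional to
one block, which makes study-scale replicates (N = 50,000, M = 2,000,
20 replicates for the parameter-recovery suite) practical on one CPU.

## Numerical choices and defaults

- Convergence: relative ELBO change < 1e-5 on two consecutive iterations;
  cap 1,000 epochs.
- σ_ε² clipped to (1e-6, 1]; π clipped to [1/M, 1−1/M].
- Update order strictly ascending variant index (required for the
  triangular scheme's correctness).
- Divergence monitor: Ση² > 100 (any real standardized architecture has
  Ση² ≈ h² ≤ 1), negative expected MSE, non-finite ELBO, or an ELBO drop
  beyond 10⁻³·|ELBO| slack.
- Harmonization: variants matched on rsID; swapped allele pairs flip the
  effect sign; other mismatches are dropped and counted. LD variants
  absent from the sumstats are retained with zero effect but never
  updated, preserving the contiguous row structure.
- Eigenvalue tolerance 1e-6; quantizing a matrix perturbs λmin by at most
  M·resolution (tested bound), so int16 is recommended when spectra
  matter.
- Ties in model selection go to the sparsest model (smallest π, smallest
  λ multiplier).

## Known limitations

- Scattered (non-contiguous) sparsity and shrinkage LD estimators are not
  supported; cross-chromosome LD is never computed.
- Single slab component; no annotation-informed or multi-component priors.
- Chunked execution is an emulation contract, not OS threading; wall-clock
  parallel speedups are out of scope.
- The pseudo-R² selection plateau means the reported "selected π" is a
  lower envelope of equally predictive models rather than a point estimate
  of the causal fraction.
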