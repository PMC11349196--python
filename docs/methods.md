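# Methods

## Model

`vbfinemap` fine-maps a GWAS locus from summary statistics.  The observed
data are per-SNP z-scores z = (z₁,…,z_M)ᵀ.  With N the GWAS sample size,
Hᵢ = 2fᵢ(1−fᵢ) the heterozygosity of SNP i and r̂ᵢⱼ the SNP–SNP Pearson
correlation (LD), define the scaled LD matrix

    a_ij = √(N·Hᵢ) · r̂ᵢⱼ .

The z-scores follow the linear summary-statistic model

    z = Aᵀβ + e ,   e_j ~ N(0, σ₀²)  (independent),

and each true effect βᵢ carries a spike-and-slab prior: with probability
π₁ the SNP is causal and βᵢ ~ N(0, σ_β²) (slab); otherwise βᵢ ~ N(0, δ²)
with δ² a small fixed spike variance standing in for a point mass.  The
locus heritability ties the hyperparameters together through
h² = σ_β²·π₁·ΣᵢHᵢ.

Exact posterior inference is intractable (2^M causal configurations), so
the package maximizes the evidence lower bound (ELBO) over the mean-field
family

    q(β, u) = ∏ᵢ Bern(uᵢ | qᵢ) · N(βᵢ | μᵢ, σᵢ²),

where qᵢ is the posterior causal probability (PIP) of SNP i.  The ELBO
decomposes as L = T1 − T2 − T3 (expected log-likelihood, u-averaged
Gaussian KL against the spike/slab components, Bernoulli KL); all six
partial derivatives (∂L/∂μᵢ, ∂L/∂σᵢ², ∂L/∂qᵢ, ∂L/∂π₁, ∂L/∂σ_β², ∂L/∂σ₀²)
are analytic and are verified against central finite differences in the
test suite — that check is the load-bearing correctness oracle for every
closed form in `model.py`.

## Optimization

Gradient ascent uses ADAM on bijectively transformed coordinates
(μ raw, σᵢ² = exp(sᵢ)), with the analytic gradients multiplied by the
bijection Jacobians.  Three design choices depart from a plain
simultaneous ascent, each forced by observed failure modes of the raw
scheme and each documented here as the package's own design:

- **Exact q updates.**  ∂L/∂qᵢ = 0 has a unique closed-form root,
  qᵢ = sigmoid(logit π₁ − log(σ_β/δᵢ) + (σᵢ²+μᵢ²)(1/2δᵢ² − 1/2σ_β²)),
  and q is set to it every iteration.  With q on gradient steps the fitted
  posterior depended on the *race* between the q- and σ²-trajectories:
  doubling the initial slab variance flipped entire loci between clean and
  degenerate (every-SNP-causal) optima.  With q an instantaneous function
  of (μ, σ²) that timing fragility disappears.
- **Null-start initialization.**  μ = 0, q = π₁, and σᵢ² at its coordinate
  optimum given those (spike-dominated), rather than σᵢ² = σ_β².  An
  all-slab start sends every SNP toward q ≈ 1 before the data can be
  consulted and unwinds extremely slowly.
- **Coordinate-ascent hyperparameter updates.**  When hyperparameters are
  learned (the default), π₁ ← mean(q), σ_β² ← Σqᵢ(σᵢ²+μᵢ²)/Σqᵢ and
  σ₀² ← E_q‖z−Aᵀβ‖²/M — each the unique root of the corresponding analytic
  derivative, applied after a warmup of 250 iterations so the state can
  commit first.  ADAM steps on log-scale hyperparameters let the
  null-dominated slab gradient walk σ_β² onto the spike (mixture
  collapse).  π₁ is clipped to [1/(10M), 0.5]; σ_β² is floored at twice
  the spike variance.

Defaults: lr = 0.05, β₁ = 0.9, β₂ = 0.999, max_iter = 2000,
min_iter = 600, tol = 1e-6 (relative ELBO change) with patience 10.
Convergence may not be declared before min_iter or before the
hyperparameters have settled — the ELBO trace has flat mid-transient
stretches that otherwise trigger premature stops.  The fitter returns the
best-ELBO state seen, so the reported ELBO never falls below its initial
value.

### Spike width

The spike variance has no canonical value — it only needs to be
"sufficiently small".  What is sufficiently small turns out to depend on
the design: the per-SNP data
precision is Σⱼa_ij² = N·Hᵢ·Σⱼr̂ᵢⱼ², which varies by an order of magnitude
between a diagonal design and a locus in strong LD.  The package therefore
sizes the spike per SNP,

    δᵢ² = c · σ₀² / Σⱼ a_ij² ,   c = 0.5 (SPIKE_SCALE),

i.e. a spike-scale effect shifts its own expected z-score by at most √c
residual standard deviations.  Too wide a spike (large c) lets an LD block
absorb a real signal as many spike-scale ridge effects without ever paying
the Bernoulli cost of declaring a causal SNP; too narrow a spike freezes
the optimization before signal SNPs can commit.  c was calibrated once on
development simulations (balancing credible-set power against purity
across heritability regimes) and is not a per-run tuning knob.

## Low-rank (PCA) backend

The only O(M²) term in the per-iteration gradient is A₂μ = −AAᵀμ.  The
low-rank backend keeps the diagonal of AAᵀ exact — it equals the row sums
of squares Σⱼa_ij² already required (exactly) by the σᵢ² gradient, and it
carries each SNP's own-data curvature — and truncates only the hollow
remainder:

    A₂μ ≈ −( colsq ⊙ μ + U'Λ'U'ᵀμ ),

with U'Λ'U'ᵀ the top-p_c eigenpairs of AAᵀ − diag(colsq), computed once by
implicit Lanczos iteration (never forming AAᵀ).  Truncating AAᵀ itself
drops most of its diagonal and lets sparse fitted effects grow unchecked
in the discarded directions; at M = 4000, p_c = 100 that collapsed σ₀².
Because the truncated quadratic form underestimates ‖Aᵀμ‖², the T1
residual used by the ELBO trace and the σ₀² update carries an exactness
correction recomputed every 20 iterations (amortized O(M²/20) per
iteration).  Default p_c = max(100, M/20): the hollow spectrum of a locus
widens with its number of LD blocks.  With p_c = M the backend reproduces
the dense posteriors to 1e-6.

## Credible sets

A level-q_thr credible set with purity η is an index set U with
Σ_{i∈U} qᵢ > q_thr and min_{i,j∈U} |r̂ᵢⱼ| > η.  Construction sorts the qᵢ
descending, seeds up to L = ⌈M·π̂₁⌉ sets with high-q variants mutually
separated below η, then grows each set in descending-q order with variants
whose absolute correlation with *every current member* exceeds η, until
the set clears q_thr; sets that never do are dropped.  Anchoring on all
members (not only the seed) guarantees the purity constraint by
construction — under decaying LD two variants can each tag the seed above
η yet fall below it with each other.  Sets are disjoint; ties in q break
by original index; for q_thr < 0.95, L is raised to ⌈M·π̂₁·0.95/q_thr⌉.
An independent verifier recomputes both constraints from scratch for every
reported set.

## Synthetic data

The simulator replaces an external haplotype tool with a latent-Gaussian
threshold model: per individual, two independent latent vectors with
block-AR(1) correlation (blocks of `ld_block_size` = 50 SNPs, within-block
decay `ld_rho` = 0.9 per position) are thresholded at the allele-frequency
quantile (frequencies uniform on [0.05, 0.5]) and summed into allele
counts.  Phenotypes follow y = c₁Gβ + c₂ε with c₁ = √(h²/var(Gβ)) and
c₂ = √(1−h²), so Var(y) ≈ 1 and Var(c₁Gβ) = h² exactly in-sample; causal
effects are βᵢ = 1 (constant mode) or βᵢ ~ N(0,1) (normal mode) on k
uniformly drawn SNPs.  z-scores come from per-SNP simple regression; the
sample LD and heterozygosities feed the fitter.  A model-consistency test
regresses observed z on c₁·Aᵀβ across replicates and requires slope 1 ±
0.1, which jointly certifies the A orientation and the GWAS scaling.
Genotype and phenotype random streams are split from one seed, so the
benchmark harness can share one genotype matrix across scenarios that
differ only in k, h² or the effect mode without changing any result.

What the simulator does not emulate: long-range LD, recombination-map
heterogeneity, allele-frequency/LD coupling, and the specific LD spectrum
of reference-panel haplotypes.  Benchmarks on it therefore exercise the
method under a *qualitatively* realistic LD difficulty, not under any
particular population's LD.

## Benchmarks and problem sizes

`run_grid` reproduces two experiment families at desk scale:
AUC grids (M ∈ {200, 1000, 2000, 4000, 8000} × k ∈ {1, 5, 10} ×
h² ∈ {0.001, 0.005, 0.01}, both effect modes; the routine test run uses
the M ≤ 2000 sub-grid at 10 replicates) and a credible-set grid
(M = 4000, k ∈ {1, 5, 10}, h² ∈ {0.005, 0.01, 0.02, 0.04}; the
acceptance script runs the k = 10, h² ∈ {0.01, 0.04} scenarios at 10
replicates).  N = 10 000 throughout.  Coverage pools reported sets across
replicates; power pools causal SNPs.  Replicate r of a configuration uses
seed `cfg.seed + r`.  Scenarios that share (M, N, LD model, seed) reuse
one genotype matrix, sample LD and scaled-LD factorization — the genotype
and phenotype random streams are independent, so pooled metrics are
unchanged.  The AUC benchmark caps fits at 1200 ADAM iterations: the PIP
ranking is stable well before the ELBO tail converges (verified on dev
loci across the h² range), while credible-set benchmarks use the full
default budget.

## Known limitations

- **Hard commitment.**  The mean-field family makes β independent of u,
  so a nonzero μᵢ with intermediate qᵢ pays a (1−qᵢ)μᵢ²/2δᵢ² spike
  penalty; the ELBO-optimal qᵢ is therefore a near-threshold function of
  the evidence.  Away from the borderline window the fitted qᵢ matches the
  exact spike-slab posterior (verified on diagonal designs); inside it the
  exact posterior is a two-component mixture the family cannot represent,
  and the fit commits to ≈0 or ≈1.  Downstream, credible sets are mostly
  singletons: the package reports fewer, purer sets than graded-PIP
  methods, with correspondingly lower power on borderline signals.
- **Independent-residual misspecification.**  GWAS z-scores computed from
  one cohort have LD-correlated sampling noise (covariance ≈ R), while the
  model assumes independent residuals.  Optimizing the ELBO far past its
  practical operating point therefore starts fitting correlated noise as
  spurious signals; the finite iteration budget doubles as early-stopping
  regularization.  A full-covariance residual model is the principled fix
  and is out of scope here.
- **Learned hyperparameters** are most reliable from a weakly informative
  start (the pipeline default: π₁ = 0.01 and slab from h² = 0.01); very
  strong slab initializations can still over-commit dense-signal loci.
- Monomorphic SNPs carry zero row weight in A and zero heterozygosity;
  zero-variance genotype columns get z = 0 with a warning.
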