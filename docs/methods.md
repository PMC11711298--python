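# Methods

This note documents the models, estimators, numerical choices and
limitations of `gwgp`, and what the simulation-based tests do and do not
establish about real data.

## Synthetic panels

**Genotypes.** SNPs are simulated under the Balding–Nichols model: an
ancestral frequency `p` is drawn uniformly on `[maf_floor, 1−maf_floor]`,
each of `K` subpopulations draws its frequency from
`Beta(p(1−F)/F, (1−p)(1−F)/F)` — a parameterization whose expected
fixation index is exactly `F` — and diploid dosages are binomial within
subpopulation. `F = 0` bypasses the Beta draw. Columns that come out
monomorphic (possible when a Beta draw lands near 0 or 1) are redrawn, up
to 20 rounds.

**Local LD** is induced by rank-preserving previous-marker copying: each
diploid call is generated from two latent uniforms, and with probability
`ld_rho` an accession re-uses its uniforms from the previous SNP on the
same chromosome. Copying the *ranks* rather than the dosage value keeps
every SNP's marginal exactly `Binomial(2, p_subpop)`; copying dosage
values directly would make each SNP's realized frequency an exponentially
weighted average of upstream SNPs and deflate realized Fst by roughly
`(1−rho)/(1+rho)`, breaking the generator's divergence contract. Adjacent
r² rises monotonically with `ld_rho`. This haplotype-free scheme is
deliberate: it is sufficient for testing LD pruning and marker redundancy
at a fraction of the cost of coalescent simulation, but it produces no
long-range haplotype structure, no recombination-map heterogeneity and no
allele-frequency/LD coupling, so tests passing here say nothing about
those features of real panels.

**Phenotypes.** Per trait, `n_qtl` SNPs receive effects drawn N(0,1); the
genetic value `g` (centered dosages × effects) is rescaled so the
per-observation ratio `Var(g)/(Var(g)+σ²_gxe+σ²_e)` equals `h2_target`,
with `σ²_gxe = gxe_var_fraction · σ²_g` (default 0.15 — the model form is
standard but no reference magnitude exists for the emulated panel, so the
fraction is exposed rather than asserted). Environment main effects
(sd 0.5), subpopulation-group effects (sd 0.3), per-accession-per-
environment G×E deviations and residuals complete one record per
accession × environment. Trait means are drawn from U(3, 10), putting
coefficients of variation in the 10–50% range typical of agronomic traits.
`h2_target = 1` with a positive G×E fraction is rejected as inconsistent.

Note the distinction between per-observation (plot) heritability and
entry-mean heritability: a BLUP over `J` environments averages non-genetic
noise, so the SNP heritability of BLUP phenotypes is
`h²/(h² + (1−h²)/J)` — above the per-observation target. Recovery tests of
the heritability estimator therefore use single-environment phenotypes,
whose SNP-h² equals the simulated target by construction.

## Marker QC and imputation

Filters follow the strict inequalities MAF > `maf_min`, heterozygote
fraction < `het_max`, missing fraction < `missing_max`; MAF and
heterozygosity are computed over observed calls, missingness over all
calls. Missing calls are then replaced by the SNP's mean observed dosage —
the standard genomic-prediction fallback. Haplotype-based imputation is
out of scope; users with Beagle-imputed VCFs can feed them in directly.
Filtering is idempotent and order-preserving; removing every SNP is an
error, not an empty success.

## Population genetics

The GRM is VanRaden method 1, `G = WW'/(2Σp_j(1−p_j))` with `W` centered
by `2p_j` and frequencies taken from the analyzed panel itself; rows sum
to zero and `G` is PSD up to numerical tolerance. PCA scores are GRM
eigenvectors scaled by the square root of their eigenvalues; explained
fractions are eigenvalues over the trace.

Fst uses the Weir & Cockerham (1984) two-level variance components
`a` (among populations), `b` (among individuals within populations) and
`c` (within individuals), computed per SNP from subpopulation sample
sizes, allele frequencies and observed heterozygosity. Multi-locus
estimates — 30-kb non-overlapping windows tiled from position 1, and the
genome-wide value — are ratios of summed components (`Σa/Σ(a+b+c)`),
never means of per-SNP ratios; per-SNP θ may be negative. Window tiling is
non-overlapping because no step size is defined for the emulated analysis;
this matches the common windowed-Fst default.

LD thinning is a greedy left-to-right scan per chromosome: a SNP is
dropped when its squared dosage correlation with any already-retained SNP
within the upstream window exceeds `r2_max`. Position ties keep the
earlier column. The output provably contains no retained pair above the
cutoff within the window (asserted in tests).

## Mixed models and REML

One spectral REML engine backs heritability, the GWAS null model and
GBLUP: for `y ~ N(Xb, σ²_g K + σ²_e I)` the restricted likelihood is
profiled on `δ = σ²_e/σ²_g` using the spectrum of `S K S` (`S` projecting
off the fixed effects), with a 64-point log₁₀δ grid on [−10, 10] followed
by bounded scalar minimization (tolerance 1e-6). Estimates at the grid
edge are flagged `at_boundary`. This is robust and exact for a single
kernel; it is why GBLUP, ridge and KRR agree to machine precision in the
equivalence tests.

The multi-environment trial model treats environment and group as fixed:
with 4 environments and 2 groups there is too little replication to
estimate their variances, so fixed treatment is the identifiable choice.
Genotype effects are random; the G×E term is random **when the data
contain within-cell replicates** — with one record per accession ×
environment (what the simulator emits) σ²_G×E is confounded with the
residual and is absorbed into it, flagged `gxe_estimable=False`. This
model is fitted by EM-REML on the mixed-model equations (restricted
log-likelihood monitored via the MME Cholesky; convergence at 1e-8 change
or 500 iterations). Corrected phenotypes are `y_c = μ + α_k + G_i` with
`μ` the intercept plus the average environment effect. The fixed group
estimate `α_k` is retained in `y_c` deliberately: with groups in the
model, `α_k` absorbs the between-group share of the *genetic* signal
(the mixed model cannot split it from `G_i`), so excluding it strips
marker-predictable variance from the prediction target — in benchmarks on
structured panels this collapsed kernel-model accuracy to near zero,
because training folds are never exactly group-balanced and
GBLUP/ridge/KRR then fit spurious group offsets along the GRM's dominant
eigenvalue. A group-centered variant (`y_c_within_group = μ + G_i`)
remains available for analyses that want within-group signal only. The
flip side, quantified in the validation design below, is that `y_c` of a
structured panel contains a between-group component that markers predict
almost perfectly regardless of heritability.

SNP heritability thins markers (r² ≤ 0.98 in 100 kb), weights each
retained SNP's centered dosage so its variance contribution scales as
`[2p(1−p)]^α` with `α = 0.75` (down-weighting common variants relative to
an unweighted GRM), normalizes the kernel by `Σ[2p(1−p)]^α`, regresses out
an intercept plus the first four PCs, and reports
`h² = σ²_g/(σ²_g+σ²_e)`. Annotation-based weighting terms are not
implemented (no functional annotations exist in scope). Two practical
caveats, documented because they shape the tests: (i) in strongly
structured panels the PC covariates absorb ancestry-linked genetic
variance, biasing ĥ² down — recovery tests therefore use panels without
between-group structure; (ii) with an LD-free equal-frequency panel the
kernel spectrum is nearly flat at `n/m ≈ 0.08` and the REML likelihood
barely identifies `h²`; panels with realistic local LD (`ld_rho = 0.5`)
concentrate the spectrum and give usable precision, and are the condition
under which recovery within ±0.1 is demonstrated.

## Association scan

The scan is P3D/EMMAX: `δ` is estimated once under the null model
(intercept + 3 PCs + polygenic term with covariance G), the data are
whitened by `(D+δI)^{-1/2}U'` with `G = UDU'`, and each marker is tested
by OLS on the whitened scale with a two-sided normal Wald test. The
standard error uses the per-marker residual variance (RSS/(n−q−1)); at
panel sizes of 200–300 this is the better-calibrated choice and keeps the
scan a P3D approximation. Constant dosage columns are reported with p = 1
and a flag so row indices stay aligned. Forcing `δ → ∞` reduces the scan
exactly to OLS with PC covariates (tested against a direct regression
oracle). Multi-set ranking takes each SNP's minimum p-value across the
supplied phenotype sets (environments and/or BLUP) and breaks ties by
(chrom, pos); significance uses Bonferroni `α/n_snps` per set. Multi-locus
iterative methods (MLMM/FarmCPU-style) are out of scope; externally
computed p-value tables can be supplied to the ranking and TAS-counting
functions instead.

## Prediction models

All penalized objectives use the convention
`(1/2)‖y−Wβ‖² + λ·P(β)` with `P_ridge = ‖β‖²/2`, `P_lasso = ‖β‖₁`,
`P_enet = l1‖β‖₁ + (1−l1)‖β‖²/2`, so that elastic net at `l1 ∈ {0,1}` is
*exactly* ridge/lasso at the same λ — those endpoints dispatch to the
exact closed-form/lasso solvers, since coordinate descent is unreliable at
`l1 = 0`. Phenotypes are centered and features standardized inside `fit`
(disable with `standardize=False`); the intercept is never penalized.

* **GBLUP** builds the VanRaden GRM on the training rows, estimates
  `λ_G = σ²_e/σ²_u` by REML (or accepts a fixed value), solves
  `(G+λ_G I)α = y−μ̂` with the GLS intercept, and predicts new accessions
  through the train–test GRM block. With the matched penalty
  `λ = λ_G · 2Σp(1−p)` on centered dosages this is algebraically identical
  to ridge (RR-BLUP equivalence, verified to 1e-8).
* **Ridge / KRR** are solved in closed form (primal or dual as dimensions
  dictate); KRR kernels are linear, polynomial `(γ⟨x,x'⟩+r)^d` (the
  default, with γ = 1/p, r = 1, d = 2) or RBF (opt-in). KRR-linear equals
  ridge exactly.
* **Lasso / elastic net** use scikit-learn coordinate descent
  (`α_sklearn = λ/n`), 10,000-sweep cap, non-convergence raised as an
  error. λ may be given absolutely or as `lam_frac`, a fraction of the
  coefficient-killing `λ_max = max_j|X_j'y|` (scaled by 1/l1 for elastic
  net) — the standard regularization-path parameterization.
* **SVR** (linear/polynomial) is standard two-sided ε-insensitive
  regression solved by libsvm with penalty C.

The generalized bridge estimator for arbitrary exponents `0<γ<1` is not
fitted — only its named special cases (lasso, ridge, elastic net) — since
no algorithm for the general case is in scope.

Hyperparameter grids: the full defaults are 13 log-spaced λ in
[1e-4, 1e4], l1 ∈ {0.1,…,0.9}, C ∈ {0.1,1,10,100}, ε ∈ {0.01,0.1,0.5},
γ ∈ {1/p, 1e-3, 1e-2}, r ∈ {0,1}, d ∈ {2,3} (so svr_poly has 144 points).
A reduced "fast" grid (5 λ for ridge, `lam_frac` ∈ {0.02,0.1,0.3} for the
sparse families, single polynomial setting) is provided for desk-scale
runs and is what the bundled benchmarks and acceptance script use; grids
are ordered so the first-best tie rule prefers smaller λ and simpler
kernels. GBLUP has no grid (REML on the training fold only — no test
leakage).

## Cross-validation engine

Fivefold CV (80/20) repeated `n_repeats` times. Per repeat a fresh fold
split is drawn; per fold each model is tuned by internal fivefold CV on
the training portion only (selection by mean internal accuracy), refitted
on the whole training fold and scored on the held-out fold by: Pearson
accuracy, unbiasedness slope `cov(y_c,y_p)/var(y_p)` (observed on
predicted), MSE and MAE over the test-fold individuals. Aggregates are
per-fold metrics averaged over folds × repeats (pooled-prediction r would
mix fold means; per-fold averaging is the reported choice and ×100 gives
the percent scale). Seeding is hierarchical — the top seed spawns one
stream per repeat — so fold splits are invariant to the model list, and a
model failing on a fold is recorded as missing without aborting the run.

The marker-subset sweep evaluates top-N GWAS-ranked panels against the
all-marker baseline under identical folds, with one model family carried
across the sweep (in practice the best all-marker model for the trait).
Ranking modes: `within_fold` (default) re-runs the scan on each training
fold only and is leakage-safe; `whole_data` ranks once using all
accessions — including the test folds — and is flagged as optimistically
biased in the report. On a pure-noise trait the whole-data mode shows a
large spurious accuracy and the within-fold mode does not; both are
provided because published pipelines are frequently ambiguous about which
they used.

A caution on null controls: for a *fixed* noise phenotype the CV accuracy
has an irreducible component of order `1/√n` that more repeats cannot
remove (repeats reshuffle folds, not the data); null checks therefore
average over several independent noise draws.

**Validation design for the CV engine.** The accuracy-band and null
checks run on the structured preset (the realistic condition); benchmark
traits set the *non-genetic* group effect to zero so that measured
accuracy reflects marker-predictable signal rather than a
shared-environment confound that happens to align with ancestry. The
monotonicity-in-heritability check runs on a panmictic panel of the same
geometry: in a structured panel the between-group genetic component of
`y_c` is predicted almost perfectly at any heritability (BLUP shrinkage
acts only on the within-group part), so low-h² traits can show *higher*
accuracy — a real property of structured panels, not an engine defect —
which would mask the within-group ordering the check is about.

## Problem sizes

The library defaults to 500 CV repeats and the full grids. The bundled
tests and the acceptance script use the package's desk-scale choices:
195 × 2,000 preset panels with the fast grids and 20 repeats for the
model-band check (10 for the monotonicity/null checks), 200 × 5,000 panels
with 5 seeds for Fst recovery, 400 × 5,000 with 20 seeds for heritability
recovery, 300 × 5,000 with 10 permutations/seeds for GWAS calibration and
power, and 400 × 5,000 with 10 repeats for the sweep. These sizes keep
every stage's Monte-Carlo error comfortably inside the asserted bands.

## Known limitations

* The simulator is additive: no dominance, epistasis or selection; G×E is
  unstructured noise rather than environment-gradient-driven.
* Mean imputation attenuates LD and GRM entries relative to
  haplotype-aware imputation.
* The single P3D scan stands in for multi-locus GWAS algorithms; its
  ranking is well calibrated but less powerful on strongly polygenic
  traits than iterative conditioning methods.
* EM-REML converges slowly when a variance component approaches zero; the
  500-iteration cap with a 1e-8 log-likelihood criterion covers the
  intended panel sizes but very unbalanced replicated designs may be slow.
* Fitted-model archives are Python pickles with a version tag — portable
  within the package's own version only.

## Addendum: inbreeding in the generator

`SimGenotypeConfig.inbreeding` (F_IS, default 0) makes a fraction of calls
autozygous by collapsing the two latent uniforms of a diploid draw into
one. This scales observed heterozygosity by `(1 − F_IS)` while leaving
allele frequencies, and therefore Fst, unchanged. The 195-accession preset
sets F_IS = 0.9 because the emulated crop is a selfing cereal: without it,
a per-SNP heterozygosity filter at <20% — sensible for inbred lines —
would discard most markers of an outbred Hardy–Weinberg panel, making the
simulated fixture incoherent with the pipeline's own QC. The GRM diagonal
under inbreeding averages `1 + F_IS` rather than 1, which the VanRaden
scaling invariant (mean diagonal in [0.5, 2]) accommodates.
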