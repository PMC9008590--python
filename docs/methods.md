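# Methods

`cyanophen` implements an integrated genomic + phenomic prediction workflow
for a quantitative leaf trait (hydrogen cyanide content, mg HCN g⁻¹ dry
weight) in an open-pollinated, genetically structured tree population. This
note records the statistical models, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the
numerical conventions.

## Study design being modeled

The population is a provenance/progeny trial of half-sib families: each
family shares a known seed parent (dam); pollen parents are unknown and
treated as independent random draws from the population, so the expected
additive relationship between half sibs is exactly 1/4. Trees are laid out
in a randomized complete block design with single-tree plots. Three data
layers are available per tree: pedigree, biallelic SNP genotypes
(~3,900 markers on 11 chromosomes after a MAF ≥ 0.05 filter), and a leaf
reflectance spectrum on a 400–2,400 nm grid.

## Models

Two model families share one fitting engine.

**Per-band heritability (models 1–2).** For each wavelength band (or each
spectral index) the response y is the raw band value and

    y = Xβ + Qv + Z₁g₁ + ε      g₁ ~ N(0, G σ²_g)     (genomic)
    y = Xβ + Pρ + Za  + ε      a  ~ N(0, A σ²_a)     (pedigree)

with X the block design, Q population-structure covariates, P provenance
indicators. Heritability is reported as the posterior mean of
σ²_g/(σ²_g+σ²_e) (resp. σ²_a/(σ²_a+σ²_e)); the structure/fixed variance is
deliberately omitted from the denominator, matching the estimand of the
profile this package produces.

**Trait prediction (models 3–14).** The response y* is the block-adjusted
trait: y is regressed once on block indicators and y* = intercept +
residual. The twelve models combine, on top of Qv: haplotype genomic values
Z₂g₂, pedigree effects Za, per-band spectral effects Z₃h ("phenomic"
regressors), and stepwise-selected spectral reflectance indices X_iβ_i as
fixed covariates. Model 13 (Qv + Za + Z₂g₂ + Z₃h) is the fully integrated
model without SRI covariates; model 14 adds them.

**A and G.** A is built by the tabular recurrence with unknown parents as
unrelated non-inbred founders. G is VanRaden method 1 on observed allele
frequencies, G = WWᵀ / (2Σp(1−p)); its mean diagonal is ≈ 1 under
Hardy–Weinberg founders. Both matrices enter the sampler through eigen
loadings L (K = LLᵀ, eigenvalues below 1e-8·λ_max truncated), so a
relationship effect becomes an ordinary regressor block with coefficients
α ~ N(0, σ²I); fitting via L is equivalent to the N(0, Kσ²) formulation and
lets all priors share one update path.

**Haplotype blocks.** Pairwise D′, LOD (log₁₀ likelihood ratio against
linkage equilibrium) and r² are computed per chromosome within a 500 kb
window, by direct gamete counting when phase is known and by two-locus EM
otherwise. Blocks follow the solid-spine rule: both end markers must be in
strong LD (D′ ≥ 0.9) with every interior marker and with each other, taking
the longest valid extension left to right; a block is kept only if its mean
pairwise D′ ≥ 0.9 and mean LOD ≥ 2 (a per-pair variant of the retention
filter is available behind a flag — the published description does not say
whether the thresholds apply pairwise or as block summaries, so the summary
reading is the default). Retained blocks are expanded into haplotype-allele
dosage columns; alleles rarer than 1% are pooled into the most frequent
(reference) allele, whose column is dropped.

**Spectral preprocessing.** Bands are centered and scaled, then a
Savitzky–Golay first derivative is taken along the wavelength axis with a
37-point window; half a window is lost at each edge. The polynomial order
is 2 by default (the common chemometrics choice for first derivatives) and
exposed in the API. SRIs are evaluated on raw reflectance, as their
published definitions require; on strided grids an index wavelength that
falls between bands is linearly interpolated (reflectance is smooth at the
10 nm scale). The registry covers LRDSI1, ARI, BRI, SR7, BGI, EGFN, EGFNR,
GMI1, SR3, SR10, NDLI, NDNI and NPCI, plus a decorator to register more.
Candidate indices are screened by bidirectional stepwise OLS under
AIC = n·log(RSS/n) + 2k; coefficient p-values, VIFs (1/(1−R²_j), bands
<10 / 10–100 / ≥100) and partial R² are reported post hoc. AIC is the sole
selection criterion; note that under the null a single candidate is
admitted with probability P(χ²₁ > 2) ≈ 0.157 — the reported p-values are
the tool for significance statements.

## The Gibbs engine

All models are fitted by a single-site Gibbs sampler over blocks of
regressors, JIT-compiled with numba. Fixed-effect blocks have flat priors.
Random blocks take one of three priors:

* **BRR** — common block variance σ², Gaussian shrinkage;
* **Bayes B** — per-regressor variances and a point mass at zero;
* **Bayes C** — common variance and a point mass at zero.

Variances carry scaled-inverse-χ² priors; π — implemented as the
probability that a regressor is *included* (so π = 1 recovers BRR exactly,
which is tested) — is fixed or given a Beta full conditional. Inclusion
indicators are sampled from the marginal likelihood ratio of the
included/excluded states. The residual variance update and the deviance use
the conditional Gaussian likelihood; DIC = 2·mean(D) − D(posterior-mean
predictor, posterior-mean σ²_e). The per-block percentage of phenotypic
variance (PV) is the posterior mean of Var_i(η_block,i)/Var_i(y*) × 100,
with the residual share reported as the remainder.

Chains are seeded and bit-reproducible. Presets: `paper`
(1,000,000 / 100,000 / 50 — the published run lengths), `desk`
(20,000 / 4,000 / 5, the default), `fast` (2,500 / 500 / 5) for sweeps that
fit hundreds of chains (per-band profiles, cross-validation grids). The
sampler was validated against closed forms: fixed-variance BRR equals the
ridge solution; a relationship effect fitted through loadings equals the
mixed-model BLUP; and the full posterior was compared with exact
grid-evaluated posteriors in the single-random-effect case (eigen-rotated
marginal likelihood), which agree to Monte-Carlo error in every
configuration tried.

### Prior defaults, and why they differ by purpose

Half-sib data identify variance ratios weakly: the family-mean variance has
an expected value of σ²_w/k even when σ²_a = 0 (k = progeny per family), so
the likelihood for σ²_a is nearly flat over a wide interval and any prior
scale shows through. Exact-posterior grid checks showed that a df = 5 prior
centered on a 50% variance share drags per-trait heritability toward ~0.4
regardless of the truth and attributes ~17% of a pure-noise trait to each
random block. The package therefore separates two use cases:

* **Estimation fits** (heritability profiles, h² of indices): flat
  reference priors on the genetic and residual variances (the df ≤ 0 limit
  of the scaled-inverse-χ² family; df = −2 is flat, df = 0 Jeffreys —
  Jeffreys is rejected for block variances because the likelihood is
  positive at σ² = 0 and the posterior would be improper). With flat priors
  the posterior tracks the exact reference posterior, and recovery is
  approximately unbiased across true h² from 0.1 to 0.7 at n = 400.
* **Prediction fits** (models 3–14): relationship blocks keep a proper
  df = 5 prior with a deliberately small 5% prior variance share;
  dense Bayes B/C blocks use a sparse inclusion prior (mean 0.05,
  weight 20), the convention of whole-genome regression software. These
  choices keep variance attribution to null blocks below ~10% while strong
  signals, carried by the likelihood, are still recovered.

## Cross-validation and model comparison

Predictive ability (PA) is the Pearson correlation between observed and
predicted y* in the held-out folds of a fivefold cross-validation (each test
fold ≈ 20% of trees; a Spearman option exists). Per fold, the model is
refitted on training rows only; held-out trees are predicted from their own
design rows (loadings, haplotype dosages, spectra) under the posterior-mean
effects, so no test response ever enters its own prediction — verified by a
response-corruption test. Fold assignment is simple random by default;
family-stratified folds are available because half-sib structure otherwise
inflates naive PA. Models are compared by DIC with the conventional rubric:
a difference > 10 is "supported", 3–10 "substantial", < 3 "not
significant"; ties at the boundaries fall to the smaller class.

## The synthetic-data generator

No field data are distributed with the trial this package targets, so
`syndata` generates populations with the statistical structure the analysis
assumes; every `simulate_*` function is a pure function of its arguments.

* **Pedigree**: n_families dams (founders), open-pollinated progeny,
  families nested in provenances, offspring spread over blocks with
  single-tree plots. Defaults: 49 families × 6 progeny, 30 blocks,
  4 provenances (≈ 300 phenotyped trees).
* **Genotypes**: founder gametes carry latent-haplotype LD blocks
  (ld_block_len = 10 markers; a block-level latent allele at a random
  frequency in [0.15, 0.85] is copied per marker with a 3% flip rate),
  giving high D′ within blocks and independence between them. Offspring
  receive one dam gamete (block-wise recombination, rate 0.1) and one fresh
  population gamete for the unknown sire. Markers failing MAF ≥ 0.05 among
  progeny are dropped. Defaults give ≈ 3,900 retained SNPs on
  11 chromosomes, ~1 marker / 11 kb. This is deliberately not a coalescent
  model: it is sufficient to exercise D′/solid-spine logic at a fraction of
  the cost, but its LD decay and frequency spectrum are not population-
  genetically realistic.
* **Spectra**: mean vegetation-like curve (green bump, NIR plateau, SWIR
  water dips) plus (i) an additive-genetic smooth deviation on ≤ 16
  Gaussian bases whose family loadings follow the half-sib model,
  (ii) an individual smooth environmental deviation, (iii) independent
  band noise. Components are standardized by their realized population SD
  per band, so realized per-band heritability equals the region targets
  (defaults: visible 0.41, NIR 0.30, SWIR 0.20 — higher genetic control in
  the visible than the SWIR, the documented shape for tree leaf spectra).
  The default grid is strided (10 nm → 201 bands); 1 nm is available via
  `step=1`. Chosen because the prediction models on 201 bands run in
  seconds rather than minutes, and profile shape is unaffected.
* **Trait**: provenance + block effects + additive-genetic component (a
  dam-transmitted polygenic deviate mixed with sparse haplotype-window
  marker effects, `qtl_share` = 0.4 of genetic variance) + a spectrally
  mediated component + Gaussian residual, affinely rescaled to the printed
  HCN range [0, 1.54] mg g⁻¹ dw with the affine map recorded (variance
  shares survive). The spectral component is a linear combination of the
  generator's *smooth latent* basis loadings — the endophenotype the
  spectra realize — not of raw band projections: band noise would be
  annihilated by derivative smoothing and make the nominal spectral share
  unrecoverable by construction. Defaults: additive share 0.35, spectral
  share 0.20. Component vectors are stored and sum to the raw trait
  exactly.

What passing tests on this generator do **not** show: performance under
real LD decay, genotype–environment interaction, non-Gaussian residuals,
or spectra whose trait-relevant information is not low-dimensional and
smooth. They do show that every algorithmic step (kinship, LD, blocks,
preprocessing, samplers, CV bookkeeping) is correct, and that the engines
recover known variance structure at the trial's scale.

## Numerical conventions and degenerate inputs

Monomorphic markers are skipped in LD (NaN, warning) and excluded from G's
denominator. A block with a single common haplotype contributes no design
columns. Zero-variance bands get NaN heritability with a flag. Exact
collinearity reports VIF = +∞; constant stepwise candidates are dropped
with a warning. D′ at a boundary (D_max = 0) is reported as 0. Eigenvalues
below 1e-8·λ_max are truncated in `decompose`. Per-band profile chains are
seeded by wavelength (and per-index chains by a hash of the column
content), so results are independent of processing order and duplicated
columns give identical estimates. Seeds derived anywhere in the package
stay below 2³¹.

## Known limitations

* Posterior-mean h² under flat reference priors retains a small tail bias
  (≈ +0.05 near h² = 0.1, ≈ −0.08 near 0.7 at n = 400); this is a property
  of the weakly identified half-sib likelihood, not of the sampler.
* In-sample PV splits variance between correlated blocks (pedigree vs
  haplotypes both carry additive signal), so single-block shares undercount
  the total genetic contribution in integrated models.
* The EM phasing fallback enumerates haplotype pairs and is limited to
  short blocks (< ~12 heterozygous sites); phased input bypasses it.
* Models 1–2 are fitted with the same Bayesian machinery as 3–14 (not
  REML); posterior SDs serve as the uncertainty measure.
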