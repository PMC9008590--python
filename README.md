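# cyanophen

Integrated genomic + phenomic Bayesian prediction of leaf hydrogen-cyanide
(HCN) content in a half-sib tree population, with heritability profiling of
the leaf reflectance spectrum.

Cyanogenic trees defend themselves by releasing HCN from cyanogenic
glycosides; the trait (mg HCN g⁻¹ dry weight) is quantitative, expensive to
assay, and of ecological and breeding interest. This package asks how well
it can be predicted from cheaper data layers — pedigree, SNP haplotypes, and
high-throughput leaf reflectance spectra (400–2,400 nm) — and how heritable
the spectrum itself is, band by band. It is aimed at quantitative
geneticists and tree breeders who want a tested, scriptable version of this
workflow, with a synthetic-data generator standing in for undeposited field
trials.

## What it computes

For trees with block-adjusted phenotypes y*, structure covariates Q,
pedigree relationship matrix A (tabular method), haplotype dosages Z₂ from
solid-spine LD blocks (D′ ≥ 0.9, LOD ≥ 2), and Savitzky–Golay-preprocessed
spectra Z₃, the package fits the model family

    y* = Qv + X_i β_i + Z a + Z₂ g₂ + Z₃ h + ε,     a ~ N(0, A σ²_a)

and all its printed sub-models (numbered 3–14; the fully integrated model
is y* = Qv + Za + Z₂g₂ + Z₃h + ε), under three whole-genome-regression
priors — Bayesian ridge (BRR), Bayes B, Bayes C — using a from-scratch,
numba-accelerated Gibbs sampler. Per-band heritability profiles use

    h²_g = σ²_g / (σ²_g + σ²_e),    h²_a = σ²_a / (σ²_a + σ²_e)

per 1-nm (or strided) wavelength band, plus heritability of named spectral
reflectance indices (NPCI, SR10, NDLI, NDNI, LRDSI1, ARI, …) with
stepwise-AIC selection and VIF screening. Models are compared by DIC
(difference > 10 "supported", 3–10 "substantial", < 3 "not significant"),
variance partition (PV per data layer), and fivefold cross-validated
predictive ability (Pearson r between observed and predicted y*).

Modules: `syndata` (synthetic half-sib trials), `relmat` (A, VanRaden G,
structure covariates, eigen-loadings), `ldblocks` (D′/LOD/r², solid-spine
blocks, haplotype design), `spectra` (preprocessing, SRI registry, stepwise
selection), `bayes` (the Gibbs engines, DIC, variance partition), `herit`
(h² profiles), `pipeline` (adjustment, CV, comparison) — see
`docs/methods.md` for the statistical details.

## Worked example

```python
from cyanophen import bayes, pipeline, syndata

ped   = syndata.simulate_pedigree(49, 6, 30, 4, seed=1)   # 294 trees
geno  = syndata.simulate_genotypes(ped, seed=2)           # ~3,900 SNPs, 11 chrom
spec  = syndata.simulate_spectra(ped, seed=3)             # 201 bands, 400-2400 nm
trait, truth = syndata.simulate_trait(ped, geno, spec,
                                      h2_additive=0.35,
                                      spectral_share=0.2, seed=4)

data  = pipeline.prepare_data(ped, geno, spec, trait)     # A, G, blocks, SRIs
f3  = pipeline.fit_model(3,  data, "bayesb", bayes.settings("fast", seed=5))
f13 = pipeline.fit_model(13, data, "bayesb", bayes.settings("fast", seed=5))
cv3 = pipeline.cross_validate(3, data, seed=1, preset="fast")
cv7 = pipeline.cross_validate(7, data, seed=1, preset="fast")
print(pipeline.compare_models([f3, f13], [cv3, cv7]))
```

prints (fast preset, seeds as above):

```
   model  method     dic    pv_g   pv_sr   pv_a     pa  delta_dic    support
0     13  bayesb -82.203   9.215  13.513  8.286    NaN      0.000       best
1      3  bayesb -32.959  10.317     NaN    NaN  0.325     49.244  supported
```

Read: on a population simulated with both genetic (35%) and spectrally
mediated (20%) trait variance, the integrated model (13) fits better than
the genomic-only model (3) by ~49 DIC units (a "supported" difference) and
attributes ~14% of phenotypic variance to the spectra block, ~9% to
haplotypes and ~8% to the pedigree; cross-validated predictive ability of
the spectra-only model (`cv7.mean_pa = 0.467`) exceeds the genomic-only
model's (`cv3.mean_pa = 0.325`).

A per-band heritability profile (every 4th band here, for speed):

```python
from cyanophen import herit
prof = herit.wavelength_h2_profile(
    spec.subset(data.ids).values[:, ::4], spec.wavelengths[::4],
    data.extras["a_loadings"], data.designs["block"],
    kind="pedigree", preset="fast", seed=7)
herit.region_means(prof)    # {'visible': 0.457, 'swir': 0.198}
```

The generator placed higher genetic control in the visible than in the
SWIR, and the estimated profile reproduces that shape.

The same steps are available from a shell:

```sh
cyanophen simulate --out pop/ --seed 1
cyanophen herit    --out h2/  --seed 1 --kind pedigree
cyanophen cv       --out rep/ --seed 1 --models 3,7,13 --engines bayesb
```

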