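"""Synthetic half-sib populations with genomic, spectral and trait structure.

The generator emulates an open-pollinated provenance/progeny trial of a
cyanogenic eucalypt: 49 half-sib families (known dam, unknown sire) laid out
in a randomized complete block design with single-tree plots, ~3,900 biallelic
SNPs on 11 chromosomes with block-wise linkage disequilibrium, leaf
reflectance spectra on a 400-2,400 nm grid whose per-band heritability is
higher in the visible than in the SWIR region, and an HCN-like quantitative
trait (mg HCN per g dry weight) with additive-genetic and spectrally mediated
variance components.

Every ``simulate_*`` function is a pure function of its arguments: the same
seed yields byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = "0"

#: Conventional bounds (nm) of the three spectral regions used throughout.
REGIONS = {"visible": (400.0, 700.0), "nir": (700.0, 1400.0), "swir": (1400.0, 2400.0)}

#: Printed upper bound of the trait scale (mg HCN per g dry weight).
HCN_MAX = 1.54


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Phased, fully observed SNP dosages with a physical marker map."""

    ids: list[str]
    dosages: np.ndarray          # (n, m) int8 in {0,1,2}
    chrom: np.ndarray            # (m,) int, 1-based
    pos: np.ndarray              # (m,) int bp, strictly increasing per chrom
    haplotypes: np.ndarray | None = None   # (n, m, 2) int8 alleles

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0

    def subset(self, ids: list[str]) -> "GenotypeMatrix":
        idx = [self.ids.index(i) for i in ids]
        hap = None if self.haplotypes is None else self.haplotypes[idx]
        return GenotypeMatrix(list(ids), self.dosages[idx], self.chrom, self.pos, hap)


@dataclass
class SpectraMatrix:
    """Reflectance spectra, one row per individual, on a shared grid."""

    ids: list[str]
    values: np.ndarray           # (n, w) reflectance in (0,1)
    wavelengths: np.ndarray      # (w,) nm, sorted
    basis_centers: np.ndarray | None = None
    basis_widths: np.ndarray | None = None
    latent_scores: np.ndarray | None = None   # (n, B) smooth per-basis loadings

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def basis_functions(self) -> np.ndarray:
        """(w, B) matrix of the Gaussian basis curves used by the generator."""
        if self.basis_centers is None:
            raise ValueError("spectra were not built from a Gaussian basis")
        lam = self.wavelengths[:, None]
        return np.exp(-0.5 * ((lam - self.basis_centers[None, :]) / self.basis_widths[None, :]) ** 2)

    def basis_scores(self) -> np.ndarray:
        """Projection of mean-removed spectra onto the generator's bases.

        These scores are linear functionals of the observed spectra, so any
        trait component built from them is recoverable from the spectra block.
        """
        phi = self.basis_functions()
        centered = self.values - self.values.mean(axis=0, keepdims=True)
        return centered @ phi

    def subset(self, ids: list[str]) -> "SpectraMatrix":
        idx = [self.ids.index(i) for i in ids]
        lat = None if self.latent_scores is None else self.latent_scores[idx]
        return SpectraMatrix(list(ids), self.values[idx], self.wavelengths,
                             self.basis_centers, self.basis_widths, lat)


@dataclass
class TrueParams:
    """Generator ground truth for recovery tests.

    Component vectors are stored on the pre-rescaling scale; they sum exactly
    to the raw trait, and the affine map to the printed HCN range is recorded
    so variance shares are preserved.
    """

    h2_additive: float
    spectral_share: float
    qtl_share: float
    causal_blocks: list[tuple[int, int]]
    causal_bases: list[int]
    provenance_effects: dict[str, float]
    block_effects: dict[int, float]
    components: pd.DataFrame      # per-individual: fixed, genetic, spectral, residual, raw
    affine_scale: float
    affine_offset: float
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "h2_additive": self.h2_additive,
            "spectral_share": self.spectral_share,
            "qtl_share": self.qtl_share,
            "causal_blocks": [list(b) for b in self.causal_blocks],
            "causal_bases": self.causal_bases,
            "provenance_effects": self.provenance_effects,
            "block_effects": {str(k): v for k, v in self.block_effects.items()},
            "affine_scale": self.affine_scale,
            "affine_offset": self.affine_offset,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(n_families: int, progeny_per_family: int, n_blocks: int,
                      n_provenances: int, seed: int) -> pd.DataFrame:
    """Half-sib pedigree: unrelated dams, open-pollinated offspring.

    Returns a topologically ordered frame with columns
    ``id, sire, dam, family, provenance, block, generation``. Dams (founders)
    carry ``block == 0`` because only offspring are planted in the trial;
    offspring blocks follow a randomized complete block layout with
    single-tree plots (a family appears at most once per block when
    ``progeny_per_family <= n_blocks``).
    """
    if min(n_families, progeny_per_family, n_blocks, n_provenances) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    fam_prov = {}
    for f in range(n_families):
        fam = f"FAM{f + 1:03d}"
        prov = f"PROV{(f % n_provenances) + 1}"
        fam_prov[fam] = prov
        rows.append((f"DAM{f + 1:03d}", UNKNOWN, UNKNOWN, fam, prov, 0, 0))
    for f in range(n_families):
        fam = f"FAM{f + 1:03d}"
        dam = f"DAM{f + 1:03d}"
        if progeny_per_family <= n_blocks:
            blocks = rng.choice(np.arange(1, n_blocks + 1), size=progeny_per_family,
                                replace=False)
        else:
            reps = -(-progeny_per_family // n_blocks)
            pool = np.concatenate([rng.permutation(np.arange(1, n_blocks + 1))
                                   for _ in range(reps)])
            blocks = pool[:progeny_per_family]
        for k in range(progeny_per_family):
            rows.append((f"{fam}_O{k + 1}", UNKNOWN, dam, fam, fam_prov[fam],
                         int(blocks[k]), 1))
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "family", "provenance",
                                       "block", "generation"])


def offspring_ids(pedigree: pd.DataFrame) -> list[str]:
    return pedigree.loc[pedigree["generation"] > 0, "id"].tolist()


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _founder_gametes(n_gametes: int, block_freq: np.ndarray, block_index: np.ndarray,
                     flip_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Population gametes with latent-haplotype LD blocks.

    Each block carries a latent 0/1 ancestral haplotype drawn at the block's
    frequency; each marker copies the latent allele, flipping with a small
    probability. Markers within a block are therefore in high D' while blocks
    are independent.
    """
    m = block_index.size
    z = rng.random((n_gametes, block_freq.size)) < block_freq[None, :]
    alleles = z[:, block_index]
    flips = rng.random((n_gametes, m)) < flip_prob
    return (alleles ^ flips).astype(np.int8)


def simulate_genotypes(pedigree: pd.DataFrame, n_chrom: int = 11,
                       snps_per_chrom: int = 355, ld_block_len: int = 10,
                       maf_min: float = 0.05, seed: int = 0,
                       flip_prob: float = 0.03,
                       recomb_prob: float = 0.1) -> GenotypeMatrix:
    """Gene-drop genotypes through a half-sib pedigree.

    Founder gametes are drawn with latent-haplotype LD blocks of
    ``ld_block_len`` consecutive markers. Each offspring receives one gamete
    from its dam (recombining between blocks with probability
    ``recomb_prob``) and, the sire being unknown, one fresh random population
    gamete (open pollination). Markers failing the minor-allele-frequency
    filter among non-founders are dropped, mirroring the SNP quality filter
    applied to real panels.
    """
    if not (0.0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    ids = pedigree["id"].tolist()
    n = len(ids)
    row = {i: k for k, i in enumerate(ids)}

    m_per = snps_per_chrom
    m_total = n_chrom * m_per
    chrom = np.repeat(np.arange(1, n_chrom + 1), m_per)
    # ~1 SNP per 11 kb, jittered, strictly increasing within chromosome
    pos = np.concatenate([
        np.cumsum(rng.integers(6_000, 16_000, size=m_per)) for _ in range(n_chrom)
    ])

    n_blocks_per = -(-m_per // ld_block_len)
    block_index = np.minimum(np.arange(m_per) // ld_block_len, n_blocks_per - 1)
    block_index_all = np.concatenate([block_index + c * n_blocks_per
                                      for c in range(n_chrom)])
    n_blocks_all = n_chrom * n_blocks_per
    block_freq = rng.uniform(0.15, 0.85, size=n_blocks_all)

    hap = np.zeros((n, m_total, 2), dtype=np.int8)
    is_founder = (pedigree["generation"] == 0).to_numpy()
    founders = np.where(is_founder)[0]
    fg = _founder_gametes(2 * founders.size, block_freq, block_index_all,
                          flip_prob, rng)
    hap[founders, :, 0] = fg[0::2]
    hap[founders, :, 1] = fg[1::2]

    # per-chromosome block boundaries for recombination during meiosis
    chrom_slices = [slice(c * m_per, (c + 1) * m_per) for c in range(n_chrom)]

    def meiose(parent_row: int) -> np.ndarray:
        gamete = np.empty(m_total, dtype=np.int8)
        for sl in chrom_slices:
            bidx = block_index_all[sl]
            nb = bidx.max() - bidx.min() + 1
            switch = rng.random(nb) < recomb_prob
            switch[0] = rng.random() < 0.5
            source = np.cumsum(switch) % 2          # per-block parental haplotype
            per_marker = source[bidx - bidx.min()]
            seg = hap[parent_row, sl, :]
            gamete[sl] = seg[np.arange(sl.stop - sl.start), per_marker]
        return gamete

    for _, rec in pedigree[~is_founder].iterrows():
        r = row[rec["id"]]
        hap[r, :, 0] = meiose(row[rec["dam"]])
        hap[r, :, 1] = _founder_gametes(1, block_freq, block_index_all,
                                        flip_prob, rng)[0]

    dosages = hap.sum(axis=2).astype(np.int8)
    progeny = ~is_founder if (~is_founder).any() else np.ones(n, bool)
    freq = dosages[progeny].mean(axis=0) / 2.0
    keep = np.minimum(freq, 1 - freq) >= maf_min
    return GenotypeMatrix(ids, dosages[:, keep], chrom[keep], pos[keep],
                          hap[:, keep, :])


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def _mean_reflectance_curve(wl: np.ndarray) -> np.ndarray:
    """Smooth vegetation-like mean curve: low visible with a green bump,
    high NIR plateau, SWIR decline with water-absorption dips."""
    curve = 0.06 + 0.04 * np.exp(-0.5 * ((wl - 550) / 40) ** 2)
    curve = curve + 0.40 / (1 + np.exp(-(wl - 720) / 18))
    curve = curve - 0.12 / (1 + np.exp(-(wl - 1400) / 90))
    curve = curve - 0.10 * np.exp(-0.5 * ((wl - 1450) / 45) ** 2)
    curve = curve - 0.14 * np.exp(-0.5 * ((wl - 1940) / 60) ** 2)
    curve = curve - 0.05 * np.exp(-0.5 * ((wl - 2300) / 80) ** 2)
    return np.clip(curve, 0.02, 0.95)


def _region_targets(region_h2, wl: np.ndarray) -> np.ndarray:
    """Per-band target heritability from a region->h2 map.

    Keys may be region names (``visible``/``nir``/``swir``) or explicit
    ``(lo, hi)`` wavelength tuples; together they must cover the grid.
    """
    target = np.full(wl.size, np.nan)
    for key, h2 in region_h2.items():
        lo, hi = REGIONS[key] if isinstance(key, str) else key
        if not (0.0 <= h2 < 1.0):
            raise ValueError(f"region h2 {h2!r} outside [0,1)")
        target[(wl >= lo) & (wl <= hi)] = h2
    if np.isnan(target).any():
        raise ValueError("region_h2 does not cover the wavelength grid")
    return target


def simulate_spectra(pedigree: pd.DataFrame, region_h2=None, n_basis: int = 16,
                     seed: int = 0, step: float = 10.0,
                     amplitude: float = 0.035) -> SpectraMatrix:
    """Family-structured reflectance spectra with region-wise heritability.

    Each spectrum is a smooth mean curve plus (i) an additive-genetic smooth
    deviation built from Gaussian bases whose family loadings follow the
    half-sib model (offspring = dam/2 + Mendelian sampling), (ii) an
    individual smooth environmental deviation on the same bases, and (iii)
    independent per-band noise. Per-band variance shares are scaled so the
    realized band heritability matches ``region_h2`` in expectation; the
    default places higher heritability in the visible than in the SWIR, the
    qualitative shape reported for tree leaf spectra.

    ``step`` controls the wavelength grid (10 nm -> 201 bands by default;
    1 nm gives the full 2,001-band grid).
    """
    if region_h2 is None:
        region_h2 = {"visible": 0.41, "nir": 0.30, "swir": 0.20}
    rng = np.random.default_rng(seed)
    wl = np.arange(400.0, 2400.0 + 0.5 * step, step)
    w = wl.size
    target = _region_targets(region_h2, wl)

    centers = np.linspace(450.0, 2350.0, n_basis)
    widths = np.linspace(30.0, 150.0, n_basis)
    phi = np.exp(-0.5 * ((wl[:, None] - centers[None, :]) / widths[None, :]) ** 2)

    ids = pedigree["id"].tolist()
    n = len(ids)
    fam_of = pedigree.set_index("id")["family"]
    dam_of = pedigree.set_index("id")["dam"]
    gen = pedigree.set_index("id")["generation"]

    # additive basis loadings: unit additive variance, half-sib covariance 1/4
    dam_load = {f: rng.standard_normal(n_basis)
                for f in pedigree.loc[pedigree["generation"] == 0, "family"]}
    U = np.empty((n, n_basis))
    for k, i in enumerate(ids):
        if gen[i] == 0:
            U[k] = dam_load[fam_of[i]]
        else:
            dam_fam = fam_of[dam_of[i]]
            U[k] = 0.5 * dam_load[dam_fam] + np.sqrt(0.75) * rng.standard_normal(n_basis)
    V = rng.standard_normal((n, n_basis))          # individual smooth deviation
    noise = rng.standard_normal((n, w))

    g_band = U @ phi.T                              # genetic band signal
    d_band = V @ phi.T                              # smooth env band signal
    # standardize each component by its realized population SD so the
    # realized per-band variance shares equal the targets exactly (with few
    # bases per region, the theoretical scaling would leave large per-seed
    # deviations of realized heritability)
    sd_g = np.where(g_band.std(axis=0) > 0, g_band.std(axis=0), 1.0)
    sd_d = np.where(d_band.std(axis=0) > 0, d_band.std(axis=0), 1.0)
    sd_n = np.where(noise.std(axis=0) > 0, noise.std(axis=0), 1.0)

    s_g = amplitude * np.sqrt(target)
    env_var = amplitude ** 2 * (1.0 - target)
    s_d = np.sqrt(0.6 * env_var)
    s_n = np.sqrt(0.4 * env_var)

    spectra = (_mean_reflectance_curve(wl)[None, :]
               + s_g[None, :] * g_band / sd_g[None, :]
               + s_d[None, :] * d_band / sd_d[None, :]
               + s_n[None, :] * noise / sd_n[None, :])
    # smooth per-basis amplitudes realized in the spectra: the latent
    # endophenotype a trait can be routed through (band noise excluded,
    # so the signal survives derivative smoothing)
    w_g = ((s_g[:, None] / sd_g[:, None]) * phi).mean(axis=0)
    w_d = ((s_d[:, None] / sd_d[:, None]) * phi).mean(axis=0)
    latent = U * w_g[None, :] + V * w_d[None, :]
    eps = 1e-4
    return SpectraMatrix(ids, np.clip(spectra, eps, 1 - eps), wl, centers, widths,
                         latent)


# ---------------------------------------------------------------------------
# trait
# ---------------------------------------------------------------------------

def simulate_trait(pedigree: pd.DataFrame, genotypes: GenotypeMatrix | None,
                   spectra: SpectraMatrix | None, block_effects=None,
                   h2_additive: float = 0.35, spectral_share: float = 0.2,
                   seed: int = 0, qtl_share: float = 0.4, n_qtl: int = 20,
                   n_causal_bases: int = 4, sd_block: float = 0.3,
                   sd_prov: float = 0.3) -> tuple[pd.DataFrame, TrueParams]:
    """HCN-like trait for the phenotyped (non-founder) individuals.

    raw trait = provenance effect + block effect
              + sqrt(h2_additive) * standardized additive-genetic component
              + sqrt(spectral_share) * standardized causal-spectral component
              + sqrt(1 - h2 - share) * N(0,1) residual

    The additive component mixes a dam-transmitted polygenic deviate with
    sparse haplotype-window marker effects (``qtl_share`` of genetic
    variance); the spectral component is a linear functional of the realized
    spectra (projection onto causal Gaussian bases), hence recoverable by
    models carrying the spectra block. The result is affinely rescaled onto
    the printed HCN range [0, 1.54] mg/g dw; the affine map is recorded so
    variance shares survive rescaling.
    """
    if not (0.0 <= h2_additive < 1.0 and 0.0 <= spectral_share < 1.0):
        raise ValueError("variance shares must lie in [0, 1)")
    if h2_additive + spectral_share >= 1.0:
        raise ValueError("h2_additive + spectral_share must be < 1")
    rng = np.random.default_rng(seed)
    off = pedigree[pedigree["generation"] > 0].reset_index(drop=True)
    ids = off["id"].tolist()
    n = len(ids)

    provs = sorted(pedigree["provenance"].unique())
    prov_eff = {p: float(e) for p, e in zip(provs, sd_prov * rng.standard_normal(len(provs)))}
    if block_effects is None:
        blocks = sorted(off["block"].unique())
        block_effects = {int(b): float(e)
                         for b, e in zip(blocks, sd_block * rng.standard_normal(len(blocks)))}
    fixed = (off["provenance"].map(prov_eff) + off["block"].map(block_effects)).to_numpy()

    # dam-transmitted polygenic deviate (unit variance, half-sib cov 1/4)
    dam_bv = {f: rng.standard_normal()
              for f in pedigree.loc[pedigree["generation"] == 0, "family"]}
    poly = np.array([0.5 * dam_bv[f] + np.sqrt(0.75) * rng.standard_normal()
                     for f in off["family"]])

    causal_blocks: list[tuple[int, int]] = []
    if genotypes is not None and qtl_share > 0:
        gsub = genotypes.subset(ids)
        m = gsub.m
        starts = rng.choice(np.arange(0, max(m - 5, 1)), size=min(n_qtl, m), replace=False)
        qtl = np.zeros(n)
        for s in np.sort(starts):
            stop = min(s + 5, m)
            causal_blocks.append((int(s), int(stop)))
            beta = rng.standard_normal(stop - s)
            qtl += gsub.dosages[:, s:stop].astype(float) @ beta
        qtl = (qtl - qtl.mean()) / max(qtl.std(), 1e-12)
        genetic = np.sqrt(1 - qtl_share) * poly + np.sqrt(qtl_share) * qtl
    else:
        qtl_share = 0.0
        genetic = poly
    genetic = (genetic - genetic.mean()) / max(genetic.std(), 1e-12)

    causal_bases: list[int] = []
    if spectra is not None and spectral_share > 0:
        ssub = spectra.subset(ids)
        scores = ssub.latent_scores if ssub.latent_scores is not None \
            else ssub.basis_scores()
        causal_bases = sorted(rng.choice(scores.shape[1],
                                         size=min(n_causal_bases, scores.shape[1]),
                                         replace=False).tolist())
        gamma = rng.standard_normal(len(causal_bases))
        spect = scores[:, causal_bases] @ gamma
        spect = (spect - spect.mean()) / max(spect.std(), 1e-12)
    else:
        spectral_share = 0.0
        spect = np.zeros(n)

    resid_share = 1.0 - h2_additive - spectral_share
    resid = np.sqrt(resid_share) * rng.standard_normal(n)
    g_comp = np.sqrt(h2_additive) * genetic
    s_comp = np.sqrt(spectral_share) * spect
    raw = fixed + g_comp + s_comp + resid

    lo, hi = raw.min(), raw.max()
    scale = HCN_MAX / (hi - lo) if hi > lo else 1.0
    offset = -lo * scale
    hcn = raw * scale + offset

    table = pd.DataFrame({
        "id": ids, "hcn": hcn, "block": off["block"].to_numpy(),
        "family": off["family"].to_numpy(), "provenance": off["provenance"].to_numpy(),
        "group": off["provenance"].to_numpy(),
    })
    comps = pd.DataFrame({"id": ids, "fixed": fixed, "genetic": g_comp,
                          "spectral": s_comp, "residual": resid, "raw": raw})
    params = TrueParams(h2_additive, spectral_share, qtl_share, causal_blocks,
                        causal_bases, prov_eff, block_effects, comps,
                        scale, offset, seed)
    return table, params


# ---------------------------------------------------------------------------
# file export
# ---------------------------------------------------------------------------

def write_population(outdir, pedigree: pd.DataFrame, genotypes: GenotypeMatrix,
                     spectra: SpectraMatrix, trait: pd.DataFrame,
                     params: TrueParams) -> None:
    """Write pedigree/dosage/VCF/spectra/trait files plus ground-truth JSON."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pedigree.to_csv(out / "pedigree.csv", index=False)
    dos = pd.DataFrame(genotypes.dosages,
                       columns=[f"snp_{c}_{p}" for c, p in zip(genotypes.chrom, genotypes.pos)])
    dos.insert(0, "id", genotypes.ids)
    dos.to_csv(out / "genotypes.csv", index=False)
    write_vcf(out / "genotypes.vcf", genotypes)
    spec = pd.DataFrame(spectra.values,
                        columns=[f"wl_{int(round(w)):04d}" for w in spectra.wavelengths])
    spec.insert(0, "id", spectra.ids)
    spec.to_csv(out / "spectra.csv", index=False, float_format="%.6f")
    trait.to_csv(out / "trait.csv", index=False)
    params.to_json(out / "true_params.json")


def write_vcf(path, genotypes: GenotypeMatrix) -> None:
    """Minimal biallelic VCF (GT only) via pysam."""
    import pysam

    header = pysam.VariantHeader()
    for c in sorted(set(genotypes.chrom.tolist())):
        header.contigs.add(str(c))
    header.formats.add("GT", 1, "String", "Genotype")
    for i in genotypes.ids:
        header.add_sample(i)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j in range(genotypes.m):
            rec = vcf.new_record(contig=str(genotypes.chrom[j]),
                                 start=int(genotypes.pos[j]) - 1,
                                 alleles=("A", "T"))
            if genotypes.haplotypes is not None:
                for k, i in enumerate(genotypes.ids):
                    a, b = genotypes.haplotypes[k, j]
                    rec.samples[i]["GT"] = (int(a), int(b))
                    rec.samples[i].phased = True
            else:
                for k, i in enumerate(genotypes.ids):
                    d = int(genotypes.dosages[k, j])
                    rec.samples[i]["GT"] = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[d]
            vcf.write(rec)
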