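"""Generator contracts: half-sib structure, LD, spectra, trait bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from cyanophen import ldblocks, syndata


class TestPedigree:
    def test_half_sib_structure_and_counts(self):
        ped = syndata.simulate_pedigree(49, 6, 30, 4, seed=1)
        founders = ped[ped.generation == 0]
        offspring = ped[ped.generation > 0]
        assert len(founders) == 49 and len(offspring) == 294
        assert (offspring.sire == syndata.UNKNOWN).all()
        # each family maps to exactly one dam
        assert offspring.groupby("family")["dam"].nunique().eq(1).all()
        # single-tree plots: a family appears at most once per block
        assert offspring.groupby(["family", "block"]).size().max() == 1
        assert offspring.block.between(1, 30).all()

    def test_two_half_sibs_share_one_dam(self):
        ped = syndata.simulate_pedigree(1, 2, 2, 1, seed=7)
        off = ped[ped.generation > 0]
        assert len(off) == 2 and off.dam.nunique() == 1

    def test_seed_determinism(self):
        a = syndata.simulate_pedigree(49, 6, 30, 4, seed=1)
        b = syndata.simulate_pedigree(49, 6, 30, 4, seed=1)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("bad", [(0, 6, 30, 4), (49, 0, 30, 4),
                                     (49, 6, 0, 4), (49, 6, 30, 0)])
    def test_rejects_nonpositive_counts(self, bad):
        with pytest.raises(ValueError):
            syndata.simulate_pedigree(*bad, seed=0)


class TestGenotypes:
    def test_maf_filter_and_shape(self, small_population):
        _, geno, _, _, _ = small_population
        f = geno.allele_freq()
        assert np.minimum(f, 1 - f).min() >= 0.05
        assert geno.dosages.shape[0] == 343
        assert set(np.unique(geno.dosages)) <= {0, 1, 2}
        assert np.array_equal(geno.dosages, geno.haplotypes.sum(axis=2))

    def test_positions_increasing_within_chromosome(self, small_population):
        _, geno, _, _, _ = small_population
        for c in range(1, 12):
            assert np.all(np.diff(geno.pos[geno.chrom == c]) > 0)

    def test_seed_determinism(self):
        ped = syndata.simulate_pedigree(5, 3, 4, 1, seed=3)
        a = syndata.simulate_genotypes(ped, n_chrom=2, snps_per_chrom=40, seed=9)
        b = syndata.simulate_genotypes(ped, n_chrom=2, snps_per_chrom=40, seed=9)
        assert np.array_equal(a.dosages, b.dosages)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_rejects_bad_maf(self):
        ped = syndata.simulate_pedigree(2, 2, 2, 1, seed=0)
        with pytest.raises(ValueError):
            syndata.simulate_genotypes(ped, maf_min=0.5)

    def test_within_block_ld_exceeds_between(self, small_population):
        """Latent-haplotype blocks must create more D' inside a block than
        between adjacent blocks (measured on the package's own LD stats)."""
        _, geno, _, _, _ = small_population
        sel = geno.chrom == 1
        sub = syndata.GenotypeMatrix(geno.ids, geno.dosages[:, sel],
                                     geno.chrom[sel], geno.pos[sel],
                                     geno.haplotypes[:, sel, :])
        ld = ldblocks.pairwise_ld(sub)
        D = ld.dprime[1]
        m = D.shape[0]
        within, between = [], []
        for i in range(m - 1):
            for j in range(i + 1, min(i + 12, m)):
                if not np.isfinite(D[i, j]):
                    continue
                (within if j - i < 5 else between).append(D[i, j])
        assert np.mean(within) > np.mean(between) + 0.1


class TestSpectra:
    def test_values_in_unit_interval_and_grid(self, small_population):
        _, _, spec, _, _ = small_population
        assert spec.values.min() > 0 and spec.values.max() < 1
        assert spec.wavelengths[0] == 400 and spec.wavelengths[-1] == 2400
        assert np.all(np.diff(spec.wavelengths) == 10)

    def test_parent_offspring_regression_orders_regions(self):
        """Realized band h2 (2x dam-offspring regression) must be higher in
        the visible than in the SWIR, as configured."""
        ped = syndata.simulate_pedigree(80, 5, 30, 4, seed=5)
        spec = syndata.simulate_spectra(
            ped, {"visible": 0.45, "nir": 0.30, "swir": 0.20}, seed=6)
        dam_row = {i: k for k, i in enumerate(spec.ids)}
        off = ped[ped.generation > 0]
        o_idx = [dam_row[i] for i in off.id]
        d_idx = [dam_row[d] for d in off.dam]
        h2 = []
        for b in range(spec.values.shape[1]):
            x = spec.values[d_idx, b]
            y = spec.values[o_idx, b]
            h2.append(2 * np.cov(x, y)[0, 1] / spec.values[:, b].var())
        h2 = np.array(h2)
        wl = spec.wavelengths
        vis = h2[(wl >= 400) & (wl <= 700)].mean()
        swir = h2[(wl >= 1400) & (wl <= 2400)].mean()
        assert vis > swir + 0.1
        assert abs(vis - 0.45) < 0.12 and abs(swir - 0.20) < 0.12

    def test_zero_heritability_means_no_family_signal(self):
        ped = syndata.simulate_pedigree(40, 6, 10, 2, seed=5)
        spec = syndata.simulate_spectra(
            ped, {"visible": 0.0, "nir": 0.0, "swir": 0.0}, seed=6)
        dam_row = {i: k for k, i in enumerate(spec.ids)}
        off = ped[ped.generation > 0]
        o_idx = [dam_row[i] for i in off.id]
        d_idx = [dam_row[d] for d in off.dam]
        slopes = []
        for b in range(0, spec.values.shape[1], 10):
            x, y = spec.values[d_idx, b], spec.values[o_idx, b]
            slopes.append(np.cov(x, y)[0, 1] / x.var())
        assert abs(np.mean(slopes)) < 0.05

    def test_seed_determinism(self):
        ped = syndata.simulate_pedigree(5, 3, 4, 1, seed=3)
        a = syndata.simulate_spectra(ped, seed=8)
        b = syndata.simulate_spectra(ped, seed=8)
        assert np.array_equal(a.values, b.values)

    def test_region_gap_rejected(self):
        ped = syndata.simulate_pedigree(2, 2, 2, 1, seed=0)
        with pytest.raises(ValueError):
            syndata.simulate_spectra(ped, {"visible": 0.4, "swir": 0.2})


class TestTrait:
    def test_printed_scale_and_bookkeeping(self, small_population):
        _, _, _, trait, params = small_population
        assert trait.hcn.min() >= 0
        assert trait.hcn.max() <= syndata.HCN_MAX + 1e-12
        c = params.components
        resid = (c.fixed + c.genetic + c.spectral + c.residual - c.raw).abs().max()
        assert resid < 1e-10

    def test_realized_additive_share(self):
        """Across 20 seeds the generator's own components must realize the
        requested 40/20 additive/spectral split within +-0.05."""
        ped = syndata.simulate_pedigree(50, 8, 30, 4, seed=2)
        geno = syndata.simulate_genotypes(ped, n_chrom=4, snps_per_chrom=80, seed=3)
        spec = syndata.simulate_spectra(ped, seed=4)
        g_shares, s_shares = [], []
        for s in range(20):
            _, p = syndata.simulate_trait(ped, geno, spec, h2_additive=0.4,
                                          spectral_share=0.2, seed=100 + s)
            c = p.components
            tot = c.genetic.var() + c.spectral.var() + c.residual.var()
            g_shares.append(c.genetic.var() / tot)
            s_shares.append(c.spectral.var() / tot)
        assert abs(np.mean(g_shares) - 0.4) < 0.05
        assert abs(np.mean(s_shares) - 0.2) < 0.05

    def test_half_sib_intraclass_correlation(self):
        """ICC of half sibs ~ h2/4 for a pure pedigree-polygenic trait."""
        ped = syndata.simulate_pedigree(150, 6, 30, 1, seed=9)
        iccs = []
        for s in range(5):
            trait, _ = syndata.simulate_trait(ped, None, None, h2_additive=0.6,
                                              spectral_share=0.0, qtl_share=0.0,
                                              sd_block=0.0, sd_prov=0.0,
                                              seed=300 + s)
            grp = trait.groupby("family")["hcn"]
            k = 6
            msb = grp.mean().var(ddof=1) * k
            msw = grp.var(ddof=1).mean()
            iccs.append((msb - msw) / (msb + (k - 1) * msw))
        assert abs(np.mean(iccs) - 0.15) < 0.05

    def test_null_trait_is_fixed_effects_plus_noise(self):
        ped = syndata.simulate_pedigree(10, 4, 8, 2, seed=1)
        _, p = syndata.simulate_trait(ped, None, None, h2_additive=0.0,
                                      spectral_share=0.0, seed=2)
        assert p.components.genetic.abs().max() == 0
        assert p.components.spectral.abs().max() == 0

    def test_invalid_shares_rejected(self):
        ped = syndata.simulate_pedigree(5, 3, 4, 1, seed=3)
        with pytest.raises(ValueError):
            syndata.simulate_trait(ped, None, None, h2_additive=0.7,
                                   spectral_share=0.4)
        with pytest.raises(ValueError):
            syndata.simulate_trait(ped, None, None, h2_additive=-0.1,
                                   spectral_share=0.0)


class TestExport:
    def test_population_round_trips_through_files(self, tmp_path):
        ped = syndata.simulate_pedigree(6, 3, 5, 2, seed=71)
        geno = syndata.simulate_genotypes(ped, n_chrom=2, snps_per_chrom=25,
                                          seed=72)
        spec = syndata.simulate_spectra(ped, seed=73)
        trait, params = syndata.simulate_trait(ped, geno, spec, seed=74)
        syndata.write_population(tmp_path, ped, geno, spec, trait, params)

        ped2 = pd.read_csv(tmp_path / "pedigree.csv",
                           dtype={"sire": str, "dam": str})
        pd.testing.assert_frame_equal(ped, ped2)
        spec2 = pd.read_csv(tmp_path / "spectra.csv")
        assert spec2.columns[1] == "wl_0400"
        assert np.allclose(spec2.iloc[:, 1:].to_numpy(), spec.values, atol=1e-6)

        from cyvcf2 import VCF
        dosages = np.array([[g[0] + g[1] for g in v.genotypes]
                            for v in VCF(str(tmp_path / "genotypes.vcf"))])
        assert np.array_equal(dosages.T, geno.dosages)
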