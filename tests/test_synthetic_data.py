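"""The forward simulator: founders, meiosis, pedigree, phenotypes, qPCR, MS."""

import math

import numpy as np
import pytest

from fecmap.allele_screen import haldane_r, morgans
from fecmap.ms_differential import (
    drop_shared_peptides,
    filter_identifications,
    genotype_exclusive,
)
from fecmap.synthetic_data import (
    ExpressionDesign,
    L_LINEAGE,
    MsDesign,
    ORModel,
    PedigreeDesign,
    SimulationConfig,
    simulate_founders,
    simulate_meiosis,
    simulate_ms_table,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_qpcr,
    substream,
)


def small_config(**kw):
    kw.setdefault("region_length", 400_000)
    kw.setdefault("n_variant_sites", 12)
    kw.setdefault("n_wild_founders", 10)
    return SimulationConfig(**kw)


class TestFounders:
    def test_unique_mutant_lineage(self, rng):
        pool = simulate_founders(small_config(), rng)
        lineages = {int(h.lineage[0]) for h in pool.wild_haplotypes}
        lineages.add(int(pool.l_haplotype.lineage[0]))
        assert len(lineages) == 11  # 10 wild + the L lineage
        causal = pool.causal_index
        assert pool.l_haplotype.alleles[causal] == 1
        assert all(h.alleles[causal] == 0 for h in pool.wild_haplotypes)

    def test_configured_sharing_rate_recovered(self, rng):
        # one site set to the 17/19 sharing frequency; check the draw
        # frequency over 5000 wild chromosomes within binomial error
        cfg = small_config(n_wild_founders=5000)
        probs = np.zeros(12)
        probs[3] = 17 / 19
        pool = simulate_founders(cfg, rng, site_share_probs=probs)
        freq = np.mean([h.alleles[3] for h in pool.wild_haplotypes])
        p = 17 / 19
        tol = 4 * math.sqrt(p * (1 - p) / 5000)
        assert abs(freq - p) < tol

    def test_zero_decay_means_no_sharing(self, rng):
        pool = simulate_founders(
            small_config(), rng, site_share_probs=np.zeros(12)
        )
        for h in pool.wild_haplotypes:
            assert (h.alleles != pool.l_haplotype.alleles).all()

    def test_no_wild_founders_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_founders(small_config(n_wild_founders=0), rng)


class TestMeiosis:
    def test_zero_length_region_copies_one_parent(self, rng):
        from fecmap.synthetic_data import Haplotype

        hap_a = Haplotype(np.array([0, 1]), np.array([1, 1]))
        hap_b = Haplotype(np.array([1, 0]), np.array([2, 2]))
        gamete, xo = simulate_meiosis(
            hap_a, hap_b, [100, 100], 1.0, rng, region=(100, 100)
        )
        assert not xo
        assert (gamete.alleles == hap_a.alleles).all() or (
            gamete.alleles == hap_b.alleles
        ).all()

    def test_haldane_recombination_fraction(self, rng):
        # two markers 195 kb apart at 1 cM/Mb; closed-form Haldane r
        n = 20_000
        from fecmap.synthetic_data import Haplotype

        hap_a = Haplotype(np.array([0, 0]), np.array([1, 1]))
        hap_b = Haplotype(np.array([1, 1]), np.array([2, 2]))
        positions = [1, 195_001]
        rec = 0
        for _ in range(n):
            g, _ = simulate_meiosis(hap_a, hap_b, positions, 1.0, rng)
            rec += g.lineage[0] != g.lineage[1]
        r = haldane_r(morgans(195_000, 1.0))
        assert r == pytest.approx(0.0019462024384340881, rel=1e-12)
        tol = 4 * math.sqrt(r * (1 - r) / n)
        assert abs(rec / n - r) < tol

    def test_unlinked_markers_segregate_independently(self, rng):
        from fecmap.synthetic_data import Haplotype

        hap_a = Haplotype(np.array([0, 0]), np.array([1, 1]))
        hap_b = Haplotype(np.array([1, 1]), np.array([2, 2]))
        # enormous map distance -> r -> 0.5: parental and recombinant
        # gametes equally frequent
        n = 4000
        rec = 0
        for _ in range(n):
            g, _ = simulate_meiosis(hap_a, hap_b, [1, 10**6], 1000.0, rng)
            rec += g.lineage[0] != g.lineage[1]
        assert abs(rec / n - 0.5) < 4 * math.sqrt(0.25 / n)

    def test_gamete_alleles_match_lineage_of_origin(self, rng):
        # ground-truth conservation: each gamete allele equals the allele
        # of its recorded parental lineage at that site
        pool = simulate_founders(small_config(), rng)
        hap_a, hap_b = pool.l_haplotype, pool.wild_haplotypes[0]
        positions = pool.marker_map.positions
        for _ in range(200):
            g, _ = simulate_meiosis(hap_a, hap_b, positions, 5.0, rng)
            for j in range(len(positions)):
                src = hap_a if g.lineage[j] == hap_a.lineage[j] else hap_b
                assert g.alleles[j] == src.alleles[j]


class TestPedigree:
    def test_default_design_has_189_animals(self, rng):
        cfg = small_config()
        pool = simulate_founders(cfg, rng)
        ped = simulate_pedigree(cfg, pool, rng)
        assert len(ped.non_founders) == 189

    def test_empty_design_gives_empty_pedigree(self, rng):
        cfg = small_config(pedigree=PedigreeDesign(0, 0, 0))
        pool = simulate_founders(cfg, rng)
        ped = simulate_pedigree(cfg, pool, rng)
        assert ped.non_founders == []

    def test_backcross_carrier_fraction_is_half(self, rng):
        cfg = small_config(
            pedigree=PedigreeDesign(n_f1=2, n_bc=500, n_f1xbc=0),
            proxy_misclassification=0.0,
        )
        pool = simulate_founders(cfg, rng)
        ped = simulate_pedigree(cfg, pool, rng)
        bc = [a for a in ped.non_founders if a.generation == "BC"]
        frac = np.mean([a.true_class == "L/+" for a in bc])
        assert abs(frac - 0.5) < 4 * math.sqrt(0.25 / 500)

    def test_missing_parents_rejected(self, rng):
        cfg = small_config(pedigree=PedigreeDesign(n_f1=0, n_bc=5, n_f1xbc=0))
        pool = simulate_founders(cfg, rng)
        with pytest.raises(ValueError):
            simulate_pedigree(cfg, pool, rng)

    def test_zero_misclassification_observed_equals_truth(self, rng):
        cfg = small_config(proxy_misclassification=0.0)
        pool = simulate_founders(cfg, rng)
        ped = simulate_pedigree(cfg, pool, rng)
        assert all(
            a.observed_class == a.true_class for a in ped.non_founders
        )


class TestPhenotypes:
    def test_noiseless_values_exact(self, rng):
        model = ORModel(base_mean=1.2, per_copy_effect=1.5, residual_sd=0.0)
        df = simulate_phenotypes([0, 1, 2], model, rng)
        assert df["ovulation_rate"].tolist() == [1.2, 2.7, 4.2]

    def test_additive_effects_recovered(self, rng):
        model = ORModel(residual_sd=0.8)
        copies = [0] * 500 + [1] * 500 + [2] * 500
        df = simulate_phenotypes(copies, model, rng)
        means = df.groupby("l_copies")["ovulation_rate"].mean()
        se = 0.8 * math.sqrt(2 / 500)
        assert abs((means[1] - means[0]) - 1.5) < 2 * se
        assert abs((means[2] - means[0]) - 3.0) < 2 * se * math.sqrt(1.5)

    def test_negative_sd_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_phenotypes([0], ORModel(residual_sd=-1.0), rng)


class TestQpcr:
    EFF = {"B4GALNT2": 2.01, "IGF2BP1": 1.98, "RPL19": 1.95}

    def test_noiseless_fold_recovered_exactly(self, rng):
        from fecmap.expression_screen import compare_genotypes

        design = ExpressionDesign(
            fold_changes={"B4GALNT2": {"GC-LF": 1000.0}},
            tissues=("GC-LF",),
            ct_noise_sd=0.0,
        )
        df = simulate_qpcr(design, self.EFF, rng)
        c = compare_genotypes(df, "B4GALNT2", "GC-LF", self.EFF)
        assert c.fold_change == pytest.approx(1000.0, rel=1e-9)

    @pytest.mark.parametrize("fold", [1.0, 6.0])
    def test_other_folds(self, rng, fold):
        from fecmap.expression_screen import compare_genotypes

        design = ExpressionDesign(
            fold_changes={"IGF2BP1": {"GC-SF": fold}},
            tissues=("GC-SF",),
            ct_noise_sd=0.0,
        )
        df = simulate_qpcr(design, self.EFF, rng)
        c = compare_genotypes(df, "IGF2BP1", "GC-SF", self.EFF)
        assert c.fold_change == pytest.approx(fold, rel=1e-9)

    def test_bad_efficiency_rejected(self, rng):
        design = ExpressionDesign(
            fold_changes={"X": {"GC-SF": 2.0}}, tissues=("GC-SF",)
        )
        with pytest.raises(ValueError):
            simulate_qpcr(design, {"X": 1.0, "RPL19": 1.95}, rng)


class TestMsTable:
    @staticmethod
    def _exclusive(df):
        retained = filter_identifications(drop_shared_peptides(df))
        return genotype_exclusive(retained)

    def test_exclusive_set_size_recovered(self, rng):
        df = simulate_ms_table(MsDesign(n_exclusive=10), rng)
        assert len(self._exclusive(df)) == 10

    def test_empty_exclusive_set(self, rng):
        df = simulate_ms_table(MsDesign(n_exclusive=0), rng)
        assert len(self._exclusive(df)) == 0

    def test_low_peptide_exclusive_protein_filtered_out(self, rng):
        design = MsDesign(
            n_exclusive=1, min_exclusive_peptides=3, mean_extra_peptides=0.0
        )
        df = simulate_ms_table(design, rng)
        excl = df[df["protein"] == "EXCL0"]
        assert (excl["n_peptides"] == 3).all()
        assert len(self._exclusive(df)) == 0  # fails the >=4 peptide rule


class TestDeterminism:
    def test_substreams_are_reproducible_and_independent(self):
        a = substream(7, "pedigree").random(4)
        b = substream(7, "pedigree").random(4)
        c = substream(7, "panels").random(4)
        assert (a == b).all()
        assert not (a == c).all()
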