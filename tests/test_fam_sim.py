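import math

import numpy as np
import pytest
from scipy import stats

from fhapminer.fam_sim import (
    PENETRANCE_SETS,
    PenetranceModel,
    StructureModel,
    assign_phenotypes,
    drop_genes,
    genotype_given_affected,
    pick_rare_haplotypes,
    prevalence,
    relative_risks,
    sample_structure,
    simulate_dataset,
    substream,
    uniform_map,
)
from fhapminer.ped_model import HaplotypeFrequencyTable, Individual, Pedigree, Sex
from fhapminer.zr_phase import enumerate_configs


class TestPenetranceAnalytics:
    def test_prevalence_examples(self):
        assert prevalence(PENETRANCE_SETS["C"], 0.1) == pytest.approx(0.0995)
        assert prevalence(PENETRANCE_SETS["A"], 0.1) == pytest.approx(0.07)
        assert prevalence((0.3, 0.3, 0.3), 0.7) == pytest.approx(0.3)

    def test_genotype_given_affected_sums_to_one(self):
        for label in PENETRANCE_SETS:
            comps = genotype_given_affected(PENETRANCE_SETS[label], 0.1)
            assert sum(comps) == pytest.approx(1.0, abs=1e-15)

    def test_flat_penetrance_returns_hwe(self):
        comps = genotype_given_affected((0.2, 0.2, 0.2), 0.3)
        assert comps == pytest.approx((0.49, 0.42, 0.09))

    def test_relative_risks(self):
        assert relative_risks(PENETRANCE_SETS["A"]) == pytest.approx((3.0, 5.0))
        assert relative_risks((0.1, 0.1, 0.5)) == pytest.approx((1.0, 5.0))
        l1, l2 = relative_risks((0.0, 0.1, 0.0))
        assert math.isinf(l1) and math.isnan(l2)

    def test_zero_prevalence_rejected(self):
        with pytest.raises(ValueError):
            genotype_given_affected((0.0, 0.0, 0.0), 0.1)


class TestStructures:
    def test_two_generations_only(self):
        rng = np.random.default_rng(0)
        model = StructureModel(p_three_gen=0.0)
        for _ in range(50):
            ped = sample_structure(model, rng)
            assert all(
                m.is_founder or ped.member(m.father_id).is_founder
                for m in ped.members
            )

    def test_three_generation_fraction_and_sizes(self):
        rng = np.random.default_rng(1)
        model = StructureModel()
        n = 10_000
        three = 0
        sizes = []
        for _ in range(n):
            ped = sample_structure(model, rng)
            sizes.append(ped.size)
            three += any(
                not m.is_founder and not ped.member(m.father_id).is_founder
                for m in ped.members
            )
        assert abs(three / n - 52 / 65) < 0.02
        assert min(sizes) >= 4 and max(sizes) <= 20
        assert abs(np.mean(sizes) - 13) < 1.0

    def test_fixed_seed_reproducible(self):
        a = sample_structure(StructureModel(), 7)
        b = sample_structure(StructureModel(), 7)
        assert a == b


class TestGeneDrop:
    def test_single_haplotype_table(self):
        table = HaplotypeFrequencyTable(["12"], [1.0])
        ped, truth = drop_genes(sample_structure(StructureModel(), 3), table, 3)
        for m in ped.members:
            assert m.genotype == [(1, 1), (2, 2)]

    def test_founder_draw_frequencies_gof(self, cf_like_table):
        # 50,000 founder haplotype draws against the table by chi-square GOF
        rng = np.random.default_rng(5)
        couple = Pedigree(
            "F",
            [
                Individual("F", "a", None, None, Sex.MALE, 0.0, []),
                Individual("F", "b", None, None, Sex.FEMALE, 0.0, []),
                Individual("F", "c", "a", "b", Sex.UNKNOWN, 0.0, []),
            ],
        )
        counts: dict[str, int] = {}
        n_draws = 0
        for _ in range(12_500):
            _, truth = drop_genes(couple, cf_like_table, rng)
            for founder in ("a", "b"):
                for hap in truth.haplotypes[founder]:
                    counts["".join(map(str, hap))] = (
                        counts.get("".join(map(str, hap)), 0) + 1
                    )
                    n_draws += 1
        assert n_draws == 50_000
        observed = [counts.get(h, 0) for h in cf_like_table.haplotypes]
        expected = [f * n_draws for f in cf_like_table.frequencies]
        gof = stats.chisquare(observed, expected)
        assert gof.pvalue > 0.01

    def test_truth_always_phaseable(self, small_table):
        rng = np.random.default_rng(6)
        for i in range(100):
            ped, truth = drop_genes(
                sample_structure(StructureModel(), rng, family_id=f"F{i}"),
                small_table,
                rng,
            )
            assert len(enumerate_configs(ped)) >= 1


class TestPhenotypes:
    def _singletons(self, table, n, rng):
        out = []
        for i in range(n):
            single = Pedigree(
                "S", [Individual("S", "x", None, None, Sex.UNKNOWN, 0.0, [])]
            )
            out.append(drop_genes(single, table, rng))
        return out

    def test_degenerate_penetrances(self, small_table):
        rng = np.random.default_rng(7)
        ped, truth = drop_genes(sample_structure(StructureModel(), rng), small_table, rng)
        model0 = PenetranceModel(0, 0, 0, risk_snp=0, risk_allele=1)
        assign_phenotypes(ped, truth, model0, rng)
        assert all(m.phenotype == 0 for m in ped.members)
        model1 = PenetranceModel(1, 1, 1, risk_snp=0, risk_allele=1)
        assign_phenotypes(ped, truth, model1, rng)
        assert all(m.phenotype == 1 for m in ped.members)

    def test_affected_fraction_converges_to_prevalence(self):
        # risk allele frequency 0.1 at the first SNP; penetrance set C gives
        # K = 0.0995 among unrelated singletons
        table = HaplotypeFrequencyTable(["11", "21"], [0.9, 0.1])
        rng = np.random.default_rng(8)
        model = PenetranceModel(*PENETRANCE_SETS["C"], risk_snp=0, risk_allele=2)
        n = 20_000
        affected = 0
        by_g = {0: [0, 0], 1: [0, 0], 2: [0, 0]}
        for single in self._singletons(table, n, rng):
            ped, truth = single
            assign_phenotypes(ped, truth, model, rng)
            g = sum(1 for h in truth.haplotypes["x"] if h[0] == 2)
            y = int(ped.members[0].phenotype)
            by_g[g][0] += 1
            by_g[g][1] += y
            affected += y
        k = 0.0995
        assert abs(affected / n - k) < 3 * math.sqrt(k * (1 - k) / n)
        # conditional rates converge to the penetrances per genotype class
        for g, f in zip((0, 1, 2), PENETRANCE_SETS["C"]):
            n_g, aff_g = by_g[g]
            assert n_g > 30
            se = math.sqrt(f * (1 - f) / n_g)
            assert abs(aff_g / n_g - f) < 4 * se

    def test_risk_snp_out_of_range(self, small_table):
        rng = np.random.default_rng(9)
        ped, truth = drop_genes(sample_structure(StructureModel(), rng), small_table, rng)
        model = PenetranceModel(0.1, 0.2, 0.3, risk_snp=99, risk_allele=1)
        with pytest.raises(ValueError, match="out of range"):
            assign_phenotypes(ped, truth, model, rng)


class TestAscertainment:
    def test_full_penetrance_accepts_everything(self, small_table):
        model = PenetranceModel(1, 1, 1, risk_snp=0, risk_allele=1)
        ds = simulate_dataset(small_table, 10, model, seed=1)
        # acceptance rate 1: family ids run F1..F10 with no rejected attempts
        assert [f.pedigree.family_id for f in ds.families] == [
            f"F{i}" for i in range(1, 11)
        ]

    def test_every_family_has_an_affected(self, small_table):
        model = PenetranceModel(0.05, 0.3, 0.5, risk_snp=1, risk_allele=1)
        ds = simulate_dataset(small_table, 20, model, seed=2)
        assert len(ds.families) == 20
        for fam in ds.families:
            assert any(m.phenotype == 1 for m in fam.pedigree.members)

    def test_risk_snp_stripped_in_single_locus_mode(self, small_table):
        model = PenetranceModel(0.05, 0.3, 0.5, risk_snp=1, risk_allele=1)
        ds = simulate_dataset(small_table, 5, model, seed=3)
        assert ds.pedigrees[0].n_markers == small_table.n_markers - 1
        assert len(ds.marker_map) == small_table.n_markers - 1
        assert ds.removed_snp == 1
        assert ds.removed_marker.name == "snp2"
        for fam in ds.families:
            for pair in fam.truth.haplotypes.values():
                assert len(pair[0]) == small_table.n_markers - 1

    def test_null_model_keeps_all_markers(self, small_table):
        ds = simulate_dataset(small_table, 5, None, seed=4, null_prevalence=0.3)
        assert ds.pedigrees[0].n_markers == small_table.n_markers

    def test_reproducible(self, small_table):
        model = PenetranceModel(0.05, 0.3, 0.5, risk_snp=0, risk_allele=1)
        d1 = simulate_dataset(small_table, 5, model, seed=5)
        d2 = simulate_dataset(small_table, 5, model, seed=5)
        assert d1.pedigrees == d2.pedigrees


class TestRareHaplotypes:
    def test_synthetic_panel_has_22_eligible(self, cf_like_table):
        eligible = [f for f in cf_like_table.frequencies if f < 0.02]
        assert len(eligible) == 22
        picked = pick_rare_haplotypes(cf_like_table, 22, rng=0)
        assert len(picked) == 22

    def test_whole_eligible_set_when_k_equals_count(self, cf_like_table):
        picked = pick_rare_haplotypes(cf_like_table, 22, rng=1)
        expected = {
            h
            for h, f in zip(cf_like_table.haplotypes, cf_like_table.frequencies)
            if f < 0.02
        }
        assert picked == expected

    def test_fixed_seed_identical_selection(self, cf_like_table):
        assert pick_rare_haplotypes(cf_like_table, 3, rng=9) == pick_rare_haplotypes(
            cf_like_table, 3, rng=9
        )

    def test_too_few_eligible(self, cf_like_table):
        with pytest.raises(ValueError, match="22"):
            pick_rare_haplotypes(cf_like_table, 23)


class TestSubstreams:
    def test_named_streams_differ_and_reproduce(self):
        a1 = substream(3, "structure").integers(0, 1 << 30)
        a2 = substream(3, "structure").integers(0, 1 << 30)
        b = substream(3, "genedrop").integers(0, 1 << 30)
        assert a1 == a2
        assert a1 != b

    def test_uniform_map_spacing(self):
        mm = uniform_map(5)
        assert [m.genetic_pos_cm for m in mm.markers] == pytest.approx(
            [0.0, 0.01, 0.02, 0.03, 0.04]
        )
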