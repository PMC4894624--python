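"""Segregation scores, weighted-sum burden test, compound-het rules."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, rankdata

from pedpipe import dmi, simkit
from pedpipe.pedio import (AFFECTED, HET, HOM_MAJOR, HOM_MINOR, MISSING,
                           UNAFFECTED, make_variant_table)

from conftest import build_pedigree, make_matrix

AFF, UNAFF, UNK = 0, 1, 2


def track_for(codes, phen, model):
    gm = make_matrix(np.asarray(codes, dtype=np.int8))
    variants = make_variant_table([
        dict(variant_id=v, chromosome="1", bp=100 * (j + 1), cm=float(j),
             allele_minor="A", allele_major="G", f_w=0.01, gene_id=np.nan)
        for j, v in enumerate(gm.variant_ids)])
    return dmi.segregation_score_track(gm, variants, np.array(phen), model)


class TestSegregationScore:
    @pytest.mark.parametrize("model,phen,code,expected", [
        (dmi.DOMINANT, AFF, HOM_MINOR, 0.8),
        (dmi.DOMINANT, AFF, HOM_MAJOR, 0.5),
        (dmi.DOMINANT, UNAFF, HET, 0.1),
        (dmi.DOMINANT, UNAFF, HOM_MINOR, 0.01),
        (dmi.DOMINANT, AFF, HET, 1.0),        # consistent carrier
        (dmi.DOMINANT, UNAFF, HOM_MAJOR, 1.0),
        (dmi.RECESSIVE, AFF, HET, 0.5),
        (dmi.RECESSIVE, AFF, HOM_MAJOR, 0.1),
        (dmi.RECESSIVE, UNAFF, HOM_MINOR, 0.1),
        (dmi.RECESSIVE, AFF, HOM_MINOR, 1.0),  # consistent homozygote
        (dmi.DOMINANT, AFF, MISSING, 1.0),
        (dmi.DOMINANT, UNK, HET, 1.0),
    ])
    def test_single_individual_weights(self, model, phen, code, expected):
        gm = make_matrix([[code]])
        score = dmi.segregation_score(gm, "v1", np.array([phen]), model)
        assert score == pytest.approx(expected)

    def test_product_over_individuals(self):
        # affected DD x unaffected Dd x affected Dd = 0.8 * 0.1 * 1
        gm = make_matrix([[HOM_MINOR], [HET], [HET]])
        score = dmi.segregation_score(gm, "v1",
                                      np.array([AFF, UNAFF, AFF]),
                                      dmi.DOMINANT)
        assert score == pytest.approx(0.08)

    def test_all_consistent_genotypes_score_one(self):
        gm = make_matrix([[HET], [HOM_MAJOR]])
        assert dmi.segregation_score(gm, "v1", np.array([AFF, UNAFF]),
                                     dmi.DOMINANT) == 1.0

    def test_unknown_model_rejected(self):
        gm = make_matrix([[HET]])
        with pytest.raises(ValueError, match="model"):
            dmi.segregation_score(gm, "v1", np.array([AFF]), "additive")

    def test_multiplicative_over_subsets(self):
        rng = np.random.default_rng(4)
        codes = rng.integers(-1, 3, size=(10, 3)).astype(np.int8)
        phen = rng.integers(0, 3, 10)
        for model in (dmi.DOMINANT, dmi.RECESSIVE):
            full = track_for(codes, phen, model)["score"].to_numpy()
            part1 = track_for(codes[:4], phen[:4], model)["score"].to_numpy()
            part2 = track_for(codes[4:], phen[4:], model)["score"].to_numpy()
            assert np.allclose(full, part1 * part2)

    def test_adding_individual_never_increases(self):
        rng = np.random.default_rng(8)
        codes = rng.integers(-1, 3, size=(6, 4)).astype(np.int8)
        phen = rng.integers(0, 3, 6)
        base = track_for(codes[:-1], phen[:-1], dmi.DOMINANT)["score"]
        ext = track_for(codes, phen, dmi.DOMINANT)["score"]
        assert (ext.to_numpy() <= base.to_numpy() + 1e-15).all()
        assert ((ext > 0) & (ext <= 1)).all()

    def test_custom_params_override(self):
        gm = make_matrix([[HOM_MINOR]])
        params = dmi.SegregationScoreParams(dom_affected_hom_minor=0.9)
        assert dmi.segregation_score(gm, "v1", np.array([AFF]),
                                     dmi.DOMINANT, params) == 0.9


class TestRanking:
    def test_descending_by_score(self):
        track = pd.DataFrame({"variant_id": ["v1", "v2"],
                              "score": [0.8, 0.008]})
        assert dmi.rank_variants_by_segregation(track) == ["v1", "v2"]

    def test_tie_breaks_by_genomic_order(self):
        track = pd.DataFrame({"variant_id": ["v1", "v2", "v3"],
                              "score": [0.5, 1.0, 1.0]})
        assert dmi.rank_variants_by_segregation(track) == ["v2", "v3", "v1"]

    def test_invariant_to_individual_order(self):
        rng = np.random.default_rng(12)
        codes = rng.integers(-1, 3, size=(8, 5)).astype(np.int8)
        phen = rng.integers(0, 2, 8)
        perm = rng.permutation(8)
        t1 = track_for(codes, phen, dmi.DOMINANT)
        t2 = track_for(codes[perm], phen[perm], dmi.DOMINANT)
        assert dmi.rank_variants_by_segregation(t1) == \
            dmi.rank_variants_by_segregation(t2)


def mb_oracle_pvalue(codes, aff_labels):
    """Independent brute-force weighted-sum oracle: enumerate all label
    assignments, recompute control-frequency weights and rank-sum for each."""
    codes = np.asarray(codes, dtype=float)
    n = codes.shape[0]
    k = int(sum(aff_labels))

    def statistic(aff_set):
        q = []
        for j in range(codes.shape[1]):
            ctrl = [codes[i, j] for i in range(n) if i not in aff_set]
            q.append((sum(ctrl) + 1) / (2 * len(ctrl) + 2))
        w = [np.sqrt(n * qj * (1 - qj)) for qj in q]
        gamma = [sum(codes[i, j] / w[j] for j in range(codes.shape[1]))
                 for i in range(n)]
        ranks = rankdata(gamma)
        return sum(ranks[i] for i in aff_set)

    obs = statistic(frozenset(np.flatnonzero(aff_labels)))
    stats = [statistic(frozenset(c)) for c in combinations(range(n), k)]
    return sum(s >= obs - 1e-9 for s in stats) / len(stats)


class TestWeightedSum:
    def fixture_gm(self):
        # 2 affected singleton-variant carriers, 2 unaffected non-carriers
        return make_matrix([[1], [1], [0], [0]]), np.array([0, 0, 1, 1])

    def test_exhaustive_matches_enumeration_oracle(self):
        gm, phen = self.fixture_gm()
        res = dmi.weighted_sum_statistic(gm, phen, ["v1"])
        assert res.exhaustive
        assert res.p_value == pytest.approx(1 / 6)
        oracle = mb_oracle_pvalue([[1], [1], [0], [0]], [1, 1, 0, 0])
        assert res.p_value == pytest.approx(oracle)

    def test_oracle_agreement_on_random_multivariant_genes(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            codes = rng.integers(0, 3, size=(7, 3)).astype(np.int8)
            phen = np.array([0, 0, 0, 1, 1, 1, 1])
            gm = make_matrix(codes)
            res = dmi.weighted_sum_statistic(gm, phen, gm.variant_ids)
            assert res.exhaustive
            assert res.p_value == pytest.approx(
                mb_oracle_pvalue(codes, phen == 0))

    def test_monte_carlo_converges_to_exact(self):
        gm, phen = self.fixture_gm()
        exact = dmi.weighted_sum_statistic(gm, phen, ["v1"])
        assert exact.exhaustive and exact.p_value == pytest.approx(1 / 6)
        mc = dmi.weighted_sum_statistic(gm, phen, ["v1"],
                                        n_permutations=4000, seed=5,
                                        method="monte_carlo")
        assert not mc.exhaustive
        assert abs(mc.p_value - 1 / 6) < 0.02

    def test_exchangeable_null_not_anticonservative(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 2, size=(8, 2)).astype(np.int8)
        gm = make_matrix(np.vstack([codes, codes]))
        phen = np.array([0] * 8 + [1] * 8)
        res = dmi.weighted_sum_statistic(gm, phen, gm.variant_ids)
        assert res.p_value >= 0.5

    def test_degenerate_all_equal_burdens(self):
        gm = make_matrix([[1], [1], [1], [1]])
        res = dmi.weighted_sum_statistic(gm, np.array([0, 0, 1, 1]), ["v1"])
        assert res.degenerate and res.p_value == 1.0 and res.z == 0.0

    def test_requires_both_phenotype_classes(self):
        gm = make_matrix([[1], [0]])
        with pytest.raises(ValueError, match="affected"):
            dmi.weighted_sum_statistic(gm, np.array([0, 0]), ["v1"])

    def test_null_pvalues_uniform(self):
        """Under genotype-independent phenotypes, permutation p-values are
        uniform (Kolmogorov-Smirnov at alpha = 0.001)."""
        rng = np.random.default_rng(42)
        n, nv = 20, 8
        pvals = []
        for rep in range(400):
            mafs = rng.uniform(0.1, 0.4, nv)
            codes = ((rng.random((n, nv)) < mafs).astype(np.int8)
                     + (rng.random((n, nv)) < mafs).astype(np.int8))
            gm = make_matrix(codes)
            phen = np.array([0] * 10 + [1] * 10)
            res = dmi.weighted_sum_statistic(gm, phen, gm.variant_ids,
                                             n_permutations=199, seed=rep)
            pvals.append(res.p_value)
        assert kstest(pvals, "uniform").pvalue > 0.001

    def test_per_gene_seeding_is_order_independent(self):
        rng = np.random.default_rng(77)
        codes = rng.integers(0, 3, size=(30, 6)).astype(np.int8)
        gm = make_matrix(codes)
        phen = np.array(([0] * 12 + [1] * 18))
        gene_map = pd.DataFrame({
            "variant_id": [f"v{j + 1}" for j in range(6)],
            "gene_id": ["gA", "gA", "gA", "gB", "gB", "gB"]})
        fwd = dmi.weighted_sum_by_gene(gm, phen, gene_map, seed=1,
                                       n_permutations=200)
        rev = dmi.weighted_sum_by_gene(
            gm, phen, gene_map.iloc[::-1].reset_index(drop=True), seed=1,
            n_permutations=200)
        by_gene = {r.gene_id: r.p_value for r in rev}
        for r in fwd:
            assert by_gene[r.gene_id] == r.p_value


def trio_with_genotypes(v1, v2, affected_child=True,
                        parent_affected=(False, False), sib=None):
    """Trio (plus optional sib) pedigree and 2-variant genotypes.

    v1/v2: (father, mother, child[, sib]) codes.
    """
    rows = [
        ("1", None, None, "male",
         AFFECTED if parent_affected[0] else UNAFFECTED),
        ("2", None, None, "female",
         AFFECTED if parent_affected[1] else UNAFFECTED),
        ("3", "1", "2", "male", AFFECTED if affected_child else UNAFFECTED),
    ]
    codes = [[v1[0], v2[0]], [v1[1], v2[1]], [v1[2], v2[2]]]
    if sib is not None:
        rows.append(("4", "1", "2", "female", sib[2]))
        codes.append([sib[0], sib[1]])
    ped = build_pedigree("F1", rows)
    gm = make_matrix(np.array(codes, dtype=np.int8))
    variants = make_variant_table([
        dict(variant_id="v1", chromosome="1", bp=100, cm=0.1,
             allele_minor="A", allele_major="G", f_w=0.01, gene_id="g1"),
        dict(variant_id="v2", chromosome="1", bp=200, cm=0.2,
             allele_minor="A", allele_major="G", f_w=0.01, gene_id="g1")])
    gene_map = pd.DataFrame({"variant_id": ["v1", "v2"],
                             "gene_id": ["g1", "g1"]})
    return ped, gm, variants, gene_map


class TestCompoundHet:
    def test_trans_trio_passes_all_rules(self):
        # v1 from father, v2 from mother, child het at both
        ped, gm, variants, gene_map = trio_with_genotypes(
            v1=(HET, HOM_MAJOR, HET), v2=(HOM_MAJOR, HET, HET))
        [res] = dmi.compound_het_scan(
            [ped], gm, variants, gene_map,
            dmi.CompoundHetConfig(min_rule_proportion=1.0))
        assert res.r4 and res.r5 and res.passes
        assert set(res.contributing_variants) == {"v1", "v2"}

    def test_cis_configuration_fails_rule5(self):
        # both variants carried only by the father
        ped, gm, variants, gene_map = trio_with_genotypes(
            v1=(HET, HOM_MAJOR, HET), v2=(HET, HOM_MAJOR, HET))
        [res] = dmi.compound_het_scan(
            [ped], gm, variants, gene_map,
            dmi.CompoundHetConfig(min_rule_proportion=1.0))
        assert res.r4 and res.r5 is False and not res.passes

    def test_unaffected_hom_minor_fails_rule2(self):
        ped, gm, variants, gene_map = trio_with_genotypes(
            v1=(HET, HET, HET), v2=(HOM_MAJOR, HET, HET),
            sib=(HOM_MINOR, HOM_MAJOR, UNAFFECTED))
        [res] = dmi.compound_het_scan(
            [ped], gm, variants, gene_map,
            dmi.CompoundHetConfig(min_rule_proportion=1.0))
        flags = res.variant_flags.set_index("variant_id")
        assert not flags.loc["v1", "r2"]

    def test_two_het_parents_fail_rule3(self):
        ped, gm, variants, gene_map = trio_with_genotypes(
            v1=(HET, HET, HET), v2=(HOM_MAJOR, HET, HET))
        [res] = dmi.compound_het_scan(
            [ped], gm, variants, gene_map,
            dmi.CompoundHetConfig(min_rule_proportion=1.0))
        flags = res.variant_flags.set_index("variant_id")
        assert not flags.loc["v1", "r3"]

    def test_affected_parent_skips_rule5(self):
        # cis configuration, but the father is affected: rule 5 is moot
        ped, gm, variants, gene_map = trio_with_genotypes(
            v1=(HET, HOM_MAJOR, HET), v2=(HET, HOM_MAJOR, HET),
            parent_affected=(True, False))
        cfg = dmi.CompoundHetConfig(min_rule_proportion=1.0,
                                    apply_rule5="auto")
        [res] = dmi.compound_het_scan([ped], gm, variants, gene_map, cfg)
        assert res.r5 is None and res.passes
        cfg_always = dmi.CompoundHetConfig(min_rule_proportion=1.0,
                                           apply_rule5="always")
        [res2] = dmi.compound_het_scan([ped], gm, variants, gene_map,
                                       cfg_always)
        assert res2.r5 is False and not res2.passes

    def test_proportion_relaxation_tolerates_one_error(self):
        """21 affected trio children, one heterozygote miscalled as
        homozygous: 20/21 > 0.95 keeps rule 1 satisfied."""
        peds, codes = [], []
        for k in range(21):
            fid = f"F{k + 1}"
            peds.append(build_pedigree(fid, [
                ("1", None, None, "male", UNAFFECTED),
                ("2", None, None, "female", UNAFFECTED),
                ("3", "1", "2", "male", AFFECTED)]))
            child_v1 = HOM_MAJOR if k == 0 else HET  # one genotyping error
            codes += [[HET, HOM_MAJOR], [HOM_MAJOR, HET], [child_v1, HET]]
        samples = [(p.family_id, iid) for p in peds for iid in
                   ("1", "2", "3")]
        from pedpipe.pedio import GenotypeMatrix
        gm = GenotypeMatrix(samples, ["v1", "v2"],
                            np.array(codes, dtype=np.int8))
        variants = make_variant_table([
            dict(variant_id="v1", chromosome="1", bp=100, cm=0.1,
                 allele_minor="A", allele_major="G", f_w=0.01, gene_id="g1"),
            dict(variant_id="v2", chromosome="1", bp=200, cm=0.2,
                 allele_minor="A", allele_major="G", f_w=0.01,
                 gene_id="g1")])
        gene_map = pd.DataFrame({"variant_id": ["v1", "v2"],
                                 "gene_id": ["g1", "g1"]})
        strict = dmi.compound_het_scan(
            peds, gm, variants, gene_map,
            dmi.CompoundHetConfig(min_rule_proportion=1.0))[0]
        relaxed = dmi.compound_het_scan(
            peds, gm, variants, gene_map,
            dmi.CompoundHetConfig(min_rule_proportion=0.95))[0]
        assert not strict.passes and relaxed.passes

    def test_gene_without_variants_absent(self):
        ped, gm, variants, gene_map = trio_with_genotypes(
            v1=(HET, HOM_MAJOR, HET), v2=(HOM_MAJOR, HET, HET))
        gene_map = pd.concat([gene_map, pd.DataFrame(
            {"variant_id": ["v99"], "gene_id": ["g2"]})])
        results = dmi.compound_het_scan([ped], gm, variants, gene_map)
        assert [r.gene_id for r in results] == ["g1"]

    def test_simulated_trans_genes_detected_without_error(self):
        sim = simkit.simulate(simkit.SimConfig(
            scenario=simkit.SCEN3, n_families=3, n_variants=60, n_genes=6,
            emit_true_ibd=False, seed=17))
        results = dmi.compound_het_scan(
            sim.pedigrees, sim.genotypes, sim.variants, sim.gene_map,
            dmi.CompoundHetConfig(min_rule_proportion=1.0))
        passing = {r.gene_id for r in results if r.passes}
        assert sim.truth.causal_gene in passing
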