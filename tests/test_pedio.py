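"""Pedigree data model, PED/MAP round trips, kinship and pair utilities."""

import numpy as np
import pytest

from pedpipe import pedio, simkit
from pedpipe.pedio import (HET, HOM_MAJOR, HOM_MINOR, MISSING,
                           ColumnCountError, DuplicateIndividualError,
                           IbdTableError, Individual, PedFileError, Pedigree,
                           UnknownParentError, bit_size)

from conftest import build_pedigree


TRIO_PED = """\
F1 1 0 0 1 1 A G A A
F1 2 0 0 2 1 G G A G
F1 3 1 2 1 2 A G 0 0
F1 4 1 2 2 1 G G A G
"""
TRIO_MAP = "1 v1 0.0 1000\n1 v2 0.0 2000\n"


def write_trio(tmp_path, ped_text=TRIO_PED, map_text=TRIO_MAP):
    ped = tmp_path / "t.ped"
    mp = tmp_path / "t.map"
    ped.write_text(ped_text)
    mp.write_text(map_text)
    return ped, mp


class TestReadPedMap:
    def test_parses_trio_with_sibling(self, tmp_path):
        peds, gm, variants = pedio.read_ped_map(*write_trio(tmp_path))
        assert len(peds) == 1 and len(peds[0]) == 4
        assert gm.codes.shape == (4, 2)
        assert list(variants["variant_id"]) == ["v1", "v2"]
        # v1: A appears 3x, G 5x -> A is provisional minor
        assert variants["allele_minor"].iloc[0] == "A"
        assert gm.genotype("F1", "1", "v1") == HET
        assert gm.genotype("F1", "1", "v2") == HOM_MINOR or \
            gm.genotype("F1", "1", "v2") == HOM_MAJOR

    def test_zero_alleles_are_missing(self, tmp_path):
        _, gm, _ = pedio.read_ped_map(*write_trio(tmp_path))
        assert gm.genotype("F1", "3", "v2") == MISSING

    def test_unknown_father_names_child_and_parent(self, tmp_path):
        bad = TRIO_PED.replace("F1 3 1 2", "F1 3 9 2")
        with pytest.raises(UnknownParentError, match=r"'9'.*'3'"):
            pedio.read_ped_map(*write_trio(tmp_path, bad))

    def test_column_count_error_reports_line(self, tmp_path):
        bad = TRIO_PED + "F1 5 0 0 1 1 A G\n"
        with pytest.raises(ColumnCountError, match="line 5"):
            pedio.read_ped_map(*write_trio(tmp_path, bad))

    def test_duplicate_individual_rejected(self, tmp_path):
        bad = TRIO_PED.replace("F1 4 1 2", "F1 3 1 2")
        with pytest.raises(DuplicateIndividualError):
            pedio.read_ped_map(*write_trio(tmp_path, bad))

    def test_half_specified_parent_rejected(self, tmp_path):
        bad = TRIO_PED.replace("F1 3 1 2", "F1 3 1 0")
        with pytest.raises(PedFileError, match="one parent"):
            pedio.read_ped_map(*write_trio(tmp_path, bad))


class TestWritePedMap:
    def test_round_trip_simulated_family(self, tmp_path):
        sim = simkit.simulate(simkit.SimConfig(
            seed=11, n_variants=30, emit_true_ibd=False))
        pedio.write_ped_map(sim.pedigrees, sim.genotypes, sim.variants,
                            tmp_path / "s.ped", tmp_path / "s.map")
        peds, gm, variants = pedio.read_ped_map(tmp_path / "s.ped",
                                                tmp_path / "s.map")
        assert [p.family_id for p in peds] == \
            [p.family_id for p in sim.pedigrees]
        assert gm.samples == sim.genotypes.samples
        # identical up to allele-label permutation (orientation flip)
        for vid in gm.variant_ids:
            a, b = gm.column(vid), sim.genotypes.column(vid)
            flipped = np.where(b >= 0, 2 - b, b)
            assert (a == b).all() or (a == flipped).all()

    def test_two_families_grouped_in_input_order(self, tmp_path):
        two = TRIO_PED + TRIO_PED.replace("F1", "F2")
        peds, gm, variants = pedio.read_ped_map(*write_trio(tmp_path, two))
        pedio.write_ped_map(peds, gm, variants, tmp_path / "o.ped",
                            tmp_path / "o.map")
        fams = [line.split()[0]
                for line in (tmp_path / "o.ped").read_text().splitlines()]
        assert fams == ["F1"] * 4 + ["F2"] * 4

    def test_empty_variant_set(self, tmp_path):
        ped_text = "".join(f"F1 {i} 0 0 1 1\n" for i in (1, 2))
        peds, gm, variants = pedio.read_ped_map(
            *write_trio(tmp_path, ped_text, ""))
        assert gm.codes.shape == (2, 0) and len(variants) == 0
        pedio.write_ped_map(peds, gm, variants, tmp_path / "e.ped",
                            tmp_path / "e.map")
        assert (tmp_path / "e.map").read_text() == ""
        assert all(len(line.split()) == 6 for line in
                   (tmp_path / "e.ped").read_text().splitlines())


class TestKinship:
    def test_closed_forms(self, three_generation_family):
        ped = three_generation_family
        assert ped.kinship("1", "3") == 0.25       # parent-offspring
        assert ped.kinship("3", "4") == 0.25       # full sibs
        assert ped.kinship("9", "11") == 0.0625    # first cousins
        assert ped.kinship("1", "2") == 0.0        # founders
        assert ped.kinship("6", "7") == 0.0        # married-in founders

    def test_symmetry(self, three_generation_family):
        ped = three_generation_family
        for a, b in [("1", "9"), ("3", "11"), ("8", "12")]:
            assert ped.kinship(a, b) == ped.kinship(b, a)

    def test_unknown_id_raises(self, nuclear_family):
        with pytest.raises(KeyError):
            nuclear_family.kinship("1", "99")

    def test_agrees_with_gene_dropping_monte_carlo(
            self, three_generation_family):
        """Independent oracle: drop one unlinked locus with unique founder
        alleles; kinship = P(one random allele from each is IBD)."""
        ped = three_generation_family
        rng = np.random.default_rng(7)
        order = [m.individual_id for m in ped.members]
        pairs = [("1", "9"), ("9", "11"), ("3", "12"), ("8", "10")]
        n_rep = 20000
        hits = {p: 0 for p in pairs}
        for _ in range(n_rep):
            alleles = {}
            counter = 0
            for iid in order:
                ind = ped[iid]
                if ind.is_founder:
                    alleles[iid] = (counter, counter + 1)
                    counter += 2
                else:
                    alleles[iid] = (
                        alleles[ind.father_id][rng.integers(2)],
                        alleles[ind.mother_id][rng.integers(2)])
            for a, b in pairs:
                hits[(a, b)] += (alleles[a][rng.integers(2)]
                                 == alleles[b][rng.integers(2)])
        for a, b in pairs:
            est = hits[(a, b)] / n_rep
            phi = ped.kinship(a, b)
            se = np.sqrt(max(phi * (1 - phi), 1e-6) / n_rep)
            assert abs(est - phi) < 3 * se + 1e-9

    def test_cycle_detection(self):
        with pytest.raises(PedFileError, match="cycle"):
            Pedigree("F1", [
                Individual("F1", "1", "2", "3"),
                Individual("F1", "2", "1", "3"),
                Individual("F1", "3", None, None, sex="female"),
            ])


class TestClassifyPair:
    def test_categories(self, three_generation_family):
        ped = three_generation_family
        assert ped.classify_pair("1", "3") == "parent_offspring"
        assert ped.classify_pair("8", "9") == "other_blood_relative"
        assert ped.classify_pair("6", "7") == "unrelated"
        assert ped.classify_pair("9", "11") == "other_blood_relative"

    def test_parent_offspring_implies_positive_kinship(
            self, three_generation_family):
        ped = three_generation_family
        ids = [m.individual_id for m in ped.members]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if ped.classify_pair(a, b) == "parent_offspring":
                    assert ped.kinship(a, b) > 0


class TestBitSize:
    def test_nuclear(self, nuclear_family):
        assert bit_size(nuclear_family) == 2

    def test_three_generation_12(self, three_generation_family):
        ped = three_generation_family
        assert len(ped.founders) == 4 and len(ped.nonfounders) == 8
        assert bit_size(ped) == 12

    def test_all_founders_is_negative(self):
        ped = build_pedigree("F1", [
            (str(i), None, None, "unknown", "unknown") for i in range(1, 4)])
        assert bit_size(ped) == -3

    def test_additive_over_disjoint_families(self, nuclear_family,
                                             three_generation_family):
        merged = Pedigree("M", [
            Individual("M", f"a{m.individual_id}",
                       f"a{m.father_id}" if m.father_id else None,
                       f"a{m.mother_id}" if m.mother_id else None,
                       m.sex, m.affection)
            for m in nuclear_family.members
        ] + [
            Individual("M", f"b{m.individual_id}",
                       f"b{m.father_id}" if m.father_id else None,
                       f"b{m.mother_id}" if m.mother_id else None,
                       m.sex, m.affection)
            for m in three_generation_family.members
        ])
        assert bit_size(merged) == (bit_size(nuclear_family)
                                    + bit_size(three_generation_family))


class TestIbdTable:
    def test_reads_record(self, tmp_path):
        path = tmp_path / "ibd.txt"
        path.write_text("F1 201 202 10.0 0.25 0.50 0.25\n")
        df = pedio.read_ibd_table(path)
        assert len(df) == 1
        rec = df.iloc[0]
        assert 1 - rec["p0"] == pytest.approx(0.75)

    def test_header_line_skipped(self, tmp_path):
        path = tmp_path / "ibd.txt"
        path.write_text("FAMILY ID1 ID2 POSITION P0 P1 P2\n"
                        "F1 201 202 10.0 0.25 0.50 0.25\n")
        assert len(pedio.read_ibd_table(path)) == 1

    def test_simplex_violation_reports_line(self, tmp_path):
        path = tmp_path / "ibd.txt"
        path.write_text("F1 201 202 10.0 0.25 0.50 0.25\n"
                        "F1 201 203 10.0 0.30 0.30 0.30\n")
        with pytest.raises(IbdTableError, match="line 2"):
            pedio.read_ibd_table(path)

    def test_simulator_true_ibd_round_trips(self, tmp_path):
        sim = simkit.simulate(simkit.SimConfig(
            pedigree_template="nuclear", seed=3, n_variants=5,
            region_length_cm=10.0))
        path = tmp_path / "ibd.txt"
        pedio.write_ibd_table(sim.true_ibd, path)
        back = pedio.read_ibd_table(path)
        assert len(back) == len(sim.true_ibd)
        assert np.allclose(back[["p0", "p1", "p2"]].to_numpy(),
                           sim.true_ibd[["p0", "p1", "p2"]].to_numpy())
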