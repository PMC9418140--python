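import re

import pytest
from hypothesis import given, settings, strategies as st

from icenuc.assay_io import ValidationError
from icenuc.construct_ops import (
    CODON_TABLE,
    Coil,
    ConstructSpec,
    Insert,
    apply_motif_mutations,
    backtranslate,
    build_construct,
    count_coil_classes,
    excise_between_paired_sites,
    insert_block,
    translate,
    uninterrupted_runs,
    verify_site_pairs,
)
from icenuc.repeat_analysis import CONSENSUS, CoilClass
from icenuc.simulator import RCOIL_TEMPLATE, generate_repeat_gene


def sixty_five_repeat_construct():
    """54 water-organizing coils followed by 11 R-coils, with flanks."""
    return build_construct(
        [CONSENSUS] * 54 + [RCOIL_TEMPLATE] * 11,
        flank5_protein="MKW" * 4,
        flank3_protein="WQD" * 4,
    )


@pytest.fixture
def construct65():
    return sixty_five_repeat_construct()


class TestExcision:
    def test_sac_style_excision_leaves_18(self, construct65):
        out = excise_between_paired_sites(construct65, 10, 57, phase=4)
        assert out.n_repeats == 18

    def test_identity_when_i_equals_j(self, construct65):
        out = excise_between_paired_sites(construct65, 10, 10, phase=4)
        assert out == construct65
        assert out.n_repeats == 65

    def test_adjacent_excision(self, construct65):
        out = excise_between_paired_sites(construct65, 1, 2, phase=4)
        assert out.n_repeats == 64

    def test_chimera_sequence_joins_phase_points(self, construct65):
        out = excise_between_paired_sites(construct65, 10, 57, phase=4)
        chimera = out.coils[9].protein
        assert chimera == CONSENSUS[:4] + RCOIL_TEMPLATE[4:]

    def test_class_accounting_after_excision(self, construct65):
        out = excise_between_paired_sites(construct65, 10, 57, phase=4)
        assert count_coil_classes(out) == (10, 8, 0)

    def test_repeat_region_stays_48_periodic(self, construct65):
        out = excise_between_paired_sites(construct65, 10, 57, phase=4)
        start, end = out.repeat_region
        assert (end - start) % 48 == 0

    def test_out_of_range_rejected(self, construct65):
        with pytest.raises(ValidationError):
            excise_between_paired_sites(construct65, 10, 66, phase=4)
        with pytest.raises(ValidationError):
            excise_between_paired_sites(construct65, 0, 5, phase=4)
        with pytest.raises(ValidationError):
            excise_between_paired_sites(construct65, 5, 10, phase=17)

    @given(
        i=st.integers(1, 65),
        j=st.integers(1, 65),
        phase=st.integers(1, 16),
    )
    @settings(max_examples=40)
    def test_conservation_and_frame(self, i, j, phase):
        c = sixty_five_repeat_construct()
        if i > j:
            i, j = j, i
        out = excise_between_paired_sites(c, i, j, phase)
        assert out.n_repeats + (j - i) == 65
        assert (len(c.dna) - len(out.dna)) % 3 == 0
        assert len(c.dna) - len(out.dna) == (j - i) * 48


class TestInsertBlock:
    def test_split_9_and_37(self, construct65):
        _, sections, longest = insert_block(construct65, 10, 19)
        assert sections == [9, 37]
        assert longest == 37

    def test_split_21_and_25(self, construct65):
        _, sections, longest = insert_block(construct65, 22, 19)
        assert sections == [21, 25]
        assert longest == 25

    def test_block_at_end_single_section(self, construct65):
        _, sections, longest = insert_block(construct65, 47, 19)
        assert sections == [46]
        assert longest == 46

    def test_out_of_range_rejected(self, construct65):
        with pytest.raises(ValidationError):
            insert_block(construct65, 48, 19)

    def test_frame_preserved(self, construct65):
        out, _, _ = insert_block(construct65, 10, 19, insert_dna="ATGGCTAAA")
        assert (len(out.dna) - len(construct65.dna)) % 3 == 0

    def test_interruptions_recorded(self, construct65):
        out, _, _ = insert_block(construct65, 10, 19, "bulky")
        assert len(out.interruptions) == 1
        assert isinstance(out.elements[9], Insert)

    @given(start=st.integers(1, 60), n=st.integers(1, 20))
    @settings(max_examples=30)
    def test_section_sum_conservation(self, start, n):
        c = sixty_five_repeat_construct()
        if start + n - 1 > 65:
            n = 65 - start + 1
        _, sections, _ = insert_block(c, start, n)
        assert sum(sections) + n == 65


class TestMotifMutations:
    def test_zones_18_and_24(self, construct65):
        # Mutating 23 repeats leaving 18 intact on the N-terminal side.
        out, runs = apply_motif_mutations(
            construct65, (19, 41), "TxT", {6: "S", 8: ["K", "Y"]}
        )
        assert runs == [18, 24]

    def test_empty_substitutions_noop(self, construct65):
        out, runs = apply_motif_mutations(construct65, (19, 41), "TxT", {})
        assert out == construct65
        assert runs == [65]

    def test_mutating_all_repeats_leaves_no_run(self, construct65):
        _, runs = apply_motif_mutations(construct65, (1, 65), "TxT", {6: "S"})
        assert runs == []

    def test_substitution_outside_motif_rejected(self, construct65):
        with pytest.raises(ValidationError, match="outside TxT"):
            apply_motif_mutations(construct65, (19, 41), "TxT", {3: "D"})

    def test_mutations_change_protein(self, construct65):
        out, _ = apply_motif_mutations(
            construct65, (19, 19), "YGS", {3: "D"}
        )
        coil = out.coils[18]
        assert coil.protein[2] == "D"
        assert coil.mutated

    def test_residue_cycling_across_coils(self, construct65):
        out, _ = apply_motif_mutations(
            construct65, (19, 22), "TxT", {6: ["S", "K"]}
        )
        residues = [out.coils[i].protein[5] for i in range(18, 22)]
        assert residues == ["S", "K", "S", "K"]

    def test_frame_preserved(self, construct65):
        out, _ = apply_motif_mutations(construct65, (19, 41), "SLT", {16: "S"})
        assert len(out.dna) == len(construct65.dna)


class TestSitePairs:
    def test_engineered_pair_480_bp_apart(self):
        c, _ = generate_repeat_gene(
            20, 0, site_plan=[("SacI", "GAGCTC", 5, 15, 11)], seed=1
        )
        report = verify_site_pairs(c, [("SacI", "GAGCTC")])["SacI"]
        assert report.is_unique_pair
        assert report.spacing == 480
        assert report.spacing_mod48 == 0
        assert report.in_frame

    def test_triple_occurrence_not_unique(self):
        coil = Coil(backtranslate(CONSENSUS), CoilClass.WATER_ORGANIZING)
        filler = Insert("GAATTC" * 3, "sites")
        c = ConstructSpec("", (coil, filler), "")
        report = verify_site_pairs(c, [("EcoRI", "GAATTC")])["EcoRI"]
        assert len(report.positions) == 3
        assert not report.is_unique_pair
        assert report.spacing is None

    def test_reverse_complement_counted_for_nonpalindromic(self):
        # BsaI-like GGTCTC: one forward site and one on the other strand.
        dna = "GGTCTC" + "AAA" * 10 + "GAGACC"  # revcomp(GGTCTC) = GAGACC
        c = ConstructSpec("", (Insert(dna, "x"),), "")
        report = verify_site_pairs(c, [("BsaI", "GGTCTC")])["BsaI"]
        assert report.is_unique_pair
        assert report.positions == (0, 36)

    def test_iupac_ambiguity_expansion(self):
        dna = "GACGTC" + "AAA" * 4 + "GTCGAC"
        c = ConstructSpec("", (Insert(dna, "x"),), "")
        # GDCGWC matches both GACGTC and GTCGAC.
        report = verify_site_pairs(c, [("amb", "GDCGWC")])["amb"]
        assert len(report.positions) >= 2

    @given(dna=st.text(alphabet="ACGT", min_size=30, max_size=120))
    @settings(max_examples=40)
    def test_brute_force_scan_oracle(self, dna):
        dna = dna[: len(dna) - len(dna) % 3]
        if not dna:
            return
        c = ConstructSpec("", (Insert(dna, "x"),), "")
        recognition = "GAATTC"  # palindromic: forward scan only
        report = verify_site_pairs(c, [("EcoRI", recognition)])["EcoRI"]
        expected = [
            i for i in range(len(dna) - 5) if dna[i:i + 6] == recognition
        ]
        assert list(report.positions) == expected


class TestConstructPlumbing:
    def test_backtranslate_translate_inverse(self):
        assert translate(backtranslate(CONSENSUS)) == CONSENSUS

    def test_json_round_trip(self, construct65):
        text = construct65.to_json()
        back = ConstructSpec.from_json(text)
        assert back == construct65

    def test_json_file_round_trip(self, tmp_path, construct65):
        p = tmp_path / "c.json"
        construct65.to_json(p)
        assert ConstructSpec.from_json(p) == construct65

    def test_count_classes_full_length(self, construct65):
        assert count_coil_classes(construct65) == (54, 11, 0)

    def test_count_classes_empty(self):
        c = ConstructSpec("", (), "")
        assert count_coil_classes(c) == (0, 0, 0)

    def test_repeat_region_divisible_by_48(self, construct65):
        start, end = construct65.repeat_region
        assert (end - start) % 48 == 0
        assert construct65.n_repeats == 65

    def test_runs_partition_unmutated_coils(self, construct65):
        out, _, _ = insert_block(construct65, 10, 19)
        runs = uninterrupted_runs(out)
        assert sum(runs) == out.n_repeats
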