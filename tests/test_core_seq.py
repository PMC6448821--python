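"""Alignment, identity-track and codon primitives against brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from maltpipe.core_seq import (
    AnalysisError,
    GeneSequence,
    InputError,
    PairwiseAlignment,
    SubstitutionClass,
    classify_codon_change,
    codon_align,
    global_align,
    percent_identity,
    sliding_identity,
    translate_cds,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def test_identical_sequences_align_without_gaps():
    aln = global_align(GeneSequence("a", "ACGT"), GeneSequence("b", "ACGT"))
    assert aln.aln_a == aln.aln_b == "ACGT"
    assert aln.score == 4.0


def test_deletion_costs_one_gap_under_default_scoring():
    aln = global_align(GeneSequence("a", "ACGT"), GeneSequence("b", "AGT"))
    assert aln.aln_b.count("-") == 1 and "-" not in aln.aln_a
    assert aln.score == 3 * 1 + 1 * (-2)


def test_empty_sequence_rejected():
    with pytest.raises(InputError):
        GeneSequence("a", "")


@pytest.mark.parametrize("pair_seed", range(10))
def test_alignment_score_matches_dp_oracle(pair_seed, rng):
    local = np.random.default_rng(1000 + pair_seed)
    a = "".join(local.choice(list("ACGT"), size=50))
    b = "".join(local.choice(list("ACGT"), size=50))
    aln = global_align(GeneSequence("a", a), GeneSequence("b", b))
    assert aln.score == oracles.nw_score(a, b)


@given(a=dna, b=dna)
def test_alignment_round_trip_reproduces_inputs(a, b):
    aln = global_align(GeneSequence("a", a), GeneSequence("b", b))
    assert aln.ungapped("a") == a and aln.ungapped("b") == b
    assert not any(
        x == "-" and y == "-" for x, y in zip(aln.aln_a, aln.aln_b)
    )


def test_percent_identity_simple_counts():
    aln = global_align(GeneSequence("x", "ACGT"), GeneSequence("y", "ACGA"))
    assert percent_identity(aln) == 75.0
    same = global_align(GeneSequence("x", "ACGT"), GeneSequence("y", "ACGT"))
    assert percent_identity(same) == 100.0


def test_percent_identity_matches_column_count_oracle(small_family):
    genes, _ = small_family
    aln = global_align(genes[0], genes[1])
    assert percent_identity(aln) == pytest.approx(
        oracles.column_identity(aln.aln_a, aln.aln_b)
    )


def test_percent_identity_symmetric_in_rows():
    aln = global_align(GeneSequence("x", "ACGTACG"), GeneSequence("y", "ACTTACG"))
    swapped = PairwiseAlignment(
        id_a=aln.id_b, id_b=aln.id_a, aln_a=aln.aln_b, aln_b=aln.aln_a,
        score=aln.score,
    )
    assert percent_identity(aln) == percent_identity(swapped)


def test_percent_identity_undefined_without_comparable_columns():
    aln = PairwiseAlignment("a", "b", "AA--", "--TT", 0.0)
    with pytest.raises(AnalysisError):
        percent_identity(aln)


def test_amino_acid_identity_of_synonymous_variants_is_total():
    # GAA->GAG is silent, so aa identity is 100 while nt identity is not
    a = GeneSequence("a", "ATGGAAGAA", is_cds=True)
    b = GeneSequence("b", "ATGGAGGAA", is_cds=True)
    aln = global_align(a, b)
    assert percent_identity(aln, level="nt") < 100.0
    assert percent_identity(aln, level="aa") == 100.0


def test_sliding_identity_on_self_is_flat_100(small_family):
    genes, _ = small_family
    aln = global_align(genes[0], genes[0])
    track = sliding_identity(aln, window=10)
    assert set(track.values) == {100.0}


def test_sliding_identity_forced_two_window_example():
    a = "A" * 20
    b = list(a)
    b[4] = b[14] = "T"  # mismatches at columns 5 and 15 (1-based)
    aln = PairwiseAlignment("a", "b", a, "".join(b), 0.0)
    track = sliding_identity(aln, window=10, step=10)
    assert list(track.values) == [90.0, 90.0]


def test_sliding_identity_full_window_equals_global_identity_gapless():
    aln = global_align(GeneSequence("a", "ACGTACGT"), GeneSequence("b", "ACTTACGA"))
    track = sliding_identity(aln, window=aln.length)
    assert len(track.values) == 1
    assert track.values[0] == pytest.approx(percent_identity(aln))


def test_sliding_identity_counts_gap_columns_as_mismatches():
    aln = PairwiseAlignment("a", "b", "ACGTACGTAC", "ACGT-CGTAC", 0.0)
    track = sliding_identity(aln, window=10)
    assert track.values[0] == 90.0


def test_sliding_identity_masks_n_rich_windows():
    aln = PairwiseAlignment("a", "b", "NNNNNNACGT", "NNNNNNACGT", 0.0)
    track = sliding_identity(aln, window=10)
    assert track.values == ()  # 6/10 N columns -> masked


def test_sliding_identity_rejects_oversized_window():
    aln = global_align(GeneSequence("a", "ACGT"), GeneSequence("b", "ACGT"))
    with pytest.raises(InputError):
        sliding_identity(aln, window=5)


@pytest.mark.parametrize(
    "seq,protein,terminal",
    [("ATGGAA", "ME", False), ("ATGTAA", "M", True), ("ATGNNA", "MX", False)],
)
def test_translate_cds(seq, protein, terminal):
    t = translate_cds(GeneSequence("x", seq, is_cds=True))
    assert t.protein == protein and t.terminal_stop is terminal


def test_translate_flags_internal_stop_with_warning():
    with pytest.warns(UserWarning, match="internal stop"):
        t = translate_cds(GeneSequence("x", "ATGTAAGAA"))
    assert t.internal_stop_positions == (1,) and not t.clean


def test_translate_rejects_frameshifted_length():
    with pytest.raises(InputError):
        translate_cds(GeneSequence("x", "ATGGA"))


def test_codon_align_expands_gaps_to_whole_codons():
    aln = codon_align(
        {"x": "M-E", "y": "MKE"},
        {
            "x": GeneSequence("x", "ATGGAA", is_cds=True),
            "y": GeneSequence("y", "ATGAAAGAA", is_cds=True),
        },
    )
    assert aln.rows["x"] == "ATG---GAA"
    assert aln.rows["y"] == "ATGAAAGAA"


def test_codon_align_round_trips_on_simulated_family(small_family):
    genes, _ = small_family
    proteins = {g.id: translate_cds(g).protein for g in genes}
    # gapless protein "alignment" (equal lengths by construction)
    aln = codon_align(proteins, {g.id: g for g in genes})
    for g in genes:
        assert aln.ungapped(g.id) == g.seq
        back = translate_cds(GeneSequence(g.id, aln.ungapped(g.id), is_cds=True))
        assert back.protein == proteins[g.id]


def test_codon_align_names_offending_position_on_mismatch():
    with pytest.raises(InputError, match="residue 2"):
        codon_align(
            {"x": "MK"}, {"x": GeneSequence("x", "ATGGAA", is_cds=True)}
        )


@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("GAA", "GAG", SubstitutionClass.SYNONYMOUS),
        ("GAA", "GTA", SubstitutionClass.NONSYNONYMOUS),
        ("GAA", "GAA", SubstitutionClass.NONE),
        ("GAA", "CTG", SubstitutionClass.MULTI_HIT),
        ("GAA", "TAA", SubstitutionClass.STOP_INVOLVED),
        ("TGA", "TGG", SubstitutionClass.STOP_INVOLVED),
    ],
)
def test_classify_codon_change_examples(ref, alt, expected):
    assert classify_codon_change(ref, alt) == expected


def test_classify_codon_change_matches_exhaustive_oracle():
    """Every single-position sense-codon pair agrees with translate-and-compare."""
    checked = 0
    for ref, alt in itertools.product(oracles.SENSE, repeat=2):
        if sum(r != a for r, a in zip(ref, alt)) != 1:
            continue
        assert classify_codon_change(ref, alt).value == oracles.classify_codon_pair(
            ref, alt
        ), (ref, alt)
        checked += 1
    assert checked > 500
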