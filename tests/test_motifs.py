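"""Motif canonicalization and composition profiling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trlandscape.motifs import (
    MotifError,
    canonical_motif,
    is_primitive,
    motif_profile_tables,
    pair_class,
    primitive_unit,
    reverse_complement,
    unique_nucleotides,
    validate_motif,
)

motif_strategy = st.text(alphabet="ACGT", min_size=3, max_size=8)


@pytest.mark.parametrize(
    "literature, canonical",
    [
        ("GGGGCC", "CCCCGG"),  # ALS hexanucleotide
        ("CAG", "AGC"),        # HD / polyglutamine
        ("GAA", "AAG"),        # FRDA
        ("CGG", "CCG"),        # FRAXA
        ("CTG", "AGC"),        # FECD / DM1-type
        ("AAGGG", "AAGGG"),    # CANVAS disease motif
        ("CCTG", "AGGC"),      # DM2
        ("TGGAA", "AATGG"),    # SCA31 insertion
    ],
)
def test_canonical_motif_matches_disease_literature_forms(literature, canonical):
    assert canonical_motif(literature) == canonical


@settings(max_examples=300, derandomize=True)
@given(motif=motif_strategy, rotation=st.integers(0, 7))
def test_canonical_motif_invariant_under_rotation_and_strand(motif, rotation):
    rotation %= len(motif)
    rotated = motif[rotation:] + motif[:rotation]
    assert canonical_motif(rotated) == canonical_motif(motif)
    assert canonical_motif(reverse_complement(motif)) == canonical_motif(motif)
    # idempotent, and the canonical form is itself a rotation of motif or its
    # reverse complement
    assert canonical_motif(canonical_motif(motif)) == canonical_motif(motif)
    doubled = motif + motif
    rc = reverse_complement(motif)
    assert canonical_motif(motif) in doubled or canonical_motif(motif) in rc + rc


def test_invalid_alphabet_rejected():
    with pytest.raises(MotifError):
        canonical_motif("ATN")
    with pytest.raises(MotifError):
        canonical_motif("")


@pytest.mark.parametrize(
    "motif, primitive, unit",
    [
        ("ATAT", False, "AT"),
        ("ACACAC", False, "AC"),
        ("AAG", True, "AAG"),
        ("AGCAGC", False, "AGC"),
        ("AAAA", False, "A"),
        ("AAGAAC", True, "AAGAAC"),
    ],
)
def test_primitivity(motif, primitive, unit):
    assert is_primitive(motif) is primitive
    assert primitive_unit(motif) == unit
    if not primitive:
        with pytest.raises(MotifError):
            validate_motif(motif)


def test_validate_motif_length_window():
    with pytest.raises(MotifError):
        validate_motif("AT")  # primitive but too short
    with pytest.raises(MotifError):
        validate_motif("AAGAAGACT")  # 9 bp
    assert validate_motif("gaa") == "GAA"


@pytest.mark.parametrize(
    "motif, n_unique, pair",
    [
        ("AAG", 2, ("A", "G")),
        ("AAGGG", 2, ("A", "G")),
        ("AGC", 3, None),
        ("CCG", 2, ("C", "G")),
        ("CTT", 2, ("A", "G")),   # canonicalizes to AAG: strand collapsed
        ("GTT", 2, ("A", "C")),   # canonicalizes to AAC
        ("ACGT", 4, None),
    ],
)
def test_unique_nucleotides_and_pair_class(motif, n_unique, pair):
    assert unique_nucleotides(motif) == n_unique
    assert pair_class(motif) == pair


@settings(max_examples=200, derandomize=True)
@given(motif=motif_strategy)
def test_pair_class_strand_invariant(motif):
    assert pair_class(motif) == pair_class(reverse_complement(motif))


def test_pair_class_without_strand_collapse_keeps_raw_pair():
    assert pair_class("CTT", collapse_strand=False) == ("C", "T")
    assert pair_class("CTT", collapse_strand=True) == ("A", "G")


def test_motif_profile_tables_frequencies_sum_to_one(bundle):
    motifs = [l.motif for l in bundle.matrix.loci]
    tables = motif_profile_tables({"dataset": motifs, "empty": []})
    for frame in tables.values():
        assert frame["dataset"].sum() == pytest.approx(1.0, abs=1e-12)
        assert frame["empty"].sum() == 0.0
        assert frame.attrs["empty_categories"] == ["empty"]


def test_motif_profile_tables_single_motif_spectrum():
    tables = motif_profile_tables({"x": ["AAAG"] * 10})
    assert tables["motif_length"].loc[4, "x"] == pytest.approx(1.0)
    assert tables["unique_nucleotides"].loc[2, "x"] == pytest.approx(1.0)
    assert tables["pair_class"].loc["A&G", "x"] == pytest.approx(1.0)
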