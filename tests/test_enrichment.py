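"""Region assignment, Alu overlap flags, and the adjusted Fisher test."""

import numpy as np
import pytest

from oracles import fisher_two_sided_exact
from trlandscape.core import AnnotationTrack, TRLocus, ValidationError
from trlandscape.enrichment import (
    assign_region,
    build_fisher_table,
    enrich_category,
    fisher_exact,
    flag_alu_overlap,
)

REGIONS = AnnotationTrack(
    name="regions",
    intervals=[
        ("1", 0, 1000, "promoter"),
        ("1", 900, 2000, "exon"),
        ("1", 2000, 5000, "intron"),
    ],
)


def _locus(start, end, contig="1", motif="AAG"):
    return TRLocus(contig=contig, start=start, end=end, motif=motif)


def test_region_assignment_inside_single_label():
    assert assign_region(_locus(2500, 2600), REGIONS) == "intron"


def test_region_assignment_priority_promoter_over_exon():
    # overlaps both promoter and exon; promoter has precedence
    assert assign_region(_locus(950, 1100), REGIONS) == "promoter"


def test_region_assignment_complement_is_intergenic():
    assert assign_region(_locus(8000, 8100), REGIONS) == "intergenic"
    assert assign_region(_locus(0, 50, contig="2"), REGIONS) == "intergenic"


def test_region_assignment_rejects_contig_outside_layout():
    from trlandscape.core import GenomeLayout

    layout = GenomeLayout({"1": 10_000})
    with pytest.raises(ValidationError):
        assign_region(_locus(0, 50, contig="7"), REGIONS, layout=layout)


ALU = AnnotationTrack(name="Alu", intervals=[("1", 299, 600, "Alu"), ("1", 300, 600, "Alu")])


def test_alu_overlap_single_base_counts():
    track = AnnotationTrack(name="Alu", intervals=[("1", 299, 600, "Alu")])
    assert flag_alu_overlap(_locus(100, 300), track) is True


def test_alu_overlap_half_open_adjacency_does_not_count():
    track = AnnotationTrack(name="Alu", intervals=[("1", 300, 600, "Alu")])
    assert flag_alu_overlap(_locus(100, 300), track) is False


def test_alu_overlap_empty_track_is_false():
    assert flag_alu_overlap(_locus(0, 100), AnnotationTrack(name="Alu", intervals=[])) is False


# Frozen reference values from bedtools fisher 2.31.1 on the same toy BEDs
# (genome sizes 10,000 / 4,000 / 10,000 bp respectively).
TOY_A = [("chr1", 100, 200), ("chr1", 1000, 1100), ("chr1", 5000, 5100)]
TOY_B = [("chr1", 150, 300), ("chr1", 1050, 1200), ("chr1", 3000, 3150), ("chr1", 7000, 7150)]
DEGEN_A = [("chr1", s, s + 400) for s in (0, 500, 1000, 1500, 2000)]
DEGEN_B = [("chr1", s, s + 400) for s in (100, 600, 1100, 2500, 3000)]
MULTI_A = [("chr1", 100, 500)]
MULTI_B = [("chr1", 120, 180), ("chr1", 300, 360), ("chr1", 700, 760)]


def test_fisher_table_matches_bedtools_construction():
    table = build_fisher_table(TOY_A, TOY_B, genome_size=10_000)
    assert table.cells == (2, 1, 2, 34)
    assert table.n_trials == 39
    assert table.defined


def test_fisher_table_degenerate_case_is_undefined():
    table = build_fisher_table(DEGEN_A, DEGEN_B, genome_size=4_000)
    assert not table.defined
    assert fisher_exact(table) == (None, None)


def test_fisher_table_counts_overlap_pairs():
    table = build_fisher_table(MULTI_A, MULTI_B, genome_size=10_000)
    assert table.n11 == 2  # one query hitting two db intervals counts twice
    assert table.n_trials == 21


def test_fisher_table_disjoint_sets_have_no_overlaps():
    table = build_fisher_table(
        [("1", 0, 100)], [("1", 500, 600)], genome_size=10_000
    )
    assert table.n11 == 0


def test_fisher_table_invariant_to_order_and_contig_renaming():
    table = build_fisher_table(TOY_A, TOY_B, genome_size=10_000)
    renamed = lambda ivs: [("ctgX" if c == "chr1" else c, s, e) for c, s, e in ivs]
    shuffled = build_fisher_table(TOY_A[::-1], renamed(TOY_B)[::-1], genome_size=10_000)
    # renaming b's contig removes overlaps entirely; rename both consistently
    consistent = build_fisher_table(
        renamed(TOY_A)[::-1], renamed(TOY_B)[::-1], genome_size=10_000
    )
    assert consistent.cells == table.cells
    assert shuffled.n11 == 0


def test_fisher_table_monotone_under_non_overlapping_b_growth():
    base = build_fisher_table(TOY_A, TOY_B, genome_size=100_000)
    grown = build_fisher_table(
        TOY_A, TOY_B + [("chr1", 9000, 9150)], genome_size=100_000
    )
    assert grown.n11 == base.n11


def test_fisher_table_rejects_empty_sets_and_bad_genome():
    with pytest.raises(ValidationError):
        build_fisher_table([], TOY_B, genome_size=1000)
    with pytest.raises(ValidationError):
        build_fisher_table(TOY_A, TOY_B, genome_size=0)


@pytest.mark.parametrize(
    "table, odds, p",
    [
        ([[3, 1], [1, 3]], 9.0, 34 / 70),
        ([[2, 2], [2, 2]], 1.0, 1.0),
        ([[0, 5], [5, 0]], 0.0, None),
    ],
)
def test_fisher_exact_known_tables(table, odds, p):
    got_odds, got_p = fisher_exact(table)
    assert got_odds == pytest.approx(odds)
    if p is not None:
        assert got_p == pytest.approx(p, rel=1e-9)


def test_fisher_exact_infinite_odds_ratio():
    odds, p = fisher_exact([[3, 0], [0, 3]])
    assert odds == np.inf and 0 < p <= 1


def test_fisher_exact_agrees_with_enumeration_on_small_tables():
    """Spot check against the exact-rational enumerator (the exhaustive sweep
    lives in the acceptance suite)."""
    rng = np.random.default_rng(4)
    for _ in range(60):
        cells = rng.integers(0, 13, size=4)
        _, p = fisher_exact([[cells[0], cells[1]], [cells[2], cells[3]]])
        expected = float(fisher_two_sided_exact(*cells))
        assert p == pytest.approx(expected, rel=1e-8, abs=1e-12)


def test_enrich_category_rejects_empty_category():
    loci = [_locus(0, 100)]
    with pytest.raises(ValidationError):
        enrich_category(loci, np.array([False]), ALU, genome_size=10_000, category="x")


def test_enrich_category_deduplicates_loci():
    locus = _locus(200, 320)
    result = enrich_category(
        [locus, locus], None, AnnotationTrack(name="Alu", intervals=[("1", 300, 600, "Alu")]),
        genome_size=100_000, category="Alu",
    )
    assert result.table.n_a == 1
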