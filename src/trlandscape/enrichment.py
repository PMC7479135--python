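"""Genomic-region assignment and interval-overlap enrichment.

Region labels are assigned by priority (promoter > TTS > exon > intron >
intergenic, the precedence used by standard annotators): the first label
with at least 1 bp of overlap wins, and loci overlapping nothing fall to
intergenic as the genomic complement.

Enrichment of one interval set in another is tested with a genomic-space-
adjusted Fisher's exact test in the construction used by ``bedtools
fisher``: the genome is modeled as ``floor(genome_size / (mean_len_a +
mean_len_b))`` placement trials, of which ``n11`` produced an overlap.  When
overlaps exceed the trial budget a cell goes negative and the table (hence
the odds ratio) is undefined — a degenerate case that genuinely occurs for
dense tracks.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import AnnotationTrack, GenomeLayout, TRLocus, ValidationError

__all__ = [
    "REGION_PRIORITY",
    "ContingencyTable2x2",
    "EnrichmentResult",
    "assign_region",
    "assign_regions",
    "flag_alu_overlap",
    "flag_alu_overlaps",
    "build_fisher_table",
    "fisher_exact",
    "enrich_category",
]

#: Label precedence for region assignment; "intergenic" is the complement.
REGION_PRIORITY = ("promoter", "TTS", "exon", "intron", "intergenic")


def _as_intervals(obj) -> list[tuple[str, int, int]]:
    if isinstance(obj, AnnotationTrack):
        return [(c, s, e) for c, s, e, _ in obj.intervals]
    out = []
    for item in obj:
        if isinstance(item, TRLocus):
            out.append((item.contig, item.start, item.end))
        else:
            contig, start, end = item[0], int(item[1]), int(item[2])
            out.append((str(contig), start, end))
    return out


def _overlap_pairs(
    a: Sequence[tuple[str, int, int]], b: Sequence[tuple[str, int, int]]
) -> int:
    """Number of intersecting (a, b) interval pairs (half-open, >= 1 bp).

    Per contig, with b's starts and ends each sorted, the pairs hitting one
    a-interval are #{b.start < a.end} - #{b.end <= a.start}.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in b:
        by_contig.setdefault(contig, []).append((start, end))
    index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig, items in by_contig.items():
        starts = np.sort(np.array([s for s, _ in items]))
        ends = np.sort(np.array([e for _, e in items]))
        index[contig] = (starts, ends)
    pairs = 0
    for contig, start, end in a:
        if contig not in index:
            continue
        starts, ends = index[contig]
        pairs += int(np.searchsorted(starts, end, side="left"))
        pairs -= int(np.searchsorted(ends, start, side="right"))
    return pairs


def assign_region(
    locus: TRLocus,
    region_track: AnnotationTrack,
    priority: Sequence[str] = REGION_PRIORITY,
    layout: GenomeLayout | None = None,
) -> str:
    """Single region label for a locus, by priority of >=1 bp overlaps."""
    if layout is not None and locus.contig not in layout:
        raise ValidationError(f"locus contig {locus.contig!r} not in layout")
    hits = {label for *_, label in region_track.overlaps(locus.contig, locus.start, locus.end)}
    for label in priority:
        if label in hits:
            return label
    return priority[-1]


def assign_regions(
    loci: Sequence[TRLocus],
    region_track: AnnotationTrack,
    priority: Sequence[str] = REGION_PRIORITY,
    layout: GenomeLayout | None = None,
) -> np.ndarray:
    return np.array(
        [assign_region(l, region_track, priority, layout) for l in loci], dtype=object
    )


def flag_alu_overlap(locus: TRLocus, alu_track: AnnotationTrack) -> bool:
    """True iff the locus interval intersects any Alu interval by >= 1 bp."""
    return bool(alu_track.overlaps(locus.contig, locus.start, locus.end))


def flag_alu_overlaps(
    loci: Sequence[TRLocus], alu_track: AnnotationTrack
) -> np.ndarray:
    return np.array([flag_alu_overlap(l, alu_track) for l in loci], dtype=bool)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Genomic-space-adjusted 2x2 overlap table (bedtools-fisher construction).

    ``n11`` = number of intersecting (A, B) interval pairs;
    ``n12 = |A| - n11``; ``n21 = |B| - n11``;
    ``n22 = n_trials - |A| - |B| + n11`` where
    ``n_trials = floor(genome_size / (mean_len_a + mean_len_b))`` and the
    mean lengths are inclusive (``end - start + 1``) interval sizes.
    The table is *undefined* when any cell is negative — overlaps exceeding
    the interval counts or the genomic trial budget, as happens for dense
    tracks (e.g. reference repeats against intergenic space).
    """

    n11: int
    n12: int
    n21: int
    n22: int
    n_trials: int
    n_a: int
    n_b: int
    mean_len_a: float
    mean_len_b: float
    genome_size: int

    @property
    def defined(self) -> bool:
        return min(self.n11, self.n12, self.n21, self.n22) >= 0

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n12, self.n21, self.n22)


def build_fisher_table(set_a, set_b, genome_size: int) -> ContingencyTable2x2:
    """Build the genomic-space-adjusted overlap table for two interval sets.

    Invariant to interval order and contig naming; both sets must be
    non-empty and ``genome_size`` positive.
    """
    a = _as_intervals(set_a)
    b = _as_intervals(set_b)
    if not a or not b:
        raise ValidationError("both interval sets must be non-empty")
    if genome_size <= 0:
        raise ValidationError("genome size must be positive")
    mean_a = float(np.mean([e - s + 1 for _, s, e in a]))
    mean_b = float(np.mean([e - s + 1 for _, s, e in b]))
    n_trials = math.floor(genome_size / (mean_a + mean_b))
    n11 = _overlap_pairs(a, b)
    return ContingencyTable2x2(
        n11=n11,
        n12=len(a) - n11,
        n21=len(b) - n11,
        n22=n_trials - len(a) - len(b) + n11,
        n_trials=n_trials,
        n_a=len(a),
        n_b=len(b),
        mean_len_a=mean_a,
        mean_len_b=mean_b,
        genome_size=int(genome_size),
    )


def fisher_exact(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
) -> tuple[float | None, float | None]:
    """Sample odds ratio and two-sided Fisher's exact p for a 2x2 table.

    The odds ratio is the unconditional sample estimate
    ``(n11 * n22) / (n12 * n21)`` (the convention of ``bedtools fisher``):
    infinity when the denominator is 0 with a positive numerator, ``nan``
    for 0/0.  The two-sided p sums the hypergeometric probabilities of all
    tables with the observed margins that are no more probable than the
    observed one.  For an undefined (negative-cell) table, returns
    ``(None, None)``.
    """
    if isinstance(table, ContingencyTable2x2):
        if not table.defined:
            return None, None
        n11, n12, n21, n22 = table.cells
    else:
        (n11, n12), (n21, n22) = table
        if min(n11, n12, n21, n22) < 0:
            return None, None
    num = n11 * n22
    den = n12 * n21
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = math.inf
    else:
        odds = math.nan
    p = float(stats.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")[1])
    return odds, p


@dataclass
class EnrichmentResult:
    """Overlap enrichment of a locus category against a reference track."""

    category: str
    odds_ratio: float | None
    p_two_sided: float | None
    table: ContingencyTable2x2

    @property
    def defined(self) -> bool:
        return self.table.defined


def enrich_category(
    loci: Sequence[TRLocus],
    mask: np.ndarray | None,
    reference_track: AnnotationTrack,
    genome_size: int,
    category: str = "",
) -> EnrichmentResult:
    """Fisher enrichment of the masked loci against a reference interval set.

    Deduplicates loci by (contig, start, end, motif) before building the
    table so multi-category loci are counted once.
    """
    if mask is None:
        selected = list(loci)
    else:
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        selected = [loci[i] for i in idx]
    unique: dict[tuple, object] = {}
    for locus in selected:
        key = locus.key if isinstance(locus, TRLocus) else tuple(locus)
        unique.setdefault(key, locus)
    if not unique:
        raise ValidationError(f"category {category!r} has no loci")
    table = build_fisher_table(list(unique.values()), reference_track, genome_size)
    odds, p = fisher_exact(table)
    return EnrichmentResult(category=category, odds_ratio=odds, p_two_sided=p, table=table)
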