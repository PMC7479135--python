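"""Core domain types: genome layout, TR loci, cohort matrices, annotation tracks.

All coordinates are 0-based half-open throughout the package (BED
convention).  A ``TRLocus`` is one repetitive region with a 3-8 bp primitive
motif; a ``CohortMatrix`` holds depth-normalized anchored in-repeat-read
(IRR) counts for a set of loci across a cohort of genomes.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .motifs import canonical_motif, validate_motif

__all__ = [
    "ValidationError",
    "GenomeLayout",
    "TRLocus",
    "CohortMatrix",
    "AnnotationTrack",
    "DiseaseLocusDef",
    "DEFAULT_REFERENCE_DEPTH",
]

#: Fold-coverage every sample is normalized to when no depth metadata is
#: available; 40x is the observed mean coverage the count matrices assume.
DEFAULT_REFERENCE_DEPTH = 40.0

INHERITANCE_MODES = ("AD", "AR", "XD", "XR")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class GenomeLayout:
    """Named contigs with lengths; holds the genome size used by enrichment."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValidationError("layout has no contigs")
        for name, length in self.lengths.items():
            if not isinstance(length, (int, np.integer)) or length <= 0:
                raise ValidationError(f"contig {name!r} has non-positive length {length}")
        object.__setattr__(self, "lengths", dict(self.lengths))

    @property
    def contigs(self) -> tuple[str, ...]:
        return tuple(self.lengths)

    @property
    def total_size(self) -> int:
        return int(sum(self.lengths.values()))

    def __contains__(self, contig: str) -> bool:
        return contig in self.lengths

    def contig_length(self, contig: str) -> int:
        try:
            return int(self.lengths[contig])
        except KeyError:
            raise ValidationError(f"unknown contig {contig!r}") from None


@dataclass(frozen=True)
class TRLocus:
    """One repetitive region: contig, 0-based half-open interval, motif.

    The motif must be a primitive unit of 3-8 bp over ACGT; the canonical
    (rotation- and strand-invariant) form is derived on construction.
    """

    contig: str
    start: int
    end: int
    motif: str
    canonical: str = field(init=False, compare=False)

    def __post_init__(self) -> None:
        if not isinstance(self.start, (int, np.integer)) or not isinstance(
            self.end, (int, np.integer)
        ):
            raise ValidationError(f"non-integer coordinates {self.start!r}, {self.end!r}")
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        object.__setattr__(self, "motif", validate_motif(self.motif))
        object.__setattr__(self, "canonical", canonical_motif(self.motif))

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.start, self.end, self.motif)

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate_against(self, layout: GenomeLayout) -> None:
        if self.end > layout.contig_length(self.contig):
            raise ValidationError(
                f"locus {self.key} extends past contig end "
                f"{layout.contig_length(self.contig)}"
            )


@dataclass
class CohortMatrix:
    """Loci x samples matrix of depth-normalized anchored IRR counts.

    ``counts[i, j]`` is the anchored IRR count of locus ``loci[i]`` in sample
    ``samples[j]``, rescaled to ``reference_depth`` fold-coverage.
    ``depths[j]`` records the sample's own coverage (all equal to
    ``reference_depth`` when depth metadata is unavailable, making the
    normalization the identity).
    """

    loci: list[TRLocus]
    samples: list[str]
    counts: np.ndarray
    depths: np.ndarray | None = None
    reference_depth: float = DEFAULT_REFERENCE_DEPTH

    def __post_init__(self) -> None:
        self.loci = list(self.loci)
        self.samples = [str(s) for s in self.samples]
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.loci), len(self.samples)):
            raise ValidationError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.loci)}, {len(self.samples)})"
            )
        if self.depths is None:
            self.depths = np.full(len(self.samples), float(self.reference_depth))
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.shape != (len(self.samples),):
            raise ValidationError("depths length does not match samples")
        if not np.all(self.depths > 0):
            raise ValidationError("sample depths must be positive")
        if self.reference_depth <= 0:
            raise ValidationError("reference depth must be positive")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts must be finite")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        keys = [locus.key for locus in self.loci]
        if len(set(keys)) != len(keys):
            seen: set[tuple] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))
            raise ValidationError(f"duplicate locus {dup}")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def locus_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": [l.contig for l in self.loci],
                "start": [l.start for l in self.loci],
                "end": [l.end for l in self.loci],
                "motif": [l.motif for l in self.loci],
                "canonical_motif": [l.canonical for l in self.loci],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        frame = self.locus_frame().drop(columns="canonical_motif")
        return pd.concat(
            [frame, pd.DataFrame(self.counts, columns=self.samples)], axis=1
        )

    def subset_loci(self, mask: np.ndarray) -> "CohortMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CohortMatrix(
            loci=[self.loci[i] for i in idx],
            samples=self.samples,
            counts=self.counts[idx],
            depths=self.depths,
            reference_depth=self.reference_depth,
        )


@dataclass
class AnnotationTrack:
    """Named set of labeled genomic intervals (region, Alu or repeat track)."""

    name: str
    intervals: list[tuple[str, int, int, str]]
    _trees: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        cleaned = []
        for iv in self.intervals:
            contig, start, end, label = iv
            start, end = int(start), int(end)
            if not 0 <= start < end:
                raise ValidationError(
                    f"track {self.name!r}: invalid interval [{start}, {end}) on {contig}"
                )
            cleaned.append((str(contig), start, end, str(label)))
        self.intervals = cleaned
        self._trees = None

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def labels(self) -> set[str]:
        return {label for *_, label in self.intervals}

    def validate_against(self, layout: GenomeLayout) -> None:
        for contig, start, end, _ in self.intervals:
            if contig not in layout:
                raise ValidationError(f"track {self.name!r}: unknown contig {contig!r}")
            if end > layout.contig_length(contig):
                raise ValidationError(
                    f"track {self.name!r}: interval [{start}, {end}) past end of {contig}"
                )

    def trees(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for contig, start, end, label in self.intervals:
                trees.setdefault(contig, IntervalTree()).addi(start, end, label)
            self._trees = trees
        return self._trees

    def overlaps(self, contig: str, start: int, end: int) -> list[tuple[int, int, str]]:
        """All track intervals intersecting [start, end) on the contig by >= 1 bp."""
        tree = self.trees().get(contig)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end))

    def coverage_bp(self) -> int:
        """Total covered base pairs (overlapping intervals merged per contig)."""
        total = 0
        for tree in self.trees().values():
            merged = IntervalTree(tree)
            merged.merge_overlaps()
            total += sum(iv.end - iv.begin for iv in merged)
        return int(total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intervals, columns=["contig", "start", "end", "label"]
        )


@dataclass(frozen=True)
class DiseaseLocusDef:
    """A known repeat-expansion disease locus.

    Motifs are stored in canonical form.  ``normal_max_repeats`` and
    ``pathogenic_min_repeats`` are literature-derived repeat-count bounds;
    either may be absent.  ``pathogenic_min_contested`` records a lower,
    contested pathogenic bound where sources disagree (screening uses the
    conservative ``pathogenic_min_repeats``).
    """

    code: str
    name: str
    inheritance: str
    contig: str
    start: int
    end: int
    reference_motif: str
    disease_motif: str
    normal_max_repeats: float | None = None
    pathogenic_min_repeats: float | None = None
    pathogenic_min_contested: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_MODES:
            raise ValidationError(
                f"{self.code}: inheritance {self.inheritance!r} not in {INHERITANCE_MODES}"
            )
        if not 0 <= self.start < self.end:
            raise ValidationError(f"{self.code}: invalid interval")
        object.__setattr__(
            self, "reference_motif", canonical_motif(validate_motif(self.reference_motif))
        )
        object.__setattr__(
            self, "disease_motif", canonical_motif(validate_motif(self.disease_motif))
        )
        if (
            self.normal_max_repeats is not None
            and self.pathogenic_min_repeats is not None
            and not self.normal_max_repeats < self.pathogenic_min_repeats
        ):
            raise ValidationError(
                f"{self.code}: normal_max_repeats {self.normal_max_repeats} must be "
                f"below pathogenic_min_repeats {self.pathogenic_min_repeats}"
            )

    @property
    def recessive(self) -> bool:
        return self.inheritance == "AR"


def loci_to_intervals(loci: Iterable[TRLocus]) -> list[tuple[str, int, int]]:
    """Plain (contig, start, end) triples for a sequence of loci."""
    return [(l.contig, l.start, l.end) for l in loci]
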