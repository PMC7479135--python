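"""Cohort-level statistics: presence calls, frequency classes, per-genome counts.

A locus is called *present* in a genome when its depth-normalized anchored
IRR count reaches the presence threshold (default 5, i.e. a repeat tract of
roughly 175 bp or more under the calibrated length model).  Loci present in
at least 1% of genomes are *common*, the rest *rare*; for a cohort of 1,115
genomes the boundary falls between 11 and 12 occurrences.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_REFERENCE_DEPTH,
    CohortMatrix,
    TRLocus,
    ValidationError,
)

__all__ = [
    "PresenceMatrix",
    "FrequencyClassification",
    "OccurrenceSpectrum",
    "DEFAULT_PRESENCE_THRESHOLD",
    "DEFAULT_RARE_FRACTION",
    "normalize_counts",
    "call_presence",
    "classify_frequency",
    "per_genome_counts",
    "occurrence_spectrum",
    "merge_sample_calls",
]

DEFAULT_PRESENCE_THRESHOLD = 5.0
DEFAULT_RARE_FRACTION = 0.01

RARE, COMMON, ABSENT = "rare", "common", "absent"


def normalize_counts(raw, sample_depth, reference_depth=DEFAULT_REFERENCE_DEPTH):
    """Rescale raw anchored IRR counts to the reference fold-coverage.

    ``normalized = raw * reference_depth / sample_depth``; scalar or array.
    """
    raw = np.asarray(raw, dtype=float)
    sample_depth = np.asarray(sample_depth, dtype=float)
    if np.any(sample_depth <= 0) or reference_depth <= 0:
        raise ValidationError("depths must be positive")
    out = raw * (float(reference_depth) / sample_depth)
    return float(out) if out.ndim == 0 else out


@dataclass
class PresenceMatrix:
    """Boolean loci x samples matrix derived from a count matrix + threshold."""

    matrix: np.ndarray
    threshold: float
    loci: list[TRLocus]
    samples: list[str]

    @property
    def n_loci(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def occurrences(self) -> np.ndarray:
        """Per-locus number of genomes the locus is present in."""
        return self.matrix.sum(axis=1)

    def restrict(self, mask: np.ndarray) -> "PresenceMatrix":
        idx = np.flatnonzero(np.asarray(mask))
        return PresenceMatrix(
            matrix=self.matrix[idx],
            threshold=self.threshold,
            loci=[self.loci[i] for i in idx],
            samples=self.samples,
        )


def call_presence(
    matrix: CohortMatrix, threshold: float = DEFAULT_PRESENCE_THRESHOLD
) -> PresenceMatrix:
    """Presence call: normalized count >= threshold (inclusive boundary)."""
    if threshold <= 0:
        raise ValidationError("presence threshold must be positive")
    return PresenceMatrix(
        matrix=matrix.counts >= threshold,
        threshold=float(threshold),
        loci=matrix.loci,
        samples=matrix.samples,
    )


@dataclass
class FrequencyClassification:
    """Rare/common labels per locus.

    ``cutoff`` is the smallest occurrence count classified as common:
    ``floor(rare_fraction * n_samples) + 1`` (12 for n = 1,115 at 1%).
    Loci present in no sample are labeled ``absent``.
    """

    occurrences: np.ndarray
    classes: np.ndarray
    cutoff: int
    rare_fraction: float
    loci: list[TRLocus] = field(default_factory=list)

    @property
    def n_rare(self) -> int:
        return int(np.sum(self.classes == RARE))

    @property
    def n_common(self) -> int:
        return int(np.sum(self.classes == COMMON))

    @property
    def n_absent(self) -> int:
        return int(np.sum(self.classes == ABSENT))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "occurrences": self.occurrences.astype(int),
                "class": self.classes,
            }
        )
        if self.loci:
            locus_cols = pd.DataFrame(
                {
                    "contig": [l.contig for l in self.loci],
                    "start": [l.start for l in self.loci],
                    "end": [l.end for l in self.loci],
                    "motif": [l.motif for l in self.loci],
                }
            )
            frame = pd.concat([locus_cols, frame], axis=1)
        return frame


def classify_frequency(
    presence: PresenceMatrix, rare_fraction: float = DEFAULT_RARE_FRACTION
) -> FrequencyClassification:
    """Classify loci as rare (< rare_fraction of genomes) or common.

    A locus is common iff its occurrence count exceeds
    ``floor(rare_fraction * n_samples)``, which places the rare/common
    boundary between 11 and 12 occurrences for n = 1,115 at the default 1%.
    """
    if presence.n_samples < 1:
        raise ValidationError("need at least one sample")
    occ = presence.occurrences.astype(int)
    cutoff = math.floor(rare_fraction * presence.n_samples) + 1
    classes = np.where(occ >= cutoff, COMMON, np.where(occ >= 1, RARE, ABSENT))
    return FrequencyClassification(
        occurrences=occ,
        classes=classes,
        cutoff=cutoff,
        rare_fraction=rare_fraction,
        loci=list(presence.loci),
    )


def per_genome_counts(
    presence: PresenceMatrix, labels: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genome locus counts by category, with median and IQR summaries.

    ``labels`` assigns one category label per locus (a partition).  Returns
    ``(counts, summary)``: ``counts`` is samples x categories; ``summary``
    has one row per category with median, Q1, Q3 and IQR (Q3 - Q1, linear
    interpolation) of the per-genome counts.
    """
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != presence.n_loci:
        raise ValidationError("one label per locus required")
    categories = sorted(set(labels))
    data = {
        cat: presence.matrix[labels == cat].sum(axis=0) for cat in categories
    }
    counts = pd.DataFrame(data, index=presence.samples)
    counts.index.name = "sample"
    rows = []
    for cat in categories:
        values = counts[cat].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        rows.append(
            {"category": cat, "median": med, "q1": q1, "q3": q3, "iqr": q3 - q1}
        )
    summary = pd.DataFrame(rows).set_index("category")
    return counts, summary


@dataclass
class OccurrenceSpectrum:
    """How many loci are seen in exactly k genomes, for k >= 1."""

    table: pd.DataFrame  # columns: occurrences, n_loci
    singleton_fraction: float

    @property
    def total_loci(self) -> int:
        return int(self.table["n_loci"].sum())


def occurrence_spectrum(presence: PresenceMatrix) -> OccurrenceSpectrum:
    """Occurrence-count spectrum over loci present in at least one genome."""
    occ = presence.occurrences.astype(int)
    occ = occ[occ >= 1]
    values, counts = np.unique(occ, return_counts=True)
    table = pd.DataFrame({"occurrences": values, "n_loci": counts})
    singletons = int(counts[values == 1].sum()) if len(values) else 0
    fraction = singletons / len(occ) if len(occ) else float("nan")
    return OccurrenceSpectrum(table=table, singleton_fraction=fraction)


def merge_sample_calls(
    calls: Mapping[str, pd.DataFrame],
    max_gap: int = 0,
    depths: Mapping[str, float] | None = None,
    reference_depth: float = DEFAULT_REFERENCE_DEPTH,
) -> CohortMatrix:
    """Merge per-sample locus calls into one cohort matrix.

    ``calls`` maps sample id to a DataFrame with columns
    ``contig, start, end, motif, count``.  Calls sharing a contig and an
    identical motif string whose intervals overlap or lie within ``max_gap``
    bp of each other are merged into a single locus spanning their union;
    counts are carried per sample (summed if one sample contributes several
    calls to a merged locus).
    """
    samples = list(calls)
    records: dict[tuple[str, str], list[tuple[int, int, str, float]]] = {}
    for sample, frame in calls.items():
        for row in frame.itertuples(index=False):
            key = (str(row.contig), str(row.motif).upper())
            records.setdefault(key, []).append(
                (int(row.start), int(row.end), sample, float(row.count))
            )
    merged_loci: list[TRLocus] = []
    merged_counts: list[dict[str, float]] = []
    for (contig, motif), items in sorted(records.items()):
        items.sort()
        cluster_start, cluster_end = items[0][0], items[0][1]
        cluster_counts: dict[str, float] = {}

        def flush(start: int, end: int, counts: dict[str, float]) -> None:
            merged_loci.append(TRLocus(contig=contig, start=start, end=end, motif=motif))
            merged_counts.append(dict(counts))

        for start, end, sample, count in items:
            if start - cluster_end > max_gap:
                flush(cluster_start, cluster_end, cluster_counts)
                cluster_start, cluster_end = start, end
                cluster_counts = {}
            cluster_end = max(cluster_end, end)
            cluster_counts[sample] = cluster_counts.get(sample, 0.0) + count
        flush(cluster_start, cluster_end, cluster_counts)

    # sort loci for a deterministic, position-ordered matrix
    idx = sorted(
        range(len(merged_loci)), key=lambda i: merged_loci[i].key
    )
    counts = np.zeros((len(merged_loci), len(samples)))
    for i, per_sample in enumerate(merged_counts):
        for sample, value in per_sample.items():
            counts[i, samples.index(sample)] = value
    depth_array = None
    if depths is not None:
        depth_array = np.array([float(depths[s]) for s in samples])
    return CohortMatrix(
        loci=[merged_loci[i] for i in idx],
        samples=samples,
        counts=counts[idx],
        depths=depth_array,
        reference_depth=reference_depth,
    )
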