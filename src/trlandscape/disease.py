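"""Disease-locus screening and the IRR-count -> repeat-length model.

Anchored IRR counts track the length of the larger allele approximately
linearly; the calibrated model is

    bases = intercept + slope * irr_count      (default 140.6 + 7.7x)

so the 5-IRR presence threshold corresponds to a repeat tract of about
175 bp.  Screening finds cohort loci overlapping known disease intervals,
classifies the observed motif against the reference and disease motifs of
the locus, converts counts to estimated repeat numbers, and flags samples
whose estimate reaches the pathogenic threshold.  For recessive conditions
a flag means "carrier-compatible" only: anchored IRR counts cannot separate
the two alleles.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DEFAULT_PRESENCE_THRESHOLD
from .core import CohortMatrix, DiseaseLocusDef, GenomeLayout, ValidationError
from .motifs import canonical_motif

__all__ = [
    "LengthModel",
    "DEFAULT_LENGTH_MODEL",
    "ScreenResult",
    "MOTIF_CATEGORIES",
    "estimate_length",
    "estimate_repeats",
    "classify_motif_at_locus",
    "screen_cohort",
    "screen_to_frame",
    "calibrate_model",
    "DEFAULT_SCREEN_SLOP",
]

#: Extra flank (bp) around a catalog interval when matching cohort loci,
#: absorbing the broad localization of anchored-IRR calls.
DEFAULT_SCREEN_SLOP = 1000


@dataclass(frozen=True)
class LengthModel:
    """Linear map from anchored IRR count to repeat-tract length in bases."""

    intercept: float = 140.6
    slope: float = 7.7
    rho: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValidationError("slope must be positive")


DEFAULT_LENGTH_MODEL = LengthModel()


def estimate_length(irr_count, model: LengthModel = DEFAULT_LENGTH_MODEL):
    """Estimated repeat-tract length in bases for a (normalized) IRR count."""
    irr_count = np.asarray(irr_count, dtype=float)
    if np.any(irr_count < 0):
        raise ValidationError("IRR count must be non-negative")
    out = model.intercept + model.slope * irr_count
    return float(out) if out.ndim == 0 else out


def estimate_repeats(irr_count, motif_length: int, model: LengthModel = DEFAULT_LENGTH_MODEL):
    """Estimated repeat count: estimated bases / motif length (real-valued)."""
    if motif_length <= 0:
        raise ValidationError("motif length must be positive")
    out = np.asarray(estimate_length(irr_count, model)) / motif_length
    return float(out) if out.ndim == 0 else out


# Motif categories relative to a disease-locus definition.
REF_EQ_DISEASE = "reference motif = disease motif"
REF_ONLY = "reference motif only"
DISEASE_ONLY = "disease motif only"
NEITHER = "neither reference nor disease motif"
MOTIF_CATEGORIES = (REF_EQ_DISEASE, REF_ONLY, DISEASE_ONLY, NEITHER)


def classify_motif_at_locus(observed_motif: str, definition: DiseaseLocusDef) -> str:
    """Classify an observed motif against a disease locus definition.

    Comparison is by canonical motif.  When the reference and disease motifs
    coincide and the observation matches, the category is "reference motif =
    disease motif"; at mutated-motif loci (e.g. the AAAAG -> AAGGG CANVAS
    locus) an observation matching only the disease motif is "disease motif
    only", one matching only the reference is "reference motif only", and
    anything else is "neither reference nor disease motif".
    """
    observed = canonical_motif(observed_motif)
    matches_ref = observed == definition.reference_motif
    matches_dis = observed == definition.disease_motif
    if matches_dis and matches_ref:
        return REF_EQ_DISEASE
    if matches_dis:
        return DISEASE_ONLY
    if matches_ref:
        return REF_ONLY
    return NEITHER


@dataclass(frozen=True)
class ScreenResult:
    """One sample x disease-locus observation from a cohort screen."""

    sample: str
    disease_code: str
    contig: str
    start: int
    end: int
    observed_motif: str
    motif_category: str
    normalized_count: float
    estimated_bases: float
    estimated_repeats: float
    pathogenic: bool | None  # None = not assessable
    carrier_only: bool


def screen_cohort(
    matrix: CohortMatrix,
    catalog: Sequence[DiseaseLocusDef],
    model: LengthModel = DEFAULT_LENGTH_MODEL,
    threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    slop: int = DEFAULT_SCREEN_SLOP,
    layout: GenomeLayout | None = None,
) -> list[ScreenResult]:
    """Screen a cohort matrix at known disease loci.

    For each catalog entry, cohort loci overlapping the disease interval
    (enlarged by ``slop`` bp on both sides) are inspected; every sample with
    a normalized count at or above the presence threshold yields a
    ``ScreenResult``.  The pathogenic flag is ``estimated repeats >=
    pathogenic_min_repeats``, assessed only when the observed motif matches
    the disease motif and the catalog provides a threshold; recessive
    conditions are marked carrier-only.
    """
    results: list[ScreenResult] = []
    for definition in catalog:
        if layout is not None:
            if definition.contig not in layout:
                raise ValidationError(
                    f"{definition.code}: contig {definition.contig!r} not in layout"
                )
            if definition.end > layout.contig_length(definition.contig):
                raise ValidationError(f"{definition.code}: locus beyond contig end")
        window = (max(0, definition.start - slop), definition.end + slop)
        for i, locus in enumerate(matrix.loci):
            if locus.contig != definition.contig:
                continue
            if locus.end <= window[0] or locus.start >= window[1]:
                continue
            category = classify_motif_at_locus(locus.motif, definition)
            motif_len = len(locus.canonical)
            for j, sample in enumerate(matrix.samples):
                count = float(matrix.counts[i, j])
                if count < threshold:
                    continue
                bases = estimate_length(count, model)
                repeats = bases / motif_len
                assessable = (
                    category in (REF_EQ_DISEASE, DISEASE_ONLY)
                    and definition.pathogenic_min_repeats is not None
                )
                results.append(
                    ScreenResult(
                        sample=sample,
                        disease_code=definition.code,
                        contig=locus.contig,
                        start=locus.start,
                        end=locus.end,
                        observed_motif=locus.canonical,
                        motif_category=category,
                        normalized_count=count,
                        estimated_bases=bases,
                        estimated_repeats=round(repeats, 1),
                        pathogenic=(
                            repeats >= definition.pathogenic_min_repeats
                            if assessable
                            else None
                        ),
                        carrier_only=definition.recessive,
                    )
                )
    return results


def screen_to_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def calibrate_model(
    pairs: Mapping[str, Sequence[tuple[float, float]]] | Sequence[tuple[float, float]],
    min_pairs: int = 3,
) -> LengthModel:
    """Fit the count -> length model from (allele size in bases, IRR count) pairs.

    ``pairs`` maps calibration locus to its (bases, count) observations (a
    bare sequence is treated as a single locus).  Each locus is fit by least
    squares of bases on count; coefficients are averaged across loci, and
    Spearman's rho per locus is recorded as calibration quality.
    """
    if not isinstance(pairs, Mapping):
        pairs = {"locus": list(pairs)}
    intercepts, slopes, rho = [], [], {}
    for name, observations in pairs.items():
        observations = list(observations)
        if len(observations) < min_pairs:
            raise ValidationError(f"locus {name!r}: need >= {min_pairs} pairs")
        bases = np.array([b for b, _ in observations], dtype=float)
        counts = np.array([c for _, c in observations], dtype=float)
        if np.ptp(counts) == 0:
            raise ValidationError(f"locus {name!r}: counts are all equal")
        slope, intercept = np.polyfit(counts, bases, 1)
        slopes.append(slope)
        intercepts.append(intercept)
        rho[name] = float(stats.spearmanr(counts, bases).statistic)
    return LengthModel(
        intercept=float(np.mean(intercepts)),
        slope=float(np.mean(slopes)),
        rho=rho,
    )
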