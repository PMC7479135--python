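"""Reference-origin matching: does an observed large TR stem from a known
reference repeat locus?

A locus *originates* from the reference when its interval overlaps a
simple-repeats record (unit length 3-8 bp) whose unit is equivalent to the
locus motif.  The default equivalence is canonical equality (reverse
complement plus cyclic rotation, since repeat phase is arbitrary between
tools); a strict reverse-complement-only mode is retained for literal
exact-string matching.  A locus matching several reference records counts
once.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnnotationTrack, TRLocus, ValidationError
from .motifs import canonical_motif, reverse_complement

__all__ = ["OriginCall", "match_reference", "match_references", "percent_from_reference"]

MATCH_MODES = ("revcomp_and_rotation", "revcomp_only")


@dataclass(frozen=True)
class OriginCall:
    locus: TRLocus
    matched: bool
    reference: tuple[int, int, str] | None = None  # (start, end, unit)


def _equivalent(motif: str, unit: str, mode: str) -> bool:
    if mode == "revcomp_and_rotation":
        return canonical_motif(motif) == canonical_motif(unit)
    if mode == "revcomp_only":
        return motif == unit or motif == reverse_complement(unit)
    raise ValidationError(f"unknown match mode {mode!r}; expected one of {MATCH_MODES}")


def match_reference(
    locus: TRLocus,
    simple_repeats: AnnotationTrack,
    mode: str = "revcomp_and_rotation",
) -> OriginCall:
    """Match one locus against the reference simple-repeats track."""
    for start, end, unit in simple_repeats.overlaps(locus.contig, locus.start, locus.end):
        if _equivalent(locus.motif, unit, mode):
            return OriginCall(locus=locus, matched=True, reference=(start, end, unit))
    _equivalent(locus.motif, locus.motif, mode)  # surface bad mode even without overlaps
    return OriginCall(locus=locus, matched=False)


def match_references(
    loci: Sequence[TRLocus],
    simple_repeats: AnnotationTrack,
    mode: str = "revcomp_and_rotation",
) -> list[OriginCall]:
    """One origin call per locus (deduplicated by construction)."""
    return [match_reference(l, simple_repeats, mode) for l in loci]


def percent_from_reference(
    calls: Sequence[OriginCall],
    categories: Mapping[str, np.ndarray] | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Percent of loci matching a reference repeat, per category.

    ``categories`` is either a per-locus label sequence, a mapping from
    category name to a boolean mask/index array over the calls, or ``None``
    for a single "all" category.  Empty categories are flagged with a NaN
    percentage.
    """
    matched = np.array([c.matched for c in calls], dtype=bool)
    if categories is None:
        groups: dict[str, np.ndarray] = {"all": np.ones(len(calls), dtype=bool)}
    elif isinstance(categories, Mapping):
        groups = {
            name: np.asarray(mask) for name, mask in categories.items()
        }
    else:
        labels = np.asarray([str(l) for l in categories])
        if len(labels) != len(calls):
            raise ValidationError("one category label per call required")
        groups = {name: labels == name for name in sorted(set(labels))}
    rows = []
    for name, mask in groups.items():
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        total = len(idx)
        hits = int(matched[idx].sum()) if total else 0
        rows.append(
            {
                "category": name,
                "total": total,
                "matched": hits,
                "percent": 100.0 * hits / total if total else float("nan"),
                "empty": total == 0,
            }
        )
    return pd.DataFrame(rows).set_index("category")
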