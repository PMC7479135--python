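"""Repeat-motif identity and composition profiling.

A tandem-repeat motif has no intrinsic strand or phase: the same locus may be
reported as any cyclic rotation of its unit, on either strand (e.g. the ALS
hexanucleotide is written GGGGCC in the literature but CCCCGG in canonical
form).  This module defines the canonical representative — the
lexicographically smallest string over all cyclic rotations of the motif and
of its reverse complement — plus the composition descriptors used to profile
a motif set: number of unique nucleotides, the unordered nucleotide pair for
two-letter motifs, and the unit length.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "MotifError",
    "MotifProfile",
    "reverse_complement",
    "is_primitive",
    "primitive_unit",
    "validate_motif",
    "canonical_motif",
    "unique_nucleotides",
    "pair_class",
    "motif_profile",
    "motif_profile_tables",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = frozenset("ACGT")

#: Unordered nucleotide pairs, in reporting order.  Under strand collapsing
#: only the first four can occur (G&T folds into A&C, C&T into A&G).
PAIR_CLASSES: tuple[tuple[str, str], ...] = (
    ("A", "C"),
    ("A", "G"),
    ("A", "T"),
    ("C", "G"),
    ("C", "T"),
    ("G", "T"),
)

MOTIF_LENGTH_RANGE = (3, 8)


class MotifError(ValueError):
    """Raised for motifs violating the alphabet, length or primitivity rules."""


def _check_alphabet(motif: str) -> str:
    motif = motif.upper()
    if not motif:
        raise MotifError("empty motif")
    bad = set(motif) - _BASES
    if bad:
        raise MotifError(f"motif {motif!r} contains non-ACGT characters {sorted(bad)}")
    return motif


def reverse_complement(motif: str) -> str:
    """Reverse complement of a DNA string."""
    return _check_alphabet(motif).translate(_COMPLEMENT)[::-1]


def primitive_unit(motif: str) -> str:
    """Smallest unit whose tandem repetition yields ``motif``.

    ``"ATAT"`` has primitive unit ``"AT"``; a primitive motif is its own unit.
    """
    motif = _check_alphabet(motif)
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return motif[:d]
    return motif


def is_primitive(motif: str) -> bool:
    """True if the motif is not a tandem repetition of a shorter unit."""
    return primitive_unit(motif) == _check_alphabet(motif)


def validate_motif(
    motif: str,
    min_len: int = MOTIF_LENGTH_RANGE[0],
    max_len: int = MOTIF_LENGTH_RANGE[1],
    require_primitive: bool = True,
) -> str:
    """Validate and upper-case a repeat unit.

    Enforces the ACGT alphabet, the configured unit-length window (3-8 bp by
    default, matching the search bounds of the upstream caller) and, by
    default, primitivity: ``"ATAT"`` is rejected in favor of its unit ``"AT"``
    so rotationally duplicated loci cannot be double counted.
    """
    motif = _check_alphabet(motif)
    if not min_len <= len(motif) <= max_len:
        raise MotifError(
            f"motif {motif!r} has length {len(motif)}, outside [{min_len}, {max_len}]"
        )
    if require_primitive and not is_primitive(motif):
        raise MotifError(
            f"motif {motif!r} is a repetition of shorter unit {primitive_unit(motif)!r}"
        )
    return motif


def canonical_motif(motif: str) -> str:
    """Canonical representative of a repeat unit.

    Returns the lexicographically smallest string among all cyclic rotations
    of the motif and all cyclic rotations of its reverse complement, so the
    result is invariant under rotation and strand flip (GGGGCC -> CCCCGG,
    CAG -> AGC, GAA -> AAG).
    """
    motif = _check_alphabet(motif)
    rc = motif.translate(_COMPLEMENT)[::-1]
    n = len(motif)
    candidates = (s[i:] + s[:i] for s in (motif, rc) for i in range(n))
    return min(candidates)


def unique_nucleotides(motif: str) -> int:
    """Number of distinct nucleotides in the motif (1-4)."""
    return len(set(_check_alphabet(motif)))


def pair_class(motif: str, collapse_strand: bool = True) -> tuple[str, str] | None:
    """Unordered nucleotide pair of a two-letter motif, else ``None``.

    With ``collapse_strand`` (default) the pair is read off the canonical
    motif so complementary reports collapse: a CT-composed motif such as CTT
    canonicalizes to AAG and reports as A&G.
    """
    motif = _check_alphabet(motif)
    if len(set(motif)) != 2:
        return None
    base = canonical_motif(motif) if collapse_strand else motif
    a, b = sorted(set(base))
    return (a, b)


@dataclass(frozen=True)
class MotifProfile:
    """Composition descriptors of a single repeat unit."""

    canonical: str
    unique_nucleotide_count: int
    pair: tuple[str, str] | None
    motif_length: int


def motif_profile(motif: str, collapse_strand: bool = True) -> MotifProfile:
    motif = _check_alphabet(motif)
    return MotifProfile(
        canonical=canonical_motif(motif),
        unique_nucleotide_count=unique_nucleotides(motif),
        pair=pair_class(motif, collapse_strand=collapse_strand),
        motif_length=len(motif),
    )


def _pair_label(pair: tuple[str, str] | None) -> str:
    return "none" if pair is None else "&".join(pair)


def motif_profile_tables(
    motifs_by_category: Mapping[str, Sequence[str]],
    collapse_strand: bool = True,
) -> dict[str, pd.DataFrame]:
    """Per-category frequency tables of motif composition.

    Parameters
    ----------
    motifs_by_category
        Mapping from category label (rare/common, region labels, Alu status,
        dataset-vs-reference, ...) to the motifs of the loci in that category.
    collapse_strand
        Passed through to :func:`pair_class`.

    Returns
    -------
    dict with keys ``"unique_nucleotides"``, ``"pair_class"`` and
    ``"motif_length"``; each value is a DataFrame of frequencies (rows =
    bins, columns = categories) summing to 1 per non-empty category.  Empty
    categories are emitted as all-zero columns and listed in
    ``df.attrs["empty_categories"]``.
    """
    uniq_bins = [1, 2, 3, 4]
    pair_bins = [_pair_label(p) for p in PAIR_CLASSES] + ["none"]
    len_bins = list(range(MOTIF_LENGTH_RANGE[0], MOTIF_LENGTH_RANGE[1] + 1))

    uniq = pd.DataFrame(0.0, index=uniq_bins, columns=list(motifs_by_category))
    pair = pd.DataFrame(0.0, index=pair_bins, columns=list(motifs_by_category))
    length = pd.DataFrame(0.0, index=len_bins, columns=list(motifs_by_category))
    empty = []
    for cat, motifs in motifs_by_category.items():
        motifs = list(motifs)
        if not motifs:
            empty.append(cat)
            continue
        n = len(motifs)
        for m in motifs:
            prof = motif_profile(m, collapse_strand=collapse_strand)
            uniq.loc[prof.unique_nucleotide_count, cat] += 1.0
            pair.loc[_pair_label(prof.pair), cat] += 1.0
            length.loc[prof.motif_length, cat] += 1.0
        for df in (uniq, pair, length):
            df[cat] /= n
    tables = {"unique_nucleotides": uniq, "pair_class": pair, "motif_length": length}
    for df in tables.values():
        df.attrs["empty_categories"] = list(empty)
        df.index.name = "bin"
        df.columns.name = "category"
    return tables
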