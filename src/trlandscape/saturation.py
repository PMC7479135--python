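"""Permutation-based discovery (saturation) curves.

Genomes are visited in random order; a locus is *novel* at the first
visited genome in which it is present.  Averaging the cumulative novel-locus
counts over many random orderings yields the expected discovery curve as a
function of sample size; the mean increment over the last few positions is
the residual rate at which new loci would still be found per additional
genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import PresenceMatrix
from .core import ValidationError

__all__ = [
    "SaturationCurve",
    "saturation_curve",
    "residual_discovery_rate",
    "DEFAULT_SATURATION_ITERATIONS",
    "DEFAULT_K_LAST",
]

DEFAULT_SATURATION_ITERATIONS = 1000
DEFAULT_K_LAST = 15


@dataclass
class SaturationCurve:
    """Mean cumulative novel-locus counts per cohort position."""

    mean_cumulative: np.ndarray
    n_iterations: int
    seed: int
    label: str = ""

    @property
    def n_samples(self) -> int:
        return len(self.mean_cumulative)

    @property
    def final(self) -> float:
        return float(self.mean_cumulative[-1])

    def increments(self) -> np.ndarray:
        """Per-position novel-locus increments (first position included)."""
        return np.diff(self.mean_cumulative, prepend=0.0)


def saturation_curve(
    presence: PresenceMatrix | np.ndarray,
    n_iterations: int = DEFAULT_SATURATION_ITERATIONS,
    seed: int = 0,
    label: str = "",
) -> SaturationCurve:
    """Monte-Carlo discovery curve over random genome orderings.

    For each iteration the samples are visited in a uniformly random order
    (Fisher-Yates via the seeded generator); each locus counts as novel at
    the first visited sample carrying it.  The returned curve is the mean
    cumulative count across iterations.  Its endpoint equals the number of
    distinct loci present in at least one sample, for every ordering.
    """
    if n_iterations < 1:
        raise ValidationError("need at least one iteration")
    matrix = presence.matrix if isinstance(presence, PresenceMatrix) else presence
    matrix = np.asarray(matrix, dtype=bool)
    n_loci, n_samples = matrix.shape
    if n_samples < 1:
        raise ValidationError("need at least one sample")
    rng = np.random.default_rng(seed)
    ever_present = matrix.any(axis=1)
    total = np.zeros(n_samples)
    for _ in range(n_iterations):
        order = rng.permutation(n_samples)
        first_seen = matrix[:, order].argmax(axis=1)
        novel_at = np.bincount(first_seen[ever_present], minlength=n_samples)
        total += np.cumsum(novel_at)
    return SaturationCurve(
        mean_cumulative=total / n_iterations,
        n_iterations=n_iterations,
        seed=seed,
        label=label,
    )


def residual_discovery_rate(
    curve: SaturationCurve, k_last: int = DEFAULT_K_LAST
) -> float:
    """Mean novel loci per additional genome over the last ``k_last`` positions."""
    if k_last < 1:
        raise ValidationError("k_last must be >= 1")
    if curve.n_samples <= k_last:
        raise ValidationError(
            f"curve of length {curve.n_samples} too short for k_last={k_last}"
        )
    cum = curve.mean_cumulative
    return float((cum[-1] - cum[-1 - k_last]) / k_last)
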