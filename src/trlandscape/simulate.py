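"""Synthetic cohort generator with a ground-truth manifest.

Emits a complete input bundle — genome layout, region and Alu tracks, a
simple-repeats table, and a loci x samples matrix of depth-normalized
anchored IRR counts — from planted truth, so every downstream stage can be
validated without external data.  The generator emulates the study
conditions of the real cohorts: ~40x mean coverage, a 3-8 bp motif
composition dominated by two-nucleotide (mostly A/G) units of length 4,
Alu elements covering ~11% of the genome with a configurable planted
overlap odds ratio, a configurable fraction of loci sitting on reference
simple repeats, and IRR counts emitted by inverting the linear length model
bases = 140.6 + 7.7 * count for carrier allele lengths above 175 bp.

All randomness flows from ``SimConfig.seed``; per-stage substreams keep the
outputs stable when unrelated stages change.
"""

from __future__ import annotations

import math
import zlib
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import DEFAULT_PRESENCE_THRESHOLD, normalize_counts
from .core import (
    AnnotationTrack,
    CohortMatrix,
    DiseaseLocusDef,
    GenomeLayout,
    TRLocus,
    ValidationError,
)
from .io import (
    write_bed_track,
    write_dense_matrix,
    write_disease_catalog,
    write_layout,
    write_simple_repeats,
)
from .motifs import canonical_motif, is_primitive

__all__ = [
    "SimConfig",
    "TruthManifest",
    "SimBundle",
    "simulate_layout_and_tracks",
    "simulate_cohort",
    "simulate_bundle",
    "plant_disease_expansion",
    "synthetic_disease_catalog",
    "write_bundle",
]


def _default_contigs() -> dict[str, int]:
    return {"1": 6_000_000, "2": 4_000_000}


def _default_region_fractions() -> dict[str, float]:
    return {"intergenic": 0.55, "intron": 0.36, "promoter": 0.04, "exon": 0.03, "TTS": 0.02}


def _default_unique_nt_weights() -> dict[int, float]:
    return {2: 0.75, 3: 0.20, 4: 0.05}


def _default_pair_weights() -> dict[tuple[str, str], float]:
    return {("A", "G"): 0.60, ("A", "T"): 0.20, ("A", "C"): 0.15, ("C", "G"): 0.05}


def _default_length_weights() -> dict[int, float]:
    return {3: 0.15, 4: 0.45, 5: 0.18, 6: 0.10, 7: 0.06, 8: 0.06}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the observed conditions of the real cohorts where those
    are known (40x mean depth, Alu fraction 0.11, length model 140.6 + 7.7x,
    3-8 bp motifs, mostly 2-nucleotide A/G-type units of length 4, planted
    Alu odds ratio 1.56, ~85% of loci on reference repeats); sample and
    locus counts are desk-scale.
    """

    seed: int = 0
    n_samples: int = 200
    contigs: Mapping[str, int] = field(default_factory=_default_contigs)
    n_common_loci: int = 100
    n_rare_loci: int = 300
    common_frequency_range: tuple[float, float] = (0.02, 0.5)
    rare_occurrence_range: tuple[int, int] | None = None  # default: 1..floor(f*n)
    rare_fraction: float = 0.01
    alu_fraction_of_genome: float = 0.11
    alu_length: int = 300
    target_alu_odds_ratio: float = 1.56
    locus_length_range: tuple[int, int] = (50, 150)
    min_locus_separation: int = 2000
    region_fractions: Mapping[str, float] = field(default_factory=_default_region_fractions)
    region_block: int = 5000
    unique_nt_weights: Mapping[int, float] = field(default_factory=_default_unique_nt_weights)
    pair_weights: Mapping[tuple[str, str], float] = field(default_factory=_default_pair_weights)
    length_weights: Mapping[int, float] = field(default_factory=_default_length_weights)
    depth_mean: float = 40.0
    depth_sd: float = 3.0
    depth_min: float = 10.0
    reference_depth: float = 40.0
    length_model_intercept: float = 140.6
    length_model_slope: float = 7.7
    allele_length_range: tuple[float, float] = (176.0, 2000.0)  # log-uniform
    emission_noise_sd: float = 0.0
    background_counts: tuple[int, ...] = (0, 1, 2)
    reference_origin_fraction: float = 0.85
    n_background_simple_repeats: int = 200
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_common_loci < 0 or self.n_rare_loci < 0:
            raise ValidationError("counts must be non-negative (>=1 sample)")
        for frac in (self.alu_fraction_of_genome, self.reference_origin_fraction):
            if not 0 <= frac <= 1:
                raise ValidationError(f"fraction {frac} outside [0, 1]")
        if sum(self.region_fractions.values()) > 1 + 1e-9:
            raise ValidationError("region fractions sum to more than 1")
        lo, hi = self.common_frequency_range
        if not 0 < lo <= hi <= 1:
            raise ValidationError("invalid common frequency range")
        if not 0 < self.rare_fraction < 1:
            raise ValidationError("rare_fraction must be in (0, 1)")
        if self.allele_length_range[0] <= self.length_model_intercept:
            raise ValidationError("allele lengths must exceed the model intercept")
        if self.target_alu_odds_ratio <= 0:
            raise ValidationError("target odds ratio must be positive")

    @property
    def rare_cutoff(self) -> int:
        """Largest occurrence count still classified as rare."""
        return math.floor(self.rare_fraction * self.n_samples)

    def layout(self) -> GenomeLayout:
        return GenomeLayout(dict(self.contigs))


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        [int(config.seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())]
    )


@dataclass
class TruthManifest:
    """Planted ground truth: per-locus classes and flags, per-carrier alleles."""

    loci: pd.DataFrame       # contig,start,end,motif,freq_class,n_carriers,alu_overlap,reference_origin
    carriers: pd.DataFrame   # locus_index,sample,allele_length,intended_count
    samples: pd.DataFrame    # sample,depth


@dataclass
class SimBundle:
    """A complete synthetic input set plus its truth manifest."""

    config: SimConfig
    layout: GenomeLayout
    region_track: AnnotationTrack
    alu_track: AnnotationTrack
    simple_repeats: AnnotationTrack
    matrix: CohortMatrix
    manifest: TruthManifest
    catalog: list[DiseaseLocusDef] = field(default_factory=list)


def simulate_layout_and_tracks(
    config: SimConfig,
) -> tuple[GenomeLayout, AnnotationTrack, AnnotationTrack]:
    """Genome layout, gene-region partition, and Alu track.

    The region track tiles each contig into blocks labeled multinomially by
    the configured genomic proportions (adjacent same-label blocks merged);
    the Alu track places non-overlapping ~300 bp elements covering the
    configured fraction of the genome to within 1%.
    """
    layout = config.layout()
    rng = _rng(config, "layout_tracks")
    labels = list(config.region_fractions)
    probs = np.array([config.region_fractions[l] for l in labels], dtype=float)
    if probs.sum() <= 0:
        raise ValidationError("region fractions must not all be zero")
    probs = probs / probs.sum()
    region_intervals: list[tuple[str, int, int, str]] = []
    for contig, length in layout.lengths.items():
        n_blocks = math.ceil(length / config.region_block)
        block_labels = rng.choice(labels, size=n_blocks, p=probs)
        start = 0
        for i in range(n_blocks):
            end = min(length, (i + 1) * config.region_block)
            if region_intervals and region_intervals[-1][0] == contig and \
                    region_intervals[-1][3] == block_labels[i] and \
                    region_intervals[-1][2] == start:
                prev = region_intervals.pop()
                region_intervals.append((contig, prev[1], end, prev[3]))
            else:
                region_intervals.append((contig, start, end, str(block_labels[i])))
            start = end
    region_track = AnnotationTrack(name="regions", intervals=region_intervals)

    alu_intervals: list[tuple[str, int, int, str]] = []
    if config.alu_fraction_of_genome > 0:
        for contig, length in layout.lengths.items():
            n_alu = int(round(config.alu_fraction_of_genome * length / config.alu_length))
            # draw non-overlapping placements from a disjoint-slot grid with
            # one element-length of guaranteed spacing
            slot = 2 * config.alu_length
            n_slots = length // slot
            if n_alu > n_slots:
                raise ValidationError(
                    f"cannot place {n_alu} Alu elements on contig {contig}"
                )
            chosen = rng.choice(n_slots, size=n_alu, replace=False)
            for s in np.sort(chosen):
                start = int(s * slot)
                alu_intervals.append((contig, start, start + config.alu_length, "Alu"))
    alu_track = AnnotationTrack(name="Alu", intervals=alu_intervals)
    return layout, region_track, alu_track


def _solve_overlap_probability(
    config: SimConfig, n_loci: int, n_alu: int, genome_size: int
) -> float:
    """Per-locus Alu-overlap probability q whose expected contingency table
    reproduces the target odds ratio under the genomic-space-adjusted test."""
    # inclusive mean interval lengths, matching the enrichment construction
    mean_locus = float(np.mean(config.locus_length_range)) + 1
    n_trials = math.floor(genome_size / (mean_locus + config.alu_length + 1))
    target = config.target_alu_odds_ratio

    def expected_log_or(q: float) -> float:
        n11 = q * n_loci
        n12 = (1 - q) * n_loci
        n21 = n_alu - n11
        n22 = n_trials - n_loci - n_alu + n11
        if n21 <= 0 or n22 <= 0:
            return math.inf
        return math.log(n11 * n22) - math.log(n12 * n21) - math.log(target)

    hi = min(1.0, n_alu / max(n_loci, 1)) - 1e-9
    if hi <= 1e-9 or expected_log_or(1e-9) > 0 or expected_log_or(hi) < 0:
        raise ValidationError(
            f"target Alu odds ratio {target} infeasible for {n_loci} loci, "
            f"{n_alu} Alu elements"
        )
    return float(brentq(expected_log_or, 1e-9, hi, xtol=1e-12))


def _plant_positions(
    config: SimConfig,
    layout: GenomeLayout,
    alu_track: AnnotationTrack,
    n_loci: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Plant locus intervals so P(Alu overlap) = q per locus, loci separated.

    Each locus independently overlaps an Alu with the solved probability q
    (overlapping placements target a uniformly chosen Alu element;
    non-overlapping placements are rejection-sampled from Alu-free space),
    which makes the planted odds ratio exact in expectation.
    """
    if n_loci == 0:
        return pd.DataFrame(columns=["contig", "start", "end", "alu_overlap"])
    alus = [(c, s, e) for c, s, e, _ in alu_track.intervals]
    if alus:
        q = _solve_overlap_probability(config, n_loci, len(alus), layout.total_size)
    else:
        if config.target_alu_odds_ratio != 1.0 and config.alu_fraction_of_genome > 0:
            raise ValidationError("no Alu space to plant the requested odds ratio")
        q = 0.0
    contigs = list(layout.lengths)
    contig_probs = np.array([layout.lengths[c] for c in contigs], dtype=float)
    contig_probs /= contig_probs.sum()
    import bisect

    # sorted-array overlap index over the (non-overlapping) Alu intervals
    alu_index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig in contigs:
        items = sorted((s, e) for c, s, e in alus if c == contig)
        alu_index[contig] = (
            np.array([s for s, _ in items]),
            np.maximum.accumulate(np.array([e for _, e in items]))
            if items
            else np.array([]),
        )

    def hits_any_alu(contig: str, start: int, end: int) -> bool:
        starts, max_ends = alu_index[contig]
        i = int(np.searchsorted(starts, end, side="left"))
        return i > 0 and bool(max_ends[i - 1] > start)

    # placed loci are mutually separated, so a neighbor check suffices
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    sep = config.min_locus_separation

    def conflicts(contig: str, start: int, end: int) -> bool:
        items = placed[contig]
        i = bisect.bisect_left(items, (start, end))
        if i > 0 and items[i - 1][1] + sep > start:
            return True
        return i < len(items) and items[i][0] - sep < end

    rows = []
    for _ in range(n_loci):
        loclen = int(rng.integers(config.locus_length_range[0], config.locus_length_range[1] + 1))
        overlap = bool(rng.random() < q)
        for _attempt in range(10_000):
            if overlap:
                contig, a_start, a_end = alus[int(rng.integers(len(alus)))]
                lo = max(0, a_start - loclen + 1)
                hi = min(layout.contig_length(contig) - loclen, a_end - 1)
                if hi < lo:
                    continue
                start = int(rng.integers(lo, hi + 1))
            else:
                contig = contigs[int(rng.choice(len(contigs), p=contig_probs))]
                start = int(rng.integers(0, layout.contig_length(contig) - loclen))
            end = start + loclen
            hits_alu = hits_any_alu(contig, start, end)
            if hits_alu != overlap:
                continue
            if conflicts(contig, start, end):
                continue
            bisect.insort(placed[contig], (start, end))
            rows.append({"contig": contig, "start": start, "end": end, "alu_overlap": overlap})
            break
        else:
            raise ValidationError("could not place loci; genome too crowded")
    return pd.DataFrame(rows)


_PAIR_CHOICES = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G")]


def _sample_motif(config: SimConfig, length: int, rng: np.random.Generator) -> str:
    """Random canonical primitive motif of the given length and configured
    unique-nucleotide / pair composition."""
    uniq_items = [(k, v) for k, v in config.unique_nt_weights.items() if k <= length]
    uw = np.array([v for _, v in uniq_items], dtype=float)
    n_uniq = uniq_items[int(rng.choice(len(uniq_items), p=uw / uw.sum()))][0]
    if n_uniq == 2:
        pair_items = list(config.pair_weights.items())
        pw = np.array([v for _, v in pair_items], dtype=float)
        alphabet = list(pair_items[int(rng.choice(len(pair_items), p=pw / pw.sum()))][0])
    else:
        alphabet = list(rng.choice(list("ACGT"), size=n_uniq, replace=False))
    for _ in range(1000):
        chars = [alphabet[int(i)] for i in rng.integers(0, len(alphabet), size=length)]
        motif = "".join(chars)
        if len(set(motif)) != len(alphabet) or not is_primitive(motif):
            continue
        return canonical_motif(motif)
    raise ValidationError(f"could not draw a primitive motif of length {length}")


def simulate_cohort(
    config: SimConfig,
    layout: GenomeLayout,
    region_track: AnnotationTrack,
    alu_track: AnnotationTrack,
) -> tuple[CohortMatrix, TruthManifest, AnnotationTrack]:
    """Plant loci and emit the cohort count matrix, truth and simple repeats.

    Carrier counts are drawn per planted frequency class; carrier allele
    lengths are log-uniform over the configured range (a modeling choice,
    not an empirical claim); the intended normalized count is
    ``round((length - intercept) / slope)`` plus optional integer noise,
    emitted as a raw count at the sample's own depth and normalized back, so
    depth normalization recovers the intended value.  Non-carriers receive
    sporadic background counts below the presence threshold.
    """
    rng_pos = _rng(config, "positions")
    rng_motif = _rng(config, "motifs")
    rng_carrier = _rng(config, "carriers")
    rng_emit = _rng(config, "emission")
    rng_depth = _rng(config, "depths")
    rng_ref = _rng(config, "reference_origin")

    n_loci = config.n_common_loci + config.n_rare_loci
    positions = _plant_positions(config, layout, alu_track, n_loci, rng_pos)
    classes = np.array(
        ["common"] * config.n_common_loci + ["rare"] * config.n_rare_loci, dtype=object
    )
    rng_pos.shuffle(classes)

    # distinct motifs cannot guarantee distinct loci keys alone; positions
    # are already unique by the separation constraint
    lengths = list(config.length_weights)
    lw = np.array([config.length_weights[l] for l in lengths], dtype=float)
    motif_lengths = [lengths[int(i)] for i in rng_motif.choice(len(lengths), size=n_loci, p=lw / lw.sum())]
    motifs = [_sample_motif(config, l, rng_motif) for l in motif_lengths]

    loci = [
        TRLocus(contig=row.contig, start=row.start, end=row.end, motif=motifs[i])
        for i, row in enumerate(positions.itertuples(index=False))
    ]

    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    depths = np.clip(
        rng_depth.normal(config.depth_mean, config.depth_sd, size=config.n_samples),
        config.depth_min,
        None,
    )

    cutoff = config.rare_cutoff
    rare_range = config.rare_occurrence_range or (1, max(1, cutoff))
    if config.n_rare_loci > 0 and rare_range[1] > cutoff:
        raise ValidationError(
            f"rare occurrence range {rare_range} exceeds the rare cutoff {cutoff} "
            f"(cohort too small to host rare loci at rare_fraction="
            f"{config.rare_fraction})"
        )
    lo_f, hi_f = config.common_frequency_range

    counts = np.zeros((n_loci, config.n_samples))
    # sporadic sub-threshold background everywhere first
    counts[:] = rng_emit.choice(config.background_counts, size=counts.shape)

    carrier_rows = []
    n_carriers = np.zeros(n_loci, dtype=int)
    intercept, slope = config.length_model_intercept, config.length_model_slope
    log_lo, log_hi = np.log(config.allele_length_range[0]), np.log(config.allele_length_range[1])
    for i in range(n_loci):
        if classes[i] == "rare":
            occ = int(rng_carrier.integers(rare_range[0], rare_range[1] + 1))
        else:
            freq = rng_carrier.uniform(lo_f, hi_f)
            occ = int(np.clip(round(freq * config.n_samples), cutoff + 1, config.n_samples))
        carriers = rng_carrier.choice(config.n_samples, size=occ, replace=False)
        n_carriers[i] = occ
        for j in carriers:
            allele = float(np.exp(rng_emit.uniform(log_lo, log_hi)))
            intended = round((allele - intercept) / slope)
            if config.emission_noise_sd > 0:
                intended += round(rng_emit.normal(0, config.emission_noise_sd))
            intended = max(0, intended)
            raw = intended * depths[j] / config.reference_depth
            counts[i, j] = normalize_counts(raw, depths[j], config.reference_depth)
            carrier_rows.append(
                {
                    "locus_index": i,
                    "sample": samples[j],
                    "allele_length": allele,
                    "intended_count": intended,
                }
            )
    # emission precision: makes the depth round trip exact at the TSV precision
    counts = np.round(counts, 9)

    # reference simple repeats under a configured fraction of loci
    ref_origin = rng_ref.random(n_loci) < config.reference_origin_fraction
    sr_intervals: list[tuple[str, int, int, str]] = []
    for i in np.flatnonzero(ref_origin):
        locus = loci[i]
        pad = int(rng_ref.integers(0, max(1, locus.length // 4)))
        unit = locus.motif
        roll = int(rng_ref.integers(len(unit)))
        unit = unit[roll:] + unit[:roll]
        if rng_ref.random() < 0.5:
            unit = unit.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        sr_intervals.append((locus.contig, locus.start + pad, locus.end, unit))
    # background reference repeats away from every planted locus
    locus_trees = AnnotationTrack(
        name="_loci",
        intervals=[(l.contig, l.start, l.end, "") for l in loci] or [("_", 0, 1, "")],
    )
    contigs = list(layout.lengths)
    contig_probs = np.array([layout.lengths[c] for c in contigs], dtype=float)
    contig_probs /= contig_probs.sum()
    guard = config.min_locus_separation // 2
    for _ in range(config.n_background_simple_repeats):
        for _attempt in range(1000):
            contig = contigs[int(rng_ref.choice(len(contigs), p=contig_probs))]
            srlen = int(rng_ref.integers(30, 200))
            start = int(rng_ref.integers(0, layout.contig_length(contig) - srlen))
            if locus_trees.overlaps(contig, max(0, start - guard), start + srlen + guard):
                continue
            unit = _sample_motif(config, int(rng_ref.choice([3, 4, 5, 6])), rng_ref)
            sr_intervals.append((contig, start, start + srlen, unit))
            break
    simple_repeats = AnnotationTrack(name="simple_repeats", intervals=sr_intervals)

    matrix = CohortMatrix(
        loci=loci,
        samples=samples,
        counts=counts,
        depths=depths,
        reference_depth=config.reference_depth,
    )
    locus_frame = pd.DataFrame(
        {
            "contig": [l.contig for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "motif": [l.motif for l in loci],
            "freq_class": classes,
            "n_carriers": n_carriers,
            "alu_overlap": positions["alu_overlap"].to_numpy() if len(positions) else [],
            "reference_origin": ref_origin,
        }
    )
    manifest = TruthManifest(
        loci=locus_frame,
        carriers=pd.DataFrame(
            carrier_rows,
            columns=["locus_index", "sample", "allele_length", "intended_count"],
        ),
        samples=pd.DataFrame({"sample": samples, "depth": depths}),
    )
    return matrix, manifest, simple_repeats


def plant_disease_expansion(
    matrix: CohortMatrix,
    manifest: TruthManifest,
    disease: DiseaseLocusDef,
    sample: str,
    repeats: float,
    layout: GenomeLayout | None = None,
) -> tuple[CohortMatrix, TruthManifest]:
    """Plant an expansion of the disease motif at a disease locus.

    Adds (or augments) a locus at the disease interval with the disease
    motif; the chosen sample receives the normalized count implied by the
    length model, ``round((repeats * motif_length - intercept) / slope)``.
    """
    if layout is not None:
        if disease.contig not in layout or disease.end > layout.contig_length(disease.contig):
            raise ValidationError(f"{disease.code}: locus outside layout")
    bases = repeats * len(disease.disease_motif)
    intercept, slope = 140.6, 7.7
    if bases <= intercept:
        raise ValidationError(
            f"{disease.code}: {repeats} repeats x {len(disease.disease_motif)} bp = "
            f"{bases} bases, at or below the length-model intercept {intercept}"
        )
    count = round((bases - intercept) / slope)
    if sample not in matrix.samples:
        raise ValidationError(f"unknown sample {sample!r}")
    j = matrix.samples.index(sample)
    locus = TRLocus(
        contig=disease.contig,
        start=disease.start,
        end=disease.end,
        motif=disease.disease_motif,
    )
    keys = [l.key for l in matrix.loci]
    if locus.key in keys:
        i = keys.index(locus.key)
        counts = matrix.counts.copy()
        counts[i, j] = count
        loci = matrix.loci
        loci_frame = manifest.loci.copy()
    else:
        i = matrix.n_loci
        loci = matrix.loci + [locus]
        counts = np.vstack([matrix.counts, np.zeros((1, matrix.n_samples))])
        counts[i, j] = count
        loci_frame = pd.concat(
            [
                manifest.loci,
                pd.DataFrame(
                    [
                        {
                            "contig": locus.contig,
                            "start": locus.start,
                            "end": locus.end,
                            "motif": locus.motif,
                            "freq_class": "rare",
                            "n_carriers": 1,
                            "alu_overlap": False,
                            "reference_origin": False,
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
    carriers = pd.concat(
        [
            manifest.carriers,
            pd.DataFrame(
                [
                    {
                        "locus_index": i,
                        "sample": sample,
                        "allele_length": float(bases),
                        "intended_count": count,
                    }
                ]
            ),
        ],
        ignore_index=True,
    )
    new_matrix = CohortMatrix(
        loci=loci,
        samples=matrix.samples,
        counts=counts,
        depths=matrix.depths,
        reference_depth=matrix.reference_depth,
    )
    new_manifest = TruthManifest(
        loci=loci_frame, carriers=carriers, samples=manifest.samples
    )
    return new_matrix, new_manifest


def synthetic_disease_catalog(layout: GenomeLayout) -> list[DiseaseLocusDef]:
    """Small synthetic stand-in catalog placed inside a synthetic layout.

    Mirrors the three motif situations of real disease loci — shared
    reference/disease motif (FRDA-like), mutated disease motif
    (CANVAS-like), and a locus where novel motifs may appear — at fixed
    positions on the synthetic contigs.
    """
    contig = layout.contigs[0]
    size = layout.contig_length(contig)
    spot = lambda frac, width: (int(size * frac), int(size * frac) + width)
    s1, e1 = spot(0.31, 20)
    s2, e2 = spot(0.62, 50)
    s3, e3 = spot(0.83, 40)
    return [
        DiseaseLocusDef(
            code="SYN_FRDA",
            name="synthetic shared-motif locus (FRDA-like)",
            inheritance="AR",
            contig=contig,
            start=s1,
            end=e1,
            reference_motif="GAA",
            disease_motif="GAA",
            normal_max_repeats=27,
            pathogenic_min_repeats=66,
        ),
        DiseaseLocusDef(
            code="SYN_CANVAS",
            name="synthetic mutated-motif locus (CANVAS-like)",
            inheritance="AR",
            contig=contig,
            start=s2,
            end=e2,
            reference_motif="AAAAG",
            disease_motif="AAGGG",
            pathogenic_min_repeats=400,
        ),
        DiseaseLocusDef(
            code="SYN_AD",
            name="synthetic dominant locus",
            inheritance="AD",
            contig=contig,
            start=s3,
            end=e3,
            reference_motif="CAG",
            disease_motif="CAG",
            normal_max_repeats=26,
            pathogenic_min_repeats=40,
        ),
    ]


def simulate_bundle(
    config: SimConfig,
    disease_plants: Sequence[tuple[DiseaseLocusDef, str, float]] = (),
) -> SimBundle:
    """Run the full generator: layout, tracks, cohort, optional disease plants."""
    layout, region_track, alu_track = simulate_layout_and_tracks(config)
    matrix, manifest, simple_repeats = simulate_cohort(
        config, layout, region_track, alu_track
    )
    catalog = []
    for definition, sample, repeats in disease_plants:
        matrix, manifest = plant_disease_expansion(
            matrix, manifest, definition, sample, repeats, layout=layout
        )
        if definition not in catalog:
            catalog.append(definition)
    return SimBundle(
        config=config,
        layout=layout,
        region_track=region_track,
        alu_track=alu_track,
        simple_repeats=simple_repeats,
        matrix=matrix,
        manifest=manifest,
        catalog=catalog,
    )


def write_bundle(bundle: SimBundle, out_dir) -> dict[str, Path]:
    """Write the bundle in the pipeline's input formats plus truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.tsv",
        "regions": out / "regions.bed",
        "alu": out / "alu.bed",
        "simple_repeats": out / "simple_repeats.tsv",
        "layout": out / "layout.tsv",
        "samples": out / "samples.tsv",
        "truth_loci": out / "truth_loci.tsv",
        "truth_carriers": out / "truth_carriers.tsv",
    }
    write_dense_matrix(bundle.matrix, paths["matrix"])
    write_bed_track(bundle.region_track, paths["regions"])
    write_bed_track(bundle.alu_track, paths["alu"])
    write_simple_repeats(bundle.simple_repeats, paths["simple_repeats"])
    write_layout(bundle.layout, paths["layout"])
    bundle.manifest.samples.to_csv(
        paths["samples"], sep="\t", index=False, float_format="%.9g"
    )
    bundle.manifest.loci.to_csv(
        paths["truth_loci"], sep="\t", index=False, float_format="%.9g"
    )
    bundle.manifest.carriers.to_csv(
        paths["truth_carriers"], sep="\t", index=False, float_format="%.9g"
    )
    if bundle.catalog:
        paths["catalog"] = out / "catalog.yaml"
        write_disease_catalog(bundle.catalog, paths["catalog"])
    return paths
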