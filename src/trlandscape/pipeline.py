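"""End-to-end pipeline: from a count matrix (or a simulation) to the full
set of report tables — frequency classes, per-genome counts, occurrence
spectra, saturation curves, region/Alu enrichment, motif profiles,
reference-origin percentages and the disease screen."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    DEFAULT_PRESENCE_THRESHOLD,
    DEFAULT_RARE_FRACTION,
    call_presence,
    classify_frequency,
    occurrence_spectrum,
    per_genome_counts,
)
from .core import (
    DEFAULT_REFERENCE_DEPTH,
    AnnotationTrack,
    CohortMatrix,
    GenomeLayout,
    ValidationError,
)
from .disease import DEFAULT_LENGTH_MODEL, DEFAULT_SCREEN_SLOP, screen_cohort, screen_to_frame
from .enrichment import assign_regions, enrich_category, flag_alu_overlaps
from .io import (
    read_bed_track,
    read_dense_matrix,
    read_disease_catalog,
    read_layout,
    read_simple_repeats,
)
from .motifs import motif_profile_tables
from .origin import match_references, percent_from_reference
from .saturation import (
    DEFAULT_K_LAST,
    DEFAULT_SATURATION_ITERATIONS,
    residual_discovery_rate,
    saturation_curve,
)

logger = logging.getLogger("trlandscape")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output directory for one pipeline run."""

    out_dir: str | Path
    matrix: str | Path | None = None
    regions: str | Path | None = None
    alu: str | Path | None = None
    simple_repeats: str | Path | None = None
    catalog: str | Path | None = None
    layout: str | Path | None = None
    sample_manifest: str | Path | None = None
    genome_size: int | None = None
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD
    rare_fraction: float = DEFAULT_RARE_FRACTION
    reference_depth: float = DEFAULT_REFERENCE_DEPTH
    saturation_iterations: int = DEFAULT_SATURATION_ITERATIONS
    saturation_seed: int = 1
    k_last: int = DEFAULT_K_LAST
    screen_slop: int = DEFAULT_SCREEN_SLOP
    simulate: object | None = None  # SimConfig; overrides file inputs

    def input_paths(self) -> dict[str, Path]:
        paths = {}
        for name in ("matrix", "regions", "alu", "simple_repeats", "catalog",
                     "layout", "sample_manifest"):
            value = getattr(self, name)
            if value is not None:
                paths[name] = Path(value)
        return paths


def _checksum(path: Path) -> str:
    digest = hashlib.md5()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _write(frame: pd.DataFrame, path: Path, written: list[Path], index=False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.9g")
    written.append(path)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every analysis stage and write one TSV per report table.

    Deterministic given the config (including seeds).  Stages whose inputs
    are absent (no Alu track, no catalog, ...) are skipped with a warning;
    any stage error removes the partial outputs and re-raises with a
    stage-identifying message.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    outputs: dict[str, Path] = {}
    stage = "load"
    try:
        bundle = None
        if config.simulate is not None:
            from .simulate import simulate_bundle

            bundle = simulate_bundle(config.simulate)
            matrix = bundle.matrix
            layout: GenomeLayout | None = bundle.layout
            region_track: AnnotationTrack | None = bundle.region_track
            alu_track: AnnotationTrack | None = bundle.alu_track
            simple_repeats: AnnotationTrack | None = bundle.simple_repeats
            catalog = bundle.catalog or None
        else:
            if config.matrix is None:
                raise ValidationError("either a matrix path or a simulate config is required")
            matrix = read_dense_matrix(
                config.matrix,
                sample_manifest=config.sample_manifest,
                reference_depth=config.reference_depth,
            )
            layout = read_layout(config.layout) if config.layout else None
            region_track = (
                read_bed_track(config.regions, name="regions", layout=layout)
                if config.regions
                else None
            )
            alu_track = (
                read_bed_track(config.alu, name="Alu", layout=layout)
                if config.alu
                else None
            )
            simple_repeats = (
                read_simple_repeats(config.simple_repeats)
                if config.simple_repeats
                else None
            )
            catalog = read_disease_catalog(config.catalog) if config.catalog else None
        genome_size = config.genome_size or (layout.total_size if layout else None)

        stage = "classify"
        presence = call_presence(matrix, threshold=config.presence_threshold)
        classification = classify_frequency(presence, rare_fraction=config.rare_fraction)
        outputs["classification"] = out_dir / "classification.tsv"
        _write(classification.to_frame(), outputs["classification"], written)

        categories: dict[str, np.ndarray] = {
            "frequency": classification.classes.astype(object)
        }
        if region_track is not None:
            categories["region"] = assign_regions(matrix.loci, region_track, layout=layout)
        else:
            logger.warning("no region track; region analyses skipped")
        if alu_track is not None:
            alu_flags = flag_alu_overlaps(matrix.loci, alu_track)
            categories["alu"] = np.where(alu_flags, "Alu", "non-Alu").astype(object)
        else:
            alu_flags = None
            logger.warning("no Alu track; Alu analyses skipped")

        stage = "per_genome_counts"
        count_frames = []
        summary_frames = []
        for scheme, labels in categories.items():
            counts, summary = per_genome_counts(presence, labels)
            counts.insert(0, "scheme", scheme)
            summary.insert(0, "scheme", scheme)
            count_frames.append(counts.reset_index())
            summary_frames.append(summary.reset_index())
        outputs["per_genome_counts"] = out_dir / "per_genome_counts.tsv"
        _write(pd.concat(count_frames, ignore_index=True), outputs["per_genome_counts"], written)
        outputs["per_genome_summary"] = out_dir / "per_genome_summary.tsv"
        _write(pd.concat(summary_frames, ignore_index=True), outputs["per_genome_summary"], written)

        stage = "spectrum"
        spectrum_rows = []
        for scheme, labels in categories.items():
            for label in sorted(set(labels)):
                sub = presence.restrict(np.asarray(labels) == label)
                spec = occurrence_spectrum(sub)
                frame = spec.table.copy()
                frame.insert(0, "category", label)
                frame.insert(0, "scheme", scheme)
                frame["singleton_fraction"] = spec.singleton_fraction
                spectrum_rows.append(frame)
        outputs["spectrum"] = out_dir / "spectrum.tsv"
        _write(pd.concat(spectrum_rows, ignore_index=True), outputs["spectrum"], written)

        stage = "saturation"
        curve_rows = []
        rate_rows = []
        for scheme, labels in categories.items():
            for label in sorted(set(labels)):
                sub = presence.restrict(np.asarray(labels) == label)
                curve = saturation_curve(
                    sub,
                    n_iterations=config.saturation_iterations,
                    seed=config.saturation_seed,
                    label=label,
                )
                curve_rows.append(
                    pd.DataFrame(
                        {
                            "scheme": scheme,
                            "category": label,
                            "position": np.arange(1, curve.n_samples + 1),
                            "mean_cumulative": curve.mean_cumulative,
                        }
                    )
                )
                if curve.n_samples > config.k_last:
                    rate = residual_discovery_rate(curve, k_last=config.k_last)
                    rate_rows.append(
                        {"scheme": scheme, "category": label, "residual_rate": rate}
                    )
        outputs["saturation"] = out_dir / "saturation.tsv"
        _write(pd.concat(curve_rows, ignore_index=True), outputs["saturation"], written)
        if rate_rows:
            outputs["residual_rates"] = out_dir / "residual_rates.tsv"
            _write(pd.DataFrame(rate_rows), outputs["residual_rates"], written)

        stage = "enrichment"
        if genome_size is not None and (region_track is not None or alu_track is not None):
            enrich_rows = []

            def add_enrichment(dataset: str, loci, track: AnnotationTrack, label: str) -> None:
                try:
                    result = enrich_category(loci, None, track, genome_size, category=label)
                except ValidationError as exc:
                    logger.warning("enrichment %s/%s skipped: %s", dataset, label, exc)
                    return
                table = result.table
                enrich_rows.append(
                    {
                        "dataset": dataset,
                        "category": label,
                        "n11": table.n11,
                        "n12": table.n12,
                        "n21": table.n21,
                        "n22": table.n22,
                        "n_trials": table.n_trials,
                        "odds_ratio": result.odds_ratio if result.defined else float("nan"),
                        "p_two_sided": result.p_two_sided if result.defined else float("nan"),
                        "defined": table.defined,
                    }
                )

            datasets = {"cohort": matrix.loci}
            if simple_repeats is not None:
                datasets["reference_repeats"] = [
                    (c, s, e) for c, s, e, _ in simple_repeats.intervals
                ]
            for dataset, loci in datasets.items():
                if region_track is not None:
                    for label in sorted(region_track.labels):
                        track = AnnotationTrack(
                            name=label,
                            intervals=[
                                iv for iv in region_track.intervals if iv[3] == label
                            ],
                        )
                        add_enrichment(dataset, loci, track, label)
                if alu_track is not None and len(alu_track):
                    add_enrichment(dataset, loci, alu_track, "Alu")
            outputs["enrichment"] = out_dir / "enrichment.tsv"
            _write(pd.DataFrame(enrich_rows), outputs["enrichment"], written)
        else:
            logger.warning("enrichment skipped (needs genome size and a track)")

        stage = "motifs"
        motif_groups: dict[str, list[str]] = {}
        for scheme, labels in categories.items():
            for label in sorted(set(labels)):
                mask = np.asarray(labels) == label
                motif_groups[label] = [
                    l.canonical for l, m in zip(matrix.loci, mask) if m
                ]
        motif_groups["dataset"] = [l.canonical for l in matrix.loci]
        if simple_repeats is not None:
            motif_groups["reference"] = [u for *_, u in simple_repeats.intervals]
        tables = motif_profile_tables(motif_groups)
        motif_frames = []
        for dimension, frame in tables.items():
            long = frame.reset_index().melt(
                id_vars="bin", var_name="category", value_name="frequency"
            )
            long.insert(0, "dimension", dimension)
            motif_frames.append(long)
        outputs["motif_tables"] = out_dir / "motif_tables.tsv"
        _write(pd.concat(motif_frames, ignore_index=True), outputs["motif_tables"], written)

        stage = "origin"
        if simple_repeats is not None:
            calls = match_references(matrix.loci, simple_repeats)
            origin_frames = []
            for scheme, labels in categories.items():
                frame = percent_from_reference(calls, labels).reset_index()
                frame.insert(0, "scheme", scheme)
                origin_frames.append(frame)
            overall = percent_from_reference(calls).reset_index()
            overall.insert(0, "scheme", "all")
            origin_frames.append(overall)
            outputs["origin"] = out_dir / "origin.tsv"
            _write(pd.concat(origin_frames, ignore_index=True), outputs["origin"], written)
        else:
            logger.warning("no simple-repeats table; origin analysis skipped")

        stage = "screen"
        if catalog:
            results = screen_cohort(
                matrix,
                catalog,
                model=DEFAULT_LENGTH_MODEL,
                threshold=config.presence_threshold,
                slop=config.screen_slop,
                layout=layout,
            )
            outputs["screen"] = out_dir / "screen.tsv"
            _write(screen_to_frame(results), outputs["screen"], written)
        else:
            logger.warning("no disease catalog; screening skipped")

        stage = "manifest"
        manifest = {
            "version": __version__,
            "parameters": {
                "presence_threshold": config.presence_threshold,
                "rare_fraction": config.rare_fraction,
                "reference_depth": config.reference_depth,
                "saturation_iterations": config.saturation_iterations,
                "saturation_seed": config.saturation_seed,
                "k_last": config.k_last,
                "screen_slop": config.screen_slop,
                "genome_size": genome_size,
            },
            "inputs": {
                name: {"path": str(path), "md5": _checksum(path)}
                for name, path in config.input_paths().items()
            },
            "n_loci": matrix.n_loci,
            "n_samples": matrix.n_samples,
            "outputs": {name: path.name for name, path in outputs.items()},
        }
        manifest_path = out_dir / "run_manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(manifest_path)
        outputs["run_manifest"] = manifest_path
        return outputs
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
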