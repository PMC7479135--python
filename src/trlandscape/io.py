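"""Readers and writers for the external formats the pipeline touches.

Formats: the dense locus x sample TSV of depth-normalized anchored IRR
counts (header ``contig  start  end  motif  <sample>...``), BED3/BED4
annotation tracks, UCSC SimpleRepeats-style tables, and the YAML disease
catalog.  All validation errors identify the offending row.
"""

from __future__ import annotations

import importlib.resources
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    DEFAULT_REFERENCE_DEPTH,
    AnnotationTrack,
    CohortMatrix,
    DiseaseLocusDef,
    GenomeLayout,
    TRLocus,
    ValidationError,
)
from .motifs import MotifError, MOTIF_LENGTH_RANGE

__all__ = [
    "read_dense_matrix",
    "write_dense_matrix",
    "read_bed_track",
    "write_bed_track",
    "read_simple_repeats",
    "write_simple_repeats",
    "read_disease_catalog",
    "write_disease_catalog",
    "default_disease_catalog",
    "read_layout",
    "write_layout",
    "read_sample_manifest",
]

REQUIRED_MATRIX_COLUMNS = ("contig", "start", "end", "motif")

#: Annotation columns sometimes present ahead of the sample columns in
#: deposited matrices; dropped by name if found.
DEFAULT_IGNORED_COLUMNS = ("chrom", "chr", "gene", "region", "annotation", "canonical_motif")


def read_sample_manifest(source) -> dict[str, float]:
    """Sample -> fold-coverage mapping from a dict, DataFrame or 2-column TSV."""
    if isinstance(source, Mapping):
        table = pd.DataFrame(
            {"sample": list(source), "depth": list(source.values())}
        )
    elif isinstance(source, pd.DataFrame):
        table = source
    else:
        table = pd.read_csv(source, sep="\t")
    if not {"sample", "depth"}.issubset(table.columns):
        raise ValidationError("sample manifest needs columns 'sample' and 'depth'")
    depths = {str(s): float(d) for s, d in zip(table["sample"], table["depth"])}
    for sample, depth in depths.items():
        if not depth > 0:
            raise ValidationError(f"sample {sample!r} has non-positive depth {depth}")
    return depths


def read_dense_matrix(
    path,
    sample_manifest=None,
    reference_depth: float = DEFAULT_REFERENCE_DEPTH,
    ignore_columns: Sequence[str] = DEFAULT_IGNORED_COLUMNS,
) -> CohortMatrix:
    """Read a dense locus x sample TSV of depth-normalized IRR counts.

    The first four recognized columns must be ``contig, start, end, motif``;
    every remaining column (after dropping any named in ``ignore_columns``)
    is taken as a sample.  Missing cells read as 0.  Without a manifest all
    samples are assigned ``reference_depth``, making normalization the
    identity.
    """
    table = pd.read_csv(path, sep="\t", dtype={"contig": str})
    table.columns = [str(c) for c in table.columns]
    missing = [c for c in REQUIRED_MATRIX_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    drop = [c for c in ignore_columns if c in table.columns]
    sample_cols = [
        c for c in table.columns if c not in REQUIRED_MATRIX_COLUMNS and c not in drop
    ]
    loci: list[TRLocus] = []
    seen: dict[tuple, int] = {}
    for row_no, row in enumerate(table.itertuples(index=False), start=2):
        try:
            locus = TRLocus(
                contig=str(row.contig),
                start=int(row.start),
                end=int(row.end),
                motif=str(row.motif),
            )
        except (MotifError, ValidationError, TypeError, OverflowError) as exc:
            raise ValidationError(f"{path}: row {row_no}: {exc}") from exc
        if locus.key in seen:
            raise ValidationError(
                f"{path}: row {row_no}: duplicate locus {locus.key} "
                f"(first at row {seen[locus.key]})"
            )
        seen[locus.key] = row_no
        loci.append(locus)
    counts = table[sample_cols].apply(pd.to_numeric, errors="coerce")
    counts = counts.fillna(0.0).to_numpy(dtype=float)
    if counts.size and counts.min() < 0:
        i, j = np.argwhere(counts < 0)[0]
        raise ValidationError(
            f"{path}: row {i + 2}: negative count for sample {sample_cols[j]!r}"
        )
    depths = None
    if sample_manifest is not None:
        manifest = read_sample_manifest(sample_manifest)
        depths = np.array(
            [manifest.get(s, float(reference_depth)) for s in sample_cols]
        )
    return CohortMatrix(
        loci=loci,
        samples=sample_cols,
        counts=counts,
        depths=depths,
        reference_depth=reference_depth,
    )


def write_dense_matrix(matrix: CohortMatrix, path, float_format: str = "%.9g") -> None:
    """Write a cohort matrix as TSV at fixed precision (round-trip stable)."""
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format=float_format)


def read_bed_track(
    path,
    name: str,
    label_column: int | None = None,
    layout: GenomeLayout | None = None,
) -> AnnotationTrack:
    """Read a BED3/BED4+ file as an annotation track (0-based half-open).

    For BED3 the label defaults to the track name; for BED4+ the fourth
    column (or ``label_column``, 0-based) supplies the label.
    """
    rows = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}: line {line_no}: fewer than 3 BED fields")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: line {line_no}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise ValidationError(
                    f"{path}: line {line_no}: invalid interval [{start}, {end})"
                )
            col = label_column if label_column is not None else 3
            label = fields[col] if len(fields) > col else name
            rows.append((contig, start, end, label))
    track = AnnotationTrack(name=name, intervals=rows)
    if layout is not None:
        track.validate_against(layout)
    return track


def write_bed_track(track: AnnotationTrack, path) -> None:
    with open(path, "w") as handle:
        for contig, start, end, label in track.intervals:
            handle.write(f"{contig}\t{start}\t{end}\t{label}\n")


_SIMPLE_REPEAT_MOTIF_COLUMNS = ("sequence", "motif", "unit")


def read_simple_repeats(path, name: str = "simple_repeats") -> AnnotationTrack:
    """Read a UCSC SimpleRepeats-style TSV as a motif-labeled track.

    Requires columns ``chrom``/``contig``, ``chromStart``/``start``,
    ``chromEnd``/``end`` and a repeat-unit column (``sequence``, ``motif`` or
    ``unit``).  Only records with ACGT units of 3-8 bp are retained (to match
    the unit-length window of the cohort); units are upper-cased.  chromStart
    is already 0-based and adopted as-is.
    """
    table = pd.read_csv(path, sep="\t")
    table.columns = [str(c) for c in table.columns]
    renames = {"chrom": "contig", "chromStart": "start", "chromEnd": "end"}
    table = table.rename(columns=renames)
    motif_col = next(
        (c for c in _SIMPLE_REPEAT_MOTIF_COLUMNS if c in table.columns), None
    )
    if motif_col is None:
        raise ValidationError(
            f"{path}: no repeat-unit column (expected one of "
            f"{_SIMPLE_REPEAT_MOTIF_COLUMNS})"
        )
    missing = [c for c in ("contig", "start", "end") if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    lo, hi = MOTIF_LENGTH_RANGE
    rows = []
    for row_no, row in enumerate(table.itertuples(index=False), start=2):
        unit = str(getattr(row, motif_col)).upper()
        if not (lo <= len(unit) <= hi) or set(unit) - set("ACGT"):
            continue
        start, end = int(row.start), int(row.end)
        if start < 0 or start >= end:
            raise ValidationError(f"{path}: row {row_no}: invalid interval")
        rows.append((str(row.contig), start, end, unit))
    return AnnotationTrack(name=name, intervals=rows)


def write_simple_repeats(track: AnnotationTrack, path) -> None:
    frame = track.to_frame().rename(
        columns={"contig": "chrom", "start": "chromStart", "end": "chromEnd",
                 "label": "sequence"}
    )
    frame.to_csv(path, sep="\t", index=False)


def _catalog_from_records(records, source) -> list[DiseaseLocusDef]:
    defs = []
    for rec in records:
        try:
            defs.append(
                DiseaseLocusDef(
                    code=str(rec["code"]),
                    name=str(rec.get("name", rec["code"])),
                    inheritance=str(rec["inheritance"]),
                    contig=str(rec["contig"]),
                    start=int(rec["start"]),
                    end=int(rec["end"]),
                    reference_motif=str(rec["reference_motif"]),
                    disease_motif=str(rec["disease_motif"]),
                    normal_max_repeats=rec.get("normal_max_repeats"),
                    pathogenic_min_repeats=rec.get("pathogenic_min_repeats"),
                    pathogenic_min_contested=rec.get("pathogenic_min_contested"),
                    notes=str(rec.get("notes", "")),
                )
            )
        except (KeyError, MotifError, ValidationError) as exc:
            raise ValidationError(
                f"{source}: invalid catalog entry {rec.get('code', rec)!r}: {exc}"
            ) from exc
    return defs


def read_disease_catalog(path) -> list[DiseaseLocusDef]:
    """Read a YAML disease catalog (``diseases:`` list of locus records)."""
    with open(path) as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, dict) or "diseases" not in doc:
        raise ValidationError(f"{path}: expected a mapping with a 'diseases' list")
    return _catalog_from_records(doc["diseases"], path)


def write_disease_catalog(catalog: Sequence[DiseaseLocusDef], path) -> None:
    records = []
    for d in catalog:
        rec = {
            "code": d.code,
            "name": d.name,
            "inheritance": d.inheritance,
            "contig": d.contig,
            "start": d.start,
            "end": d.end,
            "reference_motif": d.reference_motif,
            "disease_motif": d.disease_motif,
        }
        for key in ("normal_max_repeats", "pathogenic_min_repeats",
                    "pathogenic_min_contested"):
            value = getattr(d, key)
            if value is not None:
                rec[key] = value
        if d.notes:
            rec["notes"] = d.notes
        records.append(rec)
    with open(path, "w") as handle:
        yaml.safe_dump({"diseases": records}, handle, sort_keys=False)


def default_disease_catalog() -> list[DiseaseLocusDef]:
    """The shipped catalog of known repeat-expansion disease loci (GRCh37)."""
    ref = importlib.resources.files("trlandscape.data") / "disease_catalog.yaml"
    doc = yaml.safe_load(ref.read_text())
    return _catalog_from_records(doc["diseases"], "default catalog")


def read_layout(path) -> GenomeLayout:
    """Read a 2-column TSV (contig, length) as a genome layout."""
    table = pd.read_csv(path, sep="\t", dtype={"contig": str})
    if not {"contig", "length"}.issubset(table.columns):
        raise ValidationError(f"{path}: layout needs columns 'contig' and 'length'")
    return GenomeLayout({str(c): int(l) for c, l in zip(table["contig"], table["length"])})


def write_layout(layout: GenomeLayout, path) -> None:
    pd.DataFrame(
        {"contig": list(layout.lengths), "length": list(layout.lengths.values())}
    ).to_csv(path, sep="\t", index=False)
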