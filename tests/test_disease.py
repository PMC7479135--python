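"""Length model, motif classification at disease loci, cohort screening."""

import numpy as np
import pytest

import trlandscape as tl
from trlandscape.core import DiseaseLocusDef, ValidationError
from trlandscape.disease import (
    DISEASE_ONLY,
    NEITHER,
    REF_EQ_DISEASE,
    REF_ONLY,
    LengthModel,
    calibrate_model,
    classify_motif_at_locus,
    estimate_length,
    estimate_repeats,
    screen_cohort,
)


def test_length_model_evaluation():
    assert estimate_length(5) == pytest.approx(179.1)
    assert estimate_length(0) == pytest.approx(140.6)
    assert estimate_repeats(20, motif_length=3) == pytest.approx(294.6 / 3)


def test_length_model_rejects_negative_count_and_slope():
    with pytest.raises(ValidationError):
        estimate_length(-1)
    with pytest.raises(ValidationError):
        LengthModel(slope=0)


def test_length_model_monotonicity():
    counts = np.arange(0, 50)
    lengths = estimate_length(counts)
    assert np.all(np.diff(lengths) > 0)
    assert estimate_repeats(10, 3) > estimate_repeats(10, 6)


CANVAS = DiseaseLocusDef(
    code="CANVAS", name="", inheritance="AR", contig="4", start=100, end=200,
    reference_motif="AAAAG", disease_motif="AAGGG", pathogenic_min_repeats=400,
)
FRDA = DiseaseLocusDef(
    code="FRDA", name="", inheritance="AR", contig="9", start=100, end=200,
    reference_motif="GAA", disease_motif="GAA", normal_max_repeats=27,
    pathogenic_min_repeats=66,
)
SCA31 = DiseaseLocusDef(
    code="SCA31", name="", inheritance="AD", contig="16", start=100, end=200,
    reference_motif="TAAAA", disease_motif="TGGAA",
)


@pytest.mark.parametrize(
    "definition, observed, category",
    [
        (CANVAS, "AAGGG", DISEASE_ONLY),     # mutated disease motif, not the reference
        (CANVAS, "AAAAG", REF_ONLY),
        (FRDA, "AAG", REF_EQ_DISEASE),
        (FRDA, "GAA", REF_EQ_DISEASE),       # rotation of the same motif
        (SCA31, "AAACT", NEITHER),           # novel motif at the locus
        (SCA31, "TGGAA", DISEASE_ONLY),
    ],
)
def test_motif_classification_at_disease_loci(definition, observed, category):
    assert classify_motif_at_locus(observed, definition) == category


def test_calibration_noiseless_round_trip():
    counts = np.arange(1, 40, dtype=float)
    bases = 140.6 + 7.7 * counts
    model = calibrate_model(list(zip(bases, counts)))
    assert model.intercept == pytest.approx(140.6, abs=1e-9)
    assert model.slope == pytest.approx(7.7, abs=1e-9)
    assert model.rho["locus"] == 1.0


def test_calibration_with_noise_recovers_within_5_percent():
    rng = np.random.default_rng(42)
    counts = rng.uniform(1, 100, size=200)
    bases = 140.6 + 7.7 * counts + rng.normal(0, 5, size=200)
    model = calibrate_model(list(zip(bases, counts)))
    assert model.intercept == pytest.approx(140.6, rel=0.05)
    assert model.slope == pytest.approx(7.7, rel=0.05)


def test_calibration_averages_over_loci_and_reports_rho():
    per_locus = {
        "a": [(140.6 + 7.0 * c, c) for c in range(1, 10)],
        "b": [(140.6 + 8.4 * c, c) for c in range(1, 10)],
    }
    model = calibrate_model(per_locus)
    assert model.slope == pytest.approx(7.7, abs=1e-9)
    assert set(model.rho) == {"a", "b"}
    assert all(r == 1.0 for r in model.rho.values())


def test_calibration_rejects_degenerate_designs():
    with pytest.raises(ValidationError):
        calibrate_model([(150.0, 5.0), (160.0, 6.0)])  # too few pairs
    with pytest.raises(ValidationError):
        calibrate_model([(150.0, 5.0), (160.0, 5.0), (170.0, 5.0)])  # equal counts


def test_screen_flags_planted_pathogenic_expansion(bundle):
    catalog = tl.synthetic_disease_catalog(bundle.layout)
    frda = next(d for d in catalog if d.code == "SYN_FRDA")
    sample = bundle.matrix.samples[0]
    matrix, _ = tl.plant_disease_expansion(
        bundle.matrix, bundle.manifest, frda, sample, repeats=101
    )
    results = [r for r in screen_cohort(matrix, [frda]) if r.sample == sample
               and r.start == frda.start]
    assert len(results) == 1
    result = results[0]
    assert result.motif_category == REF_EQ_DISEASE
    assert result.pathogenic is True
    assert result.carrier_only is True  # recessive: carrier interpretation only
    assert result.estimated_repeats == pytest.approx((140.6 + 7.7 * 21) / 3, abs=0.05)


def test_screen_ignores_subthreshold_counts(bundle):
    catalog = tl.synthetic_disease_catalog(bundle.layout)
    frda = next(d for d in catalog if d.code == "SYN_FRDA")
    matrix, _ = tl.plant_disease_expansion(
        bundle.matrix, bundle.manifest, frda, bundle.matrix.samples[0], repeats=101
    )
    assert screen_cohort(matrix, [frda], threshold=50.0) == []


def test_screen_novel_motif_is_not_assessable(bundle):
    catalog = tl.synthetic_disease_catalog(bundle.layout)
    canvas = next(d for d in catalog if d.code == "SYN_CANVAS")
    novel = DiseaseLocusDef(
        code=canvas.code, name=canvas.name, inheritance=canvas.inheritance,
        contig=canvas.contig, start=canvas.start, end=canvas.end,
        reference_motif=canvas.reference_motif, disease_motif="AACCG",
        pathogenic_min_repeats=canvas.pathogenic_min_repeats,
    )
    matrix, _ = tl.plant_disease_expansion(
        bundle.matrix, bundle.manifest, novel, bundle.matrix.samples[3], repeats=500
    )
    results = [r for r in screen_cohort(matrix, [canvas])
               if r.sample == bundle.matrix.samples[3] and r.start == canvas.start]
    assert len(results) == 1
    assert results[0].motif_category == NEITHER
    assert results[0].pathogenic is None


def test_screen_rejects_catalog_locus_outside_layout(bundle):
    bad = DiseaseLocusDef(
        code="X", name="", inheritance="AD", contig="99", start=0, end=10,
        reference_motif="AAG", disease_motif="AAG",
    )
    with pytest.raises(ValidationError):
        screen_cohort(bundle.matrix, [bad], layout=bundle.layout)
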