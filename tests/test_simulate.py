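"""Synthetic-data generator: determinism, planted truth, emission model."""

import dataclasses
import filecmp

import numpy as np
import pytest

import trlandscape as tl
from trlandscape.core import ValidationError
from trlandscape.simulate import (
    SimConfig,
    plant_disease_expansion,
    simulate_bundle,
    simulate_layout_and_tracks,
    write_bundle,
)


def test_identical_config_gives_byte_identical_bundles(tmp_path):
    config = SimConfig(seed=21, n_samples=120, n_common_loci=20, n_rare_loci=40)
    paths_a = write_bundle(simulate_bundle(config), tmp_path / "a")
    paths_b = write_bundle(simulate_bundle(config), tmp_path / "b")
    assert set(paths_a) == set(paths_b)
    for name in paths_a:
        assert filecmp.cmp(paths_a[name], paths_b[name], shallow=False), name


def test_alu_track_covers_configured_fraction():
    config = SimConfig(seed=1, contigs={"1": 10_000_000})
    layout, _, alu = simulate_layout_and_tracks(config)
    fraction = alu.coverage_bp() / layout.total_size
    assert 0.10 <= fraction <= 0.12


def test_zero_alu_fraction_gives_empty_track():
    config = SimConfig(seed=1, alu_fraction_of_genome=0.0, target_alu_odds_ratio=1.0)
    _, _, alu = simulate_layout_and_tracks(config)
    assert len(alu) == 0


def test_zero_exon_fraction_means_no_exon_assignment():
    fractions = {"intergenic": 0.6, "intron": 0.37, "promoter": 0.02, "exon": 0.0, "TTS": 0.01}
    config = SimConfig(seed=5, region_fractions=fractions)
    bundle = simulate_bundle(config)
    labels = tl.assign_regions(bundle.matrix.loci, bundle.region_track)
    assert "exon" not in set(labels)


def test_region_fractions_over_one_rejected():
    with pytest.raises(ValidationError):
        SimConfig(region_fractions={"intergenic": 0.8, "intron": 0.5})


def test_emission_inverts_length_model_exactly(bundle):
    """A carrier allele of 179.1 bp at 40x must emit a normalized count of 5."""
    config = bundle.config
    depth = 40.0
    intended = round((179.1 - config.length_model_intercept) / config.length_model_slope)
    assert intended == 5
    raw = intended * depth / config.reference_depth
    assert tl.normalize_counts(raw, depth, config.reference_depth) == 5.0


def test_carrier_counts_recover_intended_values_after_depth_round_trip(bundle):
    samples = {s: j for j, s in enumerate(bundle.matrix.samples)}
    carriers = bundle.manifest.carriers
    for row in carriers.itertuples(index=False):
        value = bundle.matrix.counts[row.locus_index, samples[row.sample]]
        assert value == float(row.intended_count)


def test_no_rare_loci_config_yields_only_common_truth():
    config = SimConfig(seed=9, n_rare_loci=0, n_common_loci=25, n_samples=50)
    bundle = simulate_bundle(config)
    assert set(bundle.manifest.loci["freq_class"]) == {"common"}


def test_noise_free_classification_matches_truth(bundle, presence):
    classes = tl.classify_frequency(presence)
    np.testing.assert_array_equal(
        classes.classes, bundle.manifest.loci["freq_class"].to_numpy()
    )


def test_alu_flags_match_truth(bundle):
    flags = tl.flag_alu_overlaps(bundle.matrix.loci, bundle.alu_track)
    np.testing.assert_array_equal(
        flags, bundle.manifest.loci["alu_overlap"].to_numpy()
    )


def test_reference_origin_flags_match_truth(bundle):
    calls = tl.match_references(bundle.matrix.loci, bundle.simple_repeats)
    matched = np.array([c.matched for c in calls])
    np.testing.assert_array_equal(
        matched, bundle.manifest.loci["reference_origin"].to_numpy()
    )


def test_model_recovery_from_emitted_pairs(bundle):
    """Fitting the emitted (allele length, count) pairs recovers the length
    model within 5% despite integer rounding of counts."""
    carriers = bundle.manifest.carriers
    pairs = list(zip(carriers["allele_length"], carriers["intended_count"]))
    assert len(pairs) >= 200
    model = tl.calibrate_model(pairs)
    assert model.intercept == pytest.approx(bundle.config.length_model_intercept, rel=0.05)
    assert model.slope == pytest.approx(bundle.config.length_model_slope, rel=0.05)


def test_plant_disease_expansion_count_and_boundary(bundle):
    catalog = tl.synthetic_disease_catalog(bundle.layout)
    frda = next(d for d in catalog if d.code == "SYN_FRDA")
    sample = bundle.matrix.samples[7]
    matrix, manifest = plant_disease_expansion(
        bundle.matrix, bundle.manifest, frda, sample, repeats=101
    )
    i = [l.key for l in matrix.loci].index((frda.contig, frda.start, frda.end, "AAG"))
    j = matrix.samples.index(sample)
    assert matrix.counts[i, j] == round((101 * 3 - 140.6) / 7.7) == 21
    assert len(manifest.carriers) == len(bundle.manifest.carriers) + 1
    # exactly at the intercept: below model support
    with pytest.raises(ValidationError):
        plant_disease_expansion(
            bundle.matrix, bundle.manifest, frda, sample, repeats=140.6 / 3
        )


def test_infeasible_alu_odds_ratio_rejected():
    config = SimConfig(seed=2, target_alu_odds_ratio=500.0, n_common_loci=2000,
                       n_rare_loci=2000)
    with pytest.raises(ValidationError):
        simulate_bundle(config)


def test_rare_occurrence_range_must_stay_below_cutoff():
    config = SimConfig(seed=2, rare_occurrence_range=(1, 10), n_samples=100)
    with pytest.raises(ValidationError):
        simulate_bundle(config)
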