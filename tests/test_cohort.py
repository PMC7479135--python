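"""Depth normalization, presence calls, frequency classes, spectra, merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trlandscape as tl
from trlandscape.cohort import (
    PresenceMatrix,
    classify_frequency,
    merge_sample_calls,
    normalize_counts,
    occurrence_spectrum,
    per_genome_counts,
)
from trlandscape.core import TRLocus, ValidationError


def _presence(matrix: np.ndarray) -> PresenceMatrix:
    matrix = np.asarray(matrix, dtype=bool)
    loci = [
        TRLocus(contig="1", start=1000 * (i + 1), end=1000 * (i + 1) + 100, motif="AAG")
        for i in range(matrix.shape[0])
    ]
    samples = [f"S{j}" for j in range(matrix.shape[1])]
    return PresenceMatrix(matrix=matrix, threshold=5.0, loci=loci, samples=samples)


@pytest.mark.parametrize(
    "raw, depth, reference, expected",
    [(7, 40, 40, 7.0), (10, 80, 40, 5.0), (0, 13, 40, 0.0)],
)
def test_normalize_counts_values(raw, depth, reference, expected):
    assert normalize_counts(raw, depth, reference) == expected


@settings(max_examples=100, derandomize=True)
@given(
    raw=st.floats(0, 1e6),
    depth=st.floats(1, 200),
    k=st.floats(0.01, 100),
)
def test_normalize_counts_scale_invariance(raw, depth, k):
    a = normalize_counts(raw * k, depth * k, 40.0)
    b = normalize_counts(raw, depth, 40.0)
    assert a == pytest.approx(b, rel=1e-9, abs=1e-9)


def test_normalize_counts_rejects_bad_depth():
    with pytest.raises(ValidationError):
        normalize_counts(1.0, 0.0, 40.0)


def test_presence_threshold_boundary():
    matrix = tl.CohortMatrix(
        loci=[TRLocus("1", 0, 100, "AAG")],
        samples=["a", "b", "c"],
        counts=np.array([[5.0, 4.99, 0.0]]),
    )
    presence = tl.call_presence(matrix, threshold=5)
    np.testing.assert_array_equal(presence.matrix, [[True, False, False]])


def test_presence_all_zero_matrix_is_all_absent():
    matrix = tl.CohortMatrix(
        loci=[TRLocus("1", 0, 100, "AAG")],
        samples=["a", "b"],
        counts=np.zeros((1, 2)),
    )
    assert not tl.call_presence(matrix).matrix.any()


def test_rare_common_boundary_at_1115_genomes():
    """At n=1,115 and 1%, 11 occurrences is rare and 12 is common."""
    matrix = np.zeros((2, 1115), dtype=bool)
    matrix[0, :11] = True
    matrix[1, :12] = True
    classes = classify_frequency(_presence(matrix))
    assert classes.cutoff == 12
    assert list(classes.classes) == ["rare", "common"]


def test_rare_common_boundary_small_cohort():
    matrix = np.zeros((1, 100), dtype=bool)
    matrix[0, 0] = True
    classes = classify_frequency(_presence(matrix))
    assert classes.classes[0] == "rare"
    matrix[0, :2] = True
    assert classify_frequency(_presence(matrix)).classes[0] == "common"


def test_classification_invariant_to_sample_order_and_partitions_loci():
    rng = np.random.default_rng(5)
    matrix = rng.random((30, 50)) < 0.1
    classes = classify_frequency(_presence(matrix))
    shuffled = classify_frequency(_presence(matrix[:, rng.permutation(50)]))
    np.testing.assert_array_equal(classes.classes, shuffled.classes)
    n_with_occurrence = int((matrix.sum(axis=1) >= 1).sum())
    assert classes.n_rare + classes.n_common == n_with_occurrence


def test_per_genome_counts_and_iqr():
    matrix = np.array(
        [[1, 0], [1, 0], [1, 0], [0, 1]], dtype=bool
    )
    presence = _presence(matrix)
    counts, summary = per_genome_counts(presence, ["rare", "rare", "rare", "common"])
    assert counts.loc["S0", "rare"] == 3
    assert counts.loc["S1", "common"] == 1
    assert summary.loc["rare", "median"] == 1.5
    assert summary.loc["rare", "iqr"] == summary.loc["rare", "q3"] - summary.loc["rare", "q1"]


def test_per_genome_counts_empty_category_is_zero():
    presence = _presence(np.zeros((2, 3), dtype=bool))
    counts, summary = per_genome_counts(presence, ["rare", "rare"])
    assert counts["rare"].sum() == 0
    assert summary.loc["rare", "median"] == 0


def test_occurrence_spectrum_counts_and_singleton_fraction():
    matrix = np.array([[1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=bool)
    spectrum = occurrence_spectrum(_presence(matrix))
    table = dict(zip(spectrum.table["occurrences"], spectrum.table["n_loci"]))
    assert table == {1: 2, 2: 1}
    assert spectrum.singleton_fraction == pytest.approx(2 / 3)
    assert spectrum.total_loci == 3


def test_occurrence_spectrum_all_loci_in_all_samples():
    spectrum = occurrence_spectrum(_presence(np.ones((4, 6), dtype=bool)))
    assert spectrum.table.to_dict("list") == {"occurrences": [6], "n_loci": [4]}


def test_spectrum_matches_planted_occurrences(bundle, presence):
    """On noise-free synthetic data the spectrum equals the planted carrier
    counts exactly."""
    spectrum = occurrence_spectrum(presence)
    planted = bundle.manifest.loci["n_carriers"].value_counts().sort_index()
    observed = dict(zip(spectrum.table["occurrences"], spectrum.table["n_loci"]))
    assert observed == planted.to_dict()


def _calls(rows):
    return pd.DataFrame(rows, columns=["contig", "start", "end", "motif", "count"])


def test_merge_overlapping_same_motif_calls():
    merged = merge_sample_calls(
        {
            "A": _calls([("1", 100, 300, "AAG", 6)]),
            "B": _calls([("1", 250, 400, "AAG", 8)]),
        }
    )
    assert merged.n_loci == 1
    locus = merged.loci[0]
    assert (locus.start, locus.end) == (100, 400)
    np.testing.assert_array_equal(merged.counts, [[6.0, 8.0]])


def test_merge_keeps_different_motifs_apart():
    merged = merge_sample_calls(
        {
            "A": _calls([("1", 100, 300, "AAG", 6)]),
            "B": _calls([("1", 100, 300, "AAC", 8)]),
        }
    )
    assert merged.n_loci == 2


def test_merge_respects_max_gap():
    calls = {
        "A": _calls([("1", 100, 200, "AAG", 6)]),
        "B": _calls([("1", 800, 900, "AAG", 7)]),
    }
    assert merge_sample_calls(calls, max_gap=500).n_loci == 2
    assert merge_sample_calls(calls, max_gap=600).n_loci == 1
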