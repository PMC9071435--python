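"""Bias, fidelity, GC, spectrum and correction statistics of count matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ligfid import (
    PairCountMatrix,
    ProfileReport,
    compare_profiles,
    double_mismatch_edge_fraction,
    expected_profile,
    gc_binned_summary,
    mismatch_count_distribution,
    mismatch_spectrum,
    normalized_frequency,
    overall_fidelity,
    pattern_group_summary,
    pearson_correlation,
    per_overhang_fidelity,
    sample_events,
    synthesis_bias_correction,
    yield_percent,
)
from ligfid.overhangs import GC_COUNTS, OVERHANGS, RC_INDEX

from conftest import matrix_from_pairs


def random_symmetric_matrix(seed, scale=20):
    rng = np.random.default_rng(seed)
    raw = rng.integers(0, scale, size=(256, 256))
    return PairCountMatrix(counts=raw + raw.T)


class TestNormalizedFrequency:
    def test_uniform_wc_matrix_is_flat_one(self):
        counts = np.zeros((256, 256), dtype=np.int64)
        counts[np.arange(256), RC_INDEX] = 10
        freq = normalized_frequency(PairCountMatrix(counts=counts))
        assert freq.to_numpy() == pytest.approx(np.ones(256))

    def test_single_pair_matrix(self):
        matrix = matrix_from_pairs([("CTAT", "ATAG", 7)])
        freq = normalized_frequency(matrix)
        assert freq["CTAT"] == pytest.approx(128.0)
        assert freq["ATAG"] == pytest.approx(128.0)
        assert freq.drop(["CTAT", "ATAG"]).to_numpy() == pytest.approx(np.zeros(254))

    def test_sums_to_256(self):
        freq = normalized_frequency(random_symmetric_matrix(0))
        assert freq.sum() == pytest.approx(256.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            normalized_frequency(PairCountMatrix(counts=np.zeros((256, 256))))


class TestFidelity:
    def test_wc_only_matrix_is_perfect(self):
        counts = np.zeros((256, 256), dtype=np.int64)
        counts[np.arange(256), RC_INDEX] = 3
        matrix = PairCountMatrix(counts=counts)
        assert overall_fidelity(matrix) == 1.0
        assert per_overhang_fidelity(matrix).to_numpy() == pytest.approx(np.ones(256))

    def test_toy_matrix_three_quarters(self, toy_matrix):
        assert overall_fidelity(toy_matrix) == pytest.approx(0.75)

    def test_zero_event_overhangs_are_nan_not_zero(self, toy_matrix):
        fid = per_overhang_fidelity(toy_matrix)
        assert np.isnan(fid["AAAA"])
        assert fid["CTAT"] == 1.0
        assert fid["TGGA"] == 0.0

    def test_overall_is_event_weighted_mean_of_per_overhang(self):
        matrix = random_symmetric_matrix(1)
        fid = per_overhang_fidelity(matrix).to_numpy()
        events = matrix.counts.sum(axis=1)
        assert overall_fidelity(matrix) == pytest.approx(
            np.nansum(fid * events) / events.sum()
        )


class TestGcSummaries:
    def test_constant_input_means_one_everywhere(self):
        values = pd.Series(1.0, index=list(OVERHANGS))
        summary = gc_binned_summary(values)
        assert summary["mean"].to_numpy() == pytest.approx(np.ones(5))
        assert summary["n"].tolist() == [16, 64, 96, 64, 16]

    def test_nan_values_excluded_from_bin_means(self):
        values = pd.Series(2.0, index=list(OVERHANGS))
        values["AAAA"] = np.nan
        summary = gc_binned_summary(values)
        assert summary.loc[0, "n"] == 15
        assert summary.loc[0, "mean"] == pytest.approx(2.0)

    def test_gc_fidelity_decreases_under_anneal_coupled_tolerance(
        self, anneal_coupled_model
    ):
        """With mismatch acceptance coupled to annealing strength, expected
        fidelity falls monotonically across GC bins, the trend seen in
        end-joining profiles."""
        profile = expected_profile(anneal_coupled_model)
        fid = pd.Series(profile.per_overhang_fidelity(), index=list(OVERHANGS))
        means = gc_binned_summary(fid)["mean"].to_numpy()
        assert all(a > b for a, b in zip(means, means[1:]))


class TestMismatchSpectrum:
    def test_wc_only_matrix_has_empty_spectrum(self):
        counts = np.zeros((256, 256), dtype=np.int64)
        counts[np.arange(256), RC_INDEX] = 5
        matrix = PairCountMatrix(counts=counts)
        assert mismatch_spectrum(matrix).empty
        assert mismatch_count_distribution(matrix) == {
            0: 1.0, 1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}

    def test_single_edge_gt_pair(self):
        matrix = matrix_from_pairs([("TGGA", "TCCG", 4)])
        spectrum = mismatch_spectrum(matrix)
        assert set(spectrum["label"]) == {"G:T", "T:G"}
        assert set(spectrum["position_class"]) == {"edge"}
        assert spectrum["frequency"].to_numpy() == pytest.approx([0.5, 0.5])
        dist = mismatch_count_distribution(matrix)
        assert dist[1] == 1.0

    def test_model_restricted_to_gt_edge_yields_pure_spectrum(self, gt_edge_model):
        matrix = sample_events(gt_edge_model, 100_000, seed=13)
        spectrum = mismatch_spectrum(matrix)
        assert set(spectrum["label"]) <= {"G:T", "T:G"}
        assert set(spectrum["position_class"]) == {"edge"}

    def test_distribution_sums_to_one_and_matches_fidelity(self):
        matrix = random_symmetric_matrix(2)
        dist = mismatch_count_distribution(matrix)
        assert sum(dist.values()) == pytest.approx(1.0)
        assert dist[0] == pytest.approx(overall_fidelity(matrix))

    def test_double_mismatch_edge_fraction_extremes(self):
        middle_only = matrix_from_pairs([("ACCT", "ATTT", 3)])  # positions 2,3
        assert double_mismatch_edge_fraction(middle_only) == 0.0
        edge_and_middle = matrix_from_pairs([("GGAT", "ATTT", 3)])  # positions 1,2
        assert double_mismatch_edge_fraction(edge_and_middle) == 1.0
        wc_only = matrix_from_pairs([("CTAT", "ATAG", 1)])
        assert np.isnan(double_mismatch_edge_fraction(wc_only))


class TestPatternsAndCorrelation:
    def test_nnnn_mean_is_one_on_complete_profile(self):
        freq = normalized_frequency(random_symmetric_matrix(3))
        summary = pattern_group_summary(freq, ["NNNN", "TNNA"])
        assert summary.loc["NNNN", "mean"] == pytest.approx(1.0)
        assert summary.loc["TNNA", "n"] == 16

    def test_unmatchable_pattern_rejected(self):
        freq = normalized_frequency(random_symmetric_matrix(4))
        with pytest.raises(ValueError, match="matches no overhang"):
            pattern_group_summary(freq.iloc[:10], ["TNNA"])

    def test_self_correlation_and_anticorrelation(self):
        freq = normalized_frequency(random_symmetric_matrix(5))
        assert pearson_correlation(freq, freq) == pytest.approx(1.0)
        mirrored = 2 * freq.mean() - freq
        assert pearson_correlation(freq, mirrored) == pytest.approx(-1.0)

    def test_zero_variance_is_undefined(self):
        flat = pd.Series(1.0, index=list(OVERHANGS))
        freq = normalized_frequency(random_symmetric_matrix(6))
        assert np.isnan(pearson_correlation(flat, freq))

    def test_replicate_samples_of_same_model_correlate(self, permissive_model):
        a = normalized_frequency(sample_events(permissive_model, 1_000_000, seed=1))
        b = normalized_frequency(sample_events(permissive_model, 1_000_000, seed=2))
        assert pearson_correlation(a, b) > 0.99


class TestSynthesisBiasCorrection:
    def test_uniform_tallies_are_identity(self):
        freq = normalized_frequency(random_symmetric_matrix(7))
        tallies = np.full((6, 4), 1000)
        corrected = synthesis_bias_correction(freq, tallies)
        assert corrected.to_numpy() == pytest.approx(freq.to_numpy())

    def test_composition_skew_is_flattened_for_uniform_ligase(self):
        # overhang abundance follows the skewed synthesis composition
        # (40% A / 20% C,G,T) while the ligase itself is uniform
        base_probs = np.array([0.4, 0.2, 0.2, 0.2])
        weights = np.ones(256)
        for pos in range(4):
            from ligfid.overhangs import CODES

            weights *= base_probs[CODES[:, pos].astype(int)] * 4
        counts = np.outer(weights, weights)
        raw = normalized_frequency(counts * 1000)
        assert raw["AAAA"] > raw["CCCC"]
        tallies = np.tile((base_probs * 10000).astype(int), (6, 1))
        corrected = synthesis_bias_correction(raw, tallies)
        assert corrected.to_numpy() == pytest.approx(np.ones(256), abs=1e-6)

    def test_missing_or_degenerate_tallies_skip_with_warning(self):
        freq = normalized_frequency(random_symmetric_matrix(8))
        with pytest.warns(UserWarning, match="skipped"):
            assert synthesis_bias_correction(freq, None).equals(freq)
        tallies = np.full((6, 4), 100)
        tallies[2] = 0
        with pytest.warns(UserWarning, match="skipped"):
            assert synthesis_bias_correction(freq, tallies).equals(freq)


class TestYield:
    @pytest.mark.parametrize(
        "product,substrate,expected", [(50, 50, 50.0), (0, 10, 0.0), (3, 1, 75.0)]
    )
    def test_yield_formula(self, product, substrate, expected):
        assert yield_percent(product, substrate) == pytest.approx(expected)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            yield_percent(0, 0)
        with pytest.raises(ValueError):
            yield_percent(-1, 5)


class TestInvariances:
    @given(st.integers(0, 2**31 - 1), st.integers(2, 9))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance(self, seed, factor):
        matrix = random_symmetric_matrix(seed)
        scaled = PairCountMatrix(counts=matrix.counts * factor)
        assert overall_fidelity(matrix) == pytest.approx(overall_fidelity(scaled))
        assert normalized_frequency(matrix).to_numpy() == pytest.approx(
            normalized_frequency(scaled).to_numpy()
        )
        assert mismatch_count_distribution(matrix) == pytest.approx(
            mismatch_count_distribution(scaled)
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_top_bottom_relabel_invariance(self, seed):
        matrix = random_symmetric_matrix(seed)
        transposed = PairCountMatrix(counts=matrix.counts.T.copy())
        assert overall_fidelity(matrix) == pytest.approx(overall_fidelity(transposed))
        assert normalized_frequency(matrix).to_numpy() == pytest.approx(
            normalized_frequency(transposed).to_numpy()
        )
        a = mismatch_spectrum(matrix)
        b = mismatch_spectrum(transposed)
        pd.testing.assert_frame_equal(a, b)

    def test_fidelity_equals_complement_of_mismatch_fractions(self):
        for seed in range(5):
            matrix = random_symmetric_matrix(seed)
            dist = mismatch_count_distribution(matrix)
            assert overall_fidelity(matrix) == pytest.approx(
                1 - sum(dist[k] for k in range(1, 5))
            )


class TestReportAndCompare:
    def test_report_assembles_consistent_tables(self, permissive_model, tmp_path):
        matrix = sample_events(permissive_model, 50_000, seed=19)
        report = ProfileReport.from_matrix(matrix)
        assert len(report.per_overhang) == 256
        assert report.overall_fidelity == pytest.approx(overall_fidelity(matrix))
        assert report.pattern_groups.loc["TNNA", "n"] == 16
        report.write(tmp_path)
        assert (tmp_path / "per_overhang.csv").exists()
        assert (tmp_path / "summary.json").exists()

    def test_identical_inputs_give_zero_deltas(self, permissive_model):
        matrix = sample_events(permissive_model, 20_000, seed=23)
        report = ProfileReport.from_matrix(matrix)
        diff = compare_profiles(report, report)
        assert diff["overall_fidelity_delta"] == 0.0
        assert diff["per_overhang_deltas"]["delta_frequency"].abs().max() == 0.0
        assert diff["frequency_correlation"] == pytest.approx(1.0)

    def test_expected_profile_statistics_match_closed_forms(self, permissive_model):
        """Profiling the exact expected matrix reproduces the model's own
        closed-form fidelity and frequency to machine precision."""
        profile = expected_profile(permissive_model)
        assert overall_fidelity(profile.probs) == pytest.approx(
            profile.overall_fidelity(), abs=1e-14
        )
        assert normalized_frequency(profile.probs).to_numpy() == pytest.approx(
            profile.normalized_frequency(), abs=1e-12
        )
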