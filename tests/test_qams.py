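"""Relative correction factors, peak localization and content computation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qamskit import chromsim, fixtures
from qamskit.exceptions import ComponentLookupError, ConfigurationError, ValidationError
from qamskit.peaktable import PeakRecord, PeakTable, RunConditions
from qamskit.qams import (
    CorrectionFactor,
    compare_methods,
    content_external,
    content_qams,
    correction_factor,
    find_marker,
    locate_peaks,
    pairs_from_contents_table,
    relative_retention,
    summarize_factors,
)

COND = RunConditions(methanol_fraction=60.0, column_temperature=30.0)


def run_with(areas, times=None):
    times = times or {"L3": 5.728, "L1": 10.0, "L4": 11.271}
    return PeakTable(
        conditions=COND,
        peaks=[PeakRecord(c, times[c], a) for c, a in areas.items()],
    )


class TestCorrectionFactor:
    def test_equal_specific_responses_give_unity(self, standards):
        run = run_with({"L1": 100 * 0.1008, "L3": 100 * 0.1005})
        f = correction_factor(run, standards, "L1", "L3")
        assert f.value == pytest.approx(1.0, rel=1e-12)

    def test_hand_arithmetic_example(self, standards):
        run = run_with({"L1": 1200.0, "L3": 1500.0})
        f = correction_factor(run, standards, "L1", "L3")
        assert f.value == pytest.approx((1200 / 0.1008) / (1500 / 0.1005), rel=1e-12)
        assert f.value == pytest.approx(0.79762, abs=5e-6)

    def test_simulator_factor_equals_response_factor_ratio(self, quiet_model, standards):
        amounts = chromsim.reference_amounts(standards, 10.0)
        run = chromsim.simulate_peak_table(quiet_model, COND, amounts, seed=0)
        f = correction_factor(run, standards, "L1", "L3")
        rf = {c: quiet_model.kinetics(c).response_factor for c in ("L1", "L3")}
        assert f.value == pytest.approx(rf["L1"] / rf["L3"], rel=1e-12)

    def test_missing_peak_and_zero_area(self, standards):
        with pytest.raises(ComponentLookupError):
            correction_factor(run_with({"L1": 100.0}), standards, "L1", "L3")
        with pytest.raises(ValidationError):
            correction_factor(run_with({"L1": 100.0, "L3": 0.0}), standards, "L1", "L3")

    @given(gain=st.floats(min_value=0.1, max_value=10.0))
    @settings(derandomize=True, max_examples=25)
    def test_detector_gain_invariance(self, gain):
        standards = fixtures.default_standards()
        base = run_with({"L1": 1200.0, "L3": 1500.0})
        scaled = run_with({"L1": 1200.0 * gain, "L3": 1500.0 * gain})
        f0 = correction_factor(base, standards, "L1", "L3").value
        f1 = correction_factor(scaled, standards, "L1", "L3").value
        assert f1 == pytest.approx(f0, rel=1e-12)

    def test_reciprocal_identity(self, standards):
        run = run_with({"L1": 1200.0, "L3": 1500.0})
        fwd = correction_factor(run, standards, "L1", "L3").value
        rev = correction_factor(run, standards, "L3", "L1").value
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)


class TestFactorSummaries:
    def test_injection_volume_series_mean_and_rsd(self):
        df = fixtures.load_fixture("cf_table5")
        factors = [
            CorrectionFactor("L1", "L3", v, condition=str(iv))
            for iv, v in zip(df.injection_volume, df.f_L3_L1)
        ]
        s = summarize_factors(factors)
        assert round(s.mean, 3) == 0.985
        assert s.rsd_percent == pytest.approx(0.90, abs=0.01)

    def test_column_series_mean(self):
        df = fixtures.load_fixture("cf_columns_table6")
        factors = [
            CorrectionFactor("L1", "L4", v, condition=c)
            for c, v in zip(df.column_id, df.f_L4_L1)
        ]
        assert round(summarize_factors(factors).mean, 3) == 1.804

    def test_constant_factors_have_zero_rsd(self):
        factors = [CorrectionFactor("L1", "L3", 0.98, str(i)) for i in range(3)]
        assert summarize_factors(factors).rsd_percent == 0.0

    def test_single_factor_rejected(self):
        with pytest.raises(ConfigurationError):
            summarize_factors([CorrectionFactor("L1", "L3", 0.98)])


class TestRelativeRetention:
    def test_ratio_arithmetic(self):
        run = run_with({"L1": 1.0, "L3": 1.0}, times={"L1": 10.0, "L3": 5.728})
        assert relative_retention(run, "L1")["L3"] == pytest.approx(0.5728)

    def test_marker_relative_to_itself_excluded(self):
        run = run_with({"L1": 1.0, "L3": 1.0})
        assert "L1" not in relative_retention(run, "L1")

    def test_simulated_run_matches_study_means(self, quiet_model, standards):
        run = chromsim.simulate_peak_table(
            quiet_model, COND, chromsim.reference_amounts(standards, 10.0), seed=0
        )
        rrt = relative_retention(run, "L1")
        assert rrt["L3"] == pytest.approx(0.5728, abs=0.02)
        assert rrt["L4"] == pytest.approx(1.1271, abs=0.02)

    def test_missing_marker(self):
        run = run_with({"L3": 1.0, "L4": 1.0})
        with pytest.raises(ComponentLookupError):
            relative_retention(run, "L1")


EXPECTED_RRT = {"L3": 0.5728, "L4": 1.1271}


class TestLocatePeaks:
    def anonymous_run(self, times):
        peaks = [PeakRecord(f"p{i}", t, 100.0) for i, t in enumerate(times)]
        return PeakTable(conditions=COND, peaks=peaks)

    def test_assigns_both_analytes_by_ratio(self):
        run = self.anonymous_run([5.72, 10.05, 11.33])
        result = locate_peaks(run, 10.05, EXPECTED_RRT)
        assert result.assigned["L3"].retention_time == pytest.approx(5.72)
        assert result.assigned["L4"].retention_time == pytest.approx(11.33)
        assert result.unassigned == ()

    def test_out_of_window_peak_left_unassigned(self):
        run = self.anonymous_run([7.00, 10.0])
        result = locate_peaks(run, 10.0, {"L3": 0.5728})
        assert "L3" in result.unassigned

    def test_nearest_candidate_wins(self):
        run = self.anonymous_run([5.60, 5.70, 10.0])
        result = locate_peaks(run, 10.0, {"L3": 0.5728})
        assert result.assigned["L3"].retention_time == pytest.approx(5.70)

    def test_greedy_resolves_shared_candidate(self):
        # one in-window peak claimed by two analytes: nearer analyte wins
        run = self.anonymous_run([5.728, 10.0])
        result = locate_peaks(run, 10.0, {"L3": 0.5728, "LX": 0.58})
        assert result.assigned["L3"].retention_time == pytest.approx(5.728)
        assert result.unassigned == ("LX",)

    def test_find_marker_prefers_largest_area_in_window(self):
        peaks = [PeakRecord("a", 9.8, 50.0), PeakRecord("b", 10.1, 500.0),
                 PeakRecord("c", 12.0, 900.0)]
        run = PeakTable(conditions=COND, peaks=peaks)
        assert find_marker(run, 10.0).component_id == "b"

    def test_recovery_rate_under_retention_jitter(self, standards):
        """1000 jittered runs: the true assignment is recovered in >= 99%."""
        model = chromsim.default_model(noise_cv=0.01, rt_jitter_cv=0.01)
        amounts = chromsim.reference_amounts(standards, 10.0)
        rng = model.rng(20240901)
        hits = 0
        for _ in range(1000):
            run = chromsim.simulate_peak_table(model, COND, amounts, rng=rng)
            marker_rt = run.get("L1").retention_time
            result = locate_peaks(run.anonymized(), marker_rt, EXPECTED_RRT)
            truth = {c: run.get(c).retention_time for c in ("L3", "L4")}
            ok = all(
                c in result.assigned
                and result.assigned[c].retention_time == pytest.approx(truth[c])
                for c in ("L3", "L4")
            )
            hits += ok
        assert hits >= 990


class TestContent:
    def test_external_content_hand_arithmetic(self, standards, prep):
        ref = run_with({"L1": 1000.0})
        sample = run_with({"L1": 1000.0})
        result = content_external(sample, ref, standards, prep, "L1")
        # equal areas: sample at reference concentration 0.1008 mg/mL
        assert result.percent_content == pytest.approx(0.1008 * 50 / (0.5 * 1000) * 100)
        assert result.percent_content == pytest.approx(1.008)

    def test_zero_sample_area_gives_zero_content(self, standards, prep):
        ref = run_with({"L1": 1000.0})
        sample = run_with({"L1": 0.0})
        assert content_external(sample, ref, standards, prep, "L1").percent_content == 0.0

    def test_injection_volume_mismatch_rejected(self, standards, prep):
        ref = run_with({"L1": 1000.0})
        import dataclasses

        other = dataclasses.replace(COND, injection_volume=20.0)
        sample = PeakTable(conditions=other, peaks=[PeakRecord("L1", 10.0, 1000.0)])
        with pytest.raises(ValidationError, match="injection"):
            content_external(sample, ref, standards, prep, "L1")

    def test_qams_equals_external_with_same_reference_run(self, standards, prep, noisy_model):
        """Algebraic identity: f from the same injection cancels the marker calibration."""
        amounts = chromsim.reference_amounts(standards, 10.0)
        ref = chromsim.simulate_peak_table(noisy_model, COND, amounts, seed=11)
        sample = chromsim.simulate_peak_table(
            noisy_model, COND, {"L1": 0.9, "L3": 1.3, "L4": 0.8}, seed=12
        )
        for cid in ("L3", "L4"):
            ext = content_external(sample, ref, standards, prep, cid)
            qam = content_qams(sample, ref, standards, prep, cid)
            assert qam.percent_content == pytest.approx(ext.percent_content, rel=1e-12)

    def test_qams_with_pooled_factor_hand_value(self, standards, prep):
        ref = run_with({"L1": 1000.0})
        sample = run_with({"L1": 900.0, "L3": 1000.0})
        result = content_qams(sample, ref, standards, prep, "L3", factor=0.985)
        conc = 1000.0 * 0.985 * 0.1008 / 1000.0  # = 0.985 * 0.1008 mg/mL
        assert result.percent_content == pytest.approx(conc * 50 / (0.5 * 1000) * 100)

    def test_simulated_content_recovered_within_noise(self, standards, prep):
        model = chromsim.default_model(noise_cv=0.005)
        true_percent = 0.25
        conc = true_percent / 100 * prep.sample_mass * 1000 / prep.extract_volume
        amounts = {"L1": 1.0, "L3": conc * 10.0, "L4": 1.0}
        ref = chromsim.simulate_peak_table(
            model, COND, chromsim.reference_amounts(standards, 10.0), seed=21
        )
        sample = chromsim.simulate_peak_table(model, COND, amounts, seed=22)
        got = content_external(sample, ref, standards, prep, "L3").percent_content
        assert got == pytest.approx(true_percent, rel=0.05)


class TestMethodComparison:
    def test_identical_pairs_all_zero(self, standards, prep):
        from qamskit.qams import ContentResult

        pairs = [
            (
                ContentResult("L3", "qams", 0.28, batch="b1"),
                ContentResult("L3", "external_standard", 0.28, batch="b1"),
            )
        ]
        table, summary = compare_methods(pairs)
        assert table.difference.abs().max() == 0.0
        assert not table.flagged.any()

    def test_study_batches_agree_within_two_tenths_percent(self):
        pairs = pairs_from_contents_table(fixtures.load_fixture("contents_table9"))
        table, summary = compare_methods(pairs)
        assert table.relative_difference_percent.max() < 0.2
        assert not table.flagged.any()

    def test_simulated_batches_not_flagged_at_one_percent_noise(
        self, standards, prep, noisy_model
    ):
        amounts_ref = chromsim.reference_amounts(standards, 10.0)
        ref = chromsim.simulate_peak_table(noisy_model, COND, amounts_ref, seed=31)
        # pooled correction factor from independent reference injections
        pooled = {}
        for cid in ("L3", "L4"):
            runs = [
                chromsim.simulate_peak_table(noisy_model, COND, amounts_ref, seed=100 + i)
                for i in range(6)
            ]
            factors = [correction_factor(r, standards, "L1", cid) for r in runs]
            pooled[cid] = summarize_factors(factors).mean
        pairs = []
        rng = np.random.default_rng(32)
        for b in range(8):
            amounts = {c: float(rng.uniform(0.5, 2.0)) for c in ("L1", "L3", "L4")}
            sample = chromsim.simulate_peak_table(
                noisy_model, COND, amounts, seed=int(rng.integers(2**31))
            )
            for cid in ("L3", "L4"):
                pairs.append(
                    (
                        content_qams(sample, ref, standards, prep, cid,
                                     factor=pooled[cid], batch=f"b{b}"),
                        content_external(sample, ref, standards, prep, cid, batch=f"b{b}"),
                    )
                )
        table, _ = compare_methods(pairs)
        assert not table.flagged.any()

    def test_unpaired_batch_rejected(self):
        from qamskit.qams import ContentResult

        pairs = [
            (
                ContentResult("L3", "qams", 0.28, batch="b1"),
                ContentResult("L3", "external_standard", 0.28, batch="b2"),
            )
        ]
        with pytest.raises(ConfigurationError):
            compare_methods(pairs)
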