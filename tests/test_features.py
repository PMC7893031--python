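"""Beat detection, frequency, normalization, aggregation and landmarks."""

import numpy as np
import pandas as pd
import pytest

from cardiomea.features import (
    DetectionParams,
    aggregate_periods,
    beat_frequency,
    detect_beats,
    locate_landmarks,
    normalize_fp_metrics,
    normalize_to_baseline,
)
from cardiomea.simulate import synthesize_recording
from cardiomea.waveform import evaluate_waveform

from conftest import render_beat_trace

FS = 5000.0


def multi_beat_trace(template, n_beats, period_s, fs=FS, noise_sd=0.0, rng=None):
    length_s = n_beats * period_s + 0.5
    n = int(length_s * fs)
    t_s = np.arange(n) / fs
    trace = np.zeros(n)
    truth = []
    for k in range(n_beats):
        t_p1 = 0.3 + k * period_s
        truth.append(t_p1)
        trace += evaluate_waveform(template, (t_s - t_p1) * 1000.0)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(1)
        trace = trace + noise_sd * rng.standard_normal(n)
    return trace, np.asarray(truth)


class TestDetectBeats:
    def test_pure_noise_yields_no_beats(self):
        rng = np.random.default_rng(0)
        trace = 10.0 * rng.standard_normal(int(20 * FS))
        assert len(detect_beats(trace, FS)) == 0

    def test_all_nan_trace_errors(self):
        with pytest.raises(ValueError):
            detect_beats(np.full(1000, np.nan), FS)

    def test_noiseless_beats_detected_within_1ms(self, template):
        trace, truth = multi_beat_trace(template, n_beats=10, period_s=1.5)
        det = detect_beats(trace, FS)
        assert len(det) == 10
        assert np.max(np.abs(det - truth)) < 1e-3

    def test_noisy_beats_mostly_within_2ms(self, template):
        noise_sd = 0.1 * template.p1_amplitude_uv
        trace, truth = multi_beat_trace(template, 10, 1.5, noise_sd=noise_sd)
        det = detect_beats(trace, FS)
        hits = sum(np.min(np.abs(truth - t)) < 2e-3 for t in det)
        assert hits >= 9

    def test_refractory_spacing_enforced(self, template):
        trace, _ = multi_beat_trace(template, 10, 1.0)
        det = detect_beats(trace, FS, DetectionParams(refractory_s=0.25))
        assert np.all(np.diff(det) >= 0.25 - 1e-9)


class TestBeatFrequency:
    def test_one_hz_train_is_60_bpm(self):
        assert beat_frequency(np.arange(60.0), 60.0) == pytest.approx(60.0)

    def test_silent_segment_is_zero(self):
        assert beat_frequency(np.array([]), 60.0) == 0.0

    def test_single_spike_uses_segment_length(self):
        assert beat_frequency(np.array([5.0]), 20.0) == pytest.approx(3.0)

    def test_simulator_rate_recovered(self, small_config):
        rec = synthesize_recording(small_config)
        seg = rec.segments[0]
        for e in range(3):
            spikes = detect_beats(seg.traces_uv[e], FS)
            bpm = beat_frequency(spikes, small_config.segment_length_s)
            assert bpm == pytest.approx(seg.ground_truth.rate_bpm[e], rel=0.02)


def make_beats_frame(rows):
    return pd.DataFrame(rows, columns=["electrode", "start_h", "n_beats", "bpm"])


class TestNormalizeToBaseline:
    def test_identity_for_constant_baseline(self):
        rows = [("e1", h, 20, 40.0) for h in range(-5, 0)] + [("e1", 1.0, 20, 40.0)]
        norm, report = normalize_to_baseline(make_beats_frame(rows))
        assert report["included"].all()
        assert np.allclose(norm["normalized_bpm"], 1.0)

    def test_even_count_median_is_mean_of_central_pair(self):
        baseline = [38.0, 40.0, 42.0, 44.0]  # median 41
        rows = [("e1", -4 + i, 20, b) for i, b in enumerate(baseline)]
        rows.append(("e1", 2.0, 20, 41.0))
        norm, _ = normalize_to_baseline(make_beats_frame(rows))
        test_row = norm[norm["start_h"] == 2.0]
        assert test_row["normalized_bpm"].iloc[0] == pytest.approx(1.0)

    def test_inactive_electrode_excluded_and_reported(self):
        rows = [("e1", h, 2, 5.0) for h in range(-5, 0)]  # too few beats/segment
        rows += [("e2", h, 20, 40.0) for h in range(-5, 0)]
        norm, report = normalize_to_baseline(make_beats_frame(rows))
        assert set(norm["electrode"]) == {"e2"}
        assert len(report) == 2
        excluded = report[~report["included"]]
        assert list(excluded["electrode"]) == ["e1"]
        assert excluded["reason"].iloc[0] == "inactive_baseline"


class TestAggregatePeriods:
    def test_constant_series_gives_mean_one_sd_zero(self):
        rows = [("e1", h, 20, 40.0) for h in np.arange(-5, 10, 1.0)]
        norm, _ = normalize_to_baseline(make_beats_frame(rows))
        summary = aggregate_periods(norm, [("baseline", -20, 0), ("H7-15", 7, 15)])
        assert np.allclose(summary["mean"], 1.0)
        assert np.allclose(summary["sd"], 0.0)

    def test_hand_built_two_period_means(self):
        """Spreadsheet oracle: two electrodes, two periods, unequal counts."""
        norm = pd.DataFrame(
            {
                "electrode": ["a", "a", "b", "a", "b", "b"],
                "start_h": [1.0, 2.0, 1.0, 8.0, 8.0, 9.0],
                "normalized_bpm": [0.8, 1.0, 0.6, 0.5, 0.3, 0.5],
            }
        )
        summary = aggregate_periods(norm, [("P1", 0, 7), ("P2", 7, 15)], "normalized_bpm")
        # P1: a -> 0.9, b -> 0.6; P2: a -> 0.5, b -> 0.4
        assert summary.loc[summary["period"] == "P1", "mean"].iloc[0] == pytest.approx(0.75)
        assert summary.loc[summary["period"] == "P2", "mean"].iloc[0] == pytest.approx(0.45)

    def test_empty_period_flagged(self):
        norm = pd.DataFrame({"electrode": ["a"], "start_h": [1.0], "normalized_bpm": [1.0]})
        summary = aggregate_periods(norm, [("void", 40, 48)], "normalized_bpm")
        assert bool(summary["empty"].iloc[0])
        assert summary["n_electrodes"].iloc[0] == 0


class TestLocateLandmarks:
    def test_noiseless_identity_within_one_sample(self, template):
        trace = render_beat_trace(template)
        lm = locate_landmarks(trace, 0.3, FS)
        one_sample = 1000.0 / FS
        assert lm.depol_ms == pytest.approx(template.p1_p2_interval_ms, abs=one_sample)
        assert lm.fpd_ms == pytest.approx(template.p1_flat_interval_ms, abs=one_sample)

    @pytest.mark.parametrize("depol_mult", [1.26, 1.65])
    def test_depol_fold_recovery(self, template, depol_mult):
        trace = render_beat_trace(template, depol_mult=depol_mult, noise_sd=10.0)
        lm = locate_landmarks(trace, 0.3, FS)
        fold = lm.depol_ms / template.p1_p2_interval_ms
        assert fold == pytest.approx(depol_mult, abs=0.05)

    def test_noisy_median_within_two_samples(self, template):
        rng = np.random.default_rng(3)
        depols, fpds = [], []
        for _ in range(20):
            trace = render_beat_trace(template, noise_sd=10.0, rng=rng)
            lm = locate_landmarks(trace, 0.3, FS)
            depols.append(lm.depol_ms)
            fpds.append(lm.fpd_ms)
        two_samples = 2000.0 / FS
        assert abs(np.median(depols) - template.p1_p2_interval_ms) < two_samples
        assert abs(np.median(fpds) - template.p1_flat_interval_ms) < two_samples

    def test_monotone_in_programmed_depol(self, template):
        """Recovered depolarization time strictly increases with the program."""
        rng = np.random.default_rng(4)
        means = []
        for mult in (1.0, 1.3, 1.6):
            vals = [
                locate_landmarks(
                    render_beat_trace(template, depol_mult=mult, noise_sd=10.0, rng=rng),
                    0.3,
                    FS,
                ).depol_ms
                for _ in range(10)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_missing_flat_peak_reported_as_none(self, template):
        from dataclasses import replace as dc_replace

        flatless = dc_replace(template, flat_peak_amplitude_uv=1e-6)
        trace = render_beat_trace(flatless)
        lm = locate_landmarks(trace, 0.3, FS)
        assert lm.fpd_ms is None
        assert lm.depol_ms is not None


class TestNormalizeFpMetrics:
    def test_fold_arithmetic(self):
        rows = (
            [{"sample": "s1", "timepoint": "B1", "value": v} for v in (90.0, 110.0)]
            + [{"sample": "s1", "timepoint": "H6.5", "value": 75.0}]
            + [{"sample": "s1", "timepoint": "H24", "value": 149.0}]
        )
        folds, summary = normalize_fp_metrics(pd.DataFrame(rows), ["B1"])
        # baseline mean is 100 -> folds 0.75 and 1.49
        by_tp = folds.set_index("timepoint")["fold"]
        assert by_tp["H6.5"] == pytest.approx(0.75)
        assert by_tp["H24"] == pytest.approx(1.49)
        assert by_tp["B1"] == pytest.approx(1.0)

    def test_sample_without_baseline_excluded(self):
        rows = [
            {"sample": "s1", "timepoint": "B1", "value": 100.0},
            {"sample": "s2", "timepoint": "H24", "value": 120.0},
        ]
        folds, _ = normalize_fp_metrics(pd.DataFrame(rows), ["B1"])
        assert set(folds["sample"]) == {"s1"}
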