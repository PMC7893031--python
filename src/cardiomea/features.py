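"""Beat detection, field-potential landmarks, and rate/landmark summaries.

Detection implements what acquisition suites hide in vendor software: a
10-2000 Hz band-pass, an amplitude threshold of 6 robust (MAD-based)
noise standard deviations on the filtered trace, and a 250 ms refractory
floor.  Landmarks follow the standard extracellular definitions: depolarization time is
the interval from the first peak (P1) of the field potential to the second,
opposite-signed peak (P2); FPD is the interval from P1 to the low-amplitude
"flat peak" of repolarization, read from a smoothed trace.  All landmark
times get sub-sample parabolic refinement.

Beating frequency is normalized per electrode to the median of its own
baseline values (the 20 h before hypoxia onset) and aggregated over the
analysis periods per electrode first, so each electrode contributes equally
to the cross-electrode mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt

from cardiomea.simulate import Recording, Segment

#: Analysis periods of the full protocol (label, start_h, end_h); t = 0 at
#: hypoxia onset, reoxygenation begins at t = 24 h.
STANDARD_PERIODS: tuple[tuple[str, float, float], ...] = (
    ("baseline", -20.0, 0.0),
    ("H7-15", 7.0, 15.0),
    ("H15-24", 15.0, 24.0),
    ("R0-6", 24.0, 30.0),
    ("R6-24", 30.0, 48.0),
)


@dataclass(frozen=True)
class DetectionParams:
    band_hz: tuple[float, float] = (10.0, 2000.0)
    threshold_mads: float = 6.0
    #: floor on the threshold as a fraction of the largest deflection, so
    #: near-noiseless traces do not trigger on filter ripple
    min_amplitude_fraction: float = 0.2
    refractory_s: float = 0.25


@dataclass(frozen=True)
class LandmarkParams:
    p1_search_ms: float = 5.0           # around the detected beat anchor
    p1_smooth_ms: float = 1.0           # Gaussian pre-smoothing for spike timing
    p2_window_ms: float = 80.0          # after P1
    flat_window_ms: tuple[float, float] = (80.0, 600.0)
    smooth_ms: float = 20.0             # moving average for the flat peak
    flat_fit_halfwidth_ms: float = 45.0  # least-squares vertex window
    min_flat_uv: float = 5.0            # noise floor for a valid flat peak


@lru_cache(maxsize=8)
def _bandpass_sos(fs: float, lo: float, hi: float):
    hi = min(hi, 0.45 * fs)  # keep the corner inside Nyquist
    return butter(2, (lo, hi), btype="bandpass", fs=fs, output="sos")


def _parabolic_offset(y_m1: float, y_0: float, y_p1: float) -> float:
    """Sub-sample vertex offset of the parabola through three samples."""
    denom = y_m1 - 2.0 * y_0 + y_p1
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y_m1 - y_p1) / denom, -0.5, 0.5))


def _refine(x: np.ndarray, i: int) -> float:
    """Refined index of a local extremum of ``x`` near sample ``i``."""
    if 0 < i < len(x) - 1:
        return i + _parabolic_offset(x[i - 1], x[i], x[i + 1])
    return float(i)


def detect_beats(
    trace: np.ndarray,
    sampling_rate_hz: float,
    params: DetectionParams = DetectionParams(),
) -> np.ndarray:
    """Detect beat anchor times (s) on one electrode trace.

    Returns strictly increasing times of the dominant deflection of each
    beat, no two closer than the refractory bound.  A silent trace yields an
    empty array; an all-NaN trace is an error.
    """
    x = np.asarray(trace, dtype=float)
    if x.size == 0 or np.all(np.isnan(x)):
        raise ValueError("trace is empty or all-NaN")
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    sos = _bandpass_sos(sampling_rate_hz, *params.band_hz)
    y = sosfiltfilt(sos, x)
    a = np.abs(y)
    mad = np.median(np.abs(y - np.median(y)))
    noise_sd = mad / 0.6745
    peak = a.max()
    if peak == 0.0:
        return np.asarray([])
    threshold = max(params.threshold_mads * noise_sd, params.min_amplitude_fraction * peak)
    distance = max(1, int(round(params.refractory_s * sampling_rate_hz)))
    peaks, _ = find_peaks(a, height=threshold, distance=distance)
    refined = np.asarray([_refine(a, int(i)) for i in peaks])
    return refined / sampling_rate_hz


def beat_frequency(spike_times: np.ndarray, segment_length_s: float) -> float:
    """Beats per minute of one segment.

    With >= 2 spikes the rate is interval-based, ``60 * n_intervals /
    sum(intervals)`` (robust to edge truncation of the segment); otherwise
    ``60 * count / segment_length_s``.
    """
    if segment_length_s <= 0:
        raise ValueError("segment_length_s must be positive")
    t = np.asarray(spike_times, dtype=float)
    if t.size >= 2:
        span = t[-1] - t[0]
        if span > 0:
            return 60.0 * (t.size - 1) / span
    return 60.0 * t.size / segment_length_s


def beat_table(
    segments: Iterable[Segment],
    sampling_rate_hz: float,
    segment_length_s: float,
    electrode_labels: Sequence[str],
    params: DetectionParams = DetectionParams(),
) -> pd.DataFrame:
    """Detect beats on every electrode of every segment.

    Returns a tidy frame with columns ``electrode, start_h, n_beats, bpm``.
    """
    rows = []
    for seg in segments:
        for e, label in enumerate(electrode_labels):
            spikes = detect_beats(seg.traces_uv[e], sampling_rate_hz, params)
            rows.append(
                {
                    "electrode": label,
                    "start_h": seg.start_h,
                    "n_beats": int(spikes.size),
                    "bpm": beat_frequency(spikes, segment_length_s),
                }
            )
    return pd.DataFrame(rows)


def beat_table_from_recording(
    recording: Recording,
    segment_length_s: float | None = None,
    params: DetectionParams = DetectionParams(),
) -> pd.DataFrame:
    if segment_length_s is None:
        n = recording.segments[0].traces_uv.shape[1]
        segment_length_s = n / recording.sampling_rate_hz
    return beat_table(
        recording.segments,
        recording.sampling_rate_hz,
        segment_length_s,
        recording.geometry.electrode_ids,
        params,
    )


def normalize_to_baseline(
    beats: pd.DataFrame,
    baseline_window_h: tuple[float, float] = (-20.0, 0.0),
    min_baseline_segments: int = 3,
    min_beats_per_segment: int = 10,
    min_active_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-baseline normalization per electrode.

    An electrode is included when at least ``min_active_fraction`` of its
    baseline segments carry >= ``min_beats_per_segment`` detected beats and
    at least ``min_baseline_segments`` baseline segments have bpm > 0.
    Returns ``(normalized, exclusions)``; ``normalized`` adds a
    ``normalized_bpm`` column, ``exclusions`` reports every electrode with
    its inclusion status and reason so included + excluded = total.
    """
    lo, hi = baseline_window_h
    out_frames = []
    report = []
    for electrode, grp in beats.groupby("electrode", sort=False):
        base = grp[(grp["start_h"] >= lo) & (grp["start_h"] < hi)]
        active = base[base["bpm"] > 0]
        reason = ""
        if len(base) == 0 or (base["n_beats"] >= min_beats_per_segment).mean() < min_active_fraction:
            reason = "inactive_baseline"
        elif len(active) < min_baseline_segments:
            reason = "too_few_baseline_segments"
        else:
            median = float(np.median(active["bpm"]))
            if median <= 0:
                reason = "zero_baseline_median"
        report.append({"electrode": electrode, "included": reason == "", "reason": reason})
        if reason:
            continue
        g = grp.copy()
        g["normalized_bpm"] = g["bpm"] / median
        out_frames.append(g)
    normalized = (
        pd.concat(out_frames, ignore_index=True)
        if out_frames
        else beats.iloc[0:0].assign(normalized_bpm=[])
    )
    return normalized, pd.DataFrame(report)


def aggregate_periods(
    normalized: pd.DataFrame,
    periods: Sequence[tuple[str, float, float]] = STANDARD_PERIODS,
    value_col: str = "normalized_bpm",
) -> pd.DataFrame:
    """Per-period mean +/- sd across electrodes.

    Segments are assigned to periods half-open on their start time.  Each
    electrode is first averaged within the period, then electrodes are
    summarized with mean and sd (ddof=1), so electrodes with different
    segment counts contribute equally.
    """
    rows = []
    for label, lo, hi in periods:
        sel = normalized[(normalized["start_h"] >= lo) & (normalized["start_h"] < hi)]
        per_electrode = sel.groupby("electrode")[value_col].mean()
        n = int(per_electrode.size)
        rows.append(
            {
                "period": label,
                "n_electrodes": n,
                "mean": float(per_electrode.mean()) if n else np.nan,
                "sd": float(per_electrode.std(ddof=1)) if n > 1 else (0.0 if n == 1 else np.nan),
                "empty": n == 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FPLandmarks:
    """Landmark times (s, within the trace) and derived intervals of a beat."""

    p1_s: float
    p2_s: float | None
    flat_s: float | None

    @property
    def depol_ms(self) -> float | None:
        if self.p2_s is None:
            return None
        return (self.p2_s - self.p1_s) * 1000.0

    @property
    def fpd_ms(self) -> float | None:
        if self.flat_s is None:
            return None
        return (self.flat_s - self.p1_s) * 1000.0


def locate_landmarks(
    trace: np.ndarray,
    beat_time_s: float,
    sampling_rate_hz: float,
    params: LandmarkParams = LandmarkParams(),
) -> FPLandmarks:
    """Locate P1, P2 and the flat peak of one beat.

    P1 is the largest absolute extremum near the beat anchor
    (polarity-agnostic); P2 the largest opposite-signed extremum within the
    depolarization search window; the flat peak the largest absolute
    extremum of the moving-average-smoothed trace within the repolarization
    window.  P2/flat are ``None`` when their window leaves the trace or the
    flat peak stays below the noise floor.
    """
    x = np.asarray(trace, dtype=float)
    fs = sampling_rate_hz
    n = x.size

    # slight Gaussian smoothing at the spike-width scale: symmetric, so peak
    # positions are preserved while timing noise drops by an order of magnitude
    sigma_px = params.p1_smooth_ms / 1000.0 * fs
    xf = gaussian_filter1d(x, sigma_px) if sigma_px >= 0.5 else x

    w = int(round(params.p1_search_ms / 1000.0 * fs))
    i_anchor = int(round(beat_time_s * fs))
    lo = max(0, i_anchor - w)
    hi = min(n, i_anchor + w + 1)
    if hi <= lo:
        raise ValueError("beat time outside trace")
    i_p1 = lo + int(np.argmax(np.abs(xf[lo:hi])))
    polarity = 1.0 if xf[i_p1] >= 0 else -1.0
    p1_s = _refine(polarity * xf, i_p1) / fs

    # P2: opposite-signed extremum after P1
    j0 = i_p1 + 1
    j1 = min(n, i_p1 + int(round(params.p2_window_ms / 1000.0 * fs)) + 1)
    p2_s = None
    if j1 > j0:
        seg = -polarity * xf[j0:j1]
        i_p2 = j0 + int(np.argmax(seg))
        if -polarity * xf[i_p2] > 0:
            p2_s = _refine(-polarity * xf, i_p2) / fs

    # flat peak on the smoothed trace
    smooth_n = max(1, int(round(params.smooth_ms / 1000.0 * fs)))
    xs = uniform_filter1d(x, size=smooth_n, mode="nearest")
    k0 = i_p1 + int(round(params.flat_window_ms[0] / 1000.0 * fs))
    k1 = i_p1 + int(round(params.flat_window_ms[1] / 1000.0 * fs)) + 1
    flat_s = None
    if k0 >= 0 and k1 <= n and k1 > k0:
        i_flat = k0 + int(np.argmax(np.abs(xs[k0:k1])))
        amp = xs[i_flat]
        if abs(amp) >= params.min_flat_uv:
            flat_s = _ls_vertex(xs, i_flat, params.flat_fit_halfwidth_ms, fs) / fs
    return FPLandmarks(p1_s=p1_s, p2_s=p2_s, flat_s=flat_s)


def _ls_vertex(x: np.ndarray, i: int, halfwidth_ms: float, fs: float) -> float:
    """Vertex of a least-squares parabola around sample ``i``.

    The wide low-curvature repolarization bump needs many samples to pin its
    apex against noise; a 3-point parabola is noise-limited there.
    """
    h = int(round(halfwidth_ms / 1000.0 * fs))
    lo, hi = max(0, i - h), min(len(x), i + h + 1)
    if hi - lo < 5:
        return _refine(np.sign(x[i]) * x, i)
    idx = np.arange(lo, hi)
    coef = np.polyfit(idx - i, x[lo:hi], 2)
    if coef[0] == 0:
        return float(i)
    offset = -coef[1] / (2.0 * coef[0])
    if abs(offset) > h:
        return _refine(np.sign(x[i]) * x, i)
    return i + float(offset)


def normalize_fp_metrics(
    values: pd.DataFrame,
    baseline_timepoints: Sequence[str],
    value_col: str = "value",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample baseline-mean normalization of landmark metrics.

    ``values`` is long format with columns ``sample, timepoint, value`` (one
    row per beat).  Every sample's values are divided by the mean of its own
    baseline-timepoint values.  Returns ``(folds, summary)``: per
    sample-timepoint mean folds, and cross-sample mean +/- sd per timepoint.
    Samples without baseline data are excluded (reported via absence).
    """
    baseline_set = set(baseline_timepoints)
    folds_rows = []
    for sample, grp in values.groupby("sample", sort=False):
        base = grp[grp["timepoint"].isin(baseline_set)][value_col]
        if len(base) == 0:
            continue
        base_mean = float(base.mean())
        if base_mean == 0:
            continue
        per_tp = grp.groupby("timepoint", sort=False)[value_col].mean() / base_mean
        for tp, fold in per_tp.items():
            folds_rows.append({"sample": sample, "timepoint": tp, "fold": float(fold)})
    folds = pd.DataFrame(folds_rows)
    if folds.empty:
        return folds, pd.DataFrame(columns=["timepoint", "n_samples", "mean", "sd"])
    summary = (
        folds.groupby("timepoint", sort=False)["fold"]
        .agg(n_samples="size", mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
        .reset_index()
    )
    return folds, summary
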