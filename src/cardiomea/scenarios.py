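"""Study-condition scenarios and end-to-end recovery harnesses.

This module pins down the simulated experiment: the recording protocol
(20 h baseline recorded 1 min every hour, 24 h hypoxia and 24 h
reoxygenation recorded every 30 min), the period structure of the analysis,
and the programmed electrophysiology targets (the reference period means
for the normalized beating frequency, the landmark fold changes per
timepoint, the adjacent-electrode conduction lags, the morphometry
population parameters, and the qPCR group folds).  Each ``run_*_study``
function executes the full synthesis -> detection -> normalization ->
aggregation chain at desk scale and returns recovered summaries next to
the programmed targets.

The desk profile samples at 5 kHz with 20 s segments: landmark intervals
stay resolved to a fifth of a millisecond while a full two-day protocol
simulates in minutes on one core.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from cardiomea.conduction import activation_times, adjacent_lags, conduction_summary, p1_times
from cardiomea.features import (
    STANDARD_PERIODS,
    DetectionParams,
    LandmarkParams,
    aggregate_periods,
    beat_table,
    detect_beats,
    locate_landmarks,
    normalize_fp_metrics,
    normalize_to_baseline,
)
from cardiomea.geometry import GridGeometry
from cardiomea.imaging import (
    nucleus_areas,
    sarcomere_coverage,
    segment_nuclei,
    synth_coverage_image,
    synth_nucleus_image,
)
from cardiomea.oxygen import OxygenModel
from cardiomea.program import PhaseProgram, build_multiplier_program, constant_program
from cardiomea.qpcr import relative_expression, synth_ct_table
from cardiomea.simulate import (
    SimConfig,
    cv_for_mean_lag,
    iter_segments,
    protocol_schedule,
)
from cardiomea.waveform import WaveformTemplate, evaluate_waveform

# ---------------------------------------------------------------------------
# programmed targets (study conditions)

#: Period means of the normalized beating frequency; baseline multiplier is
#: 1 by construction (normalization is to the electrode's own baseline
#: median).  H0-7 is the decline/transition window excluded from the period
#: statistics; its level follows the gradual slowing seen after onset.
RATE_PERIOD_TARGETS: tuple[tuple[str, float, float, float], ...] = (
    ("baseline", -20.0, 0.0, 1.0),
    ("H0-7", 0.0, 7.0, 0.65),
    ("H7-15", 7.0, 15.0, 0.358),
    ("H15-24", 15.0, 24.0, 0.656),
    ("R0-6", 24.0, 30.0, 1.274),
    ("R6-24", 30.0, 48.0, 0.981),
)

#: Reference cross-electrode period means of the normalized beating frequency.
RATE_RECOVERY_TARGETS = {
    "baseline": 1.081,
    "H7-15": 0.358,
    "H15-24": 0.656,
    "R0-6": 1.274,
    "R6-24": 0.981,
}

#: Landmark fold programs per timepoint: (depolarization-time fold,
#: FPD fold), numbers of analyzed beats, and participating samples follow
#: the reference per-timepoint design (beating had stopped in two of three
#: samples at 6.5 h, in one at 8 h).
LANDMARK_TIMEPOINTS = (
    # label, depol fold, fpd fold, n_beats, sample indices
    ("B1", 1.0, 1.0, 19, (0, 1, 2)),
    ("B2", 1.0, 1.0, 19, (0, 1, 2)),
    ("H6.5", 1.26, 0.75, 4, (0,)),
    ("H8", 1.65, 0.87, 4, (0, 1)),
    ("H24", 1.49, 0.96, 13, (0, 1, 2)),
    ("R6", 1.15, 0.92, 17, (0, 1, 2)),
    ("R24", 1.52, 0.97, 14, (0, 1, 2)),
)
LANDMARK_BASELINE_TIMEPOINTS = ("B1", "B2")

#: Pooled mean adjacent-pair conduction lags (ms) per timepoint.
LAG_TARGETS_MS = {
    "baseline": 0.45,
    "H8": 0.72,
    "H24": 0.86,
    "R6": 0.71,
    "R24": 0.56,
}

#: Morphometry population parameters (control condition).
CONTROL_COVERAGE_PERCENT = 69.4
CONTROL_NUCLEUS_AREA_UM2 = 35.7
CONTROL_NUCLEUS_AREA_SD_UM2 = 16.4

#: SLC2A1 relative-expression group means, 24 h hypoxia experiment.
SLC2A1_24H_FOLDS = {"control": 1.0, "hypoxia": 48.22}
SLC2A1_24H_N = {"control": 6, "hypoxia": 5}


def analysis_geometry(n_electrodes: int = 41) -> GridGeometry:
    """Standard 60-electrode layout reduced to the analyzed electrode count.

    A typical experiment yields ~41 analyzable electrodes (4-6 per sample
    over 9 samples); the reduction drops trailing row-major positions
    deterministically -- layout is irrelevant for rate analysis, which is
    per-electrode.
    """
    base = GridGeometry.standard_60()
    positions = base.positions
    if not (1 <= n_electrodes <= len(positions)):
        raise ValueError("n_electrodes out of range")
    extra = frozenset(positions[n_electrodes:])
    return GridGeometry(8, 8, base.pitch_um, base.missing | extra)


def rate_phase_program(smoothing_h: float = 1.0) -> PhaseProgram:
    rate = build_multiplier_program(RATE_PERIOD_TARGETS, smoothing_h=smoothing_h)
    one = constant_program(1.0, -20.0, 48.0)
    return PhaseProgram(rate=rate, depol=one, fpd=one, cv=one)


def beat_rate_config(seed: int = 0, n_electrodes: int = 41) -> SimConfig:
    """Full-protocol beat-rate scenario at the desk profile."""
    return SimConfig(
        geometry=analysis_geometry(n_electrodes),
        oxygen=OxygenModel.protocol(),
        program=rate_phase_program(),
        segment_starts_h=protocol_schedule(),
        seed=seed,
    )


@dataclass
class BeatRateStudy:
    period_summary: pd.DataFrame
    exclusions: pd.DataFrame
    recovered: dict[str, float]
    targets: dict[str, float]


def run_beat_rate_study(seed: int = 0, n_electrodes: int = 41) -> BeatRateStudy:
    """Simulate the full protocol and recover the period means of the
    normalized beating frequency through the detection pipeline."""
    config = beat_rate_config(seed=seed, n_electrodes=n_electrodes)
    labels = config.geometry.electrode_ids
    beats = beat_table(
        iter_segments(config, with_ground_truth=False),
        config.sampling_rate_hz,
        config.segment_length_s,
        labels,
    )
    normalized, exclusions = normalize_to_baseline(beats)
    summary = aggregate_periods(normalized, STANDARD_PERIODS)
    recovered = dict(zip(summary["period"], summary["mean"]))
    return BeatRateStudy(
        period_summary=summary,
        exclusions=exclusions,
        recovered=recovered,
        targets=dict(RATE_RECOVERY_TARGETS),
    )


# ---------------------------------------------------------------------------
# landmark (depolarization time / FPD) study


@dataclass
class LandmarkStudy:
    depol_summary: pd.DataFrame
    fpd_summary: pd.DataFrame
    depol_targets: dict[str, float]
    fpd_targets: dict[str, float]


def _render_noisy_beat(
    template: WaveformTemplate,
    depol_mult: float,
    fpd_mult: float,
    sampling_rate_hz: float,
    noise_sd_uv: float,
    rng: np.random.Generator,
    trace_s: float = 1.2,
    p1_at_s: float = 0.3,
) -> np.ndarray:
    n = int(round(trace_s * sampling_rate_hz))
    t_ms = (np.arange(n) / sampling_rate_hz - p1_at_s) * 1000.0
    trace = evaluate_waveform(template, t_ms, depol_mult, fpd_mult)
    return trace + noise_sd_uv * rng.standard_normal(n)


def run_landmark_study(
    seed: int = 0,
    sampling_rate_hz: float = 5000.0,
    noise_sd_uv: float = 10.0,
    sample_scale_sigma: float = 0.05,
    beat_jitter_sigma: float = 0.03,
) -> LandmarkStudy:
    """Render per-timepoint noisy beats and recover the sample-normalized
    depolarization-time and FPD folds.

    Each of the three samples carries its own baseline landmark intervals
    (lognormal 5% around the template); each beat adds mean-one lognormal
    interval jitter.  Detection and landmark location run on every rendered
    trace; folds are normalized per sample to the mean of its own baseline
    values and summarized across samples.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    template = WaveformTemplate()
    n_samples = 3
    sample_scales = np.exp(
        sample_scale_sigma * np.clip(rng.standard_normal((n_samples, 2)), -3, 3)
    )
    rows = []
    params = LandmarkParams()
    for label, depol_fold, fpd_fold, n_beats, samples in LANDMARK_TIMEPOINTS:
        for s in samples:
            for _ in range(n_beats):
                jit = np.exp(
                    beat_jitter_sigma * np.clip(rng.standard_normal(2), -3, 3)
                    - beat_jitter_sigma**2 / 2.0
                )
                dm = depol_fold * sample_scales[s, 0] * jit[0]
                fm = fpd_fold * sample_scales[s, 1] * jit[1]
                trace = _render_noisy_beat(
                    template, dm, fm, sampling_rate_hz, noise_sd_uv, rng
                )
                anchors = detect_beats(trace, sampling_rate_hz)
                if len(anchors) != 1:
                    continue
                lm = locate_landmarks(trace, anchors[0], sampling_rate_hz, params)
                if lm.depol_ms is not None:
                    rows.append(
                        {"sample": s, "timepoint": label, "metric": "depol", "value": lm.depol_ms}
                    )
                if lm.fpd_ms is not None:
                    rows.append(
                        {"sample": s, "timepoint": label, "metric": "fpd", "value": lm.fpd_ms}
                    )
    df = pd.DataFrame(rows)
    out = {}
    for metric in ("depol", "fpd"):
        _, summary = normalize_fp_metrics(
            df[df["metric"] == metric], LANDMARK_BASELINE_TIMEPOINTS
        )
        out[metric] = summary
    return LandmarkStudy(
        depol_summary=out["depol"],
        fpd_summary=out["fpd"],
        depol_targets={tp: d for tp, d, _, _, _ in LANDMARK_TIMEPOINTS},
        fpd_targets={tp: f for tp, _, f, _, _ in LANDMARK_TIMEPOINTS},
    )


# ---------------------------------------------------------------------------
# conduction study

#: Segment starts per analyzed timepoint, kept clear of the program's
#: smoothed period transitions so each timepoint sits on its plateau.
CONDUCTION_TIMEPOINT_STARTS_H = {
    "baseline": (-1.5, -1.0),
    "H8": (7.5, 8.0),
    "H24": (22.5, 23.0),
    "R6": (28.5, 29.0),
    "R24": (46.5, 47.0),
}


def conduction_phase_program(smoothing_h: float = 1.0) -> PhaseProgram:
    """CV multiplier program scaled so the planar-wave mean adjacent lag
    follows the reference per-timepoint lag means (lag ~ 1 / velocity)."""
    base = LAG_TARGETS_MS["baseline"]
    cv_periods = (
        ("baseline", -20.0, 0.0, 1.0),
        ("H0-11", 0.0, 11.0, base / LAG_TARGETS_MS["H8"]),
        ("H11-24", 11.0, 24.0, base / LAG_TARGETS_MS["H24"]),
        ("R0-6", 24.0, 30.0, base / LAG_TARGETS_MS["R6"]),
        ("R6-24", 30.0, 48.0, base / LAG_TARGETS_MS["R24"]),
    )
    cv = build_multiplier_program(cv_periods, smoothing_h=smoothing_h)
    one = constant_program(1.0, -20.0, 48.0)
    return PhaseProgram(rate=one, depol=one, fpd=one, cv=cv)


def conduction_config(seed: int = 0) -> SimConfig:
    """Coherent-sheet planar-wave scenario (no per-electrode rate spread).

    Baseline conduction velocity is calibrated so the ground-truth mean
    4-neighbour lag equals the reference baseline value.
    """
    geometry = GridGeometry.standard_60()
    starts = tuple(
        sorted(t for ts in CONDUCTION_TIMEPOINT_STARTS_H.values() for t in ts)
    )
    return SimConfig(
        geometry=geometry,
        oxygen=OxygenModel.protocol(),
        program=conduction_phase_program(),
        segment_starts_h=starts,
        baseline_bpm_mean=40.0,
        baseline_bpm_rel_sd=0.0,
        baseline_rate_sigma=0.0,
        rate_jitter_sigma=0.0,
        baseline_cv_m_per_s=cv_for_mean_lag(geometry, LAG_TARGETS_MS["baseline"]),
        seed=seed,
    )


@dataclass
class ConductionStudy:
    lag_summary: pd.DataFrame
    recovered_ms: dict[str, float]
    targets_ms: dict[str, float]
    maps_per_timepoint: dict[str, int]


def run_conduction_study(seed: int = 0, min_electrodes: int = 30) -> ConductionStudy:
    config = conduction_config(seed=seed)
    start_to_tp = {
        start: tp
        for tp, starts in CONDUCTION_TIMEPOINT_STARTS_H.items()
        for start in starts
    }
    all_lags = []
    map_counts: dict[str, int] = {tp: 0 for tp in CONDUCTION_TIMEPOINT_STARTS_H}
    for seg in iter_segments(config, with_ground_truth=False):
        tp = start_to_tp[seg.start_h]
        spikes = p1_times(seg, config.sampling_rate_hz)
        maps = activation_times(spikes, config.geometry, min_electrodes=min_electrodes)
        map_counts[tp] += len(maps)
        for amap in maps:
            lags = adjacent_lags(amap)
            lags["timepoint"] = tp
            all_lags.append(lags)
    lags = pd.concat(all_lags, ignore_index=True)
    summary = conduction_summary(lags, "timepoint")
    recovered = dict(zip(summary["timepoint"], summary["mean_ms"]))
    return ConductionStudy(
        lag_summary=summary,
        recovered_ms=recovered,
        targets_ms=dict(LAG_TARGETS_MS),
        maps_per_timepoint=map_counts,
    )


# ---------------------------------------------------------------------------
# morphometry studies


@dataclass
class CoverageStudy:
    per_image_percent: np.ndarray
    recovered_mean_percent: float
    target_percent: float


def run_coverage_study(
    seed: int = 0,
    n_images: int = 124,
    target_percent: float = CONTROL_COVERAGE_PERCENT,
    between_image_sd_percent: float = 10.0,
    shape: tuple[int, int] = (256, 256),
) -> CoverageStudy:
    """Generate control-like sarcomere images and recover mean coverage.

    Per-image positive fractions are Beta-distributed with the control mean;
    the between-image spread is kept moderate -- real image sets show a much
    larger spread, from degraded-morphology fields the generator does not
    emulate.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    mu = target_percent / 100.0
    var = (between_image_sd_percent / 100.0) ** 2
    nu = mu * (1 - mu) / var - 1.0
    if nu <= 0:
        raise ValueError("between-image sd too large for a Beta model")
    alpha, beta = mu * nu, (1 - mu) * nu
    fractions = rng.beta(alpha, beta, size=n_images)
    coverages = []
    for k, frac in enumerate(fractions):
        img = synth_coverage_image(float(frac), shape=shape, rng=rng)
        coverages.append(sarcomere_coverage(img.sarcomere_mask, img.cell_mask))
    per_image = np.asarray(coverages)
    return CoverageStudy(
        per_image_percent=per_image,
        recovered_mean_percent=float(per_image.mean()),
        target_percent=target_percent,
    )


@dataclass
class NucleusStudy:
    measured_areas_um2: np.ndarray
    truth_areas_um2: np.ndarray
    recovered_mean_um2: float
    target_mean_um2: float
    accounting: dict


def run_nucleus_study(
    seed: int = 0,
    n_images: int = 18,
    nuclei_per_image: int = 30,
    mean_area_um2: float = CONTROL_NUCLEUS_AREA_UM2,
    sd_area_um2: float = CONTROL_NUCLEUS_AREA_SD_UM2,
) -> NucleusStudy:
    """Generate a control nucleus population and recover its mean area
    through the Otsu / declump / size-gate / border-gate segmentation."""
    ss = np.random.SeedSequence(seed).spawn(n_images + 1)
    measured: list[float] = []
    truth: list[float] = []
    total = {"detected": 0, "kept": 0, "size_filtered": 0, "border_filtered": 0}
    for k in range(n_images):
        img = synth_nucleus_image(
            nuclei_per_image,
            mean_area_um2=mean_area_um2,
            sd_area_um2=sd_area_um2,
            rng=np.random.default_rng(ss[k]),
        )
        truth.extend(n.area_um2 for n in img.nuclei)
        objects, acc = segment_nuclei(img.nucleus_channel, img.pixel_size_um)
        for key in total:
            total[key] += acc[key]
        areas, _ = nucleus_areas(objects)
        measured.extend(areas.tolist())
    measured_arr = np.asarray(measured)
    return NucleusStudy(
        measured_areas_um2=measured_arr,
        truth_areas_um2=np.asarray(truth),
        recovered_mean_um2=float(measured_arr.mean()),
        target_mean_um2=mean_area_um2,
        accounting=total,
    )


# ---------------------------------------------------------------------------
# qPCR study


@dataclass
class QpcrStudy:
    group_summary: pd.DataFrame
    recovered: dict[str, float]
    targets: dict[str, float]


def run_qpcr_study(seed: int = 0) -> QpcrStudy:
    """Generate a 24 h SLC2A1 Ct table and recover group mean folds."""
    ct = synth_ct_table(
        SLC2A1_24H_FOLDS,
        SLC2A1_24H_N,
        rng=np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2]),
    )
    _, summary, _ = relative_expression(ct, "SLC2A1", calibrator_group="control")
    recovered = dict(zip(summary["group"], summary["mean"]))
    return QpcrStudy(
        group_summary=summary,
        recovered=recovered,
        targets=dict(SLC2A1_24H_FOLDS),
    )
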