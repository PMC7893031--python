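"""Seeded phenomenological simulator of MEA field-potential recordings.

The simulator emulates the statistical structure of a baseline / 24 h
hypoxia / 24 h reoxygenation MEA experiment on an hiPSC-cardiomyocyte sheet:

* intermittent fixed-length segments (1 min every hour at baseline, every
  30 min during hypoxia/reoxygenation in the full protocol; shorter desk
  profiles are configurable);
* per-electrode baseline beat rates drawn log-normally (electrodes over a
  cardiac sheet report different local rates);
* a deterministic :class:`~cardiomea.program.PhaseProgram` that scales
  rate, depolarization time, FPD and conduction velocity over the protocol;
* right-skewed per-segment rate fluctuation during the baseline window
  (irregular spontaneous beating) and mild mean-one fluctuation afterwards;
* planar activation spread from a pacemaker corner with per-beat timing
  jitter; additive white Gaussian noise.

Everything random derives from ``SimConfig.seed`` through a
``numpy.random.SeedSequence`` tree, so equal configs give bit-identical
recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from cardiomea.geometry import GridGeometry
from cardiomea.oxygen import OxygenModel, oxygen_trajectory
from cardiomea.program import PhaseProgram
from cardiomea.waveform import WaveformTemplate, evaluate_waveform

#: Log-sigma of the per-segment baseline rate fluctuation.  The fluctuation
#: is lognormal with median 1, so over the baseline window the mean of the
#: median-normalized rate is exp(sigma^2 / 2) ~= 1.081 -- the right-skewed
#: spontaneous-beating variability the normalization step is designed for.
BASELINE_RATE_SIGMA = float(np.sqrt(2.0 * np.log(1.081)))

#: Default refractory floor between beats, seconds (max ~240 BPM).
REFRACTORY_S = 0.25


def planar_delays_ms(
    geometry: GridGeometry,
    pacemaker_origin: tuple[int, int],
    cv_m_per_s: float,
    direction: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-electrode activation delays (ms) for a planar wave.

    The wavefront normal defaults to the diagonal pointing from the
    pacemaker corner into the array.  Delays are relative to the earliest
    electrode (min delay = 0).
    """
    if cv_m_per_s <= 0:
        raise ValueError("conduction velocity must be positive")
    coords = geometry.coordinates_um()
    r0, c0 = pacemaker_origin
    origin = np.array([c0 * geometry.pitch_um, r0 * geometry.pitch_um])
    if direction is None:
        center = coords.mean(axis=0)
        direction = tuple(center - origin)
    d = np.asarray(direction, dtype=float)
    norm = np.hypot(*d)
    if norm == 0:
        raise ValueError("wave direction must be non-zero")
    d = d / norm
    proj_um = (coords - origin) @ d
    delays = proj_um / (cv_m_per_s * 1000.0)  # um / (um/ms)
    return delays - delays.min()


def cv_for_mean_lag(
    geometry: GridGeometry,
    target_mean_lag_ms: float,
    pacemaker_origin: tuple[int, int] = (0, 0),
    direction: tuple[float, float] | None = None,
) -> float:
    """Conduction velocity (m/s) whose ground-truth mean 4-neighbour lag
    equals ``target_mean_lag_ms`` for a planar wave on this grid."""
    delays = planar_delays_ms(geometry, pacemaker_origin, 1.0, direction)
    pairs = geometry.adjacent_pairs()
    lags = np.abs([delays[i] - delays[j] for i, j in pairs])
    return float(lags.mean() / target_mean_lag_ms)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one simulated experiment."""

    geometry: GridGeometry
    oxygen: OxygenModel
    program: PhaseProgram
    template: WaveformTemplate = field(default_factory=WaveformTemplate)
    segment_starts_h: tuple[float, ...] = ()
    segment_length_s: float = 20.0
    sampling_rate_hz: float = 5000.0
    baseline_bpm_mean: float = 42.0
    baseline_bpm_rel_sd: float = 0.20
    baseline_rate_sigma: float = BASELINE_RATE_SIGMA
    rate_jitter_sigma: float = 0.08
    pacemaker_origin: tuple[int, int] = (0, 0)
    wave_direction: tuple[float, float] | None = None
    baseline_cv_m_per_s: float = 0.314
    activation_jitter_ms: float = 0.1
    noise_sd_uv: float = 10.0
    refractory_s: float = REFRACTORY_S
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.segment_length_s <= 0:
            raise ValueError("sampling rate and segment length must be positive")
        starts = self.segment_starts_h
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")
        if any(b - a < self.segment_length_s / 3600.0 for a, b in zip(starts, starts[1:])):
            raise ValueError("segments overlap")


def protocol_schedule(
    baseline_start_h: float = -20.0,
    hypoxia_onset_h: float = 0.0,
    reox_onset_h: float = 24.0,
    end_h: float = 48.0,
    baseline_every_h: float = 1.0,
    experiment_every_h: float = 0.5,
) -> tuple[float, ...]:
    """Segment start times of the recording protocol (hours, t=0 at hypoxia
    onset): every hour during baseline, every 30 min afterwards."""
    baseline = np.arange(baseline_start_h, hypoxia_onset_h, baseline_every_h)
    experiment = np.arange(hypoxia_onset_h, end_h, experiment_every_h)
    return tuple(np.concatenate([baseline, experiment]).tolist())


@dataclass
class SegmentGroundTruth:
    spike_times: list[np.ndarray]      # per electrode, seconds within segment
    rate_bpm: np.ndarray               # realized per-electrode rate
    delays_ms: np.ndarray              # per-electrode activation delay
    depol_ms: float                    # true P1->P2 interval this segment
    fpd_ms: float                      # true P1->flat interval this segment
    po2_kpa: float


@dataclass
class Segment:
    start_h: float
    traces_uv: np.ndarray              # (n_electrodes, n_samples) float32
    ground_truth: SegmentGroundTruth | None = None


@dataclass
class Recording:
    segments: list[Segment]
    sampling_rate_hz: float
    geometry: GridGeometry
    seed: int | None = None
    base_bpm: np.ndarray | None = None  # per-electrode baseline rate (ground truth)


def _draw_base_bpm(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.geometry.n_electrodes
    sigma = float(np.sqrt(np.log(1.0 + config.baseline_bpm_rel_sd**2)))
    z = np.clip(rng.standard_normal(n), -3.0, 3.0)
    return config.baseline_bpm_mean * np.exp(sigma * z - sigma**2 / 2.0)


def simulate_segment(
    config: SimConfig,
    start_h: float,
    base_bpm: np.ndarray,
    seed_seq: np.random.SeedSequence,
    with_ground_truth: bool = True,
) -> Segment:
    """Synthesize one fixed-length segment for all electrodes."""
    rng = np.random.default_rng(seed_seq)
    fs = config.sampling_rate_hz
    length_s = config.segment_length_s
    n_samples = int(round(length_s * fs))
    n_elec = config.geometry.n_electrodes
    t_mid_h = start_h + length_s / 7200.0

    prog = config.program
    rate_mult = float(prog.rate(t_mid_h))
    depol_mult = float(prog.depol(t_mid_h))
    fpd_mult = float(prog.fpd(t_mid_h))
    cv_mult = float(prog.cv(t_mid_h))

    hypoxia_onset = prog.phase_boundaries[1]
    in_baseline = start_h < hypoxia_onset
    # segment-wide beat phase (shared so that a rate-homogeneous sheet beats
    # coherently and conduction can be mapped across electrodes)
    phase = rng.uniform()

    delays_ms = planar_delays_ms(
        config.geometry,
        config.pacemaker_origin,
        config.baseline_cv_m_per_s * cv_mult,
        config.wave_direction,
    )

    lead_ms, tail_ms = config.template.support_ms(fpd_mult)
    sample_t_s = np.arange(n_samples) / fs
    traces = np.empty((n_elec, n_samples), dtype=np.float32)
    spike_lists: list[np.ndarray] = []
    rates = np.empty(n_elec)

    for e in range(n_elec):
        if in_baseline:
            z = float(np.clip(rng.standard_normal(), -2.8, 2.8))
            jitter = np.exp(config.baseline_rate_sigma * z)  # median 1
        else:
            z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
            s = config.rate_jitter_sigma
            jitter = np.exp(s * z - s**2 / 2.0)  # mean 1
        bpm = base_bpm[e] * rate_mult * jitter
        rates[e] = bpm
        period_s = 60.0 / bpm if bpm > 0 else np.inf
        if period_s < config.refractory_s:
            raise ValueError(
                f"instantaneous rate {bpm:.0f} BPM violates the "
                f"{config.refractory_s * 1000:.0f} ms refractory floor"
            )

        # P1 times of beats whose waveform overlaps the segment
        first_k = int(np.floor((-tail_ms / 1000.0) / period_s - phase)) - 1
        last_k = int(np.ceil((length_s - lead_ms / 1000.0) / period_s - phase)) + 1
        ks = np.arange(first_k, last_k + 1)
        p1_times = (phase + ks) * period_s + delays_ms[e] / 1000.0
        p1_times = p1_times + config.activation_jitter_ms / 1000.0 * rng.standard_normal(len(p1_times))
        keep = (p1_times > -tail_ms / 1000.0) & (p1_times < length_s - lead_ms / 1000.0)
        p1_times = p1_times[keep]

        trace = config.noise_sd_uv * rng.standard_normal(n_samples)
        for t_p1 in p1_times:
            i0 = max(0, int(np.floor((t_p1 + lead_ms / 1000.0) * fs)))
            i1 = min(n_samples, int(np.ceil((t_p1 + tail_ms / 1000.0) * fs)) + 1)
            if i1 <= i0:
                continue
            rel_ms = (sample_t_s[i0:i1] - t_p1) * 1000.0
            trace[i0:i1] += evaluate_waveform(config.template, rel_ms, depol_mult, fpd_mult)
        traces[e] = trace.astype(np.float32)
        inside = p1_times[(p1_times >= 0.0) & (p1_times <= length_s)]
        spike_lists.append(np.sort(inside))

    gt = None
    if with_ground_truth:
        gt = SegmentGroundTruth(
            spike_times=spike_lists,
            rate_bpm=rates,
            delays_ms=delays_ms,
            depol_ms=config.template.p1_p2_interval_ms * depol_mult,
            fpd_ms=config.template.p1_flat_interval_ms * fpd_mult,
            po2_kpa=float(oxygen_trajectory(config.oxygen, start_h)),
        )
    return Segment(start_h=start_h, traces_uv=traces, ground_truth=gt)


def iter_segments(config: SimConfig, with_ground_truth: bool = True) -> Iterator[Segment]:
    """Stream segments one at a time (constant memory for long protocols)."""
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(1 + len(config.segment_starts_h))
    base_bpm = _draw_base_bpm(config, np.random.default_rng(children[0]))
    for k, start_h in enumerate(config.segment_starts_h):
        yield simulate_segment(config, start_h, base_bpm, children[1 + k], with_ground_truth)


def baseline_rates(config: SimConfig) -> np.ndarray:
    """Ground-truth per-electrode baseline BPM for this config's seed."""
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(1)
    return _draw_base_bpm(config, np.random.default_rng(children[0]))


def synthesize_recording(config: SimConfig, with_ground_truth: bool = True) -> Recording:
    """Materialize the full recording in memory (small protocols)."""
    segments = list(iter_segments(config, with_ground_truth))
    return Recording(
        segments=segments,
        sampling_rate_hz=config.sampling_rate_hz,
        geometry=config.geometry,
        seed=config.seed,
        base_bpm=baseline_rates(config),
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
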