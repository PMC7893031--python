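from dataclasses import replace

import numpy as np
import pytest

from cardiomea.geometry import GridGeometry
from cardiomea.oxygen import OxygenModel
from cardiomea.program import PhaseProgram
from cardiomea.simulate import SimConfig, cv_for_mean_lag
from cardiomea.waveform import WaveformTemplate, evaluate_waveform


@pytest.fixture
def template() -> WaveformTemplate:
    return WaveformTemplate()


@pytest.fixture
def small_config() -> SimConfig:
    """Two short coherent-sheet segments, quiet enough for exact checks."""
    geometry = GridGeometry.standard_60()
    return SimConfig(
        geometry=geometry,
        oxygen=OxygenModel.protocol(),
        program=PhaseProgram.identity(),
        segment_starts_h=(-2.0, -1.0),
        segment_length_s=8.0,
        baseline_bpm_mean=40.0,
        baseline_bpm_rel_sd=0.0,
        baseline_rate_sigma=0.0,
        rate_jitter_sigma=0.0,
        baseline_cv_m_per_s=cv_for_mean_lag(geometry, 0.45),
        noise_sd_uv=0.0,
        activation_jitter_ms=0.0,
        seed=11,
    )


@pytest.fixture
def noisy_config(small_config) -> SimConfig:
    return replace(small_config, noise_sd_uv=10.0, activation_jitter_ms=0.1)


def render_beat_trace(
    template: WaveformTemplate,
    depol_mult: float = 1.0,
    fpd_mult: float = 1.0,
    fs: float = 5000.0,
    noise_sd: float = 0.0,
    p1_at_s: float = 0.3,
    trace_s: float = 1.2,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One beat on a flat trace with P1 at ``p1_at_s``."""
    n = int(round(trace_s * fs))
    t_ms = (np.arange(n) / fs - p1_at_s) * 1000.0
    trace = evaluate_waveform(template, t_ms, depol_mult, fpd_mult)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        trace = trace + noise_sd * rng.standard_normal(n)
    return trace
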