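"""Phenomenological extracellular field-potential waveform of one beat.

One beat is modelled as three Gaussian components on a flat baseline:

* P1 -- the sharp positive deflection of the fast depolarizing inward
  current (the reference landmark);
* P2 -- the opposite-signed deflection completing the biphasic spike;
  the P1->P2 interval is the *depolarization time*;
* the low-amplitude "flat peak" of repolarization; the P1->flat interval
  is the *field potential duration* (FPD), the extracellular analogue of
  the action-potential duration.

The component widths are narrow relative to the landmark intervals, so the
rendered extrema sit at the programmed landmark times to numerical
precision, which makes the template usable as exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class WaveformTemplate:
    """Baseline landmark anatomy of one field potential.

    Intervals are baseline values in milliseconds; simulation scales the
    P1->P2 interval by the depolarization multiplier and the P1->flat
    interval by the FPD multiplier.
    """

    p1_amplitude_uv: float = 200.0
    p2_amplitude_uv: float = -150.0
    p1_p2_interval_ms: float = 8.0
    flat_peak_amplitude_uv: float = 30.0
    p1_flat_interval_ms: float = 350.0
    spike_width_ms: float = 1.5   # Gaussian sigma of P1/P2
    flat_width_ms: float = 40.0   # Gaussian sigma of the flat peak

    def __post_init__(self) -> None:
        if self.p1_p2_interval_ms >= self.p1_flat_interval_ms:
            raise ValueError("p1_p2_interval_ms must be < p1_flat_interval_ms")
        if abs(self.flat_peak_amplitude_uv) >= abs(self.p1_amplitude_uv):
            raise ValueError("flat peak must be smaller than P1")
        if self.spike_width_ms <= 0 or self.flat_width_ms <= 0:
            raise ValueError("component widths must be positive")

    def support_ms(self, fpd_mult: float = 1.0) -> tuple[float, float]:
        """Time span (relative to P1) outside which the beat is ~zero."""
        lead = 5 * self.spike_width_ms
        tail = self.p1_flat_interval_ms * fpd_mult + 5 * self.flat_width_ms
        return -lead, tail


def render_waveform(
    template: WaveformTemplate,
    depol_mult: float = 1.0,
    fpd_mult: float = 1.0,
    sampling_rate_hz: float = 5000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one beat; returns ``(t_ms, trace_uv)`` with P1 at t = 0.

    The true P1->P2 interval of the rendered beat is
    ``p1_p2_interval_ms * depol_mult`` and the true P1->flat interval is
    ``p1_flat_interval_ms * fpd_mult``, each exact up to sampling.
    """
    if depol_mult <= 0 or fpd_mult <= 0:
        raise ValueError("multipliers must be > 0")
    dt_ms = 1000.0 / sampling_rate_hz
    depol_ms = template.p1_p2_interval_ms * depol_mult
    fpd_ms = template.p1_flat_interval_ms * fpd_mult
    if depol_ms < 2 * dt_ms or fpd_ms < 2 * dt_ms:
        raise ValueError("landmark interval shorter than 2 samples")
    lo, hi = template.support_ms(fpd_mult)
    t_ms = np.arange(np.floor(lo / dt_ms), np.ceil(hi / dt_ms) + 1) * dt_ms
    return t_ms, evaluate_waveform(template, t_ms, depol_mult, fpd_mult)


def evaluate_waveform(
    template: WaveformTemplate,
    t_ms: np.ndarray,
    depol_mult: float = 1.0,
    fpd_mult: float = 1.0,
) -> np.ndarray:
    """Evaluate the beat waveform (uV) at times ``t_ms`` relative to P1."""
    depol_ms = template.p1_p2_interval_ms * depol_mult
    fpd_ms = template.p1_flat_interval_ms * fpd_mult
    s2 = 2 * template.spike_width_ms**2
    f2 = 2 * template.flat_width_ms**2
    out = template.p1_amplitude_uv * np.exp(-(t_ms**2) / s2)
    out += template.p2_amplitude_uv * np.exp(-((t_ms - depol_ms) ** 2) / s2)
    out += template.flat_peak_amplitude_uv * np.exp(-((t_ms - fpd_ms) ** 2) / f2)
    return out
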