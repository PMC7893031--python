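"""First-order oxygen-exchange model of the culture chamber.

Gas switching between normoxic (19 kPa) and anoxic (0 kPa) set-points does
not change the dissolved oxygen of the culture instantaneously; the culture
pO2 relaxes toward the active set-point with first-order kinetics.  The
default time constant tau = 4/3 h places the trajectory within 5% of the
step span 4 h (= 3 tau) after a switch, matching the observed stabilization
of the measured culture oxygen within about four hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default relaxation time constant, hours (3 tau = 4 h).
DEFAULT_TAU_H = 4.0 / 3.0


@dataclass(frozen=True)
class OxygenModel:
    """Piecewise first-order pO2 relaxation between gas set-points.

    Parameters
    ----------
    p_normoxic, p_hypoxic
        Gas set-points in kPa (defaults 19 and 0).
    tau_h
        First-order time constant in hours.
    switch_times
        ``(time_h, target_kPa)`` pairs, time-ordered.  The trajectory starts
        at the first target (the culture is equilibrated before the first
        switch) and relaxes toward each subsequent target.
    """

    p_normoxic: float = 19.0
    p_hypoxic: float = 0.0
    tau_h: float = DEFAULT_TAU_H
    switch_times: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.tau_h <= 0:
            raise ValueError("tau_h must be positive")
        for _, p in self.switch_times:
            if not (0.0 <= p <= 21.0):
                raise ValueError(f"target pressure {p} kPa outside [0, 21]")
        times = [t for t, _ in self.switch_times]
        if times != sorted(times):
            raise ValueError("switch_times must be time-ordered")

    @classmethod
    def protocol(
        cls,
        baseline_start_h: float = -20.0,
        hypoxia_onset_h: float = 0.0,
        reox_onset_h: float = 24.0,
        tau_h: float = DEFAULT_TAU_H,
    ) -> "OxygenModel":
        """Standard protocol: normoxic baseline, hypoxia, reoxygenation."""
        return cls(
            tau_h=tau_h,
            switch_times=(
                (baseline_start_h, 19.0),
                (hypoxia_onset_h, 0.0),
                (reox_onset_h, 19.0),
            ),
        )


def oxygen_trajectory(model: OxygenModel, t: float | np.ndarray) -> np.ndarray | float:
    """Evaluate the pO2 trajectory (kPa) at time(s) ``t`` (hours).

    The trajectory is continuous: at each switch it starts from the level
    reached under the previous target and relaxes exponentially toward the
    new one.  Times before the first switch are an error because no initial
    level is defined there.
    """
    if not model.switch_times:
        raise ValueError("OxygenModel has no switch_times")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    t0 = model.switch_times[0][0]
    if np.any(t_arr < t0):
        raise ValueError(f"time before first switch at {t0} h has no defined pO2")

    # level at each switch, propagated analytically
    levels = [model.switch_times[0][1]]
    for k in range(1, len(model.switch_times)):
        t_prev, p_prev = model.switch_times[k - 1]
        t_k = model.switch_times[k][0]
        decay = np.exp(-(t_k - t_prev) / model.tau_h)
        levels.append(p_prev + (levels[-1] - p_prev) * decay)

    out = np.empty_like(t_arr)
    switch_ts = np.asarray([s[0] for s in model.switch_times])
    idx = np.searchsorted(switch_ts, t_arr, side="right") - 1
    for k in range(len(model.switch_times)):
        sel = idx == k
        if not np.any(sel):
            continue
        t_k, target = model.switch_times[k]
        start = levels[k]
        out[sel] = target + (start - target) * np.exp(-(t_arr[sel] - t_k) / model.tau_h)
    return out if np.ndim(t) else float(out[0])
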