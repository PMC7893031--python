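"""Phase-dependent multiplier programs for the hypoxia-reoxygenation protocol.

The electrophysiological state of the preparation (beat rate, depolarization
time, FPD, conduction velocity) is modelled as a per-quantity *multiplier
program*: a piecewise-smooth, strictly positive function of time whose value
scales the per-electrode baseline.  Programs are built from period targets
(e.g. the mean normalized beating frequency per analysis period) joined by
monotone cubic (smoothstep) transitions of configurable width.

The plateau levels are not the targets themselves: smoothing a step function
changes the time average of short periods.  ``build_multiplier_program``
solves a small tridiagonal linear system so that the exact time average of
the built function over every period equals its target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

# integral of the smoothstep 3x^2 - 2x^3 over [0, 1/2] (== of 1-s over [1/2, 1])
_SMOOTHSTEP_HALF_AREA = 3.0 / 32.0


@dataclass(frozen=True)
class PeriodTarget:
    label: str
    start_h: float
    end_h: float
    target: float

    @property
    def length_h(self) -> float:
        return self.end_h - self.start_h


class MultiplierProgram:
    """Piecewise-smooth positive multiplier of time (hours).

    Callable and numpy-vectorized.  Constant outside the covered span
    (clamped to the first/last plateau).
    """

    def __init__(self, periods: Sequence[PeriodTarget], levels: np.ndarray, smoothing_h: float):
        self.periods = list(periods)
        self.levels = np.asarray(levels, dtype=float)
        self.smoothing_h = float(smoothing_h)
        self._boundaries = np.asarray([p.start_h for p in self.periods[1:]])

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self._boundaries, t_arr, side="right")
        out = self.levels[idx]
        w = self.smoothing_h
        if w > 0:
            for k, b in enumerate(self._boundaries):
                a, c = self.levels[k], self.levels[k + 1]
                sel = np.abs(t_arr - b) < w / 2
                if np.any(sel):
                    x = (t_arr[sel] - b + w / 2) / w
                    s = 3 * x**2 - 2 * x**3
                    out = np.array(out, copy=True)
                    out[sel] = a + (c - a) * s
        return out if np.ndim(t) else float(out[0])

    @property
    def span_h(self) -> tuple[float, float]:
        return self.periods[0].start_h, self.periods[-1].end_h

    def period_average(self, start_h: float, end_h: float, n: int = 4001) -> float:
        """Time average over [start_h, end_h] by trapezoid quadrature."""
        t = np.linspace(start_h, end_h, n)
        return float(np.trapezoid(self(t), t) / (end_h - start_h))


def build_multiplier_program(
    periods: Sequence[tuple[str, float, float, float]],
    smoothing_h: float = 1.0,
) -> MultiplierProgram:
    """Build a multiplier program from ``(label, start_h, end_h, target)`` rows.

    Periods must tile their span contiguously (no gaps, no overlaps) and all
    targets must be strictly positive.  The returned program's exact time
    average over every period equals the period's target.
    """
    pts = [PeriodTarget(*row) for row in periods]
    pts.sort(key=lambda p: p.start_h)
    if not pts:
        raise ValueError("at least one period is required")
    for p in pts:
        if p.length_h <= 0:
            raise ValueError(f"period {p.label!r} has non-positive length")
        if p.target <= 0:
            raise ValueError(f"period {p.label!r} target must be > 0")
    for a, b in zip(pts, pts[1:]):
        if not np.isclose(a.end_h, b.start_h):
            kind = "overlap" if a.end_h > b.start_h else "gap"
            raise ValueError(f"{kind} between periods {a.label!r} and {b.label!r}")
    if smoothing_h < 0:
        raise ValueError("smoothing_h must be >= 0")
    min_len = min(p.length_h for p in pts)
    if smoothing_h > min_len:
        raise ValueError("smoothing window exceeds the shortest period")

    n = len(pts)
    targets = np.asarray([p.target for p in pts])
    if smoothing_h == 0 or n == 1:
        return MultiplierProgram(pts, targets, smoothing_h)

    # Solve M @ levels = targets where the time average of period i is
    # a_i + k_i * sum_neighbours (a_j - a_i), k_i = smoothing * C / L_i.
    M = np.eye(n)
    for i, p in enumerate(pts):
        k = smoothing_h * _SMOOTHSTEP_HALF_AREA / p.length_h
        for j in (i - 1, i + 1):
            if 0 <= j < n:
                M[i, i] -= k
                M[i, j] += k
    levels = np.linalg.solve(M, targets)
    if np.any(levels <= 0):
        raise ValueError("period targets produce non-positive plateau levels")
    return MultiplierProgram(pts, levels, smoothing_h)


def constant_program(value: float = 1.0, start_h: float = -20.0, end_h: float = 48.0) -> MultiplierProgram:
    return build_multiplier_program([("all", start_h, end_h, value)], smoothing_h=0.0)


@dataclass(frozen=True)
class PhaseProgram:
    """Ground-truth time programs for one simulated experiment.

    All four multipliers are relative to the per-electrode baseline and
    strictly positive; ``phase_boundaries`` holds (baseline start, hypoxia
    onset, reoxygenation onset, end) in hours, with t = 0 at hypoxia onset.
    """

    rate: Callable[[np.ndarray], np.ndarray]
    depol: Callable[[np.ndarray], np.ndarray]
    fpd: Callable[[np.ndarray], np.ndarray]
    cv: Callable[[np.ndarray], np.ndarray]
    phase_boundaries: tuple[float, float, float, float] = (-20.0, 0.0, 24.0, 48.0)

    @classmethod
    def identity(cls, boundaries: tuple[float, float, float, float] = (-20.0, 0.0, 24.0, 48.0)) -> "PhaseProgram":
        start, _, _, end = boundaries
        one = constant_program(1.0, start, end)
        return cls(rate=one, depol=one, fpd=one, cv=one, phase_boundaries=boundaries)


def build_phase_program(
    rate_periods: Sequence[tuple[str, float, float, float]],
    depol_periods: Sequence[tuple[str, float, float, float]] | None = None,
    fpd_periods: Sequence[tuple[str, float, float, float]] | None = None,
    cv_periods: Sequence[tuple[str, float, float, float]] | None = None,
    smoothing_h: float = 1.0,
    phase_boundaries: tuple[float, float, float, float] = (-20.0, 0.0, 24.0, 48.0),
) -> PhaseProgram:
    """Assemble a :class:`PhaseProgram` from per-quantity period targets.

    Quantities without targets default to the identity multiplier.
    """
    start, _, _, end = phase_boundaries

    def build(rows):
        if rows is None:
            return constant_program(1.0, start, end)
        return build_multiplier_program(rows, smoothing_h=smoothing_h)

    return PhaseProgram(
        rate=build(rate_periods),
        depol=build(depol_periods),
        fpd=build(fpd_periods),
        cv=build(cv_periods),
        phase_boundaries=phase_boundaries,
    )
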