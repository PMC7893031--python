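"""Activation mapping and adjacent-electrode conduction lags.

For every sheet-wide beat, the activation time of an electrode is the P1
time of its matched field potential.  Beats are matched across electrodes
by nearest-neighbour association within a coincidence window around the
beats of a reference electrode; beats seen on too few electrodes are
skipped.  Conduction is summarized as the pooled mean +/- sd of the
absolute activation-time difference over all grid-adjacent (x or y)
electrode pairs and all beats of a timepoint -- the "lag per adjacent
pair" statistic (one positive number per timepoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cardiomea.geometry import GridGeometry
from cardiomea.features import DetectionParams, LandmarkParams, detect_beats, locate_landmarks
from cardiomea.simulate import Segment


@dataclass
class ActivationMap:
    """Relative activation times (ms) of one beat; NaN = electrode absent."""

    beat_index: int
    times_ms: np.ndarray  # (n_electrodes,), min over finite entries == 0
    geometry: GridGeometry

    def grid_matrix(self) -> np.ndarray:
        """(n_rows, n_cols) matrix of activation times, NaN where absent."""
        m = np.full((self.geometry.n_rows, self.geometry.n_cols), np.nan)
        for idx, (r, c) in enumerate(self.geometry.positions):
            m[r, c] = self.times_ms[idx]
        return m


def p1_times(
    segment: Segment,
    sampling_rate_hz: float,
    detection: DetectionParams = DetectionParams(),
    landmarks: LandmarkParams = LandmarkParams(),
) -> list[np.ndarray]:
    """Refined P1 times (s) per electrode of one segment."""
    out = []
    for trace in segment.traces_uv:
        anchors = detect_beats(trace, sampling_rate_hz, detection)
        refined = [
            locate_landmarks(trace, t, sampling_rate_hz, landmarks).p1_s for t in anchors
        ]
        out.append(np.asarray(refined))
    return out


def activation_times(
    spike_times: list[np.ndarray],
    geometry: GridGeometry,
    coincidence_window_s: float = 0.05,
    min_electrodes: int = 30,
) -> list[ActivationMap]:
    """Match beats across electrodes and build per-beat activation maps.

    ``spike_times`` holds refined P1 times (s) per electrode.  The electrode
    with the most beats serves as reference; for each of its beats, every
    other electrode contributes its nearest spike within the coincidence
    window.  Beats matched on fewer than ``min_electrodes`` electrodes are
    skipped.  Returns an empty list (nothing to map) for degenerate input.
    """
    n_elec = len(spike_times)
    if n_elec < 2:
        return []
    counts = [len(s) for s in spike_times]
    ref = int(np.argmax(counts))
    maps: list[ActivationMap] = []
    for b, t_ref in enumerate(spike_times[ref]):
        times = np.full(n_elec, np.nan)
        for e in range(n_elec):
            s = spike_times[e]
            if len(s) == 0:
                continue
            j = int(np.searchsorted(s, t_ref))
            best = None
            for cand in (j - 1, j):
                if 0 <= cand < len(s):
                    d = abs(s[cand] - t_ref)
                    if d <= coincidence_window_s and (best is None or d < abs(s[best] - t_ref)):
                        best = cand
            if best is not None:
                times[e] = s[best]
        matched = np.isfinite(times)
        if matched.sum() < min_electrodes:
            continue
        rel_ms = (times - np.nanmin(times)) * 1000.0
        maps.append(ActivationMap(beat_index=b, times_ms=rel_ms, geometry=geometry))
    return maps


def adjacent_lags(amap: ActivationMap) -> pd.DataFrame:
    """Absolute activation lags (ms) over all present 4-neighbour pairs."""
    rows = []
    ids = amap.geometry.electrode_ids
    for i, j in amap.geometry.adjacent_pairs():
        ti, tj = amap.times_ms[i], amap.times_ms[j]
        if np.isnan(ti) or np.isnan(tj):
            continue
        rows.append(
            {
                "electrode_a": ids[i],
                "electrode_b": ids[j],
                "beat_index": amap.beat_index,
                "lag_ms": abs(ti - tj),
            }
        )
    return pd.DataFrame(rows, columns=["electrode_a", "electrode_b", "beat_index", "lag_ms"])


def conduction_summary(lags: pd.DataFrame, group_col: str = "timepoint") -> pd.DataFrame:
    """Pooled mean +/- sd of lag over all pairs and beats per group."""
    rows = []
    for label, grp in lags.groupby(group_col, sort=False):
        vals = grp["lag_ms"].to_numpy()
        rows.append(
            {
                group_col: label,
                "n_lags": int(vals.size),
                "mean_ms": float(vals.mean()) if vals.size else np.nan,
                "sd_ms": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "empty": vals.size == 0,
            }
        )
    return pd.DataFrame(rows)


def activation_heatmap(amap: ActivationMap):
    """Grid matrix of relative activation times (NaN-masked where absent)."""
    return amap.grid_matrix()


def save_heatmap_figure(
    matrix: np.ndarray,
    path,
    vmax_ms: float | None = None,
    title: str | None = None,
) -> None:
    """Render an activation heatmap to an image file.

    ``vmax_ms`` fixes the colour scale so heatmaps of different timepoints
    stay comparable.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.4))
    masked = np.ma.masked_invalid(matrix)
    im = ax.imshow(masked, cmap="viridis", vmin=0.0, vmax=vmax_ms, origin="upper")
    fig.colorbar(im, ax=ax, label="activation time (ms)")
    if title:
        ax.set_title(title)
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
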