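"""Activation maps, adjacent lags and the lag-velocity duality."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from cardiomea.conduction import (
    ActivationMap,
    activation_times,
    adjacent_lags,
    conduction_summary,
    p1_times,
)
from cardiomea.geometry import GridGeometry
from cardiomea.simulate import synthesize_recording


def planar_x_spikes(geometry, v_m_per_s, n_beats=3, period_s=1.5):
    """Constructed spike trains for a plane wave travelling along +x."""
    coords = geometry.coordinates_um()
    delays_s = coords[:, 0] / (v_m_per_s * 1e6)
    return [
        np.asarray([k * period_s + d for k in range(n_beats)])
        for d in delays_s
    ]


class TestActivationTimes:
    def test_constructed_planar_wave_recovered_exactly(self):
        g = GridGeometry.standard_60()
        spikes = planar_x_spikes(g, 0.3)
        maps = activation_times(spikes, g, min_electrodes=30)
        assert len(maps) == 3
        coords = g.coordinates_um()
        expected = (coords[:, 0] - coords[:, 0].min()) / (0.3 * 1000.0)  # ms
        assert np.allclose(maps[0].times_ms, expected, atol=1e-6)

    def test_single_electrode_cannot_map(self):
        g = GridGeometry.standard_60()
        assert activation_times([np.array([0.0, 1.0])], g) == []

    def test_synchronous_beats_give_zero_relative_times(self):
        g = GridGeometry(2, 2, 200.0)
        spikes = [np.array([1.0]) for _ in range(4)]
        maps = activation_times(spikes, g, min_electrodes=4)
        assert np.allclose(maps[0].times_ms, 0.0)

    def test_minimum_electrode_count_enforced(self):
        g = GridGeometry.standard_60()
        spikes = planar_x_spikes(g, 0.3)
        spikes = [s if i < 10 else np.array([]) for i, s in enumerate(spikes)]
        assert activation_times(spikes, g, min_electrodes=30) == []


class TestAdjacentLags:
    def test_planar_x_wave_lag_geometry(self):
        g = GridGeometry.standard_60()
        v = 0.25  # m/s
        maps = activation_times(planar_x_spikes(g, v), g, min_electrodes=30)
        lags = adjacent_lags(maps[0])
        labels = {tuple(sorted((a, b))) for a, b in zip(lags["electrode_a"], lags["electrode_b"])}
        assert len(labels) == 104
        expected_x = g.pitch_um / (v * 1000.0)
        ids = g.electrode_ids
        pos = dict(zip(ids, g.positions))
        for _, row in lags.iterrows():
            (ra, ca), (rb, cb) = pos[row["electrode_a"]], pos[row["electrode_b"]]
            expected = expected_x if ca != cb else 0.0
            assert row["lag_ms"] == pytest.approx(expected, abs=1e-6)

    def test_absent_electrode_pairs_skipped(self):
        g = GridGeometry.standard_60()
        times = np.zeros(g.n_electrodes)
        times[5] = np.nan
        amap = ActivationMap(0, times, g)
        lags = adjacent_lags(amap)
        assert not lags[["electrode_a", "electrode_b"]].isin([g.electrode_ids[5]]).any().any()


class TestConductionSummary:
    def test_hand_list_mean(self):
        lags = pd.DataFrame({"timepoint": ["b", "b"], "lag_ms": [0.4, 0.5]})
        s = conduction_summary(lags)
        assert s["mean_ms"].iloc[0] == pytest.approx(0.45)

    def test_constant_lags_zero_sd(self):
        lags = pd.DataFrame({"timepoint": ["b"] * 5, "lag_ms": [0.45] * 5})
        s = conduction_summary(lags)
        assert s["sd_ms"].iloc[0] == pytest.approx(0.0)


class TestEndToEnd:
    def test_lag_velocity_duality_within_2pct(self, small_config):
        """pitch / mean axis-projected lag recovers the programmed velocity."""
        rec = synthesize_recording(small_config)
        seg = rec.segments[0]
        spikes = p1_times(seg, rec.sampling_rate_hz)
        maps = activation_times(spikes, rec.geometry, min_electrodes=30)
        assert maps
        lags = pd.concat([adjacent_lags(m) for m in maps], ignore_index=True)
        # diagonal plane wave: every 4-neighbour lag is pitch/sqrt(2)/v
        mean_lag_ms = lags["lag_ms"].mean()
        v_rec = rec.geometry.pitch_um / np.sqrt(2) / (mean_lag_ms * 1000.0)
        assert v_rec == pytest.approx(small_config.baseline_cv_m_per_s, rel=0.02)

    def test_halved_cv_doubles_recovered_lag(self, small_config):
        def mean_lag(cfg):
            rec = synthesize_recording(cfg)
            seg = rec.segments[0]
            maps = activation_times(
                p1_times(seg, rec.sampling_rate_hz), rec.geometry, min_electrodes=30
            )
            lags = pd.concat([adjacent_lags(m) for m in maps], ignore_index=True)
            return lags["lag_ms"].mean()

        fast = mean_lag(small_config)
        slow = mean_lag(replace(small_config, baseline_cv_m_per_s=small_config.baseline_cv_m_per_s / 2))
        assert slow == pytest.approx(2.0 * fast, rel=0.03)

    def test_heatmap_matrix_properties(self, small_config):
        rec = synthesize_recording(small_config)
        seg = rec.segments[0]
        maps = activation_times(
            p1_times(seg, rec.sampling_rate_hz), rec.geometry, min_electrodes=30
        )
        m = maps[0].grid_matrix()
        assert m.shape == (8, 8)
        assert np.isnan(m[0, 0]) and np.isnan(m[7, 7])  # corners absent
        assert np.nanmin(m) == pytest.approx(0.0, abs=1e-9)
        # diagonal wave from the (0,0) corner: rows and columns increase
        finite_cols = np.nanmean(m, axis=0)
        assert np.all(np.diff(finite_cols) > 0)
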