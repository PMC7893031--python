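"""Reading and writing of recordings and result tables.

The package HDF5 dialect (the ingestion boundary for MEA data; vendor
binary formats are out of scope) is::

    /                       attrs: sampling_rate_hz, seed (optional)
    /geometry               attrs: n_rows, n_cols, pitch_um
        missing             (k, 2) int  absent grid positions
    /segments/<k>           attrs: start_h
        traces              (n_electrodes, n_samples) float32, microvolts
    /ground_truth           (optional)
        base_bpm            (n_electrodes,) float
        segments/<k>
            spikes          (n_spikes, 2) float  [electrode index, time s]
            delays_ms       (n_electrodes,) float
            attrs: depol_ms, fpd_ms, po2_kpa

Datasets are written with ``track_times=False`` so identically seeded runs
produce byte-identical files.

ASCII spike exports are whitespace-delimited ``<electrode label> <time s>``
lines with ``#`` comments, one file per segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from cardiomea.geometry import GridGeometry
from cardiomea.simulate import Recording, Segment, SegmentGroundTruth


class FormatError(ValueError):
    """A file does not conform to the documented layout."""


_DS_OPTS = dict(track_times=False)


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` in the package HDF5 dialect."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate_hz"] = float(recording.sampling_rate_hz)
        if recording.seed is not None:
            f.attrs["seed"] = int(recording.seed)
        geo = f.create_group("geometry")
        geo.attrs["n_rows"] = recording.geometry.n_rows
        geo.attrs["n_cols"] = recording.geometry.n_cols
        geo.attrs["pitch_um"] = recording.geometry.pitch_um
        missing = np.asarray(sorted(recording.geometry.missing), dtype=np.int64)
        geo.create_dataset("missing", data=missing.reshape(-1, 2), **_DS_OPTS)
        seg_grp = f.create_group("segments")
        any_gt = any(s.ground_truth is not None for s in recording.segments)
        gt_grp = f.create_group("ground_truth") if any_gt or recording.base_bpm is not None else None
        if recording.base_bpm is not None:
            gt_grp.create_dataset("base_bpm", data=np.asarray(recording.base_bpm, float), **_DS_OPTS)
        for k, seg in enumerate(recording.segments):
            g = seg_grp.create_group(str(k))
            g.attrs["start_h"] = float(seg.start_h)
            g.create_dataset("traces", data=np.asarray(seg.traces_uv, np.float32), **_DS_OPTS)
            if seg.ground_truth is not None:
                sg = gt_grp.create_group(f"segments/{k}")
                gt = seg.ground_truth
                rows = [
                    (float(e), float(t))
                    for e, times in enumerate(gt.spike_times)
                    for t in times
                ]
                spikes = np.asarray(rows, dtype=float).reshape(-1, 2)
                sg.create_dataset("spikes", data=spikes, **_DS_OPTS)
                sg.create_dataset("delays_ms", data=gt.delays_ms, **_DS_OPTS)
                sg.create_dataset("rate_bpm", data=gt.rate_bpm, **_DS_OPTS)
                sg.attrs["depol_ms"] = gt.depol_ms
                sg.attrs["fpd_ms"] = gt.fpd_ms
                sg.attrs["po2_kpa"] = gt.po2_kpa


def _require_attr(obj, name: str, where: str):
    if name not in obj.attrs:
        raise FormatError(f"missing required attribute {name!r} at {where}")
    return obj.attrs[name]


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`FormatError` naming the offending path when required
    groups or attributes are absent.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        fs = float(_require_attr(f, "sampling_rate_hz", "/"))
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        if "geometry" not in f:
            raise FormatError("missing required group '/geometry'")
        geo = f["geometry"]
        missing = frozenset(
            (int(r), int(c)) for r, c in np.asarray(geo["missing"]).reshape(-1, 2)
        )
        geometry = GridGeometry(
            n_rows=int(_require_attr(geo, "n_rows", "/geometry")),
            n_cols=int(_require_attr(geo, "n_cols", "/geometry")),
            pitch_um=float(_require_attr(geo, "pitch_um", "/geometry")),
            missing=missing,
        )
        if "segments" not in f:
            raise FormatError("missing required group '/segments'")
        n_elec = geometry.n_electrodes
        base_bpm = None
        if "ground_truth" in f and "base_bpm" in f["ground_truth"]:
            base_bpm = np.asarray(f["ground_truth/base_bpm"])
        segments = []
        keys = sorted(f["segments"].keys(), key=int)
        for k in keys:
            g = f["segments"][k]
            start_h = float(_require_attr(g, "start_h", f"/segments/{k}"))
            traces = np.asarray(g["traces"], dtype=np.float32)
            gt = None
            gt_path = f"ground_truth/segments/{k}"
            if gt_path in f:
                sg = f[gt_path]
                spikes = np.asarray(sg["spikes"]).reshape(-1, 2)
                spike_times = [
                    np.sort(spikes[spikes[:, 0] == e, 1]) for e in range(n_elec)
                ]
                gt = SegmentGroundTruth(
                    spike_times=spike_times,
                    rate_bpm=np.asarray(sg["rate_bpm"]),
                    delays_ms=np.asarray(sg["delays_ms"]),
                    depol_ms=float(sg.attrs["depol_ms"]),
                    fpd_ms=float(sg.attrs["fpd_ms"]),
                    po2_kpa=float(sg.attrs["po2_kpa"]),
                )
            segments.append(Segment(start_h=start_h, traces_uv=traces, ground_truth=gt))
    return Recording(
        segments=segments,
        sampling_rate_hz=fs,
        geometry=geometry,
        seed=seed,
        base_bpm=base_bpm,
    )


@dataclass
class SpikeExport:
    """Per-electrode spike timestamps of one segment (ASCII exchange)."""

    spike_times: dict[str, np.ndarray] = field(default_factory=dict)
    segment_start_h: float | None = None


def write_spike_ascii(export: SpikeExport, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# electrode_label time_s\n")
        if export.segment_start_h is not None:
            fh.write(f"# segment_start_h {export.segment_start_h}\n")
        for label in export.spike_times:
            for t in export.spike_times[label]:
                fh.write(f"{label}\t{t:.6f}\n")


def read_spike_ascii(path: str | Path) -> SpikeExport:
    """Parse a whitespace-delimited ``label  time_s`` export.

    ``#`` lines are comments; a ``# segment_start_h <h>`` comment is parsed
    back.  Non-monotone timestamps for an electrode raise an error citing
    the line number.
    """
    path = Path(path)
    times: dict[str, list[float]] = {}
    start_h = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] == "segment_start_h":
                    start_h = float(parts[1])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path.name}:{lineno}: expected 'label time_s'")
            label, t_str = parts
            t = float(t_str)
            bucket = times.setdefault(label, [])
            if bucket and t <= bucket[-1]:
                raise FormatError(
                    f"{path.name}:{lineno}: non-monotone timestamp for electrode {label}"
                )
            bucket.append(t)
    return SpikeExport(
        spike_times={k: np.asarray(v) for k, v in times.items()},
        segment_start_h=start_h,
    )


def write_result_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy long-format result table as CSV with a header row."""
    key_cols = [c for c in ("sample", "electrode", "time_h", "period", "metric") if c in df.columns]
    if key_cols and df.duplicated(subset=key_cols).any():
        raise ValueError(f"duplicate result rows for keys {key_cols}")
    df.to_csv(path, index=False)
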