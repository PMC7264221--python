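"""Readers/writers for the pipeline's on-disk formats.

Traces travel as tabular text (one column per ROI, header row) or HDF5;
movies as multi-page TIFF; labels, spike trains, ROI centroids and
experiment summaries as CSV.
"""

from __future__ import annotations

from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import RAW, FluorescenceMovie, SpikeTrain, Trace


def traces_to_frame(traces: Sequence[Trace]) -> pd.DataFrame:
    """Traces as a table with one ``roi_<id>`` column per ROI."""
    return pd.DataFrame({f"roi_{tr.roi_id}": tr.values for tr in traces})


def save_traces_csv(traces: Sequence[Trace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def load_traces_csv(path, frame_rate_hz: float, stage: str = RAW) -> list[Trace]:
    df = pd.read_csv(path)
    return [
        Trace(df[col].to_numpy(), frame_rate_hz, stage, int(col.removeprefix("roi_")))
        for col in df.columns
    ]


def save_traces_hdf5(traces: Sequence[Trace], path, stage_attr: str | None = None) -> None:
    with h5py.File(path, "w") as f:
        for tr in traces:
            ds = f.create_dataset(f"roi_{tr.roi_id}", data=tr.values)
            ds.attrs["frame_rate_hz"] = tr.frame_rate_hz
            ds.attrs["stage"] = stage_attr or tr.stage


def load_traces_hdf5(path) -> list[Trace]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f, key=lambda n: int(n.removeprefix("roi_"))):
            ds = f[name]
            out.append(
                Trace(
                    ds[()],
                    float(ds.attrs["frame_rate_hz"]),
                    str(ds.attrs["stage"]),
                    int(name.removeprefix("roi_")),
                )
            )
    return out


def save_movie_tiff(movie: FluorescenceMovie, path) -> None:
    tifffile.imwrite(path, movie.frames.astype(np.float32), metadata={"axes": "TYX"})


def load_movie_tiff(path, frame_rate_hz: float) -> FluorescenceMovie:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    return FluorescenceMovie(np.asarray(frames, dtype=float), frame_rate_hz)


def spikes_to_frame(trains: Sequence[SpikeTrain]) -> pd.DataFrame:
    """Long-format spike table: roi_id, frame, time_s, window."""
    rows = []
    for tr in trains:
        for frame, t in zip(tr.spike_frames, tr.spike_times_s):
            rows.append(
                {"roi_id": tr.roi_id, "frame": int(frame), "time_s": float(t),
                 "window": tr.window or ""}
            )
    return pd.DataFrame(rows, columns=["roi_id", "frame", "time_s", "window"])


def save_spikes_csv(trains: Sequence[SpikeTrain], path) -> None:
    spikes_to_frame(trains).to_csv(path, index=False)


def load_spikes_csv(path, frame_rate_hz: float) -> list[SpikeTrain]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for (roi_id, window), grp in df.groupby(["roi_id", "window"], sort=True):
        out.append(
            SpikeTrain(
                int(roi_id),
                np.sort(grp["time_s"].to_numpy(dtype=float)),
                frame_rate_hz,
                window=window or None,
            )
        )
    return out


def save_table_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
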