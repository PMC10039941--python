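"""Readers and writers for the on-disk containers.

Recordings and st-SCA tensors are HDF5; spike trains and tabular outputs
are RFC-4180 CSV with a header row; geometry is JSON (see
:meth:`stsca.core.ArrayGeometry.to_json`).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import ArrayGeometry, LagAxes, Recording, SpikeTrain
from .stsca import StSCAResult

__all__ = [
    "write_recording_h5",
    "read_recording_h5",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_stsca_h5",
    "read_stsca_h5",
    "write_sta_csv",
    "write_radial_csv",
]


def write_recording_h5(path, recording: Recording, dtype=np.float64) -> None:
    """Write a recording; pass ``dtype=np.float32`` to halve file size at
    the cost of exact round-tripping."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=recording.signals.astype(dtype))
        f["fs_hz"] = float(recording.fs_hz)
        f["t0_s"] = float(recording.t0_s)
        f.create_dataset("channel_ids", data=recording.channel_ids)
        if recording.exclusion_mask is not None:
            f.create_dataset("exclusion_mask", data=recording.exclusion_mask)


def read_recording_h5(path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            signals=f["signals"][()].astype(np.float64),
            fs_hz=float(f["fs_hz"][()]),
            channel_ids=f["channel_ids"][()],
            t0_s=float(f["t0_s"][()]) if "t0_s" in f else 0.0,
            exclusion_mask=f["exclusion_mask"][()] if "exclusion_mask" in f else None,
        )


def write_spikes_csv(path, spikes: SpikeTrain) -> None:
    df = pd.DataFrame(
        {"channel_id": spikes.channel_ids, "time_s": spikes.times_s}
    )
    df.to_csv(path, index=False, float_format="%.9f", lineterminator="\n")


def read_spikes_csv(path, fs_hz: float) -> SpikeTrain:
    """Load a channel_id,time_s table; times are converted to sample
    indices at ``fs_hz``."""
    df = pd.read_csv(path)
    idx = np.round(df["time_s"].to_numpy(dtype=np.float64) * fs_hz).astype(np.int64)
    ch = df["channel_id"].to_numpy(dtype=np.int64)
    order = np.lexsort((ch, idx))
    return SpikeTrain(ch[order], idx[order], fs_hz)


def write_stsca_h5(path, result: StSCAResult, snr_db_map: np.ndarray | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=result.values)
        f.create_dataset("counts", data=result.counts)
        f.create_dataset("spatial_lags_mm", data=result.axes.spatial_lags_mm)
        f.create_dataset("spatial_lags_px", data=result.axes.spatial_lags_px)
        f.create_dataset("temporal_lags_s", data=result.axes.temporal_lags_s)
        f["n_spikes"] = int(result.n_spikes)
        f["frame_fs_hz"] = float(result.frame_fs_hz)
        f["params"] = json.dumps(result.provenance)
        if snr_db_map is not None:
            f.create_dataset("snr_db", data=snr_db_map)


def read_stsca_h5(path) -> StSCAResult:
    with h5py.File(path, "r") as f:
        px = f["spatial_lags_px"][()]
        mm = f["spatial_lags_mm"][()]
        ts = f["temporal_lags_s"][()]
        fs = float(f["frame_fs_hz"][()])
        axes = LagAxes(
            spatial_lags_px=px,
            spatial_lags_mm=mm,
            temporal_lags_samples=np.round(ts * fs).astype(np.int64),
            temporal_lags_s=ts,
        )
        return StSCAResult(
            values=f["values"][()],
            counts=f["counts"][()],
            axes=axes,
            n_spikes=int(f["n_spikes"][()]),
            frame_fs_hz=fs,
            provenance=json.loads(f["params"][()]),
        )


def write_sta_csv(path, sta_result, sidecar_path=None, params: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "lag_s": sta_result.lags_s,
            "sta_uv": sta_result.values,
            "noise_uv": sta_result.noise_estimate,
        }
    )
    df.to_csv(path, index=False, float_format="%.9f", lineterminator="\n")
    if sidecar_path is not None:
        meta = {
            "n_spikes": sta_result.n_spikes,
            "n_dropped": sta_result.n_dropped,
            "snr_db": None if not np.isfinite(sta_result.snr_db) else sta_result.snr_db,
            "params": params or {},
        }
        Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def write_radial_csv(path, radial) -> None:
    """Long-form r_mm,tau_s,value_uv table of the radial st-SCA."""
    n_bins, n_t = radial.values.shape
    r = np.repeat(radial.r_bin_centers_mm, n_t)
    tau = np.tile(radial.temporal_lags_s, n_bins)
    df = pd.DataFrame({"r_mm": r, "tau_s": tau, "value_uv": radial.values.ravel()})
    df.to_csv(path, index=False, float_format="%.9f", lineterminator="\n")
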