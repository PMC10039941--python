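"""Band splitting, threshold spike detection, and LFP reduction utilities."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import Recording, SpikeTrain

__all__ = [
    "FilterSpec",
    "DetectionSpec",
    "bandpass",
    "detect_spikes",
    "array_mean_lfp",
    "decimate_lfp",
    "LFP_BAND",
    "MUA_BAND",
]

log = logging.getLogger(__name__)

#: Default low-frequency band for the field potential, Hz.
LFP_BAND = (2.0, 50.0)
#: Default band for multi-unit spike detection, Hz.
MUA_BAND = (300.0, 3000.0)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification.

    ``zero_phase`` selects forward-backward filtering so that the output
    has no group delay (a symmetric pulse stays symmetric).
    """

    band_low_hz: float
    band_high_hz: float
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs_hz: float) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        if self.band_high_hz >= fs_hz / 2:
            raise ValueError(
                f"band_high_hz={self.band_high_hz} exceeds Nyquist for fs={fs_hz}"
            )
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, fs_hz: float) -> np.ndarray:
        self.validate(fs_hz)
        return signal.butter(
            self.order,
            [self.band_low_hz, self.band_high_hz],
            btype="bandpass",
            fs=fs_hz,
            output="sos",
        )


@dataclass(frozen=True)
class DetectionSpec:
    """Threshold-crossing detection of negative multi-unit deflections.

    Events are local minima deeper than ``center - threshold_sd * scale``
    of the band-passed trace; troughs closer than ``dead_time_ms`` keep the
    deeper one.  With ``robust=True`` the center/scale are median and
    1.4826*MAD instead of mean and SD.
    """

    threshold_sd: float = 4.0
    dead_time_ms: float = 1.0
    robust: bool = False

    def validate(self) -> None:
        if not self.threshold_sd > 0:
            raise ValueError("threshold_sd must be positive")
        if self.dead_time_ms < 0:
            raise ValueError("dead_time_ms must be >= 0")


def bandpass(recording: Recording, spec: FilterSpec) -> Recording:
    """Band-pass every channel; zero-phase when the spec requests it."""
    sos = spec.sos(recording.fs_hz)
    if spec.zero_phase:
        out = signal.sosfiltfilt(sos, recording.signals, axis=1)
    else:
        out = signal.sosfilt(sos, recording.signals, axis=1)
    return Recording(
        out,
        recording.fs_hz,
        recording.channel_ids,
        recording.t0_s,
        None if recording.exclusion_mask is None else recording.exclusion_mask.copy(),
    )


def detect_spikes(recording_mua: Recording, spec: DetectionSpec | None = None) -> SpikeTrain:
    """Detect negative threshold crossings per channel on a MUA-band recording.

    The per-channel statistics are computed over valid samples only;
    invalid samples are replaced by the channel center so they can neither
    trigger nor shadow an event.
    """
    spec = spec or DetectionSpec()
    spec.validate()
    fs = recording_mua.fs_hz
    distance = max(1, int(round(spec.dead_time_ms * 1e-3 * fs)))
    mask = recording_mua.valid_mask()
    chans, idxs = [], []
    for row, ch in enumerate(recording_mua.channel_ids):
        x = recording_mua.signals[row]
        m = mask[row]
        if not m.any():
            log.warning("channel %d fully masked; no events", ch)
            continue
        xv = x[m]
        if spec.robust:
            center = float(np.median(xv))
            scale = 1.4826 * float(np.median(np.abs(xv - center)))
        else:
            center = float(np.mean(xv))
            scale = float(np.std(xv))
        if scale == 0.0:
            continue
        thr = center - spec.threshold_sd * scale
        xw = np.where(m, x, center)
        peaks, _ = signal.find_peaks(-xw, height=-thr, distance=distance)
        chans.append(np.full(peaks.shape, int(ch), dtype=np.int64))
        idxs.append(peaks.astype(np.int64))
    if chans:
        ch_arr = np.concatenate(chans)
        ix_arr = np.concatenate(idxs)
    else:
        ch_arr = np.empty(0, dtype=np.int64)
        ix_arr = np.empty(0, dtype=np.int64)
    order = np.lexsort((ch_arr, ix_arr))
    return SpikeTrain(ch_arr[order], ix_arr[order], fs)


def array_mean_lfp(recording_lfp: Recording) -> np.ndarray:
    """Per-sample mean over valid channels; samples with no valid channel
    become NaN (a warning is emitted)."""
    mask = recording_lfp.valid_mask()
    n_valid = mask.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(mask, recording_lfp.signals, 0.0).sum(axis=0) / n_valid
    if np.any(n_valid == 0):
        warnings.warn("samples with zero valid channels set to NaN", RuntimeWarning)
        out[n_valid == 0] = np.nan
    return out


def decimate_lfp(recording: Recording, target_fs_hz: float) -> Recording:
    """Anti-aliased resampling of an LFP-band recording to ``target_fs_hz``.

    Spike indices remain convertible through time in seconds.  The validity
    mask is carried over by nearest-sample lookup when present.
    """
    if target_fs_hz > recording.fs_hz:
        raise ValueError("target_fs_hz must not exceed the recording rate")
    if target_fs_hz == recording.fs_hz:
        return recording
    frac = Fraction(target_fs_hz / recording.fs_hz).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(recording.signals, up, down, axis=1)
    mask = None
    if recording.exclusion_mask is not None:
        src = np.minimum(
            (np.arange(out.shape[1]) * down / up).round().astype(int),
            recording.n_samples - 1,
        )
        mask = recording.exclusion_mask[:, src]
    return Recording(out, recording.fs_hz * up / down, recording.channel_ids, recording.t0_s, mask)
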