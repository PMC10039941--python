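"""Spike-centered spatiotemporal averaging on a gridded electrode array.

For every retained spike the whole-array LFP frame around the spike time is
translated so the spiking electrode sits at the spatial origin, then frames
are accumulated on a ``(2W - 1) x (2W - 1) x (2n + 1)`` lag grid together
with per-cell contribution counts; the average is the elementwise ratio.
Cells never reached by any translated electrode (the corner regions) stay
undefined (NaN).

Also provides the spike-time randomization control and ZCA spatial
whitening of the multichannel LFP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import ArrayGeometry, LagAxes, Recording, SpikeTrain
from .noisestats import PlusMinusEstimate, combine_plus_minus

__all__ = [
    "StSCAResult",
    "compute_stsca",
    "compute_stsca_with_noise",
    "plus_minus_stsca",
    "spatial_map",
    "randomize_spike_times",
    "WhiteningModel",
    "fit_whitening",
    "apply_whitening",
]


@dataclass(eq=False)
class StSCAResult:
    """Spike-centered average tensor with contribution counts.

    ``values`` is NaN wherever ``counts`` is zero.  ``counts`` is kept per
    temporal lag even though it is constant across lags under the
    edge-dropping policy (masked samples can still make it vary).
    """

    values: np.ndarray
    counts: np.ndarray
    axes: LagAxes
    n_spikes: int
    frame_fs_hz: float
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def origin_trace(self) -> np.ndarray:
        """Average at the spatial origin over temporal lags (the spiking
        channel's own triggered average)."""
        i, j, _ = self.axes.origin_index
        return self.values[i, j, :]

    def defined(self) -> np.ndarray:
        return self.counts > 0


def _frame_indices(spikes: SpikeTrain, frame_fs_hz: float) -> np.ndarray:
    if spikes.fs_hz == frame_fs_hz:
        return spikes.sample_indices.copy()
    return np.asarray(
        np.round(spikes.sample_indices * (frame_fs_hz / spikes.fs_hz)), dtype=np.int64
    )


def accumulate_stsca(
    recording_lfp: Recording,
    spikes: SpikeTrain,
    geometry: ArrayGeometry,
    window_s: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Raw accumulation: returns (sums, counts, n_retained) without dividing.

    Used directly by the plus-minus splitter so even/odd halves combine
    exactly into the full average.
    """
    fs = recording_lfp.fs_hz
    half = int(round(window_s * fs))
    if half < 0:
        raise ValueError("window_s must be >= 0")
    w = geometry.grid_side
    p = 2 * w - 1
    t = 2 * half + 1
    sums = np.zeros((p, p, t), dtype=np.float64)
    counts = np.zeros((p, p, t), dtype=np.int64)

    rc = geometry.positions_for(recording_lfp.channel_ids)
    rows_g = rc[:, 0]
    cols_g = rc[:, 1]
    mask = recording_lfp.exclusion_mask  # None = all valid
    sig = recording_lfp.signals
    n_samples = recording_lfp.n_samples

    idx = _frame_indices(spikes, fs)
    retained = 0
    ones = np.ones(t, dtype=np.int64)
    for ch, s0 in zip(spikes.channel_ids, idx):
        r0, c0 = geometry.position(int(ch))  # raises on unknown channel
        if s0 - half < 0 or s0 + half >= n_samples:
            continue
        retained += 1
        sl = slice(s0 - half, s0 + half + 1)
        ri = rows_g - r0 + (w - 1)
        ci = cols_g - c0 + (w - 1)
        frame = sig[:, sl]
        if mask is None:
            sums[ri, ci, :] += frame
            counts[ri, ci, :] += ones
        else:
            fm = mask[:, sl]
            sums[ri, ci, :] += np.where(fm, frame, 0.0)
            counts[ri, ci, :] += fm
    return sums, counts, retained


def compute_stsca(
    recording_lfp: Recording,
    spikes: SpikeTrain,
    geometry: ArrayGeometry,
    window_s: float,
) -> StSCAResult:
    """Spike-centered average of the LFP over spatial and temporal lags.

    Parameters
    ----------
    recording_lfp : Recording
        LFP-band recording at the frame rate (already decimated).
    spikes : SpikeTrain
        Trigger events; indices may refer to a different rate and are
        converted through time.  A spike on a channel missing from the
        geometry is an error.
    geometry : ArrayGeometry
    window_s : float
        Temporal half-window in seconds.  Spikes whose window leaves the
        recording are dropped entirely.
    """
    sums, counts, retained = accumulate_stsca(recording_lfp, spikes, geometry, window_s)
    if retained == 0:
        raise ValueError("no spikes retained inside the recording window")
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    half = int(round(window_s * recording_lfp.fs_hz))
    axes = LagAxes.build(geometry, half, recording_lfp.fs_hz)
    return StSCAResult(
        values=values,
        counts=counts,
        axes=axes,
        n_spikes=retained,
        frame_fs_hz=recording_lfp.fs_hz,
        provenance={
            "window_s": window_s,
            "n_events_input": len(spikes),
            "frame_fs_hz": recording_lfp.fs_hz,
        },
    )


def plus_minus_stsca(
    recording_lfp: Recording,
    spikes: SpikeTrain,
    geometry: ArrayGeometry,
    window_s: float,
) -> PlusMinusEstimate:
    """Plus-minus (even/odd spike split) noise estimate of the st-SCA."""
    from .noisestats import split_even_odd

    even, odd = split_even_odd(spikes)
    se, ce, _ = accumulate_stsca(recording_lfp, even, geometry, window_s)
    so, co, _ = accumulate_stsca(recording_lfp, odd, geometry, window_s)
    return combine_plus_minus(se, ce, so, co)


def compute_stsca_with_noise(
    recording_lfp: Recording,
    spikes: SpikeTrain,
    geometry: ArrayGeometry,
    window_s: float,
) -> tuple[StSCAResult, PlusMinusEstimate]:
    """One-pass even/odd accumulation yielding both the st-SCA (from the
    combined sums, identical to :func:`compute_stsca`) and its plus-minus
    noise estimate."""
    from .noisestats import split_even_odd

    even, odd = split_even_odd(spikes)
    se, ce, ne = accumulate_stsca(recording_lfp, even, geometry, window_s)
    so, co, no = accumulate_stsca(recording_lfp, odd, geometry, window_s)
    if ne + no == 0:
        raise ValueError("no spikes retained inside the recording window")
    pm = combine_plus_minus(se, ce, so, co)
    counts = ce + co
    half = int(round(window_s * recording_lfp.fs_hz))
    axes = LagAxes.build(geometry, half, recording_lfp.fs_hz)
    result = StSCAResult(
        values=pm.signal,
        counts=counts,
        axes=axes,
        n_spikes=ne + no,
        frame_fs_hz=recording_lfp.fs_hz,
        provenance={
            "window_s": window_s,
            "n_events_input": len(spikes),
            "frame_fs_hz": recording_lfp.fs_hz,
        },
    )
    return result, pm


def spatial_map(result: StSCAResult, tau_window_s: float = 0.035) -> np.ndarray:
    """Count-weighted temporal integration of the st-SCA over |tau| <=
    ``tau_window_s``, yielding the 2-D spatial topography.  Undefined
    spatial cells are NaN."""
    keep = np.abs(result.axes.temporal_lags_s) <= tau_window_s + 1e-12
    if not keep.any():
        raise ValueError("tau window excludes every temporal lag")
    c = result.counts[:, :, keep].astype(np.float64)
    v = np.where(c > 0, result.values[:, :, keep], 0.0)
    num = (v * c).sum(axis=2)
    den = c.sum(axis=2)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    return out


def randomize_spike_times(
    spikes: SpikeTrain, duration_s: float, seed: int
) -> SpikeTrain:
    """Surrogate spike train: per-channel event counts preserved, times
    redrawn uniformly (without replacement) over the recording.

    Destroys any spike-locked LFP structure while keeping the spatial
    distribution of triggers, so surviving st-SCA structure is attributable
    to chance.
    """
    n_samples = int(np.floor(duration_s * spikes.fs_hz))
    if n_samples < 1:
        raise ValueError("duration too short")
    if len(spikes) and int(spikes.sample_indices.max()) >= n_samples:
        raise ValueError("duration shorter than the latest spike")
    rng = np.random.default_rng(seed)
    chans, idxs = [], []
    for ch in np.unique(spikes.channel_ids):
        k = int(np.count_nonzero(spikes.channel_ids == ch))
        new = np.sort(rng.choice(n_samples, size=k, replace=False))
        chans.append(np.full(k, ch, dtype=np.int64))
        idxs.append(new.astype(np.int64))
    ch_arr = np.concatenate(chans) if chans else np.empty(0, dtype=np.int64)
    ix_arr = np.concatenate(idxs) if idxs else np.empty(0, dtype=np.int64)
    order = np.lexsort((ch_arr, ix_arr))
    return SpikeTrain(ch_arr[order], ix_arr[order], spikes.fs_hz)


@dataclass(eq=False)
class WhiteningModel:
    """ZCA whitening: W = E diag(lambda^-1/2) E^T of the channel covariance.

    ``eigenvalue_power`` records the exponent applied to the eigenvalues
    (-0.5 for ZCA; -1.0 reproduces a plain covariance inverse, exposed for
    comparison)."""

    w_matrix: np.ndarray
    eigenvalues: np.ndarray
    mean_vector: np.ndarray
    channel_ids: np.ndarray
    eigenvalue_power: float = -0.5


def fit_whitening(
    recording_lfp: Recording,
    ridge: float = 0.0,
    eigenvalue_power: float = -0.5,
) -> WhiteningModel:
    """Fit the spatial whitening matrix from the channel covariance.

    Raises on rank-deficient covariance; pass ``ridge > 0`` to add a
    diagonal loading (in units of the mean eigenvalue) instead.
    """
    x = recording_lfp.signals
    n_ch, n_s = x.shape
    if n_s < n_ch + 1:
        raise ValueError("need at least channels + 1 samples to fit a covariance")
    mean = x.mean(axis=1)
    cov = np.cov(x, ddof=1)
    lam, e = np.linalg.eigh(cov)
    if ridge > 0:
        lam = lam + ridge * lam.mean()
    if lam.min() <= lam.max() * 1e-12:
        raise np.linalg.LinAlgError(
            "covariance is rank deficient; consider the ridge option"
        )
    w = (e * lam**eigenvalue_power) @ e.T
    return WhiteningModel(
        w_matrix=w,
        eigenvalues=lam,
        mean_vector=mean,
        channel_ids=recording_lfp.channel_ids.copy(),
        eigenvalue_power=eigenvalue_power,
    )


def apply_whitening(recording_lfp: Recording, model: WhiteningModel) -> Recording:
    """Mean-remove and multiply each sample's channel vector by W."""
    if not np.array_equal(recording_lfp.channel_ids, model.channel_ids):
        raise ValueError("channel sets of recording and whitening model differ")
    y = model.w_matrix @ (recording_lfp.signals - model.mean_vector[:, None])
    return Recording(
        y,
        recording_lfp.fs_hz,
        recording_lfp.channel_ids,
        recording_lfp.t0_s,
        None if recording_lfp.exclusion_mask is None else recording_lfp.exclusion_mask.copy(),
    )
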