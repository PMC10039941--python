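"""Plus-minus noise estimation, SNR in decibels, and Rose-criterion masking.

The plus-minus estimate splits the retained spikes into even/odd halves by
chronological index, re-runs the same accumulation on each half, and forms

* ``signal`` — the average over all spikes (combined sums / combined counts),
* ``noise``  — ``(even_average - odd_average) / 2``.

With N spikes contributing i.i.d. noise of variance s^2 per cell, each half
average has variance 2 s^2 / N, so the half-difference over 2 has variance
s^2 / N — the same as the residual noise of the full average.  The noise
rms therefore calibrates the SNR of the full average directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import SpikeTrain

__all__ = [
    "PlusMinusEstimate",
    "plus_minus",
    "split_even_odd",
    "snr_db",
    "rose_mask",
    "combine_plus_minus",
    "per_cell_snr_db",
    "nan_rms",
]


def nan_rms(x: np.ndarray) -> float:
    """Root mean square over finite entries."""
    x = np.asarray(x, dtype=np.float64)
    finite = np.isfinite(x)
    if not finite.any():
        return float("nan")
    return float(np.sqrt(np.mean(np.square(x[finite]))))


def snr_db(signal_rms: float, noise_rms: float) -> float:
    """20 * log10(signal_rms / noise_rms); +inf when noise_rms is zero."""
    if noise_rms < 0 or signal_rms < 0:
        raise ValueError("rms values must be non-negative")
    if noise_rms == 0.0:
        return float("inf")
    return float(20.0 * np.log10(signal_rms / noise_rms))


def rose_mask(per_cell_snr_db: np.ndarray, threshold_db: float = 12.0) -> tuple[np.ndarray, int]:
    """Boolean reliability map: True where SNR >= threshold.

    Undefined (non-finite, except +inf) cells are False.  Also returns the
    number of *defined* cells that fail the criterion.
    """
    snr = np.asarray(per_cell_snr_db, dtype=np.float64)
    defined = ~np.isnan(snr)
    ok = defined & (snr >= threshold_db)
    n_fail = int(np.count_nonzero(defined & ~ok))
    return ok, n_fail


@dataclass(eq=False)
class PlusMinusEstimate:
    """Even/odd split averages with derived signal, noise and global SNR."""

    even_average: np.ndarray
    odd_average: np.ndarray
    signal: np.ndarray
    noise: np.ndarray
    snr_db: float
    n_even: int
    n_odd: int


def split_even_odd(spikes: SpikeTrain) -> tuple[SpikeTrain, SpikeTrain]:
    """Partition by parity of chronological index; an odd spike count puts
    the extra spike in the even half."""
    order = spikes.chronological_order()
    return spikes.subset(order[0::2]), spikes.subset(order[1::2])


def plus_minus(
    accumulate: Callable[[SpikeTrain], tuple[np.ndarray, np.ndarray]],
    spikes: SpikeTrain,
) -> PlusMinusEstimate:
    """Run ``accumulate`` (returning per-cell sums and contribution counts)
    on even and odd spike halves and derive the plus-minus estimate.

    Cells with zero contributions in a half are NaN there; the combined
    signal is defined wherever either half contributed.
    """
    if len(spikes) < 2:
        raise ValueError("plus-minus estimation needs at least 2 spikes")
    even, odd = split_even_odd(spikes)
    se, ce = accumulate(even)
    so, co = accumulate(odd)
    est = combine_plus_minus(se, ce, so, co)
    est.n_even = len(even)
    est.n_odd = len(odd)
    return est


def combine_plus_minus(se, ce, so, co) -> PlusMinusEstimate:
    """Assemble a plus-minus estimate from even/odd (sums, counts) pairs."""
    se = np.asarray(se, dtype=np.float64)
    so = np.asarray(so, dtype=np.float64)
    ce = np.asarray(ce, dtype=np.float64)
    co = np.asarray(co, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        even_avg = np.where(ce > 0, se / np.where(ce > 0, ce, 1), np.nan)
        odd_avg = np.where(co > 0, so / np.where(co > 0, co, 1), np.nan)
        ct = ce + co
        sig = np.where(ct > 0, (se + so) / np.where(ct > 0, ct, 1), np.nan)
    noise = (even_avg - odd_avg) / 2.0
    return PlusMinusEstimate(
        even_average=even_avg,
        odd_average=odd_avg,
        signal=sig,
        noise=noise,
        snr_db=snr_db(nan_rms(sig), nan_rms(noise)),
        n_even=0,
        n_odd=0,
    )


def per_cell_snr_db(estimate: PlusMinusEstimate, temporal_axis: int = -1) -> np.ndarray:
    """Per-spatial-cell SNR map: rms over the temporal axis of signal vs noise.

    Cells whose signal is undefined at every lag come out NaN.
    """
    import warnings

    sig = np.asarray(estimate.signal, dtype=np.float64)
    noi = np.asarray(estimate.noise, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s_rms = np.sqrt(np.nanmean(np.square(sig), axis=temporal_axis))
        n_rms = np.sqrt(np.nanmean(np.square(noi), axis=temporal_axis))
        out = 20.0 * np.log10(s_rms / n_rms)
    out[np.isnan(s_rms) | np.isnan(n_rms)] = np.nan
    return out
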