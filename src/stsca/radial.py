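"""Polar reduction of the st-SCA and ring-geometry quantification.

The Cartesian lag plane (xi, psi) is collapsed onto radius
``r = sqrt(xi^2 + psi^2) * pitch`` using count-weighted bin means; the
angle is averaged out.  Bin k covers ``[k*bw, (k+1)*bw)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .stsca import StSCAResult

__all__ = ["RadialStSCA", "radial_reduce", "marginals", "peak_separation", "symmetry_score"]


@dataclass(eq=False)
class RadialStSCA:
    """(radial bin x temporal lag) reduction of an st-SCA tensor.

    ``r_bin_centers_mm`` are count-weighted mean member radii per bin (NaN
    for empty bins).  Bins whose radius exceeds the per-axis maximum lag are
    angularly incomplete on the square lag grid; ``incomplete`` flags them.
    """

    values: np.ndarray
    counts: np.ndarray
    r_bin_edges_mm: np.ndarray
    r_bin_centers_mm: np.ndarray
    temporal_lags_s: np.ndarray
    incomplete: np.ndarray
    temporal_component: np.ndarray = field(default=None)  # type: ignore[assignment]
    spatial_component: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


def radial_reduce(
    result: StSCAResult,
    bin_width_mm: float | None = None,
    tau_window_s: float | None = None,
) -> RadialStSCA:
    """Reduce an st-SCA tensor to (radius, temporal lag).

    ``bin_width_mm`` defaults to the lag-grid spacing (the electrode
    pitch).  ``tau_window_s`` sets the integration window of the stored
    spatial component (default: all lags).
    """
    mm = result.axes.spatial_lags_mm
    pitch = float(mm[1] - mm[0])
    bw = pitch if bin_width_mm is None else float(bin_width_mm)
    if not bw > 0:
        raise ValueError("bin width must be positive")
    if not np.any(result.counts > 0):
        raise ValueError("st-SCA has no defined cells")

    xi, psi = np.meshgrid(mm, mm, indexing="xy")  # values[psi_idx, xi_idx]
    radius = np.sqrt(xi**2 + psi**2)  # (P, P)
    r_max = float(radius.max())
    n_bins = int(np.floor(r_max / bw)) + 1
    bin_idx = np.minimum((radius / bw).astype(np.int64), n_bins - 1)
    edges = np.arange(n_bins + 1) * bw

    t = result.values.shape[2]
    vals = np.zeros((n_bins, t))
    cnts = np.zeros((n_bins, t))
    r_num = np.zeros(n_bins)
    r_den = np.zeros(n_bins)
    c = result.counts.astype(np.float64)
    v = np.where(c > 0, result.values, 0.0)
    flat = bin_idx.ravel()
    np.add.at(vals, flat, (v * c).reshape(-1, t))
    np.add.at(cnts, flat, c.reshape(-1, t))
    c_spatial = c.sum(axis=2).ravel()
    np.add.at(r_num, flat, radius.ravel() * c_spatial)
    np.add.at(r_den, flat, c_spatial)

    with np.errstate(invalid="ignore"):
        values = np.where(cnts > 0, vals / np.where(cnts > 0, cnts, 1), np.nan)
        centers = np.where(r_den > 0, r_num / np.where(r_den > 0, r_den, 1), np.nan)
    incomplete = edges[:-1] > float(np.max(np.abs(mm))) + 1e-12
    out = RadialStSCA(
        values=values,
        counts=cnts,
        r_bin_edges_mm=edges,
        r_bin_centers_mm=centers,
        temporal_lags_s=result.axes.temporal_lags_s.astype(np.float64),
        incomplete=incomplete,
    )
    temporal, spatial = marginals(out, tau_window_s)
    out.temporal_component = temporal
    out.spatial_component = spatial
    return out


def marginals(
    radial: RadialStSCA, tau_window_s: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Count-weighted marginals of the radial st-SCA.

    Returns ``(temporal_component, spatial_component)``: the temporal
    component is the weighted mean over radius at each lag (identical to
    the array-mean-LFP STA when every channel is valid); the spatial
    component is the weighted mean over ``|tau| <= tau_window_s`` at each
    radius.
    """
    c = radial.counts
    v = np.where(c > 0, radial.values, 0.0)
    with np.errstate(invalid="ignore"):
        den_t = c.sum(axis=0)
        temporal = np.where(den_t > 0, (v * c).sum(axis=0) / np.where(den_t > 0, den_t, 1), np.nan)
        if tau_window_s is None:
            keep = np.ones(radial.temporal_lags_s.shape, dtype=bool)
        else:
            keep = np.abs(radial.temporal_lags_s) <= tau_window_s + 1e-12
            if not keep.any():
                raise ValueError("tau window excludes every temporal lag")
        ck = c[:, keep]
        vk = v[:, keep]
        den_r = ck.sum(axis=1)
        spatial = np.where(den_r > 0, (vk * ck).sum(axis=1) / np.where(den_r > 0, den_r, 1), np.nan)
    return temporal, spatial


def peak_separation(
    spatial_component: np.ndarray, r_axis_mm: np.ndarray
) -> float | None:
    """Distance in mm between the two highest local maxima flanking the
    central trough of a radial profile.

    The profile (a function of radius >= 0) is mirrored about r = 0, the
    global minimum located, and the highest local maximum found on each
    side; returns None when either side has no local maximum (e.g. a
    monotone well).
    """
    v = np.asarray(spatial_component, dtype=np.float64)
    r = np.asarray(r_axis_mm, dtype=np.float64)
    ok = np.isfinite(v) & np.isfinite(r)
    v, r = v[ok], r[ok]
    if v.size < 3:
        return None
    order = np.argsort(r)
    v, r = v[order], r[order]
    # mirror about r=0 (skip duplicated origin sample if present)
    start = 1 if r[0] == 0.0 else 0
    r_full = np.concatenate([-r[::-1], r[start:]])
    v_full = np.concatenate([v[::-1], v[start:]])
    i_min = int(np.argmin(v_full))
    peaks, props = find_peaks(v_full)
    left = peaks[peaks < i_min]
    right = peaks[peaks > i_min]
    if left.size == 0 or right.size == 0:
        return None
    i_l = left[np.argmax(v_full[left])]
    i_r = right[np.argmax(v_full[right])]
    return float(r_full[i_r] - r_full[i_l])


def symmetry_score(result: StSCAResult, tau_window_s: float = 0.035) -> float:
    """Deviation from radial symmetry of the spatial topography.

    Computed as the mean per-cell SD across the four 90-degree rotations of
    the tau-integrated map, divided by the mean absolute value of the map.
    0 means perfectly 4-fold symmetric.
    """
    from .stsca import spatial_map

    m = spatial_map(result, tau_window_s)
    stack = np.stack([np.rot90(m, k) for k in range(4)])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(stack, axis=0)
        denom = np.nanmean(np.abs(m))
        score = np.nanmean(sd) / denom if denom > 0 else np.nan
    return float(score)
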