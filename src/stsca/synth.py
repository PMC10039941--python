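"""Synthetic MEA data with known spike-LFP kernels, and the rect/sinc
impulse-response model.

Every generated recording injects a chosen spatiotemporal kernel at each
ground-truth spike so that downstream estimators can be validated against
exact expectations.  The theory helpers integrate a kernel over a bounded
spatial or temporal window (the idealized electrode / epoch) and check the
rect <-> sinc Fourier pair numerically.

The sinc convention throughout is the normalized one,
``sinc(x) = sin(pi x) / (pi x)``; scale parameters are defined relative to
the first zero, which is convention-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate

from .core import ArrayGeometry, Recording, SpikeTrain

__all__ = [
    "KernelSpec",
    "SimulationConfig",
    "eval_kernel",
    "simulate_recording",
    "inject_mua",
    "uir_temporal",
    "uir_spatial",
    "rect_sinc_check",
    "SINC_FIRST_MIN",
]

#: First positive root of tan(x) = x, divided by pi: the (normalized) sinc
#: function's first local minimum sits at this abscissa.
SINC_FIRST_MIN = 4.493409457909064 / math.pi

_FAMILIES = ("radial_sinc_2d", "separable_sinc", "cos_rt", "gaussian_well")


@dataclass(frozen=True)
class KernelSpec:
    """A spike-associated LFP kernel K(xi, psi, tau).

    family
        ``radial_sinc_2d``: A * sinc(r / s_r) * sinc(tau / s_t)
        ``separable_sinc``: A * sinc(xi / s_r) * sinc(psi / s_r) * sinc(tau / s_t)
        ``cos_rt``:         A * cos(r * tau / (s_r * s_t))
        ``gaussian_well``:  -|A| * exp(-r^2 / (2 s_r^2)) * exp(-tau^2 / (2 s_t^2))
    with r in mm, tau in s, s_r = ``spatial_scale_mm``, s_t =
    ``temporal_scale_s``.
    """

    family: str
    amplitude_uv: float
    spatial_scale_mm: float
    temporal_scale_s: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if not (self.spatial_scale_mm > 0 and self.temporal_scale_s > 0):
            raise ValueError("kernel scales must be positive")

    @property
    def first_ring_radius_mm(self) -> float | None:
        """Radius of the first flanking ring of the radial profile.

        For a (negative-amplitude) radial sinc this is the sinc's first
        local minimum, ``SINC_FIRST_MIN * s_r``.  None for families with no
        ring structure.
        """
        if self.family in ("radial_sinc_2d", "separable_sinc"):
            return SINC_FIRST_MIN * self.spatial_scale_mm
        return None

    @classmethod
    def radial_sinc_from_ring(
        cls, first_ring_radius_mm: float, amplitude_uv: float, temporal_scale_s: float
    ) -> "KernelSpec":
        """Radial sinc kernel parameterized by its first-ring radius."""
        return cls(
            "radial_sinc_2d",
            amplitude_uv,
            first_ring_radius_mm / SINC_FIRST_MIN,
            temporal_scale_s,
        )


def eval_kernel(spec: KernelSpec, xi_mm, psi_mm, tau_s) -> np.ndarray:
    """Evaluate the kernel; arguments broadcast like numpy ufunc inputs."""
    xi = np.asarray(xi_mm, dtype=np.float64)
    psi = np.asarray(psi_mm, dtype=np.float64)
    tau = np.asarray(tau_s, dtype=np.float64)
    a = spec.amplitude_uv
    sr = spec.spatial_scale_mm
    st = spec.temporal_scale_s
    r = np.sqrt(xi**2 + psi**2)
    if spec.family == "radial_sinc_2d":
        out = a * np.sinc(r / sr) * np.sinc(tau / st)
    elif spec.family == "separable_sinc":
        out = a * np.sinc(xi / sr) * np.sinc(psi / sr) * np.sinc(tau / st)
    elif spec.family == "cos_rt":
        out = a * np.cos(r * tau / (sr * st))
    elif spec.family == "gaussian_well":
        out = -abs(a) * np.exp(-(r**2) / (2 * sr**2)) * np.exp(-(tau**2) / (2 * st**2))
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(spec.family)
    return out


@dataclass(eq=False)
class SimulationConfig:
    """Parameters of a synthetic MEA recording.

    Spikes are either Poisson per channel at ``rate_hz`` or taken verbatim
    from ``spikes``.  The LFP is the superposition of one kernel per spike
    (truncated at ``kernel_support_s`` half-width in time) plus Gaussian
    noise of SD ``noise_sd_uv``, optionally spatially correlated over
    ``noise_corr_mm``.
    """

    geometry: ArrayGeometry
    duration_s: float
    fs_hz: float
    kernel: KernelSpec
    seed: int
    rate_hz: float = 0.0
    spikes: SpikeTrain | None = None
    kernel_support_s: float = 0.25
    noise_sd_uv: float = 0.0
    noise_corr_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.rate_hz < 0 or self.noise_sd_uv < 0 or self.noise_corr_mm < 0:
            raise ValueError("rates and noise parameters must be >= 0")
        if not (self.duration_s > 0 and self.fs_hz > 0):
            raise ValueError("duration_s and fs_hz must be positive")
        if 2 * self.kernel_support_s >= self.duration_s:
            raise ValueError("kernel support wider than the recording")


def _poisson_spikes(cfg: SimulationConfig, rng: np.random.Generator) -> SpikeTrain:
    n_samples = int(round(cfg.duration_s * cfg.fs_hz))
    chans, idxs = [], []
    for ch in cfg.geometry.channel_ids:
        k = rng.poisson(cfg.rate_hz * cfg.duration_s)
        k = min(k, n_samples)
        if k == 0:
            continue
        new = np.sort(rng.choice(n_samples, size=k, replace=False))
        chans.append(np.full(k, ch, dtype=np.int64))
        idxs.append(new.astype(np.int64))
    ch_arr = np.concatenate(chans) if chans else np.empty(0, dtype=np.int64)
    ix_arr = np.concatenate(idxs) if idxs else np.empty(0, dtype=np.int64)
    order = np.lexsort((ch_arr, ix_arr))
    return SpikeTrain(ch_arr[order], ix_arr[order], cfg.fs_hz)


def _correlated_noise(
    cfg: SimulationConfig, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    geom = cfg.geometry
    white = rng.standard_normal((geom.n_channels, n_samples))
    if cfg.noise_corr_mm == 0:
        return cfg.noise_sd_uv * white
    pos = geom.positions_for(geom.channel_ids).astype(np.float64) * geom.pitch_mm
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    k = np.exp(-d2 / (2 * cfg.noise_corr_mm**2))
    # mixing matrix normalized so each channel keeps unit variance
    lam, e = np.linalg.eigh(k + 1e-10 * np.eye(len(k)))
    mix = e * np.sqrt(np.clip(lam, 0, None))
    mix /= np.sqrt((mix**2).sum(axis=1, keepdims=True))
    return cfg.noise_sd_uv * (mix @ white)


def simulate_recording(cfg: SimulationConfig) -> tuple[Recording, SpikeTrain]:
    """Generate (LFP-band recording, ground-truth spike train).

    The recording is returned at ``cfg.fs_hz`` directly in the LFP band —
    kernels model the spike-associated LFP itself, not broadband waveforms
    (use :func:`inject_mua` for a detectable high-band companion signal).
    """
    rng = np.random.default_rng(cfg.seed)
    geom = cfg.geometry
    n_samples = int(round(cfg.duration_s * cfg.fs_hz))
    spikes = cfg.spikes if cfg.spikes is not None else _poisson_spikes(cfg, rng)
    half = int(round(cfg.kernel_support_s * cfg.fs_hz))
    taus = np.arange(-half, half + 1) / cfg.fs_hz

    # kernel block cache: source position -> (channels x time) block
    ids = geom.channel_ids
    pos = geom.positions_for(ids).astype(np.float64)
    blocks: dict[tuple[int, int], np.ndarray] = {}

    def block_for(r0: int, c0: int) -> np.ndarray:
        key = (r0, c0)
        if key not in blocks:
            psi = (pos[:, 0] - r0) * geom.pitch_mm
            xi = (pos[:, 1] - c0) * geom.pitch_mm
            blocks[key] = eval_kernel(
                cfg.kernel, xi[:, None], psi[:, None], taus[None, :]
            )
        return blocks[key]

    sig = np.zeros((geom.n_channels, n_samples))
    for ch, s0 in zip(spikes.channel_ids, spikes.sample_indices):
        r0, c0 = geom.position(int(ch))
        b = block_for(r0, c0)
        lo = s0 - half
        hi = s0 + half + 1
        blo = max(0, -lo)
        bhi = b.shape[1] - max(0, hi - n_samples)
        sig[:, max(0, lo) : min(n_samples, hi)] += b[:, blo:bhi]
    if cfg.noise_sd_uv > 0:
        sig += _correlated_noise(cfg, n_samples, rng)
    rec = Recording(sig, cfg.fs_hz, ids)
    return rec, spikes


def inject_mua(
    geometry: ArrayGeometry,
    spikes: SpikeTrain,
    duration_s: float,
    fs_hz: float,
    seed: int,
    background_sd_uv: float = 1.0,
    depth_sd: float = 10.0,
    width_ms: float = 1.0,
) -> Recording:
    """Gaussian background with a triangular negative deflection of depth
    ``depth_sd`` background SDs at every spike, for detector testing."""
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs_hz))
    sig = background_sd_uv * rng.standard_normal((geometry.n_channels, n_samples))
    halfw = max(1, int(round(width_ms * 1e-3 * fs_hz / 2)))
    tri = -depth_sd * background_sd_uv * (1 - np.abs(np.arange(-halfw, halfw + 1)) / (halfw + 1))
    row_of = {int(c): i for i, c in enumerate(geometry.channel_ids)}
    idx = (
        spikes.sample_indices
        if spikes.fs_hz == fs_hz
        else np.round(spikes.sample_indices * (fs_hz / spikes.fs_hz)).astype(np.int64)
    )
    for ch, s0 in zip(spikes.channel_ids, idx):
        lo, hi = s0 - halfw, s0 + halfw + 1
        tlo = max(0, -lo)
        thi = tri.shape[0] - max(0, hi - n_samples)
        sig[row_of[int(ch)], max(0, lo) : min(n_samples, hi)] += tri[tlo:thi]
    return Recording(sig, fs_hz, geometry.channel_ids)


def _kernel_1d(spec: KernelSpec) -> Callable[[float, float], float]:
    return lambda r, tau: float(eval_kernel(spec, r, 0.0, tau))


def uir_temporal(
    spec: KernelSpec, r_max_mm: float, tau_grid_s: np.ndarray
) -> np.ndarray:
    """Impulse response in time: quadrature of K(r, tau) over the bounded
    electrode extent r in [-R, R], per temporal sample."""
    if not r_max_mm > 0:
        raise ValueError("r_max_mm must be positive")
    f = _kernel_1d(spec)
    out = np.empty(len(tau_grid_s))
    for i, tau in enumerate(np.asarray(tau_grid_s, dtype=np.float64)):
        val, _ = integrate.quad(f, -r_max_mm, r_max_mm, args=(tau,), limit=200, epsabs=1e-12, epsrel=1e-12)
        if not np.isfinite(val):
            raise FloatingPointError("non-finite kernel integral")
        out[i] = val
    return out


def uir_spatial(spec: KernelSpec, t_max_s: float, r_grid_mm: np.ndarray) -> np.ndarray:
    """Impulse response in space: quadrature of K(r, tau) over the bounded
    epoch tau in [-T, T], per radius sample."""
    if not t_max_s > 0:
        raise ValueError("t_max_s must be positive")
    f = _kernel_1d(spec)
    out = np.empty(len(r_grid_mm))
    for i, r in enumerate(np.asarray(r_grid_mm, dtype=np.float64)):
        val, _ = integrate.quad(
            lambda tau: f(r, tau), -t_max_s, t_max_s, limit=200, epsabs=1e-12, epsrel=1e-12
        )
        if not np.isfinite(val):
            raise FloatingPointError("non-finite kernel integral")
        out[i] = val
    return out


def rect_sinc_check(r_half_width: float, n_grid: int = 2**14, domain_half_width: float | None = None):
    """Compare the DFT of a rectangular window against the analytic
    transform 2 sin(w R) / w (= 2R sinc(w R / pi)).

    Edge samples are fractionally weighted by their cell's overlap with
    [-R, R] so the discretization error is O(dx^2).  Returns
    ``(max_relative_deviation, freqs_rad, numeric, analytic)`` where the
    deviation is relative to the transform's peak 2R.
    """
    if r_half_width < 0:
        raise ValueError("R must be >= 0")
    if domain_half_width is None:
        domain_half_width = max(8.0 * r_half_width, 8.0)
    n = int(n_grid)
    dx = 2 * domain_half_width / n
    x = (np.arange(n) - n // 2) * dx
    lo = np.maximum(x - dx / 2, -r_half_width)
    hi = np.minimum(x + dx / 2, r_half_width)
    w = np.clip(hi - lo, 0.0, None) / dx  # fractional coverage per cell
    spec = dx * np.fft.fft(np.fft.ifftshift(w))
    freqs = 2 * np.pi * np.fft.fftfreq(n, dx)
    numeric = np.fft.fftshift(spec.real)
    freqs = np.fft.fftshift(freqs)
    with np.errstate(invalid="ignore", divide="ignore"):
        analytic = np.where(
            freqs == 0, 2.0 * r_half_width, 2.0 * np.sin(freqs * r_half_width) / np.where(freqs == 0, 1, freqs)
        )
    if r_half_width == 0:
        max_dev = float(np.max(np.abs(numeric)))
    else:
        max_dev = float(np.max(np.abs(numeric - analytic)) / (2 * r_half_width))
    return max_dev, freqs, numeric, analytic
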