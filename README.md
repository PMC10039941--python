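# stsca

Spatiotemporal spike-centered averaging for gridded microelectrode array
(MEA) recordings.

The classic spike-triggered average (STA) characterizes the spike–LFP
relationship in time only. This package adds the spatial dimension: for
every multi-unit spike, the whole-array LFP frame around the spike time is
spatially translated so the spiking electrode sits at the origin, and the
translated frames are averaged on a lag grid roughly twice the array's
extent (19 × 19 cells, ±3.6 mm, for the default 10 × 10 / 0.4 mm-pitch /
96-channel array with empty corners). The result is a tensor over
(spatial lag ξ, spatial lag ψ, temporal lag τ) with per-cell contribution
counts; cells never reached by a translated electrode stay undefined.

Included alongside the core accumulator:

- **Preprocessing** — Butterworth band splitting (2–50 Hz LFP,
  0.3–3 kHz multi-unit band), zero-phase by default; threshold-crossing
  spike detection (negative deflections ≥ 4 SD); anti-aliased decimation;
  array-mean LFP.
- **STA variants** — plain, channel-subset (sparse sampling), and
  cross-population (decoupled trigger/signal channel sets).
- **Statistics** — plus-minus (even/odd spike split) noise estimation,
  SNR in dB (20·log10), Rose-criterion reliability masking.
- **Spatial whitening** — ZCA (`W = E D^{-1/2} Eᵀ` of the channel
  covariance) as a decorrelation control.
- **Radial reduction** — polar collapse of the lag plane to (r, τ) with
  count-weighted bins, spatial/temporal marginal components, and
  peak-separation measurement of ring-shaped profiles.
- **Controls** — spike-time randomization surrogates.
- **Synthetic data + theory** — MEA simulator that injects known
  spatiotemporal kernels (radial 2-D sinc, separable sinc, cos(r·τ),
  Gaussian well) plus noise; windowed-integral impulse-response helpers and
  a numerical rect ↔ sinc Fourier-pair check.

## Quick start (API)

```python
import stsca

geometry = stsca.ArrayGeometry.utah96()          # 10x10, 96 ch, 0.4 mm pitch
kernel = stsca.KernelSpec.radial_sinc_from_ring( # first ring at 1.25 mm
    1.25, amplitude_uv=-10.0, temporal_scale_s=0.05)
cfg = stsca.SimulationConfig(
    geometry=geometry, duration_s=60.0, fs_hz=500.0, kernel=kernel,
    seed=1, rate_hz=0.2, noise_sd_uv=10.0)
rec, spikes = stsca.simulate_recording(cfg)

result, noise = stsca.compute_stsca_with_noise(rec, spikes, geometry, window_s=0.1)
radial = stsca.radial_reduce(result, tau_window_s=0.035)
sep = stsca.peak_separation(radial.spatial_component, radial.r_bin_centers_mm)
print(f"ring-to-ring distance: {sep:.2f} mm, SNR {noise.snr_db:.1f} dB")
```

## Command line

The `stsca` entry point exposes the pipeline stages as subcommands:

```sh
stsca simulate --config sim.json --out rec.h5 --spikes-out truth.csv
stsca detect   --recording broadband.h5 --out spikes.csv
stsca stsca    --recording lfp.h5 --spikes spikes.csv --window-s 5 \
               --frame-fs 1000 --out stsca.h5
stsca radial   --stsca stsca.h5 --out radial.csv
stsca snr      --stsca stsca.h5
stsca shuffle-control --spikes spikes.csv --duration-s 120 --fs 30000 \
               --seed 7 --out surrogate.csv
stsca whiten   --recording lfp.h5 --out whitened.h5
stsca run      --config run.json       # full pipeline, writes a summary
```

Recordings are HDF5 (`/signals`, `/fs_hz`, `/channel_ids`, optional
validity mask), spike trains are `channel_id,time_s` CSV, geometry is
JSON. `stsca run` writes STA/radial/marginal CSVs, the st-SCA HDF5 with
its SNR map, and a `summary.json` with stage counts and control results;
runs are deterministic given config + seed.

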