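import numpy as np
import pytest

import stsca


@pytest.fixture(scope="session")
def utah():
    return stsca.ArrayGeometry.utah96()


@pytest.fixture(scope="session")
def full10():
    return stsca.ArrayGeometry.full_grid(10, 10, 0.4)


def make_nonoverlapping_spikes(geometry, n_spikes, gap_samples, fs_hz, seed):
    """Spikes on random channels at strictly increasing, well-separated times."""
    rng = np.random.default_rng(seed)
    idx = (np.arange(n_spikes) + 1) * gap_samples
    ch = rng.choice(geometry.channel_ids, n_spikes)
    return stsca.SpikeTrain(ch, idx, fs_hz)


@pytest.fixture(scope="session")
def exact_sinc_fixture(utah):
    """Zero-noise non-overlapping radial-sinc injection: st-SCA must equal
    the kernel exactly at every defined cell."""
    kernel = stsca.KernelSpec("radial_sinc_2d", -8.0, 1.0, 0.04)
    fs = 500.0
    support = 0.1
    gap = int(2 * support * fs) + 10
    spikes = make_nonoverlapping_spikes(utah, 200, gap, fs, seed=0)
    cfg = stsca.SimulationConfig(
        geometry=utah,
        duration_s=(spikes.sample_indices[-1] + gap) / fs,
        fs_hz=fs,
        kernel=kernel,
        seed=0,
        spikes=spikes,
        kernel_support_s=support,
        noise_sd_uv=0.0,
    )
    rec, _ = stsca.simulate_recording(cfg)
    result = stsca.compute_stsca(rec, spikes, utah, window_s=0.08)
    return {"kernel": kernel, "rec": rec, "spikes": spikes, "result": result, "fs": fs}


@pytest.fixture(scope="session")
def noisy_sinc_fixture(utah):
    """Poisson spikes, radial sinc with first ring at 1.25 mm, noise SD equal
    to the kernel amplitude: the standard stochastic recovery fixture."""
    kernel = stsca.KernelSpec.radial_sinc_from_ring(1.25, -10.0, 0.05)
    fs = 500.0
    cfg = stsca.SimulationConfig(
        geometry=utah,
        duration_s=60.0,
        fs_hz=fs,
        kernel=kernel,
        seed=1,
        rate_hz=0.18,  # ~1000 spikes over 96 channels x 60 s
        kernel_support_s=0.15,
        noise_sd_uv=abs(kernel.amplitude_uv),
    )
    rec, spikes = stsca.simulate_recording(cfg)
    result, pm = stsca.compute_stsca_with_noise(rec, spikes, utah, window_s=0.1)
    return {
        "kernel": kernel,
        "rec": rec,
        "spikes": spikes,
        "result": result,
        "pm": pm,
        "fs": fs,
        "cfg": cfg,
    }


@pytest.fixture(scope="session")
def low_noise_sinc_fixture(utah):
    """Same kernel as the noisy fixture but with mild noise: used where the
    check concerns structure, not noise robustness (e.g. sparse-subset STAs)."""
    kernel = stsca.KernelSpec.radial_sinc_from_ring(1.25, -10.0, 0.05)
    cfg = stsca.SimulationConfig(
        geometry=utah,
        duration_s=60.0,
        fs_hz=500.0,
        kernel=kernel,
        seed=5,
        rate_hz=0.18,
        kernel_support_s=0.15,
        noise_sd_uv=2.0,
    )
    rec, spikes = stsca.simulate_recording(cfg)
    return {"kernel": kernel, "rec": rec, "spikes": spikes, "cfg": cfg}
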