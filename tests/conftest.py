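import numpy as np
import pytest

from stimgait.simulate import MuscleSpec, SimulationConfig
from stimgait.types import Block, EMGRecording

FS = 2048.0


def tian(amplitude: float = 1.0) -> MuscleSpec:
    """Reference muscle: burst peaking at cycle start."""
    return MuscleSpec(
        muscle="TiAn", side="R",
        burst_onset_frac=-0.15, burst_duration_frac=0.30,
        burst_amplitude=amplitude,
    )


def quiet_config(**overrides) -> SimulationConfig:
    """Single-muscle config with every noise/artifact source disabled."""
    base = dict(
        duration_s=45.0,
        cadence_jitter_frac=0.0,
        muscles=[tian()],
        tonic_frac=0.05,
        stim_amplitude=0.0,
        line_amplitude=0.0,
        motion_artifact_rate_per_min=0.0,
        background_noise_sd=0.0,
        rng_seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def single_channel_recording(x: np.ndarray, fs: float = FS, label: str = "TiAn_R") -> EMGRecording:
    """Wrap a 1-D array as a one-block recording for filter tests."""
    x = np.asarray(x, dtype=float)
    return EMGRecording(
        signal=x[None, :],
        fs=fs,
        channels=[label],
        blocks=[Block("OFF-PRE", 0, x.size)],
    )


@pytest.fixture
def sine_recording():
    """Factory: 10 s single-channel sinusoid at a given frequency."""

    def make(freq_hz: float, amplitude: float = 1.0, fs: float = FS, duration_s: float = 10.0):
        t = np.arange(int(duration_s * fs)) / fs
        return single_channel_recording(amplitude * np.sin(2 * np.pi * freq_hz * t), fs)

    return make


def periodic_envelope(
    n_cycles: int = 12,
    period: int = 288,
    duty: float = 0.3,
    fs: float = 64.0,
    baseline: float = 0.05,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic envelope of raised-cosine bursts peaking at multiples of the period.

    Returns (envelope, true cycle-start sample indices).  Burst k peaks
    at sample k * period, so cycle starts coincide with burst peaks —
    the same convention as the generator's reference muscle.
    """
    n = n_cycles * period
    t = np.arange(n)
    env = np.full(n, baseline)
    half = duty * period / 2
    for k in range(n_cycles + 1):
        c = k * period
        m = np.abs(t - c) <= half
        env[m] += 0.5 * (1 + np.cos(np.pi * (t[m] - c) / half))
    if noise_sd > 0 and rng is not None:
        env = env + noise_sd * rng.standard_normal(n)
    starts = np.arange(1, n_cycles) * period  # interior events
    return env, starts
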