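"""Ground-truthed synthetic gait EMG with stimulation and line artifacts.

The generator emulates the statistical structure the downstream analysis
assumes: per-muscle activation bursts locked to a slow gait cycle
(~4.5 s), an EMG carrier of band-limited Gaussian noise (20-450 Hz),
50 Hz line interference, a 30 Hz biphasic stimulation pulse train during
the ON block only, sparse low-frequency motion transients, broadband
background noise, and configurable multiplicative pre-to-post amplitude
effects per channel.  Cycle-start times, stimulation pulse times and the
injected effects are returned as ground truth for validation.

The default reference muscle (tibialis anterior, ``TiAn``) is given a
burst that peaks exactly at cycle start — the dorsiflexor burst around
heel strike — so that EMG-derived cycle boundaries are directly
comparable to the generator's cycle-start events.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import signal as sps

from .types import BLOCK_LABELS, Block, EMGRecording

__all__ = [
    "MuscleSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_recording",
    "inject_effect",
]

_CARRIER_BAND = (20.0, 450.0)  # Hz, surface-EMG energy band
_MOTION_DECAY_S = 0.2
_MOTION_DUR_S = 1.0


class MuscleSpec(BaseModel):
    """One recorded muscle: where in the gait cycle it fires and how hard.

    ``burst_onset_frac`` may be negative: the burst then begins before the
    nominal cycle start (e.g. pre-activation before heel strike).
    """

    model_config = ConfigDict(extra="forbid")

    muscle: str
    side: str
    burst_onset_frac: float = Field(ge=-0.5, le=1.0)
    burst_duration_frac: float = Field(gt=0.0, le=1.0)
    burst_amplitude: float = Field(ge=0.0)

    @property
    def channel(self) -> str:
        return f"{self.muscle}_{self.side}"


def _default_muscles() -> list[MuscleSpec]:
    # Plausible burst timings for slow assisted gait, phase 0 = heel strike.
    # TiAn is the reference muscle: its burst peaks at cycle start.
    rows = [
        ("TiAn", -0.15, 0.30, 1.0),
        ("GaLa", 0.15, 0.35, 1.0),
        ("ReFe", -0.05, 0.30, 0.8),
        ("BiFe", 0.75, 0.30, 0.8),
        ("GlMe", 0.00, 0.40, 0.6),
        ("ErSp", 0.45, 0.25, 0.5),
        ("ReAb", 0.50, 0.30, 0.4),
    ]
    out = []
    for side in ("R", "L"):
        for muscle, onset, dur, amp in rows:
            out.append(
                MuscleSpec(
                    muscle=muscle,
                    side=side,
                    burst_onset_frac=onset,
                    burst_duration_frac=dur,
                    burst_amplitude=amp,
                )
            )
    return out


class SimulationConfig(BaseModel):
    """Study conditions for one synthetic walking session.

    Defaults follow the recording setup the analysis targets: 3-minute
    blocks sampled at 2048 Hz, a 4.5 s nominal gait cycle with 10%
    cadence jitter, 30 Hz / 1 ms biphasic stimulation during the ON
    block, and 50 Hz line interference.  Amplitudes are relative to a
    unit-variance EMG carrier at burst peak.
    """

    model_config = ConfigDict(extra="forbid")

    duration_s: float = Field(default=180.0, gt=0.0, description="seconds per block")
    fs: float = Field(default=2048.0, gt=0.0)
    cycle_period_s: float = Field(default=4.5, gt=0.0)
    cadence_jitter_frac: float = Field(default=0.10, ge=0.0, lt=0.25)
    muscles: list[MuscleSpec] = Field(default_factory=_default_muscles)
    tonic_frac: float = Field(
        default=0.05, ge=0.0, lt=1.0,
        description="tonic activation as a fraction of burst amplitude",
    )
    stim_freq_hz: float = Field(default=30.0, gt=0.0)
    stim_pulse_width_ms: float = Field(default=1.0, gt=0.0)
    stim_amplitude: float = Field(default=4.0, ge=0.0)
    line_freq_hz: float = Field(default=50.0, gt=0.0)
    line_amplitude: float = Field(default=0.3, ge=0.0)
    motion_artifact_rate_per_min: float = Field(default=4.0, ge=0.0)
    motion_artifact_amplitude: float = Field(default=1.5, ge=0.0)
    background_noise_sd: float = Field(default=0.15, ge=0.0)
    effect_map: dict[str, float] = Field(default_factory=dict)
    blocks: tuple[str, ...] = BLOCK_LABELS
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check_invariants(self) -> "SimulationConfig":
        if self.duration_s <= 2 * self.cycle_period_s:
            raise ValueError(
                f"duration_s={self.duration_s} must exceed "
                f"2*cycle_period_s={2 * self.cycle_period_s}"
            )
        if self.fs / 2 <= 500.0:
            raise ValueError(f"fs={self.fs}: Nyquist must exceed 500 Hz")
        if not self.blocks or any(b not in BLOCK_LABELS for b in self.blocks):
            raise ValueError(f"blocks must be drawn from {BLOCK_LABELS}")
        channels = [m.channel for m in self.muscles]
        if len(set(channels)) != len(channels):
            raise ValueError("duplicate muscle/side entries")
        for ch in self.effect_map:
            if ch not in channels:
                raise ValueError(f"effect_map channel {ch!r} not among muscles")
        return self

    @property
    def channels(self) -> list[str]:
        return [m.channel for m in self.muscles]


@dataclass
class GroundTruth:
    """What the generator actually put into the signal.

    ``event_times_s`` holds true cycle-start times (session clock,
    seconds) per block; ``cycle_periods_s`` the matching per-cycle
    periods.  ``artifact_times_s`` are stimulation pulse onsets and exist
    only inside the ON block.
    """

    event_times_s: dict[str, np.ndarray]
    cycle_periods_s: dict[str, np.ndarray]
    artifact_times_s: np.ndarray
    injected_effects: dict[str, float] = dc_field(default_factory=dict)

    def all_events(self) -> np.ndarray:
        if not self.event_times_s:
            return np.empty(0)
        return np.concatenate([self.event_times_s[b] for b in self.event_times_s])


def _cycle_events(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Block-relative cycle-start times and periods; jitter clipped to 3 SD."""
    starts, periods = [], []
    t = 0.0
    while t < cfg.duration_s:
        z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
        T = cfg.cycle_period_s * (1.0 + cfg.cadence_jitter_frac * z)
        starts.append(t)
        periods.append(T)
        t += T
    return np.asarray(starts), np.asarray(periods)


def _burst_envelope(
    n: int, fs: float, events: np.ndarray, periods: np.ndarray, spec: MuscleSpec
) -> np.ndarray:
    """Sum of raised-cosine bursts, peak 1, clipped to the block."""
    env = np.zeros(n)
    for t0, T in zip(events, periods):
        b0 = t0 + spec.burst_onset_frac * T
        dur = spec.burst_duration_frac * T
        i0 = max(0, int(np.ceil(b0 * fs)))
        i1 = min(n, int(np.floor((b0 + dur) * fs)) + 1)
        if i1 <= i0:
            continue
        t = np.arange(i0, i1) / fs
        env[i0:i1] += 0.5 * (1.0 - np.cos(2.0 * np.pi * (t - b0) / dur))
    return env


def _bandlimited_carrier(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to the surface-EMG band."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, _CARRIER_BAND, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    sd = x.std()
    return x / sd if sd > 0 else x


def _stim_pulse_train(
    n: int, fs: float, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Biphasic pulse train sampled through an 8x-oversampled anti-aliased path.

    Building the train on a fine grid and decimating emulates the analog
    anti-alias filter of a real amplifier: harmonics above Nyquist do not
    fold back into the EMG band, so in-band artifact energy sits exactly
    at multiples of the stimulation frequency.
    """
    up = 8
    fs_hi = fs * up
    n_hi = n * up
    x = np.zeros(n_hi)
    pw = cfg.stim_pulse_width_ms / 1000.0
    period = 1.0 / cfg.stim_freq_hz
    times = np.arange(0.0, n / fs, period)
    for t0 in times:
        i0 = int(round(t0 * fs_hi))
        i1 = min(n_hi, i0 + int(round(pw * fs_hi)))
        i2 = min(n_hi, i0 + 2 * int(round(pw * fs_hi)))
        x[i0:i1] += cfg.stim_amplitude
        x[i1:i2] -= cfg.stim_amplitude
    x = sps.resample_poly(x, 1, up)
    return x[:n], times


def _motion_transients(
    n: int, fs: float, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Sparse damped low-frequency (<10 Hz) sinusoid transients."""
    out = np.zeros(n)
    lam = cfg.motion_artifact_rate_per_min * (n / fs) / 60.0
    n_events = rng.poisson(lam)
    for _ in range(n_events):
        t0 = rng.uniform(0.0, n / fs)
        f = rng.uniform(2.0, 8.0)
        amp = cfg.motion_artifact_amplitude * rng.choice([-1.0, 1.0])
        i0 = int(t0 * fs)
        i1 = min(n, i0 + int(_MOTION_DUR_S * fs))
        t = np.arange(i1 - i0) / fs
        out[i0:i1] += amp * np.exp(-t / _MOTION_DECAY_S) * np.sin(2 * np.pi * f * t)
    return out


def generate_recording(
    config: SimulationConfig, session: str = "without_exo"
) -> tuple[EMGRecording, GroundTruth]:
    """Generate one annotated multi-block recording plus its ground truth.

    Each channel is burst-envelope-modulated band-limited noise, plus a
    common-frequency line sinusoid (random phase per channel), plus the
    stimulation pulse train during ON blocks, plus motion transients and
    white background noise.  OFF-POST samples of channels named in
    ``config.effect_map`` are scaled by ``1 + fraction``.  The same
    ``rng_seed`` yields bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    n_block = int(round(cfg.duration_s * cfg.fs))
    n_ch = len(cfg.muscles)
    n_total = n_block * len(cfg.blocks)

    signal = np.zeros((n_ch, n_total))
    blocks: list[Block] = []
    event_times: dict[str, np.ndarray] = {}
    periods_map: dict[str, np.ndarray] = {}
    artifact_times: list[float] = []
    line_phase = rng.uniform(0.0, 2.0 * np.pi, size=n_ch)

    for bi, label in enumerate(cfg.blocks):
        s0 = bi * n_block
        blocks.append(Block(label, s0, s0 + n_block))
        events, periods = _cycle_events(cfg, rng)
        event_times[label] = events + s0 / cfg.fs
        periods_map[label] = periods

        t_abs = (s0 + np.arange(n_block)) / cfg.fs
        stim = None
        if label == "ON" and cfg.stim_amplitude > 0:
            stim, pulse_t = _stim_pulse_train(n_block, cfg.fs, cfg)
            artifact_times.extend((pulse_t + s0 / cfg.fs).tolist())

        for ci, mspec in enumerate(cfg.muscles):
            env = _burst_envelope(n_block, cfg.fs, events, periods, mspec)
            modulation = mspec.burst_amplitude * (cfg.tonic_frac + (1 - cfg.tonic_frac) * env)
            x = modulation * _bandlimited_carrier(n_block, cfg.fs, rng)
            if cfg.line_amplitude > 0:
                x = x + cfg.line_amplitude * np.sin(
                    2 * np.pi * cfg.line_freq_hz * t_abs + line_phase[ci]
                )
            if stim is not None:
                x = x + stim
            if cfg.motion_artifact_rate_per_min > 0 and cfg.motion_artifact_amplitude > 0:
                x = x + _motion_transients(n_block, cfg.fs, cfg, rng)
            if cfg.background_noise_sd > 0:
                x = x + cfg.background_noise_sd * rng.standard_normal(n_block)
            if label == "OFF-POST":
                x = x * (1.0 + cfg.effect_map.get(mspec.channel, 0.0))
            signal[ci, s0 : s0 + n_block] = x

    rec = EMGRecording(
        signal=signal,
        fs=cfg.fs,
        channels=cfg.channels,
        blocks=blocks,
        session=session,
        processing_log=[f"simulated(seed={cfg.rng_seed})"],
    )
    truth = GroundTruth(
        event_times_s=event_times,
        cycle_periods_s=periods_map,
        artifact_times_s=np.asarray(artifact_times),
        injected_effects=dict(cfg.effect_map),
    )
    return rec, truth


def inject_effect(
    recording: EMGRecording, channel: str, block: str, fraction: float
) -> EMGRecording:
    """Scale one channel within one block by ``1 + fraction``.

    All other samples are untouched; raises ``KeyError`` for unknown
    channel or block labels.
    """
    ci = recording.channel_index(channel)
    b = recording.block(block)
    out = recording.copy()
    out.signal[ci, b.start : b.end] *= 1.0 + fraction
    out.log_stage(f"inject_effect({channel}, {block}, {fraction:+g})")
    return out
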