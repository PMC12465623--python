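"""Core data containers for multi-channel gait-EMG recordings.

Conventions
-----------
* Signals are ``(n_channels, n_samples)`` float64 arrays.
* Channel labels are ``"<Muscle>_<Side>"`` strings, e.g. ``"TiAn_R"``.
* Block annotations are half-open sample intervals, 0-based.
* The three walking blocks of a stimulation session are labelled
  ``OFF-PRE`` (before stimulation), ``ON`` (stimulation applied) and
  ``OFF-POST`` (after stimulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

BLOCK_LABELS = ("OFF-PRE", "ON", "OFF-POST")
SESSIONS = ("without_exo", "with_exo")


class ValidationError(ValueError):
    """A container or parameter violates its invariants."""


@dataclass(frozen=True)
class Block:
    """Half-open sample interval ``[start, end)`` with a condition label."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"block {self.label!r}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class EMGRecording:
    """Multi-channel surface EMG recording with block annotations.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        EMG in ``units``.
    fs : float
        Sampling rate in samples/s.
    channels : list of str
        Unique ``"<Muscle>_<Side>"`` labels, one per signal row.
    blocks : list of Block
        Contiguous, non-overlapping condition annotations covering
        ``[0, n_samples)``.
    session : str
        ``"without_exo"`` or ``"with_exo"``.
    units : str
        Physical units of ``signal`` (arbitrary units for synthetic data).
    processing_log : list of str
        Ordered descriptors of the stages applied so far.
    """

    signal: np.ndarray
    fs: float
    channels: list[str]
    blocks: list[Block]
    session: str = "without_exo"
    units: str = "a.u."
    processing_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.signal.ndim != 2:
            raise ValidationError("signal must be (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if len(self.channels) != self.signal.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} channel labels for "
                f"{self.signal.shape[0]} signal rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel labels must be unique")
        if self.session not in SESSIONS:
            raise ValidationError(f"unknown session {self.session!r}")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal contains NaN/Inf")
        if not self.blocks:
            raise ValidationError("at least one block annotation required")
        pos = 0
        for b in self.blocks:
            if b.start != pos:
                raise ValidationError(
                    f"blocks must be contiguous: {b.label!r} starts at "
                    f"{b.start}, expected {pos}"
                )
            pos = b.end
        if pos != self.n_samples:
            raise ValidationError(
                f"blocks cover [0, {pos}) but recording has {self.n_samples} samples"
            )

    # -- accessors -------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(
                f"unknown channel {channel!r}; have {self.channels}"
            ) from None

    def block(self, label: str) -> Block:
        for b in self.blocks:
            if b.label == label:
                return b
        raise KeyError(f"unknown block {label!r}; have {[b.label for b in self.blocks]}")

    def block_of_sample(self, sample: int) -> str | None:
        for b in self.blocks:
            if b.start <= sample < b.end:
                return b.label
        return None

    def copy(self, *, signal: np.ndarray | None = None) -> "EMGRecording":
        return replace(
            self,
            signal=self.signal.copy() if signal is None else signal,
            channels=list(self.channels),
            blocks=list(self.blocks),
            processing_log=list(self.processing_log),
        )

    def subset(self, channels: list[str]) -> "EMGRecording":
        """Recording restricted to the given channels (copying the data)."""
        idx = [self.channel_index(c) for c in channels]
        return replace(
            self,
            signal=self.signal[idx].copy(),
            channels=list(channels),
            blocks=list(self.blocks),
            processing_log=list(self.processing_log),
        )

    def log_stage(self, descriptor: str) -> None:
        self.processing_log.append(descriptor)


def muscle_side(channel: str) -> tuple[str, str]:
    """Split a ``"<Muscle>_<Side>"`` label into its parts."""
    muscle, _, side = channel.rpartition("_")
    if not muscle:
        raise ValueError(f"channel label {channel!r} is not '<Muscle>_<Side>'")
    return muscle, side
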