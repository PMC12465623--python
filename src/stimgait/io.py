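"""Reading and writing recordings, ground truth and result tables.

Two interchangeable on-disk formats:

* **matrix + sidecar** — a ``.npy`` float64 matrix next to a ``.json``
  metadata sidecar (fs, channels, blocks, session, units, log).
  Lossless and dependency-free; the format the test suite exercises.
* **EDF+C** — one 16-bit signal per channel with block annotations, for
  interoperability with standard biosignal viewers.  Writing is
  implemented here (a compact EDF+C writer); reading goes through
  ``mne`` (optional dependency), and is quantized to 16 bits by nature
  of the format.

Ground truth serializes to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .simulate import GroundTruth
from .types import Block, EMGRecording, ValidationError

__all__ = [
    "ParseError",
    "save_recording",
    "load_recording",
    "read_recording",
    "write_edf",
    "read_edf",
    "save_ground_truth",
    "load_ground_truth",
]

SIDECAR_SCHEMA = "stimgait-recording/1"


class ParseError(ValidationError):
    """A file could not be parsed into a recording."""


# ---------------------------------------------------------------------------
# matrix + JSON sidecar
# ---------------------------------------------------------------------------

def save_recording(recording: EMGRecording, path: str | Path) -> Path:
    """Write ``<path>.npy`` + ``<path>.json``; returns the sidecar path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), recording.signal)
    meta = {
        "schema": SIDECAR_SCHEMA,
        "fs": recording.fs,
        "channels": recording.channels,
        "blocks": [[b.label, b.start, b.end] for b in recording.blocks],
        "session": recording.session,
        "units": recording.units,
        "processing_log": recording.processing_log,
    }
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def load_recording(path: str | Path) -> EMGRecording:
    """Read a matrix + sidecar recording written by :func:`save_recording`."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ParseError(f"missing sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"malformed sidecar {sidecar}: {e}") from e
    for key in ("fs", "channels", "blocks"):
        if key not in meta:
            raise ParseError(f"sidecar {sidecar} missing required field {key!r}")
    signal = np.load(path.with_suffix(".npy"))
    return EMGRecording(
        signal=signal,
        fs=float(meta["fs"]),
        channels=list(meta["channels"]),
        blocks=[Block(str(l), int(s), int(e)) for l, s, e in meta["blocks"]],
        session=meta.get("session", "without_exo"),
        units=meta.get("units", "a.u."),
        processing_log=list(meta.get("processing_log", [])),
    )


def read_recording(path: str | Path) -> EMGRecording:
    """Dispatch on extension: ``.edf`` via :func:`read_edf`, else sidecar format."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    return load_recording(path)


# ---------------------------------------------------------------------------
# EDF+C
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        b = b[:width]
    return b.ljust(width)


def write_edf(recording: EMGRecording, path: str | Path) -> Path:
    """Write an EDF+C file: one signal per channel plus block annotations.

    Samples are quantized to 16 bits over each channel's amplitude
    range.  Record duration is 1 s; the final partial record, if any, is
    zero-padded (the sidecar format is lossless — prefer it for exact
    round-trips).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fs = recording.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValidationError(f"EDF writer requires an integer sampling rate, got {fs}")
    n_records = int(np.ceil(recording.n_samples / spr))

    # Physical scaling per channel (symmetric, 16-bit).
    phys_max = np.maximum(np.abs(recording.signal).max(axis=1), 1e-9)
    dig_max, dig_min = 32767, -32767

    # Annotations: one timestamp TAL per record; block annotations in record 0.
    tals = []
    for r in range(n_records):
        tal = f"+{r}\x14\x14\x00"
        if r == 0:
            for b in recording.blocks:
                onset = b.start / fs
                dur = b.n_samples / fs
                tal += f"+{onset:g}\x15{dur:g}\x14{b.label}\x14\x00"
        tals.append(tal.encode("ascii", errors="replace"))
    ann_bytes = max(len(t) for t in tals)
    ann_spr = (ann_bytes + 1) // 2 + 1  # samples are 2 bytes

    ns = recording.n_channels + 1
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field(f"Startdate X X X X session_{recording.session}", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (1 + ns)), 8),
            _edf_field("EDF+C", 44),
            _edf_field(str(n_records), 8),
            _edf_field("1", 8),
            _edf_field(str(ns), 4),
        ]
    )
    labels = [ch for ch in recording.channels] + ["EDF Annotations"]
    sig_fields = [
        (labels, 16),
        ([""] * ns, 80),  # transducer
        (["uV"] * recording.n_channels + [""], 8),
        ([f"{-p:.6g}"[:8] for p in phys_max] + ["-1"], 8),
        ([f"{p:.6g}"[:8] for p in phys_max] + ["1"], 8),
        ([str(dig_min)] * recording.n_channels + ["-32768"], 8),
        ([str(dig_max)] * recording.n_channels + ["32767"], 8),
        ([""] * ns, 80),  # prefiltering
        ([str(spr)] * recording.n_channels + [str(ann_spr)], 8),
        ([""] * ns, 32),
    ]
    header += b"".join(
        b"".join(_edf_field(v, w) for v in values) for values, w in sig_fields
    )

    # Digital data, one record at a time.
    scale = dig_max / phys_max
    padded = np.zeros((recording.n_channels, n_records * spr))
    padded[:, : recording.n_samples] = recording.signal
    digital = np.clip(
        np.round(padded * scale[:, None]), dig_min, dig_max
    ).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_records):
            f.write(digital[:, r * spr : (r + 1) * spr].tobytes())
            f.write(tals[r].ljust(2 * ann_spr, b"\x00"))
    return path


def read_edf(path: str | Path) -> EMGRecording:
    """Read an EDF/EDF+ recording through mne; blocks from annotations.

    Annotation labels matching the standard block names become block
    annotations; a file without them raises, since downstream
    comparisons need the OFF-PRE/ON/OFF-POST structure.
    """
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ParseError("reading EDF requires the optional 'mne' dependency") from e

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()  # volts for uV-dimensioned channels
    # Undo mne's SI scaling: our EDF writer stores uV.
    signal = data * 1e6
    n = signal.shape[1]
    blocks = []
    for onset, duration, label in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        if label in ("OFF-PRE", "ON", "OFF-POST"):
            blocks.append(
                Block(label, int(round(onset * fs)), int(round((onset + duration) * fs)))
            )
    if not blocks:
        raise ParseError(f"{path}: no OFF-PRE/ON/OFF-POST block annotations found")
    blocks.sort(key=lambda b: b.start)
    if blocks[-1].end < n:  # zero-padding from whole-second records
        signal = signal[:, : blocks[-1].end]
    with open(path, "rb") as f:  # session token lives in the recording-id field
        rec_id = f.read(168)[88:168].decode("ascii", errors="replace")
    session = "with_exo" if "session_with_exo" in rec_id else "without_exo"
    return EMGRecording(
        signal=signal,
        fs=fs,
        channels=list(raw.ch_names),
        blocks=blocks,
        session=session,
        units="uV",
    )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def save_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "event_times_s": {k: v.tolist() for k, v in truth.event_times_s.items()},
        "cycle_periods_s": {k: v.tolist() for k, v in truth.cycle_periods_s.items()},
        "artifact_times_s": truth.artifact_times_s.tolist(),
        "injected_effects": truth.injected_effects,
    }
    path.write_text(json.dumps(doc))
    return path


def load_ground_truth(path: str | Path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    return GroundTruth(
        event_times_s={k: np.asarray(v) for k, v in doc["event_times_s"].items()},
        cycle_periods_s={k: np.asarray(v) for k, v in doc["cycle_periods_s"].items()},
        artifact_times_s=np.asarray(doc["artifact_times_s"]),
        injected_effects=dict(doc["injected_effects"]),
    )
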