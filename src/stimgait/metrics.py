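"""Per-cycle EMG amplitude metrics: RMS and integrated EMG (iEMG).

Both are computed on the filtered, artifact-removed wide-band signal
within cycle boundaries — not on the 1 Hz envelope, whose RMS would
conflate amplitude with burst shape.  RMS (signal units) tracks the
activation level; iEMG (units x seconds), the trapezoidal integral of
the rectified signal, tracks the effort generated over the cycle.  An
``on_envelope`` flag is available for sensitivity analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import SegmentationResult
from .types import EMGRecording, ValidationError

__all__ = ["compute_rms", "compute_iemg", "metrics_for_cycles"]


def compute_rms(segment: np.ndarray, fs: float | None = None) -> float:
    """Root mean square of a cycle's samples (``fs`` unused, kept for symmetry)."""
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise ValidationError("empty segment")
    return float(np.sqrt(np.mean(np.square(x))))


def compute_iemg(segment: np.ndarray, fs: float) -> float:
    """Trapezoidal integral of the rectified signal over the segment (units x s)."""
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise ValidationError("empty segment")
    return float(np.trapezoid(np.abs(x), dx=1.0 / fs))


def metrics_for_cycles(
    recording: EMGRecording,
    segmentation: SegmentationResult,
    selected_only: bool = True,
    on_envelope: bool = False,
) -> pd.DataFrame:
    """One row of cycle metrics per (channel, selected cycle).

    ``recording`` should be the artifact-removed band-passed signal
    (``PreprocessResult.filtered``) unless ``on_envelope`` is set, in
    which case pass the envelope recording.  Columns: session, channel,
    block, cycle_index, duration_s, rms, iemg.  Deterministic.
    """
    fs = recording.fs
    rows = []
    for ch in recording.channels:
        # Boundaries and selection are defined on the reference channel and
        # shared by all muscles; fall back to it for channels without their
        # own (envelope-bearing) cycle set.
        cyc = segmentation.cycles.get(ch, segmentation.reference)
        sig = recording.signal[recording.channel_index(ch)]
        blocks = cyc.blocks if cyc.blocks is not None else [None] * cyc.n_cycles
        for i, (s, e) in enumerate(cyc.boundaries):
            if selected_only and not cyc.selected[i]:
                continue
            if not (0 <= s < e <= sig.size):
                raise ValidationError(
                    f"cycle [{s}, {e}) outside signal of length {sig.size}"
                )
            block = blocks[i] if blocks[i] is not None else recording.block_of_sample(s)
            seg = sig[s:e]
            rows.append(
                {
                    "session": recording.session,
                    "channel": ch,
                    "block": block,
                    "cycle_index": i,
                    "duration_s": (e - s) / fs,
                    "rms": compute_rms(seg),
                    "iemg": compute_iemg(seg, fs),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["session", "channel", "block", "cycle_index", "duration_s", "rms", "iemg"],
    )
    return df
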