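"""End-to-end driver: preprocess -> segment -> metrics -> compare -> report.

A single JSON-serializable :class:`PipelineConfig` (versioned schema,
unknown keys rejected) fully determines a run; the output manifest
records the config hash, seed and a checksum per written artifact, so
identical config + input reproduce identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import io as sio
from .metrics import metrics_for_cycles
from .preprocessing import EnvelopeSpec, PreprocessResult, StimulationSpec, preprocess
from .segmentation import SegmentationResult, normalize_envelopes, segment_recording
from .simulate import GroundTruth, SimulationConfig, generate_recording
from .stats import compare_blocks, summary_table
from .types import EMGRecording, ValidationError

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]

PIPELINE_SCHEMA = "stimgait-pipeline/1"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class SegmentationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    ref_channel: str = "TiAn_R"
    expected_period_s: float = Field(default=4.5, gt=0.0)
    work_fs: float = Field(default=64.0, gt=0.0)
    band_frac: float = Field(default=0.25, gt=0.0, lt=1.0)
    min_corr: float = Field(default=0.7, ge=-1.0, le=1.0)
    duration_band: float = Field(default=0.3, gt=0.0, lt=1.0)


class StatsSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    holm: bool = False
    use_median: bool = False


class PipelineConfig(BaseModel):
    """Everything one run needs, as a single JSON document."""

    model_config = ConfigDict(extra="forbid")

    schema_tag: str = PIPELINE_SCHEMA
    input_path: str | None = None
    simulation: SimulationConfig | None = None
    band: tuple[float, float] = (20.0, 500.0)
    band_order: int = 2
    notch_hz: float = 50.0
    notch_bandwidth_hz: float = 1.5
    stim: StimulationSpec | None = Field(default_factory=StimulationSpec)
    median_window_s: float = 0.02
    envelope: EnvelopeSpec = Field(default_factory=EnvelopeSpec)
    segmentation: SegmentationSettings = Field(default_factory=SegmentationSettings)
    stats: StatsSettings = Field(default_factory=StatsSettings)
    rng_seed: int | None = None

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()


@dataclass
class PipelineResult:
    recording: EMGRecording
    truth: GroundTruth | None
    preprocessed: PreprocessResult
    segmentation: SegmentationResult
    metrics: pd.DataFrame
    comparisons: pd.DataFrame
    summary: pd.DataFrame
    manifest: dict


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full chain; optionally write all artifacts to ``out_dir``."""
    cfg = config
    truth = None
    if cfg.input_path is not None:
        try:
            recording = sio.read_recording(cfg.input_path)
        except (OSError, ValidationError) as e:
            raise PipelineError("read", str(e)) from e
    elif cfg.simulation is not None:
        sim = cfg.simulation
        if cfg.rng_seed is not None:
            sim = sim.model_copy(update={"rng_seed": cfg.rng_seed})
        recording, truth = generate_recording(sim)
    else:
        raise PipelineError("config", "need input_path or a simulation block")

    try:
        pre = preprocess(
            recording,
            band=cfg.band,
            band_order=cfg.band_order,
            notch_hz=cfg.notch_hz,
            notch_bandwidth_hz=cfg.notch_bandwidth_hz,
            stim=cfg.stim,
            median_window_s=cfg.median_window_s,
            envelope_spec=cfg.envelope,
        )
    except ValidationError as e:
        raise PipelineError("preprocess", str(e)) from e

    s = cfg.segmentation
    try:
        seg = segment_recording(
            pre.envelopes,
            ref_channel=s.ref_channel,
            expected_period_s=s.expected_period_s,
            work_fs=s.work_fs,
            band_frac=s.band_frac,
            min_corr=s.min_corr,
            duration_band=s.duration_band,
        )
        for ch in seg.cycles:
            if seg.cycles[ch].n_selected:
                seg.cycles[ch] = normalize_envelopes(seg.cycles[ch])
    except ValidationError as e:
        raise PipelineError("segment", str(e)) from e

    try:
        metrics = metrics_for_cycles(pre.filtered, seg)
        comparisons = compare_blocks(
            metrics,
            alpha=cfg.stats.alpha,
            holm=cfg.stats.holm,
            use_median=cfg.stats.use_median,
        )
        summary = (
            summary_table(comparisons, mode="full") if len(comparisons) else pd.DataFrame()
        )
    except ValidationError as e:
        raise PipelineError("stats", str(e)) from e

    manifest = {
        "schema": PIPELINE_SCHEMA,
        "config_hash": cfg.config_hash(),
        "config": json.loads(cfg.model_dump_json()),
        "seed": cfg.rng_seed,
        "artifacts": {},
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "metrics.csv", index=False)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        summary.to_csv(out / "summary.csv")
        cyc = seg.reference
        pd.DataFrame(
            {
                "start_sample": [b[0] for b in cyc.boundaries],
                "end_sample": [b[1] for b in cyc.boundaries],
                "block": cyc.blocks if cyc.blocks else [None] * cyc.n_cycles,
                "selected": cyc.selected,
                "reason": [cyc.selection_reason.get(i, "") for i in range(cyc.n_cycles)],
            }
        ).to_csv(out / "cycles.csv", index=False)
        if cyc.normalized_envelopes is not None:
            pd.DataFrame(
                cyc.normalized_envelopes,
                columns=[f"pct_{i}" for i in range(cyc.normalized_envelopes.shape[1])],
            ).to_csv(out / "normalized_envelopes.csv", index=False)
        if truth is not None:
            sio.save_ground_truth(truth, out / "ground_truth.json")
        for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
            if p.name != "manifest.json":
                manifest["artifacts"][p.name] = _checksum(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return PipelineResult(
        recording=recording,
        truth=truth,
        preprocessed=pre,
        segmentation=seg,
        metrics=metrics,
        comparisons=comparisons,
        summary=summary,
        manifest=manifest,
    )
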