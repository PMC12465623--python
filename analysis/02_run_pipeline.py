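#!/usr/bin/env python
"""Run the full EMG analysis chain on both simulated sessions.

For each session: band-pass 20-500 Hz, 50 Hz notch, stimulation-harmonic
comb on the ON block, median smoothing, 1 Hz envelopes; DTW gait-cycle
segmentation on the right tibialis anterior with boundary propagation to
all muscles; per-cycle RMS/iEMG; OFF-PRE vs OFF-POST rank-sum tests.
Writes cycle metrics, comparison rows and the percent-change summary
table under results/<session>/.

Requires analysis/01_simulate_sessions.py to have been run first.
"""

from pathlib import Path

from stimgait.pipeline import PipelineConfig, run_pipeline

DATA = Path("scratch/data")
OUT = Path("results")


def main() -> None:
    for session in ("without_exo", "with_exo"):
        cfg = PipelineConfig(input_path=str(DATA / f"{session}.json"))
        res = run_pipeline(cfg, out_dir=OUT / session)
        ref = res.segmentation.reference
        print(f"\n=== {session} ===")
        print(
            f"cycles: {ref.n_cycles} segmented, {ref.n_selected} selected"
            + ("  [UNDER-COUNT]" if ref.under_count else "")
        )
        sig = res.comparisons[res.comparisons.significant]
        print(f"significant OFF-PRE vs OFF-POST changes ({len(sig)}):")
        for r in sig.itertuples():
            print(
                f"  {r.channel:8s} {r.metric:4s} {r.percent_change:+6.2f}%  "
                f"p={r.p_value:.4f}"
            )
    print(f"\ntables written under {OUT}/<session>/")


if __name__ == "__main__":
    main()
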