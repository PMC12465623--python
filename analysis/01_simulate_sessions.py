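#!/usr/bin/env python
"""Generate the two synthetic walking sessions the analysis operates on.

Mirrors the study design: one session without and one with exoskeleton
assistance, each made of three 3-minute blocks (OFF-PRE / ON / OFF-POST)
at 2048 Hz with the full 14-channel muscle set.  The "without" session
carries injected OFF-POST effects on the knee extensor and ankle muscles
(the muscle group reported as most stimulation-responsive); the "with"
session carries a smaller, sparser effect pattern.  Raw signals are
large and binary, so they go to scratch/; ground truth (JSON) goes with
them.

Run from the repository root:  python analysis/01_simulate_sessions.py
"""

from pathlib import Path

from stimgait.io import save_ground_truth, save_recording
from stimgait.simulate import SimulationConfig, generate_recording

OUT = Path("scratch/data")

SESSIONS = {
    "without_exo": dict(
        rng_seed=101,
        effect_map={"ReFe_R": 0.08, "ReFe_L": 0.06, "GaLa_R": 0.05},
    ),
    "with_exo": dict(
        rng_seed=202,
        effect_map={"ReFe_L": -0.06, "BiFe_R": -0.05},
    ),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for session, kwargs in SESSIONS.items():
        cfg = SimulationConfig(**kwargs)
        rec, truth = generate_recording(cfg, session=session)
        save_recording(rec, OUT / f"{session}")
        save_ground_truth(truth, OUT / f"{session}_truth.json")
        print(
            f"{session}: {rec.n_channels} channels x {rec.duration_s:.0f} s, "
            f"effects {truth.injected_effects}"
        )
    print(f"wrote recordings to {OUT}/")


if __name__ == "__main__":
    main()
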