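# stimgait

Artifact-robust analysis of surface EMG recorded during walking with
transcutaneous spinal cord stimulation (tSCS) and exoskeleton
assistance.

## The problem

When tSCS (here: 30 Hz, 1 ms biphasic pulses over T11–T12) is applied
while a person walks — with or without a lower-limb exoskeleton — the
surface EMG of the leg muscles is contaminated by three things at once:
the stimulation pulse train and its harmonics, 50 Hz line interference,
and motion/cable artifacts.  The clinical question is whether muscle
activation changes from the walking block *before* stimulation
(OFF-PRE) to the block *after* it (OFF-POST), per muscle and side, in
sessions walked at very slow cadence (gait cycles around 4.5 s).

`stimgait` implements the full processing chain for that comparison:

1. **Filtering** — zero-phase 2nd-order Butterworth band-pass
   (20–500 Hz), 50 Hz notch, and a comb filter built by pole–zero
   placement: unit-circle zeros at every harmonic *k*·30 Hz below
   Nyquist with matching poles at radius *r* = 0.9985 (≈1 Hz notches),
   applied to the stimulation-ON block; then a running median and
   envelope extraction (rectify + 1 Hz 2nd-order Butterworth low-pass,
   cutoff adjusted upward for faster cadence).
2. **Gait-cycle segmentation** — a cycle template is bootstrapped from
   the reference muscle's envelope (autocorrelation → period, burst
   peaks → phase, pointwise median → shape) and matched repeatedly along
   the envelope by greedy subsequence dynamic time warping with a
   warped-length constraint, followed by rigid matched-filter refinement
   of each boundary.  Boundaries are shared by all muscles; cycles are
   kept if their envelope correlates with the template (r ≥ 0.7) and
   their duration is typical (median ± 30%), with a flag when fewer than
   10 survive.
3. **Per-cycle metrics** — RMS (activation level) and iEMG, the
   trapezoidal integral of the rectified signal (effort), computed on
   the filtered wide-band signal inside each selected cycle.
4. **Statistics** — per muscle/side/metric, OFF-PRE vs OFF-POST cycle
   values are compared with a two-sided Wilcoxon rank-sum test (exact by
   enumeration for n ≤ 20, normal approximation with tie/continuity
   correction otherwise), uncorrected α = 0.05 by default (Holm behind a
   flag), and summarized as a signed percent-change table with
   significance markers.

Because no public recordings exist for this paradigm, the package ships
a first-class synthetic-data generator (`stimgait.simulate`) that
produces ground-truthed multi-channel gait EMG: gait-phase-locked
activation bursts on a 20–450 Hz noise carrier, the 30 Hz biphasic
artifact during ON only, 50 Hz line, motion transients, background
noise, and configurable OFF-POST amplitude effects per channel.  Every
validation number the package quotes is computed against this ground
truth.

## Worked example

```python
from stimgait import (PipelineConfig, SimulationConfig, run_pipeline)

cfg = PipelineConfig(
    simulation=SimulationConfig(effect_map={"ReFe_R": 0.08}, rng_seed=101),
)
res = run_pipeline(cfg, out_dir="results/demo")
print(res.comparisons[res.comparisons.significant]
      [["channel", "metric", "percent_change", "p_value"]])
```

This simulates a three-block session (3 min each) in which the right
rectus femoris is 8% stronger after stimulation, runs the whole chain,
and prints the significant rows, e.g.:

```
   channel metric  percent_change       p_value
22  ReFe_R    rms        7.728384  1.103365e-13
23  ReFe_R   iemg        6.063713  1.564337e-02
```

The recovered +7.7% on ReFe_R RMS matches the injected +8% within the
cycle-to-cycle sampling noise of ~40 gait cycles per block; `p_value`
is the rank-sum p over OFF-PRE vs OFF-POST cycle values, and no other
channel reaches significance.

The numbered scripts under `analysis/` run the complete study-shaped
analysis: `01_simulate_sessions.py` (two sessions, with/without
exoskeleton), `02_run_pipeline.py` (full chain + percent-change
tables), `03_validate_segmentation.py` (segmentation F1/RMSE against
ground truth) and `04_effect_recovery.py` (50-run effect-recovery
benchmark).  Outputs land in `results/`; raw simulated signals in
`scratch/`.

## Command-line interface

A thin CLI wraps the library: `stimgait simulate | preprocess-cmd |
segment | analyze | run`.  Exit codes: 0 success, 2 validation error,
3 parse error, 4 computation error.

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices and known limitations.
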