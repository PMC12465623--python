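# Methods

This note documents what `stimgait` computes, the assumptions behind
each stage, the defaults that matter, and what the synthetic-data
validation does and does not demonstrate.

## Signal model and synthetic data

The generator (`stimgait.simulate`) emulates surface EMG recorded at
2048 Hz from walking at very slow, assisted cadence, in three
contiguous annotated blocks (OFF-PRE, ON, OFF-POST; 180 s each by
default).  Each channel is

```
x(t) = A_m · (tonic + burst(t)) · c(t)  +  line(t)  +  stim(t)  +  motion(t)  +  w(t)
```

* **Bursts** — one activation burst per muscle per gait cycle, a raised
  cosine whose onset and duration are fractions of that cycle's period.
  Cycle periods are 4.5 s × (1 + 0.10·z), z standard normal clipped at
  ±3 — the 10% cadence jitter of unsteady slow gait.  The default
  muscle set covers the seven SENIAM lower-limb/trunk muscles
  bilaterally with physiologically plausible burst phases.  The
  reference muscle (tibialis anterior, `TiAn_R`) has its burst centered
  on cycle start (onset −0.15, duration 0.30 of a cycle): the
  dorsiflexor burst around heel strike.  This convention matters — see
  *Segmentation* below.
* **Carrier** `c(t)` — unit-variance Gaussian noise band-limited to
  20–450 Hz, the surface-EMG energy band.  Amplitude modulation, not
  waveform shape, carries all the physiological information the
  analysis uses.
* **Stimulation artifact** — a symmetric biphasic rectangular pulse
  (1 ms per phase) at 30 Hz, constant amplitude (default 4× the burst
  peak), present only in the ON block.  The train is synthesized on an
  8×-oversampled grid and decimated through an anti-aliasing filter, as
  a real amplifier's analog front end would, so its in-band energy sits
  exactly on the 30 Hz harmonic grid rather than folding to off-grid
  frequencies.  No physiological evoked response is modeled: the
  pipeline treats stimulation content purely as artifact.
* **Line, motion, background** — a 50 Hz sinusoid (amplitude 0.3,
  random phase per channel); sparse damped 2–8 Hz sinusoid transients
  (4/min, amplitude 1.5, 0.2 s decay) standing in for cable/robot
  interference; white Gaussian background (SD 0.15).
* **Injected effects** — `effect_map` scales all OFF-POST samples of a
  channel by (1 + f), giving a known multiplicative ground truth for
  pre/post recovery tests.

Defaults are chosen once as plausible for this recording setting; no
claim is made that they match any particular real recording.  The same
seed reproduces a recording bit-for-bit.

**What the generator does not emulate:** non-stationary waveform shape
(real EMG is not Gaussian), electrode lift-off and impedance drift,
stimulation-evoked reflex responses, crosstalk between channels, or
amplitude drift within a block.  Passing the validation suite therefore
demonstrates that the *algorithms* are correct under the stated
statistical structure, not that the pipeline is robust to every failure
mode of clinical recordings.

## Filtering chain

Order fixed: band-pass → notch → comb → median → envelope.  All IIR
stages run forward–backward (`sosfiltfilt`): offline analysis permits
zero phase, and cycle-boundary timing must not be skewed by group
delay.  The effective order (and stop-band attenuation) consequently
doubles relative to the nominal design.

* **Band-pass**: Butterworth, order 2, 20–500 Hz.
* **Notch**: IIR notch at 50 Hz, −3 dB bandwidth 1.5 Hz.
* **Comb** (pole–zero placement): one biquad per harmonic k·30 Hz
  below Nyquist (k ≤ 34 at 2048 Hz), zero pair on the unit circle at
  the harmonic angle, pole pair at radius r on the same angle.  The
  notch bandwidth is ≈ (1−r)·fs/π; the default r = 0.9985 gives ≈1 Hz
  notches, chosen so that inter-harmonic EMG content is preserved
  (measured: ≤ 1% power loss in 35–55 Hz away from the notches, and
  envelope correlation ≥ 0.999 on artifact-free channels) while
  harmonic bands drop by far more than 30 dB.  Overall gain is
  normalized to 1 at the mid-harmonic frequencies.  By default the comb
  is applied to the ON block only, since the artifact exists only while
  the stimulator runs; `apply_to` can name all blocks when strict
  cross-block comparability of the transfer function is preferred.
* **Median**: running median per channel, default window 0.02 s
  (41 samples).  Its purpose is impulsive residue — stimulation
  remnants and cable pops — which it removes for any window ≫ the
  2-sample pulse width.  The window deliberately stays short: a running
  median of a zero-mean wide-band signal attenuates it by roughly
  1/√N_eff while preserving the amplitude modulation, and a long window
  (e.g. 0.1 s) leaves the subsequent 1 Hz envelope averaging only a
  handful of independent amplitude samples, which measurably degrades
  cycle-boundary timing (mean RMSE 59 ms vs 40 ms over 10 seeded
  trials).  0.02 s keeps the artifact margin (20× the pulse width,
  ~70× shorter than a burst) without that cost.
* **Envelope**: full-wave rectification then 2nd-order Butterworth
  low-pass.  The cutoff is max(1 Hz, cadence): at this study's slow
  speeds (cycle rate ≈ 0.22 Hz) the 1 Hz floor applies; for faster
  walking the rule guarantees at least one envelope oscillation per
  cycle.

Per-cycle RMS/iEMG are computed on the signal after band-pass, notch
and comb but **before** the median and rectification: the median is an
envelope-conditioning step, and amplitude metrics on the wide-band
signal are the standard definition.  (`metrics_for_cycles(...,
on_envelope=True)` exists for sensitivity analysis.)

## Gait-cycle segmentation

The published source algorithm for EMG-envelope DTW segmentation is not
reproduced anywhere in detail; the scheme here is this package's own
concrete realization with the same inputs and outputs.

1. **Template bootstrap** (`derive_template`): the cycle period is the
   envelope autocorrelation peak nearest the expected period (within
   [0.5, 2]× of it; among peaks at least half the height of the
   strongest, the nearest is taken, so a 2-period subharmonic cannot
   win on a perfectly periodic envelope).  Windows of one period are
   anchored at envelope burst peaks and reduced by a pointwise median.
   The template therefore *starts at the burst peak*.
2. **Anchor convention**: a boundary is the reference muscle's burst
   peak.  Peak position is unbiased under the symmetric smoothing of
   the envelope filter, unlike any onset/threshold anchor, which
   inherits a bias of a sizeable fraction of the burst rise time.  With
   the tibialis anterior as reference (burst peaking at heel strike),
   boundaries estimate cycle starts directly — which is also exactly
   how the generator defines its ground-truth events.
3. **Subsequence DTW** (`segment_cycles_dtw` over `stimgait._dtw`): the
   envelope is decimated to a 64 Hz working rate (it has no content
   above a few hertz; DTW cost falls with the square of the rate), and
   the template is aligned repeatedly with open start and end.  The
   dynamic program propagates each path's start column, which lets the
   warping be constrained globally: a match's warped length must lie
   within (1 ± 0.25)× the template length — the package's realization
   of a Sakoe–Chiba-style band for matches whose diagonal anchor is
   unknown a priori.  The best-scoring match is accepted, its span
   masked (infinite local cost, so matches are disjoint), the affected
   region of the dynamic program recomputed, and matching repeats until
   no gap of half a template remains.  Cycles with warped length
   outside [0.7, 1.3]× the template are rejected.
4. **Boundary refinement**: DTW path endpoints wander on 1 Hz
   envelopes because the alignment cost is nearly flat across the broad
   burst peak.  Each boundary edge is therefore re-anchored by rigid
   matched filtering: the template's burst region (±0.35 period around
   the anchor) is cross-correlated — zero-mean, normalized, no
   warping — against the envelope over shifts of ±0.12 period, and the
   edge moves to the correlation maximum.  Averaging over the whole
   burst rather than locating its peak cuts the timing error roughly in
   half at the default noise levels.
5. **Propagation and selection**: segmentation runs per block (cycle
   structure restarts at block boundaries) on one reference channel;
   boundaries are shared by all muscles so every muscle uses the same
   cycle definitions.  Automated selection replaces the human rater:
   keep a cycle iff its duration is within median ± 30% and its
   length-normalized envelope correlates with the template at r ≥ 0.7.
   Fewer than 10 survivors raises an `under_count` flag (never an
   error).  Selected envelopes are resampled to 101 points (0–100% of
   the cycle) and scaled by the mean of per-cycle peaks within each
   channel/block, for visualization and QA only — statistics always use
   unnormalized cycles.

**Measured performance** (20 seeded 180 s trials, 4.5 s cycles, 10%
jitter, default noise; recomputed by `scripts/acceptance.py` and
`analysis/03_validate_segmentation.py`): mean event-detection F1 ≈ 0.97
at 150 ms tolerance, mean timing RMSE ≈ 44 ms.  The 150 ms tolerance is
a deliberate compromise: much larger than the timing error, vastly
smaller than the 4.5 s cycle.

## Event-detection scoring

`evaluate_segmentation` matches predicted to true events one-to-one,
greedily by increasing |timing error| within the tolerance; precision,
recall and F1 come from the matched counts, and RMSE is computed over
matched pairs only (so a constant 50 ms offset scores F1 = 1,
RMSE = 50 ms).

## Statistics

Per session (never pooled across sessions), per muscle/side and metric,
OFF-PRE vs OFF-POST cycle values are compared with a two-sided Wilcoxon
rank-sum test.  For n₁+n₂ ≤ 20 the null distribution is enumerated over
all C(n, n₁) group assignments using midranks, which handles ties
exactly (identical samples give p = 1); larger samples use the normal
approximation with tie and continuity corrections.  The two-sided p is
twice the smaller tail, capped at 1.  Percent change is 100·(mean_post −
mean_pre)/mean_pre over cycle values (median by option).  No
multiple-testing correction is applied by default — mirroring the
uncorrected α = 0.05 convention of the clinical analysis this package
reimplements — with Holm adjustment behind a flag.  The summary table
renders signed percent changes with `*` (p < 0.05) and `**` (p < 0.001),
blanking non-significant cells in "paper" mode.

Two caveats are inherent to cycle-level testing and worth stating:

* **Cycles are not independent.**  Consecutive cycles share boundaries,
  and a boundary shift lengthens one cycle while shortening its
  neighbor; cycle RMS consequently shows negative serial correlation
  (lag-1 ≈ −0.5 for a short-burst reference muscle).  Negative
  correlation makes the rank-sum *conservative*: in the 50-run
  effect-recovery benchmark the null channels are flagged at ≈0%
  rather than the nominal 5%, while under genuine i.i.d. sampling the
  test's level is exact (measured 0.05 over 200 simulations).  False
  positives are therefore not inflated by the cycle design; power is
  what pays.
* **iEMG is duration-weighted.**  iEMG multiplies mean rectified
  amplitude by cycle duration, so with 10% cadence jitter its per-cycle
  spread is dominated by duration variance; a +10% amplitude effect is
  reliably *detected* in iEMG (98% of 50 runs) but its recovered
  percent change scatters several points around +10, where RMS recovers
  +10.1 ± 0.7.

## Numerical choices and degenerate inputs

* 0-based half-open sample intervals everywhere; blocks must tile the
  recording exactly.
* Constant envelopes raise a periodicity error in template derivation;
  all-zero selected cycles raise a degenerate-signal error in peak
  normalization; empty metric segments and empty test samples raise.
* The comb's zeros are placed analytically, so |H| at a harmonic is 0
  to machine precision; stability holds by construction (pole modulus
  = r < 1).
* filtfilt edge transients: block-wise comb application leaves ~1 s of
  transient at block edges; spectral measurements in the validation
  suite use block interiors.
* Determinism: every random draw flows from `numpy.random.default_rng`
  seeded from the config; rerunning a pipeline config reproduces all
  artifacts bit-for-bit (checksummed in the run manifest).

## Problem sizes used in validation

Segmentation benchmark: 20 trials × 180 s × 1 reference channel.
Effect recovery: 50 runs × 3 blocks × 180 s × 3 channels (≈40 cycles
per block).  Type-I check: 200 two-sample draws at n = 10 + 10.  These
sizes give the binomial/normal error bars quoted above while keeping a
full validation run in the minutes range on one CPU core.

## I/O formats

Lossless interchange uses a `.npy` signal matrix plus a JSON sidecar
(sampling rate, channel labels, block annotations, session, processing
log).  EDF+C export (16-bit, 1 s records, block annotations as EDF+
TALs) is provided for interoperability with standard viewers and is
read back through `mne`; EDF round-trips are exact only up to 16-bit
quantization, so the sidecar format is canonical for computation.

## Known limitations

* The segmentation anchor assumes the reference muscle has one
  dominant burst per cycle; muscles with bimodal activation should not
  be used as reference.
* Boundary sharing across muscles assumes all channels follow the same
  cycle clock — true by construction here, approximately true in gait.
* The comb removes only energy exactly on the harmonic grid; stimulator
  frequency drift would require retuning `stim_freq_hz` or widening the
  notches (smaller pole radius).
* Percent changes compare block means of cycle values; with ~40 cycles
  per block the 95% margin on a recovered amplitude change is roughly
  ±1.5 points at the default noise level.
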