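"""Gait-cycle segmentation from EMG envelopes via DTW template matching.

Pipeline: a cycle template is bootstrapped from the reference channel's
envelope (autocorrelation for the period, burst-peak alignment for the
phase, pointwise median for the shape), then matched repeatedly along
the envelope by greedy subsequence DTW.  Cycle boundaries are anchored
at the reference burst peak, so with a reference muscle whose burst
peaks at cycle start (tibialis anterior around heel strike) boundary
times estimate cycle-start times directly.

Segmentation runs on the envelope decimated to a low working rate
(default 64 Hz): the envelope carries no content above a few hertz, and
the DTW cost drops quadratically with the rate.  Boundaries are mapped
back to full-rate sample indices.

"Most representative cycle" selection replaces the visual inspection of
a human rater with an explicit rule: a cycle is kept iff its
length-normalized envelope correlates with the template at >= ``min_corr``
and its duration lies within ``median * (1 ± duration_band)``.  At least
10 selected cycles per block are expected from a 3-minute walk; an
under-count raises a flag, never an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from ._dtw import greedy_subsequence_matches
from .types import EMGRecording, ValidationError

__all__ = [
    "GaitCycleSet",
    "SegmentationQuality",
    "PeriodicityError",
    "derive_template",
    "segment_cycles_dtw",
    "select_cycles",
    "normalize_envelopes",
    "evaluate_segmentation",
    "segment_recording",
    "SegmentationResult",
]

MIN_CYCLES = 10
N_NORM_POINTS = 101  # 0-100% of the gait cycle in 1% steps


class PeriodicityError(ValidationError):
    """The envelope shows no usable periodic structure."""


@dataclass
class GaitCycleSet:
    """Cycle boundaries and per-cycle bookkeeping for one channel.

    Boundaries are half-open sample intervals at rate ``fs`` (the rate of
    ``envelope``), strictly ordered and non-overlapping.  ``blocks``
    holds the condition label of each cycle (None if it straddles a
    block boundary).  ``normalized_envelopes`` (selected cycles only) are
    resampled to 101 points and scaled so the mean of per-cycle peaks is
    1 within each channel/block group.
    """

    channel: str
    fs: float
    envelope: np.ndarray
    template: np.ndarray
    boundaries: list[tuple[int, int]]
    match_costs: np.ndarray
    selected: np.ndarray
    selection_reason: dict[int, str] = field(default_factory=dict)
    blocks: list[str | None] | None = None
    normalized_envelopes: np.ndarray | None = None
    under_count: bool = False

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries)

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def durations_s(self) -> np.ndarray:
        return np.array([(e - s) / self.fs for s, e in self.boundaries])

    def start_times_s(self) -> np.ndarray:
        return np.array([s / self.fs for s, _ in self.boundaries])

    def event_times_s(self) -> np.ndarray:
        """Detected cycle-start events: every boundary start plus the final end."""
        if not self.boundaries:
            return np.empty(0)
        ev = [s for s, _ in self.boundaries] + [self.boundaries[-1][1]]
        return np.unique(np.asarray(ev, dtype=float)) / self.fs


@dataclass(frozen=True)
class SegmentationQuality:
    """Event-detection quality against ground truth at tolerance ``tol_ms``."""

    f1: float
    precision: float
    recall: float
    rmse_ms: float
    n_matched: int
    n_predicted: int
    n_true: int
    tol_ms: float


def derive_template(
    envelope: np.ndarray,
    fs: float,
    expected_period_s: float,
    min_autocorr: float = 0.1,
) -> np.ndarray:
    """Bootstrap a one-cycle template from a periodic envelope.

    The cycle period is the autocorrelation peak nearest the expected
    period (within [0.5, 2] x expected); the template is the pointwise
    median of burst-peak-aligned windows of that length, hence anchored
    at the burst peak.
    """
    x = np.asarray(envelope, dtype=float)
    n = x.size
    if n < 3 * expected_period_s * fs:
        raise ValidationError(
            f"envelope ({n / fs:.1f} s) shorter than 3 expected periods "
            f"({3 * expected_period_s:.1f} s)"
        )
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom <= 0:
        raise PeriodicityError("constant envelope has no periodic structure")
    ac = sps.fftconvolve(xc, xc[::-1])[n - 1 :] / denom
    lo = max(2, int(round(0.5 * expected_period_s * fs)))
    hi = min(n - 2, int(round(2.0 * expected_period_s * fs)))
    if hi <= lo:
        raise PeriodicityError("autocorrelation window is empty")
    seg = ac[lo : hi + 1]
    peaks, _ = sps.find_peaks(seg)
    if peaks.size == 0 or seg[peaks].max() < min_autocorr:
        raise PeriodicityError(
            f"no autocorrelation peak >= {min_autocorr} in "
            f"[{0.5 * expected_period_s:.2f}, {2 * expected_period_s:.2f}] s"
        )
    strong = peaks[seg[peaks] >= 0.5 * seg[peaks].max()]
    period = int(lo + strong[np.argmin(np.abs(strong + lo - expected_period_s * fs))])

    # Phase: align windows at the envelope burst peaks.
    prom = 0.3 * (np.percentile(x, 95) - np.percentile(x, 10))
    bursts, _ = sps.find_peaks(x, distance=max(1, int(0.7 * period)), prominence=prom)
    windows = [x[p : p + period] for p in bursts if p + period <= n]
    if not windows:
        raise PeriodicityError("no complete burst-aligned window for the template")
    return np.median(np.asarray(windows), axis=0)


def _refine_edges(
    x: np.ndarray,
    edges: np.ndarray,
    template: np.ndarray,
    search_frac: float = 0.12,
    half_frac: float = 0.35,
) -> np.ndarray:
    """Rigid matched-filter refinement of boundary edges.

    The template is anchored at the reference burst peak, so each
    boundary edge should sit on a burst.  For each edge, the template's
    anchor region (the burst, i.e. the template's wrap-around ends) is
    cross-correlated — zero-mean, normalized, no warping — against the
    envelope over shifts within ``±search_frac`` of a period, and the
    edge moves to the correlation maximum.  Averaging over the whole
    burst makes the edge estimate far less sensitive to envelope noise
    than the DTW path endpoints or the raw peak position.
    """
    P = template.size
    L = max(2, int(half_frac * P))
    search = max(1, int(search_frac * P))
    snip = np.roll(template, L)[: 2 * L]
    snip = snip - snip.mean()
    ns = np.linalg.norm(snip)
    refined = []
    for e in edges:
        shifts = np.arange(-search, search + 1)
        best_c, best_d = -np.inf, 0
        for d in shifts:
            a, b = e + d - L, e + d + L
            if a < 0 or b > x.size:
                continue
            seg = x[a:b] - x[a:b].mean()
            den = np.linalg.norm(seg) * ns
            if den > 0:
                c = float(seg @ snip) / den
                if c > best_c:
                    best_c, best_d = c, d
        refined.append(e + best_d)
    out = np.asarray(refined)
    return np.maximum.accumulate(out)  # keep edge order monotone


def segment_cycles_dtw(
    envelope: np.ndarray,
    template: np.ndarray,
    fs: float,
    band_frac: float = 0.25,
    refine: bool = True,
    channel: str = "",
) -> GaitCycleSet:
    """Segment an envelope into cycles by greedy subsequence DTW.

    The template is repeatedly aligned (open start/end, warped length
    within ``(1 ± band_frac) x template length``), each best match is
    masked, and matching continues until less than half a template of
    signal remains.  With ``refine`` (default), boundary edges are then
    re-anchored by rigid matched-filter alignment of the template's
    burst region.  Cycles with warped length outside ``[0.7, 1.3] x
    template length`` are rejected outright.
    """
    x = np.asarray(envelope, dtype=float)
    t = np.asarray(template, dtype=float)
    if x.size < 2 * t.size:
        raise ValidationError(
            f"envelope ({x.size}) shorter than 2 template lengths ({2 * t.size})"
        )
    matches = greedy_subsequence_matches(x, t, band_frac=band_frac)
    if refine and matches:
        edges = np.unique(
            np.concatenate([[a for a, _, _ in matches], [b for _, b, _ in matches]])
        )
        refined = dict(zip(edges.tolist(), _refine_edges(x, edges, t).tolist()))
        matches = [
            (refined[a], max(refined[b], refined[a] + 1), c) for a, b, c in matches
        ]
    keep = [
        (a, b, c)
        for a, b, c in matches
        if 0.7 * t.size <= (b - a) <= 1.3 * t.size
    ]
    boundaries = [(a, b) for a, b, _ in keep]
    costs = np.array([c for _, _, c in keep])
    return GaitCycleSet(
        channel=channel,
        fs=fs,
        envelope=x,
        template=t,
        boundaries=boundaries,
        match_costs=costs,
        selected=np.ones(len(boundaries), dtype=bool),
        blocks=None,
    )


def _resample(y: np.ndarray, n: int) -> np.ndarray:
    """Linear resampling onto ``n`` evenly spaced points (endpoints kept)."""
    if y.size == n:
        return y.astype(float)
    return np.interp(np.linspace(0.0, y.size - 1.0, n), np.arange(y.size), y)


def select_cycles(
    cycles: GaitCycleSet,
    min_corr: float = 0.7,
    duration_band: float = 0.3,
) -> GaitCycleSet:
    """Keep the representative cycles: template-correlated, typical duration.

    A cycle survives iff the Pearson correlation of its length-normalized
    envelope with the template is >= ``min_corr`` and its duration lies
    within ``median duration * (1 ± duration_band)``.  Fewer than 10
    survivors set ``under_count`` (flag, not failure).
    """
    n = cycles.n_cycles
    selected = np.zeros(n, dtype=bool)
    reasons: dict[int, str] = {}
    if n:
        durations = np.array([e - s for s, e in cycles.boundaries], dtype=float)
        med = float(np.median(durations))
        t = cycles.template
        for i, (s, e) in enumerate(cycles.boundaries):
            if not (med * (1 - duration_band) <= durations[i] <= med * (1 + duration_band)):
                reasons[i] = "atypical_duration"
                continue
            seg = _resample(cycles.envelope[s:e], t.size)
            if seg.std() == 0 or t.std() == 0:
                corr = 0.0
            else:
                corr = float(np.corrcoef(seg, t)[0, 1])
            if corr < min_corr:
                reasons[i] = "low_correlation"
            else:
                selected[i] = True
    return replace(
        cycles,
        selected=selected,
        selection_reason=reasons,
        under_count=bool(selected.sum() < MIN_CYCLES),
    )


def normalize_envelopes(cycles: GaitCycleSet) -> GaitCycleSet:
    """Time- and amplitude-normalize the selected cycles' envelopes.

    Each selected cycle is resampled to 101 points (0-100% of the gait
    cycle) and divided by the mean of per-cycle peaks, computed within
    each channel/block group, so the mean of normalized peaks is 1 by
    construction.  Intended for visualization/QA: downstream RMS/iEMG
    statistics use unnormalized cycles.
    """
    idx = np.flatnonzero(cycles.selected)
    if idx.size == 0:
        raise ValidationError("no selected cycles to normalize")
    resampled = np.array(
        [_resample(cycles.envelope[s:e], N_NORM_POINTS) for s, e in
         (cycles.boundaries[i] for i in idx)]
    )
    groups: dict[str | None, np.ndarray] = {}
    labels = (
        [cycles.blocks[i] for i in idx] if cycles.blocks is not None else [None] * idx.size
    )
    for lab in set(labels):
        groups[lab] = np.flatnonzero([l == lab for l in labels])
    out = resampled.copy()
    for lab, g in groups.items():
        mean_peak = resampled[g].max(axis=1).mean()
        if mean_peak <= 0:
            raise ValidationError(f"degenerate (zero-peak) envelopes in block {lab!r}")
        out[g] = resampled[g] / mean_peak
    return replace(cycles, normalized_envelopes=out)


def evaluate_segmentation(
    predicted_events_s: np.ndarray,
    true_events_s: np.ndarray,
    tol_ms: float = 150.0,
) -> SegmentationQuality:
    """Greedy one-to-one event matching within ``tol_ms``; F1 and timing RMSE.

    Pairs are accepted in order of increasing |timing error|; each
    predicted and each true event is used at most once, so
    ``|predicted| = TP + FP`` and ``|truth| = TP + FN`` by construction.
    """
    pred = np.sort(np.asarray(predicted_events_s, dtype=float))
    true = np.sort(np.asarray(true_events_s, dtype=float))
    if true.size == 0:
        raise ValidationError("empty ground truth: recall undefined")
    tol_s = tol_ms / 1000.0
    pairs = [
        (abs(p - t), i, j)
        for i, p in enumerate(pred)
        for j, t in enumerate(true)
        if abs(p - t) <= tol_s
    ]
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    errors = []
    for d, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        errors.append(d)
    tp = len(errors)
    precision = tp / pred.size if pred.size else 0.0
    recall = tp / true.size
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    rmse_ms = float(np.sqrt(np.mean(np.square(errors))) * 1000.0) if errors else float("nan")
    return SegmentationQuality(
        f1=f1,
        precision=precision,
        recall=recall,
        rmse_ms=rmse_ms,
        n_matched=tp,
        n_predicted=int(pred.size),
        n_true=int(true.size),
        tol_ms=tol_ms,
    )


@dataclass
class SegmentationResult:
    """Per-channel cycle sets sharing the reference channel's boundaries."""

    cycles: dict[str, GaitCycleSet]
    ref_channel: str
    work_fs: float

    @property
    def reference(self) -> GaitCycleSet:
        return self.cycles[self.ref_channel]


def segment_recording(
    envelopes: EMGRecording,
    ref_channel: str,
    expected_period_s: float = 4.5,
    work_fs: float = 64.0,
    band_frac: float = 0.25,
    min_corr: float = 0.7,
    duration_band: float = 0.3,
    per_block: bool = True,
) -> SegmentationResult:
    """Segment a whole recording on a reference channel and propagate.

    The reference envelope is decimated to ``work_fs``, a template is
    derived from the full reference envelope, each block is segmented
    independently (cycle structure restarts at block boundaries), and
    the resulting boundaries — mapped back to full-rate samples — are
    shared by every channel so all muscles use the same cycle
    definitions.  Cycle selection is decided on the reference channel.
    """
    fs = envelopes.fs
    decim = max(1, int(round(fs / work_fs)))
    wfs = fs / decim
    ref = envelopes.signal[envelopes.channel_index(ref_channel), ::decim]
    template = derive_template(ref, wfs, expected_period_s)

    spans = (
        [(b.label, b.start // decim, b.end // decim) for b in envelopes.blocks]
        if per_block
        else [(None, 0, ref.size)]
    )
    boundaries: list[tuple[int, int]] = []
    labels: list[str | None] = []
    costs: list[float] = []
    for lab, s0, s1 in spans:
        seg = ref[s0:s1]
        if seg.size < 2 * template.size:
            continue
        cs = segment_cycles_dtw(seg, template, wfs, band_frac=band_frac)
        for (a, b), c in zip(cs.boundaries, cs.match_costs):
            boundaries.append(((a + s0) * decim, (b + s0) * decim))
            labels.append(lab)
            costs.append(float(c))

    order = np.argsort([s for s, _ in boundaries]) if boundaries else np.empty(0, int)
    boundaries = [boundaries[i] for i in order]
    labels = [labels[i] for i in order]
    costs_arr = np.asarray(costs)[order] if len(costs) else np.empty(0)

    ref_set = GaitCycleSet(
        channel=ref_channel,
        fs=fs,
        envelope=envelopes.signal[envelopes.channel_index(ref_channel)],
        template=_resample(template, template.size * decim),
        boundaries=boundaries,
        match_costs=costs_arr,
        selected=np.ones(len(boundaries), dtype=bool),
        blocks=labels,
    )
    ref_set = select_cycles(ref_set, min_corr=min_corr, duration_band=duration_band)

    cycles: dict[str, GaitCycleSet] = {}
    for ch in envelopes.channels:
        if ch == ref_channel:
            cycles[ch] = ref_set
        else:
            cycles[ch] = replace(
                ref_set,
                channel=ch,
                envelope=envelopes.signal[envelopes.channel_index(ch)],
                template=ref_set.template,
            )
    return SegmentationResult(cycles=cycles, ref_channel=ref_channel, work_fs=wfs)
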