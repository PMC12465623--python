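import numpy as np
import pytest
from scipy import signal as sps

from stimgait.segmentation import (
    GaitCycleSet,
    PeriodicityError,
    derive_template,
    evaluate_segmentation,
    normalize_envelopes,
    segment_cycles_dtw,
    select_cycles,
)
from stimgait.types import ValidationError

from conftest import periodic_envelope

WFS = 64.0
PERIOD = 288  # 4.5 s at 64 Hz


def autocorr_oracle_period(env: np.ndarray, expected: int) -> int:
    """Brute-force periodicity oracle: argmax of the autocorrelation."""
    x = env - env.mean()
    n = x.size
    ac = np.array([x[: n - k] @ x[k:] for k in range(n // 2)])
    lo, hi = expected // 2, 2 * expected
    return int(lo + np.argmax(ac[lo:hi]))


class TestDeriveTemplate:
    def test_noiseless_period_recovered_within_one_sample(self):
        env, _ = periodic_envelope(n_cycles=10, period=PERIOD)
        t = derive_template(env, WFS, PERIOD / WFS)
        oracle = autocorr_oracle_period(env, PERIOD)
        assert abs(t.size - PERIOD) <= 1
        assert abs(t.size - oracle) <= 1

    def test_template_anchored_at_burst_peak(self):
        env, _ = periodic_envelope(n_cycles=10, period=PERIOD)
        t = derive_template(env, WFS, PERIOD / WFS)
        assert np.argmax(t) in (0, t.size - 1)

    def test_constant_envelope_raises_periodicity_error(self):
        with pytest.raises(PeriodicityError):
            derive_template(np.full(3000, 0.5), WFS, PERIOD / WFS)

    def test_too_short_envelope_raises(self):
        env, _ = periodic_envelope(n_cycles=2, period=PERIOD)
        with pytest.raises(ValidationError):
            derive_template(env, WFS, PERIOD / WFS)


class TestSegmentCyclesDtw:
    def test_noiseless_boundaries_match_ground_truth(self):
        env, starts = periodic_envelope(n_cycles=12, period=PERIOD)
        t = derive_template(env, WFS, PERIOD / WFS)
        cs = segment_cycles_dtw(env, t, WFS)
        pred = np.array([s for s, _ in cs.boundaries])
        # every interior true start recovered within +/- 1 sample
        for s in starts[1:-1]:
            assert np.min(np.abs(pred - s)) <= 1

    def test_agrees_with_autocorrelation_oracle_boundaries(self):
        env, _ = periodic_envelope(n_cycles=12, period=PERIOD)
        period = autocorr_oracle_period(env, PERIOD)
        peaks, _ = sps.find_peaks(env, distance=int(0.7 * period))
        t = derive_template(env, WFS, PERIOD / WFS)
        cs = segment_cycles_dtw(env, t, WFS)
        pred = np.array([s for s, _ in cs.boundaries])
        for p in peaks[1:-1]:
            assert np.min(np.abs(pred - p)) <= 1

    def test_shift_equivariance(self):
        env, _ = periodic_envelope(n_cycles=12, period=PERIOD)
        t = derive_template(env, WFS, PERIOD / WFS)
        delta = 37
        shifted = np.concatenate([np.full(delta, env[:50].min()), env])[: env.size]
        a = segment_cycles_dtw(env, t, WFS).boundaries
        b = segment_cycles_dtw(shifted, t, WFS).boundaries
        a_starts = np.array([s for s, _ in a])
        b_starts = np.array([s for s, _ in b])
        common = [s for s in a_starts if s + delta < env.size - PERIOD]
        for s in common[1:-1]:
            assert np.min(np.abs(b_starts - (s + delta))) <= 1

    def test_envelope_shorter_than_two_templates_raises(self):
        env, _ = periodic_envelope(n_cycles=12, period=PERIOD)
        t = derive_template(env, WFS, PERIOD / WFS)
        with pytest.raises(ValidationError):
            segment_cycles_dtw(env[: int(1.5 * t.size)], t, WFS)


def make_cycleset(envelope, boundaries, template, blocks=None):
    return GaitCycleSet(
        channel="TiAn_R",
        fs=WFS,
        envelope=np.asarray(envelope, dtype=float),
        template=np.asarray(template, dtype=float),
        boundaries=list(boundaries),
        match_costs=np.zeros(len(boundaries)),
        selected=np.ones(len(boundaries), dtype=bool),
        blocks=blocks,
    )


class TestSelectCycles:
    def test_identical_cycles_all_selected(self):
        env, _ = periodic_envelope(n_cycles=12, period=PERIOD)
        t = env[:PERIOD].copy()
        bounds = [(k * PERIOD, (k + 1) * PERIOD) for k in range(12)]
        out = select_cycles(make_cycleset(env, bounds, t))
        assert out.selected.all()
        assert not out.under_count

    def test_noise_cycle_rejected_for_low_correlation(self):
        rng = np.random.default_rng(0)
        env, _ = periodic_envelope(n_cycles=12, period=PERIOD)
        env[3 * PERIOD : 4 * PERIOD] = 0.2 + 0.05 * rng.standard_normal(PERIOD)
        t = env[:PERIOD].copy()
        bounds = [(k * PERIOD, (k + 1) * PERIOD) for k in range(12)]
        out = select_cycles(make_cycleset(env, bounds, t))
        assert not out.selected[3]
        assert out.selection_reason[3] == "low_correlation"
        assert out.selected.sum() == 11

    def test_atypical_duration_rejected(self):
        env, _ = periodic_envelope(n_cycles=12, period=PERIOD)
        t = env[:PERIOD].copy()
        bounds = [(k * PERIOD, (k + 1) * PERIOD) for k in range(11)]
        bounds.append((11 * PERIOD, 12 * PERIOD - int(0.4 * PERIOD)))
        out = select_cycles(make_cycleset(env, bounds, t))
        assert out.selection_reason.get(11) == "atypical_duration"

    def test_under_count_flag(self):
        env, _ = periodic_envelope(n_cycles=5, period=PERIOD)
        t = env[:PERIOD].copy()
        bounds = [(k * PERIOD, (k + 1) * PERIOD) for k in range(5)]
        out = select_cycles(make_cycleset(env, bounds, t))
        assert out.under_count  # fewer than 10 cycles, flagged not failed
        assert out.selected.sum() == 5


class TestNormalizeEnvelopes:
    def test_identical_cycles_normalize_to_unit_peak(self):
        env, _ = periodic_envelope(n_cycles=6, period=PERIOD)
        t = env[:PERIOD].copy()
        bounds = [(k * PERIOD, (k + 1) * PERIOD) for k in range(6)]
        out = normalize_envelopes(make_cycleset(env, bounds, t))
        assert out.normalized_envelopes.shape == (6, 101)
        np.testing.assert_allclose(out.normalized_envelopes.max(axis=1), 1.0, rtol=1e-6)

    def test_two_cycles_with_peaks_one_and_three(self):
        period = 100
        env = np.zeros(200)
        env[:period] = np.sin(np.linspace(0, np.pi, period))  # peak 1
        env[period:] = 3 * np.sin(np.linspace(0, np.pi, period))  # peak 3
        out = normalize_envelopes(make_cycleset(env, [(0, 100), (100, 200)], env[:100]))
        np.testing.assert_allclose(
            np.sort(out.normalized_envelopes.max(axis=1)), [0.5, 1.5], rtol=1e-6
        )

    def test_scale_invariance(self):
        env, _ = periodic_envelope(n_cycles=6, period=PERIOD)
        bounds = [(k * PERIOD, (k + 1) * PERIOD) for k in range(6)]
        a = normalize_envelopes(make_cycleset(env, bounds, env[:PERIOD]))
        b = normalize_envelopes(make_cycleset(7.3 * env, bounds, env[:PERIOD]))
        np.testing.assert_allclose(
            a.normalized_envelopes, b.normalized_envelopes, rtol=1e-9
        )

    def test_zero_envelope_raises(self):
        with pytest.raises(ValidationError):
            normalize_envelopes(
                make_cycleset(np.zeros(200), [(0, 100), (100, 200)], np.zeros(100))
            )


class TestEvaluateSegmentation:
    def test_perfect_prediction(self):
        truth = np.array([0.0, 1.0, 2.0, 3.0])
        q = evaluate_segmentation(truth, truth)
        assert q.f1 == 1.0 and q.rmse_ms == 0.0

    def test_no_predictions(self):
        q = evaluate_segmentation(np.array([]), np.array([0.0, 1.0]))
        assert q.f1 == 0.0

    def test_constant_offset(self):
        truth = np.array([0.0, 1.0, 2.0, 3.0])
        q = evaluate_segmentation(truth + 0.05, truth, tol_ms=150.0)
        assert q.f1 == 1.0
        assert q.rmse_ms == pytest.approx(50.0, abs=1e-9)

    def test_matching_is_one_to_one_and_conserves_counts(self):
        rng = np.random.default_rng(7)
        truth = np.sort(rng.uniform(0, 100, 30))
        pred = np.sort(rng.uniform(0, 100, 25))
        q = evaluate_segmentation(pred, truth, tol_ms=500.0)
        assert q.n_matched <= min(q.n_predicted, q.n_true)
        assert q.n_predicted == 25 and q.n_true == 30
        # precision/recall consistent with TP + FP / TP + FN conservation
        assert q.precision == pytest.approx(q.n_matched / 25)
        assert q.recall == pytest.approx(q.n_matched / 30)

    def test_empty_truth_raises(self):
        with pytest.raises(ValidationError):
            evaluate_segmentation(np.array([1.0]), np.array([]))
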