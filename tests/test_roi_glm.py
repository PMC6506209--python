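import numpy as np
import pytest

from lossaversion.roi_glm import (DESIGN_COLUMNS, EventSchedule, GlmBetas,
                                  RoiTimeSeries, build_design, canonical_hrf,
                                  dct_basis, fit_roi_glm, highpass_dct,
                                  neural_loss_aversion, ols_betas)
from lossaversion.synthetic_data import simulate_roi_bold
from lossaversion.task_design import build_mixed_trials


def _mixed_schedule():
    """Factorial mixed trials on a regular 12 s grid."""
    trials = build_mixed_trials()
    onsets = 12.0 * np.arange(len(trials)) + 2.0
    gains = np.array([max(t.gamble.outcomes) for t in trials])
    losses = np.array([-min(t.gamble.outcomes) for t in trials])
    return EventSchedule(onsets=onsets, gain=gains, loss=losses,
                         sure=np.zeros_like(gains),
                         decision_onsets=onsets + 2.0)


class TestCanonicalHrf:
    def test_zero_at_origin_and_unit_peak(self):
        h = canonical_hrf(0.1)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)

    def test_peak_latency_about_five_seconds(self):
        h = canonical_hrf(0.1)
        assert 0.1 * h.argmax() == pytest.approx(5.0, abs=1.0)

    def test_single_undershoot(self):
        h = canonical_hrf(0.1)
        signs = np.sign(h[np.abs(h) > 1e-12])
        changes = np.count_nonzero(np.diff(signs))
        assert changes == 1


class TestBuildDesign:
    def test_constant_modulators_vanish_after_centering(self):
        s = _mixed_schedule()
        s = EventSchedule(onsets=s.onsets, gain=np.full_like(s.gain, 10.0),
                          loss=s.loss, sure=s.sure,
                          decision_onsets=s.decision_onsets)
        X = build_design(s, tr=2.0, n_scans=900)
        assert np.allclose(X[:, 1], 0.0)

    def test_single_event_column_is_shifted_hrf(self):
        s = EventSchedule(onsets=[10.0], gain=[1.0], loss=[0.0], sure=[0.0],
                          decision_onsets=[12.0])
        X = build_design(s, tr=0.5, n_scans=120, center=False)
        hrf = canonical_hrf(0.5 / 16)[::16]
        col = X[:, 1]
        start = int(10.0 / 0.5)
        np.testing.assert_allclose(col[start:start + hrf.size], hrf, atol=1e-12)
        assert np.allclose(col[:start], 0.0)

    def test_factorial_design_decorrelates_gain_and_loss(self):
        X = build_design(_mixed_schedule(), tr=2.0, n_scans=900)
        r = np.corrcoef(X[:, 1], X[:, 2])[0, 1]
        assert abs(r) < 0.05

    def test_identical_onsets_collapse_with_summed_modulators(self):
        a = EventSchedule(onsets=[10.0, 10.0], gain=[1.0, 2.0],
                          loss=[0.0, 0.0], sure=[0.0, 0.0],
                          decision_onsets=[12.0, 12.0])
        b = EventSchedule(onsets=[10.0], gain=[3.0], loss=[0.0], sure=[0.0],
                          decision_onsets=[12.0])
        Xa = build_design(a, tr=1.0, n_scans=60, center=False)
        Xb = build_design(b, tr=1.0, n_scans=60, center=False)
        np.testing.assert_allclose(Xa[:, 1], Xb[:, 1], atol=1e-12)


class TestHighpass:
    def test_constant_series_zeroed(self):
        out = highpass_dct(RoiTimeSeries(np.full(500, 7.0), tr=2.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_slow_drift_removed(self):
        t = 2.0 * np.arange(500)
        drift = np.cos(2 * np.pi * t / 400.0)
        out = highpass_dct(RoiTimeSeries(drift, tr=2.0), cutoff=128.0)
        assert np.std(out) < 0.05 * np.std(drift)  # > 95% attenuated

    def test_white_noise_variance_roughly_preserved(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        out = highpass_dct(RoiTimeSeries(x, tr=2.0))
        assert np.var(out) / np.var(x) > 0.9

    def test_cutoff_guard(self):
        with pytest.raises(ValueError):
            dct_basis(100, tr=2.0, cutoff=3.0)


class TestOlsBetas:
    def test_matches_normal_equations_on_small_instance(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.standard_normal((50, 5)), np.ones(50)])
        y = rng.standard_normal(50)
        ours = ols_betas(X, y)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        got = [ours.beta_onset, ours.beta_gain, ours.beta_loss,
               ours.beta_sure, ours.beta_decision, ours.beta_intercept]
        np.testing.assert_allclose(got, oracle, atol=1e-10)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.standard_normal((40, 5)), np.ones(40)])
        X[:, 2] = 2 * X[:, 1]
        with pytest.raises(ValueError, match="gain"):
            ols_betas(X, rng.standard_normal(40))

    def test_unbiased_under_noise(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.standard_normal((200, 5)), np.ones(200)])
        truth = np.array([1.0, 0.5, -0.8, 0.2, 0.3, 0.0])
        signal = X @ truth
        est = np.linalg.pinv(X) @ (signal[:, None]
                                   + rng.standard_normal((200, 200))).squeeze()
        np.testing.assert_allclose(est.mean(axis=1), truth, atol=0.05)


class TestNeuralLossAversion:
    def test_sign_arithmetic(self):
        b = GlmBetas(1.0, 0.5, -0.8, 0.2, 0.3, 0.0)
        assert neural_loss_aversion(b) == pytest.approx(0.3)
        z = GlmBetas(1.0, 0.0, 0.0, 0.2, 0.3, 0.0)
        assert neural_loss_aversion(z) == 0.0

    def test_invariant_to_sure_beta_and_drift(self, task0):
        schedule = EventSchedule.from_task(task0)
        nlas = []
        for beta_sure in (0.0, 0.7):
            ts = simulate_roi_bold(task0, (0.5, -0.8, beta_sure), noise_sd=0.0)
            t = 2.0 * np.arange(len(ts))
            drifted = RoiTimeSeries(ts.values + 3.0 * np.sin(2 * np.pi * t / 600),
                                    tr=2.0)
            nlas.append(neural_loss_aversion(fit_roi_glm(schedule, drifted)))
        assert nlas[0] == pytest.approx(0.3, abs=1e-3)
        assert nlas[1] == pytest.approx(nlas[0], abs=1e-6)


def test_full_loop_recovery_with_noise(task0):
    """simulate -> design -> filter -> OLS recovers betas with small bias."""
    schedule = EventSchedule.from_task(task0)
    ts0 = simulate_roi_bold(task0, (0.5, -0.8, 0.2), noise_sd=0.0)
    signal_sd = ts0.values.std()
    X = build_design(schedule, ts0.tr, len(ts0))
    pinv = np.linalg.pinv(X)
    rng = np.random.default_rng(4)
    noise = 0.5 * signal_sd * rng.standard_normal((100, len(ts0)))
    betas = pinv @ (ts0.values + noise).T
    assert betas[1].mean() == pytest.approx(0.5, rel=0.02)
    assert betas[2].mean() == pytest.approx(-0.8, rel=0.02)


def test_schedule_csv_roundtrip(tmp_path, task0):
    s = EventSchedule.from_task(task0)
    s.to_csv(tmp_path / "events.csv")
    loaded = EventSchedule.from_csv(tmp_path / "events.csv")
    np.testing.assert_allclose(loaded.onsets, s.onsets)
    np.testing.assert_allclose(loaded.loss, s.loss)
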