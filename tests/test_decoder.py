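"""Kalman/UKF decoding, feature extraction and closed-loop adaptation."""

from dataclasses import replace

import numpy as np
import pytest

from gaitbci.decoder import (CLDAState, DecoderConfig, DecoderModel,
                             FeatureConfig, KalmanState, UKFConfig, clda_blend,
                             clda_fit, extract_features, kf_predict,
                             kf_update, models_equal, run_closed_loop,
                             ukf_step)
from tests.conftest import SHORT_PROTOCOL


# --- independent textbook oracle -------------------------------------------

def textbook_kf_step(x, P, F, H, Q, R, y, bias=None):
    """Straight transcription of the linear Kalman recursion, coded
    independently of the package (explicit inverses, no shared helpers)."""
    bias = np.zeros(H.shape[0]) if bias is None else bias
    x_pred = F @ x
    P_pred = F @ P @ F.T + Q
    z = H @ x_pred + bias
    S = H @ P_pred @ H.T + R
    K = P_pred @ H.T @ np.linalg.inv(S)
    x_new = x_pred + K @ (y - z)
    P_new = (np.eye(len(x)) - K @ H) @ P_pred
    return x_new, P_new


def _toy_model(rng, n=2, m=2, rho=0.95):
    A = rng.standard_normal((n, n))
    F = rho * A / np.abs(np.linalg.eigvals(A)).max()
    H = rng.standard_normal((m, n))
    Lq = rng.standard_normal((n, n)) * 0.1
    Lr = rng.standard_normal((m, m)) * 0.1
    return DecoderModel(F=F, H=H, Q=Lq @ Lq.T + 0.01 * np.eye(n),
                        R=Lr @ Lr.T + 0.01 * np.eye(m))


class TestFeatures:
    def test_zero_input_gives_zero_features(self):
        out = extract_features(np.zeros((500, 3)))
        assert np.all(out == 0.0)

    def test_lag_embedding_dimension(self):
        cfg = FeatureConfig(n_lags=4, lag_step=5)
        out = extract_features(np.random.default_rng(0).normal(size=(200, 7)),
                               cfg)
        assert out.shape == (200, 7 * 5)

    def test_out_of_band_tone_attenuated(self):
        # a 10 Hz tone must sit >= 20 dB below a 1 Hz tone of equal amplitude
        fs = 100.0
        t = np.arange(3000) / fs
        cfg = FeatureConfig(standardize=False)
        amp = {}
        for f in (1.0, 10.0):
            y = extract_features(np.sin(2 * np.pi * f * t), cfg)
            amp[f] = np.abs(y[1500:]).max()     # steady state
        assert 20 * np.log10(amp[1.0] / amp[10.0]) >= 20.0

    def test_invalid_band_edges_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            FeatureConfig(band=(0.1, 60.0))
        with pytest.raises(ValueError, match="band"):
            FeatureConfig(band=(3.0, 0.1))

    def test_causality_of_standardized_features(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(400, 2))
        full = extract_features(x)
        prefix = extract_features(x[:250])
        assert np.allclose(full[:250], prefix)


class TestKalman:
    def test_static_model_prediction_is_identity(self):
        state = KalmanState(np.array([1.0, -2.0]), np.eye(2) * 3.0)
        model = DecoderModel(F=np.eye(2), H=np.eye(2), Q=np.zeros((2, 2)),
                             R=np.eye(2))
        pred = kf_predict(state, model)
        assert np.array_equal(pred.x_pred, state.x)
        assert np.array_equal(pred.P_pred, state.P)

    def test_predict_matches_hand_multiplied_matrices(self):
        F = np.array([[1.0, 0.1], [0.0, 1.0]])
        Q = np.array([[0.2, 0.05], [0.05, 0.1]])
        x = np.array([2.0, -1.0])
        P = np.array([[1.0, 0.3], [0.3, 2.0]])
        model = DecoderModel(F=F, H=np.eye(2), Q=Q, R=np.eye(2))
        pred = kf_predict(KalmanState(x, P), model)
        assert np.allclose(pred.x_pred, F @ x)
        assert np.allclose(pred.P_pred, F @ P @ F.T + Q)

    def test_prediction_preserves_positive_semidefiniteness(self, rng):
        for _ in range(100):
            L = rng.standard_normal((3, 3))
            Lq = rng.standard_normal((3, 3))
            model = DecoderModel(F=rng.standard_normal((3, 3)),
                                 H=np.eye(3), Q=Lq @ Lq.T, R=np.eye(3))
            pred = kf_predict(KalmanState(np.zeros(3), L @ L.T), model)
            assert np.min(np.linalg.eigvalsh(pred.P_pred)) >= -1e-10

    def test_zero_innovation_keeps_prediction(self, rng):
        model = _toy_model(rng)
        state = kf_predict(KalmanState(rng.normal(size=2), np.eye(2)), model)
        y = model.H @ state.x_pred + model.bias
        new = kf_update(state, model, y)
        assert np.allclose(new.x, state.x_pred)

    def test_scalar_noiseless_observation_is_fully_trusted(self):
        model = DecoderModel(F=np.eye(1), H=np.eye(1), Q=np.eye(1) * 0.1,
                             R=np.zeros((1, 1)))
        state = kf_predict(KalmanState(np.array([5.0]), np.eye(1)), model)
        new = kf_update(state, model, np.array([-3.0]))
        assert new.x[0] == pytest.approx(-3.0)

    def test_single_step_matches_textbook_oracle(self, rng):
        model = _toy_model(rng)
        x0, P0 = rng.normal(size=2), np.eye(2) * 0.5
        y = rng.normal(size=2)
        got = kf_update(kf_predict(KalmanState(x0, P0), model), model, y)
        x_ref, P_ref = textbook_kf_step(x0, P0, model.F, model.H, model.Q,
                                        model.R, y)
        assert np.allclose(got.x, x_ref, atol=1e-10)
        assert np.allclose(got.P, P_ref, atol=1e-10)

    def test_singular_innovation_is_damped_not_fatal(self):
        model = DecoderModel(F=np.eye(2), H=np.zeros((2, 2)),
                             Q=np.zeros((2, 2)), R=np.zeros((2, 2)))
        state = kf_predict(KalmanState(np.zeros(2), np.zeros((2, 2))), model)
        new = kf_update(state, model, np.array([1.0, 1.0]))
        assert np.all(np.isfinite(new.x))


class TestUKF:
    def test_sigma_weights_sum_to_one(self):
        wm, wc, _ = UKFConfig().weights(6)
        assert wm.sum() == pytest.approx(1.0)
        assert len(wm) == 13 and len(wc) == 13

    def test_linear_equivalence_with_kf(self, rng):
        model = _toy_model(rng, n=3, m=4)
        ukf_cfg = UKFConfig()
        kf_state = KalmanState(np.zeros(3), np.eye(3))
        ukf_state = KalmanState(np.zeros(3), np.eye(3))
        worst = 0.0
        for _ in range(1000):
            y = rng.normal(size=4)
            kf_state = kf_update(kf_predict(kf_state, model), model, y)
            ukf_state = ukf_step(ukf_state, model, ukf_cfg, y)
            worst = max(worst, np.max(np.abs(kf_state.x - ukf_state.x)))
        assert worst < 1e-6

    def test_quadratic_observation_matches_monte_carlo(self, rng):
        # 1-state toy with z = a x + b x²: the unscented estimate of the
        # predicted observation must match brute-force sampling
        a, b = 1.5, 0.8
        model = DecoderModel(F=np.eye(1) * 0.9, H=np.array([[a]]),
                             Q=np.eye(1) * 0.3, R=np.eye(1) * 0.5,
                             H_quad=np.array([[b]]))
        cfg = UKFConfig(alpha=0.5, observation_order="quadratic")
        x0, P0 = np.array([0.7]), np.eye(1) * 0.4
        state = ukf_step(KalmanState(x0, P0), model, cfg, np.array([0.0]))
        # Monte-Carlo propagation of z through predict + observe
        draws = 0.9 * x0[0] + np.sqrt(0.9 ** 2 * P0[0, 0] + 0.3) \
            * rng.standard_normal(100_000)
        z_mc = a * draws + b * draws ** 2
        se = z_mc.std() / np.sqrt(draws.size)
        assert abs(state.z[0] - z_mc.mean()) < 3 * se

    def test_noiseless_consistent_track_locks_on(self, rng):
        model = _toy_model(rng, n=2, m=2)
        model = DecoderModel(F=model.F, H=model.H, Q=np.zeros((2, 2)),
                             R=np.zeros((2, 2)))
        x_true = np.array([1.0, -1.0])
        state = KalmanState(np.zeros(2), np.eye(2))
        for _ in range(50):
            x_true = model.F @ x_true
            state = ukf_step(state, model, UKFConfig(), model.H @ x_true)
        assert np.allclose(state.x, x_true, atol=1e-6)


class TestCLDA:
    def _simulate_buffer(self, rng, n=6000, m=12, state_noise=0.05,
                         obs_noise=0.05):
        A = rng.standard_normal((6, 6))
        F_star = 0.97 * A / np.abs(np.linalg.eigvals(A)).max()
        H_star = rng.standard_normal((m, 6))
        x = np.zeros((n, 6))
        for t in range(1, n):
            x[t] = F_star @ x[t - 1] + state_noise * rng.standard_normal(6)
        feats = x @ H_star.T + obs_noise * rng.standard_normal((n, m))
        return feats, x, F_star, H_star

    def test_parameter_recovery(self, rng):
        feats, x, F_star, H_star = self._simulate_buffer(rng)
        model = clda_fit(feats, x)
        f_err = np.linalg.norm(model.F - F_star) / np.linalg.norm(F_star)
        h_err = np.linalg.norm(model.H - H_star) / np.linalg.norm(H_star)
        assert f_err < 0.05 and h_err < 0.05

    def test_noiseless_buffer_gives_vanishing_noise_estimates(self, rng):
        feats, x, _, _ = self._simulate_buffer(rng, n=2000, state_noise=0.05,
                                               obs_noise=0.0)
        model = clda_fit(feats, x)
        assert np.abs(model.R).max() < 1e-12

    def test_constant_states_exercise_ridge_path(self, caplog):
        import logging

        x = np.ones((100, 6))
        feats = np.ones((100, 4))
        with caplog.at_level(logging.WARNING, logger="gaitbci.decoder"):
            model = clda_fit(feats, x)
        assert np.all(np.isfinite(model.F))
        assert "ridge" in caplog.text

    def test_blend_endpoints_and_midpoint(self, rng):
        old = _toy_model(rng)
        new = _toy_model(rng)
        assert models_equal(clda_blend(old, new, 1.0), new)
        assert models_equal(clda_blend(old, new, 0.0), old)
        half = clda_blend(old, new, 0.5)
        assert np.allclose(half.F, (old.F + new.F) / 2)
        assert np.allclose(half.R, (old.R + new.R) / 2)

    def test_refit_while_inactive_rejected(self):
        clda = CLDAState(active=False)
        with pytest.raises(RuntimeError, match="inactive"):
            clda.refit(np.zeros((10, 2)), np.zeros((10, 6)))


@pytest.fixture(scope="module")
def result(short_session):
    bundle, _ = short_session
    return run_closed_loop(bundle, SHORT_PROTOCOL, DecoderConfig())


class TestClosedLoop:
    def test_refit_count_matches_walk_duration(self, result):
        assert result.events.n_clda_updates == int(SHORT_PROTOCOL.walk // 60)
        assert len(result.events.of_id(13)) == result.events.n_clda_updates

    def test_left_leg_always_mirrors_measured(self, result):
        for pair in ("HL", "KL", "AL"):
            assert np.array_equal(result.joints.column("P" + pair),
                                  result.joints.column("G" + pair))

    def test_right_leg_mirrors_only_outside_bci(self, result):
        sl = result.bci_sample_slice
        phr = result.joints.column("PHR")
        ghr = result.joints.column("GHR")
        assert np.array_equal(phr[:sl.start], ghr[:sl.start])
        assert not np.array_equal(phr[sl], ghr[sl])

    def test_model_frozen_through_bci_phase(self, result):
        assert models_equal(result.model_at_bci_start, result.model_at_end)
        assert models_equal(result.model, result.model_at_bci_start)

    def test_event_stream_structure(self, result):
        t10 = result.events.of_id(10)
        t8 = result.events.of_id(8)
        assert list(t10) == [SHORT_PROTOCOL.walk_start,
                             SHORT_PROTOCOL.bci_end]
        assert list(t8) == [SHORT_PROTOCOL.walk_start,
                            SHORT_PROTOCOL.bci_start]
        assert len(result.events.of_id(9)) == 1

    def test_determinism(self, short_session, result):
        bundle, _ = short_session
        again = run_closed_loop(bundle, SHORT_PROTOCOL, DecoderConfig())
        assert np.array_equal(again.decoded_states, result.decoded_states)
        assert models_equal(again.model, result.model)

    def test_kf_variant_close_to_ukf(self, short_session, result):
        bundle, _ = short_session
        kf = run_closed_loop(bundle, SHORT_PROTOCOL,
                             DecoderConfig(filter_type="kf"))
        assert np.allclose(kf.decoded_states, result.decoded_states,
                           atol=1e-3)

    def test_session_shorter_than_protocol_rejected(self, short_session):
        bundle, _ = short_session
        long_protocol = replace(SHORT_PROTOCOL, walk_bci=4000.0)
        with pytest.raises(ValueError, match="shorter than the protocol"):
            run_closed_loop(bundle, long_protocol, DecoderConfig())
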