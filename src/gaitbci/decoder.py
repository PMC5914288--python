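"""State-space decoding of lower-limb joint angles from delta-band EEG.

The decoder estimates the six sagittal joint angles

    x_t = [θ_rh, θ_rk, θ_ra, θ_lh, θ_lk, θ_la]ᵀ   (degrees)

from per-sample EEG features y_t (amplitude fluctuations of slow cortical
potentials in the 0.1–3 Hz delta band).  The generative model is linear-
Gaussian: a movement model x_t = F x_{t−1} + v, v ~ N(0, Q), and a neural
model y_t = H x_t + b + w, w ~ N(0, R).  Inference is the classic Kalman
recursion

    x′ = F x,   P′ = F P Fᵀ + Q
    z = H x′ + b,   S = H P′ Hᵀ + R,   K = P′ Hᵀ S⁻¹
    x = x′ + K (y − z),   P = (I − K H) P′

or its unscented variant, which propagates 2n+1 sigma points through the
movement and observation models and therefore also admits a nonlinear
(quadratic) neural model; with linear models the two coincide.

The model matrices are trained by closed-loop decoder adaptation (CLDA):
during the walk phase, paired (features, measured angles) samples stream
into a buffer and every minute a new F, H, Q, R is fit by least squares and
blended with the previous model by a weighted sum.  At the walk → walk+BCI
transition the model freezes and decoder output drives the avatar's right
leg while the left leg keeps mirroring the goniometers.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .formats import (EventLog, JointFrame, JOINT_LABELS, SessionBundle,
                      SignalFrame)
from .hinf import HinfConfig, hinf_filter
from .protocol import Protocol

__all__ = [
    "FeatureConfig", "DecoderModel", "KalmanState", "UKFConfig",
    "CLDAState", "DecoderConfig", "ClosedLoopResult",
    "extract_features", "kf_predict", "kf_update", "ukf_step",
    "clda_fit", "clda_blend", "run_closed_loop", "models_equal",
]

logger = logging.getLogger(__name__)

N_STATE = 6


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureConfig:
    """Delta-band feature extraction.

    band: causal Butterworth band edges in Hz (default 0.1–3, the slow
        cortical potential range); order: filter order per band edge;
        n_lags/lag_step: lag embedding — L extra copies of each channel
        delayed by multiples of ``lag_step`` samples (feature dimension
        C·(L+1)); standardize: causal per-channel running z-score with an
        exponential window of ``zscore_tau`` seconds; ``zscore_floor`` (µV²)
        keeps early-stream variance estimates from exploding and maps zero
        input to zero features.
    """

    band: tuple[float, float] = (0.1, 3.0)
    order: int = 2
    fs: float = 100.0
    n_lags: int = 0
    lag_step: int = 10
    standardize: bool = True
    zscore_tau: float = 30.0
    zscore_floor: float = 1.0
    channels: tuple[str, ...] | None = None   # None → all EEG channels

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError(f"band edges must satisfy 0 < low < high < "
                             f"Nyquist ({self.fs / 2} Hz), got {self.band}")
        if self.n_lags < 0 or self.lag_step < 1:
            raise ValueError("n_lags must be >= 0 and lag_step >= 1")


def _ema(x: np.ndarray, alpha: float) -> np.ndarray:
    """Causal exponential moving average along axis 0 (zero initial state)."""
    return sps.lfilter([alpha], [1.0, alpha - 1.0], x, axis=0)


def extract_features(signal, config: FeatureConfig | None = None) -> np.ndarray:
    """Per-sample delta-band features from a cleaned EEG stream.

    ``signal`` is a :class:`SignalFrame` (EOG channels are excluded) or a
    raw (n, channels) array.  The pipeline is strictly causal: band-pass →
    optional running z-score → optional lag embedding, one feature vector
    per input sample.
    """
    config = config or FeatureConfig()
    if isinstance(signal, SignalFrame):
        labels = (config.channels if config.channels is not None
                  else signal.eeg_labels)
        data = np.column_stack([signal.column(l) for l in labels])
    else:
        data = np.asarray(signal, dtype=float)
        if data.ndim == 1:
            data = data[:, None]
    sos = sps.butter(config.order, config.band, btype="bandpass",
                     fs=config.fs, output="sos")
    x = sps.sosfilt(sos, data, axis=0)
    if config.standardize:
        alpha = 1.0 / (config.zscore_tau * config.fs)
        mean = _ema(x, alpha)
        msq = _ema(x * x, alpha)
        var = np.maximum(msq - mean * mean, 0.0)
        x = (x - mean) / np.sqrt(var + config.zscore_floor)
    if config.n_lags:
        cols = [x]
        for k in range(1, config.n_lags + 1):
            lagged = np.zeros_like(x)
            d = k * config.lag_step
            if d < x.shape[0]:
                lagged[d:] = x[:-d]
            cols.append(lagged)
        x = np.concatenate(cols, axis=1)
    return x


# ---------------------------------------------------------------------------
# Model and filter state
# ---------------------------------------------------------------------------

def _sym(m: np.ndarray) -> np.ndarray:
    return 0.5 * (m + m.T)


@dataclass(eq=False)
class DecoderModel:
    """State-space decoder parameters.

    F: (6, 6) movement model; H: (m, 6) neural model; bias: (m,) feature
    offset absorbed by the observation equation; Q/R: process and
    observation noise covariances; H_quad: optional (m, 6) quadratic term
    for the nonlinear neural model z = H x + H_quad x² + b.
    """

    F: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    bias: np.ndarray | None = None
    H_quad: np.ndarray | None = None
    feature_config: FeatureConfig | None = None

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        self.Q = _sym(np.asarray(self.Q, dtype=float))
        self.R = _sym(np.asarray(self.R, dtype=float))
        n = self.F.shape[0]
        m = self.H.shape[0]
        if self.F.shape != (n, n) or self.H.shape[1] != n:
            raise ValueError("inconsistent F/H dimensions")
        if self.Q.shape != (n, n) or self.R.shape != (m, m):
            raise ValueError("inconsistent Q/R dimensions")
        if self.bias is None:
            self.bias = np.zeros(m)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.H_quad is not None:
            self.H_quad = np.asarray(self.H_quad, dtype=float)
            if self.H_quad.shape != self.H.shape:
                raise ValueError("H_quad must match H's shape")

    @property
    def n_state(self) -> int:
        return self.F.shape[0]

    @property
    def n_obs(self) -> int:
        return self.H.shape[0]

    def observe(self, x: np.ndarray) -> np.ndarray:
        """Neural model h(x): linear, plus quadratic term when present."""
        z = self.H @ x + self.bias
        if self.H_quad is not None:
            z = z + self.H_quad @ (x * x)
        return z

    def copy(self) -> "DecoderModel":
        return copy.deepcopy(self)


def models_equal(a: DecoderModel, b: DecoderModel) -> bool:
    """Element-wise equality of all model matrices (freeze check)."""
    if (a.H_quad is None) != (b.H_quad is None):
        return False
    same = (np.array_equal(a.F, b.F) and np.array_equal(a.H, b.H)
            and np.array_equal(a.Q, b.Q) and np.array_equal(a.R, b.R)
            and np.array_equal(a.bias, b.bias))
    if a.H_quad is not None:
        same = same and np.array_equal(a.H_quad, b.H_quad)
    return bool(same)


@dataclass(eq=False)
class KalmanState:
    """Filter state x, P and the intermediates of the last step."""

    x: np.ndarray
    P: np.ndarray
    x_pred: np.ndarray | None = None
    P_pred: np.ndarray | None = None
    z: np.ndarray | None = None
    S: np.ndarray | None = None
    K: np.ndarray | None = None
    innovation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.P = _sym(np.asarray(self.P, dtype=float))


@dataclass(frozen=True)
class UKFConfig:
    """Scaled sigma-point parameters and the neural-model order."""

    alpha: float = 1e-3
    beta: float = 2.0
    kappa: float = 0.0
    observation_order: str = "linear"     # 'linear' | 'quadratic'

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.observation_order not in ("linear", "quadratic"):
            raise ValueError("observation_order must be linear|quadratic")

    def weights(self, n: int) -> tuple[np.ndarray, np.ndarray, float]:
        """Mean/covariance weights (each summing to 1) and scaling λ+n."""
        lam = self.alpha ** 2 * (n + self.kappa) - n
        c = n + lam
        wm = np.full(2 * n + 1, 1.0 / (2 * c))
        wc = wm.copy()
        wm[0] = lam / c
        wc[0] = lam / c + (1.0 - self.alpha ** 2 + self.beta)
        return wm, wc, c


# ---------------------------------------------------------------------------
# Kalman recursion
# ---------------------------------------------------------------------------

def kf_predict(state: KalmanState, model: DecoderModel) -> KalmanState:
    """Time update: x′ = F x, P′ = F P Fᵀ + Q."""
    if model.F.shape[0] != state.x.shape[0]:
        raise ValueError("model/state dimension mismatch")
    x_pred = model.F @ state.x
    P_pred = _sym(model.F @ state.P @ model.F.T + model.Q)
    return replace(state, x_pred=x_pred, P_pred=P_pred)


def _solve_innovation(S: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve S X = rhs; on singular S apply logged damping and retry."""
    try:
        return np.linalg.solve(S, rhs)
    except np.linalg.LinAlgError:
        damp = 1e-8 * max(np.trace(S) / S.shape[0], 1.0)
        logger.warning("singular innovation covariance; damped with %.3e on "
                       "the diagonal", damp)
        return np.linalg.solve(S + damp * np.eye(S.shape[0]), rhs)


def kf_update(state: KalmanState, model: DecoderModel,
              y_t: np.ndarray) -> KalmanState:
    """Measurement update from the predicted state.

    Requires a preceding :func:`kf_predict` (uses x′, P′).  The innovation
    y − z is retained for diagnostics.
    """
    if state.x_pred is None or state.P_pred is None:
        raise ValueError("kf_update requires a predicted state; call "
                         "kf_predict first")
    y = np.asarray(y_t, dtype=float)
    z = model.H @ state.x_pred + model.bias
    S = _sym(model.H @ state.P_pred @ model.H.T + model.R)
    # K = P' Hᵀ S⁻¹ computed via the transposed solve
    K = _solve_innovation(S, model.H @ state.P_pred.T).T
    innovation = y - z
    x = state.x_pred + K @ innovation
    P = _sym((np.eye(model.n_state) - K @ model.H) @ state.P_pred)
    return KalmanState(x, P, x_pred=state.x_pred, P_pred=state.P_pred,
                       z=z, S=S, K=K, innovation=innovation)


def _sigma_points(x: np.ndarray, P: np.ndarray, c: float) -> np.ndarray:
    """(2n+1, n) scaled sigma points; jitter and retry once on a failed
    Cholesky factorization."""
    n = x.shape[0]
    A = c * P
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        jitter = 1e-12 * max(np.trace(A) / n, 1.0)
        logger.warning("sigma-point Cholesky failed; retrying with jitter "
                       "%.3e", jitter)
        L = np.linalg.cholesky(A + jitter * np.eye(n))   # may raise again
    pts = np.empty((2 * n + 1, n))
    pts[0] = x
    pts[1:n + 1] = x + L.T
    pts[n + 1:] = x - L.T
    return pts


def ukf_step(state: KalmanState, model: DecoderModel, ukf_config: UKFConfig,
             y_t: np.ndarray) -> KalmanState:
    """One unscented predict+update cycle.

    Sigma points are propagated through the movement model, re-drawn from
    the predicted density, then propagated through the (possibly quadratic)
    neural model.  With linear models the result equals kf_predict followed
    by kf_update.
    """
    y = np.asarray(y_t, dtype=float)
    n = state.x.shape[0]
    wm, wc, c = ukf_config.weights(n)

    chi = _sigma_points(state.x, state.P, c)
    chi_f = chi @ model.F.T
    x_pred = wm @ chi_f
    d = chi_f - x_pred
    P_pred = _sym(d.T @ (wc[:, None] * d) + model.Q)

    chi2 = _sigma_points(x_pred, P_pred, c)
    if ukf_config.observation_order == "quadratic" and model.H_quad is not None:
        Z = chi2 @ model.H.T + (chi2 * chi2) @ model.H_quad.T + model.bias
    else:
        Z = chi2 @ model.H.T + model.bias
    z = wm @ Z
    dz = Z - z
    dx = chi2 - x_pred
    S = _sym(dz.T @ (wc[:, None] * dz) + model.R)
    C = dx.T @ (wc[:, None] * dz)
    K = _solve_innovation(S, C.T).T
    innovation = y - z
    x = x_pred + K @ innovation
    P = _sym(P_pred - K @ S @ K.T)
    return KalmanState(x, P, x_pred=x_pred, P_pred=P_pred, z=z, S=S, K=K,
                       innovation=innovation)


# ---------------------------------------------------------------------------
# Closed-loop decoder adaptation
# ---------------------------------------------------------------------------

def _lstsq_or_ridge(X: np.ndarray, Y: np.ndarray,
                    what: str) -> np.ndarray:
    """Coefficients B minimizing ‖X B − Y‖²; ridge fallback when X is
    rank-deficient (logged penalty 1e-6 · trace(XᵀX)/p)."""
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        G = X.T @ X
        penalty = 1e-6 * max(np.trace(G) / X.shape[1], 1.0)
        logger.warning("rank-deficient regressors while fitting %s "
                       "(rank %d < %d); ridge penalty %.3e applied",
                       what, rank, X.shape[1], penalty)
        coef = np.linalg.solve(G + penalty * np.eye(X.shape[1]), X.T @ Y)
    return coef


def clda_fit(features: np.ndarray, states: np.ndarray,
             feature_config: FeatureConfig | None = None) -> DecoderModel:
    """Fit F, H, Q, R from a buffer of paired (features, joint angles).

    F regresses x_t on x_{t−1}; H (with a bias column) regresses features on
    states; Q and R are the corresponding residual covariances.  Rank
    deficiency falls back to ridge with a logged penalty.
    """
    feats = np.asarray(features, dtype=float)
    x = np.asarray(states, dtype=float)
    if feats.shape[0] != x.shape[0]:
        raise ValueError("features and states must be paired sample-wise")
    if feats.shape[0] < max(x.shape[1] + 2, 3):
        raise ValueError("buffer too short to fit the decoder")

    F = _lstsq_or_ridge(x[:-1], x[1:], "F").T
    res_f = x[1:] - x[:-1] @ F.T
    Q = _sym(res_f.T @ res_f / max(res_f.shape[0] - 1, 1))

    Xb = np.column_stack([x, np.ones(x.shape[0])])
    coef = _lstsq_or_ridge(Xb, feats, "H")            # (n_state+1, m)
    H = coef[:-1].T
    bias = coef[-1]
    res_h = feats - Xb @ coef
    R = _sym(res_h.T @ res_h / max(res_h.shape[0] - 1, 1))
    return DecoderModel(F=F, H=H, Q=Q, R=R, bias=bias,
                        feature_config=feature_config)


def clda_blend(old_model: DecoderModel, new_model: DecoderModel,
               blend_weight: float) -> DecoderModel:
    """Weighted sum of two models: λ·new + (1−λ)·old element-wise."""
    lam = float(blend_weight)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("blend weight must lie in [0, 1]")

    def mix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        if a.shape != b.shape:
            raise ValueError("cannot blend models of different dimensions")
        return lam * b + (1.0 - lam) * a

    quad = None
    if old_model.H_quad is not None and new_model.H_quad is not None:
        quad = mix(old_model.H_quad, new_model.H_quad)
    return DecoderModel(F=mix(old_model.F, new_model.F),
                        H=mix(old_model.H, new_model.H),
                        Q=mix(old_model.Q, new_model.Q),
                        R=mix(old_model.R, new_model.R),
                        bias=mix(old_model.bias, new_model.bias),
                        H_quad=quad,
                        feature_config=new_model.feature_config)


@dataclass
class CLDAState:
    """Adaptation bookkeeping during the walk phase."""

    update_interval: float = 60.0
    blend_weight: float = 0.5
    active: bool = False
    update_count: int = 0
    buffer_start: int = 0           # index of the first buffered sample
    model: DecoderModel | None = None

    def refit(self, features: np.ndarray, states: np.ndarray,
              feature_config: FeatureConfig | None = None) -> DecoderModel:
        if not self.active:
            raise RuntimeError("CLDA refit requested while inactive")
        new = clda_fit(features, states, feature_config)
        self.model = (new if self.model is None
                      else clda_blend(self.model, new, self.blend_weight))
        self.update_count += 1
        return self.model


# ---------------------------------------------------------------------------
# Closed-loop orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecoderConfig:
    """End-to-end closed-loop configuration."""

    feature: FeatureConfig = field(default_factory=FeatureConfig)
    ukf: UKFConfig = field(default_factory=UKFConfig)
    filter_type: str = "ukf"              # 'ukf' | 'kf'
    clda_blend_weight: float = 0.5
    buffer_policy: str = "growing"        # 'growing' | 'sliding'
    sliding_window: float = 300.0         # seconds, for 'sliding'
    refit_noise: bool = True              # refit Q, R each cycle
    clean_eog: bool = True
    hinf: HinfConfig = field(default_factory=HinfConfig)
    event16_rate: float = 1.0             # Hz; 0 disables sample-registered events

    def __post_init__(self) -> None:
        if self.filter_type not in ("ukf", "kf"):
            raise ValueError("filter_type must be ukf|kf")
        if self.buffer_policy not in ("growing", "sliding"):
            raise ValueError("buffer_policy must be growing|sliding")


@dataclass(eq=False)
class ClosedLoopResult:
    """Output of one simulated closed-loop run."""

    joints: JointFrame                  # P columns filled
    events: EventLog
    model: DecoderModel                 # model in force during walk+BCI
    model_at_bci_start: DecoderModel
    model_at_end: DecoderModel
    model_history: list[tuple[float, DecoderModel]]
    decoded_states: np.ndarray          # (n_bci, 6) decoder trajectory
    bci_sample_slice: slice


def run_closed_loop(session: SessionBundle, protocol: Protocol | None = None,
                    config: DecoderConfig | None = None) -> ClosedLoopResult:
    """Replay the full trial protocol over one session.

    During walk: paired features/angles stream to the CLDA buffer and the
    decoder is refit every ``protocol.clda_interval`` seconds (one id-13
    event per refit) while the displayed (P) angles mirror the measured (G)
    ones.  During walk+BCI the model is frozen; the right-leg P columns
    carry the decoder output, the left-leg P columns keep mirroring the
    measured angles.  Treadmill (10), CLDA start/stop (8), sample-registered
    (16, thinned) and quit (9) events are emitted per the conductor legend.
    """
    protocol = protocol or Protocol()
    config = config or DecoderConfig()
    t0 = float(session.signal.timestamps[0])
    t = session.signal.timestamps - t0
    if protocol.bci_end > t[-1] + 1.5 / protocol.fs:
        raise ValueError("session shorter than the protocol timeline")

    sig = (hinf_filter(session.signal, config.hinf) if config.clean_eog
           else session.signal)
    feats = extract_features(sig, config.feature)
    measured = session.joints.measured()

    events: list[tuple[float, int]] = [(protocol.walk_start, 10),
                                       (protocol.walk_start, 8)]

    clda = CLDAState(update_interval=protocol.clda_interval,
                     blend_weight=config.clda_blend_weight, active=True)
    history: list[tuple[float, DecoderModel]] = []
    walk_i0 = int(np.searchsorted(t, protocol.walk_start))
    for k in range(1, protocol.n_clda_updates + 1):
        rt = protocol.walk_start + k * protocol.clda_interval
        hi = int(np.searchsorted(t, rt))
        lo = walk_i0
        if config.buffer_policy == "sliding":
            lo = max(walk_i0,
                     int(np.searchsorted(t, rt - config.sliding_window)))
        prev = clda.model
        model = clda.refit(feats[lo:hi], measured[lo:hi], config.feature)
        if not config.refit_noise and prev is not None:
            model = replace_noise(model, prev)
            clda.model = model
        history.append((rt, model.copy()))
        events.append((rt, 13))
    if clda.model is None:
        raise ValueError("walk phase shorter than one CLDA interval: "
                         "no decoder was trained")
    clda.active = False
    events.append((protocol.bci_start, 8))
    model = clda.model.copy()
    model_at_bci_start = model.copy()

    bci_i0 = int(np.searchsorted(t, protocol.bci_start))
    bci_i1 = int(np.searchsorted(t, protocol.bci_end))
    state = KalmanState(x=measured[bci_i0].copy(),
                        P=model.Q + 1e-6 * np.eye(model.n_state))
    decoded = np.empty((bci_i1 - bci_i0, N_STATE))
    use_ukf = config.filter_type == "ukf"
    for j, i in enumerate(range(bci_i0, bci_i1)):
        if use_ukf:
            state = ukf_step(state, model, config.ukf, feats[i])
        else:
            state = kf_update(kf_predict(state, model), model, feats[i])
        decoded[j] = state.x

    # assemble output joints: P mirrors G everywhere except the decoded
    # right leg during walk+BCI
    angles = np.empty((t.size, 12))
    for ci, label in enumerate(JOINT_LABELS):
        if label.startswith("G"):
            angles[:, ci] = session.joints.column(label)
        else:
            angles[:, ci] = session.joints.column("G" + label[1:])
    for leg_col, state_col in (("PHR", 0), ("PKR", 1), ("PAR", 2)):
        angles[bci_i0:bci_i1, JOINT_LABELS.index(leg_col)] = decoded[:, state_col]
    joints_out = JointFrame(session.joints.timestamps.copy(), JOINT_LABELS,
                            angles, session.joints.joint_factors.copy())

    events.append((protocol.bci_end, 10))
    if config.event16_rate > 0:
        step = 1.0 / config.event16_rate
        events.extend((tau, 16) for tau in
                      np.arange(0.0, float(t[-1]) + 1e-9, step))
    events.append((float(t[-1]), 9))
    events.sort(key=lambda p: (p[0], p[1]))
    log = EventLog(np.array([p[0] for p in events]),
                   np.array([p[1] for p in events], dtype=int),
                   n_clda_updates=clda.update_count)

    return ClosedLoopResult(joints=joints_out, events=log, model=model,
                            model_at_bci_start=model_at_bci_start,
                            model_at_end=model.copy(),
                            model_history=history, decoded_states=decoded,
                            bci_sample_slice=slice(bci_i0, bci_i1))


def replace_noise(model: DecoderModel, source: DecoderModel) -> DecoderModel:
    """Copy of ``model`` carrying Q and R from ``source`` (held-noise CLDA)."""
    return DecoderModel(F=model.F, H=model.H, Q=source.Q, R=source.R,
                        bias=model.bias, H_quad=model.H_quad,
                        feature_config=model.feature_config)
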