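"""Real-time H∞ adaptive cancellation of ocular artifacts.

Every EEG channel is cleaned independently, one sample at a time, using the
two-element EOG reference

    r_t = [TP9_t − TP10_t, FT9_t − FT10_t]ᵀ

(vertical and horizontal eye movement).  A per-channel weight vector w_t
estimates the artifact contribution, leaving the cleaned sample

    y_t = s_t − r_tᵀ w_t.

The weights adapt by the H∞ (worst-case-optimal) recursion with robustness
bound γ and drift parameter q:

    P_t      = [P̃_t⁻¹ − γ⁻² r_t r_tᵀ]⁻¹
    w_{t+1}  = w_t + P_t r_t / (1 + r_tᵀ P_t r_t) · y_t
    P̃_{t+1} = [P̃_t⁻¹ + (1 − γ⁻²) r_t r_tᵀ]⁻¹ + q I

As γ → ∞ the recursion reduces to q-regularized recursive least squares.
Because P̃ and P depend only on the shared reference r_t, a single 2×2
covariance recursion serves all channels; only the weights are per-channel,
which keeps the per-sample cost O(channels).

The γ⁻² correction defines an indefinite metric: at isolated samples
(initialization, the first large blink) P̃⁻¹ − γ⁻² r rᵀ can lose positive
definiteness.  Such steps fall back to the uncorrected gain P = P̃ and are
counted; a full state reset is reserved for non-finite corruption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .formats import EOG_CHANNELS, SignalFrame

__all__ = ["HinfConfig", "HinfState", "HinfFilter", "make_reference",
           "hinf_step", "hinf_filter"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HinfConfig:
    """Hyperparameters of the H∞ artifact filter.

    gamma: robustness bound γ > 1 (γ⁻² < 1 keeps the covariance update a
        valid correction); q: random-walk drift of the weights; p0: initial
        weight uncertainty; literal_equations: use the printed no-inverse
        reading of the covariance recursions instead of the standard
        adaptive-noise-cancellation form (for comparison only).
    """

    gamma: float = 5.0
    q: float = 1e-10
    p0: float = 1.0
    literal_equations: bool = False

    def __post_init__(self) -> None:
        if self.gamma <= 1:
            raise ValueError("gamma must exceed 1")
        if self.q < 0 or self.p0 <= 0:
            raise ValueError("q must be >= 0 and p0 > 0")


def make_reference(eog_sample) -> np.ndarray:
    """EOG reference r_t = [TP9 − TP10, FT9 − FT10].

    ``eog_sample`` is a mapping with keys TP9, TP10, FT9, FT10 or a
    length-4 sequence in that order.
    """
    if hasattr(eog_sample, "keys"):
        missing = [ch for ch in EOG_CHANNELS if ch not in eog_sample]
        if missing:
            raise KeyError(f"missing EOG channel(s): {missing}")
        tp9, tp10, ft9, ft10 = (float(eog_sample[ch]) for ch in EOG_CHANNELS)
    else:
        vals = np.asarray(eog_sample, dtype=float)
        if vals.shape != (4,):
            raise ValueError("eog_sample must have exactly 4 values "
                             "(TP9, TP10, FT9, FT10)")
        tp9, tp10, ft9, ft10 = vals
    return np.array([tp9 - tp10, ft9 - ft10])


def _inv2(m: np.ndarray) -> np.ndarray:
    """Closed-form 2×2 inverse."""
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if det == 0 or not np.isfinite(det):
        raise np.linalg.LinAlgError("singular 2x2 matrix")
    return np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det


def _is_pd2(m: np.ndarray) -> bool:
    """Positive definiteness of a symmetric 2×2 via determinant and trace."""
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    return bool(np.isfinite(det) and det > 0 and m[0, 0] + m[1, 1] > 0)


@dataclass
class HinfState:
    """Adaptive-filter state shared across channels.

    ``w`` holds one 2-element weight column per channel; ``P_tilde`` is the
    shared 2×2 auxiliary covariance (symmetric by construction).
    """

    w: np.ndarray                 # (2, n_channels)
    P_tilde: np.ndarray           # (2, 2)
    config: HinfConfig = field(default_factory=HinfConfig)
    n_fallbacks: int = 0          # steps where the γ correction was infeasible
    n_resets: int = 0             # full reinitializations (corrupted state)
    t: int = 0

    @classmethod
    def initial(cls, n_channels: int = 1,
                config: HinfConfig | None = None) -> "HinfState":
        config = config or HinfConfig()
        return cls(w=np.zeros((2, n_channels)),
                   P_tilde=np.eye(2) * config.p0, config=config)


class HinfFilter:
    """Streaming multi-channel H∞ filter (one step per call, O(1) memory)."""

    def __init__(self, n_channels: int, config: HinfConfig | None = None):
        self.state = HinfState.initial(n_channels, config)

    def step(self, s_t: np.ndarray, r_t: np.ndarray) -> np.ndarray:
        """Clean one multi-channel sample; returns y_t = s_t − r_tᵀ w_t."""
        st = self.state
        cfg = st.config
        r = np.asarray(r_t, dtype=float).reshape(2)
        s = np.asarray(s_t, dtype=float)
        if not np.all(np.isfinite(st.P_tilde)) or not np.all(np.isfinite(st.w)):
            logger.warning("hinf state non-finite at sample %d; "
                           "reinitializing", st.t)
            fresh = HinfState.initial(st.w.shape[1], cfg)
            st.w, st.P_tilde = fresh.w, fresh.P_tilde
            st.n_resets += 1

        y = s - r @ st.w

        g2 = cfg.gamma ** -2
        rrT = np.outer(r, r)
        if cfg.literal_equations:
            P = st.P_tilde - g2 * rrT
            if not _is_pd2(P):
                P = st.P_tilde.copy()
                st.n_fallbacks += 1
            P_tilde_next = st.P_tilde + (1.0 - g2) * rrT + cfg.q * np.eye(2)
        else:
            P_tilde_inv = _inv2(st.P_tilde)
            corrected = P_tilde_inv - g2 * rrT
            if _is_pd2(corrected):
                P = _inv2(corrected)
            else:
                # transient infeasibility of the indefinite H∞ metric:
                # use the uncorrected (RLS) gain for this sample
                P = st.P_tilde.copy()
                st.n_fallbacks += 1
            P_tilde_next = _inv2(P_tilde_inv + (1.0 - g2) * rrT) \
                + cfg.q * np.eye(2)

        Pr = P @ r
        gain = Pr / (1.0 + r @ Pr)
        st.w = st.w + np.outer(gain, y)
        st.P_tilde = 0.5 * (P_tilde_next + P_tilde_next.T)
        st.t += 1
        return y


def hinf_step(state: HinfState, s_t, r_t) -> tuple[np.ndarray, HinfState]:
    """Functional single-step interface: returns (y_t, updated state)."""
    filt = HinfFilter.__new__(HinfFilter)
    filt.state = state
    s = np.atleast_1d(np.asarray(s_t, dtype=float))
    y = filt.step(s, r_t)
    if np.isscalar(s_t):
        return float(y[0]), filt.state
    return y, filt.state


def hinf_filter(frame: SignalFrame,
                config: HinfConfig | None = None) -> SignalFrame:
    """Clean all EEG channels of a signal frame; EOG channels pass through.

    Processing is strictly causal and sample-by-sample: truncating the
    input to its first k samples yields the same first k outputs.
    """
    config = config or HinfConfig()
    missing = [ch for ch in EOG_CHANNELS if ch not in frame.channels]
    if missing:
        raise KeyError(f"signal frame lacks EOG channel(s): {missing}")
    eog_idx = [frame.channels.index(ch) for ch in EOG_CHANNELS]
    eeg_idx = [i for i, ch in enumerate(frame.channels)
               if ch not in EOG_CHANNELS]
    tp9, tp10, ft9, ft10 = (frame.data[:, i] for i in eog_idx)
    refs = np.column_stack([tp9 - tp10, ft9 - ft10])

    filt = HinfFilter(len(eeg_idx), config)
    out = frame.data.copy()
    eeg = frame.data[:, eeg_idx]
    cleaned = np.empty_like(eeg)
    for t in range(frame.n_samples):
        cleaned[t] = filt.step(eeg[t], refs[t])
    out[:, eeg_idx] = cleaned
    if filt.state.n_fallbacks:
        logger.info("hinf: gamma-correction infeasible at %d of %d samples "
                    "(uncorrected gain used)", filt.state.n_fallbacks,
                    frame.n_samples)
    return SignalFrame(frame.timestamps.copy(), frame.channels, out)
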