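"""Synthetic treadmill-BCI sessions with known ground truth.

The generator emulates the statistical structure the pipeline assumes, so
every stage is testable without the published recordings:

* periodic sagittal-plane joint kinematics (Fourier templates per joint
  class, left/right legs in anti-phase) riding the four-phase protocol
  timeline, plus goniometer noise and slow drift;
* EEG whose delta-band component is a known linear forward model H* of the
  band-limited joint trajectories, embedded in 1/f background noise;
* EOG channels carrying Poisson blink bursts (vertical pair) and saccade
  steps (horizontal pair), with configurable leakage into the EEG;
* the conductor event stream, log-normal impedance tables and an idealized
  spherical electrode digitization — i.e. all seven files of a trial
  folder.

The ground truth (effective H*, clean trajectories, blink times, phase
boundaries) is returned alongside every session to support parameter-
recovery tests; it is not part of the trial-folder layout.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .formats import (DEFAULT_CHANNELS, EOG_CHANNELS, JOINT_LABELS,
                      ElectrodePosition, EventLog, ImpedanceRecord,
                      JointFrame, Montage, SessionBundle, SignalFrame,
                      write_session)
from .protocol import Protocol

__all__ = ["SynthConfig", "GroundTruth", "gen_kinematics", "gen_eog",
           "gen_eeg", "gen_session", "write_ground_truth", "template_montage"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of a generated session.

    Defaults reproduce the recorded protocol: 100 Hz sampling, 1 mph
    (0.45 m/s) treadmill with a slow ~0.75 Hz stride, 2/15/5/2-minute
    stand/walk/walk+BCI/stand phases.  ``snr_db`` is the in-band (0.1–3 Hz)
    power ratio of the gait-coupled EEG component to the 1/f background.
    """

    seed: int = 0
    subject: int = 1
    trial: int = 1
    protocol: Protocol = field(default_factory=Protocol)
    stride_freq: float = 0.75           # Hz, ~0.45 m/s slow walking
    treadmill_speed: float = 0.45       # m/s (1 mph)
    snr_db: float = 0.0
    noise_rms: float = 20.0             # µV, EEG background
    hstar_scale: float = 1.0
    blink_rate: float = 12.0            # per minute
    blink_amp: float = 120.0            # µV on the upper vertical electrode
    blink_width: float = 0.30           # s
    saccade_rate: float = 8.0           # per minute
    saccade_amp: float = 30.0           # µV
    eog_noise: float = 2.0              # µV sensor noise on EOG electrodes
    leakage: float = 0.3                # EOG→EEG mixing scale
    gonio_noise: float = 0.5            # degrees rms
    gonio_drift: float = 0.1            # degrees per minute
    cap_size: float = 56.0              # cm head circumference
    head_shape: str = "round"
    event16_rate: float = 1.0           # Hz (thinned); 0 disables
    timestamp_jitter: float = 0.0       # s rms on the ideal 10 ms grid

    @classmethod
    def preset(cls, name: str, seed: int = 0, **overrides) -> "SynthConfig":
        """Named condition: 'default', 'high-snr', 'null' or 'noisy'."""
        presets = {
            "default": {},
            # strong, clean gait↔EEG coupling for recovery tests
            "high-snr": {"snr_db": 20.0, "leakage": 0.15},
            # no coupling at all: decoder r-values should center on 0
            "null": {"hstar_scale": 0.0},
            "noisy": {"snr_db": -10.0, "leakage": 0.6, "gonio_noise": 1.0},
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}; choose from "
                             f"{sorted(presets)}")
        return cls(seed=seed, **{**presets[name], **overrides})


@dataclass(eq=False)
class GroundTruth:
    """What the generator actually used, for recovery tests."""

    config: SynthConfig
    clean_joints: np.ndarray            # (n, 6) noise-free angles, degrees
    phase_boundaries: tuple[float, float, float, float]
    stride_freq: float
    n_strides_walk: float               # strides in the 15-min walk phase
    H_star: np.ndarray | None = None    # effective (60, 6) forward model
    blink_times: np.ndarray | None = None
    saccade_times: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Electrode digitization template
# ---------------------------------------------------------------------------

_ROW_INCLINATION = {     # sagittal angle from the vertex, + front / − back
    "Fp": 72.0, "AF": 54.0, "F": 36.0, "FC": 18.0, "FT": 18.0,
    "C": 0.0, "T": 0.0, "CP": -18.0, "TP": -18.0,
    "P": -36.0, "PO": -54.0, "O": -72.0,
}
_COL_ANGLE = {0: 0.0, 1: 18.0, 2: 18.0, 3: 36.0, 4: 36.0, 5: 54.0, 6: 54.0,
              7: 72.0, 8: 72.0, 9: 90.0, 10: 90.0}


def _ideal_direction(label: str) -> np.ndarray:
    """Unit direction of a 10-10 electrode on an idealized spherical head.

    x points to the right ear, y to the nasion, z to the vertex.  Odd
    column numbers are left-hemisphere, even right, z the midline.
    """
    m = re.match(r"^([A-Za-z]+?)(z|\d+)$", label)
    if m is None:
        raise ValueError(f"cannot parse electrode label {label!r}")
    row, col = m.group(1), m.group(2)
    alpha = math.radians(_ROW_INCLINATION[row])
    if col == "z":
        lam = 0.0
    else:
        num = int(col)
        lam = math.radians(_COL_ANGLE[num])
        if num % 2 == 1:
            lam = -lam              # odd = left hemisphere (negative x)
    x = math.sin(lam)
    y = math.cos(lam) * math.sin(alpha)
    z = math.cos(lam) * math.cos(alpha)
    return np.array([x, y, z])


def template_montage(cap_size: float = 56.0, head_shape: str = "round",
                     jitter_mm: float = 0.0,
                     rng: np.random.Generator | None = None) -> Montage:
    """Idealized spherical digitization of the 64-channel layout.

    The head radius follows the cap circumference; optional Gaussian jitter
    (mm) emulates digitizer noise.  Polar coordinates are recomputed from
    the jittered Cartesian ones, so both representations agree exactly.
    """
    radius = cap_size * 10.0 / (2.0 * math.pi)     # mm
    rng = rng or np.random.default_rng(0)
    electrodes: dict[str, ElectrodePosition] = {}
    for label in DEFAULT_CHANNELS:
        xyz = _ideal_direction(label) * radius
        if jitter_mm > 0:
            xyz = xyz + rng.normal(0.0, jitter_mm, size=3)
        electrodes[label] = ElectrodePosition.from_cartesian(*xyz)
    return Montage(cap_size, head_shape, electrodes)


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

#: Fourier templates per joint class: mean plus (harmonic, amplitude,
#: phase) terms of the stride cycle, degrees.  Ranges stay within the
#: physiological envelopes (hip/knee within [0, 90], ankle within [−20, 43]).
_JOINT_TEMPLATES = {
    "hip": (18.0, ((1, 14.0, 0.0), (2, 3.0, 1.2))),
    "knee": (25.0, ((1, 10.0, -1.5), (2, 14.0, 0.6))),
    "ankle": (8.0, ((1, 10.0, 2.0), (2, 4.0, -0.8))),
}
#: Standing posture (degrees) per joint class.
_STAND_POSTURE = {"hip": 2.0, "knee": 4.0, "ankle": 0.0}
#: Canonical state order: right hip, knee, ankle, then left.
_STATE_JOINTS = (("hip", 0.0), ("knee", 0.0), ("ankle", 0.0),
                 ("hip", math.pi), ("knee", math.pi), ("ankle", math.pi))

_TRANSITION = 1.5    # s, smooth stand↔walk crossfade


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _walk_envelope(t: np.ndarray, protocol: Protocol) -> np.ndarray:
    """0→1 weight of the walking pattern vs the standing posture."""
    up = _smoothstep((t - protocol.walk_start) / _TRANSITION)
    down = _smoothstep((protocol.bci_end - t) / _TRANSITION)
    return np.minimum(up, down)


def gen_kinematics(config: SynthConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[JointFrame, GroundTruth]:
    """Six periodic joint trajectories on the protocol timeline.

    Left and right legs are half a stride out of phase; stand phases hold a
    near-constant posture.  Measured (G) columns carry additive goniometer
    noise and slow drift; predicted (P) columns mirror the measured ones
    (decoded output is produced by the decoder, not the generator).
    """
    protocol = config.protocol
    rng = rng or np.random.default_rng([config.seed, config.subject,
                                        config.trial, 1])
    n = protocol.n_samples
    t = np.arange(n) / protocol.fs
    phase = 2.0 * math.pi * config.stride_freq * (t - protocol.walk_start)
    env = _walk_envelope(t, protocol)

    clean = np.empty((n, 6))
    for j, (cls, leg_shift) in enumerate(_STATE_JOINTS):
        mean, harmonics = _JOINT_TEMPLATES[cls]
        pattern = np.full(n, mean)
        for k, amp, ph in harmonics:
            pattern = pattern + amp * np.sin(k * (phase + leg_shift) + ph)
        clean[:, j] = _STAND_POSTURE[cls] + env * (pattern - _STAND_POSTURE[cls])

    drift = (config.gonio_drift / 60.0) * t[:, None] \
        * rng.standard_normal(6)[None, :]
    noisy = clean + config.gonio_noise * rng.standard_normal((n, 6)) + drift
    angles = np.concatenate([noisy, noisy], axis=1)   # G then P (mirrored)

    factors = np.empty(6)
    for j, (cls, _) in enumerate(_STATE_JOINTS):
        lo, hi = (36.0, 43.0) if cls == "ankle" else (80.0, 92.0)
        factors[j] = rng.uniform(lo, hi)

    frame = JointFrame(t, JOINT_LABELS, angles, factors)
    truth = GroundTruth(
        config=config, clean_joints=clean,
        phase_boundaries=(protocol.walk_start, protocol.bci_start,
                          protocol.bci_end, protocol.total),
        stride_freq=config.stride_freq,
        n_strides_walk=config.stride_freq * protocol.walk)
    return frame, truth


# ---------------------------------------------------------------------------
# EOG and EEG
# ---------------------------------------------------------------------------

def gen_eog(n: int, fs: float, config: SynthConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray,
                                               np.ndarray, np.ndarray]:
    """Four EOG traces (TP9, TP10, FT9, FT10) with blinks and saccades.

    Returns (eog (n, 4), vertical reference, horizontal reference,
    blink onset times).  Blinks are Poisson bumps on the vertical pair;
    saccades are Poisson step changes split between the horizontal pair.
    """
    t = np.arange(n) / fs
    v = np.zeros(n)
    n_blinks = rng.poisson(config.blink_rate / 60.0 * n / fs)
    blink_times = np.sort(rng.uniform(0.0, n / fs, size=n_blinks))
    width = config.blink_width
    for bt in blink_times:
        i0 = max(0, int(bt * fs))
        i1 = min(n, int((bt + width) * fs))
        if i1 <= i0:
            continue
        u = (t[i0:i1] - bt) / width
        v[i0:i1] += config.blink_amp * np.sin(np.pi * u) ** 2
    h = np.zeros(n)
    n_sac = rng.poisson(config.saccade_rate / 60.0 * n / fs)
    sac_times = np.sort(rng.uniform(0.0, n / fs, size=n_sac))
    level = 0.0
    prev = 0
    for st_ in sac_times:
        i = min(n, int(st_ * fs))
        h[prev:i] = level
        level = rng.uniform(-config.saccade_amp, config.saccade_amp)
        prev = i
    h[prev:] = level

    noise = config.eog_noise * rng.standard_normal((n, 4))
    eog = np.column_stack([
        0.75 * v, -0.25 * v,          # TP9 above / TP10 below the left eye
        0.5 * h, -0.5 * h,            # FT9 / FT10 at the temples
    ]) + noise
    v_ref = eog[:, 0] - eog[:, 1]
    h_ref = eog[:, 2] - eog[:, 3]
    return eog, v_ref, h_ref, blink_times


def _pink_noise(shape: tuple[int, int], rng: np.random.Generator,
                fs: float) -> np.ndarray:
    """1/f-amplitude noise per column, unit variance."""
    n, c = shape
    white = rng.standard_normal((n, c))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale[:, None], n=n, axis=0)
    sd = pink.std(axis=0)
    sd[sd == 0] = 1.0
    return pink / sd


def gen_eeg(joints: JointFrame, truth: GroundTruth,
            rng: np.random.Generator | None = None) -> SignalFrame:
    """64-channel stream: gait-coupled EEG, 1/f background, EOG channels.

    EEG = H*·(delta-band-limited clean joint angles) + pink noise +
    leakage·EOG, with H* scaled so the coupled component sits ``snr_db``
    above the in-band background power.  The effective H* (after scaling)
    and the blink times are recorded in the ground truth.
    """
    config = truth.config
    protocol = config.protocol
    rng = rng or np.random.default_rng([config.seed, config.subject,
                                        config.trial, 2])
    n = joints.n_samples
    fs = protocol.fs
    n_eeg = 64 - len(EOG_CHANNELS)

    sos = sps.butter(2, (0.1, 3.0), btype="bandpass", fs=fs, output="sos")
    centered = truth.clean_joints - truth.clean_joints.mean(axis=0)
    band_states = sps.sosfilt(sos, centered, axis=0)

    H_star = config.hstar_scale * rng.standard_normal((n_eeg, 6))
    coupled = band_states @ H_star.T

    noise = config.noise_rms * _pink_noise((n, n_eeg), rng, fs)
    inband_noise_rms = float(np.sqrt(np.mean(
        sps.sosfilt(sos, noise, axis=0) ** 2)))
    coupled_rms = float(np.sqrt(np.mean(coupled ** 2)))
    if coupled_rms > 0:
        gain = inband_noise_rms / coupled_rms * 10.0 ** (config.snr_db / 20.0)
    else:
        gain = 0.0
    coupled = coupled * gain
    truth.H_star = H_star * gain

    eog, v_ref, h_ref, blink_times = gen_eog(n, fs, config, rng)
    truth.blink_times = blink_times
    leak_v = config.leakage * rng.uniform(0.2, 1.0, n_eeg) \
        * rng.choice([-1.0, 1.0], n_eeg)
    leak_h = 0.5 * config.leakage * rng.uniform(0.2, 1.0, n_eeg) \
        * rng.choice([-1.0, 1.0], n_eeg)
    eeg = coupled + noise + np.outer(v_ref, leak_v) + np.outer(h_ref, leak_h)

    data = np.empty((n, 64))
    eeg_iter = iter(range(n_eeg))
    eog_order = {ch: k for k, ch in enumerate(EOG_CHANNELS)}
    for ci, ch in enumerate(DEFAULT_CHANNELS):
        if ch in eog_order:
            data[:, ci] = eog[:, eog_order[ch]]
        else:
            data[:, ci] = eeg[:, next(eeg_iter)]

    t = joints.timestamps.copy()
    if config.timestamp_jitter > 0:
        jit = rng.normal(0.0, config.timestamp_jitter, n)
        t = np.sort(t + np.clip(jit, -4e-3, 4e-3))
    return SignalFrame(t, DEFAULT_CHANNELS, data)


# ---------------------------------------------------------------------------
# Full session
# ---------------------------------------------------------------------------

def _gen_events(config: SynthConfig) -> EventLog:
    p = config.protocol
    events: list[tuple[float, int]] = [
        (p.walk_start, 10), (p.walk_start, 8),           # treadmill + CLDA on
        (p.bci_start, 8),                                # CLDA off
        (p.bci_end, 10),                                 # treadmill off
        (p.total - 1.0 / p.fs, 9),                       # quit
    ]
    n_updates = p.n_clda_updates
    events.extend((p.walk_start + k * p.clda_interval, 13)
                  for k in range(1, n_updates + 1))
    if config.event16_rate > 0:
        step = 1.0 / config.event16_rate
        events.extend((tau, 16) for tau in
                      np.arange(0.0, p.total - 1e-9, step))
    events.sort(key=lambda e: (e[0], e[1]))
    return EventLog(np.array([e[0] for e in events]),
                    np.array([e[1] for e in events], dtype=int),
                    n_clda_updates=n_updates)


def _gen_impedances(config: SynthConfig,
                    rng: np.random.Generator) -> dict[str, ImpedanceRecord]:
    # log-normal contact impedances; gel settles overnight so the post-
    # session distribution shifts down with a heavier high tail
    before = rng.lognormal(math.log(20.0), 0.5, 64)
    after = rng.lognormal(math.log(9.0), 0.9, 64)
    return {"before": ImpedanceRecord(DEFAULT_CHANNELS, before, "before"),
            "after": ImpedanceRecord(DEFAULT_CHANNELS, after, "after")}


def gen_session(config: SynthConfig,
                out_dir: str | Path | None = None,
                force: bool = False) -> tuple[SessionBundle, GroundTruth]:
    """Generate one complete trial.

    Montage and impedances are drawn from a per-subject/day stream (trials
    1 and 2 share a day, hence identical files, like the recorded layout);
    signals and kinematics from a per-trial stream.  Equal seeds give
    byte-identical output folders.  When ``out_dir`` is given the session
    is also written as ``out_dir/SLxx-Tyy``.
    """
    day = 1 if config.trial <= 2 else 2
    rng_subject = np.random.default_rng([config.seed, config.subject, day])
    rng_trial = np.random.default_rng([config.seed, config.subject,
                                       config.trial])

    joints, truth = gen_kinematics(config, rng_trial)
    signal = gen_eeg(joints, truth, rng_trial)
    events = _gen_events(config)
    montage = template_montage(config.cap_size, config.head_shape,
                               jitter_mm=1.0, rng=rng_subject)
    impedances = _gen_impedances(config, rng_subject)
    bundle = SessionBundle(signal, joints, events, montage, impedances,
                           subject_id=config.subject, trial_id=config.trial)
    bundle.validate()
    if out_dir is not None:
        folder = write_session(bundle, out_dir, force=force)
        write_ground_truth(truth, folder / "groundtruth.json")
    return bundle, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Sidecar ground-truth file (documented schema, not part of the
    trial-folder layout).  Large per-sample arrays are summarized."""
    payload = {
        "schema_version": 1,
        "seed": truth.config.seed,
        "subject": truth.config.subject,
        "trial": truth.config.trial,
        "stride_freq_hz": truth.stride_freq,
        "n_strides_walk": truth.n_strides_walk,
        "phase_boundaries_s": list(truth.phase_boundaries),
        "snr_db": truth.config.snr_db,
        "H_star": (truth.H_star.tolist() if truth.H_star is not None
                   else None),
        "blink_times_s": (truth.blink_times.tolist()
                          if truth.blink_times is not None else None),
        "clean_joint_ranges_deg": {
            label: [float(truth.clean_joints[:, j].min()),
                    float(truth.clean_joints[:, j].max())]
            for j, label in enumerate(("rh", "rk", "ra", "lh", "lk", "la"))},
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")
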