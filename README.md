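# gaitbci

Tools for mobile brain-body imaging (MoBI) sessions recorded during
treadmill walking with a closed-loop brain-computer interface: the
per-trial dataset layout, goniometer calibration, real-time ocular-artifact
removal, joint-angle decoding from slow cortical potentials, closed-loop
decoder adaptation, and per-gait-cycle performance evaluation — plus a
synthetic-session generator with known ground truth, so the entire pipeline
is testable without any recordings.

It is written for researchers working with synchronized EEG + lower-limb
kinematics: people building offline decoders of gait from EEG, studying
gait-cycle-coupled cortical activity, or benchmarking closed-loop decoder
adaptation schemes.

## The data model

A trial folder `SLxx-Tyy` holds seven plain-text files: `eeg.txt`
(timestamp + 64 channels at 100 Hz: 60 EEG, 4 electrodes repurposed as EOG
at TP9/TP10/FT9/FT10), `joints.txt` (timestamp + 12 angle columns — six
goniometer-measured `G??` and six predicted/displayed `P??` for hip, knee,
ankle of both legs — with the per-joint calibration factors in the header),
`conductor.txt` (timestamped protocol events), `digitizer.bvct` (XML
electrode digitization) and two impedance tables. The trial timeline is 2
min standing, 15 min treadmill walking, 5 min walking with the BCI driving
the avatar's right leg, and 2 min standing (24 min per trial, 72 min of
signal per subject over three trials).

## The methods

**Goniometer calibration.** Sensors are zeroed standing upright and read
again in a reference posture (90° seated hip/knee flexion; 43° ankle
dorsiflexion on an inclined platform). A raw reading y maps linearly to
`y_map = (y − zero) / x · x0`, where x is the measured excursion (the
"joint factor") and x0 ∈ {90°, 43°}.

**H∞ artifact removal.** Each EEG channel is cleaned sample by sample
against the EOG reference `r_t = [TP9−TP10, FT9−FT10]ᵀ`:
`y_t = s_t − r_tᵀ w_t`, with weights adapted by the H∞ recursion
(robustness bound γ = 5, drift q = 1e-10)

    P_t      = [P̃_t⁻¹ − γ⁻² r_t r_tᵀ]⁻¹
    w_{t+1}  = w_t + P_t r_t / (1 + r_tᵀ P_t r_t) · y_t
    P̃_{t+1} = [P̃_t⁻¹ + (1 − γ⁻²) r_t r_tᵀ]⁻¹ + q I

which reduces to regularized recursive least squares as γ → ∞.

**Decoding.** The state is the six joint angles
`x_t = [θ_rh, θ_rk, θ_ra, θ_lh, θ_lk, θ_la]ᵀ`; observations are delta-band
(0.1–3 Hz) EEG features. A Kalman filter — or its unscented variant, which
propagates sigma points and admits a quadratic neural model — runs the
standard predict/update recursion with movement model F, neural model H and
noise covariances Q, R. During the walk phase those matrices are retrained
every minute from buffered data by least squares and blended with the
previous model (closed-loop decoder adaptation, CLDA); at the walk → walk+BCI
transition the model freezes and its output drives the avatar's right leg.

**Evaluation.** Gait cycles are segmented at right-hip flexion peaks;
decoding quality is the per-cycle Pearson r between measured and predicted
angles, compared between the last 5 min of walk and the walk+BCI phase
(Wilcoxon rank-sum), alongside electrode-impedance QC against 60 kΩ.

## Worked example

```python
from dataclasses import replace
from gaitbci.protocol import Protocol
from gaitbci.synth import SynthConfig, gen_session
from gaitbci.decoder import DecoderConfig, run_closed_loop
from gaitbci.evaluation import evaluate_session

# a shortened trial: 10 s stand, 3 min walk, 1 min walk+BCI, 10 s stand
protocol = Protocol(stand_pre=10, walk=180, walk_bci=60, stand_post=10)
config = replace(SynthConfig.preset("high-snr", seed=7), protocol=protocol)
bundle, truth = gen_session(config)

result = run_closed_loop(bundle, protocol, DecoderConfig())
report = evaluate_session(result.joints, protocol)
print(f"decoder refits during walk: {result.events.n_clda_updates}")
print(f"gait cycles (walk / walk+BCI): {report.walk_cycles} / {report.bci_cycles}")
print(f"median per-cycle right-hip r, walk:     {report.median_walk:.3f}")
print(f"median per-cycle right-hip r, walk+BCI: {report.median_bci:.3f}")
```

prints

```
decoder refits during walk: 3
gait cycles (walk / walk+BCI): 135 / 44
median per-cycle right-hip r, walk:     1.000
median per-cycle right-hip r, walk+BCI: 0.995
```

Three refits = ⌊180 s / 60 s⌋ per-minute CLDA updates. During walk the
displayed angles mirror the goniometers, so r is 1 by construction; during
walk+BCI the 0.995 median says the frozen decoder tracks the right hip
almost perfectly on this high-SNR synthetic session. On real recordings —
where the gait–EEG coupling is far weaker than this generator's high-SNR
preset — typical medians are much lower.

The same pipeline is available from the shell:

```sh
gaitbci simulate --seed 7 --out sessions --preset high-snr
gaitbci validate sessions/SL01-T01
gaitbci clean sessions/SL01-T01 --out cleaned-eeg.txt
gaitbci decode sessions/SL01-T01 --out decoded
gaitbci evaluate sessions/SL01-T01 --json report.json
```

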