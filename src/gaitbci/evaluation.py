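"""Quality control and decoder-performance metrics.

Three checks mirror how such a session is validated in practice:

* electrode-impedance QC against a 60 kΩ threshold, before vs after the
  experiment;
* a synchronization audit (delegated to the session loader's cross-file
  checks);
* per-gait-cycle decoding performance — the Pearson correlation between the
  measured and predicted angle of a joint within each gait cycle, compared
  between the last five minutes of the walk phase (adaptation still active)
  and the walk+BCI phase (model frozen).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .formats import ImpedanceRecord, JointFrame, SessionBundle
from .goniometry import GaitCycle, segment_gait
from .protocol import Protocol

__all__ = ["PerformanceReport", "ImpedanceQC", "cycle_r", "phase_compare",
           "impedance_qc", "evaluate_session", "IMPEDANCE_THRESHOLD_KOHM"]

#: Default high-impedance threshold (kΩ) applied at the end of a session.
IMPEDANCE_THRESHOLD_KOHM = 60.0


def cycle_r(measured_trace, predicted_trace,
            cycles: list[GaitCycle]) -> list[float]:
    """Pearson r between the two traces within each gait cycle.

    Cycles shorter than 3 samples or with zero variance in either trace are
    omitted with a warning (r is undefined there).
    """
    g = np.asarray(measured_trace, dtype=float)
    p = np.asarray(predicted_trace, dtype=float)
    if g.shape != p.shape:
        raise ValueError("measured and predicted traces must be aligned")
    out: list[float] = []
    skipped = 0
    for cyc in cycles:
        a = g[cyc.start_index:cyc.end_index]
        b = p[cyc.start_index:cyc.end_index]
        if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
            skipped += 1
            continue
        out.append(float(stats.pearsonr(a, b).statistic))
    if skipped:
        warnings.warn(f"omitted {skipped} cycle(s) with <3 samples or zero "
                      f"variance", stacklevel=2)
    return out


@dataclass(eq=False)
class PerformanceReport:
    """Per-cycle decoding performance for one joint, split by phase."""

    joint_label: str
    walk_r: list[float]             # last 5 min of the walk phase
    bci_r: list[float]              # whole walk+BCI phase
    walk_cycles: int = 0
    bci_cycles: int = 0

    @property
    def median_walk(self) -> float:
        return float(np.median(self.walk_r)) if self.walk_r else float("nan")

    @property
    def median_bci(self) -> float:
        return float(np.median(self.bci_r)) if self.bci_r else float("nan")

    def to_dict(self) -> dict:
        return {
            "joint": self.joint_label,
            "walk": {"n_cycles": self.walk_cycles,
                     "n_r_values": len(self.walk_r),
                     "median_r": self.median_walk},
            "walk_bci": {"n_cycles": self.bci_cycles,
                         "n_r_values": len(self.bci_r),
                         "median_r": self.median_bci},
        }


def phase_compare(report: PerformanceReport) -> dict:
    """Compare the two phases' r-value distributions.

    Returns per-phase medians, their difference (walk − walk+BCI) and a
    two-sided Wilcoxon rank-sum p-value.  The distributions are non-Gaussian
    and the cycles are not paired across phases, hence the rank-based test.
    """
    if len(report.walk_r) < 2 or len(report.bci_r) < 2:
        raise ValueError("both phases need at least 2 per-cycle r-values")
    test = stats.ranksums(report.walk_r, report.bci_r)
    return {
        "median_walk": report.median_walk,
        "median_bci": report.median_bci,
        "median_difference": report.median_walk - report.median_bci,
        "p_value": float(test.pvalue),
        "statistic": float(test.statistic),
        "n_walk": len(report.walk_r),
        "n_bci": len(report.bci_r),
    }


@dataclass(eq=False)
class ImpedanceQC:
    """High-impedance channel counts against a threshold, per phase."""

    threshold: float
    labels: tuple[str, ...]
    before_fail: np.ndarray          # bool per channel
    after_fail: np.ndarray
    delta: np.ndarray                # after − before, kΩ
    summary: dict = field(default_factory=dict)

    @property
    def n_fail_before(self) -> int:
        return int(np.sum(self.before_fail))

    @property
    def n_fail_after(self) -> int:
        return int(np.sum(self.after_fail))

    @property
    def fraction_fail_after(self) -> float:
        return self.n_fail_after / len(self.labels)

    @property
    def fraction_fail_before(self) -> float:
        return self.n_fail_before / len(self.labels)


def impedance_qc(before: ImpedanceRecord, after: ImpedanceRecord,
                 threshold: float = IMPEDANCE_THRESHOLD_KOHM) -> ImpedanceQC:
    """Count channels above ``threshold`` kΩ in each phase.

    Requires matching label sets; also reports per-phase mean ± sd and the
    per-channel before→after change.
    """
    if set(before.labels) != set(after.labels):
        raise ValueError("impedance records cover different label sets")
    order = [after.labels.index(l) for l in before.labels]
    after_vals = after.values[order]
    qc = ImpedanceQC(
        threshold=float(threshold),
        labels=tuple(before.labels),
        before_fail=before.values > threshold,
        after_fail=after_vals > threshold,
        delta=after_vals - before.values,
    )
    qc.summary = {
        "before_mean": float(np.mean(before.values)),
        "before_sd": float(np.std(before.values, ddof=1))
        if len(before.labels) > 1 else 0.0,
        "after_mean": float(np.mean(after_vals)),
        "after_sd": float(np.std(after_vals, ddof=1))
        if len(before.labels) > 1 else 0.0,
        "n_fail_after": qc.n_fail_after,
        "fraction_fail_after": qc.fraction_fail_after,
    }
    return qc


def evaluate_session(joints: JointFrame | SessionBundle,
                     protocol: Protocol | None = None,
                     joint: str = "HR",
                     cadence_bounds: tuple[float, float] = (0.4, 1.5),
                     ) -> PerformanceReport:
    """Per-gait-cycle decoding performance of one joint (default right hip).

    Gait cycles are segmented from the measured (G) trace; r-values are
    computed against the predicted (P) trace, separately for the last five
    minutes of the walk phase and for the whole walk+BCI phase.
    """
    if isinstance(joints, SessionBundle):
        joints = joints.joints
    protocol = protocol or Protocol()
    t = joints.timestamps - joints.timestamps[0]
    fs = protocol.fs
    g = joints.column("G" + joint)
    p = joints.column("P" + joint)

    def window_r(t_lo: float, t_hi: float) -> tuple[list[float], int]:
        lo = int(np.searchsorted(t, t_lo))
        hi = int(np.searchsorted(t, t_hi))
        cycles = segment_gait(g[lo:hi], fs, cadence_bounds)
        return cycle_r(g[lo:hi], p[lo:hi], cycles), len(cycles)

    walk_r, n_walk = window_r(max(protocol.walk_start,
                                  protocol.bci_start - 300.0),
                              protocol.bci_start)
    bci_r, n_bci = window_r(protocol.bci_start, protocol.bci_end)
    return PerformanceReport(joint_label=joint, walk_r=walk_r, bci_r=bci_r,
                             walk_cycles=n_walk, bci_cycles=n_bci)
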