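"""Trial protocol timeline.

A trial has four consecutive phases: a standing baseline, a treadmill walk
phase during which the decoder is adapted, a walk+BCI phase during which the
frozen decoder drives the avatar's right leg, and a closing standing baseline.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Protocol:
    """Phase durations (seconds) and the decoder-adaptation cadence.

    Defaults are the study protocol: 2 min stand, 15 min walk, 5 min
    walk+BCI, 2 min stand, sampled at 100 Hz, with a decoder refit every
    60 s of the walk phase.
    """

    stand_pre: float = 120.0
    walk: float = 900.0
    walk_bci: float = 300.0
    stand_post: float = 120.0
    fs: float = 100.0
    clda_interval: float = 60.0

    def __post_init__(self) -> None:
        for name in ("stand_pre", "walk", "walk_bci", "stand_post"):
            if getattr(self, name) <= 0:
                raise ValueError(f"phase duration {name!r} must be positive")
        if self.fs <= 0 or self.clda_interval <= 0:
            raise ValueError("fs and clda_interval must be positive")

    @property
    def total(self) -> float:
        """Total trial duration in seconds."""
        return self.stand_pre + self.walk + self.walk_bci + self.stand_post

    @property
    def walk_start(self) -> float:
        return self.stand_pre

    @property
    def bci_start(self) -> float:
        return self.stand_pre + self.walk

    @property
    def bci_end(self) -> float:
        return self.stand_pre + self.walk + self.walk_bci

    @property
    def n_samples(self) -> int:
        return int(round(self.total * self.fs))

    @property
    def n_clda_updates(self) -> int:
        """Number of per-minute decoder refits the walk phase admits."""
        return int(self.walk // self.clda_interval)

    def phase_of(self, t: float) -> str:
        """Phase label ('stand', 'walk', 'walk+bci') at trial time ``t``."""
        if t < self.walk_start:
            return "stand"
        if t < self.bci_start:
            return "walk"
        if t < self.bci_end:
            return "walk+bci"
        return "stand"
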