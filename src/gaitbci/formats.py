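"""Readers, writers and validators for the per-trial dataset layout.

Each trial folder ``SLxx-Tyy`` holds seven plain-text files:

* ``eeg.txt`` — "64 channels" header, then rows of timestamp + 64 samples
  (60 EEG channels plus 4 electrodes repurposed as EOG at TP9, TP10, FT9,
  FT10), all in microvolts at a nominal 100 Hz.
* ``joints.txt`` — two header lines (label list; per-joint calibration
  "joint factors"), then rows of timestamp + 12 joint angles in degrees:
  six goniometer-measured columns (G...) and six predicted/displayed
  columns (P...).
* ``conductor.txt`` — two header lines (verbatim title line; number of
  closed-loop decoder updates), then timestamped integer event ids.
* ``digitizer.bvct`` — XML with cap size, head shape and per-electrode
  Cartesian and polar coordinates.
* ``impedances-before.txt`` / ``impedances-after.txt`` — index, label and
  impedance in kΩ per electrode.

Reads accept any run of whitespace as delimiter; writes emit a single tab.
Numeric payloads are written with 6 significant digits, timestamps at full
float precision, so write→read round-trips are the identity at the printed
precision.
"""

from __future__ import annotations

import math
import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file violates the dataset's layout rules."""


class SchemaError(FormatError):
    """Header/label schema violation."""


class SynchronizationError(FormatError):
    """Cross-file sample/timestamp mismatch within a session."""


#: The four electrodes moved from their 10-20 scalp sites to periocular
#: positions: TP9 above / TP10 below the left eye (vertical EOG pair),
#: FT9 left of the left eye / FT10 right of the right eye (horizontal pair).
EOG_CHANNELS: tuple[str, ...] = ("TP9", "TP10", "FT9", "FT10")

#: Default 64-channel layout: a 64-electrode actiCap arrangement with T7/T8
#: relocated to FCz/AFz (freeing earlobe ground/reference sites) and the four
#: EOG electrodes above.  Column order doubles as the impedance-file index
#: order used to label eeg.txt columns.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "FCz",
    "C3", "Cz", "C4", "AFz",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
)
assert len(DEFAULT_CHANNELS) == 64
assert all(ch in DEFAULT_CHANNELS for ch in EOG_CHANNELS)

#: eeg.txt / joints.txt column count including the timestamp column.
N_SIGNAL_COLUMNS = 65

#: The 12 joint-angle labels XYZ: X∈{G,P} measured/predicted, Y∈{H,K,A}
#: hip/knee/ankle, Z∈{R,L} right/left.  GHR is first by construction.
JOINT_LABELS: tuple[str, ...] = (
    "GHR", "GKR", "GAR", "GHL", "GKL", "GAL",
    "PHR", "PKR", "PAR", "PHL", "PKL", "PAL",
)
MEASURED_LABELS: tuple[str, ...] = JOINT_LABELS[:6]
PREDICTED_LABELS: tuple[str, ...] = JOINT_LABELS[6:]

#: conductor.txt event-id legend.
EVENT_LEGEND: dict[int, str] = {
    8: "Start/stop training of the decoder",
    9: "Quit program",
    10: "Start/stop treadmill",
    11: "Turn on/off the graphic display of decoding results",
    13: "Decoder updated",
    16: "Input signal (one EEG sample and one goniometer sample) registered",
    17: "Turn on/off an obsolete graphic display",
}

_FLOAT_FMT = "%.6g"          # volts / degrees / kΩ payloads
_FOLDER_RE = re.compile(r"^SL(\d{2})-T(\d{2})$")


def describe_event(event_id: int) -> str:
    """Legend text for a conductor event id ('unknown' if out of legend)."""
    return EVENT_LEGEND.get(int(event_id), "unknown")


def folder_name(subject_id: int, trial_id: int) -> str:
    return f"SL{subject_id:02d}-T{trial_id:02d}"


def parse_folder_name(name: str) -> tuple[int, int]:
    """Parse ``SLxx-Tyy`` into (subject_id, trial_id)."""
    m = _FOLDER_RE.match(name)
    if m is None:
        raise FormatError(f"folder name {name!r} does not match SLxx-Tyy")
    return int(m.group(1)), int(m.group(2))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class SignalFrame:
    """Synchronized 64-channel EEG/EOG stream at a nominal 100 Hz."""

    timestamps: np.ndarray          # (n,) seconds, strictly increasing
    channels: tuple[str, ...]       # 64 ordered labels
    data: np.ndarray                # (n, 64) microvolts

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        self.validate()

    def validate(self) -> None:
        if len(self.channels) != 64:
            raise SchemaError(
                f"expected exactly 64 channels, got {len(self.channels)}")
        if self.data.ndim != 2 or self.data.shape[1] != 64:
            raise SchemaError(f"data must be (n, 64), got {self.data.shape}")
        if self.data.shape[0] != self.timestamps.shape[0]:
            raise SchemaError("row count of data must equal timestamp count")
        if self.timestamps.size and np.any(np.diff(self.timestamps) <= 0):
            raise FormatError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def eog_labels(self) -> tuple[str, ...]:
        return tuple(ch for ch in self.channels if ch in EOG_CHANNELS)

    @property
    def eeg_labels(self) -> tuple[str, ...]:
        return tuple(ch for ch in self.channels if ch not in EOG_CHANNELS)

    def column(self, label: str) -> np.ndarray:
        try:
            return self.data[:, self.channels.index(label)]
        except ValueError:
            raise KeyError(f"no channel labeled {label!r}") from None

    def to_mne(self, montage: "Montage | None" = None):
        """One-way export to an :class:`mne.io.RawArray` (volts, 100 Hz).

        Convenience for downstream tooling; not part of the round-trip
        contract.  Requires the optional ``mne`` dependency.
        """
        import mne  # local import: optional dependency

        fs = 1.0 / float(np.median(np.diff(self.timestamps)))
        types = ["eog" if ch in EOG_CHANNELS else "eeg" for ch in self.channels]
        info = mne.create_info(list(self.channels), sfreq=fs, ch_types=types)
        raw = mne.io.RawArray(self.data.T * 1e-6, info, verbose="error")
        if montage is not None:
            pos = {lab: np.array([e.x, e.y, e.z]) * 1e-3
                   for lab, e in montage.electrodes.items()}
            raw.set_montage(mne.channels.make_dig_montage(ch_pos=pos),
                            on_missing="ignore", verbose="error")
        return raw


@dataclass(eq=False)
class JointFrame:
    """Timestamped 12-column joint-angle stream plus calibration factors.

    Columns hold degrees; ``joint_factors`` are the six per-joint calibration
    maxima x (the denominators of the linear goniometer mapping), in the
    order of the six measured labels GHR GKR GAR GHL GKL GAL.
    """

    timestamps: np.ndarray
    labels: tuple[str, ...]
    angles: np.ndarray              # (n, 12) degrees
    joint_factors: np.ndarray       # (6,)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.joint_factors = np.asarray(self.joint_factors, dtype=float)
        self.labels = tuple(self.labels)
        self.validate()

    def validate(self) -> None:
        if len(self.labels) != 12 or len(set(self.labels)) != 12:
            raise SchemaError("exactly 12 unique angle labels required")
        missing = set(JOINT_LABELS) - set(self.labels)
        if missing:
            raise SchemaError(f"missing joint labels: {sorted(missing)}")
        if self.labels[0] != "GHR":
            raise SchemaError(
                f"first angle column must be GHR, got {self.labels[0]!r}")
        if self.angles.ndim != 2 or self.angles.shape[1] != 12:
            raise SchemaError(f"angles must be (n, 12), got {self.angles.shape}")
        if self.angles.shape[0] != self.timestamps.shape[0]:
            raise SchemaError("row count of angles must equal timestamp count")
        if self.joint_factors.shape != (6,):
            raise SchemaError("exactly 6 joint factors required")
        if np.any(self.joint_factors <= 0):
            raise FormatError("joint factors must be strictly positive")

    @property
    def n_samples(self) -> int:
        return self.angles.shape[0]

    def column(self, label: str) -> np.ndarray:
        try:
            return self.angles[:, self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no joint column labeled {label!r}") from None

    def measured(self) -> np.ndarray:
        """(n, 6) measured angles in canonical order GHR GKR GAR GHL GKL GAL."""
        return np.column_stack([self.column(l) for l in MEASURED_LABELS])

    def predicted(self) -> np.ndarray:
        """(n, 6) predicted angles in canonical order PHR ... PAL."""
        return np.column_stack([self.column(l) for l in PREDICTED_LABELS])

    def predicted_mirrors_measured(self, until_time: float | None = None,
                                   tol: float = 1e-9) -> bool:
        """True if every P column equals its G partner (up to ``until_time``).

        Before the walk+BCI phase the displayed (predicted) angles track the
        goniometer measurement exactly, deviating only while the decoder
        drives the avatar.
        """
        mask = (slice(None) if until_time is None
                else self.timestamps < until_time)
        g = self.measured()[mask]
        p = self.predicted()[mask]
        return bool(np.all(np.abs(g - p) <= tol))


@dataclass(eq=False)
class EventLog:
    """Timestamped conductor events plus the decoder-update count header."""

    times: np.ndarray
    event_ids: np.ndarray
    n_clda_updates: int
    header_line: str = "conductor events: time event"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.event_ids = np.asarray(self.event_ids, dtype=int)
        self.validate()

    def validate(self) -> None:
        if self.times.shape != self.event_ids.shape:
            raise SchemaError("times and event ids must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise FormatError("event times must be non-decreasing")
        unknown = sorted(set(int(e) for e in self.event_ids) - set(EVENT_LEGEND))
        if unknown:
            warnings.warn(f"unknown conductor event ids retained: {unknown}",
                          stacklevel=2)

    def __len__(self) -> int:
        return self.times.size

    def of_id(self, event_id: int) -> np.ndarray:
        """Times of all events with the given id."""
        return self.times[self.event_ids == int(event_id)]

    def describe(self, event_id: int) -> str:
        return describe_event(event_id)


@dataclass(frozen=True)
class ElectrodePosition:
    """One digitized electrode: Cartesian (mm) and polar coordinates.

    ``theta`` is the inclination from the vertex (+z) in degrees, ``phi``
    the azimuth from +x (right ear) in degrees, ``r`` the radius in mm.
    """

    x: float
    y: float
    z: float
    theta: float
    phi: float
    r: float

    @classmethod
    def from_cartesian(cls, x: float, y: float, z: float) -> "ElectrodePosition":
        x, y, z = float(x), float(y), float(z)
        r = math.sqrt(x * x + y * y + z * z)
        theta = math.degrees(math.acos(z / r)) if r > 0 else 0.0
        phi = math.degrees(math.atan2(y, x))
        return cls(x, y, z, theta, phi, r)

    def cartesian_from_polar(self) -> tuple[float, float, float]:
        th = math.radians(self.theta)
        ph = math.radians(self.phi)
        return (self.r * math.sin(th) * math.cos(ph),
                self.r * math.sin(th) * math.sin(ph),
                self.r * math.cos(th))

    def consistent(self, tol_mm: float = 0.1) -> bool:
        cx, cy, cz = self.cartesian_from_polar()
        return max(abs(cx - self.x), abs(cy - self.y), abs(cz - self.z)) <= tol_mm


@dataclass(eq=False)
class Montage:
    """Digitized electrode locations plus cap size and head shape."""

    cap_size: float                         # head circumference, cm
    head_shape: str                         # 'round' | 'oval'
    electrodes: dict[str, ElectrodePosition]

    def validate(self, tol_mm: float = 0.1) -> None:
        if self.head_shape not in ("round", "oval"):
            raise FormatError(f"head shape must be round|oval, "
                              f"got {self.head_shape!r}")
        for label, e in self.electrodes.items():
            if not e.consistent(tol_mm):
                raise FormatError(
                    f"electrode {label}: Cartesian and polar coordinates "
                    f"disagree beyond {tol_mm} mm")

    def covers(self, labels: Iterable[str]) -> list[str]:
        """Labels from ``labels`` that have no digitized position."""
        return [l for l in labels if l not in self.electrodes]

    def equals(self, other: "Montage", tol: float = 0.0) -> bool:
        if (self.cap_size != other.cap_size
                or self.head_shape != other.head_shape
                or set(self.electrodes) != set(other.electrodes)):
            return False
        for lab, e in self.electrodes.items():
            o = other.electrodes[lab]
            if max(abs(e.x - o.x), abs(e.y - o.y), abs(e.z - o.z)) > tol:
                return False
        return True


@dataclass(eq=False)
class ImpedanceRecord:
    """Per-electrode contact impedances in kΩ, before or after a session."""

    labels: tuple[str, ...]
    values: np.ndarray              # kΩ
    phase: str                      # 'before' | 'after'
    indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.indices is None:
            self.indices = np.arange(1, len(self.labels) + 1)
        self.indices = np.asarray(self.indices, dtype=int)
        self.validate()

    def validate(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise FormatError(f"duplicate impedance labels: {dupes}")
        if self.values.shape[0] != len(self.labels):
            raise SchemaError("one impedance value per label required")
        if np.any(self.values < 0):
            raise FormatError("impedances must be non-negative")
        if self.phase not in ("before", "after"):
            raise FormatError(f"phase must be before|after, got {self.phase!r}")

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.labels.index(label)])

    @property
    def eog_labels(self) -> tuple[str, ...]:
        """Labels repurposed as EOG electrodes."""
        return tuple(l for l in self.labels if l in EOG_CHANNELS)


@dataclass(eq=False)
class SessionBundle:
    """One trial folder held in memory with cross-file guarantees."""

    signal: SignalFrame
    joints: JointFrame
    events: EventLog
    montage: Montage
    impedances: dict[str, ImpedanceRecord]   # keys 'before', 'after'
    subject_id: int
    trial_id: int

    @property
    def folder_name(self) -> str:
        return folder_name(self.subject_id, self.trial_id)

    def validate(self, timestamp_tol: float = 1e-6) -> list[str]:
        """Run cross-file consistency checks; return non-fatal warnings.

        Raises :class:`SynchronizationError` on sample-count or timestamp
        mismatch (the two streams are recorded in pairs) and
        :class:`FormatError` on montage/impedance coverage failures.
        """
        warnings_: list[str] = []
        if self.signal.n_samples != self.joints.n_samples:
            raise SynchronizationError(
                f"eeg.txt has {self.signal.n_samples} samples but joints.txt "
                f"has {self.joints.n_samples}; streams must be recorded in pairs")
        if self.signal.n_samples and not np.allclose(
                self.signal.timestamps, self.joints.timestamps,
                atol=timestamp_tol, rtol=0):
            raise SynchronizationError(
                "eeg.txt and joints.txt timestamps are not pairwise aligned")
        missing = self.montage.covers(self.signal.channels)
        if missing:
            raise FormatError(
                f"digitizer.bvct lacks coordinates for channels: {missing}")
        for phase in ("before", "after"):
            if phase not in self.impedances:
                raise FormatError(f"missing impedance record: {phase}")
            rec = self.impedances[phase]
            if tuple(rec.labels) != tuple(self.signal.channels):
                warnings_.append(
                    f"impedances-{phase}.txt label order differs from the "
                    f"signal channel order")
        n13 = int(np.sum(self.events.event_ids == 13))
        if n13 != self.events.n_clda_updates:
            warnings_.append(
                f"conductor.txt header declares {self.events.n_clda_updates} "
                f"decoder updates but {n13} id-13 events are present")
        return warnings_


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_table(path: Path, skiprows: int, n_cols: int) -> np.ndarray:
    """Whitespace-delimited float table with strict column-count checking."""
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, skiprows=skiprows,
                         dtype=float)
    except pd.errors.EmptyDataError:
        return np.empty((0, n_cols))
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc
    except ValueError as exc:
        raise FormatError(f"{path.name}: non-numeric data row: {exc}") from exc
    if df.shape[1] != n_cols:
        raise FormatError(
            f"{path.name}: expected {n_cols} columns per data row, "
            f"found {df.shape[1]}")
    arr = df.to_numpy(dtype=float)
    bad = np.nonzero(np.isnan(arr).any(axis=1))[0]
    if bad.size:
        raise FormatError(
            f"{path.name}: wrong column count or non-numeric field at data "
            f"row {bad[0] + 1} (line {bad[0] + 1 + skiprows})")
    return arr


def read_signal(path: str | Path,
                channel_labels: Sequence[str] | None = None) -> SignalFrame:
    """Parse ``eeg.txt``.

    The single header line declares the channel count ("64 channels"); data
    rows carry a timestamp plus one sample per channel.  Channel labels are
    the impedance-file index order when ``channel_labels`` is given, else
    positional ``ch01..ch64``.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    m = re.match(r"\s*(\d+)\s+channels", header, flags=re.IGNORECASE)
    if m is None:
        raise SchemaError(f"{path.name}: malformed header {header.strip()!r}; "
                          f"expected '<n> channels'")
    n_ch = int(m.group(1))
    if n_ch != 64:
        raise SchemaError(f"{path.name}: header declares {n_ch} channels; "
                          f"exactly 64 are expected")
    table = _read_table(path, skiprows=1, n_cols=n_ch + 1)
    if table.shape[0] == 0:
        raise FormatError(f"{path.name}: empty signal stream")
    if channel_labels is None:
        channels = tuple(f"ch{i:02d}" for i in range(1, n_ch + 1))
    else:
        channels = tuple(channel_labels)
        if len(channels) != n_ch:
            raise SchemaError(f"{path.name}: {len(channels)} labels supplied "
                              f"for {n_ch} channels")
    ts = table[:, 0]
    if np.any(np.diff(ts) <= 0):
        bad = int(np.nonzero(np.diff(ts) <= 0)[0][0]) + 2
        raise FormatError(f"{path.name}: non-monotonic timestamp at data "
                          f"row {bad}")
    return SignalFrame(ts, channels, table[:, 1:])


def read_joints(path: str | Path) -> JointFrame:
    """Parse ``joints.txt`` (two header lines, then 13 columns)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        line1 = fh.readline()
        line2 = fh.readline()
    labels = tuple(re.findall(r"\b[GP][HKA][RL]\b", line1))
    if len(labels) != 12:
        missing = sorted(set(JOINT_LABELS) - set(labels))
        raise SchemaError(
            f"{path.name}: header lists {len(labels)} joint labels, "
            f"expected 12; missing {missing}")
    if not re.search(r"factor", line2, flags=re.IGNORECASE):
        raise SchemaError(f"{path.name}: second header line must carry the "
                          f"joint factors")
    factors = [float(v) for v in re.findall(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?",
                                            line2)]
    if len(factors) != 6:
        raise SchemaError(f"{path.name}: expected 6 joint factors, "
                          f"found {len(factors)}")
    table = _read_table(path, skiprows=2, n_cols=13)
    return JointFrame(table[:, 0], labels, table[:, 1:], np.asarray(factors))


def read_events(path: str | Path) -> EventLog:
    """Parse ``conductor.txt``.

    Header line 1 (title + column labels) is stored verbatim; header line 2
    carries the number of decoder (CLDA) updates.  Unknown event ids warn
    and are retained; unparseable times fail.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        line1 = fh.readline().rstrip("\n")
        line2 = fh.readline()
        rows = fh.readlines()
    m = re.search(r"\d+", line2)
    if m is None:
        raise SchemaError(f"{path.name}: second header line must state the "
                          f"number of CLDA updates")
    n_clda = int(m.group(0))
    times: list[float] = []
    ids: list[int] = []
    for i, row in enumerate(rows, start=3):
        if not row.strip():
            continue
        parts = row.split()
        if len(parts) != 2:
            raise FormatError(f"{path.name}: line {i}: expected 'time event', "
                              f"got {row.strip()!r}")
        try:
            t = float(parts[0])
        except ValueError:
            raise FormatError(f"{path.name}: line {i}: unparseable time "
                              f"{parts[0]!r}") from None
        try:
            e = int(parts[1])
        except ValueError:
            raise FormatError(f"{path.name}: line {i}: unparseable event id "
                              f"{parts[1]!r}") from None
        times.append(t)
        ids.append(e)
    return EventLog(np.asarray(times), np.asarray(ids, dtype=int), n_clda,
                    header_line=line1)


def read_montage(path: str | Path, tol_mm: float = 0.1) -> Montage:
    """Parse ``digitizer.bvct`` (CapTrak-style XML).

    Unknown nodes are tolerated and ignored; each electrode needs a Name,
    Cartesian X/Y/Z and polar Theta/Phi/Radius, which must agree within
    ``tol_mm``.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"{path.name}: malformed XML: {exc}") from exc
    root = tree.getroot()
    cap = root.attrib.get("CapSize")
    shape = root.attrib.get("HeadShape", "round")
    if cap is None:
        raise SchemaError(f"{path.name}: missing CapSize attribute")
    electrodes: dict[str, ElectrodePosition] = {}
    for node in root.iter("Electrode"):
        fields = {child.tag: (child.text or "").strip() for child in node}
        missing = [k for k in ("Name", "X", "Y", "Z", "Theta", "Phi", "Radius")
                   if k not in fields]
        if missing:
            raise SchemaError(f"{path.name}: electrode node missing "
                              f"{missing}")
        electrodes[fields["Name"]] = ElectrodePosition(
            float(fields["X"]), float(fields["Y"]), float(fields["Z"]),
            float(fields["Theta"]), float(fields["Phi"]),
            float(fields["Radius"]))
    if not electrodes:
        raise SchemaError(f"{path.name}: no Electrode nodes found")
    montage = Montage(float(cap), shape, electrodes)
    montage.validate(tol_mm)
    return montage


def read_impedances(path: str | Path, phase: str | None = None) -> ImpedanceRecord:
    """Parse an ``impedances-before.txt`` / ``impedances-after.txt`` file."""
    path = Path(path)
    if phase is None:
        phase = "after" if "after" in path.name.lower() else "before"
    indices: list[int] = []
    labels: list[str] = []
    values: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for i, row in enumerate(fh, start=1):
            if not row.strip():
                continue
            parts = row.split()
            if i == 1 and not parts[0].lstrip("+-").isdigit():
                continue   # optional column-name header
            if len(parts) != 3:
                raise FormatError(f"{path.name}: line {i}: expected "
                                  f"'index label impedance'")
            indices.append(int(parts[0]))
            labels.append(parts[1])
            values.append(float(parts[2]))
    if not labels:
        raise FormatError(f"{path.name}: no impedance records")
    return ImpedanceRecord(tuple(labels), np.asarray(values), phase,
                           np.asarray(indices))


# ---------------------------------------------------------------------------
# Writers (single-tab delimiter, UTF-8)
# ---------------------------------------------------------------------------

def _format_rows(timestamps: np.ndarray, payload: np.ndarray) -> pd.DataFrame:
    # timestamps at full float precision (repr round-trips exactly);
    # payload at 6 significant digits
    df = pd.DataFrame(payload)
    df.insert(0, "t", [repr(float(t)) for t in timestamps])
    return df


def write_signal(frame: SignalFrame, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(frame.channels)} channels\n")
        _format_rows(frame.timestamps, frame.data).to_csv(
            fh, sep="\t", header=False, index=False, float_format=_FLOAT_FMT,
            lineterminator="\n")


def write_joints(frame: JointFrame, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("6 joints: " + " ".join(frame.labels) + "\n")
        fh.write("joint factors: "
                 + " ".join(_FLOAT_FMT % v for v in frame.joint_factors) + "\n")
        _format_rows(frame.timestamps, frame.angles).to_csv(
            fh, sep="\t", header=False, index=False, float_format=_FLOAT_FMT,
            lineterminator="\n")


def write_events(log: EventLog, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(log.header_line.rstrip("\n") + "\n")
        fh.write(f"{log.n_clda_updates} CLDA updates\n")
        for t, e in zip(log.times, log.event_ids):
            fh.write(f"{float(t)!r}\t{int(e)}\n")


def write_montage(montage: Montage, path: str | Path) -> None:
    root = ET.Element("CapTrakElectrodeList",
                      CapSize=_FLOAT_FMT % montage.cap_size,
                      HeadShape=montage.head_shape, Version="1")
    for label, e in montage.electrodes.items():
        node = ET.SubElement(root, "Electrode")
        for tag, value in (("Name", label),
                           ("X", repr(e.x)), ("Y", repr(e.y)), ("Z", repr(e.z)),
                           ("Theta", repr(e.theta)), ("Phi", repr(e.phi)),
                           ("Radius", repr(e.r))):
            ET.SubElement(node, tag).text = str(value)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)


def write_impedances(record: ImpedanceRecord, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("index\tlabel\timpedance_kohm\n")
        for i, label, v in zip(record.indices, record.labels, record.values):
            fh.write(f"{int(i)}\t{label}\t{_FLOAT_FMT % v}\n")


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

SESSION_FILES = ("eeg.txt", "joints.txt", "conductor.txt", "digitizer.bvct",
                 "impedances-before.txt", "impedances-after.txt")


def load_session(folder: str | Path, strict: bool = True) -> SessionBundle:
    """Load and cross-validate one ``SLxx-Tyy`` trial folder.

    With ``strict`` (default) any cross-file inconsistency raises; otherwise
    non-fatal findings are emitted as warnings.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"session folder not found: {folder}")
    missing = [f for f in SESSION_FILES if not (folder / f).exists()]
    if missing:
        raise FormatError(f"{folder.name}: missing session files: {missing}")
    try:
        subject_id, trial_id = parse_folder_name(folder.name)
    except FormatError:
        if strict:
            raise
        warnings.warn(f"folder {folder.name!r} does not match SLxx-Tyy; "
                      f"using subject 0, trial 0", stacklevel=2)
        subject_id = trial_id = 0
    imped = {phase: read_impedances(folder / f"impedances-{phase}.txt", phase)
             for phase in ("before", "after")}
    signal = read_signal(folder / "eeg.txt",
                         channel_labels=imped["before"].labels)
    joints = read_joints(folder / "joints.txt")
    events = read_events(folder / "conductor.txt")
    montage = read_montage(folder / "digitizer.bvct")
    bundle = SessionBundle(signal, joints, events, montage, imped,
                           subject_id, trial_id)
    for msg in bundle.validate():
        warnings.warn(f"{folder.name}: {msg}", stacklevel=2)
    return bundle


def write_session(bundle: SessionBundle, parent: str | Path,
                  force: bool = False) -> Path:
    """Write a bundle as a trial folder under ``parent``; returns the folder."""
    parent = Path(parent)
    folder = parent / bundle.folder_name
    if folder.exists() and not force:
        raise FileExistsError(f"refusing to overwrite existing session "
                              f"folder {folder} (use force=True)")
    folder.mkdir(parents=True, exist_ok=True)
    write_signal(bundle.signal, folder / "eeg.txt")
    write_joints(bundle.joints, folder / "joints.txt")
    write_events(bundle.events, folder / "conductor.txt")
    write_montage(bundle.montage, folder / "digitizer.bvct")
    for phase in ("before", "after"):
        write_impedances(bundle.impedances[phase],
                         folder / f"impedances-{phase}.txt")
    return folder
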