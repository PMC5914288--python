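"""File-format readers/writers and cross-file session validation."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from gaitbci import formats
from gaitbci.formats import (DEFAULT_CHANNELS, EOG_CHANNELS, JOINT_LABELS,
                             EventLog, FormatError, ImpedanceRecord,
                             JointFrame, SchemaError, SignalFrame,
                             SynchronizationError, describe_event,
                             load_session, parse_folder_name, read_events,
                             read_impedances, read_joints, read_montage,
                             read_signal, write_session, write_signal)
from gaitbci.synth import SynthConfig, gen_session, template_montage
from tests.conftest import SHORT_PROTOCOL


def _tiny_signal(n=3):
    rng = np.random.default_rng(0)
    return SignalFrame(np.arange(n) / 100.0, DEFAULT_CHANNELS,
                       rng.normal(0, 20, (n, 64)))


class TestSignal:
    def test_read_conforming_file(self, tmp_path):
        path = tmp_path / "eeg.txt"
        write_signal(_tiny_signal(3), path)
        assert path.read_text().splitlines()[0] == "64 channels"
        frame = read_signal(path, channel_labels=DEFAULT_CHANNELS)
        assert frame.n_samples == 3
        assert len(frame.channels) == 64

    def test_positional_labels_without_impedance_file(self, tmp_path):
        path = tmp_path / "eeg.txt"
        write_signal(_tiny_signal(2), path)
        frame = read_signal(path)
        assert frame.channels[0] == "ch01" and frame.channels[-1] == "ch64"

    def test_empty_stream_rejected(self, tmp_path):
        path = tmp_path / "eeg.txt"
        path.write_text("64 channels\n")
        with pytest.raises(FormatError, match="empty signal stream"):
            read_signal(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "eeg.txt"
        path.write_text("hello world\n0.0\t" + "\t".join(["1"] * 64) + "\n")
        with pytest.raises(SchemaError, match="malformed header"):
            read_signal(path)

    def test_wrong_column_count_reports_row(self, tmp_path):
        path = tmp_path / "eeg.txt"
        good = "\t".join(["0.5"] * 65)
        bad = "\t".join(["0.6"] * 60)
        path.write_text("64 channels\n" + good + "\n" + bad + "\n")
        with pytest.raises(FormatError, match=r"(row|line)\s*\d+"):
            read_signal(path)

    def test_non_monotonic_timestamps_rejected(self, tmp_path):
        path = tmp_path / "eeg.txt"
        rows = ["\t".join([t] + ["1.0"] * 64) for t in ("0.0", "0.2", "0.1")]
        path.write_text("64 channels\n" + "\n".join(rows) + "\n")
        with pytest.raises(FormatError, match="non-monotonic"):
            read_signal(path)

    def test_round_trip_identity(self, tmp_path):
        frame = _tiny_signal(50)
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_signal(frame, p1)
        write_signal(read_signal(p1, DEFAULT_CHANNELS), p2)
        # re-serializing the parsed file reproduces it byte for byte
        assert p1.read_bytes() == p2.read_bytes()


class TestJoints:
    def test_first_column_is_ghr(self, session_folder):
        frame = read_joints(session_folder / "joints.txt")
        assert frame.labels[0] == "GHR"
        assert set(frame.labels) == set(JOINT_LABELS)
        assert frame.joint_factors.shape == (6,)
        assert np.all(frame.joint_factors > 0)

    def test_missing_label_named(self, session_folder, tmp_path):
        text = (session_folder / "joints.txt").read_text().splitlines()
        bad = tmp_path / "joints.txt"
        bad.write_text(text[0].replace(" PAL", "") + "\n"
                       + "\n".join(text[1:]) + "\n")
        with pytest.raises(SchemaError, match="PAL"):
            read_joints(bad)

    def test_predicted_mirrors_measured_flag(self, short_session):
        bundle, _ = short_session
        # generated sessions mirror the measured angles everywhere
        assert bundle.joints.predicted_mirrors_measured()
        modified = bundle.joints.angles.copy()
        modified[-1, JOINT_LABELS.index("PHR")] += 5.0
        frame = JointFrame(bundle.joints.timestamps, JOINT_LABELS, modified,
                           bundle.joints.joint_factors)
        assert not frame.predicted_mirrors_measured()
        assert frame.predicted_mirrors_measured(
            until_time=float(frame.timestamps[-1]))


class TestEvents:
    @pytest.mark.parametrize("event_id,description", [
        (13, "Decoder updated"),
        (10, "Start/stop treadmill"),
        (9, "Quit program"),
        (99, "unknown"),
    ])
    def test_legend(self, event_id, description):
        assert describe_event(event_id) == description

    def test_unknown_id_warns_and_is_retained(self, tmp_path):
        path = tmp_path / "conductor.txt"
        path.write_text("conductor events: time event\n0 CLDA updates\n"
                        "1.0\t10\n2.0\t99\n")
        with pytest.warns(UserWarning, match="99"):
            log = read_events(path)
        assert 99 in log.event_ids

    def test_unparseable_time_fails(self, tmp_path):
        path = tmp_path / "conductor.txt"
        path.write_text("conductor events: time event\n0 CLDA updates\n"
                        "oops\t10\n")
        with pytest.raises(FormatError, match="unparseable time"):
            read_events(path)

    def test_decreasing_times_rejected(self):
        with pytest.raises(FormatError, match="non-decreasing"):
            EventLog(np.array([2.0, 1.0]), np.array([10, 10]), 0)

    def test_header_line_round_trips_verbatim(self, tmp_path):
        path = tmp_path / "conductor.txt"
        header = "My Conductor Log (time, event)"
        path.write_text(header + "\n3 CLDA updates\n1.0\t13\n")
        log = read_events(path)
        assert log.header_line == header
        assert log.n_clda_updates == 3


class TestMontage:
    def test_fixture_has_64_electrodes(self, session_folder):
        montage = read_montage(session_folder / "digitizer.bvct")
        assert len(montage.electrodes) == 64
        assert not montage.covers(DEFAULT_CHANNELS)

    def test_pole_consistency(self):
        e = formats.ElectrodePosition.from_cartesian(0.0, 0.0, 87.0)
        assert e.theta == pytest.approx(0.0, abs=1e-9)
        assert e.consistent(tol_mm=1e-6)

    def test_same_subject_same_day_montages_equal(self):
        c1 = SynthConfig(seed=9, subject=3, trial=1,
                         protocol=replace(SHORT_PROTOCOL, walk=65.0))
        c2 = replace(c1, trial=2)
        b1, _ = gen_session(c1)
        b2, _ = gen_session(c2)
        assert b1.montage.equals(b2.montage)
        assert np.array_equal(b1.impedances["before"].values,
                              b2.impedances["before"].values)

    def test_inconsistent_polar_pair_rejected(self, tmp_path):
        m = template_montage()
        bad = dict(m.electrodes)
        e = bad["Cz"]
        bad["Cz"] = formats.ElectrodePosition(e.x, e.y, e.z, e.theta + 30.0,
                                              e.phi, e.r)
        path = tmp_path / "digitizer.bvct"
        formats.write_montage(formats.Montage(m.cap_size, m.head_shape, bad),
                              path)
        with pytest.raises(FormatError, match="disagree"):
            read_montage(path)


class TestImpedances:
    def test_uniform_values(self, tmp_path):
        rec = ImpedanceRecord(DEFAULT_CHANNELS, np.full(64, 15.0), "before")
        path = tmp_path / "impedances-before.txt"
        formats.write_impedances(rec, path)
        loaded = read_impedances(path)
        assert np.all(loaded.values == 15.0)
        assert loaded.phase == "before"

    def test_eog_labels_flagged(self, session_folder):
        rec = read_impedances(session_folder / "impedances-before.txt")
        assert set(rec.eog_labels) == set(EOG_CHANNELS)

    def test_high_impedance_channel_loads(self, tmp_path):
        values = np.full(64, 15.0)
        values[5] = 75.0
        rec = ImpedanceRecord(DEFAULT_CHANNELS, values, "after")
        path = tmp_path / "impedances-after.txt"
        formats.write_impedances(rec, path)
        assert read_impedances(path)[DEFAULT_CHANNELS[5]] == 75.0

    def test_duplicate_label_rejected(self):
        labels = ("Fp1",) * 2 + DEFAULT_CHANNELS[2:]
        with pytest.raises(FormatError, match="duplicate"):
            ImpedanceRecord(labels, np.full(64, 10.0), "before")

    def test_negative_impedance_rejected(self):
        with pytest.raises(FormatError, match="non-negative"):
            ImpedanceRecord(DEFAULT_CHANNELS, np.full(64, -1.0), "before")


class TestSession:
    def test_folder_name_parsing(self):
        assert parse_folder_name("SL04-T03") == (4, 3)
        with pytest.raises(FormatError):
            parse_folder_name("subject4-trial3")

    def test_generated_session_loads_without_warnings(self, session_folder):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            bundle = load_session(session_folder)
        assert bundle.signal.n_samples == bundle.joints.n_samples

    def test_round_trip_preserves_numeric_content(self, short_session,
                                                  tmp_path):
        bundle, _ = short_session
        folder = write_session(bundle, tmp_path)
        again = load_session(folder)
        assert np.array_equal(bundle.signal.timestamps,
                              again.signal.timestamps)
        assert np.allclose(bundle.signal.data, again.signal.data,
                           rtol=1e-5, atol=1e-8)
        assert np.allclose(bundle.joints.angles, again.joints.angles,
                           rtol=1e-5, atol=1e-8)
        assert np.allclose(bundle.joints.joint_factors,
                           again.joints.joint_factors, rtol=1e-5)
        assert np.array_equal(bundle.events.event_ids, again.events.event_ids)
        assert bundle.montage.equals(again.montage)

    def test_deleted_joints_row_breaks_synchronization(self, session_folder,
                                                      tmp_path):
        import shutil

        broken = tmp_path / session_folder.name
        shutil.copytree(session_folder, broken)
        lines = (broken / "joints.txt").read_text().splitlines()
        (broken / "joints.txt").write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(SynchronizationError, match="eeg.txt.*joints.txt"):
            load_session(broken)

    def test_missing_file_named(self, session_folder, tmp_path):
        import shutil

        broken = tmp_path / session_folder.name
        shutil.copytree(session_folder, broken)
        (broken / "joints.txt").unlink()
        with pytest.raises(FormatError, match="joints.txt"):
            load_session(broken)
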