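"""WFDB round-trips, AAMI mapping, segmentation and balanced splitting."""

from pathlib import Path

import numpy as np
import pytest

from memae.autoencoder import ECGBeat
from memae.ecg_io import (
    ECGRecord,
    balance_and_split,
    beats_to_csv,
    map_aami,
    read_beats_csv,
    read_wfdb_record,
    segment_beats,
    write_wfdb_record,
)
from memae.synthetic import generate_pacing_record

MITDB_DIR = Path(__file__).resolve().parent.parent / "data" / "mitdb"


@pytest.fixture
def fixture_record():
    """A 2-lead synthetic record with annotations, written/read as WFDB."""
    record = generate_pacing_record(n_beats=8, heart_rate_bpm=75, fs=360,
                                    duration_s=8.0, leads=2, seed=0, symbol="N")
    return record


class TestWfdbRoundTrip:
    def test_signal_round_trips_to_format_precision(self, tmp_path, fixture_record):
        gain = 400.0
        base = write_wfdb_record(fixture_record, tmp_path, "fix01", gain=gain)
        loaded = read_wfdb_record(base)
        assert loaded.sampling_rate == fixture_record.sampling_rate
        assert loaded.lead_names == fixture_record.lead_names
        np.testing.assert_allclose(loaded.signal, fixture_record.signal,
                                   atol=0.5 / gain + 1e-12)

    def test_annotations_round_trip_exactly(self, tmp_path, fixture_record):
        base = write_wfdb_record(fixture_record, tmp_path, "fix02")
        loaded = read_wfdb_record(base)
        assert loaded.annotations == sorted(fixture_record.annotations)

    def test_long_gap_annotations_use_skip_words(self, tmp_path):
        record = ECGRecord(signal=np.zeros((1, 20000)), sampling_rate=360.0,
                           lead_names=["MLII"],
                           annotations=[(10, "N"), (15000, "V")])
        base = write_wfdb_record(record, tmp_path, "fix03")
        assert read_wfdb_record(base).annotations == [(10, "N"), (15000, "V")]

    def test_missing_annotation_file_is_explicit(self, tmp_path, fixture_record):
        base = write_wfdb_record(fixture_record, tmp_path, "fix04")
        base.with_suffix(".atr").unlink()
        with pytest.raises(FileNotFoundError, match="annotation"):
            read_wfdb_record(base)

    def test_missing_header_is_explicit(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="header"):
            read_wfdb_record(tmp_path / "nope")

    def test_lead_selection(self, tmp_path, fixture_record):
        base = write_wfdb_record(fixture_record, tmp_path, "fix05")
        lead = fixture_record.lead_names[1]
        loaded = read_wfdb_record(base, lead=lead)
        assert loaded.lead_names == [lead]
        assert loaded.signal.shape[0] == 1


class TestAamiMapping:
    @pytest.mark.parametrize("symbol, expected", [
        ("N", "N"), ("L", "N"), ("R", "N"), ("e", "N"), ("j", "N"),
        ("A", "S"), ("a", "S"), ("J", "S"), ("S", "S"),
        ("V", "V"), ("E", "V"),
        ("F", "F"),
        ("/", "Q"), ("f", "Q"), ("Q", "Q"),
    ])
    def test_beat_symbols(self, symbol, expected):
        assert map_aami(symbol) == expected

    @pytest.mark.parametrize("symbol", ["+", "~", "|", "\"", "[", "]", "!", "x"])
    def test_non_beat_symbols_rejected(self, symbol):
        assert map_aami(symbol) is None


class TestSegmentBeats:
    def make_record(self, length, annotations, fs=360.0):
        rng = np.random.default_rng(0)
        return ECGRecord(signal=rng.normal(size=(1, length)), sampling_rate=fs,
                         lead_names=["MLII"], annotations=annotations)

    def test_exact_boundary_fit(self):
        record = self.make_record(235, [(117, "N")])
        beats = segment_beats(record, window=235)
        assert len(beats) == 1 and beats[0].length == 235
        np.testing.assert_array_equal(beats[0].samples[0], record.signal[0])

    def test_edge_annotation_discarded(self):
        record = self.make_record(235, [(50, "N")])
        assert segment_beats(record, window=235) == []

    def test_counts_after_edge_and_symbol_filtering(self):
        anns = [(300 + 200 * i, "N") for i in range(10)]      # 10 interior beats
        anns += [(30, "N"), (2950, "N")]                       # 2 edge discards
        anns += [(800, "+"), (900, "~")]                       # non-beat symbols
        record = self.make_record(3000, sorted(anns))
        beats = segment_beats(record, window=235)
        assert len(beats) == 10
        assert all(b.label == "N" for b in beats)
        assert all(b.length == 235 for b in beats)

    def test_window_centering(self):
        record = self.make_record(1000, [(500, "V")])
        beat = segment_beats(record, window=235)[0]
        np.testing.assert_array_equal(beat.samples[0],
                                      record.signal[0, 500 - 117: 500 + 118])

    def test_idempotent_and_order_stable(self):
        record = self.make_record(3000, [(500, "N"), (1000, "V"), (1500, "A")])
        a = segment_beats(record, window=235)
        b = segment_beats(record, window=235)
        assert [x.source_id for x in a] == [x.source_id for x in b]
        assert [x.label for x in a] == ["N", "V", "S"]


class TestBalanceAndSplit:
    def make_labelled(self, counts, t_len=32):
        rng = np.random.default_rng(1)
        beats = []
        for label, n in counts.items():
            for i in range(n):
                beats.append(ECGBeat(samples=rng.normal(size=(1, t_len)),
                                     label=label, source_id=f"{label}-{i}"))
        return beats

    def test_five_classes_600_test_beats(self):
        beats = self.make_labelled({c: 500 for c in "NSVFQ"})
        split = balance_and_split(beats, ratio=(3, 1), n_test=600, seed=0)
        assert split.per_class_test == {c: 120 for c in "NSVFQ"}
        assert split.per_class_train == {c: 360 for c in "NSVFQ"}
        assert len(split.test) == 600

    def test_seeded_membership_is_reproducible(self):
        beats = self.make_labelled({"a": 40, "b": 40})
        s1 = balance_and_split(beats, seed=7)
        s2 = balance_and_split(beats, seed=7)
        assert [b.source_id for b in s1.train] == [b.source_id for b in s2.train]
        assert [b.source_id for b in s1.test] == [b.source_id for b in s2.test]

    def test_partitions_disjoint(self):
        beats = self.make_labelled({"a": 40, "b": 40})
        split = balance_and_split(beats, seed=3)
        train_ids = {b.source_id for b in split.train}
        test_ids = {b.source_id for b in split.test}
        assert not train_ids & test_ids

    def test_shortfall_names_the_class(self):
        beats = self.make_labelled({"a": 100, "b": 10})
        with pytest.raises(ValueError, match="'b'"):
            balance_and_split(beats, n_test=40, seed=0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balance_and_split(self.make_labelled({"a": 40}))


class TestCsvBeatTables:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        beats = [ECGBeat(samples=rng.normal(size=(1, 16)), label="N",
                         source_id=f"r:{i}") for i in range(5)]
        path = tmp_path / "beats.csv"
        beats_to_csv(beats, path)
        loaded = read_beats_csv(path)
        assert len(loaded) == 5
        for a, b in zip(beats, loaded):
            np.testing.assert_allclose(a.samples, b.samples, atol=1e-12)
            assert (a.label, a.source_id) == (b.label, b.source_id)

    def test_multichannel_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            beats_to_csv([ECGBeat(samples=np.zeros((2, 8)))], tmp_path / "x.csv")


def test_mitdb_record_100_metadata():
    """MIT-BIH record 100 is 360 Hz with MLII as the first lead. Needs a
    local copy of the database; skipped when it is not present."""
    if not (MITDB_DIR / "100.hea").exists():
        pytest.skip(f"MIT-BIH database not present at {MITDB_DIR}")
    record = read_wfdb_record(MITDB_DIR / "100")
    assert record.sampling_rate == 360.0
    assert record.lead_names[0] == "MLII"
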