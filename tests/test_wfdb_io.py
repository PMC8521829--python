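"""WFDB reader/writer round trips and the 10-s segmentation rule."""

import numpy as np
import pytest

from ecgtb.synthetic import generate_dataset
from ecgtb.wfdb_io import (
    AnnotationStream,
    SegmentationRule,
    extract_segments,
    read_record,
    write_dataset_wfdb,
    write_record,
)


def test_record_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    samples = rng.normal(0, 0.5, 2000)
    ann = AnnotationStream(
        beat_marks=[(100, "N"), (500, "V"), (900, "A"), (1500, "N")],
        rhythm_marks=[(0, "(N"), (800, "(AFIB"), (1400, "(N")],
    )
    hea = write_record(tmp_path, "r1", samples, 250.0, ann, gain=200.0)
    got, fs, got_ann = read_record(hea)
    assert fs == 250.0
    assert len(got) == len(samples)
    # format-16 quantization error is at most half an ADC step
    assert np.max(np.abs(got - samples)) <= 0.5 / 200.0 + 1e-12
    assert got_ann.beat_marks == ann.beat_marks
    assert got_ann.rhythm_marks == ann.rhythm_marks


def test_round_trip_with_long_gaps(tmp_path):
    """Annotation deltas >= 1024 samples exercise the SKIP pseudo-annotation."""
    samples = np.zeros(20000)
    ann = AnnotationStream(beat_marks=[(10, "N"), (15000, "V"), (19999, "A")])
    hea = write_record(tmp_path, "gap", samples, 360.0, ann)
    _, _, got_ann = read_record(hea)
    assert got_ann.beat_marks == ann.beat_marks


def test_format_212_parsing(tmp_path):
    """Hand-packed 12-bit sample pairs decode to the expected ADC counts."""
    pairs = [(1, 2), (-1, -2048), (2047, 0)]

    def pack(a, b):
        a &= 0xFFF
        b &= 0xFFF
        return bytes([a & 0xFF, ((b >> 4) & 0xF0) | ((a >> 8) & 0x0F), b & 0xFF])

    (tmp_path / "f212.dat").write_bytes(b"".join(pack(a, b) for a, b in pairs))
    (tmp_path / "f212.hea").write_text(
        "f212 1 360 6\nf212.dat 212 200(0)/mV 12 0 0 0 0 ECG\n"
    )
    samples, fs, _ = read_record(tmp_path / "f212.hea")
    flat = [v for p in pairs for v in p]
    np.testing.assert_allclose(samples, np.asarray(flat) / 200.0)


def test_annotation_stream_validation():
    with pytest.raises(ValueError, match="non-decreasing"):
        AnnotationStream(beat_marks=[(100, "N"), (50, "N")])


def test_extract_segments_strict_homogeneity():
    fs, win = 100.0, 1000  # 10-s windows of 1000 samples
    samples = np.zeros(3 * win)
    ann = AnnotationStream(
        beat_marks=[
            (100, "N"), (500, "N"),            # window 0: pure Norm
            (win + 100, "N"), (win + 500, "V"),  # window 1: mixed -> dropped
            (2 * win + 100, "V"), (2 * win + 500, "V"),  # window 2: pure PVC
        ]
    )
    segs = extract_segments(samples, fs, ann, SegmentationRule(), record_id="x")
    assert [s.label for s in segs] == ["Norm", "PVC"]
    assert [s.start_sample for s in segs] == [0, 2 * win]
    assert all(len(s.samples) == win for s in segs)


def test_extract_segments_majority_homogeneity():
    fs, win = 100.0, 1000
    samples = np.zeros(2 * win)
    ann = AnnotationStream(
        beat_marks=[
            (100, "N"), (300, "N"), (500, "V"),  # majority Norm
            (win + 100, "N"), (win + 500, "V"),  # tie -> dropped
        ]
    )
    rule = SegmentationRule(homogeneity="majority")
    segs = extract_segments(samples, fs, ann, rule)
    assert [s.label for s in segs] == ["Norm"]


def test_afib_span_overrides_beat_codes():
    fs, win = 100.0, 1000
    samples = np.zeros(2 * win)
    ann = AnnotationStream(
        beat_marks=[(100, "N"), (win + 100, "N")],
        rhythm_marks=[(0, "(AFIB"), (win, "(N")],
    )
    segs = extract_segments(samples, fs, ann, SegmentationRule())
    assert [s.label for s in segs] == ["AF", "Norm"]


def test_windows_without_beats_discarded():
    fs, win = 100.0, 1000
    samples = np.zeros(2 * win)
    ann = AnnotationStream(beat_marks=[(win + 100, "N")])
    segs = extract_segments(samples, fs, ann, SegmentationRule())
    assert [s.start_sample for s in segs] == [win]


def test_empty_annotations_warn_and_return_nothing():
    with pytest.warns(UserWarning, match="empty annotation"):
        assert extract_segments(np.zeros(1000), 100.0, AnnotationStream()) == []


def test_dataset_round_trip_through_wfdb(tmp_path):
    """Synthetic segments written as one WFDB record segment back with the
    same labels in the same order."""
    segments = generate_dataset({"Norm": 3, "AF": 2, "PVC": 2, "APB": 2}, seed=9)
    hea = write_dataset_wfdb(segments, tmp_path, "syn")
    samples, fs, ann = read_record(hea)
    assert fs == 360.0
    assert len(samples) == sum(len(s.samples) for s in segments)
    got = extract_segments(samples, fs, ann, SegmentationRule(), record_id="syn")
    assert [s.label for s in got] == [s.label for s in segments]
    # signal content survives up to ADC quantization
    first = segments[0].samples
    assert np.max(np.abs(samples[: len(first)] - first)) <= 0.5 / 200.0 + 1e-12


def test_segmentation_rule_validation():
    with pytest.raises(ValueError):
        SegmentationRule(segment_len=0.0)
    with pytest.raises(ValueError):
        SegmentationRule(homogeneity="bogus")


def test_read_record_missing_files(tmp_path):
    with pytest.raises(IOError, match="header"):
        read_record(tmp_path / "nope")
    (tmp_path / "r.hea").write_text("r 1 360 100\nr.dat 16 200(0)/mV 16 0 0 0 0 ECG\n")
    with pytest.raises(IOError, match="signal"):
        read_record(tmp_path / "r.hea")
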