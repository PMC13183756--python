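"""Segment I/O: parsing, time-of-day filtering, windowing, counting."""

import numpy as np
import pytest

from vocalib.segments_io import (
    ClipCounts,
    Segment,
    filter_time_of_day,
    read_clip_counts,
    read_metadata,
    read_segments,
    recording_counts,
    window_counts,
    write_clip_counts,
    write_segments,
)
from vocalib.speakers import SpeakerClass

CSV_HEADER = "recording_id,annotator_id,speaker_type,segment_onset,segment_offset\n"


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


# -------------------------------------------------------------------- parsing


def test_csv_millisecond_conversion(tmp_path):
    path = write(tmp_path, "a.csv", CSV_HEADER + "rec1,human,FEM,1000,2500\n")
    (seg,) = read_segments(path)
    assert seg.speaker is SpeakerClass.FEM
    assert seg.onset == 1.0 and seg.offset == 2.5


def test_csv_without_annotator_column(tmp_path):
    path = write(
        tmp_path,
        "a.csv",
        "recording_id,speaker_type,segment_onset,segment_offset\nrec1,CHI,0,400\n",
    )
    (seg,) = read_segments(path, annotator_id="coder1")
    assert seg.annotator_id == "coder1"


def test_empty_csv(tmp_path):
    path = write(tmp_path, "a.csv", CSV_HEADER)
    assert read_segments(path) == []


def test_unknown_labels_dropped_and_logged(tmp_path, caplog):
    path = write(
        tmp_path,
        "a.csv",
        CSV_HEADER + "rec1,human,FEM,0,100\nrec1,human,TVN,100,300\nrec1,human,SIL,400,600\n",
    )
    with caplog.at_level("INFO", logger="vocalib.segments_io"):
        segments = read_segments(path)
    assert len(segments) == 1
    assert any("dropped 2" in rec.message for rec in caplog.records)


def test_malformed_csv_names_line(tmp_path):
    path = write(tmp_path, "a.csv", CSV_HEADER + "rec1,human,FEM,500,100\n")
    with pytest.raises(ValueError, match="line 2"):
        read_segments(path)


def test_rttm_parsing(tmp_path):
    path = write(
        tmp_path,
        "a.rttm",
        "SPEAKER rec1 1 3.50 1.25 <NA> <NA> CHI <NA> <NA>\n"
        "SPEAKER rec1 1 5.00 0.80 <NA> <NA> FEM <NA> <NA>\n",
    )
    segments = read_segments(path, annotator_id="vtc")
    assert [s.speaker for s in segments] == [SpeakerClass.CHI, SpeakerClass.FEM]
    assert segments[0].offset == pytest.approx(4.75)


def test_rttm_nonpositive_duration_fails_at_line(tmp_path):
    path = write(
        tmp_path,
        "a.rttm",
        "SPEAKER rec1 1 3.50 1.25 <NA> <NA> CHI <NA> <NA>\n"
        "SPEAKER rec1 1 5.00 0.00 <NA> <NA> FEM <NA> <NA>\n",
    )
    with pytest.raises(ValueError, match="line 2"):
        read_segments(path)


def test_unknown_format_rejected(tmp_path):
    path = write(tmp_path, "a.xyz", "")
    with pytest.raises(ValueError, match="format"):
        read_segments(path, format="xyz")
    with pytest.raises(FileNotFoundError):
        read_segments(tmp_path / "missing.csv")


def test_roundtrip_is_idempotent(tmp_path):
    segments = [
        Segment("rec1", "human", SpeakerClass.CHI, 0.25, 1.5),
        Segment("rec1", "vtc", SpeakerClass.MAL, 10.0, 12.75),
        Segment("rec2", "human", SpeakerClass.OCH, 3.0, 3.125),
    ]
    path = tmp_path / "out.csv"
    write_segments(segments, path)
    back = read_segments(path)
    assert back == segments
    write_segments(back, tmp_path / "out2.csv")
    assert (tmp_path / "out2.csv").read_text() == path.read_text()


def test_segment_invariants():
    with pytest.raises(ValueError):
        Segment("r", "h", SpeakerClass.CHI, 2.0, 1.0)
    with pytest.raises(ValueError):
        Segment("r", "h", SpeakerClass.CHI, -1.0, 1.0)


# ------------------------------------------------------------------ filtering


def test_time_of_day_half_open_bounds():
    start = {"rec1": "09:00"}

    def seg(onset_clock_minutes):
        onset = onset_clock_minutes * 60.0 - 9 * 3600.0
        return Segment("rec1", "h", SpeakerClass.CHI, onset, onset + 1.0)

    segments = [seg(9 * 60 + 59), seg(10 * 60), seg(17 * 60 + 59), seg(18 * 60)]
    kept = filter_time_of_day(segments, start)
    onsets = [s.onset for s in kept]
    assert onsets == [segments[1].onset, segments[2].onset]


def test_time_of_day_missing_start_clock():
    segments = [Segment("unknown_rec", "h", SpeakerClass.CHI, 0.0, 1.0)]
    with pytest.raises(ValueError, match="unknown_rec"):
        filter_time_of_day(segments, {})


# ------------------------------------------------------------------ windowing


def test_two_minute_clip_yields_eight_windows():
    out = window_counts([], {"clip1": ("rec1", 0.0, 120.0)})
    assert len(out) == 8
    assert all(np.array_equal(c.v, np.zeros(4)) for c in out)


def test_non_multiple_duration_rejected():
    with pytest.raises(ValueError, match="multiple"):
        window_counts([], {"clip1": ("rec1", 0.0, 100.0)})


def test_onset_rule_boundary_assignment():
    segments = [
        Segment("rec1", "human", SpeakerClass.FEM, 1.0, 2.0),
        Segment("rec1", "human", SpeakerClass.FEM, 5.0, 6.0),
        Segment("rec1", "human", SpeakerClass.FEM, 9.0, 10.0),
        # onset at 14.9 s straddles the window boundary: counted in window 0
        Segment("rec1", "human", SpeakerClass.CHI, 14.9, 16.0),
    ]
    out = window_counts(segments, {"clip1": ("rec1", 0.0, 30.0)})
    w0, w1 = out
    assert w0.v[SpeakerClass.FEM] == 3 and w0.v[SpeakerClass.CHI] == 1
    assert w1.v.sum() == 0


def test_window_sums_match_totals_and_order_invariance(rng):
    segments = []
    for k in range(60):
        onset = float(rng.uniform(0, 120))
        speaker = SpeakerClass(int(rng.integers(4)))
        annot = "human" if rng.random() < 0.5 else "vtc"
        segments.append(Segment("rec1", annot, speaker, onset, onset + 0.5))
    bounds = {"clip1": ("rec1", 0.0, 120.0)}
    out = window_counts(segments, bounds)
    total_v = sum(c.v for c in out)
    total_n = sum(c.n["vtc"] for c in out)
    by_annot = recording_counts(segments)["rec1"]
    assert np.array_equal(total_v, by_annot["human"])
    assert np.array_equal(total_n, by_annot["vtc"])
    shuffled = list(segments)
    rng.shuffle(shuffled)
    out2 = window_counts(shuffled, bounds)
    assert all(np.array_equal(a.v, b.v) for a, b in zip(out, out2))


# ------------------------------------------------------------------- counting


def test_recording_counts_expert_example():
    # two female-adult vocalizations found by the expert
    segments = [
        Segment("rec1", "expert", SpeakerClass.FEM, 0.0, 1.0),
        Segment("rec1", "expert", SpeakerClass.FEM, 2.0, 3.0),
        Segment("rec1", "expert", SpeakerClass.CHI, 4.0, 5.0),
    ]
    counts = recording_counts(segments)
    assert counts["rec1"]["expert"][SpeakerClass.FEM] == 2


def test_recording_counts_additivity():
    seg_a = [Segment("a", "h", SpeakerClass.CHI, 0.0, 1.0)]
    seg_b = [Segment("b", "h", SpeakerClass.CHI, 0.0, 1.0)] * 2
    merged = recording_counts(seg_a + seg_b)
    assert merged["a"]["h"][0] == 1 and merged["b"]["h"][0] == 2
    assert recording_counts([]) == {}


# ----------------------------------------------------------------- clip files


def test_clip_counts_roundtrip(tmp_path):
    clips = [
        ClipCounts("c0:0", "rec1", 0, np.array([1, 0, 2, 0]), {"vtc": np.array([1, 1, 1, 0])}),
        ClipCounts("c0:1", "rec1", 1, np.array([0, 0, 0, 0]), {"vtc": np.array([0, 0, 1, 0])}),
    ]
    path = tmp_path / "clips.csv"
    write_clip_counts(clips, path)
    back = read_clip_counts(path)
    assert len(back) == 2
    assert np.array_equal(back[0].v, clips[0].v)
    assert np.array_equal(back[1].n["vtc"], clips[1].n["vtc"])


def test_metadata_requires_columns(tmp_path):
    path = tmp_path / "meta.csv"
    path.write_text("recording_id,child_id\nr1,c1\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_metadata(path)
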