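"""Reading, filtering and counting diarization segments.

A *segment* is one labeled speech interval (a "vocalization"): speaker
class, onset and offset within a recording, plus the annotator (human or
classifier) that produced it.  Two plain-text formats are supported:

* CSV with columns ``recording_id, speaker_type, segment_onset,
  segment_offset`` (onset/offset in integer milliseconds) and an optional
  ``annotator_id`` column;
* RTTM ``SPEAKER`` records (times in seconds).

Intervals are half-open ``[onset, offset)``.  A vocalization is attributed
to the 15-s window containing its *onset*, which avoids double counting and
is independent of segment ordering.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .speakers import N_CLASSES, SPEAKER_LABELS, SpeakerClass

__all__ = [
    "Segment",
    "ClipCounts",
    "RecordingRecord",
    "read_segments",
    "write_segments",
    "read_metadata",
    "filter_time_of_day",
    "window_counts",
    "recording_counts",
    "build_recording_records",
    "read_clip_counts",
    "write_clip_counts",
]

logger = logging.getLogger(__name__)

CSV_COLUMNS = ("recording_id", "annotator_id", "speaker_type", "segment_onset", "segment_offset")
METADATA_COLUMNS = ("recording_id", "child_id", "corpus_id", "age_months", "n_siblings")


@dataclass(frozen=True)
class Segment:
    """One labeled vocalization within a recording (times in seconds)."""

    recording_id: str
    annotator_id: str
    speaker: SpeakerClass
    onset: float
    offset: float

    def __post_init__(self):
        if not (np.isfinite(self.onset) and np.isfinite(self.offset)):
            raise ValueError("segment times must be finite")
        if self.onset < 0:
            raise ValueError("segment onset must be >= 0")
        if self.offset <= self.onset:
            raise ValueError("segment offset must be greater than onset")


@dataclass
class ClipCounts:
    """Per 15-s window, paired true and classifier counts (CHI,OCH,FEM,MAL)."""

    clip_id: str
    recording_id: str
    window_index: int
    v: np.ndarray
    n: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=np.int64)
        if self.v.shape != (N_CLASSES,) or np.any(self.v < 0):
            raise ValueError("v must be a length-4 vector of non-negative integers")
        self.n = {k: np.asarray(a, dtype=np.int64) for k, a in self.n.items()}
        for key, arr in self.n.items():
            if arr.shape != (N_CLASSES,) or np.any(arr < 0):
                raise ValueError(f"counts for {key!r} must be length-4 and non-negative")


@dataclass
class RecordingRecord:
    """Recording-level metadata and per-annotator counts."""

    recording_id: str
    child_id: str
    corpus_id: str
    age_months: float
    n_siblings: int
    n: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.age_months < 0:
            raise ValueError("age_months must be >= 0")
        if self.n_siblings < 0:
            raise ValueError("n_siblings must be >= 0")
        self.n = {k: np.asarray(a, dtype=np.int64) for k, a in self.n.items()}


def _parse_csv(path: Path, default_annotator: str) -> list[Segment]:
    frame = pd.read_csv(path, dtype={"recording_id": str})
    required = {"recording_id", "speaker_type", "segment_onset", "segment_offset"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns: {sorted(missing)}")
    if "annotator_id" not in frame.columns:
        frame["annotator_id"] = default_annotator
    segments, dropped = [], 0
    for row in frame.itertuples():
        lineno = row.Index + 2  # header line + 1-based
        label = str(row.speaker_type).strip().upper()
        if label not in SPEAKER_LABELS:
            dropped += 1
            continue
        try:
            segments.append(
                Segment(
                    recording_id=str(row.recording_id),
                    annotator_id=str(row.annotator_id),
                    speaker=SpeakerClass[label],
                    onset=float(row.segment_onset) / 1000.0,
                    offset=float(row.segment_offset) / 1000.0,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed segment on line {lineno}: {exc}") from exc
    if dropped:
        logger.info("%s: dropped %d segments with out-of-scope speaker labels", path, dropped)
    return segments


def _parse_rttm(path: Path, default_annotator: str) -> list[Segment]:
    segments, dropped = [], 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 8 or fields[0] != "SPEAKER":
            raise ValueError(f"{path}: malformed RTTM line {lineno}: {line!r}")
        label = fields[7].strip().upper()
        if label not in SPEAKER_LABELS:
            dropped += 1
            continue
        try:
            onset = float(fields[3])
            duration = float(fields[4])
            segments.append(
                Segment(
                    recording_id=fields[1],
                    annotator_id=default_annotator,
                    speaker=SpeakerClass[label],
                    onset=onset,
                    offset=onset + duration,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: malformed RTTM line {lineno}: {exc}") from exc
    if dropped:
        logger.info("%s: dropped %d segments with out-of-scope speaker labels", path, dropped)
    return segments


def read_segments(path, format: str | None = None, annotator_id: str = "human") -> list[Segment]:
    """Read a segment table; ``format`` is ``"csv"`` or ``"rttm"``.

    If ``format`` is omitted it is inferred from the file suffix.  Speaker
    labels outside {CHI, OCH, FEM, MAL} (e.g., electronic noise) are dropped
    and the dropped count is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "csv":
        return _parse_csv(path, annotator_id)
    if format == "rttm":
        return _parse_rttm(path, annotator_id)
    raise ValueError(f"unknown segment format: {format!r} (expected 'csv' or 'rttm')")


def write_segments(segments: Iterable[Segment], path) -> None:
    """Write segments as the canonical CSV (milliseconds, UTF-8)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_COLUMNS)
        for seg in segments:
            writer.writerow(
                [
                    seg.recording_id,
                    seg.annotator_id,
                    seg.speaker.name,
                    round(seg.onset * 1000),
                    round(seg.offset * 1000),
                ]
            )


def read_metadata(path) -> pd.DataFrame:
    """Read the recording-metadata CSV (one row per recording)."""
    frame = pd.read_csv(path, dtype={"recording_id": str, "child_id": str, "corpus_id": str})
    missing = set(METADATA_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: metadata is missing columns: {sorted(missing)}")
    return frame


def _clock_to_seconds(clock: str) -> float:
    hours, minutes = clock.split(":")
    return 3600.0 * int(hours) + 60.0 * int(minutes)


def filter_time_of_day(
    segments: Iterable[Segment],
    recording_start_clock: Mapping[str, str],
    lo: str = "10:00",
    hi: str = "18:00",
) -> list[Segment]:
    """Keep segments whose onset clock time lies in the half-open [lo, hi).

    ``recording_start_clock`` maps recording id to its start time ("HH:MM").
    Restricting analysis to a fixed daytime range makes recordings of
    different lengths and start times comparable.
    """
    segments = list(segments)
    known = set(recording_start_clock)
    unknown = sorted({s.recording_id for s in segments} - known)
    if unknown:
        raise ValueError(f"missing start clock time for recordings: {unknown}")
    lo_s, hi_s = _clock_to_seconds(lo), _clock_to_seconds(hi)
    kept = []
    for seg in segments:
        clock = _clock_to_seconds(recording_start_clock[seg.recording_id]) + seg.onset
        if lo_s <= clock < hi_s:
            kept.append(seg)
    return kept


def window_counts(
    segments: Iterable[Segment],
    clip_bounds: Mapping[str, tuple[str, float, float]],
    window_s: float = 15.0,
    truth_annotator: str = "human",
) -> list[ClipCounts]:
    """Split annotated clips into fixed windows and count vocalizations.

    ``clip_bounds`` maps clip id to ``(recording_id, clip_onset,
    clip_offset)`` in seconds; every clip duration must be a multiple of
    ``window_s``.  A vocalization is counted in the window containing its
    onset.  Counts from ``truth_annotator`` populate ``v``; every other
    annotator's counts go into the ``n`` map.
    """
    out: list[ClipCounts] = []
    index: dict[tuple[str, int], ClipCounts] = {}
    for clip_id, (recording_id, onset, offset) in clip_bounds.items():
        duration = offset - onset
        n_win = duration / window_s
        if abs(n_win - round(n_win)) > 1e-9 or duration <= 0:
            raise ValueError(
                f"clip {clip_id!r} duration {duration:g}s is not a positive multiple of {window_s:g}s"
            )
        for w in range(int(round(n_win))):
            cc = ClipCounts(
                clip_id=f"{clip_id}:{w}",
                recording_id=recording_id,
                window_index=w,
                v=np.zeros(N_CLASSES, dtype=np.int64),
            )
            out.append(cc)
            index[(clip_id, w)] = cc
    for seg in segments:
        for clip_id, (recording_id, onset, offset) in clip_bounds.items():
            if seg.recording_id != recording_id or not (onset <= seg.onset < offset):
                continue
            w = int((seg.onset - onset) // window_s)
            cc = index[(clip_id, w)]
            if seg.annotator_id == truth_annotator:
                cc.v[seg.speaker] += 1
            else:
                if seg.annotator_id not in cc.n:
                    cc.n[seg.annotator_id] = np.zeros(N_CLASSES, dtype=np.int64)
                cc.n[seg.annotator_id][seg.speaker] += 1
    # every window carries a (possibly zero) count vector for every annotator
    annotators = {s.annotator_id for s in segments} - {truth_annotator}
    for cc in out:
        for name in annotators:
            cc.n.setdefault(name, np.zeros(N_CLASSES, dtype=np.int64))
    return out


def write_clip_counts(clips: Iterable[ClipCounts], path) -> None:
    """Write windowed counts as tidy CSV (one row per window and annotator)."""
    rows = []
    for clip in clips:
        base = {
            "clip_id": clip.clip_id,
            "recording_id": clip.recording_id,
            "window_index": clip.window_index,
        }
        rows.append({**base, "annotator_id": "human", **dict(zip(SPEAKER_LABELS, clip.v))})
        for name, counts in sorted(clip.n.items()):
            rows.append({**base, "annotator_id": name, **dict(zip(SPEAKER_LABELS, counts))})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_clip_counts(path, truth_annotator: str = "human") -> list[ClipCounts]:
    """Read windowed counts written by :func:`write_clip_counts`."""
    frame = pd.read_csv(path, dtype={"clip_id": str, "recording_id": str})
    clips = []
    for (clip_id, rec_id, w), group in frame.groupby(
        ["clip_id", "recording_id", "window_index"], sort=False
    ):
        by_annot = {
            row.annotator_id: np.array([getattr(row, s) for s in SPEAKER_LABELS], dtype=np.int64)
            for row in group.itertuples()
        }
        if truth_annotator not in by_annot:
            raise ValueError(f"{path}: window {clip_id!r} lacks {truth_annotator!r} counts")
        v = by_annot.pop(truth_annotator)
        clips.append(
            ClipCounts(clip_id=clip_id, recording_id=rec_id, window_index=int(w), v=v, n=by_annot)
        )
    return clips


def recording_counts(segments: Iterable[Segment]) -> dict[str, dict[str, np.ndarray]]:
    """Count vocalizations per recording, annotator and speaker class.

    Returns ``counts[recording_id][annotator_id]`` as a length-4 vector.
    """
    counts: dict[str, dict[str, np.ndarray]] = {}
    for seg in segments:
        rec = counts.setdefault(seg.recording_id, {})
        if seg.annotator_id not in rec:
            rec[seg.annotator_id] = np.zeros(N_CLASSES, dtype=np.int64)
        rec[seg.annotator_id][seg.speaker] += 1
    return counts


def build_recording_records(
    segments: Iterable[Segment], metadata: pd.DataFrame
) -> list[RecordingRecord]:
    """Join per-recording counts with the metadata table."""
    counts = recording_counts(segments)
    records = []
    for row in metadata.itertuples():
        records.append(
            RecordingRecord(
                recording_id=row.recording_id,
                child_id=row.child_id,
                corpus_id=row.corpus_id,
                age_months=float(row.age_months),
                n_siblings=int(row.n_siblings),
                n=counts.get(row.recording_id, {}),
            )
        )
    return records
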