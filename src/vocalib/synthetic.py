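"""Synthetic fixtures: calibration clips, corpora, classifier outputs.

Everything the fits and tests consume can be generated here with no
external data: 15-s calibration windows with paired true/classifier counts,
and full longitudinal corpora (metadata + true counts + classifier counts +
a truth sidecar for scoring).  All generators are deterministic given the
seed, and their file outputs parse back through the package loaders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import BehaviorParams, SyntheticCorpus, simulate_true_counts
from .calibration import CalibrationDataset, dataset_from_frames, simulate_classifier_counts
from .confusion import (
    ConfusionProfile,
    precision_biased_profile,
    recall_biased_profile,
    sample_confusion,
    simulate_counts,
)
from .segments_io import ClipCounts
from .speakers import N_CLASSES, SPEAKER_LABELS

__all__ = ["FixtureSpec", "make_calibration_clips", "make_corpus", "write_corpus", "load_corpus"]

#: mean true vocalizations per speaker in a 15-s calibration window
DEFAULT_WINDOW_MEANS = (1.2, 0.5, 1.8, 0.8)


@dataclass
class FixtureSpec:
    """Sizes, parameters and profiles for the synthetic generators."""

    n_children: int = 50
    recordings_per_child: int = 3
    n_clip_recordings: int = 10
    windows_per_recording: int = 30
    window_means: tuple = DEFAULT_WINDOW_MEANS
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    profiles: dict = field(
        default_factory=lambda: {
            "recall_biased": recall_biased_profile(),
            "precision_biased": precision_biased_profile(),
        }
    )
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_children", "recordings_per_child", "n_clip_recordings", "windows_per_recording"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def make_calibration_clips(spec: FixtureSpec) -> list[ClipCounts]:
    """Simulate human-annotated 15-s windows and the classifiers' counts.

    True counts per window are Poisson around ``spec.window_means``;
    each recording gets its own confusion-rate draw per classifier, then
    per-window counts from the double-Poisson confusion model.
    """
    rng = np.random.default_rng(spec.rng_seed)
    clips = []
    for r in range(spec.n_clip_recordings):
        rec_id = f"calib{r:03d}"
        draws = {name: sample_confusion(p, rng) for name, p in spec.profiles.items()}
        for w in range(spec.windows_per_recording):
            v = rng.poisson(spec.window_means).astype(np.int64)
            n = {
                name: simulate_counts(v, draws[name], spec.profiles[name].tau, rng)
                for name in spec.profiles
            }
            clips.append(
                ClipCounts(
                    clip_id=f"{rec_id}:{w}",
                    recording_id=rec_id,
                    window_index=w,
                    v=v,
                    n=n,
                )
            )
    return clips


def make_corpus(spec: FixtureSpec) -> tuple[SyntheticCorpus, pd.DataFrame]:
    """Simulate a corpus and its classifier counts.

    Returns ``(corpus, counts)`` where ``counts`` is a tidy table with one
    row per (recording, annotator): the annotator ``"truth"`` rows hold the
    true counts, one row per classifier holds its simulated output.
    """
    rng = np.random.default_rng(spec.rng_seed)
    corpus = simulate_true_counts(
        spec.behavior, spec.n_children, spec.recordings_per_child, rng
    )
    frames = []
    truth = corpus.recordings[["recording_id"]].copy()
    truth["annotator_id"] = "truth"
    for s in SPEAKER_LABELS:
        truth[s] = corpus.recordings[f"v_{s}"]
    frames.append(truth)
    for name, profile in spec.profiles.items():
        meas = simulate_classifier_counts(corpus, profile, rng, classifier=name)
        block = meas[["recording_id"]].copy()
        block["annotator_id"] = name
        for s in SPEAKER_LABELS:
            block[s] = meas[f"n_{s}"]
        frames.append(block)
    counts = pd.concat(frames, ignore_index=True)
    return corpus, counts


def write_corpus(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Generate a corpus and write it as plain-text CSV files.

    ``metadata.csv`` (recording_id, child_id, corpus_id, age_months,
    n_siblings, start_clock), ``counts.csv`` (tidy per-annotator counts,
    classifiers only) and ``truth.csv`` (the sidecar with true counts and
    child-level latent state for scoring).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus, counts = make_corpus(spec)
    meta = corpus.recordings[
        ["recording_id", "child_id", "corpus_id", "age_months", "n_siblings"]
    ].copy()
    meta["start_clock"] = "10:00"
    paths = {
        "metadata": out / "metadata.csv",
        "counts": out / "counts.csv",
        "truth": out / "truth.csv",
    }
    meta.to_csv(paths["metadata"], index=False)
    counts[counts["annotator_id"] != "truth"].to_csv(paths["counts"], index=False)
    truth = corpus.recordings.merge(
        corpus.children[["child_id", "alpha_c_dev", "adult_input_level"]], on="child_id"
    )
    truth.to_csv(paths["truth"], index=False)
    return paths


def load_corpus(directory, classifier: str, clips=()) -> CalibrationDataset:
    """Load a written corpus back as a dataset for one classifier."""
    directory = Path(directory)
    from .segments_io import read_metadata

    meta = read_metadata(directory / "metadata.csv")
    counts = pd.read_csv(directory / "counts.csv", dtype={"recording_id": str})
    return dataset_from_frames(meta, counts, classifier, clips=clips)
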