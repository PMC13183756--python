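"""Agreement and association metrics for vocalization counts.

Pearson correlations between speakers' counts (at clip, recording or child
level), intraclass correlation between two raters' counts on the same
units, and derived speech-quantity measures.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .speakers import SPEAKER_LABELS, SpeakerClass

__all__ = ["pearson_by_speaker_pair", "icc", "female_adult_proportion"]

LEVEL_KEYS = {"clip": "clip_id", "recording": "recording_id", "child": "child_id"}


def _aggregate(counts: pd.DataFrame, level: str) -> pd.DataFrame:
    if level not in LEVEL_KEYS:
        raise ValueError(f"level must be one of {sorted(LEVEL_KEYS)}")
    key = LEVEL_KEYS[level]
    if key not in counts.columns:
        raise ValueError(f"counts table lacks the {key!r} column required for level={level!r}")
    cols = list(SPEAKER_LABELS)
    if level == "clip":
        return counts[cols]
    if level == "recording":
        return counts.groupby(key)[cols].sum()
    # child level: mean of recording-level counts per child
    if "recording_id" in counts.columns:
        per_rec = counts.groupby(["child_id", "recording_id"])[cols].sum()
        return per_rec.groupby("child_id").mean()
    return counts.groupby(key)[cols].mean()


def pearson_by_speaker_pair(counts: pd.DataFrame, level: str = "recording"):
    """Pairwise Pearson correlations between speakers' counts.

    ``counts`` is a tidy table with columns CHI, OCH, FEM, MAL plus the unit
    identifiers required by ``level`` (clip_id / recording_id / child_id).
    Returns ``(tidy, R)`` where ``tidy`` has one row per ordered speaker
    pair (speaker_i, speaker_j, level, R, p, N) and ``R`` is the symmetric
    4x4 correlation matrix as a DataFrame.  Constant columns give NaN
    entries, flagged with a warning, never a silent zero.
    """
    data = _aggregate(counts, level)
    n = len(data)
    if n < 3:
        raise ValueError("need at least 3 units to estimate a correlation")
    R = np.eye(4)
    P = np.zeros((4, 4))
    rows = []
    for i, si in enumerate(SPEAKER_LABELS):
        for j, sj in enumerate(SPEAKER_LABELS):
            if i < j:
                x, y = data[si].to_numpy(float), data[sj].to_numpy(float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    warnings.warn(
                        f"constant counts for {si if np.ptp(x) == 0 else sj}: "
                        "correlation undefined",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    r, p = np.nan, np.nan
                else:
                    res = pearsonr(x, y)
                    r, p = float(res.statistic), float(res.pvalue)
                R[i, j] = R[j, i] = r
                P[i, j] = P[j, i] = p
            if i != j:
                rows.append(
                    {
                        "speaker_i": si,
                        "speaker_j": sj,
                        "level": level,
                        "R": R[i, j] if i < j else R[j, i],
                        "p": P[i, j] if i < j else P[j, i],
                        "N": n,
                    }
                )
    matrix = pd.DataFrame(R, index=SPEAKER_LABELS, columns=SPEAKER_LABELS)
    return pd.DataFrame(rows), matrix


_ICC_ALIASES = {
    "ICC1": "ICC(1,1)",
    "ICC2": "ICC(A,1)",
    "ICC3": "ICC(C,1)",
}


def icc(x, y, variant: str = "ICC2") -> float:
    """Intraclass correlation between two raters' counts on the same units.

    Default is the two-way absolute-agreement single-measure form ICC(A,1) —
    appropriate when the raters' counts are meant to agree in absolute
    value, not merely co-vary.  Other variants ("ICC1" one-way, "ICC3"
    consistency) are accepted as sensitivity knobs; computation is
    delegated to pingouin.
    """
    import pingouin as pg

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired units")
    if np.ptp(np.concatenate([x, y])) == 0:
        warnings.warn("degenerate (constant) counts: ICC undefined", RuntimeWarning, stacklevel=2)
        return np.nan
    long = pd.DataFrame(
        {
            "unit": np.tile(np.arange(x.size), 2),
            "rater": np.repeat(["x", "y"], x.size),
            "score": np.concatenate([x, y]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(long, targets="unit", raters="rater", ratings="score")
    label = _ICC_ALIASES.get(variant, variant)
    return float(table.set_index("Type").loc[label, "ICC"])


def female_adult_proportion(counts) -> float:
    """Share of adult speech attributed to female adults: FEM / (FEM + MAL)."""
    counts = np.asarray(counts, dtype=float)
    fem, mal = counts[..., SpeakerClass.FEM], counts[..., SpeakerClass.MAL]
    total = fem + mal
    if np.any(total == 0):
        warnings.warn("FEM + MAL = 0: proportion undefined", RuntimeWarning, stacklevel=2)
        return np.nan if np.ndim(total) == 0 else np.where(total == 0, np.nan, fem / total)
    out = fem / total
    return float(out) if out.ndim == 0 else out
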