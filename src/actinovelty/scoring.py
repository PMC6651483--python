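"""Prediction-error novelty scoring of 8-second movement fragments.

A fragment is scored by the Pearson correlation between the forecaster's
2 s prediction and the observed 2 s continuation.  Fragments with
``r < th`` (default 0.5) are flagged "non-similar": movement patterns the
control-trained model could not anticipate.  Counts of non-similar
fragments per participant — overall and per intensity bin — are the
statistic the group comparison runs on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lstm import ForecasterParams, forward
from .segmentation import IntensityBins, assign_bin

_DEGENERATE_VARIANCE = 1e-12


class ScoringError(ValueError):
    pass


@dataclass
class FragmentScore:
    participant_id: str
    window_index: int
    r: float
    intensity_sd: float
    bin: int
    is_similar: bool


@dataclass
class ParticipantSummary:
    """Non-similar fragment counts for one participant."""

    participant_id: str
    group: str
    total_windows: int
    non_similar_total: int
    non_similar_per_bin: np.ndarray  # length n_bins
    windows_per_bin: np.ndarray = field(default=None)


def pearson(pred: np.ndarray, actual: np.ndarray, mode: str = "flat") -> float:
    """Pearson correlation between predicted and observed 2 s segments.

    ``mode='flat'`` correlates the two flattened 80-value vectors (channels
    concatenated); ``mode='per_channel_mean'`` averages the four per-channel
    correlations.  Either vector with variance below 1e-12 yields r = 0:
    an uninformative (constant) prediction must not count as a match.
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ScoringError(f"shape mismatch: {pred.shape} vs {actual.shape}")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(actual))):
        raise ScoringError("non-finite values in scored segments")
    if mode == "flat":
        return _pearson_1d(pred.ravel(), actual.ravel())
    if mode == "per_channel_mean":
        return float(
            np.mean(
                [_pearson_1d(pred[:, c], actual[:, c]) for c in range(pred.shape[1])]
            )
        )
    raise ScoringError(f"unknown pearson mode {mode!r}")


def _pearson_1d(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = np.var(a), np.var(b)
    if va < _DEGENERATE_VARIANCE or vb < _DEGENERATE_VARIANCE:
        return 0.0
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def score_participant(
    windows: list,
    models: ForecasterParams | dict,
    th: float = 0.5,
    bins: IntensityBins | None = None,
    group: str = "",
    pearson_mode: str = "flat",
) -> tuple:
    """Score every window of one participant and aggregate the counts.

    ``models`` is either a single ForecasterParams applied to all windows,
    or a mapping bin index -> ForecasterParams for per-intensity-interval
    models (a missing bin is a configuration error).
    """
    bins = bins or IntensityBins()
    if not windows:
        return [], ParticipantSummary(
            participant_id="",
            group=group,
            total_windows=0,
            non_similar_total=0,
            non_similar_per_bin=np.zeros(bins.n_bins, dtype=int),
            windows_per_bin=np.zeros(bins.n_bins, dtype=int),
        )
    bin_of = np.array([assign_bin(w.intensity_sd, bins) for w in windows])
    preds = [None] * len(windows)
    if isinstance(models, dict):
        for b in np.unique(bin_of):
            if int(b) not in models:
                raise ScoringError(f"no model configured for intensity bin {int(b)}")
            idx = np.flatnonzero(bin_of == b)
            batch = forward(models[int(b)], np.stack([windows[j].x for j in idx]))
            for j, p in zip(idx, batch):
                preds[j] = p
    else:
        batch = forward(models, np.stack([w.x for w in windows]))
        preds = list(batch)

    scores = []
    per_bin = np.zeros(bins.n_bins, dtype=int)
    windows_per_bin = np.zeros(bins.n_bins, dtype=int)
    for w, b, pred in zip(windows, bin_of, preds):
        r = pearson(pred, w.y, mode=pearson_mode)
        similar = r >= th
        scores.append(
            FragmentScore(
                participant_id=w.participant_id,
                window_index=w.window_index,
                r=r,
                intensity_sd=w.intensity_sd,
                bin=int(b),
                is_similar=bool(similar),
            )
        )
        windows_per_bin[b] += 1
        if not similar:
            per_bin[b] += 1
    summary = ParticipantSummary(
        participant_id=windows[0].participant_id,
        group=group,
        total_windows=len(windows),
        non_similar_total=int(per_bin.sum()),
        non_similar_per_bin=per_bin,
        windows_per_bin=windows_per_bin,
    )
    return scores, summary


def counts_at_threshold(
    scores: list, th: float, bins: IntensityBins
) -> ParticipantSummary:
    """Re-aggregate one participant's counts at a new similarity threshold
    from already-computed fragment correlations (no model re-run)."""
    per_bin = np.zeros(bins.n_bins, dtype=int)
    windows_per_bin = np.zeros(bins.n_bins, dtype=int)
    for s in scores:
        windows_per_bin[s.bin] += 1
        if s.r < th:
            per_bin[s.bin] += 1
    return ParticipantSummary(
        participant_id=scores[0].participant_id if scores else "",
        group="",
        total_windows=len(scores),
        non_similar_total=int(per_bin.sum()),
        non_similar_per_bin=per_bin,
        windows_per_bin=windows_per_bin,
    )


def scores_to_frame(scores: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "window_index": s.window_index,
                "r": s.r,
                "intensity_sd": s.intensity_sd,
                "bin": s.bin,
                "is_similar": s.is_similar,
            }
            for s in scores
        ]
    )


def summaries_to_frame(summaries: list, bins: IntensityBins) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "participant_id": s.participant_id,
            "group": s.group,
            "total_windows": s.total_windows,
            "non_similar_total": s.non_similar_total,
        }
        for b, label in enumerate(bins.labels()):
            row[f"non_similar_{label}"] = int(s.non_similar_per_bin[b])
        rows.append(row)
    return pd.DataFrame(rows)
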