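"""Model/Results interface over the movement-divergence pipeline.

``MovementNoveltyModel`` holds a segmented cohort (windows per participant
plus group labels) and the analysis configuration; ``fit()`` trains the
LSTM forecaster on the designated training controls, scores every held-out
participant, and returns a ``MovementNoveltyResults`` with the counts,
group comparisons, and reporting helpers::

    model = MovementNoveltyModel.from_cohort(cohort)
    res = model.fit()
    print(res.summary())
    res.per_bin_pvalues()          # DataFrame of p per (bin, case group)
    res.threshold_sweep(np.arange(0.3, 0.71, 0.1), case_group="atypical")
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lstm import ForecasterParams, TrainConfig, train
from .preprocessing import SyncParams, preprocess_participant
from .scoring import (
    ParticipantSummary,
    score_participant,
    scores_to_frame,
    summaries_to_frame,
)
from .segmentation import IntensityBins, assign_bin, segment_windows
from .stats import (
    GroupComparison,
    overall_comparisons,
    per_bin_comparisons,
    roc_auc,
    threshold_sweep,
)


class ModelError(ValueError):
    pass


class MovementNoveltyModel:
    """Movement-pattern divergence analysis bound to one segmented cohort.

    Parameters
    ----------
    windows : dict
        participant_id -> list of WindowPair.
    groups : dict
        participant_id -> group label.  The ``train_group`` participants
        supply the training windows and are excluded from scoring.
    bins : IntensityBins, optional
        Movement-intensity stratification (default edges 0..1 g by 0.2).
    """

    def __init__(
        self,
        windows: dict,
        groups: dict,
        bins: IntensityBins | None = None,
        train_group: str = "control_train",
        control_group: str = "control_test",
        case_groups: list | None = None,
    ):
        if set(windows) != set(groups):
            raise ModelError("windows and groups must cover the same participants")
        labels = set(groups.values())
        if train_group not in labels:
            raise ModelError(f"no participants in training group {train_group!r}")
        if control_group not in labels:
            raise ModelError(f"no participants in control group {control_group!r}")
        self.windows = windows
        self.groups = dict(groups)
        self.bins = bins or IntensityBins()
        self.train_group = train_group
        self.control_group = control_group
        self.case_groups = case_groups or sorted(
            labels - {train_group, control_group}
        )
        if not self.case_groups:
            raise ModelError("need at least one evaluation case group")

    @classmethod
    def from_cohort(
        cls,
        cohort,
        window_N: int = 20,
        sync: SyncParams | None = None,
        bins: IntensityBins | None = None,
        **kwargs,
    ) -> "MovementNoveltyModel":
        """Preprocess and segment a synthetic Cohort into a model."""
        windows = {}
        groups = {}
        for p in cohort.participants:
            rec = preprocess_participant(
                p.traces, window_N=window_N, sync=sync, participant_id=p.participant_id
            )
            windows[p.participant_id] = segment_windows(rec)
            groups[p.participant_id] = p.group
        return cls(windows, groups, bins=bins, **kwargs)

    @classmethod
    def from_recordings(
        cls, recordings: list, groups: dict, bins: IntensityBins | None = None, **kwargs
    ) -> "MovementNoveltyModel":
        """Build from already-synchronized recordings."""
        windows = {r.participant_id: segment_windows(r) for r in recordings}
        return cls(windows, groups, bins=bins, **kwargs)

    @property
    def training_windows(self) -> list:
        out = []
        for pid, g in self.groups.items():
            if g == self.train_group:
                out.extend(self.windows[pid])
        return out

    def fit(
        self,
        train_config: TrainConfig | None = None,
        per_bin: bool = False,
        hidden_sizes: tuple = (50, 20),
        th: float = 0.5,
        pearson_mode: str = "flat",
    ) -> "MovementNoveltyResults":
        """Train the forecaster(s) on the training controls and score the rest.

        ``per_bin=True`` trains one model per intensity interval on the
        training windows falling in that interval (intervals with no
        training data get no model and must not occur in scoring).
        """
        train_config = train_config or TrainConfig()
        train_windows = self.training_windows
        if not train_windows:
            raise ModelError("no training windows")
        if per_bin:
            models: dict[int, ForecasterParams] = {}
            for b in range(self.bins.n_bins):
                if any(
                    assign_bin(w.intensity_sd, self.bins) == b for w in train_windows
                ):
                    models[b] = train(
                        train_windows,
                        train_config,
                        bin=b,
                        bins=self.bins,
                        hidden_sizes=hidden_sizes,
                    )
            fitted: ForecasterParams | dict = models
        else:
            fitted = train(train_windows, train_config, hidden_sizes=hidden_sizes)

        scores_by_participant = {}
        summaries = []
        for pid, g in self.groups.items():
            if g == self.train_group:
                continue
            scores, summary = score_participant(
                self.windows[pid],
                fitted,
                th=th,
                bins=self.bins,
                group=g,
                pearson_mode=pearson_mode,
            )
            summary.participant_id = pid
            scores_by_participant[pid] = scores
            summaries.append(summary)

        overall = overall_comparisons(
            summaries, self.control_group, self.case_groups, th=th
        )
        per_bin_comps = per_bin_comparisons(
            summaries, self.bins, self.control_group, self.case_groups, th=th
        )
        return MovementNoveltyResults(
            model=self,
            params=fitted,
            th=th,
            scores_by_participant=scores_by_participant,
            summaries=summaries,
            comparisons_overall=overall,
            comparisons_per_bin=per_bin_comps,
        )


@dataclass
class MovementNoveltyResults:
    """Fitted forecaster, fragment scores, counts, and group comparisons."""

    model: MovementNoveltyModel
    params: ForecasterParams | dict
    th: float
    scores_by_participant: dict
    summaries: list
    comparisons_overall: list
    comparisons_per_bin: list

    # -- reporting ---------------------------------------------------------

    def counts(self, group: str, bin: int | None = None) -> np.ndarray:
        """Per-participant non-similar counts for one group."""
        out = [
            s.non_similar_total if bin is None else int(s.non_similar_per_bin[bin])
            for s in self.summaries
            if s.group == group
        ]
        return np.asarray(out, dtype=int)

    def band_counts(self, group: str, band: tuple) -> np.ndarray:
        """Counts aggregated over the bins wholly inside ``band``."""
        idx = self.model.bins.indices_in_band(band)
        if not idx:
            raise ModelError(f"no intensity bins inside band {band}")
        return np.asarray(
            [
                int(s.non_similar_per_bin[idx].sum())
                for s in self.summaries
                if s.group == group
            ],
            dtype=int,
        )

    def summaries_frame(self) -> pd.DataFrame:
        return summaries_to_frame(self.summaries, self.model.bins)

    def scores_frame(self) -> pd.DataFrame:
        frames = [scores_to_frame(s) for s in self.scores_by_participant.values()]
        return pd.concat(frames, ignore_index=True)

    def per_bin_pvalues(self) -> pd.DataFrame:
        rows = [c.as_dict() for c in self.comparisons_per_bin]
        return pd.DataFrame(rows)

    def threshold_sweep(
        self, th_grid, case_group: str, bin: int | None = None
    ) -> list:
        """p-value per similarity threshold, from stored correlations."""
        return threshold_sweep(
            self.scores_by_participant,
            {pid: self.model.groups[pid] for pid in self.scores_by_participant},
            th_grid,
            self.model.control_group,
            case_group,
            bins=self.model.bins,
            bin=bin,
        )

    def roc_auc(self, case_group: str, bin: int | None = None, band: tuple | None = None):
        """Group separability from per-participant counts."""
        if band is not None:
            case = self.band_counts(case_group, band)
            control = self.band_counts(self.model.control_group, band)
        else:
            case = self.counts(case_group, bin)
            control = self.counts(self.model.control_group, bin)
        return roc_auc(case, control)

    def summary(self) -> str:
        """Human-readable report of counts and group comparisons."""
        bins = self.model.bins
        lines = []
        lines.append("Movement-pattern divergence analysis")
        lines.append("=" * 68)
        lines.append(
            f"similarity threshold th = {self.th};"
            f" control group: {self.model.control_group};"
            f" {len(self.comparisons_per_bin) + len(self.comparisons_overall)}"
            " comparisons (uncorrected)"
        )
        lines.append("")
        lines.append(
            f"{'group':<16}{'n':>4}{'total':>9}{'mean/participant':>18}{'SD':>10}"
        )
        lines.append("-" * 68)
        groups = [self.model.control_group] + list(self.model.case_groups)
        for g in groups:
            c = self.counts(g)
            lines.append(
                f"{g:<16}{c.size:>4}{c.sum():>9}{c.mean():>18.1f}{c.std(ddof=1):>10.1f}"
            )
        lines.append("")
        lines.append("one-sided t-tests, case > control (all intensities):")
        for comp in self.comparisons_overall:
            lines.append(
                f"  {comp.group_b:<16} t = {comp.t:6.3f}  df = {comp.df:4.0f}"
                f"  p = {comp.p:.4f}"
            )
        lines.append("")
        lines.append("per intensity bin (combined SD, g units):")
        header = f"{'bin':<14}" + "".join(
            f"{g[:12]:>14}" for g in self.model.case_groups
        )
        lines.append(header)
        for b in range(bins.n_bins):
            row = f"{bins.labels()[b]:<14}"
            for g in self.model.case_groups:
                comp = next(
                    c
                    for c in self.comparisons_per_bin
                    if c.bin == bins.labels()[b] and c.group_b == g
                )
                cell = "undef" if comp.undefined else format(comp.p, ".4f")
                row += f"{cell:>14}"
            lines.append(row)
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "th": self.th,
            "bins": list(self.model.bins.edges[:-1]) + ["inf"],
            "groups": {
                g: {
                    "n": int(self.counts(g).size),
                    "mean": float(self.counts(g).mean()),
                    "sd": float(self.counts(g).std(ddof=1)),
                    "total": int(self.counts(g).sum()),
                }
                for g in [self.model.control_group] + list(self.model.case_groups)
            },
            "overall": [c.as_dict() for c in self.comparisons_overall],
            "per_bin": [c.as_dict() for c in self.comparisons_per_bin],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def plot_pvalues(self, case_group: str, ax=None):
        """Bar plot of per-bin p-values for one case group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        comps = [c for c in self.comparisons_per_bin if c.group_b == case_group]
        labels = [c.bin for c in comps]
        ps = [c.p for c in comps]
        ax.bar(range(len(ps)), ps)
        ax.axhline(0.05, color="red", linestyle="--", linewidth=1)
        ax.set_xticks(range(len(ps)), labels, rotation=45, ha="right")
        ax.set_ylabel("one-sided p")
        ax.set_xlabel("combined SD interval (g)")
        ax.set_title(f"{case_group} vs {self.model.control_group}")
        return ax
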