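"""Group-level inference on per-participant non-similar fragment counts.

The case groups (e.g. medicated / non-medicated) are compared with the
control test group by a pooled-variance two-sample t-test, one-sided for
the alternative "case mean exceeds control mean" — the direction the
novelty-count construction predicts.  Comparisons run overall and per
movement-intensity bin; a similarity-threshold sweep re-derives counts
from stored fragment correlations, and group separability is summarised
by the pairwise-comparison AUC with a Youden-optimal operating point.
No multiple-testing correction is applied across bins; the number of
comparisons is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .segmentation import IntensityBins


class StatsError(ValueError):
    pass


@dataclass
class GroupSummaryStats:
    """Count summary for one group: n participants, mean and sample SD."""

    group: str
    n: int
    mean: float
    sd: float
    total: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise StatsError("group summaries need n >= 2")
        if self.sd < 0:
            raise StatsError("sd must be non-negative")

    @classmethod
    def from_counts(cls, group: str, counts) -> "GroupSummaryStats":
        counts = np.asarray(counts, dtype=float)
        return cls(
            group=group,
            n=counts.size,
            mean=float(counts.mean()),
            sd=float(counts.std(ddof=1)),
            total=float(counts.sum()),
        )


@dataclass
class GroupComparison:
    group_a: str  # reference (control)
    group_b: str  # case
    t: float
    df: float
    p: float
    bin: str = "all"
    th: float | None = None
    mean_a: float = np.nan
    mean_b: float = np.nan
    sd_a: float = np.nan
    sd_b: float = np.nan
    n_a: int = 0
    n_b: int = 0
    degenerate: bool = False
    undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "control": self.group_a,
            "case": self.group_b,
            "bin": self.bin,
            "th": self.th,
            "n": [self.n_a, self.n_b],
            "mean": [self.mean_a, self.mean_b],
            "sd": [self.sd_a, self.sd_b],
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "degenerate": self.degenerate,
            "undefined": self.undefined,
        }


def t_test_counts(
    a: GroupSummaryStats | list | np.ndarray,
    b: GroupSummaryStats | list | np.ndarray,
    welch: bool = False,
    group_a: str = "control",
    group_b: str = "case",
) -> GroupComparison:
    """One-sided two-sample t-test for ``mean_b > mean_a``.

    Accepts ready-made summaries or raw per-participant counts.  The pooled
    variance form with ``df = n_a + n_b - 2`` is the default; ``welch=True``
    switches to the unequal-variance form with Welch-Satterthwaite degrees
    of freedom.  Zero pooled variance with equal means yields the null
    convention p = 0.5; with unequal means the comparison is flagged
    degenerate (p = 0 in the predicted direction, 1 otherwise).
    """
    if not isinstance(a, GroupSummaryStats):
        a = GroupSummaryStats.from_counts(group_a, a)
    if not isinstance(b, GroupSummaryStats):
        b = GroupSummaryStats.from_counts(group_b, b)
    va, vb = a.sd**2, b.sd**2
    if welch:
        se2 = va / a.n + vb / b.n
        if se2 > 0:
            df = se2**2 / (
                (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
            )
        else:
            df = a.n + b.n - 2
    else:
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / (a.n + b.n - 2)
        se2 = sp2 * (1.0 / a.n + 1.0 / b.n)
        df = a.n + b.n - 2
    diff = b.mean - a.mean
    if se2 <= 0.0:
        if diff == 0.0:
            t, p, degenerate = 0.0, 0.5, False
        else:
            t = np.inf if diff > 0 else -np.inf
            p, degenerate = (0.0 if diff > 0 else 1.0), True
    else:
        t = diff / np.sqrt(se2)
        p = float(sps.t.sf(t, df))
        degenerate = False
    return GroupComparison(
        group_a=a.group,
        group_b=b.group,
        t=float(t),
        df=float(df),
        p=p,
        mean_a=a.mean,
        mean_b=b.mean,
        sd_a=a.sd,
        sd_b=b.sd,
        n_a=a.n,
        n_b=b.n,
        degenerate=degenerate,
    )


def _counts_by_group(summaries: list, attr_bin: int | None) -> dict:
    out: dict[str, list] = {}
    for s in summaries:
        c = (
            s.non_similar_total
            if attr_bin is None
            else int(s.non_similar_per_bin[attr_bin])
        )
        out.setdefault(s.group, []).append(c)
    return out


def per_bin_comparisons(
    summaries: list,
    bins: IntensityBins,
    control_group: str,
    case_groups: list,
    th: float | None = None,
    welch: bool = False,
) -> list:
    """One comparison per (intensity bin, case group).

    A bin with zero pooled variance in both groups (e.g. no fragments at
    all) is returned flagged ``undefined`` rather than silently dropped.
    """
    comparisons = []
    for b in range(bins.n_bins):
        groups = _counts_by_group(summaries, b)
        if control_group not in groups:
            raise StatsError(f"no participants in control group {control_group!r}")
        for case in case_groups:
            if case not in groups:
                raise StatsError(f"no participants in case group {case!r}")
            comp = t_test_counts(
                np.asarray(groups[control_group]),
                np.asarray(groups[case]),
                welch=welch,
                group_a=control_group,
                group_b=case,
            )
            comp.bin = bins.labels()[b]
            comp.th = th
            if comp.sd_a == 0.0 and comp.sd_b == 0.0:
                comp.undefined = True
            comparisons.append(comp)
    return comparisons


def overall_comparisons(
    summaries: list,
    control_group: str,
    case_groups: list,
    th: float | None = None,
    welch: bool = False,
) -> list:
    groups = _counts_by_group(summaries, None)
    out = []
    for case in case_groups:
        comp = t_test_counts(
            np.asarray(groups[control_group]),
            np.asarray(groups[case]),
            welch=welch,
            group_a=control_group,
            group_b=case,
        )
        comp.th = th
        out.append(comp)
    return out


def threshold_sweep(
    scores_by_participant: dict,
    groups: dict,
    th_grid,
    control_group: str,
    case_group: str,
    bins: IntensityBins | None = None,
    bin: int | None = None,
) -> list:
    """Recompute counts and the t-test at each similarity threshold.

    Uses the stored fragment correlations only — the forecaster is not
    re-run.  ``bin`` restricts the counts to one intensity bin.  Returns a
    list of (th, GroupComparison); a threshold where both groups have zero
    count variance comes back flagged ``undefined``.
    """
    from .scoring import counts_at_threshold

    bins = bins or IntensityBins()
    out = []
    for th in th_grid:
        if not (0.0 < th < 1.0):
            raise StatsError(f"threshold {th} outside (0, 1)")
        counts: dict[str, list] = {control_group: [], case_group: []}
        for pid, scores in scores_by_participant.items():
            g = groups[pid]
            if g not in counts:
                continue
            summ = counts_at_threshold(scores, th, bins)
            c = (
                summ.non_similar_total
                if bin is None
                else int(summ.non_similar_per_bin[bin])
            )
            counts[g].append(c)
        comp = t_test_counts(
            np.asarray(counts[control_group]),
            np.asarray(counts[case_group]),
            group_a=control_group,
            group_b=case_group,
        )
        comp.th = float(th)
        if bin is not None:
            comp.bin = bins.labels()[bin]
        if comp.sd_a == 0.0 and comp.sd_b == 0.0:
            comp.undefined = True
        out.append((float(th), comp))
    return out


@dataclass
class OperatingPoint:
    threshold: float  # classify "case" when count >= threshold
    sensitivity: float
    false_positive_rate: float
    n_case_above: int
    n_case: int
    n_control_above: int
    n_control: int


def roc_auc(case_counts, control_counts) -> tuple:
    """Pairwise-comparison AUC and the Youden-optimal operating point.

    AUC is the fraction of (case, control) pairs with the case count higher
    (ties count 1/2) — the Mann-Whitney statistic scaled to [0, 1].  The
    operating point is the smallest count threshold maximising
    sensitivity - false positive rate, classifying a participant as "case"
    when their non-similar count is at or above the threshold.
    """
    case = np.asarray(case_counts, dtype=float)
    control = np.asarray(control_counts, dtype=float)
    if case.size == 0 or control.size == 0:
        raise StatsError("both count lists must be non-empty")
    greater = (case[:, None] > control[None, :]).sum()
    ties = (case[:, None] == control[None, :]).sum()
    auc = (greater + 0.5 * ties) / (case.size * control.size)
    thresholds = np.unique(np.concatenate([case, control, [max(case.max(), control.max()) + 1]]))
    best = None
    for thr in thresholds:
        sens = float((case >= thr).mean())
        fpr = float((control >= thr).mean())
        youden = sens - fpr
        if best is None or youden > best[0] + 1e-12:
            best = (youden, thr, sens, fpr)
    _, thr, sens, fpr = best
    op = OperatingPoint(
        threshold=float(thr),
        sensitivity=sens,
        false_positive_rate=fpr,
        n_case_above=int((case >= thr).sum()),
        n_case=case.size,
        n_control_above=int((control >= thr).sum()),
        n_control=control.size,
    )
    return float(auc), op
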