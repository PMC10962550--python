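"""Resected-vs-spared distinguishability (D_RS) and outcome evaluation.

D_RS is the Mann-Whitney AUC for distinguishing resected from spared
regions by their band-power abnormality, with spared as the positive
class: D_RS < .5 means abnormality is concentrated in resected tissue
(the localizing direction), D_RS > .5 in spared tissue. Ties receive
midrank (half) credit throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normative import AbnormalityMatrix

__all__ = [
    "DrsSeries",
    "PatientSummary",
    "OutcomeEvaluation",
    "label_resected_regions",
    "compute_drs",
    "drs_timeseries",
    "localizing_percentage",
    "summarize_patient",
    "evaluate_outcomes",
    "mann_whitney_auc",
]


@dataclass
class DrsSeries:
    """Per-window D_RS values with window start times."""

    values: np.ndarray  # in [0, 1]
    window_starts: np.ndarray  # seconds

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        if self.values.shape != self.window_starts.shape:
            raise ValueError("values and window_starts must align")
        if self.values.size and (np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1):
            raise ValueError("D_RS values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class PatientSummary:
    patient_id: str
    ilae_class: int
    n_windows: int
    median_drs: float
    localizing_pct: float
    condition_medians: dict[str, float]  # e.g. interictal/peri-ictal/peak/trough
    condition_counts: dict[str, int]

    @property
    def seizure_free(self) -> bool:
        return self.ilae_class == 1


@dataclass
class OutcomeEvaluation:
    """Cohort-level discrimination of surgical outcome by median D_RS."""

    auc: float
    ranksum_p: float  # one-sided: ILAE>1 medians stochastically larger
    signed_rank_p_poor: float  # ILAE>1 medians > .5
    signed_rank_p_good: float  # ILAE=1 medians < .5
    roc_points: pd.DataFrame  # columns fpr, tpr, threshold
    n_good: int
    n_poor: int


def label_resected_regions(meta: pd.DataFrame, threshold: float = 0.25) -> pd.Series:
    """Region-level resected flags from per-contact flags.

    A region counts as resected iff strictly more than ``threshold`` of
    its contacts were removed (>25% rule; exactly 25% is not resected).
    """
    assigned = meta[meta["region_id"].notna()]
    frac = assigned.groupby("region_id")["resected"].mean()
    return frac > threshold


def mann_whitney_auc(positive: np.ndarray, negative: np.ndarray) -> float:
    """AUC via midranks: P(pos > neg) + 0.5 P(pos == neg)."""
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def compute_drs(abnormalities: np.ndarray, resected: np.ndarray) -> float:
    """D_RS of one window: AUC for spared (positive) vs resected regions.

    Equivalent to pairwise counting: over all (spared, resected) pairs,
    full credit when spared abnormality is higher, half credit on ties,
    divided by n_spared * n_resected.
    """
    a = np.asarray(abnormalities, dtype=float)
    r = np.asarray(resected, dtype=bool)
    if a.shape != r.shape:
        raise ValueError("abnormalities and resected flags must align")
    if not r.any() or r.all():
        raise ValueError("D_RS needs at least one resected and one spared region")
    return mann_whitney_auc(a[~r], a[r])


def drs_timeseries(abnorm: AbnormalityMatrix, resected: pd.Series | dict) -> DrsSeries:
    """D_RS per valid window of an abnormality matrix.

    ``resected`` maps region_id -> bool; regions of the matrix must be
    covered. Windows that are invalid, contain non-finite abnormalities,
    or lack one of the two classes are omitted.
    """
    flags = np.array([bool(resected[r]) for r in abnorm.region_ids])
    if not flags.any() or flags.all():
        raise ValueError("need both resected and spared regions with coverage")
    vals = abnorm.values
    ok = abnorm.valid & np.isfinite(vals).all(axis=1)
    idx = np.nonzero(ok)[0]
    if idx.size == 0:
        raise ValueError("no window with computable D_RS")
    sub = vals[idx]
    # vectorised midrank AUC across windows
    ranks = stats.rankdata(sub, axis=1)
    n_res = int(flags.sum())
    n_spa = flags.size - n_res
    u = ranks[:, ~flags].sum(axis=1) - n_spa * (n_spa + 1) / 2
    return DrsSeries(values=u / (n_spa * n_res), window_starts=abnorm.window_starts[idx])


def localizing_percentage(series: DrsSeries) -> float:
    """Percentage of windows with D_RS <= .5 (boundary inclusive)."""
    if len(series) == 0:
        raise ValueError("empty D_RS series")
    return float(100.0 * np.mean(series.values <= 0.5))


def summarize_patient(
    series: DrsSeries,
    labels: pd.DataFrame | None = None,
    patient_id: str = "patient",
    ilae_class: int = 1,
) -> PatientSummary:
    """Per-patient D_RS summary: overall and per-condition medians.

    ``labels`` is a window-label table (from :mod:`abnmap.temporal`) with
    a ``window_start_s`` column plus ``seizure_label`` and/or
    ``circadian_label``; medians are reported for each condition value
    present among the series' windows, and conditions with zero windows
    are simply absent from the summary.
    """
    if len(series) == 0:
        raise ValueError("empty D_RS series")
    cond_medians: dict[str, float] = {}
    cond_counts: dict[str, int] = {}
    if labels is not None:
        lab = labels.set_index("window_start_s")
        for col in ("seizure_label", "circadian_label"):
            if col not in lab.columns:
                continue
            win_labels = lab[col].reindex(series.window_starts).to_numpy()
            for value in pd.unique(win_labels[pd.notna(win_labels)]):
                if value == "neither":
                    continue
                sel = series.values[win_labels == value]
                if sel.size:
                    cond_medians[str(value)] = float(np.median(sel))
                    cond_counts[str(value)] = int(sel.size)
    return PatientSummary(
        patient_id=patient_id,
        ilae_class=int(ilae_class),
        n_windows=len(series),
        median_drs=float(np.median(series.values)),
        localizing_pct=localizing_percentage(series),
        condition_medians=cond_medians,
        condition_counts=cond_counts,
    )


def _median_scores(summaries: list[PatientSummary], statistic: str) -> np.ndarray:
    if statistic == "overall":
        return np.array([s.median_drs for s in summaries])
    return np.array([s.condition_medians[statistic] for s in summaries])


def evaluate_outcomes(summaries: list[PatientSummary], statistic: str = "overall") -> OutcomeEvaluation:
    """Outcome discrimination by median D_RS across a patient cohort.

    The positive class is not-seizure-free (ILAE > 1); scores are the
    requested median (overall or a condition such as ``interictal``).
    Tests: one-sided Wilcoxon rank-sum for ILAE>1 medians being larger
    (exact when both groups are <= 10 and tie-free, otherwise normal
    approximation with continuity correction) and one-sided signed-rank
    tests of each group's medians against .5.
    """
    summaries = [s for s in summaries if statistic == "overall" or statistic in s.condition_medians]
    good = [s for s in summaries if s.seizure_free]
    poor = [s for s in summaries if not s.seizure_free]
    if not good or not poor:
        raise ValueError("both outcome groups must be nonempty")
    g = _median_scores(good, statistic)
    p = _median_scores(poor, statistic)
    auc = mann_whitney_auc(p, g)
    scores = np.concatenate([p, g])
    has_ties = np.unique(scores).size < scores.size
    method = "exact" if (len(g) <= 10 and len(p) <= 10 and not has_ties) else "asymptotic"
    ranksum = stats.mannwhitneyu(p, g, alternative="greater", method=method)
    def _signed_rank(d: np.ndarray, alternative: str) -> float:
        if d.size < 2 or np.all(d == 0):
            return 1.0  # no evidence either way
        return float(stats.wilcoxon(d, alternative=alternative).pvalue)

    sr_poor = _signed_rank(p - 0.5, "greater")
    sr_good = _signed_rank(g - 0.5, "less")

    # ROC curve: thresholds on median D_RS, higher score => predicted poor outcome
    order = np.argsort(-scores, kind="stable")
    y = np.concatenate([np.ones(len(p)), np.zeros(len(g))])[order]
    tpr = np.concatenate([[0.0], np.cumsum(y) / len(p)])
    fpr = np.concatenate([[0.0], np.cumsum(1 - y) / len(g)])
    thresholds = np.concatenate([[np.inf], scores[order]])
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return OutcomeEvaluation(
        auc=auc,
        ranksum_p=float(ranksum.pvalue),
        signed_rank_p_poor=sr_poor,
        signed_rank_p_good=sr_good,
        roc_points=roc,
        n_good=len(g),
        n_poor=len(p),
    )
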