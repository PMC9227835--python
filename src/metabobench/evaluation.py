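"""Operating characteristics of a selection procedure against planted truth.

A "false positive" here is a metabolite selected by a method but not
planted as directly associated with the outcome — even when its
marginal association is real because it is correlated with a true
metabolite.  The five reported characteristics are sensitivity,
specificity, the positive and negative predictive values, and the
false-positive count.  Undefined rates (e.g. PPV of an empty
selection) are reported as missing, never imputed as 0 or 1, and
excluded from replicate averages with the contributing count recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionSummary",
    "confusion",
    "top10_hit_rate",
    "power_by_effect_size",
    "aggregate",
    "fp_cluster_overlap",
]

RATE_FIELDS = ("sensitivity", "specificity", "ppv", "npv")


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float  # NaN when tp + fp = 0
    npv: float  # NaN when tn + fn = 0

    @property
    def fp_count(self) -> int:
        return self.fp


def _rate(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def confusion(selected: Iterable[int], truth_set: Iterable[int], m: int) -> ConfusionSummary:
    """TP/FP/TN/FN of a selected set against the planted truth among m metabolites."""
    sel = set(int(i) for i in selected)
    truth = set(int(i) for i in truth_set)
    for s in sel | truth:
        if not 0 <= s < m:
            raise ValueError(f"index {s} outside [0, {m})")
    tp = len(sel & truth)
    fp = len(sel - truth)
    fn = len(truth - sel)
    tn = m - tp - fp - fn
    return ConfusionSummary(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        ppv=_rate(tp, tp + fp),
        npv=_rate(tn, tn + fn),
    )


def top10_hit_rate(
    replicate_rankings: Sequence[Sequence[int]],
    truth_set: Iterable[int],
    k: int = 10,
) -> pd.Series:
    """Per-true-metabolite fraction of replicates ranking it among the top k."""
    if len(replicate_rankings) == 0:
        raise ValueError("at least one replicate ranking is required")
    truth = sorted(int(i) for i in truth_set)
    hits = {t: 0 for t in truth}
    for ranking in replicate_rankings:
        if len(ranking) < k:
            raise ValueError(f"ranking shorter than k={k}")
        top = set(int(i) for i in ranking[:k])
        for t in truth:
            if t in top:
                hits[t] += 1
    n = len(replicate_rankings)
    return pd.Series({t: hits[t] / n for t in truth}, name=f"top{k}_hit_rate")


def power_by_effect_size(
    replicate_selections: Sequence[Iterable[int]], beta: np.ndarray
) -> pd.DataFrame:
    """Detection rate of each true metabolite, sorted by |effect size|."""
    beta = np.asarray(beta, dtype=float)
    truth = np.flatnonzero(beta != 0)
    if len(truth) == 0:
        raise ValueError("beta has no nonzero entries")
    n = len(replicate_selections)
    rows = []
    for t in truth:
        rate = sum(1 for sel in replicate_selections if int(t) in set(map(int, sel))) / n
        rows.append({"metabolite": int(t), "effect_size": float(beta[t]), "detection_rate": rate})
    df = pd.DataFrame(rows)
    return df.reindex(df["effect_size"].abs().sort_values().index).reset_index(drop=True)


def aggregate(replicate_summaries: Sequence[ConfusionSummary]) -> pd.DataFrame:
    """Mean and Monte-Carlo SE of each characteristic over replicates.

    Undefined (NaN) values are skipped; the count of contributing
    replicates is reported per metric.  A metric undefined in every
    replicate is reported with mean/se missing and count 0.
    """
    if len(replicate_summaries) == 0:
        raise ValueError("at least one replicate summary is required")
    rows = []
    metrics = {
        "sensitivity": [s.sensitivity for s in replicate_summaries],
        "specificity": [s.specificity for s in replicate_summaries],
        "ppv": [s.ppv for s in replicate_summaries],
        "npv": [s.npv for s in replicate_summaries],
        "fp_count": [float(s.fp) for s in replicate_summaries],
    }
    for name, vals in metrics.items():
        arr = np.asarray(vals, dtype=float)
        ok = ~np.isnan(arr)
        n = int(ok.sum())
        if n == 0:
            rows.append({"metric": name, "mean": math.nan, "se": math.nan, "n_reps": 0})
        else:
            mean = float(arr[ok].mean())
            se = float(arr[ok].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            rows.append({"metric": name, "mean": mean, "se": se, "n_reps": n})
    return pd.DataFrame(rows)


def fp_cluster_overlap(
    selected: Iterable[int],
    truth_set: Iterable[int],
    cluster_labels: np.ndarray,
) -> pd.DataFrame:
    """Companion tabulation: does each false positive share a cluster with a truth?

    Quantifies correlation-induced selection — such hits are "false"
    only against the planted (conditional) truth, not marginally.
    """
    labels = np.asarray(cluster_labels)
    truth = set(int(i) for i in truth_set)
    truth_clusters = {int(labels[t]) for t in truth}
    rows = []
    for j in sorted(set(int(i) for i in selected) - truth):
        rows.append(
            {
                "metabolite": j,
                "cluster": int(labels[j]),
                "shares_cluster_with_truth": int(labels[j]) in truth_clusters,
            }
        )
    return pd.DataFrame(rows, columns=["metabolite", "cluster", "shares_cluster_with_truth"])
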