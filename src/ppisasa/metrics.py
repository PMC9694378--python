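"""Virtual-screening evaluation: ROC AUC, enrichment factors, BEDROC.

AUC is the Mann-Whitney statistic (ties count 1/2).  EF_chi counts actives
among the top ceil(chi * N) compounds of the ranked list, with ties at the
cutoff resolved by a stable (score, compound_id) ordering.  BEDROC follows
the Truchon-Bayly exponential rank weighting, mapped to [0, 1] by its exact
min/max so that a perfect ranking scores 1 and a fully inverted one 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class UndefinedMetricError(ValueError):
    """Raised when a metric needs both classes and only one is present."""


@dataclass
class ScreenMetrics:
    auc: float
    ef: dict[float, float]
    bedroc: float
    alpha: float
    n_actives: int
    n_total: int


def _check_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise UndefinedMetricError("both classes required")


def _validate(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must align")
    if not np.all((labels == 0) | (labels == 1)):
        raise ValueError("labels must be 0/1")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    _check_classes(labels)
    return labels, scores


def roc_auc(labels, scores, higher_better: bool = True) -> float:
    """P(score_active > score_inactive) + 0.5 P(tie), via midranks."""
    labels, scores = _validate(labels, scores)
    if not higher_better:
        scores = -scores
    ranks = rankdata(scores, method="average")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _ranked_order(labels: np.ndarray, scores: np.ndarray, ids=None) -> np.ndarray:
    """Indices sorted best-first; ties broken stably by compound id."""
    if ids is None:
        ids = np.arange(len(scores))
    order = np.lexsort((np.asarray(ids), -scores))
    return order


def enrichment_factor(labels, scores, fraction: float, ids=None) -> float:
    """EF_chi = (a_chi / n_chi) / (A / N) with n_chi = ceil(chi * N)."""
    labels, scores = _validate(labels, scores)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_total = len(labels)
    n_top = math.ceil(fraction * n_total)
    order = _ranked_order(labels, scores, ids)
    a_top = int(labels[order[:n_top]].sum())
    n_actives = int(labels.sum())
    return float((a_top / n_top) / (n_actives / n_total))


def bedroc(labels, scores, alpha: float = 20.0, ids=None) -> float:
    """Exponentially weighted early-recognition score in [0, 1].

    S = sum_i exp(-alpha r_i / N) over active ranks r_i (1-based); BEDROC =
    (S - S_min) / (S_max - S_min) where S_max/S_min place the actives at the
    very top/bottom of the list.
    """
    labels, scores = _validate(labels, scores)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    n_total = len(labels)
    order = _ranked_order(labels, scores, ids)
    active_ranks = np.nonzero(labels[order] == 1)[0] + 1  # 1-based
    n_act = len(active_ranks)
    s = np.exp(-alpha * active_ranks / n_total).sum()
    best = np.exp(-alpha * np.arange(1, n_act + 1) / n_total).sum()
    worst = np.exp(-alpha * np.arange(n_total - n_act + 1, n_total + 1) / n_total).sum()
    return float((s - worst) / (best - worst))


def screen_metrics(
    labels,
    scores,
    fractions: tuple[float, ...] = (0.01, 0.05),
    alpha: float = 20.0,
    ids=None,
) -> ScreenMetrics:
    labels_arr = np.asarray(labels, dtype=int)
    return ScreenMetrics(
        auc=roc_auc(labels, scores),
        ef={f: enrichment_factor(labels, scores, f, ids=ids) for f in fractions},
        bedroc=bedroc(labels, scores, alpha=alpha, ids=ids),
        alpha=alpha,
        n_actives=int(labels_arr.sum()),
        n_total=len(labels_arr),
    )


def screen_report(
    labels,
    score_columns: pd.DataFrame,
    fractions: tuple[float, ...] = (0.01, 0.05),
    alpha: float = 20.0,
    ids=None,
) -> pd.DataFrame:
    """One metrics row per score column (all columns oriented higher=better)."""
    if score_columns.shape[1] < 1:
        raise ValueError("need at least one score column")
    rows = []
    for col in score_columns.columns:
        m = screen_metrics(labels, score_columns[col], fractions, alpha, ids=ids)
        row = {"score": col, "auc": m.auc, "bedroc": m.bedroc, "alpha": m.alpha}
        for f in fractions:
            row[f"ef{f * 100:g}%"] = m.ef[f]
        row["n_actives"] = m.n_actives
        row["n_total"] = m.n_total
        rows.append(row)
    return pd.DataFrame(rows)
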