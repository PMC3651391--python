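"""Performance evaluation: confusion metrics, ROC/AUC, cut-off selection,
rank-sum comparison of score distributions and leave-one-out jackknife.

Conventions follow the MSH6 study protocol: SIFT calls a variant pathogenic
at score <= 0.05 (low SIFT = damaging), PolyPhen-2 at score >= 0.446, the
joint score at q > 0.56 and the domain-normalized MAPP score at > 1.0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .combiner import (
    T_LOW,
    FeatureVector,
    CompleteSeparationError,
    fit_logistic,
    joint_score,
)

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_metrics",
    "counts_from_calls",
    "DEFAULT_THRESHOLDS",
    "binarize_scores",
    "roc_points",
    "roc_auc",
    "optimal_cutoff",
    "wilcoxon_rank_sum",
    "jackknife_loo",
    "JackknifeResult",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("at least one observation required")


@dataclass(frozen=True)
class MetricReport:
    ppv: float | None
    npv: float | None
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    fractions: dict[str, str]


def _ratio(num: int, den: int, name: str, fractions: dict[str, str]) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning, stacklevel=3)
        fractions[name] = f"{num}/0"
        return None
    fractions[name] = f"{num}/{den}"
    return float(Fraction(num, den))


def confusion_metrics(counts: ConfusionCounts) -> MetricReport:
    """PPV, NPV, sensitivity, specificity and accuracy as exact ratios.

    Metrics with a zero denominator are reported as ``None`` (with a
    warning), never as 0.
    """
    c = counts
    fr: dict[str, str] = {}
    return MetricReport(
        ppv=_ratio(c.tp, c.tp + c.fp, "ppv", fr),
        npv=_ratio(c.tn, c.fn + c.tn, "npv", fr),
        sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity", fr),
        specificity=_ratio(c.tn, c.fp + c.tn, "specificity", fr),
        accuracy=_ratio(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn, "accuracy", fr),
        fractions=fr,
    )


def counts_from_calls(calls: Sequence[bool], labels: Sequence[int]) -> ConfusionCounts:
    calls = np.asarray(calls, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels differ in length")
    return ConfusionCounts(
        tp=int(np.sum(calls & labels)),
        fp=int(np.sum(calls & ~labels)),
        tn=int(np.sum(~calls & ~labels)),
        fn=int(np.sum(~calls & labels)),
    )


# tool -> (threshold, pathogenic side)
DEFAULT_THRESHOLDS: dict[str, tuple[float, str]] = {
    "sift": (0.05, "le"),  # low SIFT = damaging
    "pph2_humvar": (0.446, "ge"),
    "codp": (T_LOW, "gt"),
    "mapp_norm": (1.0, "gt"),
}


def binarize_scores(
    scores: Sequence[float], tool: str, threshold: float | None = None
) -> np.ndarray:
    """Boolean pathogenic calls from raw tool scores under the study thresholds."""
    if tool not in DEFAULT_THRESHOLDS:
        raise ValueError(f"unknown tool {tool!r}; known: {sorted(DEFAULT_THRESHOLDS)}")
    default_t, side = DEFAULT_THRESHOLDS[tool]
    t = default_t if threshold is None else threshold
    s = np.asarray(scores, dtype=float)
    if side == "le":
        return s <= t
    if side == "ge":
        return s >= t
    return s > t


def _check_two_class(labels: np.ndarray):
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """ROC points (fpr, tpr) over all distinct thresholds, higher score = positive call."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_two_class(y)
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    p, n = y.sum(), (~y).sum()
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    pts = np.column_stack([fps[distinct] / n, tps[distinct] / p])
    return np.vstack([[0.0, 0.0], pts])


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, np.ndarray]:
    """AUC by the midrank Mann-Whitney identity, plus the ROC points.

    Equals the trapezoidal area under the ROC over all distinct thresholds;
    ties contribute half weight.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    _check_two_class(y)
    ranks = stats.rankdata(s)  # midranks
    n1 = int(y.sum())
    n2 = int((~y).sum())
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2)), roc_points(s, y)


def optimal_cutoff(
    scores: Sequence[float],
    labels: Sequence[int],
    rule: str = "youden",
) -> float | None:
    """Score threshold for "pathogenic if score > t" chosen on the ROC.

    Candidates are midpoints between adjacent distinct scores; ties are
    broken toward the smaller threshold.  ``rule`` is ``"youden"``
    (maximize sensitivity + specificity - 1) or ``"closest"`` (closest to
    the (0, 1) corner).  All scores identical is degenerate and returns
    ``None`` with a warning.
    """
    if rule not in ("youden", "closest"):
        raise ValueError("rule must be 'youden' or 'closest'")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_two_class(y)
    distinct = np.unique(s)
    if len(distinct) == 1:
        warnings.warn("all scores identical; no informative cut-off", RuntimeWarning)
        return None
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best_t, best_val = None, -np.inf
    for t in candidates:  # ascending, so ties keep the smaller threshold
        calls = s > t
        sens = (calls & y).sum() / y.sum()
        spec = (~calls & ~y).sum() / (~y).sum()
        val = (
            sens + spec - 1.0
            if rule == "youden"
            else -math.hypot(1.0 - sens, 1.0 - spec)
        )
        if val > best_val + 1e-12:
            best_val, best_t = val, float(t)
    return best_t


def _exact_enumeration_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p over all rank assignments (handles ties via midranks)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    us = np.array(
        [ranks[list(idx)].sum() - offset for idx in combinations(range(len(pooled)), n1)]
    )
    p_le = float(np.mean(us <= u_obs + 1e-12))
    p_ge = float(np.mean(us >= u_obs - 1e-12))
    # doubled one-sided tail, capped at 1
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test; returns (p, U).

    ``mode='auto'`` uses the exact null distribution when the pooled sample
    has at most 20 observations and no ties, and the tie-corrected,
    continuity-corrected normal approximation otherwise.  ``'exact'`` or
    ``'approx'`` force a mode; forcing exact on tied data falls back to
    complete enumeration over rank assignments with midranks.
    U is the Mann-Whitney statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError("mode must be auto, exact or approx")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (len(pooled) <= 20 and not has_ties) else "approx"
    u = float(stats.rankdata(pooled)[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0)
    if mode == "exact":
        if has_ties:
            return _exact_enumeration_p(x, y), u
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.pvalue), u
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue), u


@dataclass(frozen=True)
class JackknifeResult:
    predictions: "np.ndarray"  # held-out pathogenic calls (bool, NaN-free rows only)
    held_out_q: "np.ndarray"
    labels: "np.ndarray"
    accuracy: float
    per_class_accuracy: dict[int, float]
    n_failed: int


def jackknife_loo(
    features: Sequence[FeatureVector] | np.ndarray,
    labels: Sequence[int],
    threshold: float = T_LOW,
    ridge: float = 0.0,
) -> JackknifeResult:
    """Leave-one-out jackknife of the logistic combiner.

    Each item is predicted by a model refit on the remaining items
    (component scores are fixed inputs; only the regression is refit) and
    called pathogenic at ``q > threshold``.  Items whose refit fails by
    complete separation are flagged and excluded from the summary.
    """
    if isinstance(features, np.ndarray):
        fvs = [FeatureVector(*row) for row in np.asarray(features, dtype=float)]
    else:
        fvs = list(features)
    y = np.asarray(labels, dtype=int)
    if len(fvs) != len(y):
        raise ValueError("features and labels differ in length")
    if (y == 1).sum() < 3 or (y == 0).sum() < 3:
        raise ValueError("need at least 3 items per class")

    qs, calls, kept, failed = [], [], [], 0
    for i in range(len(fvs)):
        rest_f = [f for j, f in enumerate(fvs) if j != i]
        rest_y = np.delete(y, i)
        try:
            fit = fit_logistic(rest_f, rest_y, ridge=ridge)
        except CompleteSeparationError:
            failed += 1
            warnings.warn(
                f"leave-one-out refit for item {i} hit complete separation; item skipped",
                RuntimeWarning,
            )
            continue
        q = joint_score(fvs[i], fit.model)
        qs.append(q)
        calls.append(q > threshold)
        kept.append(i)
    if not kept:
        raise CompleteSeparationError("every leave-one-out refit failed")
    calls_arr = np.asarray(calls, dtype=bool)
    y_kept = y[kept]
    acc = float((calls_arr == y_kept.astype(bool)).mean())
    per_class = {
        c: float((calls_arr[y_kept == c] == bool(c)).mean())
        for c in (0, 1)
        if (y_kept == c).any()
    }
    return JackknifeResult(
        predictions=calls_arr,
        held_out_q=np.asarray(qs),
        labels=y_kept,
        accuracy=acc,
        per_class_accuracy=per_class,
        n_failed=failed,
    )


def plot_score_distributions(score_map: dict[str, tuple[Sequence[float], Sequence[float]]], path):
    """Box-and-whisker plots of pathogenic vs benign score distributions per tool.

    ``score_map`` maps tool name to (pathogenic scores, benign scores);
    whiskers extend to 1.5 x IQR, points beyond are drawn as outliers.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(score_map), figsize=(3 * len(score_map), 4), squeeze=False)
    for ax, (name, (path_scores, benign_scores)) in zip(axes[0], score_map.items()):
        ax.boxplot([list(path_scores), list(benign_scores)], tick_labels=["LLS", "ULS"], whis=1.5)
        ax.set_title(name)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
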