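"""Slide-level metrics with bootstrap CIs, ROC construction and the
equal-/clinical-balance test-split builders.

Positive calls use the convention ``score >= threshold``.  The ROC is built
by sweeping the threshold over the observed scores (plus sentinels), so its
endpoints are exactly (0,0) and (1,1); AUC is the trapezoidal integral of
TPR over FPR.  Bootstrap intervals are percentile intervals over
slide-level resamples with replacement.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .annotation import NEGATIVE, NEOPLASTIC, SlideRecord
from .errors import ShortfallError, UndefinedMetricError

__all__ = [
    "ScoredSlide",
    "RocCurve",
    "MetricsReport",
    "SplitSpec",
    "roc_curve",
    "auc",
    "log_loss",
    "threshold_metrics",
    "bootstrap_ci",
    "build_test_split",
    "evaluate",
]

_CLIP = 1e-15


@dataclass(frozen=True)
class ScoredSlide:
    slide_id: str
    score: float
    true_label: str  # "negative" | "neoplastic"

    @property
    def y(self) -> int:
        return 1 if self.true_label == NEOPLASTIC else 0


def _split_scores(scored: Sequence[ScoredSlide]) -> tuple[np.ndarray, np.ndarray]:
    scores = np.array([s.score for s in scored], dtype=float)
    labels = np.array([s.y for s in scored], dtype=int)
    return scores, labels


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray


def roc_curve(scored: Sequence[ScoredSlide]) -> RocCurve:
    """Threshold sweep over sorted unique scores plus sentinels.

    A sentinel above the maximum score yields the (0,0) endpoint; threshold
    0 calls everything positive and yields (1,1).  Raises
    :class:`UndefinedMetricError` on single-class input.
    """
    scores, labels = _split_scores(scored)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    # last index of each distinct score = the operating point at threshold s
    boundary = np.nonzero(np.diff(s_sorted))[0]
    boundary = np.concatenate((boundary, [len(s_sorted) - 1]))
    tp = np.cumsum(y_sorted)[boundary]
    fp = np.cumsum(1 - y_sorted)[boundary]
    thresholds = np.concatenate(([s_sorted[0] + 1.0], s_sorted[boundary]))
    tpr = np.concatenate(([0.0], tp / n_pos))
    fpr = np.concatenate(([0.0], fp / n_neg))
    if thresholds[-1] > 0:  # threshold 0 calls everything positive
        thresholds = np.concatenate((thresholds, [0.0]))
        tpr = np.concatenate((tpr, [1.0]))
        fpr = np.concatenate((fpr, [1.0]))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr)


def auc(curve: RocCurve) -> float:
    """Trapezoidal integral of TPR over FPR."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def roc_auc(scored: Sequence[ScoredSlide]) -> float:
    return auc(roc_curve(scored))


def log_loss(scored: Sequence[ScoredSlide]) -> float:
    """Mean binary cross-entropy with scores clipped to [1e-15, 1-1e-15]."""
    if not len(scored):
        raise UndefinedMetricError("log loss of an empty set")
    scores, labels = _split_scores(scored)
    p = np.clip(scores, _CLIP, 1 - _CLIP)
    return float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))


def threshold_metrics(
    scored: Sequence[ScoredSlide], threshold: float = 0.5
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with positive call iff score >= t."""
    scores, labels = _split_scores(scored)
    if len(scores) == 0:
        raise UndefinedMetricError("metrics of an empty set")
    calls = scores >= threshold
    tp = int((calls & (labels == 1)).sum())
    tn = int((~calls & (labels == 0)).sum())
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if n_pos == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive slides")
    if n_neg == 0:
        raise UndefinedMetricError("specificity undefined: no negative slides")
    return (tp + tn) / len(scores), tp / n_pos, tn / n_neg


def bootstrap_ci(
    scored: Sequence[ScoredSlide],
    metric: Callable[[Sequence[ScoredSlide]], float],
    n_iter: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    max_redraws: int = 1000,
) -> tuple[float, float]:
    """Percentile bootstrap interval over slide-level resamples.

    Resamples on which the metric is undefined (e.g. single-class draws for
    AUC) are redrawn; if no computable resample can be drawn the interval is
    an error.
    """
    if not len(scored):
        raise UndefinedMetricError("bootstrap of an empty set")
    rng = np.random.default_rng(seed)
    n = len(scored)
    stats = np.empty(n_iter)
    for b in range(n_iter):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            sample = [scored[i] for i in idx]
            try:
                stats[b] = metric(sample)
                break
            except UndefinedMetricError:
                continue
        else:
            raise UndefinedMetricError(
                "metric undefined on every bootstrap resample drawn"
            )
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass(frozen=True)
class SplitSpec:
    """Test-split design: 1:1 (equal) or ratio:1 (clinical) negative:neoplastic."""

    design: str  # "equal_balance" | "clinical_balance"
    n_neoplastic: int
    negative_to_neoplastic_ratio: int = 10
    class_quotas: dict | None = None  # optional {cytology class value: count}

    def __post_init__(self):
        if self.design not in {"equal_balance", "clinical_balance"}:
            raise ValueError(f"unknown split design {self.design!r}")
        if self.negative_to_neoplastic_ratio < 1:
            raise ValueError("ratio must be >= 1")

    @property
    def n_negative(self) -> int:
        if self.design == "equal_balance":
            return self.n_neoplastic
        return self.negative_to_neoplastic_ratio * self.n_neoplastic


def build_test_split(
    pool: Sequence[SlideRecord], spec: SplitSpec, seed: int = 0
) -> list[SlideRecord]:
    """Sample a test split without replacement from a record pool.

    Honours optional per-class quotas exactly; otherwise draws the requested
    numbers of negative and neoplastic records irrespective of class.  Raises
    :class:`ShortfallError` naming the deficient class when the pool cannot
    satisfy the request.
    """
    rng = np.random.default_rng(seed)
    chosen: list[SlideRecord] = []
    if spec.class_quotas:
        total_by_label = {NEGATIVE: 0, NEOPLASTIC: 0}
        for cls_value, quota in spec.class_quotas.items():
            members = [r for r in pool if r.cytology_class.value == str(cls_value)]
            if len(members) < quota:
                raise ShortfallError(
                    f"pool has {len(members)} class-{cls_value} slides, need {quota}",
                    deficient=str(cls_value),
                )
            picks = rng.choice(len(members), size=quota, replace=False)
            chosen.extend(members[i] for i in picks)
            total_by_label[members[0].label] += quota if members else 0
        if total_by_label[NEGATIVE] != spec.n_negative or total_by_label[
            NEOPLASTIC
        ] != spec.n_neoplastic:
            raise ValueError("class quotas do not sum to the design totals")
        return chosen
    for label, want in ((NEGATIVE, spec.n_negative), (NEOPLASTIC, spec.n_neoplastic)):
        members = [r for r in pool if r.label == label]
        if len(members) < want:
            raise ShortfallError(
                f"pool has {len(members)} {label} slides, need {want}", deficient=label
            )
        picks = rng.choice(len(members), size=want, replace=False)
        chosen.extend(members[i] for i in picks)
    return chosen


@dataclass
class MetricEstimate:
    point: float
    lo: float
    hi: float

    def as_dict(self) -> dict:
        return {"point": self.point, "ci_lo": self.lo, "ci_hi": self.hi}


@dataclass
class MetricsReport:
    roc_auc: MetricEstimate
    log_loss: MetricEstimate
    accuracy: MetricEstimate
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    n_bootstrap: int
    decision_threshold: float
    n_slides: int

    def as_dict(self) -> dict:
        out = {
            name: getattr(self, name).as_dict()
            for name in ("roc_auc", "log_loss", "accuracy", "sensitivity", "specificity")
        }
        out["n_bootstrap"] = self.n_bootstrap
        out["decision_threshold"] = self.decision_threshold
        out["n_slides"] = self.n_slides
        return out


def evaluate(
    scored: Sequence[ScoredSlide],
    threshold: float = 0.5,
    n_bootstrap: int = 1000,
    seed: int = 0,
    report_path: str | Path | None = None,
    roc_plot_path: str | Path | None = None,
) -> MetricsReport:
    """Compute all slide-level metrics with percentile bootstrap CIs."""
    metrics: dict[str, Callable] = {
        "roc_auc": roc_auc,
        "log_loss": log_loss,
        "accuracy": lambda s: threshold_metrics(s, threshold)[0],
        "sensitivity": lambda s: threshold_metrics(s, threshold)[1],
        "specificity": lambda s: threshold_metrics(s, threshold)[2],
    }
    estimates = {}
    for i, (name, fn) in enumerate(metrics.items()):
        point = fn(scored)
        lo, hi = bootstrap_ci(scored, fn, n_iter=n_bootstrap, seed=seed + i)
        # the point estimate always lies inside the reported interval
        estimates[name] = MetricEstimate(point=point, lo=min(lo, point), hi=max(hi, point))
    report = MetricsReport(
        **estimates,
        n_bootstrap=n_bootstrap,
        decision_threshold=threshold,
        n_slides=len(scored),
    )
    if report_path is not None:
        Path(report_path).write_text(json.dumps(report.as_dict(), indent=2))
    if roc_plot_path is not None:
        plot_roc(scored, roc_plot_path)
    return report


def plot_roc(scored: Sequence[ScoredSlide], path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curve = roc_curve(scored)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.fpr, curve.tpr, lw=1.5, label=f"AUC = {auc(curve):.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def score_manifest(
    records: Sequence[SlideRecord], scores: dict[str, float], split: str | None = "test"
) -> list[ScoredSlide]:
    """Join manifest records with a predictions table; missing -> error."""
    scored = []
    for rec in records:
        if split is not None and rec.split != split:
            continue
        if rec.slide_id not in scores:
            raise KeyError(f"no prediction for slide {rec.slide_id}")
        scored.append(
            ScoredSlide(slide_id=rec.slide_id, score=scores[rec.slide_id], true_label=rec.label)
        )
    return scored
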