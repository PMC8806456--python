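"""Diagnostic metric panel, ROC/AUC, merged-layer width search and ablation.

The panel mirrors the standard diagnostic-test report: sensitivity,
specificity, positive and negative predictive value, accuracy and AUC.
Metrics with a zero denominator are reported as None and flagged, never
silently coerced to 0.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .fmc_core import ArchitectureSpec, build_architecture
from .training import TrainConfig, TrainHistory, train

logger = logging.getLogger(__name__)

DEFAULT_WIDTHS = (32, 64, 128, 256, 512, 1024, 2048, 4096)


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    auc: float | None = None
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class SearchResult:
    widths: list[int]
    accuracies: list[float]
    selected_width: int
    failures: dict[int, str] = field(default_factory=dict)


def confusion(scores: np.ndarray, labels: np.ndarray,
              threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts calling positive where score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise EvaluationError("cannot evaluate an empty score set")
    if scores.shape != labels.shape:
        raise EvaluationError("scores and labels differ in length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: int, den: int):
    return num / den if den > 0 else None


def metric_panel(c: ConfusionCounts) -> MetricReport:
    """Closed-form panel from confusion counts; AUC is filled separately."""
    values = {
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "ppv": _ratio(c.tp, c.tp + c.fp),
        "npv": _ratio(c.tn, c.tn + c.fn),
        "accuracy": _ratio(c.tp + c.tn, c.n),
    }
    undefined = tuple(k for k, v in values.items() if v is None)
    return MetricReport(**values, undefined=undefined)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[RocCurve, float]:
    """ROC curve from a full threshold sweep plus trapezoid-rule AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr), auc


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney (tie-corrected midrank) AUC — independent of roc_auc.

    AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg) with midranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("rank AUC requires both classes present")
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_model(model, x: np.ndarray, y: np.ndarray,
                   threshold: float = 0.5, batch_size: int = 64) -> MetricReport:
    """Full panel (including AUC) of a model on one split."""
    probs = np.concatenate([model.predict_proba(x[i:i + batch_size])
                            for i in range(0, len(x), batch_size)])
    report = metric_panel(confusion(probs, y, threshold))
    try:
        _, report.auc = roc_auc(probs, y)
    except EvaluationError:
        report.undefined = report.undefined + ("auc",)
    return report


# ---------------------------------------------------------------------------
# protocols

def _default_trainer(base_spec: ArchitectureSpec, config: TrainConfig,
                     splits, seed: int):
    def trainer(width: int) -> float:
        spec = dataclasses.replace(base_spec, merged_width=width)
        model = build_architecture(spec, rng=np.random.default_rng(seed))
        model, _ = train(model, splits, config)
        x_val, y_val = splits["val"]
        probs = model.predict_proba(x_val)
        return float(((probs >= 0.5).astype(int) == y_val).mean())
    return trainer


def width_search(widths=DEFAULT_WIDTHS, splits=None,
                 base_spec: ArchitectureSpec | None = None,
                 config: TrainConfig | None = None,
                 trainer=None, seed: int = 0) -> SearchResult:
    """Sweep merged-layer widths, scoring each by validation accuracy.

    One model is trained per candidate width with a fixed seed; the width
    with the highest validation accuracy wins, ties going to the smallest
    width.  ``trainer`` may be injected (width -> accuracy) for testing or
    alternative protocols; widths whose training fails are excluded with a
    warning.
    """
    widths = list(widths)
    if not widths:
        raise ValueError("width_search needs at least one candidate width")
    if trainer is None:
        if splits is None or base_spec is None or config is None:
            raise ValueError("either a trainer or (splits, base_spec, config) is required")
        trainer = _default_trainer(base_spec, config, splits, seed)
    kept, accs, failures = [], [], {}
    for w in widths:
        try:
            accs.append(float(trainer(w)))
            kept.append(w)
        except Exception as e:  # noqa: BLE001 - per-width isolation is the contract
            logger.warning("width %d failed: %s", w, e)
            failures[w] = str(e)
    if not kept:
        raise EvaluationError("every candidate width failed to train")
    best = max(range(len(kept)), key=lambda i: (accs[i], -kept[i]))
    return SearchResult(widths=kept, accuracies=accs,
                        selected_width=kept[best], failures=failures)


def run_ablation(variants, splits, config: TrainConfig,
                 base_spec: ArchitectureSpec | None = None,
                 seed: int = 0, threshold: float = 0.5) -> pd.DataFrame:
    """Train each connection-pattern variant and report its test-set panel.

    Returns one row per variant (name, accuracy, sensitivity, specificity,
    PPV, NPV, AUC); per-variant failures are isolated into NaN rows.
    """
    base_spec = base_spec or ArchitectureSpec(size_profile="tiny")
    rows = []
    for variant in variants:
        if isinstance(variant, str):
            spec = dataclasses.replace(base_spec, variant=variant)
        else:
            spec = variant
        name = spec.variant
        try:
            model = build_architecture(spec, rng=np.random.default_rng(seed))
            model, _ = train(model, splits, config)
            x_test, y_test = splits["test"]
            report = evaluate_model(model, x_test, y_test, threshold)
            rows.append({"variant": name, "accuracy": report.accuracy,
                         "sensitivity": report.sensitivity,
                         "specificity": report.specificity,
                         "ppv": report.ppv, "npv": report.npv, "auc": report.auc})
        except Exception as e:  # noqa: BLE001 - per-variant isolation is the contract
            logger.warning("variant %s failed: %s", name, e)
            rows.append({"variant": name, "accuracy": np.nan, "sensitivity": np.nan,
                         "specificity": np.nan, "ppv": np.nan, "npv": np.nan,
                         "auc": np.nan})
    return pd.DataFrame(rows)
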