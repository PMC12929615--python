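"""Localization and classification metrics for saliency evaluation.

Implements the pointing-game style protocol used for weakly supervised
pathology localization:

* **hit rate** — for each (image, pathology) case with a non-empty expert
  mask, find the saliency map's maximum pixel; the case is a *hit* if that
  pixel lies inside the mask.  The hit rate is the fraction of hits.
* **mIoU over TP/FP/FN** — saliency maps are binarized with one tuned
  threshold per pathology; a case is TP (positive label, non-empty predicted
  mask), FP (negative label, non-empty mask), FN (positive label, empty
  mask) or TN (negative label, empty mask).  IoU is computed for TPs, FPs
  and FNs contribute 0 by convention (their IoU against the respective
  empty set is 0), TNs are excluded, and the mean is taken over all
  included cases.  A TP-only variant averages over TPs alone.
* **classification metrics** — AUROC, plus sensitivity/specificity/accuracy
  at the Youden threshold (maximizing sensitivity + specificity on a
  validation split).
* **bootstrap CIs** — percentile intervals from resampling cases with
  replacement.

Determinism conventions: saliency argmax ties break toward the smallest
row-major pixel index; binarization is strict (``value > t``); threshold
ties break toward the larger threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .saliency import SaliencyMap

__all__ = [
    "EvalCase",
    "MetricReport",
    "hit_indicator",
    "hit_rate",
    "binarize",
    "iou",
    "case_category",
    "miou",
    "tune_thresholds",
    "classification_thresholds",
    "auroc",
    "sensitivity_specificity_accuracy",
    "bootstrap_ci",
    "metrics_table",
]


def _map_values(m: SaliencyMap | np.ndarray) -> np.ndarray:
    return m.values if isinstance(m, SaliencyMap) else np.asarray(m, dtype=np.float64)


def _as_mask(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    return m.astype(bool)


@dataclass
class EvalCase:
    """One (image, pathology) pair for metric computation."""

    image_id: str
    label_name: str
    ground_truth_label: int
    saliency: SaliencyMap | np.ndarray
    gt_mask: np.ndarray | None = None
    hit: int | None = field(default=None)

    def __post_init__(self) -> None:
        if self.ground_truth_label not in (0, 1):
            raise ValueError("ground_truth_label must be 0 or 1")
        if self.gt_mask is not None:
            self.gt_mask = _as_mask(self.gt_mask).astype(np.uint8)

    @property
    def has_nonempty_mask(self) -> bool:
        return self.gt_mask is not None and bool(self.gt_mask.any())


@dataclass(frozen=True)
class MetricReport:
    """Point estimate with percentile-bootstrap bounds."""

    name: str
    estimate: float
    ci_lower: float | None
    ci_upper: float | None
    n_cases: int
    resamples: int
    skipped_resamples: int = 0

    def __post_init__(self) -> None:
        if self.resamples > 0 and self.ci_lower is not None:
            if not (self.ci_lower <= self.estimate + 1e-12
                    and self.estimate - 1e-12 <= self.ci_upper):
                raise ValueError(
                    f"{self.name}: estimate {self.estimate} outside "
                    f"CI [{self.ci_lower}, {self.ci_upper}]"
                )


def hit_indicator(
    smap: SaliencyMap | np.ndarray,
    gt_mask: np.ndarray,
    permissive: bool = False,
) -> int:
    """1 iff the saliency argmax pixel lies inside the ground-truth mask.

    Ties at the maximum break toward the smallest row-major pixel index
    (deterministic; block-constant maps make ties common).  With
    ``permissive=True`` the case counts as a hit if *any* maximal pixel is
    inside the mask.
    """
    values = _map_values(smap)
    gt = _as_mask(gt_mask)
    if values.shape != gt.shape:
        raise ValueError(f"shape mismatch: map {values.shape} vs mask {gt.shape}")
    if not gt.any():
        raise ValueError("hit indicator undefined for an empty ground-truth mask")
    if permissive:
        at_max = values == values.max()
        return int((at_max & gt).any())
    idx = int(np.argmax(values))  # first occurrence in row-major order
    return int(gt.flat[idx])


def hit_rate(cases: Sequence[EvalCase]) -> float:
    """Mean hit indicator over cases; every case must have ``hit`` computed."""
    if len(cases) == 0:
        raise ValueError("hit rate undefined for an empty case set")
    hits = []
    for c in cases:
        if c.hit is None:
            raise ValueError(f"case {c.image_id}/{c.label_name} has no computed hit")
        hits.append(c.hit)
    return float(np.mean(hits))


def compute_hits(cases: Sequence[EvalCase], permissive: bool = False) -> list[EvalCase]:
    """Fill ``hit`` for every case with a non-empty mask; returns those cases.

    Cases without a (non-empty) ground-truth mask are excluded — the hit
    indicator is undefined for them.
    """
    out = []
    for c in cases:
        if c.has_nonempty_mask:
            c.hit = hit_indicator(c.saliency, c.gt_mask, permissive=permissive)
            out.append(c)
    return out


def binarize(smap: SaliencyMap | np.ndarray, threshold: float) -> np.ndarray:
    """Strict thresholding: pixel is 1 iff its saliency value exceeds ``threshold``."""
    if not np.isfinite(threshold) and threshold != -np.inf:
        raise ValueError(f"threshold must be finite or -inf, got {threshold}")
    return (_map_values(smap) > threshold).astype(np.uint8)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection area over union area of two binary masks."""
    a, b = _as_mask(a), _as_mask(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("IoU undefined when both masks are empty")
    return float(np.logical_and(a, b).sum() / union)


def case_category(label: int, predicted_mask: np.ndarray) -> str:
    """TP/FP/FN/TN from the ground-truth label and predicted-mask emptiness."""
    nonempty = bool(np.asarray(predicted_mask).any())
    if label == 1:
        return "TP" if nonempty else "FN"
    return "FP" if nonempty else "TN"


def _case_iou(case: EvalCase, threshold: float) -> tuple[str, float]:
    pred = binarize(case.saliency, threshold)
    cat = case_category(case.ground_truth_label, pred)
    if cat == "TP":
        if case.gt_mask is None:
            raise ValueError(
                f"case {case.image_id}/{case.label_name}: positive label without gt mask"
            )
        if not case.gt_mask.any():
            # positive label but annotator drew nothing: overlap is zero
            return cat, 0.0
        return cat, iou(pred, case.gt_mask)
    # FN: empty prediction vs non-empty truth -> 0; FP: prediction vs empty truth -> 0
    return cat, 0.0


def miou(
    cases: Sequence[EvalCase],
    threshold: float | dict[str, float],
    mode: str = "tp_fp_fn",
) -> float:
    """Mean IoU of thresholded saliency against ground truth.

    ``threshold`` is a single scalar or a per-label-name dict.  ``tp_fp_fn``
    averages over TP, FP and FN cases with FP/FN contributing zero (they are
    mismatches against an empty set); TNs are excluded.  ``tp_only``
    averages over TP cases alone.
    """
    if mode not in ("tp_fp_fn", "tp_only"):
        raise ValueError(f"unknown mode {mode!r}")
    vals = []
    for c in cases:
        t = threshold[c.label_name] if isinstance(threshold, dict) else threshold
        cat, v = _case_iou(c, float(t))
        if cat == "TN":
            continue
        if mode == "tp_only" and cat != "TP":
            continue
        vals.append(v)
    if not vals:
        raise ValueError(f"no cases to average in mode {mode!r}")
    return float(np.mean(vals))


def _threshold_candidates(values: np.ndarray, grid_size: int) -> np.ndarray:
    qs = np.linspace(0.0, 1.0, grid_size)
    cand = np.unique(np.quantile(values, qs))
    return np.concatenate(([-np.inf], cand))


def tune_thresholds(
    val_cases: Sequence[EvalCase],
    grid_size: int = 100,
    mode: str = "tp_fp_fn",
) -> dict[str, float]:
    """Per-label saliency threshold maximizing validation mIoU.

    Candidates are ``grid_size`` quantiles of the pooled validation saliency
    values for that label (deduplicated) plus a ``-inf`` sentinel (the
    everything-is-predicted mask); ties break toward the larger threshold.
    """
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    by_label: dict[str, list[EvalCase]] = {}
    for c in val_cases:
        by_label.setdefault(c.label_name, []).append(c)
    thresholds: dict[str, float] = {}
    for label, cases in by_label.items():
        pooled = np.concatenate([_map_values(c.saliency).ravel() for c in cases])
        candidates = _threshold_candidates(pooled, grid_size)
        if candidates.size == 0:
            raise ValueError(f"no threshold candidates for label {label!r}")
        best_t, best_v = None, -np.inf
        for t in candidates:
            try:
                v = miou(cases, float(t), mode=mode)
            except ValueError:  # all cases TN at this threshold
                continue
            if v > best_v or (v == best_v and (best_t is None or t > best_t)):
                best_t, best_v = float(t), v
        if best_t is None:
            raise ValueError(f"threshold tuning degenerate for label {label!r}")
        thresholds[label] = best_t
    return thresholds


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (ties contribute one half).

    Equals the probability that a random positive case outscores a random
    negative one (the normalized Mann-Whitney U statistic).  Undefined when
    only one class is present.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined with a single class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def classification_thresholds(
    scores: dict[str, np.ndarray],
    labels: dict[str, np.ndarray],
) -> dict[str, float]:
    """Per-label Youden threshold: maximize sensitivity + specificity.

    The classification rule is ``score > t``.  Candidates are midpoints
    between adjacent sorted unique scores plus sentinels outside the score
    range; ties break toward the larger threshold.  Labels with a single
    class are skipped with a warning.
    """
    out: dict[str, float] = {}
    for name in scores:
        s = np.asarray(scores[name], dtype=np.float64)
        y = np.asarray(labels[name])
        if len(np.unique(y)) < 2:
            warnings.warn(
                f"label {name!r} has a single class; Youden threshold skipped",
                stacklevel=2,
            )
            continue
        uniq = np.unique(s)
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
        best_t, best_j = None, -np.inf
        for t in candidates:
            pred = s > t
            sens = (pred & (y == 1)).sum() / (y == 1).sum()
            spec = (~pred & (y == 0)).sum() / (y == 0).sum()
            j = sens + spec
            if j > best_j or (j == best_j and t > best_t):
                best_t, best_j = float(t), float(j)
        out[name] = best_t
    return out


def sensitivity_specificity_accuracy(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float, float]:
    """Operating-point metrics at a fixed threshold (rule: ``score > t``)."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    pred = s > threshold
    pos, neg = (y == 1).sum(), (y == 0).sum()
    sens = float((pred & (y == 1)).sum() / pos) if pos else float("nan")
    spec = float((~pred & (y == 0)).sum() / neg) if neg else float("nan")
    acc = float((pred == (y == 1)).mean())
    return sens, spec, acc


def bootstrap_ci(
    metric: Callable[[Sequence], float],
    cases: Sequence,
    resamples: int = 100_000,
    seed: int = 0,
    name: str = "metric",
    alpha: float = 0.05,
) -> MetricReport:
    """Percentile bootstrap CI by resampling cases with replacement.

    Each resample draws N cases (same N) with replacement and recomputes the
    metric; the interval is the ``alpha/2`` and ``1 - alpha/2`` percentiles.
    Resamples on which the metric is undefined (raises ``ValueError``, e.g.
    a single-class draw) are skipped and counted.  Deterministic given
    ``seed``.  ``resamples=0`` reports the point estimate only.
    """
    cases = list(cases)
    n = len(cases)
    if n == 0:
        raise ValueError("cannot bootstrap an empty case set")
    estimate = float(metric(cases))
    if resamples < 1:
        return MetricReport(name, estimate, None, None, n, 0)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(resamples, n))
    stats, skipped = [], 0
    for row in idx:
        try:
            stats.append(float(metric([cases[i] for i in row])))
        except ValueError:
            skipped += 1
    if not stats:
        raise ValueError(f"metric {name!r} undefined on every resample")
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    # with heavy skipping the point estimate can fall outside the percentile
    # band; widen to include it rather than report an inconsistent interval
    lo, hi = min(float(lo), estimate), max(float(hi), estimate)
    return MetricReport(name, estimate, lo, hi, n, len(stats), skipped)


def metrics_table(reports: Sequence[tuple[str, MetricReport]]) -> pd.DataFrame:
    """Tabulate (label, metric) reports: one row each, CI bounds and N included."""
    rows = []
    for label, r in reports:
        rows.append(
            {
                "label": label,
                "metric": r.name,
                "estimate": r.estimate,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "n_cases": r.n_cases,
                "resamples": r.resamples,
                "skipped_resamples": r.skipped_resamples,
            }
        )
    return pd.DataFrame(rows)
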