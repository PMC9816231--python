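"""Model evaluation: ROC/confusion metrics with bootstrap CIs, integrated
discrimination improvement (IDI), and nested cross-validation stability.

AUC uses the rank (Mann-Whitney) statistic with midranks for ties, so it is
invariant under strictly monotone transforms of the scores.  Confusion
metrics are computed at a probability cut-off (default 0.5, the natural
threshold under class-balanced logistic weights).  Confidence intervals are
percentile bootstrap over patients; resamples that lose one of the classes
are redrawn so the number of effective resamples is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "IDIResult",
    "NestedCVReport",
    "auc_score",
    "confusion_metrics",
    "evaluate",
    "compute_idi",
    "nested_cv",
]

_METRICS = ("auc", "accuracy", "sensitivity", "specificity", "ppv", "npv")


def auc_score(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve via the midrank statistic."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def confusion_metrics(labels: np.ndarray, probs: np.ndarray, threshold: float) -> Dict[str, float]:
    y = np.asarray(labels).astype(int)
    pred = (np.asarray(probs, dtype=float) >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    out = {
        "accuracy": (tp + tn) / y.size,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "ppv": tp / (tp + fp) if tp + fp else np.nan,
        "npv": tn / (tn + fn) if tn + fn else np.nan,
    }
    out["confusion"] = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    return out


@dataclass
class EvaluationReport:
    variant: str
    cohort: str
    n: int
    threshold: float
    metrics: Dict[str, float]
    ci_95: Dict[str, List[float]]
    confusion: Dict[str, int]
    n_bootstrap: int

    def as_dict(self) -> dict:
        return {
            "variant": self.variant,
            "cohort": self.cohort,
            "n": self.n,
            "threshold": self.threshold,
            "n_bootstrap": self.n_bootstrap,
            "metrics": self.metrics,
            "ci_95": self.ci_95,
            "confusion": self.confusion,
        }


def evaluate(
    labels: Sequence[int],
    probs: Sequence[float],
    variant: str = "",
    cohort: str = "test",
    threshold: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvaluationReport:
    """Point metrics plus 95% percentile-bootstrap confidence intervals."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probs, dtype=float)
    if y.size != p.size:
        raise ValueError("labels and probabilities differ in length")
    point = {"auc": auc_score(y, p)}
    cm = confusion_metrics(y, p, threshold)
    confusion = cm.pop("confusion")
    point.update(cm)

    rng = np.random.default_rng(seed)
    boot = {m: [] for m in _METRICS}
    n = y.size
    redraws = 0
    for _ in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                break
            redraws += 1
        yb, pb = y[idx], p[idx]
        boot["auc"].append(auc_score(yb, pb))
        cmb = confusion_metrics(yb, pb, threshold)
        for m in _METRICS[1:]:
            boot[m].append(cmb[m])
    if redraws:
        logger.info("redrew %d single-class bootstrap resamples", redraws)
    if n_boot > 0:
        with np.errstate(invalid="ignore"):
            ci = {
                m: [float(v) for v in np.nanpercentile(boot[m], [2.5, 97.5])]
                for m in _METRICS
            }
    else:
        ci = {m: [float("nan"), float("nan")] for m in _METRICS}
    return EvaluationReport(
        variant=variant,
        cohort=cohort,
        n=n,
        threshold=threshold,
        metrics={k: float(v) for k, v in point.items()},
        ci_95=ci,
        confusion=confusion,
        n_bootstrap=n_boot,
    )


@dataclass
class IDIResult:
    idi: float
    z: float
    p_value: float
    baseline: str = "baseline"
    extended: str = "extended"


def compute_idi(
    base_probs: Sequence[float],
    ext_probs: Sequence[float],
    labels: Sequence[int],
    baseline: str = "baseline",
    extended: str = "extended",
) -> IDIResult:
    """Integrated discrimination improvement between two risk models.

    IDI = (mean p_ext - mean p_base | events) + (mean p_base - mean p_ext |
    non-events); the z statistic uses the standard error of the per-patient
    probability differences within each outcome group.
    """
    y = np.asarray(labels).astype(int)
    pb = np.asarray(base_probs, dtype=float)
    pe = np.asarray(ext_probs, dtype=float)
    if not (y.size == pb.size == pe.size):
        raise ValueError("probability vectors must cover the same patients")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 events and 2 non-events")
    d = pe - pb
    d_ev, d_ne = d[y == 1], d[y == 0]
    idi = float(d_ev.mean() - d_ne.mean())
    se = float(np.sqrt(d_ev.var(ddof=1) / n_pos + d_ne.var(ddof=1) / n_neg))
    z = idi / se if se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return IDIResult(idi=idi, z=float(z), p_value=p, baseline=baseline, extended=extended)


@dataclass
class NestedCVReport:
    outer_splits: int
    auc_by_variant: Dict[str, List[float]]
    selected_by_split: List[Dict[str, List[str]]]
    variability_sd: Dict[str, float] = field(default_factory=dict)
    variability_range: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for v, aucs in self.auc_by_variant.items():
            arr = np.asarray(aucs, dtype=float)
            self.variability_sd[v] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            self.variability_range[v] = float(arr.max() - arr.min()) if arr.size else 0.0


def nested_cv(
    run_split: Callable[[int], Dict[str, object]],
    outer_splits: int = 5,
    seed: int = 0,
) -> NestedCVReport:
    """Stability assessment over ``outer_splits`` random outer splits.

    ``run_split(split_seed)`` must rerun the entire selection + training
    pipeline inside the outer training set and return
    ``{"auc": {variant: test_auc}, "selected": {kind: [features]}}``.
    Reported variability per variant is both the standard deviation and the
    range of the outer test AUCs.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=outer_splits)
    auc_by_variant: Dict[str, List[float]] = {}
    selected: List[Dict[str, List[str]]] = []
    for s in seeds:
        res = run_split(int(s))
        for variant, auc in res["auc"].items():
            auc_by_variant.setdefault(variant, []).append(float(auc))
        selected.append({k: list(v) for k, v in res.get("selected", {}).items()})
    return NestedCVReport(
        outer_splits=outer_splits,
        auc_by_variant=auc_by_variant,
        selected_by_split=selected,
    )
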