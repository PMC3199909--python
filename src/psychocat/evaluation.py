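"""Screening evaluation: sample splitting, ROC/AUC, specificity-targeted
cutoff selection, agreement statistics and CAT efficiency summaries."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

from .cat import CatTrace

__all__ = [
    "SplitSpec",
    "split_sample",
    "roc_and_auc",
    "choose_cutoff",
    "sens_spec",
    "cohens_kappa",
    "efficiency_summary",
    "EvalReport",
    "evaluate_decisions",
]


@dataclass
class SplitSpec:
    calibration_ids: np.ndarray
    validation_ids: np.ndarray
    seed: int


def split_sample(person_ids, n_calibration: int, seed: int = 0) -> SplitSpec:
    """Uniform random split without replacement into calibration/validation."""
    ids = np.asarray(list(person_ids), int)
    if n_calibration >= ids.size:
        raise ValueError("n_calibration must be smaller than the cohort")
    if n_calibration < 1:
        raise ValueError("n_calibration must be positive")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    return SplitSpec(
        calibration_ids=np.sort(perm[:n_calibration]),
        validation_ids=np.sort(perm[n_calibration:]),
        seed=seed,
    )


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_and_auc(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[pd.DataFrame, float, tuple[float, float]]:
    """ROC points, rank-based AUC (ties count one half) and a stratified
    percentile-bootstrap CI."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present for ROC analysis")
    auc = _mann_whitney_auc(scores, labels)

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    pos, neg = scores[labels], scores[~labels]
    tpr = [(pos >= t).mean() for t in thresholds]
    fpr = [(neg >= t).mean() for t in thresholds]
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        p = pos[rng.integers(len(pos), size=len(pos))]
        n = neg[rng.integers(len(neg), size=len(neg))]
        s = np.concatenate([p, n])
        l = np.concatenate([np.ones(len(p), bool), np.zeros(len(n), bool)])
        boots[b] = _mann_whitney_auc(s, l)
    alpha = 1 - ci_level
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return roc, auc, (float(lo), float(hi))


def choose_cutoff(scores, labels, target_specificity: float = 0.90) -> float:
    """Smallest observed score (or +inf) whose rule ``positive iff score >=
    cutoff`` reaches the target specificity — maximizing sensitivity subject
    to the specificity constraint."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if not 0 < target_specificity < 1:
        if target_specificity == 0:
            return float(scores.min())
        raise ValueError("target specificity must be in [0, 1)")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to choose a cutoff")
    neg = scores[~labels]
    for c in np.unique(scores):  # ascending
        if (neg < c).mean() >= target_specificity:
            return float(c)
    import warnings

    warnings.warn("target specificity only attainable by the all-negative rule")
    return float(np.inf)


def _wilson(k: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def sens_spec(decisions, labels) -> dict:
    """Sensitivity/specificity with Wilson CIs plus overall correct fraction."""
    decisions = np.asarray(decisions, bool)
    labels = np.asarray(labels, bool)
    if decisions.size == 0:
        raise ValueError("empty inputs")
    if decisions.shape != labels.shape:
        raise ValueError("decisions and labels must have equal length")
    tp = int(np.sum(decisions & labels))
    fn = int(np.sum(~decisions & labels))
    fp = int(np.sum(decisions & ~labels))
    tn = int(np.sum(~decisions & ~labels))
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both label classes must be present")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "sensitivity": sens,
        "sensitivity_ci": _wilson(tp, tp + fn),
        "specificity": spec,
        "specificity_ci": _wilson(tn, tn + fp),
        "correct_fraction": (tp + tn) / decisions.size,
        "confusion": {"tp": tp, "fn": fn, "fp": fp, "tn": tn},
    }


def cohens_kappa(a, b) -> float:
    """Cohen's kappa for two binary vectors; exactly 1 when chance agreement
    is 1 and the vectors agree."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("inputs must be nonempty and of equal length")
    p_o = float(np.mean(a == b))
    p_a, p_b = a.mean(), b.mean()
    p_e = p_a * p_b + (1 - p_a) * (1 - p_b)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1 - p_e))


def efficiency_summary(
    traces: list[CatTrace],
    full_scores: np.ndarray | None = None,
    criterion_scores: np.ndarray | None = None,
) -> dict:
    """Decision-rule efficiency: how many items were needed, who never
    converged, and where the undecided sit (near the cutoff, typically)."""
    if not traces:
        raise ValueError("no traces to summarize")
    n_items = np.array([t.n_items for t in traces])
    decided = np.array([t.decision != "undecided" for t in traces])
    out: dict = {"n_persons": len(traces), "decided_fraction": float(decided.mean())}
    if decided.any():
        d = n_items[decided]
        out.update(
            mean_items=float(d.mean()),
            sd_items=float(d.std(ddof=1)) if d.size > 1 else 0.0,
            median_items=float(np.median(d)),
            quantiles={
                str(q): float(np.quantile(d, q)) for q in (0.25, 0.5, 0.75, 0.9)
            },
        )
        kmax = int(n_items.max())
        ks = np.arange(1, kmax + 1)
        out["decided_by_k"] = {
            int(k): float(np.mean(decided & (n_items <= k))) for k in ks
        }
    if full_scores is not None and (~decided).any():
        out["undecided_mean_theta"] = float(np.asarray(full_scores)[~decided].mean())
    if criterion_scores is not None and (~decided).any():
        out["undecided_mean_criterion"] = float(
            np.asarray(criterion_scores, float)[~decided].mean()
        )
    return out


@dataclass
class EvalReport:
    group: str
    criterion: str
    cutoff: float
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    kappa: float
    correct_fraction: float
    confusion: dict
    efficiency: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_decisions(
    theta_hat,
    labels,
    cutoff: float,
    group: str = "validation",
    criterion: str = "clinical",
    efficiency: dict | None = None,
    seed: int = 0,
) -> EvalReport:
    """Assemble the full report: AUC on the continuous score, then the
    confusion-table statistics of the dichotomized score at ``cutoff``."""
    theta_hat = np.asarray(theta_hat, float)
    labels = np.asarray(labels, bool)
    _, auc, auc_ci = roc_and_auc(theta_hat, labels, seed=seed)
    positive = theta_hat >= cutoff
    ss = sens_spec(positive, labels)
    kappa = cohens_kappa(positive, labels)
    return EvalReport(
        group=group,
        criterion=criterion,
        cutoff=float(cutoff),
        auc=auc,
        auc_ci=auc_ci,
        sensitivity=ss["sensitivity"],
        sensitivity_ci=ss["sensitivity_ci"],
        specificity=ss["specificity"],
        specificity_ci=ss["specificity_ci"],
        kappa=kappa,
        correct_fraction=ss["correct_fraction"],
        confusion=ss["confusion"],
        efficiency=efficiency or {},
    )
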