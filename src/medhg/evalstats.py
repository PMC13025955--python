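"""Classification metrics, DeLong's paired AUROC test, bootstrap intervals.

AUROC is computed through the tie-corrected Mann-Whitney statistic
(midranks; ties count one half), which is also the quantity DeLong's
structural components decompose.  AUPRC is the step-integrated
precision-recall area (average precision).  Thresholded metrics come from
the confusion matrix at an explicit, recorded threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import average_precision_score


def auroc(y, scores) -> float:
    """Mann-Whitney AUROC with tie correction (ties count 1/2)."""
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined with a single class")
    ranks = rankdata(scores)  # midranks
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(y, scores) -> float:
    return float(average_precision_score(np.asarray(y, int), np.asarray(scores, float)))


@dataclass
class MetricsReport:
    auroc: float
    auprc: float
    f1: float
    precision: float
    recall: float
    specificity: float
    threshold: float
    n: int
    tp: int
    fp: int
    fn: int
    tn: int
    undefined: list = field(default_factory=list)
    ci: dict = field(default_factory=dict)
    n_boot: int = 0
    seed: int | None = None

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("auroc", "auprc", "f1", "precision", "recall", "specificity",
              "threshold", "n", "tp", "fp", "fn", "tn", "n_boot", "seed")}
        d["undefined"] = list(self.undefined)
        d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


def classification_metrics(y, scores, threshold: float = 0.5) -> MetricsReport:
    """Full metric battery; zero-denominator ratios report 0 and are flagged."""
    y = np.asarray(y, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s) or len(y) == 0:
        raise ValueError("y and scores must be nonempty and of equal length")
    undefined = []
    if len(np.unique(y)) < 2:
        a = p = np.nan
        undefined += ["auroc", "auprc"]
    else:
        a, p = auroc(y, s), auprc(y, s)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    f1 = ratio(2 * precision * recall, precision + recall, "f1") \
        if (precision + recall) > 0 else 0.0
    return MetricsReport(auroc=a, auprc=p, f1=f1, precision=precision,
                         recall=recall, specificity=specificity,
                         threshold=threshold, n=len(y), tp=tp, fp=fp,
                         fn=fn, tn=tn, undefined=undefined)


def youden_threshold(y, scores) -> float:
    """Threshold maximizing sensitivity + specificity - 1 on the given data."""
    y = np.asarray(y, int)
    s = np.asarray(scores, float)
    cand = np.unique(s)
    best_t, best_j = 0.5, -np.inf
    n_pos, n_neg = y.sum(), (1 - y).sum()
    for t in cand:
        pred = s >= t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        if sens + spec - 1 > best_j:
            best_j, best_t = sens + spec - 1, float(t)
    return best_t


# ---------------------------------------------------------------------------
# DeLong's test
# ---------------------------------------------------------------------------

def _structural_components(y, scores):
    """Placement values V10 (cases) and V01 (controls) via midranks."""
    y = np.asarray(y, int)
    s = np.asarray(scores, float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks, neg_ranks = all_ranks[:m], all_ranks[m:]
    v10 = (pos_ranks - rankdata(pos)) / n            # per-case placement
    v01 = 1.0 - (neg_ranks - rankdata(neg)) / m      # per-control placement
    return v10, v01


@dataclass
class DeLongResult:
    auc_1: float
    auc_2: float
    z: float
    p_value: float
    var_diff: float


def delong_test(y, scores_1, scores_2) -> DeLongResult:
    """Paired comparison of two correlated AUROCs (DeLong et al. 1988)."""
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("DeLong's test needs both classes")
    v10_1, v01_1 = _structural_components(y, scores_1)
    v10_2, v01_2 = _structural_components(y, scores_2)
    a1, a2 = float(v10_1.mean()), float(v10_2.mean())
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        if np.isclose(a1, a2):
            return DeLongResult(a1, a2, 0.0, 1.0, float(max(var, 0.0)))
        raise ValueError("degenerate variance with unequal AUCs")
    z = (a1 - a2) / np.sqrt(var)
    p = float(2 * norm.sf(abs(z)))
    return DeLongResult(a1, a2, float(z), p, float(var))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(y, scores, metric="auroc", n_boot: int = 1000,
                 level: float = 0.95, seed: int = 0):
    """Stratified percentile bootstrap interval for a score metric.

    Cases and controls are resampled separately with replacement, so every
    replicate contains both classes even for rare outcomes.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y = np.asarray(y, int)
    s = np.asarray(scores, float)
    fn = {"auroc": auroc, "auprc": auprc}.get(metric, metric)
    pos_idx, neg_idx = np.where(y == 1)[0], np.where(y == 0)[0]
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("bootstrap needs both classes")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate([rng.choice(pos_idx, len(pos_idx), replace=True),
                               rng.choice(neg_idx, len(neg_idx), replace=True)])
        stats[b] = fn(y[take], s[take])
    alpha = (1 - level) / 2
    return (float(np.quantile(stats, alpha)), float(np.quantile(stats, 1 - alpha)))
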