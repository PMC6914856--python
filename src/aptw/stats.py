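"""Group-level statistics: Wilcoxon rank-sum comparisons with
Benjamini-Hochberg control, and ROC analysis of clustered lesion data with a
Youden-index operating point.

Lesions are nested within patients, so the pooled Mann-Whitney AUC is
reported with a clustered variance: placement values are summed per cluster
(patient) and the between-cluster empirical covariance of those sums, weighted
by cluster sizes, estimates the sampling variance.  With one lesion per
cluster this reduces exactly to the iid (DeLong-style) placement-value
variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .features import HISTOGRAM_PARAMS

DEFAULT_FDR = 0.10
POSITIVE_LABEL = "MSL"
NEGATIVE_LABEL = "WMH"
#: largest combined sample size for which the exact rank-sum null is enumerated
EXACT_MAX_N = 12


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float   # rank sum of the first sample (midranks)
    pvalue: float


@dataclass(frozen=True)
class TestResult:
    parameter: str
    statistic: float
    p_raw: float
    p_adjusted: float
    rejected: bool


@dataclass(frozen=True)
class OperatingPoint:
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    youden_j: float


@dataclass(frozen=True)
class ROCResult:
    auc: float
    variance: float
    se: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_pos: int
    n_neg: int
    n_clusters: int


def wilcoxon_rank_sum(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test.

    Midranks for ties.  The null distribution is enumerated exactly when the
    combined sample size is <= 12 and there are no ties; otherwise the
    tie-corrected normal approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = sps.rankdata(np.concatenate([x, y]))
    statistic = float(ranks[: x.size].sum())
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return WilcoxonResult(statistic=statistic, pvalue=1.0)
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return WilcoxonResult(statistic=statistic, pvalue=float(min(res.pvalue, 1.0)))


@dataclass(frozen=True)
class BHResult:
    adjusted: np.ndarray
    rejected: np.ndarray
    fdr: float


def bh_adjust(p_values, fdr: float = DEFAULT_FDR) -> BHResult:
    """Benjamini-Hochberg step-up adjustment; reject where adjusted p <= fdr."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return BHResult(adjusted=p.copy(), rejected=p.astype(bool), fdr=fdr)
    _, adjusted, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return BHResult(adjusted=adjusted, rejected=adjusted <= fdr, fdr=fdr)


def _placements(pos: np.ndarray, neg: np.ndarray):
    """Placement values (ties count 1/2) and the pooled Mann-Whitney AUC."""
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    n_pos, n_neg = pos.size, neg.size
    lo = np.searchsorted(neg_sorted, pos, side="left")
    hi = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lo + hi) / (2.0 * n_neg)                      # P(neg < pos) + ties/2
    lo_p = np.searchsorted(pos_sorted, neg, side="left")
    hi_p = np.searchsorted(pos_sorted, neg, side="right")
    v01 = (n_pos - (lo_p + hi_p) / 2.0) / n_pos          # P(pos > neg) + ties/2
    auc = float(v10.mean())
    return v10, v01, auc


def auc_mann_whitney(pos, neg) -> float:
    """Pooled AUC: probability a positive exceeds a negative, ties count 1/2."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    return _placements(pos, neg)[2]


def youden_operating_point(values, labels, positive_label: str = POSITIVE_LABEL) -> OperatingPoint:
    """Cutoff maximising J = sensitivity + specificity - 1.

    Candidates are the observed values; classification is positive when
    value >= cutoff; ties in J are broken by the lowest cutoff.  Accuracy is
    pooled over all observations.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = np.sort(values[labels == positive_label])
    neg = np.sort(values[labels != positive_label])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    cutoffs = np.unique(values)
    sens = 1.0 - np.searchsorted(pos, cutoffs, side="left") / pos.size
    spec = np.searchsorted(neg, cutoffs, side="left") / neg.size
    j = sens + spec - 1.0
    best = int(np.argmax(j))   # first (lowest-cutoff) maximiser
    accuracy = (sens[best] * pos.size + spec[best] * neg.size) / (pos.size + neg.size)
    return OperatingPoint(cutoff=float(cutoffs[best]),
                          sensitivity=float(sens[best]),
                          specificity=float(spec[best]),
                          accuracy=float(accuracy),
                          youden_j=float(j[best]))


def roc_clustered(values, labels, clusters,
                  positive_label: str = POSITIVE_LABEL,
                  ci_level: float = 0.95) -> ROCResult:
    """Pooled Mann-Whitney AUC for lesion-level data clustered by patient.

    Variance by the placement-value components method: per-cluster sums of
    centred placement values, with small-sample factors I1/(I1-1) and
    I2/(I2-1) on the two variance components and I12/(I12-1) on the
    cross covariance (I1/I2/I12 = numbers of clusters containing positives /
    negatives / both).  The CI is AUC +- z*SE on the AUC scale, truncated to
    [0, 1].
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    clusters = np.asarray(clusters)
    if values.shape != labels.shape or values.shape != clusters.shape:
        raise ValueError("values, labels and clusters must align")
    is_pos = labels == positive_label
    pos, neg = values[is_pos], values[~is_pos]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes need at least one lesion")
    v10, v01, auc = _placements(pos, neg)

    cluster_ids = np.unique(clusters)
    pos_clusters = clusters[is_pos]
    neg_clusters = clusters[~is_pos]
    s10 = np.array([np.sum(v10[pos_clusters == c] - auc) for c in cluster_ids])
    s01 = np.array([np.sum(v01[neg_clusters == c] - auc) for c in cluster_ids])
    has_pos = np.array([np.any(pos_clusters == c) for c in cluster_ids])
    has_neg = np.array([np.any(neg_clusters == c) for c in cluster_ids])
    i1 = int(has_pos.sum())
    i2 = int(has_neg.sum())
    i12 = int((has_pos & has_neg).sum())
    if i1 < 2 or i2 < 2:
        raise ValueError("need at least two clusters per class for a variance")
    c1 = i1 / (i1 - 1.0)
    c2 = i2 / (i2 - 1.0)
    c12 = i12 / (i12 - 1.0) if i12 > 1 else 1.0
    m, n = pos.size, neg.size
    variance = (c1 * np.sum(s10**2) / m**2
                + c2 * np.sum(s01**2) / n**2
                + 2.0 * c12 * np.sum(s10 * s01) / (m * n))
    variance = float(max(variance, 0.0))
    se = float(np.sqrt(variance))
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    ci_low = float(max(0.0, auc - z * se))
    ci_high = float(min(1.0, auc + z * se))

    op = youden_operating_point(values, labels, positive_label=positive_label)
    return ROCResult(auc=auc, variance=variance, se=se,
                     ci_low=ci_low, ci_high=ci_high,
                     cutoff=op.cutoff, sensitivity=op.sensitivity,
                     specificity=op.specificity, accuracy=op.accuracy,
                     n_pos=int(m), n_neg=int(n), n_clusters=int(cluster_ids.size))


def roc_curve_points(values, labels, positive_label: str = POSITIVE_LABEL) -> pd.DataFrame:
    """Empirical ROC curve (FPR, TPR) over all observed cutoffs, for export."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = np.sort(values[labels == positive_label])
    neg = np.sort(values[labels != positive_label])
    cutoffs = np.concatenate([np.unique(values), [np.inf]])
    tpr = 1.0 - np.searchsorted(pos, cutoffs, side="left") / pos.size
    fpr = 1.0 - np.searchsorted(neg, cutoffs, side="left") / neg.size
    return pd.DataFrame({"cutoff": cutoffs, "fpr": fpr, "tpr": tpr})


def compare_groups(patients: pd.DataFrame,
                   params=HISTOGRAM_PARAMS,
                   fdr: float = DEFAULT_FDR,
                   groups=(POSITIVE_LABEL, NEGATIVE_LABEL)) -> pd.DataFrame:
    """Wilcoxon rank-sum per histogram parameter on per-patient means, with
    Benjamini-Hochberg adjustment across the parameters."""
    ga, gb = groups
    a = patients[patients["group"] == ga]
    b = patients[patients["group"] == gb]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two patients")
    results = []
    for p in params:
        res = wilcoxon_rank_sum(a[p].to_numpy(), b[p].to_numpy())
        results.append((p, res.statistic, res.pvalue))
    bh = bh_adjust([r[2] for r in results], fdr=fdr)
    return pd.DataFrame(
        [{"parameter": p, "statistic": s, "p_raw": praw,
          "p_adjusted": float(adj), "rejected": bool(rej)}
         for (p, s, praw), adj, rej in zip(results, bh.adjusted, bh.rejected)],
        columns=["parameter", "statistic", "p_raw", "p_adjusted", "rejected"])


def roc_by_parameter(lesions: pd.DataFrame,
                     params=HISTOGRAM_PARAMS,
                     positive_label: str = POSITIVE_LABEL) -> pd.DataFrame:
    """Clustered ROC (patient = cluster) per histogram parameter at lesion level."""
    rows = []
    for p in params:
        r = roc_clustered(lesions[p].to_numpy(), lesions["group"].to_numpy(),
                          lesions["patient_id"].to_numpy(),
                          positive_label=positive_label)
        rows.append({"parameter": p, "auc": r.auc, "se": r.se,
                     "ci_low": r.ci_low, "ci_high": r.ci_high,
                     "cutoff": r.cutoff, "sensitivity": r.sensitivity,
                     "specificity": r.specificity, "accuracy": r.accuracy,
                     "n_pos": r.n_pos, "n_neg": r.n_neg,
                     "n_clusters": r.n_clusters})
    return pd.DataFrame(rows)
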