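"""Evaluation statistics for comparing genetic models.

The quantities computed here judge how well a (model, method) pair separates
the truly causal SNPs of a simulated dataset from the null SNPs:

* discrimination ``d``: mean -log10(p) score of causal SNPs divided by the
  mean score of null SNPs (NaN scores excluded);
* precision at a BH-adjusted p cutoff (default 0.05);
* ratio metrics dOR and PR: for two models, the per-dataset ratio of their
  discriminations (or precisions), averaged over datasets — a mean of
  ratios, not a ratio of means;
* ROC curves on a shared -log10(p) threshold grid, averaged pointwise across
  datasets, with trapezoid AUC; and a paired two-tailed t test on
  per-dataset AUCs.

The shared threshold grid spans score 0 (everything called positive) to just
above the attainable score cap (nothing called positive), so every curve is
anchored at (1,1) and (0,0).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: number of points in the default score-threshold grid
GRID_POINTS = 1001
#: top of the default grid; above the -log10(p) cap of 300, so the strictest
#: threshold calls nothing positive
GRID_MAX = 301.0


def default_score_grid() -> np.ndarray:
    """Evenly spaced -log10(p) thresholds from 0 to just above the score cap."""
    return np.linspace(0.0, GRID_MAX, GRID_POINTS)


def _clean(scores, is_causal):
    scores = np.asarray(scores, float)
    is_causal = np.asarray(is_causal, bool)
    if scores.shape != is_causal.shape:
        raise ValueError("scores and truth labels must align")
    keep = ~np.isnan(scores)
    return scores[keep], is_causal[keep]


def discrimination(scores, is_causal) -> float:
    """Mean causal score over mean null score; NaN when undefined.

    NaN scores are excluded.  Returns NaN if either class is empty after
    exclusion or the null mean is zero.
    """
    s, c = _clean(scores, is_causal)
    if not c.any() or c.all():
        return np.nan
    null_mean = s[~c].mean()
    if null_mean == 0.0:
        return np.nan
    return float(s[c].mean() / null_mean)


def precision_at_cutoff(p_bh, is_causal, cutoff: float = 0.05) -> tuple[float, int]:
    """Precision of calling SNPs with BH-adjusted p <= cutoff positive.

    Returns (precision, number of positive calls); precision is NaN when
    nothing is called positive.  NaN adjusted p-values are never positive.
    """
    p_bh = np.asarray(p_bh, float)
    is_causal = np.asarray(is_causal, bool)
    with np.errstate(invalid="ignore"):
        positive = p_bh <= cutoff
    n_pos = int(positive.sum())
    if n_pos == 0:
        return np.nan, 0
    tp = int((positive & is_causal).sum())
    return tp / n_pos, n_pos


def ratio_metric(values_1, values_2) -> float:
    """Mean over datasets of the paired ratio value1/value2.

    Pairs with NaN in either member (or a zero denominator) are dropped;
    returns NaN if no pair survives.  Used for both dOR (on discriminations)
    and PR (on precisions).
    """
    v1 = np.asarray(values_1, float)
    v2 = np.asarray(values_2, float)
    if v1.shape != v2.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(v1) | np.isnan(v2)) & (v2 != 0.0)
    if not keep.any():
        return np.nan
    return float(np.mean(v1[keep] / v2[keep]))


def roc_curve(scores, is_causal, grid=None) -> tuple[np.ndarray, np.ndarray]:
    """TPR/FPR of the causal-vs-null classification over score thresholds.

    At threshold t a SNP is called positive iff its score >= t.  NaN scores
    are excluded from both numerator and denominator.  Raises if either class
    is empty.
    """
    if grid is None:
        grid = default_score_grid()
    grid = np.asarray(grid, float)
    s, c = _clean(scores, is_causal)
    n_causal = int(c.sum())
    n_null = int((~c).sum())
    if n_causal == 0 or n_null == 0:
        raise ValueError("ROC requires at least one causal and one null SNP")
    causal_sorted = np.sort(s[c])
    null_sorted = np.sort(s[~c])
    # count of scores >= t via searchsorted on the sorted arrays
    tpr = 1.0 - np.searchsorted(causal_sorted, grid, side="left") / n_causal
    fpr = 1.0 - np.searchsorted(null_sorted, grid, side="left") / n_null
    return tpr, fpr


def auc_from_points(tpr, fpr) -> float:
    """Trapezoid area under ROC points, anchored at (0,0) and (1,1)."""
    tpr = np.concatenate([[0.0], np.asarray(tpr, float), [1.0]])
    fpr = np.concatenate([[0.0], np.asarray(fpr, float), [1.0]])
    order = np.argsort(fpr, kind="stable")
    fpr, tpr = fpr[order], tpr[order]
    return float(np.trapezoid(tpr, fpr))


def mean_roc_and_auc(curves) -> tuple[np.ndarray, np.ndarray, float]:
    """Pointwise mean of per-dataset (tpr, fpr) curves and its trapezoid AUC.

    All curves must share the threshold grid.  Returns
    (mean_tpr, mean_fpr, auc).
    """
    curves = list(curves)
    if not curves:
        raise ValueError("mean_roc_and_auc requires at least one curve")
    tprs = np.stack([np.asarray(t, float) for t, _ in curves])
    fprs = np.stack([np.asarray(f, float) for _, f in curves])
    if tprs.shape != fprs.shape:
        raise ValueError("curves must share the grid")
    mean_tpr = tprs.mean(axis=0)
    mean_fpr = fprs.mean(axis=0)
    return mean_tpr, mean_fpr, auc_from_points(mean_tpr, mean_fpr)


def auc_t_test(auc_1, auc_2) -> float:
    """Paired two-tailed t test on per-dataset AUC differences.

    Returns the p-value; NaN for fewer than two pairs or zero-variance
    differences (degenerate t statistic).
    """
    a1 = np.asarray(auc_1, float)
    a2 = np.asarray(auc_2, float)
    if a1.shape != a2.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a1) | np.isnan(a2))
    a1, a2 = a1[keep], a2[keep]
    if a1.size < 2:
        return np.nan
    diff = a1 - a2
    if diff.std(ddof=1) == 0.0:
        return np.nan
    return float(stats.ttest_rel(a1, a2).pvalue)
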