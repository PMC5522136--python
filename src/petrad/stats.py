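"""Univariate screening of radiomic features against a binary outcome.

Implements the univariate arm of the analysis: two-sided Wilcoxon rank-sum
tests between relapsing and non-relapsing patients, ROC AUC per feature with
stratified-bootstrap percentile confidence intervals, and the subset-size
stability experiment (mean p-values over random subsets of the larger group).

No multiple-testing correction is applied across the 11 features: the
univariate table reports raw p-values (this is recorded in the table
metadata by the pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES

__all__ = [
    "wilcoxon_test",
    "roc_auc",
    "bootstrap_auc_ci",
    "UnivariateResult",
    "univariate_table",
    "subset_stability",
]

#: Outcome encoding used across the package.
POSITIVE_LABEL = "relapse"


def wilcoxon_test(x, y, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``method='auto'`` uses the exact null distribution when the pooled sample
    has at most 20 observations and no ties, and the normal approximation
    with tie and continuity correction otherwise; ``'exact'``/``'asymptotic'``
    force one of the two.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        pooled = np.concatenate([x, y])
        ties = np.unique(pooled).size < pooled.size
        method = "exact" if (pooled.size <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def roc_auc(scores, labels) -> float:
    """ROC AUC with higher score predicting the positive class (no auto-flip).

    AUC = U / (n1 * n0) with the Mann-Whitney U statistic; tied score pairs
    count 1/2. ``labels`` may be 0/1 integers or booleans.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def bootstrap_auc_ci(
    scores,
    labels,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = 0,
) -> tuple[float, float]:
    """Percentile CI of the AUC over stratified bootstrap resamples.

    Each replicate resamples the positive and negative classes independently
    with replacement (stratified bootstrap); the interval is the
    ``(1-level)/2`` and ``1-(1-level)/2`` percentiles of the replicate AUCs.
    Deterministic for a fixed seed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each class needs at least 2 members for the bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bp = pos[rng.integers(0, pos.size, size=(n_boot, pos.size))]
    bn = neg[rng.integers(0, neg.size, size=(n_boot, neg.size))]
    # pairwise comparison, vectorised over replicates; ties count 1/2
    gt = (bp[:, :, None] > bn[:, None, :]).sum(axis=(1, 2))
    eq = (bp[:, :, None] == bn[:, None, :]).sum(axis=(1, 2))
    aucs = (gt + 0.5 * eq) / (pos.size * neg.size)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass(frozen=True)
class UnivariateResult:
    """One row of the univariate table."""

    feature: str
    p_value: float
    auc: float
    ci_low: float
    ci_high: float


def univariate_table(
    cohort: pd.DataFrame,
    group: str | None = None,
    features: tuple[str, ...] = FEATURE_NAMES,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Per-feature Wilcoxon p, AUC and bootstrap CI within one scanner group.

    ``cohort`` needs columns ``group``, ``outcome`` (``'relapse'`` /
    ``'no_relapse'`` or 0/1) and one column per feature. Returns a DataFrame
    indexed by feature with columns ``p_value``, ``auc``, ``ci_low``,
    ``ci_high``.
    """
    sub = cohort if group is None else cohort[cohort["group"] == group]
    if len(sub) == 0:
        raise ValueError(f"group {group!r} is empty")
    y = _outcome_vector(sub)
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present in the group")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for name in features:
        v = sub[name].to_numpy(dtype=float)
        p = wilcoxon_test(v[y], v[~y])
        auc = roc_auc(v, y)
        lo, hi = bootstrap_auc_ci(v, y, n_boot=n_boot, seed=rng)
        rows.append(UnivariateResult(name, p, auc, lo, hi))
    return pd.DataFrame(
        [(r.feature, r.p_value, r.auc, r.ci_low, r.ci_high) for r in rows],
        columns=["feature", "p_value", "auc", "ci_low", "ci_high"],
    ).set_index("feature")


def _outcome_vector(df: pd.DataFrame) -> np.ndarray:
    out = df["outcome"]
    if out.dtype == object:
        return (out == POSITIVE_LABEL).to_numpy()
    return out.to_numpy().astype(bool)


def subset_stability(
    cohort: pd.DataFrame,
    group: str,
    subset_size: int = 39,
    n_draws: int = 100,
    seed: int | None = 0,
    features: tuple[str, ...] = FEATURE_NAMES,
) -> pd.Series:
    """Mean per-feature Wilcoxon p-value over random patient subsets.

    Draws ``n_draws`` subsets of ``subset_size`` patients (without
    replacement within a draw) from the given group, recomputes the
    univariate p-values on each subset, and returns the per-feature mean —
    quantifying how much significance depends on cohort size. Draws with a
    single outcome class are redrawn.
    """
    sub = cohort[cohort["group"] == group].reset_index(drop=True)
    n = len(sub)
    if subset_size > n:
        raise ValueError(f"subset_size {subset_size} exceeds group size {n}")
    rng = np.random.default_rng(seed)
    y_all = _outcome_vector(sub)
    feats = sub[list(features)].to_numpy(dtype=float)
    acc = np.zeros(len(features))
    for _ in range(n_draws):
        for _attempt in range(1000):
            idx = rng.choice(n, size=subset_size, replace=False)
            y = y_all[idx]
            if y.any() and not y.all():
                break
        else:
            raise RuntimeError("could not draw a subset containing both classes")
        for k in range(len(features)):
            v = feats[idx, k]
            acc[k] += wilcoxon_test(v[y], v[~y])
    return pd.Series(acc / n_draws, index=list(features), name="mean_p_value")
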