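"""Blood-biomarker statistics.

* a permutation Jonckheere-Terpstra trend test over ordinal severity groups
  (e.g. Glasgow Prognostic Score 0/1/2), one-sided, with the add-one
  permutation p estimator;
* repeated random-forest feature selection using R-randomForest-style mean
  decrease in accuracy (per-tree out-of-bag permutation importance,
  z-scaled), with a percentile confidence interval across trials and a
  selection threshold on the mean scaled MDA;
* cross-model overlap of selected features with direction concordance;
* univariate (rank-statistic) and logistic-combination ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "TrendResult",
    "jt_statistic",
    "jonckheere_trend",
    "SelectionResult",
    "rf_mda_select",
    "model_overlap",
    "roc_auc",
    "logistic_combination_auc",
]


# --------------------------------------------------------------------------
# Jonckheere-Terpstra


@dataclass(frozen=True)
class TrendResult:
    statistic: float
    p: float
    n_permutations: int
    direction: str
    seed: int | None


def jt_statistic(values: np.ndarray, group_sizes: Sequence[int]) -> float:
    """Jonckheere-Terpstra statistic on concatenated group values.

    Sum over ordered group pairs (a before b) of Mann-Whitney counts
    #(x_a < x_b), ties counted 1/2.
    """
    blocks = []
    start = 0
    for s in group_sizes:
        blocks.append(values[start : start + s])
        start += s
    stat = 0.0
    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            a, b = blocks[i], blocks[j]
            stat += np.sum(a[:, None] < b[None, :]) + 0.5 * np.sum(a[:, None] == b[None, :])
    return float(stat)


def _jt_batch(matrix: np.ndarray, group_sizes: Sequence[int]) -> np.ndarray:
    """JT statistic of each row of a (B, n) matrix."""
    bounds = np.cumsum([0, *group_sizes])
    stat = np.zeros(matrix.shape[0])
    for i in range(len(group_sizes)):
        for j in range(i + 1, len(group_sizes)):
            a = matrix[:, bounds[i] : bounds[i + 1]]
            b = matrix[:, bounds[j] : bounds[j + 1]]
            lt = (a[:, :, None] < b[:, None, :]).sum(axis=(1, 2))
            eq = (a[:, :, None] == b[:, None, :]).sum(axis=(1, 2))
            stat += lt + 0.5 * eq
    return stat


def jonckheere_trend(
    groups: Sequence[Sequence[float]],
    direction: str = "increasing",
    n_perm: int = 10000,
    seed: int | None = None,
) -> TrendResult:
    """One-sided permutation Jonckheere-Terpstra trend test.

    ``groups`` is an ordered list of value lists (lowest severity first).
    ``direction="increasing"`` tests for an upward trend along the group
    order, ``"decreasing"`` for a downward trend (implemented by negating
    the values, which reverses every pairwise comparison).  The p-value is
    the add-one permutation estimator (1 + #{permuted JT >= observed}) /
    (1 + n_perm), so p >= 1/(n_perm + 1) always.
    """
    if len(groups) < 3:
        raise ValueError("need >=3 ordered groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if direction not in ("increasing", "decreasing"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "increasing" else -1.0
    pooled = sign * np.concatenate(arrays)
    sizes = [a.size for a in arrays]
    observed = jt_statistic(pooled, sizes)

    rng = np.random.default_rng(seed)
    # one shuffled copy of the pooled values per permutation
    keys = rng.random((n_perm, pooled.size))
    order = np.argsort(keys, axis=1)
    shuffled = pooled[order]
    null = _jt_batch(shuffled, sizes)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    # report the statistic on the original scale
    stat = observed if direction == "increasing" else jt_statistic(np.concatenate(arrays), sizes)
    return TrendResult(
        statistic=float(stat), p=float(p), n_permutations=n_perm,
        direction=direction, seed=seed,
    )


# --------------------------------------------------------------------------
# random-forest MDA selection


@dataclass(frozen=True)
class SelectionResult:
    feature: str
    mda_mean: float
    ci_low: float
    ci_high: float
    selected: bool
    direction: str  # "up" or "down" in the case class relative to controls
    threshold: float


def _forest_mda(
    X: np.ndarray, y: np.ndarray, n_trees: int, rng: np.random.Generator
) -> np.ndarray:
    """Scaled mean-decrease-accuracy per feature from one forest.

    Per tree: bootstrap the training set, measure out-of-bag accuracy, then
    re-measure with each feature's OOB column permuted; the importance is
    the accuracy drop.  Scaled MDA = mean over trees / (sd / sqrt(n_trees)),
    the z-scaling convention of the reference forest implementation; a zero
    sd yields 0.
    """
    n, p = X.shape
    per_tree = np.full((n_trees, p), np.nan)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        base = np.mean(tree.predict(X[oob]) == y[oob])
        for j in range(p):
            Xp = X[oob].copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            per_tree[t, j] = base - np.mean(tree.predict(Xp) == y[oob])
    means = np.nanmean(per_tree, axis=0)
    sds = np.nanstd(per_tree, axis=0, ddof=1)
    k = np.sum(~np.isnan(per_tree[:, 0]))
    se = sds / np.sqrt(max(k, 1))
    scaled = np.where(se > 0, means / np.where(se > 0, se, 1.0), 0.0)
    return scaled


def rf_mda_select(
    data: pd.DataFrame,
    labels: Sequence,
    *,
    n_trials: int = 20,
    n_trees: int = 500,
    threshold: float = 1.5,
    seed: int | None = None,
    case_label=None,
) -> list[SelectionResult]:
    """Repeated random-forest MDA feature selection.

    ``data`` is samples x features.  Each trial grows one forest from a
    distinct derived seed and yields one scaled MDA per feature; across
    trials the mean and the percentile 95% CI are reported, and a feature
    is selected when its mean scaled MDA exceeds ``threshold``.  The
    direction is the sign of the case-vs-control mean difference
    (``case_label`` defaults to the second sorted class label).
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    for c in classes:
        if np.sum(y == c) < 5:
            raise ValueError(f"class {c!r} has <5 samples")
    if n_trials < 2:
        raise ValueError("need >=2 trials for a confidence interval")
    case = case_label if case_label is not None else classes[-1]

    X = data.to_numpy(dtype=float)
    master = np.random.default_rng(seed)
    trial_seeds = master.integers(0, 2**31 - 1, size=n_trials)
    mdas = np.stack(
        [_forest_mda(X, y, n_trees, np.random.default_rng(int(s))) for s in trial_seeds]
    )
    means = mdas.mean(axis=0)
    lo = np.percentile(mdas, 2.5, axis=0)
    hi = np.percentile(mdas, 97.5, axis=0)
    case_mean = X[y == case].mean(axis=0)
    ctrl_mean = X[y != case].mean(axis=0)
    return [
        SelectionResult(
            feature=str(col),
            mda_mean=float(means[j]),
            ci_low=float(lo[j]),
            ci_high=float(hi[j]),
            selected=bool(means[j] > threshold),
            direction="up" if case_mean[j] >= ctrl_mean[j] else "down",
            threshold=threshold,
        )
        for j, col in enumerate(data.columns)
    ]


def model_overlap(
    selected_a: Sequence[SelectionResult], selected_b: Sequence[SelectionResult]
) -> dict:
    """Concordant overlap of two selection runs, with Venn counts."""
    a = {r.feature: r.direction for r in selected_a if r.selected}
    b = {r.feature: r.direction for r in selected_b if r.selected}
    both = set(a) & set(b)
    concordant = frozenset(f for f in both if a[f] == b[f])
    return {
        "overlap": concordant,
        "venn": {
            "a_only": len(set(a) - set(b)),
            "b_only": len(set(b) - set(a)),
            "both_concordant": len(concordant),
            "both_discordant": len(both) - len(concordant),
        },
    }


# --------------------------------------------------------------------------
# ROC


def roc_auc(scores: Sequence[float], labels: Sequence, case_label=None) -> float:
    """Univariate AUC by the rank statistic, ties counted 1/2."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    case = case_label if case_label is not None else classes[-1]
    pos = s[y == case]
    neg = s[y != case]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("one class is empty")
    greater = np.sum(pos[:, None] > neg[None, :])
    ties = np.sum(pos[:, None] == neg[None, :])
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def logistic_combination_auc(
    data: pd.DataFrame, labels: Sequence, case_label=None
) -> dict:
    """AUC of the maximum-likelihood logistic combination of the features."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    case = case_label if case_label is not None else classes[-1]
    yy = (y == case).astype(float)
    X = sm.add_constant(data.to_numpy(dtype=float))
    fit = sm.Logit(yy, X).fit(disp=0)
    score = fit.predict(X)
    return {
        "auc": roc_auc(score, yy, case_label=1.0),
        "coefficients": dict(zip(["intercept", *map(str, data.columns)], map(float, fit.params))),
    }
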