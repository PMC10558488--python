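"""Abundance-dependent enzyme decline statistics.

Quantifies the observation that highly expressed cofactor-related liver
enzymes decline as a group under cachexia:

* the depression slope — OLS slope of log2 fold change on log10 protein
  concentration, reported in permille (x1000); negative values mean
  abundance-dependent downregulation;
* a coarse-grained high/low x up/down classification with a Fisher exact
  test for enrichment of a focal enzyme group in the high-and-down cell;
* abundance-weighted membership fractions of enzyme groups;
* a multiple regression of log2 FC on a cofactor-class dummy plus log10
  abundance, with generalized variance-inflation factors (GVIF) as the
  collinearity diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "depression_slope",
    "ClassificationTable",
    "binary_classify",
    "abundance_weighted_fraction",
    "RegressionResult",
    "cofactor_regression",
]


def depression_slope(conc_mM: Sequence[float], log2fc: Sequence[float]) -> float:
    """OLS slope of log2 FC on log10 concentration, in permille.

    Proteins with non-positive concentration are excluded.  The convention
    is log2-FC units per log10-concentration decade, times 1000.
    """
    conc = np.asarray(conc_mM, dtype=float)
    fc = np.asarray(log2fc, dtype=float)
    usable = conc > 0
    conc, fc = conc[usable], fc[usable]
    if conc.size < 3:
        raise ValueError(f"need >=3 proteins with positive concentration, got {conc.size}")
    x = np.log10(conc)
    if np.ptp(x) == 0:
        raise ValueError("degenerate abundance axis: all concentrations equal")
    slope = np.polyfit(x, fc, 1)[0]
    return float(slope * 1000.0)


@dataclass(frozen=True)
class ClassificationTable:
    """High/low x up/down counts for a focal group vs the rest."""

    counts: pd.DataFrame  # index: (focal, rest); columns: high_down, high_up, low_down, low_up
    split_rule: str
    fisher_p: float
    n_excluded_zero_fc: int


def binary_classify(
    conc_mM: Mapping[str, float],
    log2fc: Mapping[str, float],
    focal_ids: Iterable[str],
    *,
    split: Literal["mean", "quartile"] = "mean",
    reference_conc: Mapping[str, float] | None = None,
    mean_scale: Literal["log10", "linear"] = "log10",
) -> ClassificationTable:
    """Classify proteins as high/low abundance and up/down fold change.

    ``split="mean"`` thresholds at the mean concentration of the analyzed
    proteins (on log10 scale by default); ``split="quartile"`` thresholds at
    the 75th percentile of an external reference proteome's concentrations
    (``reference_conc`` required).  Ties at the threshold go to "low";
    proteins with log2 FC exactly 0 are excluded from up/down.  The Fisher
    two-sided p tests enrichment of the focal group in the high-down cell.
    """
    ids = [i for i in conc_mM if i in log2fc and conc_mM[i] > 0]
    focal = set(focal_ids) & set(ids)
    if not focal:
        raise ValueError("focal group is empty after matching to data")

    conc = np.array([conc_mM[i] for i in ids])
    if split == "mean":
        vals = np.log10(conc) if mean_scale == "log10" else conc
        threshold_space = vals
        threshold = float(vals.mean())
        rule = f"mean({mean_scale})"
    elif split == "quartile":
        if reference_conc is None:
            raise ValueError("quartile split requires a reference proteome")
        ref = np.asarray([v for v in reference_conc.values() if v > 0], dtype=float)
        threshold = float(np.percentile(ref, 75))
        threshold_space = conc
        rule = "reference-quartile"
    else:
        raise ValueError(f"unknown split rule {split!r}")

    rows = {"focal": {}, "rest": {}}
    excluded = 0
    high_down = np.zeros((2, 2), dtype=int)  # rows: focal/rest; cols: high-down / not
    for i, t in zip(ids, threshold_space):
        fc = log2fc[i]
        if fc == 0:
            excluded += 1
            continue
        hi = t > threshold
        down = fc < 0
        cell = ("high" if hi else "low") + ("_down" if down else "_up")
        grp = "focal" if i in focal else "rest"
        rows[grp][cell] = rows[grp].get(cell, 0) + 1
        high_down[0 if grp == "focal" else 1, 0 if (hi and down) else 1] += 1

    counts = pd.DataFrame(rows).T.reindex(
        columns=["high_down", "high_up", "low_down", "low_up"]
    ).fillna(0).astype(int)
    _, fisher_p = stats.fisher_exact(high_down, alternative="two-sided")
    return ClassificationTable(
        counts=counts, split_rule=rule, fisher_p=float(fisher_p), n_excluded_zero_fc=excluded
    )


def abundance_weighted_fraction(
    member_ids: Iterable[str],
    conc_mM: Mapping[str, float],
    denominator_ids: Iterable[str] | None = None,
) -> float:
    """Percent of total abundance contributed by the member set.

    ``denominator_ids`` defaults to every id in ``conc_mM``.
    """
    denom_ids = set(denominator_ids) if denominator_ids is not None else set(conc_mM)
    members = set(member_ids)
    if not members <= denom_ids:
        raise ValueError("member ids must be a subset of the denominator group")
    denom = sum(conc_mM[i] for i in denom_ids if i in conc_mM)
    if denom <= 0:
        raise ValueError("denominator abundance is zero")
    num = sum(conc_mM[i] for i in members if i in conc_mM)
    return 100.0 * num / denom


@dataclass(frozen=True)
class RegressionResult:
    """OLS of log2 FC on a cofactor dummy + log10 abundance."""

    coefficients: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    gvif: dict[str, float]
    n: int


def cofactor_regression(
    log2fc: Sequence[float],
    is_focal: Sequence[bool],
    conc_mM: Sequence[float],
) -> RegressionResult:
    """Multiple regression of log2 FC on (focal dummy, log10 concentration).

    GVIF_j = 1 / (1 - R_j^2), with R_j^2 from regressing predictor j on the
    other predictor; with two predictors both GVIFs coincide.
    """
    y = np.asarray(log2fc, dtype=float)
    dummy = np.asarray(is_focal, dtype=float)
    conc = np.asarray(conc_mM, dtype=float)
    if not (y.size == dummy.size == conc.size):
        raise ValueError("inputs must be aligned")
    if y.size < 10:
        raise ValueError(f"need >=10 enzymes, got {y.size}")
    if len(np.unique(dummy)) < 2:
        raise ValueError("both dummy levels must be present")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    log_conc = np.log10(conc)

    r = float(np.corrcoef(dummy, log_conc)[0, 1])
    if abs(r) >= 1.0 - 1e-12:
        raise ValueError("perfect collinearity between dummy and log10 abundance")
    gvif = 1.0 / (1.0 - r**2)

    X = sm.add_constant(np.column_stack([dummy, log_conc]))
    fit = sm.OLS(y, X).fit()
    names = ["intercept", "dummy", "log10_abundance"]
    return RegressionResult(
        coefficients=dict(zip(names, map(float, fit.params))),
        p_values=dict(zip(names, map(float, fit.pvalues))),
        r_squared=float(fit.rsquared),
        gvif={"dummy": gvif, "log10_abundance": gvif},
        n=int(y.size),
    )
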