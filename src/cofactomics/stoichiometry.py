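"""Metabolite-enzyme stoichiometry statistics.

Log-log regression between paired molar quantities, per-object molar ratios
with the +/-1 log10 "gray zone" (the operational definition of near one-to-
one stoichiometry), grouped cross-species ratio summaries, and linear
fold-change response fits between metabolite and enzyme fold changes across
experimental models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import CofactorObject

__all__ = [
    "LogLogFit",
    "loglog_fit",
    "RatioResult",
    "molar_ratio",
    "species_ratio_summary",
    "linear_response_fit",
    "GRAY_ZONE_LOG10",
]

#: half-width of the gray zone on log10(metabolite/enzyme); inclusive bounds
GRAY_ZONE_LOG10 = 1.0


@dataclass(frozen=True)
class LogLogFit:
    """OLS fit on log10-transformed paired data."""

    slope: float
    intercept: float
    pearson_r: float
    p: float
    n: int
    excluded: int

    def predict_log10(self, x_log10: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x_log10)


def _fit_logged(xl: np.ndarray, yl: np.ndarray, excluded: int) -> LogLogFit:
    n = xl.size
    if n < 3:
        raise ValueError(f"need >=3 usable pairs for a fit, got {n}")
    if np.ptp(xl) == 0:
        raise ValueError("degenerate fit: all x values identical")
    if np.ptp(yl) == 0:
        # constant response: slope 0 by convention, correlation undefined
        return LogLogFit(
            slope=0.0, intercept=float(yl[0]), pearson_r=float("nan"), p=float("nan"),
            n=n, excluded=excluded,
        )
    res = stats.linregress(xl, yl)
    return LogLogFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p=float(res.pvalue),
        n=n,
        excluded=excluded,
    )


def loglog_fit(x_mM: Sequence[float], y_mM: Sequence[float]) -> LogLogFit:
    """OLS of log10(y) on log10(x); Pearson r and two-sided p on logged data.

    Pairs where either value is non-positive are excluded and counted in
    ``excluded`` (no offset shifting).
    """
    x = np.asarray(x_mM, dtype=float)
    y = np.asarray(y_mM, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    usable = (x > 0) & (y > 0)
    excluded = int((~usable).sum())
    return _fit_logged(np.log10(x[usable]), np.log10(y[usable]), excluded)


@dataclass(frozen=True)
class RatioResult:
    """Metabolite:enzyme molar ratio of one cofactor object."""

    name: str
    ratio: float
    log10_ratio: float
    in_gray_zone: bool


def molar_ratio(obj: CofactorObject) -> RatioResult:
    """Ratio = metabolite_mM / enzyme_mM, with the inclusive gray-zone flag."""
    if obj.enzyme_mM <= 0:
        raise ValueError(f"object {obj.name!r}: ratio undefined (enzyme_mM = {obj.enzyme_mM})")
    if obj.metabolite_mM <= 0:
        raise ValueError(f"object {obj.name!r}: ratio undefined (metabolite_mM <= 0)")
    ratio = obj.metabolite_mM / obj.enzyme_mM
    log10_ratio = math.log10(ratio)
    return RatioResult(
        name=obj.name,
        ratio=ratio,
        log10_ratio=log10_ratio,
        in_gray_zone=abs(log10_ratio) <= GRAY_ZONE_LOG10,
    )


def species_ratio_summary(
    objects_by_species: Mapping[str, Sequence[CofactorObject]],
) -> dict:
    """Per-species median ratios and cross-species per-vitamin means.

    Returns a dict with:

    * ``per_object``: DataFrame (species, name, ratio, log10_ratio,
      in_gray_zone);
    * ``species_median``: per-species median of ratios;
    * ``vitamin_geometric_mean``: per-vitamin 10**mean(log10 ratio) across
      species (primary cross-species average);
    * ``vitamin_arithmetic_mean``: per-vitamin arithmetic mean of ratios;
    * ``gray_zone_fraction``: overall fraction of objects in the gray zone.
    """
    rows = []
    for species, objects in objects_by_species.items():
        if not objects:
            raise ValueError(f"species {species!r} has no objects")
        for obj in objects:
            r = molar_ratio(obj)
            rows.append(
                {
                    "species": species,
                    "name": r.name,
                    "ratio": r.ratio,
                    "log10_ratio": r.log10_ratio,
                    "in_gray_zone": r.in_gray_zone,
                }
            )
    per_object = pd.DataFrame(rows)
    species_median = per_object.groupby("species")["ratio"].median()
    by_vitamin = per_object.groupby("name")
    vitamin_geometric_mean = 10.0 ** by_vitamin["log10_ratio"].mean()
    vitamin_arithmetic_mean = by_vitamin["ratio"].mean()
    return {
        "per_object": per_object,
        "species_median": species_median,
        "vitamin_geometric_mean": vitamin_geometric_mean,
        "vitamin_arithmetic_mean": vitamin_arithmetic_mean,
        "gray_zone_fraction": float(per_object["in_gray_zone"].mean()),
    }


def linear_response_fit(
    metab_fc_by_model: Mapping[str, float],
    enzyme_fc_by_model: Mapping[str, float],
    *,
    exclude_models: Sequence[str] = (),
) -> LogLogFit:
    """OLS of enzyme log2 FC on metabolite log2 FC across models.

    ``exclude_models`` drops named models (e.g. the starvation arm) before
    fitting.  Constant enzyme response is reported as slope 0 with the
    correlation flagged NaN.
    """
    models = [
        m
        for m in metab_fc_by_model
        if m in enzyme_fc_by_model and m not in set(exclude_models)
    ]
    if len(models) < 3:
        raise ValueError(f"need >=3 models with both fold changes, got {len(models)}")
    x = np.log2([metab_fc_by_model[m] for m in models])
    y = np.log2([enzyme_fc_by_model[m] for m in models])
    return _fit_logged(x, y, excluded=0)
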