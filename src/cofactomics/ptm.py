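"""Acyl-lysine PTM competition analysis.

Reactive acyl-CoA species (acetyl-, malonyl-, succinyl-CoA) compete for the
same nucleophilic lysine residues, so sites quantified in all three acyl
datasets can be compared directly.  This module intersects the three site
tables on (protein, residue position), adjusts each site's fold change by
its parent protein's fold change (isolating the modification-level change),
applies the strict (0.03, 32) adjusted-FC filter, and compares the three
acyl groups on log2 adjusted FC by one-way ANOVA followed by many-to-one
comparisons against malonylation (Dunnett's multivariate-t test, with a
seeded permutation max-t fallback).  A liver-origin tagger computes the
abundance-weighted percentage of liver-derived proteins in a plasma set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ACYL_TYPES",
    "PTMSiteTable",
    "read_ptm_table",
    "find_shared_sites",
    "adjust_fc",
    "filter_adjusted",
    "acyl_group_compare",
    "tag_liver_origin",
]

ACYL_TYPES = ("aceK", "malK", "sucK")

#: strict open interval retained by the adjusted-FC filter
ADJUSTED_FC_BOUNDS = (0.03, 32.0)


@dataclass(frozen=True)
class PTMSiteTable:
    """Acyl-lysine site records for one acyl type.

    Columns: accession, position (1-based), acyl, fc; optionally
    adjusted_fc.  (accession, position, acyl) is unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"accession", "position", "acyl", "fc"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"PTM table missing column(s): {sorted(missing)}")
        if (self.table["position"] < 1).any():
            raise ValueError("residue positions are 1-based (>= 1)")
        if (self.table["fc"] <= 0).any():
            raise ValueError("PTM fold changes must be positive")
        bad = set(self.table["acyl"]) - set(ACYL_TYPES)
        if bad:
            raise ValueError(f"unknown acyl type(s): {sorted(bad)}")
        if self.table.duplicated(["accession", "position", "acyl"]).any():
            raise ValueError("duplicate (accession, position, acyl) keys")

    def keys(self) -> frozenset[tuple[str, int]]:
        return frozenset(
            zip(self.table["accession"], self.table["position"].astype(int))
        )


def read_ptm_table(path: str | Path) -> PTMSiteTable:
    return PTMSiteTable(table=pd.read_csv(path, sep="\t"))


def find_shared_sites(
    ace: PTMSiteTable, mal: PTMSiteTable, suc: PTMSiteTable
) -> pd.DataFrame:
    """Sites present in all three acyl tables, one row per (protein, position).

    Returns a frame with columns accession, position and one fc (and, when
    available, adjusted_fc) column per acyl type.
    """
    shared = ace.keys() & mal.keys() & suc.keys()
    frames = []
    for t in (ace, mal, suc):
        acyl = t.table["acyl"].iloc[0] if len(t.table) else None
        sub = t.table.set_index(["accession", "position"])
        cols = ["fc"] + (["adjusted_fc"] if "adjusted_fc" in sub.columns else [])
        sub = sub.loc[sub.index.isin(shared), cols]
        sub.columns = [f"{c}_{acyl}" for c in cols]
        frames.append(sub)
    out = pd.concat(frames, axis=1, join="inner").reset_index()
    return out.sort_values(["accession", "position"]).reset_index(drop=True)


def adjust_fc(
    sites: PTMSiteTable, protein_fc: Mapping[str, float]
) -> tuple[PTMSiteTable, int]:
    """Divide each site's FC by its protein's FC; drop sites without one.

    Returns the table with an ``adjusted_fc`` column and the count of
    dropped sites.
    """
    t = sites.table.copy()
    have = t["accession"].map(lambda a: a in protein_fc and protein_fc[a] > 0)
    dropped = int((~have).sum())
    if dropped:
        warnings.warn(f"{dropped} site(s) without a protein fold change dropped", stacklevel=2)
    t = t.loc[have].copy()
    t["adjusted_fc"] = t["fc"] / t["accession"].map(protein_fc)
    return PTMSiteTable(table=t.reset_index(drop=True)), dropped


def filter_adjusted(sites: PTMSiteTable) -> PTMSiteTable:
    """Keep sites with adjusted FC strictly inside (0.03, 32)."""
    if "adjusted_fc" not in sites.table.columns:
        raise ValueError("adjusted_fc not set; call adjust_fc first")
    lo, hi = ADJUSTED_FC_BOUNDS
    keep = (sites.table["adjusted_fc"] > lo) & (sites.table["adjusted_fc"] < hi)
    return PTMSiteTable(table=sites.table.loc[keep].reset_index(drop=True))


def _permutation_max_t(
    groups: Sequence[np.ndarray], control_idx: int, n_perm: int, seed: int | None
) -> list[float]:
    """Max-t permutation many-to-one p-values vs the control group."""
    rng = np.random.default_rng(seed)
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)

    def tstats(parts: list[np.ndarray]) -> np.ndarray:
        c = parts[control_idx]
        out = []
        for i, g in enumerate(parts):
            if i == control_idx:
                continue
            se = np.sqrt(g.var(ddof=1) / g.size + c.var(ddof=1) / c.size)
            out.append(abs(g.mean() - c.mean()) / se if se > 0 else 0.0)
        return np.asarray(out)

    observed = tstats(list(groups))
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(pooled)
        parts, start = [], 0
        for s in sizes:
            parts.append(perm[start : start + s])
            start += s
        max_null[b] = tstats(parts).max()
    # adjusted p per comparison: share of permuted max-t >= observed t
    return [float((1 + np.sum(max_null >= t)) / (1 + n_perm)) for t in observed]


def acyl_group_compare(
    shared: pd.DataFrame,
    *,
    method: str = "dunnett",
    n_perm: int = 10000,
    seed: int | None = None,
) -> dict:
    """One-way ANOVA + many-to-one comparison of aceK/sucK against malK.

    Comparisons are made on log2 adjusted FC.  ``method="dunnett"`` uses the
    multivariate-t Dunnett test; ``method="permutation"`` uses a seeded
    max-t permutation procedure.  Returns a dict with the ANOVA p, per-
    comparison adjusted p-values, group medians, and the method record.
    """
    cols = {a: f"adjusted_fc_{a}" for a in ACYL_TYPES}
    missing = [c for c in cols.values() if c not in shared.columns]
    if missing:
        raise ValueError(f"shared-site table missing column(s): {missing}")
    groups = {a: np.log2(shared[c].to_numpy(dtype=float)) for a, c in cols.items()}
    for a, g in groups.items():
        if g.size < 2:
            raise ValueError(f"acyl group {a!r} has <2 values")

    anova_p = float(stats.f_oneway(*groups.values()).pvalue)
    treatments = [a for a in ACYL_TYPES if a != "malK"]
    if method == "dunnett":
        res = stats.dunnett(*(groups[a] for a in treatments), control=groups["malK"])
        pvals = {f"{a}_vs_malK": float(p) for a, p in zip(treatments, res.pvalue)}
    elif method == "permutation":
        ordered = [groups[a] for a in treatments] + [groups["malK"]]
        p = _permutation_max_t(ordered, control_idx=len(treatments), n_perm=n_perm, seed=seed)
        pvals = {f"{a}_vs_malK": pi for a, pi in zip(treatments, p)}
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "anova_p": anova_p,
        "comparisons": pvals,
        "medians_log2": {a: float(np.median(g)) for a, g in groups.items()},
        "n_sites": int(len(shared)),
        "method": method if method == "dunnett" else f"permutation(n_perm={n_perm}, seed={seed})",
    }


def tag_liver_origin(
    accessions: Iterable[str],
    liver_reference: Iterable[str],
    abundance: Mapping[str, float],
) -> tuple[dict[str, bool], float]:
    """Flag liver-derived proteins and compute the weighted percentage.

    Weighted percent = 100 * sum(abundance of liver-derived) /
    sum(abundance of all listed proteins).
    """
    ref = set(liver_reference)
    accs = list(accessions)
    flags = {a: a in ref for a in accs}
    total = sum(abundance.get(a, 0.0) for a in accs)
    if total <= 0:
        return flags, float("nan")
    liver = sum(abundance.get(a, 0.0) for a in accs if flags[a])
    return flags, 100.0 * liver / total
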