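"""Tabular IO, missing-value handling, normalization and group fold changes.

The pipeline's quantitative inputs are concentration matrices (entities in
rows, samples in columns) carrying an explicit unit tag, together with a
sample-design table mapping each sample to a tumour model and an arm
(experimental vs control).  This module reads and writes those tables and
applies the preprocessing rules used throughout the analysis:

* metabolome matrices: drop entities with no observed value anywhere, then
  replace every remaining missing cell with one half of the global minimum
  observed value of the whole matrix;
* proteome matrices: drop any protein row containing a missing value
  (proteins are never imputed);
* TMT-style intensity matrices: median-ratio normalization against a
  reference sample;
* per-model fold changes (ratio of arithmetic group means by default,
  ratio of group medians as an option) with optional Welch two-sided
  p-values for volcano plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcentrationMatrix",
    "SampleDesign",
    "read_concentration_table",
    "read_design_table",
    "read_workbook_metabolome",
    "drop_all_missing_entities",
    "impute_half_minimum",
    "drop_incomplete_proteins",
    "median_ratio_normalize",
    "group_fold_change",
    "welch_volcano",
    "write_fold_change_table",
    "read_fold_change_table",
]

VALID_UNITS = ("umol_per_g", "mM", "share", "ppm", "mg_per_100g", "intensity")
VALID_KINDS = ("metabolite", "protein", "transcript")

#: strings accepted as missing values in delimited inputs
MISSING_TOKENS = ("", "NA", "NaN", "nan", "na", "N/A")


@dataclass(frozen=True)
class ConcentrationMatrix:
    """Entities x samples matrix of non-negative concentrations.

    ``data`` holds entities in rows and samples in columns; missing cells are
    NaN.  ``unit`` is one of :data:`VALID_UNITS`, ``entity_kind`` one of
    :data:`VALID_KINDS`.
    """

    data: pd.DataFrame
    unit: str
    entity_kind: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit tag {self.unit!r}; expected one of {VALID_UNITS}")
        if self.entity_kind not in VALID_KINDS:
            raise ValueError(
                f"unknown entity kind {self.entity_kind!r}; expected one of {VALID_KINDS}"
            )
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate entity id(s): {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s): {dupes}")
        values = self.data.to_numpy(dtype=float)
        if np.any(values[np.isfinite(values)] < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def with_data(self, data: pd.DataFrame) -> "ConcentrationMatrix":
        return replace(self, data=data)


@dataclass(frozen=True)
class SampleDesign:
    """Maps sample id to (model, arm, tissue, sex)."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "model", "arm")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"design table missing required column {col!r}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("design table has duplicate sample ids")
        bad = set(self.table["arm"]) - {"experimental", "control"}
        if bad:
            raise ValueError(f"unknown arm label(s): {sorted(bad)}")

    def models(self) -> list[str]:
        return sorted(self.table["model"].unique())

    def samples_for(self, model: str, arm: str) -> list[str]:
        t = self.table
        return list(t.loc[(t["model"] == model) & (t["arm"] == arm), "sample_id"])


def _parse_numeric(frame: pd.DataFrame) -> pd.DataFrame:
    """Coerce all cells to float; unparseable cells become NaN."""
    out = frame.apply(pd.to_numeric, errors="coerce")
    return out.astype(float)


def read_concentration_table(
    path: str | Path,
    *,
    unit: str,
    entity_kind: str,
    sep: str | None = None,
) -> ConcentrationMatrix:
    """Read a delimited concentration table (entity ids in the first column).

    ``sep=None`` sniffs comma vs tab from the file extension (.tsv/.txt ->
    tab, otherwise comma).  Empty cells and the usual NA spellings become
    missing values; any other unparseable numeric cell does too.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(
        path, sep=sep, index_col=0, na_values=list(MISSING_TOKENS), keep_default_na=False
    )
    raw.index = raw.index.astype(str)
    numeric = _parse_numeric(raw)
    if (numeric.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative concentration values are not allowed")
    return ConcentrationMatrix(data=numeric, unit=unit, entity_kind=entity_kind)


def read_design_table(path: str | Path, *, sep: str | None = None) -> SampleDesign:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table = pd.read_csv(path, sep=sep, dtype=str)
    return SampleDesign(table=table)


def read_workbook_metabolome(
    path: str | Path, *, unit: str = "umol_per_g"
) -> dict[str, ConcentrationMatrix]:
    """Read a one-sheet-per-tissue metabolome workbook (first column = name).

    Returns a mapping tissue (sheet name) -> matrix.  Requires openpyxl.
    """
    sheets = pd.read_excel(path, sheet_name=None, index_col=0)
    out: dict[str, ConcentrationMatrix] = {}
    for tissue, frame in sheets.items():
        frame.index = frame.index.astype(str)
        out[tissue] = ConcentrationMatrix(
            data=_parse_numeric(frame), unit=unit, entity_kind="metabolite"
        )
    return out


def drop_all_missing_entities(m: ConcentrationMatrix) -> ConcentrationMatrix:
    """Remove entities for which every sample is missing."""
    keep = m.data.notna().any(axis=1)
    return m.with_data(m.data.loc[keep])


def impute_half_minimum(m: ConcentrationMatrix) -> ConcentrationMatrix:
    """Replace missing cells with half of the global minimum present value.

    The minimum is taken over all present values of the whole matrix (all
    entities, all samples), not per row.
    """
    values = m.data.to_numpy(dtype=float)
    present = values[np.isfinite(values)]
    if present.size == 0:
        raise ValueError("cannot impute a matrix with no present values")
    fill = 0.5 * float(present.min())
    return m.with_data(m.data.fillna(fill))


def drop_incomplete_proteins(m: ConcentrationMatrix) -> ConcentrationMatrix:
    """Keep only rows with a value in every sample (proteins are not imputed)."""
    keep = m.data.notna().all(axis=1)
    if not keep.any():
        warnings.warn("all rows contain missing values; result is empty", stacklevel=2)
    return m.with_data(m.data.loc[keep])


def median_ratio_normalize(
    m: ConcentrationMatrix, reference_sample: str
) -> tuple[ConcentrationMatrix, pd.Series]:
    """Median-ratio normalization against a reference sample.

    Each sample is divided by its scale factor, the median over entities of
    (sample value / reference value).  Entities whose reference value is 0
    are excluded from the scale-factor median with a warning.  Returns the
    normalized matrix and the per-sample scale factors.
    """
    if reference_sample not in m.data.columns:
        raise ValueError(f"reference sample {reference_sample!r} not in matrix")
    ref = m.data[reference_sample]
    usable = ref > 0
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} entities have reference value 0; "
            "excluded from scale-factor medians",
            stacklevel=2,
        )
    if not usable.any():
        raise ValueError("reference sample has no positive values")
    ratios = m.data.loc[usable].div(ref.loc[usable], axis=0)
    scales = ratios.median(axis=0)
    return m.with_data(m.data.div(scales, axis=1)), scales


@dataclass(frozen=True)
class FoldChangeTable:
    """Per-entity fold change of one model versus its control group."""

    table: pd.DataFrame  # columns: entity_id, model, fc, log2fc, n_exp, n_ctl[, p]
    excluded: tuple[str, ...] = field(default_factory=tuple)

    COLUMNS = ("entity_id", "model", "fc", "log2fc", "n_exp", "n_ctl")

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.table.columns:
                raise ValueError(f"fold-change table missing column {col!r}")
        if (self.table["fc"] <= 0).any():
            raise ValueError("fold changes must be positive")


def _group_values(
    m: ConcentrationMatrix, design: SampleDesign, model: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    exp = design.samples_for(model, "experimental")
    ctl = design.samples_for(model, "control")
    if model not in design.models():
        raise ValueError(f"model {model!r} absent from design")
    if not exp or not ctl:
        raise ValueError(f"model {model!r} needs >=1 sample per arm")
    missing = [s for s in exp + ctl if s not in m.data.columns]
    if missing:
        raise ValueError(f"design samples absent from matrix: {missing}")
    return m.data[exp], m.data[ctl]


def group_fold_change(
    m: ConcentrationMatrix,
    design: SampleDesign,
    model: str,
    *,
    estimator: Literal["mean", "median"] = "mean",
) -> FoldChangeTable:
    """Fold change = experimental group mean / control group mean per entity.

    ``estimator="median"`` swaps in group medians.  Entities whose control
    summary is 0 are excluded and listed in ``excluded``.
    """
    exp, ctl = _group_values(m, design, model)
    agg = (lambda df: df.mean(axis=1)) if estimator == "mean" else (lambda df: df.median(axis=1))
    exp_s, ctl_s = agg(exp), agg(ctl)
    bad = ctl_s == 0
    fc = exp_s[~bad] / ctl_s[~bad]
    table = pd.DataFrame(
        {
            "entity_id": fc.index,
            "model": model,
            "fc": fc.to_numpy(),
            "log2fc": np.log2(fc.to_numpy()),
            "n_exp": exp.shape[1],
            "n_ctl": ctl.shape[1],
        }
    ).reset_index(drop=True)
    return FoldChangeTable(table=table, excluded=tuple(exp_s.index[bad]))


def welch_volcano(
    m: ConcentrationMatrix,
    design: SampleDesign,
    model: str,
    *,
    estimator: Literal["mean", "median"] = "mean",
) -> FoldChangeTable:
    """Fold changes plus per-entity Welch two-sided t-test p-values.

    Two exactly identical groups are assigned p = 1 (zero statistic); groups
    with zero variance but different means get p = 0 without a division
    error.
    """
    exp, ctl = _group_values(m, design, model)
    if exp.shape[1] < 2 or ctl.shape[1] < 2:
        raise ValueError("Welch test needs >=2 samples per arm")
    base = group_fold_change(m, design, model, estimator=estimator)
    a = exp.to_numpy(dtype=float)
    b = ctl.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    same_mean = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[zero_var & same_mean] = 1.0
    p[zero_var & ~same_mean] = 0.0
    pmap = pd.Series(p, index=m.data.index)
    table = base.table.copy()
    table["p"] = pmap.loc[table["entity_id"]].to_numpy()
    return FoldChangeTable(table=table, excluded=base.excluded)


def write_fold_change_table(fc: FoldChangeTable, path: str | Path) -> None:
    fc.table.to_csv(path, sep="\t", index=False)


def read_fold_change_table(path: str | Path) -> FoldChangeTable:
    return FoldChangeTable(table=pd.read_csv(path, sep="\t"))
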