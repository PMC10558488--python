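"""Annotation catalogs, boolean search formulas, and cofactor objects.

A cofactor object is a named cofactor class (NIA, B6, PA, B2, SAM, ATP,
Gly, C1, B1, Biotin, Folate, B12, ...) carrying two aggregate molarities:
the summed molar concentration of its member metabolites and the summed
molar concentration of its member enzymes.  Membership is decided purely by
annotation: enzymes are selected by evaluating a boolean search formula
over a UniProt-style catalog export (accession, entry name, EC numbers,
catalytic-activity text, nucleotide-binding text, keyword ids, ChEBI ids);
metabolites are selected through their ChEBI identifiers.

All quantities are converted to a common millimolar scale before
aggregation: tissue amounts via a tissue density of 1.0 g/cm^3 (so
1 umol/g = 1 mM), proteome abundance shares via an assumed total protein
concentration of 5 mM, and food-composition masses (mg per 100 g) via the
vitamin molecular-weight table.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AnnotationRecord",
    "AnnotationCatalog",
    "Leaf",
    "And",
    "Or",
    "Not",
    "formula_from_dict",
    "load_formulas",
    "DEFAULT_FORMULAS",
    "COFACTOR_CHEBI",
    "MW_TABLE",
    "TOTAL_PROTEIN_MM",
    "evaluate_search_formula",
    "EnzymePartition",
    "partition_proteome",
    "aggregate_concentration",
    "tissue_to_molar",
    "proteome_share_to_molar",
    "mass_to_molar",
    "link_metabolite_enzymes",
    "CofactorObject",
    "build_cofactor_objects",
    "read_catalog",
    "RLDRecord",
    "rld_summary",
]

#: vitamin molecular weights (g/mol) used in all molar conversions
MW_TABLE: dict[str, float] = {
    "B1": 265.355,
    "B2": 376.36,
    "NIA": 123.111,
    "B6": 169.18,
    "PA": 219.23,
    "Biotin": 244.31,
    "Folate": 441.4,
    "B12": 1355.388,
}

#: assumed total cellular protein concentration (mM) for share -> molar
TOTAL_PROTEIN_MM = 5.0

#: canonical ChEBI anchors per cofactor class (reconstructed defaults;
#: override with your own formula/ChEBI files for a real catalog)
COFACTOR_CHEBI: dict[str, tuple[str, ...]] = {
    "NIA": ("CHEBI:57540", "CHEBI:58349", "CHEBI:17154"),  # NAD, NADP, nicotinamide
    "B6": ("CHEBI:597326",),  # pyridoxal 5'-phosphate
    "PA": ("CHEBI:57287",),  # coenzyme A
    "B2": ("CHEBI:57692", "CHEBI:57986"),  # FAD, FMN
    "B1": ("CHEBI:58937",),  # thiamine diphosphate
    "SAM": ("CHEBI:59789",),  # S-adenosyl-L-methionine
    "ATP": ("CHEBI:30616",),
    "Gly": ("CHEBI:57305",),  # glycine zwitterion
    "C1": ("CHEBI:15636", "CHEBI:57453"),  # 5,10-CH2-THF, 5-CH3-THF
    "Biotin": ("CHEBI:57586",),
    "Folate": ("CHEBI:57453", "CHEBI:67016"),
    "B12": ("CHEBI:28115",),
}

TEXT_FIELDS = ("entry_name", "catalytic_activity", "nucleotide_binding")
LIST_FIELDS = ("ec_numbers",)
SET_FIELDS = ("keyword_ids", "chebi_ids")
ALL_FIELDS = ("accession",) + TEXT_FIELDS + LIST_FIELDS + SET_FIELDS


@dataclass(frozen=True)
class AnnotationRecord:
    """One UniProt-style protein record."""

    accession: str
    entry_name: str = ""
    ec_numbers: tuple[str, ...] = ()
    catalytic_activity: str = ""
    nucleotide_binding: str = ""
    keyword_ids: frozenset[str] = frozenset()
    chebi_ids: frozenset[str] = frozenset()


@dataclass(frozen=True)
class AnnotationCatalog:
    """Accession-keyed collection of annotation records."""

    records: tuple[AnnotationRecord, ...]

    def __post_init__(self) -> None:
        accs = [r.accession for r in self.records]
        if len(set(accs)) != len(accs):
            raise ValueError("duplicate accessions in catalog")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def accessions(self) -> frozenset[str]:
        return frozenset(r.accession for r in self.records)

    def get(self, accession: str) -> AnnotationRecord:
        for r in self.records:
            if r.accession == accession:
                return r
        raise KeyError(accession)


# --------------------------------------------------------------------------
# search-formula grammar


class Formula:
    """Base class for boolean search formulas."""

    def matches(self, record: AnnotationRecord) -> bool:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class Leaf(Formula):
    """A single field predicate.

    ``mode``: ``substring`` (case-insensitive), ``regex`` (case-insensitive
    search), or ``tag`` (exact membership, for keyword/ChEBI id sets).
    """

    field: str
    mode: str
    pattern: str

    def __post_init__(self) -> None:
        if self.field not in ALL_FIELDS:
            raise ValueError(f"unknown field {self.field!r}")
        if self.mode not in ("substring", "regex", "tag"):
            raise ValueError(f"unknown match mode {self.mode!r}")
        if self.mode == "regex":
            try:
                re.compile(self.pattern)
            except re.error as exc:
                raise ValueError(
                    f"invalid regex {self.pattern!r} in leaf on field {self.field!r}: {exc}"
                ) from exc

    def _field_texts(self, record: AnnotationRecord) -> tuple[str, ...]:
        value = getattr(record, self.field)
        if isinstance(value, str):
            return (value,)
        return tuple(value)

    def matches(self, record: AnnotationRecord) -> bool:
        value = getattr(record, self.field)
        if self.mode == "tag":
            if isinstance(value, str):
                return value == self.pattern
            return self.pattern in value
        texts = self._field_texts(record)
        if self.mode == "substring":
            pat = self.pattern.lower()
            return any(pat in t.lower() for t in texts)
        rx = re.compile(self.pattern, re.IGNORECASE)
        return any(rx.search(t) for t in texts)


@dataclass(frozen=True)
class And(Formula):
    terms: tuple[Formula, ...]

    def matches(self, record: AnnotationRecord) -> bool:
        return all(t.matches(record) for t in self.terms)


@dataclass(frozen=True)
class Or(Formula):
    terms: tuple[Formula, ...]

    def matches(self, record: AnnotationRecord) -> bool:
        return any(t.matches(record) for t in self.terms)


@dataclass(frozen=True)
class Not(Formula):
    term: Formula

    def matches(self, record: AnnotationRecord) -> bool:
        return not self.term.matches(record)


def formula_from_dict(spec: Mapping | Sequence) -> Formula:
    """Build a formula from its serialized (YAML/JSON) form.

    Leaves are ``{"field": ..., "mode": ..., "pattern": ...}``; internal
    nodes are ``{"and": [...]}, {"or": [...]}, {"not": ...}``.
    """
    if not isinstance(spec, Mapping):
        raise ValueError(f"malformed formula node: {spec!r}")
    if "and" in spec:
        return And(tuple(formula_from_dict(s) for s in spec["and"]))
    if "or" in spec:
        return Or(tuple(formula_from_dict(s) for s in spec["or"]))
    if "not" in spec:
        return Not(formula_from_dict(spec["not"]))
    if "field" in spec:
        return Leaf(field=spec["field"], mode=spec.get("mode", "substring"), pattern=spec["pattern"])
    raise ValueError(f"malformed formula node: {spec!r}")


def _chebi_or(name: str) -> dict:
    return {"or": [{"field": "chebi_ids", "mode": "tag", "pattern": c} for c in COFACTOR_CHEBI[name]]}


def _default_formula_specs() -> dict[str, dict]:
    specs: dict[str, dict] = {
        # any record carrying an EC number counts as an enzyme
        "all_enzymes": {"field": "ec_numbers", "mode": "regex", "pattern": r"\d"},
        "b_vitamin_enzymes": {
            "or": [_chebi_or(n) for n in ("NIA", "B6", "PA", "B2", "B1", "Biotin", "Folate", "B12")]
        },
    }
    for name in COFACTOR_CHEBI:
        specs[name] = _chebi_or(name)
    return specs


#: reconstructed default search formulas, one per cofactor object plus the
#: "all enzymes" and "B vitamin enzymes" selectors; any catalog/formula pair
#: supplied by the user overrides these
DEFAULT_FORMULAS: dict[str, Formula] = {
    name: formula_from_dict(spec) for name, spec in _default_formula_specs().items()
}


def load_formulas(path: str | Path) -> dict[str, Formula]:
    """Load named formulas from a YAML file (name -> serialized formula)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: formula_from_dict(spec) for name, spec in raw.items()}


def evaluate_search_formula(catalog: AnnotationCatalog, formula: Formula) -> frozenset[str]:
    """Accessions of exactly the records satisfying the formula."""
    return frozenset(r.accession for r in catalog if formula.matches(r))


# --------------------------------------------------------------------------
# proteome partition


@dataclass(frozen=True)
class EnzymePartition:
    """Three mutually exclusive proteome groups covering the catalog."""

    b_vitamin_enzymes: frozenset[str]
    other_enzymes: frozenset[str]
    non_enzymes: frozenset[str]

    def __post_init__(self) -> None:
        groups = (self.b_vitamin_enzymes, self.other_enzymes, self.non_enzymes)
        total = sum(len(g) for g in groups)
        union = frozenset().union(*groups)
        if total != len(union):
            raise ValueError("partition groups overlap")

    def group_of(self, accession: str) -> str:
        if accession in self.b_vitamin_enzymes:
            return "b_vitamin_enzymes"
        if accession in self.other_enzymes:
            return "other_enzymes"
        if accession in self.non_enzymes:
            return "non_enzymes"
        raise KeyError(accession)


def partition_proteome(
    catalog: AnnotationCatalog,
    all_enzymes_formula: Formula | None = None,
    b_vitamin_formula: Formula | None = None,
) -> EnzymePartition:
    """Split the catalog into B-vitamin enzymes / other enzymes / non-enzymes.

    B-vitamin membership takes precedence within the enzyme set; the three
    groups are disjoint and cover the catalog by construction.
    """
    all_f = all_enzymes_formula or DEFAULT_FORMULAS["all_enzymes"]
    bv_f = b_vitamin_formula or DEFAULT_FORMULAS["b_vitamin_enzymes"]
    enzymes = evaluate_search_formula(catalog, all_f)
    bvit = enzymes & evaluate_search_formula(catalog, bv_f)
    return EnzymePartition(
        b_vitamin_enzymes=bvit,
        other_enzymes=enzymes - bvit,
        non_enzymes=catalog.accessions() - enzymes,
    )


# --------------------------------------------------------------------------
# molar conversions and aggregation


def aggregate_concentration(ids: Iterable[str], molar_values: Mapping[str, float]) -> float:
    """Simple addition of member concentrations (each id counted once)."""
    unique = set(ids)
    missing = [i for i in unique if i not in molar_values]
    if missing:
        warnings.warn(f"{len(missing)} id(s) absent from concentration map; skipped", stacklevel=2)
    if not unique:
        warnings.warn("aggregating an empty id set", stacklevel=2)
    return float(sum(molar_values[i] for i in unique if i in molar_values))


def tissue_to_molar(value: float, unit: str = "umol_per_g") -> float:
    """Tissue amount per gram -> mM, assuming tissue density 1.0 g/cm^3."""
    if value < 0:
        raise ValueError("tissue concentrations must be non-negative")
    scale = {"umol_per_g": 1.0, "nmol_per_g": 1e-3}
    if unit not in scale:
        raise ValueError(f"unknown tissue unit {unit!r}")
    return value * scale[unit]


def proteome_share_to_molar(share: float, unit: str = "share") -> float:
    """Proteome abundance share (or ppm) -> mM via a 5 mM total protein pool."""
    if unit == "ppm":
        share = share / 1e6
    elif unit != "share":
        raise ValueError(f"unknown proteome unit {unit!r}")
    if not 0 <= share <= 1:
        raise ValueError(f"abundance share {share} outside [0, 1]")
    return share * TOTAL_PROTEIN_MM


def mass_to_molar(mg_per_100g: float, vitamin: str) -> float:
    """Food-table mass (mg per 100 g) -> mM, assuming 100 g ~ 100 mL.

    mM = (mg_per_100g / MW) * 10.
    """
    if vitamin not in MW_TABLE:
        raise ValueError(f"unknown vitamin tag {vitamin!r}")
    if mg_per_100g < 0:
        raise ValueError("masses must be non-negative")
    return mg_per_100g / MW_TABLE[vitamin] * 10.0


def link_metabolite_enzymes(
    catalog: AnnotationCatalog, metabolite_chebi_map: Mapping[str, Iterable[str]]
) -> dict[str, frozenset[str]]:
    """Per-metabolite enzyme sets via shared ChEBI identifiers.

    A metabolite maps to every catalog record whose ChEBI ids intersect the
    metabolite's ChEBI ids.  Metabolites with an empty ChEBI mapping are
    omitted with a warning.
    """
    out: dict[str, frozenset[str]] = {}
    skipped = 0
    for met, chebis in metabolite_chebi_map.items():
        cset = frozenset(chebis)
        if not cset:
            skipped += 1
            continue
        out[met] = frozenset(r.accession for r in catalog if r.chebi_ids & cset)
    if skipped:
        warnings.warn(f"{skipped} metabolite(s) had no ChEBI mapping; omitted", stacklevel=2)
    return out


# --------------------------------------------------------------------------
# cofactor objects


@dataclass(frozen=True)
class CofactorObject:
    """A cofactor class with its members and two aggregate molarities (mM)."""

    name: str
    metabolite_ids: frozenset[str]
    enzyme_accessions: frozenset[str]
    metabolite_mM: float
    enzyme_mM: float


def build_cofactor_objects(
    catalog: AnnotationCatalog,
    metabolome_mM: Mapping[str, float],
    proteome_mM: Mapping[str, float],
    metabolite_chebi_map: Mapping[str, Iterable[str]],
    formulas: Mapping[str, Formula] | None = None,
    object_names: Sequence[str] | None = None,
) -> list[CofactorObject]:
    """Build one cofactor object per named class.

    Enzyme members come from evaluating the class formula over the catalog;
    metabolite members are metabolites whose ChEBI ids intersect the class's
    anchor ChEBI ids.  Objects may overlap in membership; only the three-way
    proteome partition is exclusive.
    """
    formulas = dict(formulas) if formulas is not None else dict(DEFAULT_FORMULAS)
    names = list(object_names) if object_names is not None else [
        n for n in formulas if n in COFACTOR_CHEBI
    ]
    if len(set(names)) != len(names):
        raise ValueError("cofactor object names collide")
    objects = []
    for name in names:
        enzymes = evaluate_search_formula(catalog, formulas[name])
        anchors = frozenset(COFACTOR_CHEBI.get(name, ()))
        mets = frozenset(
            m for m, chebis in metabolite_chebi_map.items() if frozenset(chebis) & anchors
        )
        obj = CofactorObject(
            name=name,
            metabolite_ids=mets,
            enzyme_accessions=enzymes,
            metabolite_mM=aggregate_concentration(mets, metabolome_mM) if mets else 0.0,
            enzyme_mM=aggregate_concentration(enzymes, proteome_mM) if enzymes else 0.0,
        )
        if not enzymes:
            warnings.warn(f"cofactor object {name!r} has no member enzymes", stacklevel=2)
        objects.append(obj)
    return objects


def objects_to_frame(objects: Sequence[CofactorObject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [o.name for o in objects],
            "n_metabolites": [len(o.metabolite_ids) for o in objects],
            "n_enzymes": [len(o.enzyme_accessions) for o in objects],
            "metabolite_mM": [o.metabolite_mM for o in objects],
            "enzyme_mM": [o.enzyme_mM for o in objects],
        }
    )


# --------------------------------------------------------------------------
# catalog IO


def _split_multi(cell: str) -> tuple[str, ...]:
    if not isinstance(cell, str) or not cell.strip():
        return ()
    return tuple(p.strip() for p in cell.split(";") if p.strip())


def read_catalog(path: str | Path) -> AnnotationCatalog:
    """Read a TSV mirroring a UniProt column export.

    Expected headers: accession, entry_name, ec_number, catalytic_activity,
    nucleotide_binding, keyword_id, chebi_id; multi-valued cells are
    semicolon-separated.
    """
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = tuple(
        AnnotationRecord(
            accession=row["accession"],
            entry_name=row.get("entry_name", ""),
            ec_numbers=_split_multi(row.get("ec_number", "")),
            catalytic_activity=row.get("catalytic_activity", ""),
            nucleotide_binding=row.get("nucleotide_binding", ""),
            keyword_ids=frozenset(_split_multi(row.get("keyword_id", ""))),
            chebi_ids=frozenset(_split_multi(row.get("chebi_id", ""))),
        )
        for _, row in table.iterrows()
    )
    return AnnotationCatalog(records=records)


def write_catalog(catalog: AnnotationCatalog, path: str | Path) -> None:
    pd.DataFrame(
        {
            "accession": [r.accession for r in catalog],
            "entry_name": [r.entry_name for r in catalog],
            "ec_number": [";".join(r.ec_numbers) for r in catalog],
            "catalytic_activity": [r.catalytic_activity for r in catalog],
            "nucleotide_binding": [r.nucleotide_binding for r in catalog],
            "keyword_id": [";".join(sorted(r.keyword_ids)) for r in catalog],
            "chebi_id": [";".join(sorted(r.chebi_ids)) for r in catalog],
        }
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Rossmann-like domain summaries


@dataclass(frozen=True)
class RLDRecord:
    """Rossmann-like domain annotation for one enzyme chain."""

    enzyme_id: str
    chain_length_aa: int
    rld_lengths_aa: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.chain_length_aa <= 0:
            raise ValueError("chain length must be positive")
        if any(l <= 0 for l in self.rld_lengths_aa):
            raise ValueError("RLD lengths must be positive")
        if sum(self.rld_lengths_aa) > self.chain_length_aa:
            raise ValueError("summed RLD length exceeds chain length")


def rld_summary(records: Sequence[RLDRecord]) -> dict:
    """Percent-of-chain lengths, RLD-count histogram, and median total length.

    percent = 100 * sum(RLD lengths) / chain length per enzyme; histogram
    bins the per-enzyme RLD counts into {1, 2, >2}.
    """
    with_rld = [r for r in records if r.rld_lengths_aa]
    percents = {
        r.enzyme_id: 100.0 * sum(r.rld_lengths_aa) / r.chain_length_aa for r in with_rld
    }
    counts = [len(r.rld_lengths_aa) for r in with_rld]
    histogram = {
        "1": sum(1 for c in counts if c == 1),
        "2": sum(1 for c in counts if c == 2),
        ">2": sum(1 for c in counts if c > 2),
    }
    totals = [sum(r.rld_lengths_aa) for r in with_rld]
    return {
        "percent_lengths": percents,
        "count_histogram": histogram,
        "median_total_rld_aa": float(np.median(totals)) if totals else float("nan"),
        "median_percent": float(np.median(list(percents.values()))) if percents else float("nan"),
    }
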