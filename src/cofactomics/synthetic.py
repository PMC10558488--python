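"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes can be generated here, so all stages are
testable without downloads.  The generators emulate the structure of the
study data:

* a UniProt-style annotation catalog whose proteins belong to cofactor
  classes (NIA, B6, PA, B2, ATP, SAM, Gly, C1), to a plain-enzyme class or
  to a non-enzyme class, with log-normal abundances spanning roughly the
  -6..0 log10 mM window and an upward abundance shift for B-vitamin
  classes (hepatic B-vitamin enzymes are highly expressed);
* a metabolite pool per cofactor object whose total molarity is the enzyme
  total times 10**Normal(ratio_mean, ratio_sd) — planting a near-unity
  metabolite:enzyme molar ratio;
* a five-model cachexia experiment (MEWO, LNCA, SEKI, CRCA, STRV) whose
  experimental arms apply a planted abundance-dependent log2 fold-change
  decline per enzyme group;
* acyl-PTM site tables with a planted malonylation-specific shift on
  lysine sites shared by all three acyl types;
* a patient metabolite panel with a planted monotone trend over ordinal
  GPS severity groups and cachexia labels driven by two of the metabolites.

Every generator is a pure function of (parameters, seed); the returned
``truth`` dict records all planted quantities and the seed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import COFACTOR_CHEBI, AnnotationCatalog, AnnotationRecord
from .ptm import ACYL_TYPES, PTMSiteTable
from .tables_io import ConcentrationMatrix, SampleDesign

__all__ = [
    "MODELS",
    "generate_catalog",
    "generate_metabolome",
    "generate_cachexia_experiment",
    "generate_ptm_tables",
    "generate_patient_panel",
]

MODELS = ("MEWO", "LNCA", "SEKI", "CRCA", "STRV")

#: default class probabilities; remainder after these and the plain-enzyme
#: share is non-enzymatic.  Chosen so that a 1057-protein catalog roughly
#: reproduces the reference compartment sizes (96 NIA+B6+C1 enzymes, 292
#: other enzymes, 669 non-enzymes).
DEFAULT_CLASS_PROBS: dict[str, float] = {
    "NIA": 0.045,
    "B6": 0.025,
    "C1": 0.021,
    "PA": 0.030,
    "B2": 0.020,
    "SAM": 0.030,
    "ATP": 0.050,
    "Gly": 0.020,
}
DEFAULT_OTHER_ENZYME_PROB = 0.125

B_VITAMIN_CLASSES = ("NIA", "B6", "PA", "B2", "B1", "Biotin", "Folate", "B12")

_ENZYME_KEYWORD = "KW-0560"  # oxidoreductase-style enzyme keyword tag


def generate_catalog(
    n_proteins: int = 1057,
    cofactor_class_probs: Mapping[str, float] | None = None,
    *,
    other_enzyme_prob: float = DEFAULT_OTHER_ENZYME_PROB,
    abundance_log10_mean: float = -3.0,
    abundance_log10_sd: float = 1.0,
    b_vitamin_shift_log10: float = 0.5,
    seed: int | None = None,
) -> tuple[AnnotationCatalog, dict[str, float], dict]:
    """Generate an annotation catalog with log-normal abundances (mM).

    Returns (catalog, abundance mM per accession, truth).  Cofactor-class
    proteins carry an EC number plus their class's anchor ChEBI ids, so the
    default search formulas recover the planted classes exactly; plain
    enzymes carry only an EC number; non-enzymes carry neither.  Abundances
    are log10-normal; B-vitamin-class proteins are shifted upward by
    ``b_vitamin_shift_log10`` decades before the pool is renormalized to a
    5 mM total.
    """
    probs = dict(cofactor_class_probs) if cofactor_class_probs is not None else dict(
        DEFAULT_CLASS_PROBS
    )
    unknown = set(probs) - set(COFACTOR_CHEBI)
    if unknown:
        raise ValueError(f"unknown cofactor class(es): {sorted(unknown)}")
    total = sum(probs.values()) + other_enzyme_prob
    if any(p < 0 for p in probs.values()) or other_enzyme_prob < 0 or total > 1:
        raise ValueError("class probabilities must be non-negative and sum to <= 1")

    rng = np.random.default_rng(seed)
    classes = list(probs) + ["other_enzyme", "none"]
    weights = list(probs.values()) + [other_enzyme_prob, 1.0 - total]
    assignment = rng.choice(classes, size=n_proteins, p=weights)

    records = []
    log10_abund = rng.normal(abundance_log10_mean, abundance_log10_sd, size=n_proteins)
    for i, cls in enumerate(assignment):
        acc = f"P{i:05d}"
        is_enzyme = cls != "none"
        chebis = frozenset(COFACTOR_CHEBI[cls]) if cls in COFACTOR_CHEBI else frozenset()
        ec = (f"1.1.1.{i % 200 + 1}",) if is_enzyme else ()
        records.append(
            AnnotationRecord(
                accession=acc,
                entry_name=f"{cls.upper()}_{i}" if is_enzyme else f"PROT_{i}",
                ec_numbers=ec,
                catalytic_activity="catalyzes a reaction" if is_enzyme else "",
                nucleotide_binding="NAD" if cls == "NIA" else "",
                keyword_ids=frozenset({_ENZYME_KEYWORD}) if is_enzyme else frozenset(),
                chebi_ids=chebis,
            )
        )
        if cls in B_VITAMIN_CLASSES:
            log10_abund[i] += b_vitamin_shift_log10

    conc = 10.0 ** log10_abund
    conc *= 5.0 / conc.sum()  # renormalize the pool to a 5 mM total
    abundance = {r.accession: float(c) for r, c in zip(records, conc)}
    truth = {
        "seed": seed,
        "class_of": {r.accession: c for r, c in zip(records, assignment)},
        "class_counts": {c: int(np.sum(assignment == c)) for c in classes},
        "b_vitamin_shift_log10": b_vitamin_shift_log10,
    }
    return AnnotationCatalog(records=tuple(records)), abundance, truth


def generate_metabolome(
    catalog_truth: dict,
    abundance_mM: Mapping[str, float],
    *,
    ratio_mean: float = 0.0,
    ratio_sd: float = 0.3,
    mets_per_object: int = 3,
    seed: int | None = None,
) -> tuple[dict[str, float], dict[str, tuple[str, ...]], dict]:
    """Metabolite pools with planted metabolite:enzyme molar ratios.

    For each cofactor class present in the catalog, the metabolite pool
    total equals the class's summed enzyme molarity times
    10**Normal(ratio_mean, ratio_sd); the total is split randomly among
    ``mets_per_object`` member metabolites.  Returns (metabolite mM map,
    metabolite -> ChEBI map, truth with planted log10 ratios).
    """
    rng = np.random.default_rng(seed)
    class_of = catalog_truth["class_of"]
    enzyme_total: dict[str, float] = {}
    for acc, cls in class_of.items():
        if cls in COFACTOR_CHEBI:
            enzyme_total[cls] = enzyme_total.get(cls, 0.0) + abundance_mM[acc]

    metabolome: dict[str, float] = {}
    chebi_map: dict[str, tuple[str, ...]] = {}
    planted: dict[str, float] = {}
    for cls in sorted(enzyme_total):
        log10_ratio = float(rng.normal(ratio_mean, ratio_sd))
        planted[cls] = log10_ratio
        pool = enzyme_total[cls] * 10.0**log10_ratio
        shares = rng.dirichlet(np.ones(mets_per_object))
        for k in range(mets_per_object):
            name = f"{cls}_met{k + 1}"
            metabolome[name] = float(pool * shares[k])
            chebi_map[name] = (COFACTOR_CHEBI[cls][0],)
    truth = {"seed": seed, "log10_ratio": planted, "ratio_mean": ratio_mean, "ratio_sd": ratio_sd}
    return metabolome, chebi_map, truth


DEFAULT_SLOPES_PERMILLE: dict[str, dict[str, float]] = {
    # severity gradient: mild models barely respond, severe models plant the
    # full abundance-dependent decline on the focal (NIA/B6/PA) classes
    "MEWO": {},
    "LNCA": {"NIA": -40.0, "B6": -40.0, "PA": -40.0},
    "SEKI": {"NIA": -100.0, "B6": -100.0, "PA": -100.0},
    "CRCA": {"NIA": -100.0, "B6": -100.0, "PA": -100.0},
    "STRV": {},
}


def generate_cachexia_experiment(
    catalog: AnnotationCatalog,
    abundance_mM: Mapping[str, float],
    catalog_truth: dict,
    *,
    slopes_permille: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 0.2,
    sample_noise_sd: float = 0.05,
    fc_anchor_log10: float = -6.0,
    n_per_arm: int = 3,
    seed: int | None = None,
) -> tuple[ConcentrationMatrix, SampleDesign, dict]:
    """Five-model experiment with planted abundance-dependent declines.

    Control samples scatter log-normally around each protein's planted
    abundance.  Experimental samples apply a per-protein
    log2 FC = (slope_g/1000) * (log10(abundance) - fc_anchor_log10)
    + Normal(0, noise_sd), where slope_g is the planted permille slope of
    the protein's class in that model (0 when unspecified).  The anchor is
    the abundance (default 1e-6 mM, the bottom of the synthetic dynamic
    range) at which the planted change vanishes, so a negative slope makes
    abundant proteins decline — the regression slope itself is unaffected
    by the anchor.  Returns (matrix, design, truth) with the per-model,
    per-protein planted log2 FCs recorded in truth.
    """
    slopes = (
        {m: dict(v) for m, v in slopes_permille.items()}
        if slopes_permille is not None
        else {m: dict(v) for m, v in DEFAULT_SLOPES_PERMILLE.items()}
    )
    rng = np.random.default_rng(seed)
    accs = [r.accession for r in catalog]
    conc = np.array([abundance_mM[a] for a in accs])
    log10_conc = np.log10(conc)
    class_of = catalog_truth["class_of"]

    columns: dict[str, np.ndarray] = {}
    design_rows = []
    truth_fc: dict[str, dict[str, float]] = {}
    for model in slopes:
        model_slopes = slopes[model]
        slope_vec = np.array([model_slopes.get(class_of[a], 0.0) for a in accs])
        log2fc = (slope_vec / 1000.0) * (log10_conc - fc_anchor_log10) + rng.normal(
            0, noise_sd, size=len(accs)
        )
        truth_fc[model] = dict(zip(accs, map(float, log2fc)))
        for arm, mult in (("control", np.ones(len(accs))), ("experimental", 2.0**log2fc)):
            for k in range(n_per_arm):
                sid = f"{model}_{arm[:3]}_{k + 1}"
                noise = 2.0 ** rng.normal(0, sample_noise_sd, size=len(accs))
                columns[sid] = conc * mult * noise
                design_rows.append(
                    {"sample_id": sid, "model": model, "arm": arm, "tissue": "liver", "sex": "F"}
                )

    matrix = ConcentrationMatrix(
        data=pd.DataFrame(columns, index=accs), unit="mM", entity_kind="protein"
    )
    design = SampleDesign(table=pd.DataFrame(design_rows))
    truth = {
        "seed": seed,
        "slopes_permille": slopes,
        "noise_sd": noise_sd,
        "log2fc": truth_fc,
    }
    return matrix, design, truth


def generate_ptm_tables(
    catalog: AnnotationCatalog,
    *,
    n_shared_sites: int = 300,
    delta_mal_log2: float = 1.0,
    sigma: float = 0.3,
    n_extra_per_table: int = 50,
    seed: int | None = None,
) -> tuple[dict[str, PTMSiteTable], dict[str, float], dict]:
    """Three acyl site tables with a planted malonylation-specific decline.

    Shared lysine sites carry log2 adjusted FC ~ Normal(0, sigma) for aceK
    and sucK and Normal(-delta, sigma) for malK; each table additionally
    gets non-shared sites.  Site FCs are the adjusted FCs multiplied by the
    parent protein's FC, so dividing by the protein FC recovers them.
    Returns ({acyl: table}, protein FC map, truth).
    """
    if n_shared_sites < 1:
        raise ValueError("need >=1 shared site")
    rng = np.random.default_rng(seed)
    accs = [r.accession for r in catalog]
    protein_fc = {a: float(2.0 ** rng.normal(0, 0.3)) for a in accs}

    site_accs = rng.choice(accs, size=n_shared_sites, replace=True)
    positions: dict[str, set[int]] = {}
    shared_sites = []
    for a in site_accs:
        pos = int(rng.integers(1, 600))
        while pos in positions.setdefault(a, set()):
            pos = int(rng.integers(1, 600))
        positions[a].add(pos)
        shared_sites.append((a, pos))

    tables: dict[str, PTMSiteTable] = {}
    for acyl in ACYL_TYPES:
        shift = -delta_mal_log2 if acyl == "malK" else 0.0
        adj = 2.0 ** rng.normal(shift, sigma, size=n_shared_sites)
        rows = [
            {
                "accession": a,
                "position": p,
                "acyl": acyl,
                "fc": adj[k] * protein_fc[a],
            }
            for k, (a, p) in enumerate(shared_sites)
        ]
        for _ in range(n_extra_per_table):
            a = str(rng.choice(accs))
            pos = int(rng.integers(600, 1200))  # disjoint position range: never shared
            rows.append(
                {
                    "accession": a,
                    "position": pos,
                    "acyl": acyl,
                    "fc": float(2.0 ** rng.normal(0, sigma)) * protein_fc[a],
                }
            )
        frame = pd.DataFrame(rows).drop_duplicates(["accession", "position", "acyl"])
        tables[acyl] = PTMSiteTable(table=frame)

    truth = {
        "seed": seed,
        "n_shared_sites": n_shared_sites,
        "delta_mal_log2": delta_mal_log2,
        "sigma": sigma,
        "shared_sites": shared_sites,
    }
    return tables, protein_fc, truth


PANEL_METABOLITES = ("betaine", "Ser", "Thr", "choline", "GAA", "Trp")


def generate_patient_panel(
    n_per_gps: Sequence[int] = (20, 10, 27),
    *,
    trend_effects: Mapping[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Patient panel with a planted monotone decline over GPS 0/1/2.

    Metabolite value = -effect * GPS + Normal(0, noise_sd) per patient (so a
    positive effect plants a decreasing trend).  Cachexia labels are driven
    by the planted choline and Trp signals through a logistic link, making
    their combination the best discriminator by construction.
    """
    effects = dict(trend_effects) if trend_effects is not None else {
        m: 0.8 for m in PANEL_METABOLITES
    }
    rng = np.random.default_rng(seed)
    gps = np.concatenate([np.full(n, level) for level, n in enumerate(n_per_gps)])
    data = {
        m: -effects.get(m, 0.0) * gps + rng.normal(0, noise_sd, size=gps.size)
        for m in PANEL_METABOLITES
    }
    frame = pd.DataFrame(data)
    logit = -(frame["choline"] + frame["Trp"]) - 1.0
    p_cachexia = 1.0 / (1.0 + np.exp(-logit))
    frame["GPS"] = gps
    frame["cachexia"] = (rng.random(gps.size) < p_cachexia).astype(int)
    truth = {"seed": seed, "trend_effects": effects, "noise_sd": noise_sd}
    return frame, truth
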