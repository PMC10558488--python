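# cofactomics

Cofactor-centric integration of liver metabolome, proteome, PTM and
blood-biomarker data, built for studies of systemic metabolic disease —
in particular cancer cachexia, where B-vitamin-related liver enzymes
decline together with their cofactor metabolites.

The package is aimed at computational biologists who have per-tissue
concentration matrices (CE-MS metabolomics, TMT or label-free proteomics),
a UniProt-style annotation export, acyl-lysine PTM site tables, and patient
metabolite panels, and who want to reproduce or extend this style of
analysis on their own data. Every stage is also exercisable on a bundled
synthetic-data generator with planted ground truth, so the statistics can
be validated without any downloads.

## What it computes

**Cofactor objects and stoichiometry.** For each cofactor class *c* (NIA,
B6, PA, B2, B1, SAM, ATP, Gly, C1, Biotin, Folate, B12) a *cofactor
object* carries two aggregate molarities obtained by simple addition over
annotation-defined members:

    M_c = Σ_{i ∈ metabolites(c)} m_i   [mM],
    E_c = Σ_{j ∈ enzymes(c)} e_j       [mM]

with all quantities converted to a common molar scale (tissue density
1.0 g/cm³, so 1 µmol/g = 1 mM; proteome shares × 5 mM total protein;
food-table mg/100 g via the vitamin molecular-weight table). The molar
ratio R_c = M_c / E_c is summarized per species, with the "gray zone"
|log₁₀ R_c| ≤ 1 flagging near one-to-one stoichiometry, plus log-log OLS
fits between the two aggregates.

**Abundance-dependent decline.** The *depression slope* is the OLS slope
of log₂ fold change on log₁₀ protein concentration, × 1000 (permille);
a coarse high/low × up/down classification with Fisher's exact test; and
the multiple regression

    log₂ FC = β₀ + β₁·1[focal cofactor class] + β₂·log₁₀(concentration)

with GVIF = 1/(1 − r²) as the collinearity diagnostic.

**Matched resampling.** Repeated subsampling of a proteome to fixed
per-compartment counts (default 96 NIA+B6+C1 enzymes + 292 other enzymes
+ 669 non-enzymes = 1057 proteins), scored by correlation-matrix PCA; the
separability of severe vs other disease models is summarized by the
maximal margin 2/‖w‖ of a linear soft-margin SVM (cost 1) on the PC1/PC2
plane.

**Acyl-PTM competition.** Lysine sites shared by acetylation,
malonylation and succinylation, protein-adjusted fold changes
(FC_site / FC_protein), the strict (0.03, 32) filter, one-way ANOVA and
many-to-one Dunnett comparisons against malonylation.

**Biomarker trends.** A one-sided permutation Jonckheere–Terpstra trend
test over ordinal severity scores (GPS 0/1/2), repeated random-forest
feature selection by scaled mean decrease in accuracy (MDA > 1.5), and
univariate/logistic-combination ROC AUC.

## Worked example

```python
from cofactomics import annotations, severity, stoichiometry, synthetic, tables_io

# a synthetic liver study: annotated proteome + metabolite pools + a
# five-model cachexia experiment, all with planted ground truth
catalog, abundance, truth = synthetic.generate_catalog(1057, seed=7)
metabolome, chebi_map, _ = synthetic.generate_metabolome(truth, abundance, seed=8)

objects = annotations.build_cofactor_objects(catalog, metabolome, abundance, chebi_map)
usable = [o for o in objects if o.enzyme_mM > 0 and o.metabolite_mM > 0]
summary = stoichiometry.species_ratio_summary({"mouse": usable})
print(f"objects: {len(usable)}, median metabolite:enzyme ratio = "
      f"{summary['species_median']['mouse']:.2f}, "
      f"gray-zone fraction = {summary['gray_zone_fraction']:.2f}")

matrix, design, _ = synthetic.generate_cachexia_experiment(catalog, abundance, truth, seed=9)
fc = tables_io.group_fold_change(matrix, design, "CRCA")
fc_map = dict(zip(fc.table["entity_id"], fc.table["log2fc"]))
focal = [a for a, c in truth["class_of"].items() if c in ("NIA", "B6", "PA")]
slope = severity.depression_slope([abundance[a] for a in focal], [fc_map[a] for a in focal])
print(f"CRCA focal (NIA/B6/PA) depression slope = {slope:.1f} permille")

enzymes = [a for a, c in truth["class_of"].items() if c != "none"]
reg = severity.cofactor_regression(
    [fc_map[a] for a in enzymes],
    [truth["class_of"][a] in ("NIA", "B6", "PA") for a in enzymes],
    [abundance[a] for a in enzymes],
)
print(f"dummy coefficient = {reg.coefficients['dummy']:.3f} "
      f"(p = {reg.p_values['dummy']:.2e}), GVIF = {reg.gvif['dummy']:.3f}")
```

prints

```
objects: 8, median metabolite:enzyme ratio = 0.95, gray-zone fraction = 1.00
CRCA focal (NIA/B6/PA) depression slope = -119.2 permille
dummy coefficient = -0.264 (p = 1.84e-25), GVIF = 1.003
```

The median ratio near 1 with every object inside the gray zone reflects
the planted near-unity stoichiometry; the strongly negative depression
slope (planted at −100‰, estimated under noise) says that the more
abundant a focal enzyme is, the more it declines in the severe model; and
the negative dummy coefficient shows the focal cofactor classes decline
beyond what abundance alone explains, with GVIF ≈ 1 confirming the two
predictors are essentially uncorrelated.

A thin CLI mirrors the main steps (`cofactomics fc`, `objects`, `ratios`,
`slopes`, `jt`, `simulate`); run `cofactomics --help` for details.

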