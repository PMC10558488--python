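# Methods

This note documents the models, conventions and numerical choices behind
`cofactomics`, in the order the pipeline runs.

## Preprocessing conventions

Concentration matrices hold entities in rows, samples in columns, with an
explicit unit tag (`umol_per_g`, `mM`, `share`, `ppm`, `mg_per_100g`,
`intensity`) and entity kind. Missing cells may be written as empty, `NA`
or `NaN`; negative values are rejected outright because every supported
unit is a non-negative concentration.

Metabolome matrices are cleaned in two steps: entities missing in every
sample are removed, then each remaining missing cell is replaced by one
half of the **global** minimum present value of the whole matrix — not a
per-row minimum. The global rule keeps imputed values comparable across
metabolites whose detection limits are shared by the platform rather than
by the analyte. Proteome matrices are never imputed; rows containing any
missing value are dropped, because a protein absent from one TMT channel
usually reflects identification failure rather than a low concentration.

Median-ratio normalization divides each sample by the median over entities
of (sample value / reference value); entities with a zero reference value
are excluded from that median with a warning. The operation is idempotent:
a second pass yields scale factors of 1.

Fold changes are ratios of arithmetic group means on the linear scale
(experimental over control), with a ratio-of-medians option since
TMT-style normalization is itself median-based; entities whose control
mean is zero are excluded and listed. Welch's two-sided t-test supplies
volcano p-values; two exactly identical groups are defined to have p = 1
(zero statistic), and zero-variance groups with different means get p = 0
without a division error.

## Annotation search and cofactor objects

Search formulas form a small boolean grammar — AND/OR/NOT over field
predicates — where each leaf names an annotation field, a match mode
(case-insensitive substring, case-insensitive regex, or exact tag for the
keyword/ChEBI id sets) and a pattern. Free-text UniProt fields are prose,
so substring matching is the default and regex is opt-in per leaf. The
shipped default formulas are reconstructed, deliberately minimal anchors
(one ChEBI id list per cofactor class; "any EC number" as the all-enzymes
selector) and are fully overridable from a YAML file; any catalog/formula
pair is accepted.

The three-way proteome partition (B-vitamin enzymes / other enzymes /
non-enzymes) is exclusive by construction, with B-vitamin membership
taking precedence inside the enzyme set. Cofactor objects, in contrast,
may overlap — a C1 enzyme can also be a B6 enzyme — since overlap is a
property of the biology, not a bookkeeping error.

Aggregation is simple addition over the member set, each id counted once;
ids without a concentration are skipped with a logged count. Molar
conversions are linear: tissue amounts assume a density of 1.0 g/cm³
(1 µmol/g = 1 mM); proteome shares are multiplied by an assumed 5 mM
total protein pool, so a whole proteome of shares sums to exactly 5 mM;
food-composition masses convert via the vitamin molecular-weight table
(B1 265.355, B2 376.36, NIA 123.111, B6 169.18, PA 219.23, Biotin 244.31,
Folate 441.4, B12 1355.388 g/mol) assuming 100 g of food ≈ 100 mL — a
density the food tables do not state, so 1.0 is adopted for symmetry with
the tissue convention.

## Stoichiometry statistics

Log-log fits are OLS on (log₁₀ x, log₁₀ y) with Pearson's r and its
two-sided p computed on the logged data. Non-positive pairs are excluded
and counted, never offset-shifted: an additive pseudo-count would bend
the low end of a six-decade axis. Fits need at least 3 usable pairs; a
constant response is reported as slope 0 with the correlation flagged
NaN rather than raising.

The molar-ratio gray zone |log₁₀(M/E)| ≤ 1 uses **inclusive** bounds
("within ±1" read as a closed interval); the choice only matters for
ratios exactly at 0.1 or 10. Cross-species averages are primarily
geometric means (mean of log₁₀ ratios, exponentiated), because ratios are
multiplicative; the arithmetic mean is also emitted for comparison.
Linear response fits between metabolite and enzyme fold changes across
models are OLS on log₂ FC, with an opt-in exclusion list for models (the
starvation arm) that sit off the cancer trend.

## Abundance-dependent decline

The depression slope is the OLS slope of log₂ FC on log₁₀ concentration,
reported ×1000 — log₂-FC units per decade of abundance, in permille. The
high/low split in the coarse classification is the mean of **log₁₀**
concentrations by default (all abundance axes in this analysis are
logarithmic; a linear-scale mean is a recorded option); ties at the
threshold go to "low", and proteins with log₂ FC exactly 0 are excluded
from up/down (only degenerate synthetic data is affected). The quartile
variant thresholds at the 75th percentile of an **external reference**
proteome, matching the use of public abundance estimates rather than the
analyzed dataset's own distribution. The cofactor regression uses log₂ FC
as response and (class dummy, log₁₀ mM) as predictors; with two
predictors both GVIFs coincide and equal 1/(1 − r²) of their correlation.
Perfect collinearity raises an error naming the predictors.

## Matched resampling and SVM margins

Comparing severe-vs-other separability between two tissues is confounded
by proteome composition, so the larger proteome is repeatedly subsampled
to exact per-compartment counts (default 96 / 292 / 669, total 1057,
matching the smaller tissue). A master seed derives per-draw seeds, so
the full draw list is reproducible from one integer. Each draw is scored
by PCA after unit-variance scaling (correlation-matrix PCA;
zero-variance variables are dropped with a warning), and a linear
soft-margin SVM with cost 1 — the stated library default — is fitted on
the PC1/PC2 score plane, the space in which the separating hyperplanes
are drawn; fitting in the full variable space is available as an option.
The margin is 2/‖w‖; for non-separable draws the same width is reported
with the count of margin violations attached, and a fully degenerate fit
(zero weight vector) reports an infinite width. In margin comparisons a
tie counts as not-greater.

## Acyl-PTM competition

Site identity is (protein accession, 1-based residue position); peptide
context is assumed resolved upstream. Shared sites are the exact triple
intersection across the acetylation, malonylation and succinylation
tables. Adjusted FC = site FC / protein FC isolates modification-level
change and is invariant to any common rescaling of both tables. The
retention filter is the strict open interval (0.03, 32) on adjusted FC
and is applied before intersection by default. Group comparisons run on
log₂ adjusted FC: one-way ANOVA, then many-to-one comparisons of aceK
and sucK against malK via the multivariate-t Dunnett test, with a seeded
max-t permutation fallback (default 10,000 permutations); the method used
is always recorded in the output. Strong shifts can underflow the
multivariate-t tail, in which case the adjusted p prints as 0.

## Biomarker trends

The Jonckheere–Terpstra statistic sums Mann–Whitney counts over ordered
group pairs, ties counted ½. The one-sided p is the add-one permutation
estimator (1 + #{permuted JT ≥ observed}) / (1 + B), which can never be 0;
a decreasing alternative is tested by negating the values, which reverses
every pairwise comparison. B defaults to 10,000 and is always logged
with the seed.

Random-forest feature selection mirrors the classical forest importance:
per tree, out-of-bag accuracy is re-measured with each feature's OOB
column permuted, and the scaled MDA is the mean importance over trees
divided by its standard error (z-scaling, the type-1 convention;
implementations differ, so the convention is stated here). Trials use
distinct seeds derived from one master seed — full reproducibility is
preferred over literally unseeded trials — and across trials the mean and
a percentile 95% CI are reported, with selection at mean scaled MDA > 1.5.

Univariate AUC is the exact rank statistic with ties counted ½ (so
AUC(s) + AUC(−s) = 1 identically); multivariate AUC scores samples by a
maximum-likelihood logistic fit of the feature combination.

## Synthetic data: what it emulates, and what it does not

Abundances are log₁₀-normal (mean −3, sd 1 on log₁₀ mM, renormalized to
a 5 mM pool), spanning the ~6-decade window typical of deep liver
proteomes, with a +0.5-decade shift for B-vitamin classes emulating their
high hepatic expression. Class probabilities default to values that make
a 1057-protein catalog roughly reproduce the reference compartment sizes
(96/292/669). Metabolite pools plant log₁₀(M/E) ~ Normal(0, 0.3) per
cofactor object, split over three metabolites by a Dirichlet draw.

The cachexia experiment plants, per model and enzyme class, a permille
slope s: log₂ FC = (s/1000)·(log₁₀ conc − (−6)) + Normal(0, 0.2), with
5% multiplicative per-sample noise. The anchor at the bottom of the
abundance window makes a negative slope an actual *decline* of abundant
enzymes (the slope estimate itself is anchor-invariant; only the
intercept moves) — an uncentered planting would assign abundant proteins
fold changes near zero and low-abundance proteins spuriously positive
ones, inverting the group-level sign of the dummy regression. Default
slopes follow a severity gradient: 0 for MEWO and STRV, −40‰ for LNCA,
−100‰ for SEKI and CRCA on the NIA/B6/PA classes.

PTM tables plant log₂ adjusted FC ~ Normal(0, σ) for aceK/sucK and
Normal(−δ, σ) for malK on n shared sites (defaults δ = 1, σ = 0.3,
n = 300), plus non-shared sites in a disjoint position range. The patient
panel plants a monotone decline of six metabolites (betaine, Ser, Thr,
choline, GAA, Trp) over GPS 0/1/2 at 0.8 sd per level, with cachexia
labels drawn from a logistic model of the choline and Trp signals so
their combination is the best discriminator by construction.

What the generators do **not** emulate: batch effects, missingness
mechanisms tied to abundance, correlated enzyme co-regulation within
pathways, compositional (closed-sum) distortions of TMT ratios, or
peptide-level quantification noise. Tests passing on this synthetic data
therefore validate the statistics and bookkeeping, not robustness to
those real-data artifacts.

## Study sizes and runtime choices

The package's default desk-scale study uses a 2500-protein catalog for
resampling (so every compartment pool safely exceeds its draw), 200
matched draws, 10 random-forest trials of 200 trees, and 10,000 trend
permutations; `scripts/acceptance.py` reports every quantity together
with the problem size used. The weak-response ("muscle-like") tissue in
the margin comparison scales the whole planted response down — slopes ÷4
and model-level FC noise 0.2 → 0.05 — because tissue response strength
lives in both terms; scaling only the slopes would leave both tissues
dominated by identical model-level noise and make the margin comparison
uninformative by construction.

## Known limitations

Default search formulas are minimal reconstructions, not a curated
annotation set; real analyses should supply their own formula file and
ChEBI map. The Dunnett step assumes approximate normality of log₂
adjusted FCs within acyl groups (the permutation fallback does not). The
SVM margin is a geometric descriptor of a score plot, not a validated
classifier. Fold-change estimation by ratio of means is sensitive to
heavy-tailed outliers; the median option trades efficiency for
robustness.
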