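# Methods

This note documents the models behind `markertrait`, the choices made
where the design was genuinely open, and what the synthetic-trial tests
do and do not demonstrate about real data.

## Study design the package targets

A provenance–progeny common-garden trial: open-pollinated seed collected
from 3–5 mother trees per natural population, several populations per
species, up to ~10 genotyped offspring per family, grown in randomized
blocks. Offspring of one mother are treated as half-sibs (unknown,
assumed-unrelated fathers; expected additive relationship 0.25).
Phenology is scored in days relative to the first tree at the site to
reach the stage; growth as total height (mm) and annual increment.

## Phenotype derivation

**Budburst.** Observations are (day, stage 1–7) per tree. The day a tree
reaches stage *s* is the first assessment with recorded stage ≥ *s*; a
stage skipped between two assessments gets the midpoint of the bracketing
assessment dates; a stage never reached is missing. Timing is reported
relative to the site-wide first tree per stage (recomputed after
cleaning), so timings are invariant to shifting all dates. Duration is
the raw-day interval from stage 4 to stage 6.

**Heights.** A height lower than the last retained height is physically
impossible (measurement error or leader loss) and is set to missing.
Increments are defined between adjacent years only; an increment spanning
a cleaned-away year is left missing rather than back-filled, because the
increment is the rise from one year to the next, not across a gap.

**Correlations** are pairwise-complete Pearson r with the t-transform
p-value (n−2 df), reported with per-cell n; p-values are not
multiplicity-adjusted. Pairwise- rather than listwise-complete was chosen
because trait missingness is trait-specific (a tree missing one height
year still informs other pairs); the per-cell n makes the choice visible.

**Nested ANOVA** is a linear mixed model (statsmodels, REML) with
population fixed and family-within-population and block as variance
components; the population effect is a joint Wald test. A single-level
block factor is dropped with a warning.

## Genotype QC

Samples with call rate strictly below 0.80 are removed (a sample at
exactly 80% is retained). Samples are filtered before per-subset locus
classification; the order matters only marginally and is documented here.
Per subset a locus is `CR<80` if its within-subset call rate is < 0.80,
else `Mono` if a single genotype class segregates, else `Poly`
(precedence CR<80 > Mono > Poly). A class is "shared" by a species
combination only when every member species assigns that class; the
precedence plus every-member rule is our reading of shared-count tables,
stated here because no formal definition exists. MAF is computed within
each analysis subset over non-missing calls (allele orientation is fixed
globally), so a locus can be common in one dataset and rare in another;
the boundary MAF = 0.05 is classed common because the association filter
excludes strictly MAF < 0.05.

## Kinship and covariates

Kinship is the centred-IBS (VanRaden-style) genomic relationship
K = WWᵀ / Σₗ 2pₗ(1−pₗ), with W the locus-mean-centred call matrix and pₗ
the sample allele frequency. Missing calls are mean-imputed per locus for
K and PCA only, which keeps K a Gram matrix (PSD). The expected diagonal
is ≈ 1+F; published "centred IBS" implementations differ by global scale
factors, so downstream models normalize K to mean diagonal 1 (trace/n)
before fitting — mixed-model tests are invariant to the scale, and the
normalization makes h² the per-individual variance fraction and invariant
to the convention of the supplied matrix. PC covariates are eigenvectors
of the centred genotype covariance scaled by singular values. The
D'Agostino skewness test (scipy's `skewtest`, n ≥ 8) diagnoses the
half-sib signature: a positive tail in the kinship distribution.

## GREML

Model: y = Xβ + g + e, cov(g) = σ²g K, e ~ N(0, σ²e I). One
eigendecomposition of K reduces the restricted likelihood to a 1-D
profile in γ = σ²g/σ²e, maximized over log γ ∈ [log 1e−6, log 1e6] by a
41-point grid plus Brent refinement (the one-component profile is
unimodal in practice; a derivative-free bracket is robust). The trait is
standardized internally so estimation is exactly scale-equivariant.
Boundary optima are flagged. The SE of h² comes from the observed
information (central differences in (σ²g, σ²e)) and the delta method; at
a boundary it is reported missing rather than extrapolated. For
multi-species data the fixed-effect design X may include species
indicators; both pooled and species-adjusted fits are exposed because
either convention is defensible for a combined-species h².

## Association

**MLM.** Each locus is tested in y = μ + PCγ + x b + g + e with
cov(g) ∝ K. The default engine is P3D: variance components are estimated
once on the null model, the data are whitened by V^(−1/2) from the
eigendecomposition, and every marker is tested by partitioned OLS in the
rotated space — O(loci) cost. The exact mode re-optimizes per locus and
is reserved for small problems; on traits with a genuine polygenic
component the two agree closely (the unit tests require −log₁₀p agreement
within ~0.2 for strong signals), while for a single huge QTL with no
background the null model absorbs marker variance and P3D is
conservative. Monomorphic loci are skipped with a reason; loci collinear
with covariates are flagged, not fatal. Default 5 PCs (configurable, and
recorded in pipeline output) — the covariate count is rarely stated in
published analyses.

**FDR** is Benjamini–Hochberg (statsmodels), applied per dataset × trait
(matching the per-trait retention rule), threshold q < 0.05.

**MLMM.** Kinship only, no PCs. Forward steps add the most significant
marker below the p < 0.001 entry screen as a fixed cofactor and
re-estimate variance components; backward steps drop cofactors whose
joint-model p rises above the screen. The reported model is the largest
set along the path whose cofactors all have p < 0.05/m (m = polymorphic
markers tested) — the multiple-Bonferroni criterion. Ties in minimum p
break by locus order; of two perfectly collinear markers only the first
can enter. Note the criterion's family-wise error is ~5% by construction,
so pure-null scans select a non-empty model in about 1 run in 20.

**Power.** Closed form: power = P(χ²₁(ncp) > χ²₁;1−α) with
ncp = n·q/(1−q)/(1+λ), q the QTL's share of phenotypic variance and λ the
polygenic background expressed relative to the non-QTL phenotypic
variance. The formula treats the background as exchangeable noise; the
built-in simulation oracle implements exactly that generative model and
applies the 1-df test at the true variance components, isolating the
formula from estimator noise. When the background is instead correlated
with sample structure, a mixed model exploits the correlation and real
power is slightly higher than the formula — the formula is therefore
mildly conservative for structured samples. The expression is a plain
function and can be swapped for any published alternative.

## Prediction

SNP sets are unions of significant loci over chosen source datasets with
merged provenance; any locus monomorphic in a target dataset (training
subset or either independent site) is dropped and reported. Missing
genotypes are replaced by family means, falling back to population then
dataset means. Small associated sets are fitted by OLS (rank-deficient
designs error by default, naming constant loci; assessment uses a mode
that zeroes such coefficients, as R's `lm` NA's them). The all-SNP model
is RR-BLUP: û = Zᵀ(ZZᵀ + λI)⁻¹(y − ȳ), λ = σ²e/σ²u with σ²u from REML on
the marker-based relationship matrix — algebraically identical to GBLUP
on the same markers (asserted to 1e−8 in tests). Shrinkage is
re-estimated per training set. Random control sets match the reference
set's common/rare composition, sampled without replacement from all
polymorphic loci; their accuracy is summarized with a normal 95% CI
(mean ± 1.96·SD/√10). The internal 60/40 split is random by individual by
default; half-sibs straddling the split inflate r, so a family-stratified
split is available. Predicted-vs-observed comparisons use raw phenotypes
throughout. Selection comparison: the k = 10 highest model-predicted
trees vs the k tallest before the second growing season, compared on mean
final height, CV (SD/mean × 100) and overlap with the true final top-k;
ties at rank k break by id order. External models are fitted once on
training data and applied to sites as-is.

## Diversity statistics

Nei/Chesser estimators with the small-sample correction: per locus
H_O = mean within-population heterozygote frequency,
H_S = ñ/(ñ−1)·(mean within-population gene diversity − H_O/2ñ) with ñ the
harmonic mean population size, H_T from the mean allele frequency with
the standard correction terms, F_IS = 1 − H_O/H_S and
F_ST = (H_T − H_S)/H_T. Overall values are ratios of locus averages
(ratio-of-averages); loci monomorphic overall are excluded and counted.

## The synthetic trial generator

Allele frequencies are hierarchical Balding–Nichols: ancestral frequency
per locus from a configurable spectrum (default Beta(0.5, 2), giving a
realistic excess of rare variants), species frequencies drifted with
F_ST,species = 0.25, population frequencies drifted with
F_ST,pop = 0.05. A configurable fraction of loci (default 0.5) is
polymorphic in every species; these represent shared ancestral variation
and are held at intermediate frequencies (ancestral MAF ≥ 0.15, species
≥ 0.10, population ≥ 0.05) so the designated fraction is realized in
finite samples; species-private loci follow the full spectrum. Mothers
are drawn at population frequencies; offspring get one Mendelian maternal
gamete and one pollen gamete at the population frequency (open
pollination), giving half-sib families with expected relatedness 0.25.

Traits (bud set, budburst, height/increment) each have a QTL component
(default 10 loci, 15% of phenotypic variance), a genome-wide background
(default 45%), population mean shifts (SD 0.4 trait SD) and species means
echoing the field ordering (bud set earliest in the dwarf species, the
tall species roughly twice the dwarf's height by year three). The
background is by default the sum of many small effects at polymorphic
non-QTL loci ("markers" mode): on a gene-based array the polygenic
background is tagged by the genotyped loci themselves, which is what lets
an all-SNP ridge model outperform a small causal set, as observed in real
trials. A "pedigree" mode (family-structured MVN with half-sib covariance
0.25 σ²g and no marker effects) is available; it is the construction used
by the null-trait harness, whose contract is zero per-marker effects.
Maternal effects are a per-family N(0, 30 mm) intercept on first-year
height, decaying by 0.5 per year of age — early-height correlations fade
with age, as provenance trials show. Heights accumulate over three
seasons (25/35/40% of final); increments are height differences.
Missingness is injected per call (2%) with a 2% subsample of low-call
samples at 35% missingness, so the call-rate filter has work to do.

`simulate_independent_sites` adds a glasshouse-like training cohort
("GH") and ≥ 2 field sites sharing the same families; growth genetics are
shared with site-specific means (`site_effects`, mm), and with
`phenology_flip` the budburst genetic component enters with a positive
sign in the glasshouse and first site but reversed at the second — the
chilling-requirement mechanism by which early-flushing genotypes under
glass flush late in the field. The flip is imposed, not mechanistically
derived from climate.

What the generator does **not** emulate: linkage and LD decay (loci are
exchangeable, so "nearby-marker tagging" is absent and prediction
accuracies are driven by direct genotyping of causal loci plus
structure), selfing and inbreeding, dominance/epistasis, genotyping-array
ascertainment bias, spatial block effects within sites, and climate-driven
year effects. Passing tests therefore demonstrate the statistical
machinery — calibration, recovery, ordering, sign conventions — under the
assumed sampling design, not the field performance of any particular
real-data model.

## Numerical choices and degenerate inputs

- GREML ratio bounded to [1e−6, 1e6]; boundary hits flagged; K equal to
  (a multiple of) the identity is rejected as unidentifiable; non-PSD K
  rejected (tolerance 1e−8 relative).
- Whitening clips tiny negative eigenvalues of K at 0.
- Scan denominators below 1e−8 of the maximum mark a locus collinear.
- Genomic-control λ is median χ²/0.4549 from the p-values.
- Pearson cells with < 3 complete pairs, constant vectors, or
  near-constant predictions (relative SD ≤ 1e−12) are missing, never 0.
- All simulator randomness derives from one integer seed through named
  `SeedSequence` sub-streams (frequencies, genotypes, phenotypes,
  missingness), so adding draws to one stream does not perturb others.
- Pipeline tables are written with `%.10g` floats; manifests record
  SHA-256 of every artifact, and identical configuration + seed
  reproduces identical hashes.

## Problem sizes used by the validation experiments

The calibration experiments (`markertrait.validation`) use: one
structured null trial of ~384 offspring × 2000 loci for type-I error;
100 simulations of 500 offspring × 400 loci (20 causal at 2.5% variance
each) for FDR; 100 traits per h² level on a 500-offspring kinship for
GREML recovery; 100 signal and 200 null simulations at n = 500 × 500 loci
for the MLMM; 20 replicates of 480 offspring × 2000 loci for the
prediction-model ordering; 20 replicates (sign flip) and 50 replicates
(selection) of two-site trials; and a 2000-replicate oracle at n = 400
for power. These sizes give Monte-Carlo error comfortably below the
assertion bands while keeping a full run in the minutes range on one CPU.
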