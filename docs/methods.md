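# Methods

This note documents the statistical machinery in `lvgwas`: the models, the
defaults and why they were chosen, what the synthetic cohort does and does
not emulate, and the numerical conventions that matter for reproducing its
output.

## Phenotype derivation

Seven LV traits are derived per sample: LVEDV and LVESV (mL, as measured),
SV = LVEDV − LVESV, LVEF = SV/LVEDV (a fraction in (0, 1] for physiologic
volumes), and the three BSA-indexed volumes using Mosteller body surface
area √(height_cm · weight_kg / 3600) in m². A record with LVESV > LVEDV is
flagged invalid rather than clipped — such inversions indicate measurement
failure and must stay visible to the exclusion stage.

Automated volume measurements can carry a platform-specific linear bias;
`apply_bias_correction` applies `corrected = a + b·raw` to LVEDV and LVESV
only (coefficients come from configuration and default to the identity,
since no universal values exist) and then re-derives every downstream trait
so the identities above always hold on the corrected scale. A zero slope is
rejected as degenerate.

Volume outliers are flagged when LVEDV or LVESV falls strictly beyond the
Tukey fences Q1 − 1.5·IQR or Q3 + 1.5·IQR. Quartiles use the
linear-interpolation quantile definition (the numpy/R type-7 default), not
Tukey hinges, so independent reimplementations agree; values exactly on a
fence are retained ("beyond" read strictly). The flag marks studies for
manual review; in the pipeline the flag itself stands in for that review.

Cohort exclusions are applied in the fixed precedence order mistracing →
genotype QC → prevalent disease. A sample carrying several labels is
charged to the earliest category, which makes the accounting table conserve
exactly: final = initial − Σ per-category removals.

The rank-based inverse-normal transform uses the Blom offset,
Φ⁻¹((r − 3/8)/(n + 1/4)), with average ranks for ties. The offset choice is
conventional rather than consequential; it is recorded in the function
signature so any other offset can be configured. INT is applied to the raw
trait, and covariates are handled inside the scan rather than by
pre-residualizing.

## Genotype quality control

Variant filters mirror imputed-biobank practice: genotyping call rate
≥ 0.95, imputation INFO ≥ 0.3, MAF ≥ 0.001, and effective minor allele
count ≥ 100, where eMAC = MAF × 2N × INFO discounts the allele count by
imputation quality. "Number of alleles" is 2N for diploid autosomes. All
inequalities are strict in the removal direction: a variant sitting exactly
on a threshold is retained. The overall mask is the conjunction of the
individual masks, so filter order is irrelevant and per-filter attrition is
reported non-exclusively.

The Hardy–Weinberg exact test conditions on the observed allele counts and
sums the probabilities of all heterozygote counts no more probable than the
observed one (plain tail sum, not mid-p), computed by the standard
two-sided recurrence. The test suite checks it against an exact-fraction
enumeration for every genotype triple with total ≤ 60. In the pipeline the
HWE screen (p ≥ 10⁻⁶) is applied to lead SNPs, matching the protocol the
package follows; a flag extends it to all variants.

## Association scan

The scan residualizes the INT trait and every dosage column once on the
covariate design (intercept; five ancestry PCs; sex; birth year; age at
MRI; one-hot scanner id) and computes per-variant slope β = ⟨g̃,ỹ⟩/⟨g̃,g̃⟩,
SE from the residual variance with n − k − 2 degrees of freedom, and a
two-sided t p-value. By Frisch–Waugh–Lovell this equals the joint OLS fit
with covariates, at a fraction of the cost. Variants monomorphic after
residualization are emitted with β = 0, p = 1 and a flag rather than
dropped, keeping row alignment with the panel.

No mixed-model (relatedness) correction is implemented. The synthetic
cohort is unrelated by construction, and cohorts supplied in real-data mode
are assumed pre-pruned for close relatives; users with substantial
relatedness need a dedicated mixed-model tool for the scan stage and can
re-enter this pipeline at the summary-statistics level.

Genomic-control λ is the median test χ² over the theoretical χ²₁ median
(≈ 0.4549). LD scores are computed in-panel as 1 + Σ r² over a sliding
window (default 500 variants, a rough 1-cM-equivalent at the simulated
density), and LD-score regression fits χ² on LD score by weighted least
squares with weights 1/max(ℓ, 1) — a deliberately simple heteroskedasticity
proxy — excluding MAF < 0.01 variants. Under a null trait the intercept is
~1; uniform χ² inflation moves the intercept, polygenic signal moves the
slope.

SNP-heritability uses Haseman–Elston regression: phenotype cross-products
y_i·y_j (standardized y, i < j) regressed on GRM entries A_ij from
standardized dosages; the slope estimates h². The bivariate version
estimates genetic correlation as the cross-trait slope over the geometric
mean of the per-trait slopes. The reported SE is the naive OLS one and
ignores dependence between pairs sharing a sample, so it is mildly
optimistic — adequate for the parameter-recovery checks here, not for
publication-grade inference. Estimates are clamped to [−0.05, 1.05] for
reporting with the raw value retained. HE regression is a method-of-moments
stand-in for REML: unbiased but noisier, which is the right trade at
desk scale.

## Locus definition and enrichment

Clumping is greedy best-first by ascending p among genome-wide significant
variants (default p < 5×10⁻⁸; 5×10⁻⁹ available as a sensitivity
threshold). Each lead absorbs significant variants within 500 kb with
r² ≥ 0.2 as members; significant variants inside the window but below the
r² threshold are attached as secondary (allelically heterogeneous) signals
of the locus and do not seed further loci, so lead SNPs of distinct loci
are always more than a window apart. Greedy-by-p is the standard clumping
convention.

Nearest-gene annotation uses interval distance (0 inside the gene body),
not TSS distance; ties go to the smaller start coordinate and are flagged.
Panel-gene overlap counts a SNP when it lies within a 500 kb radius of any
panel-gene interval, boundary inclusive, the interval inflated on both
sides — the same radius convention as the annotation window.

Null SNP sets for enrichment match each lead on four properties computed
identically for leads and candidates: MAF (±0.02 absolute), LD-buddy count
(r² ≥ 0.5 within the window; ±20%), distance to nearest gene (±20%), and
gene density (±20%), each relative band floored at 1 unit so zero-valued
properties still admit matches. Leads are excluded from every pool and a
SNP is not reused within one set. A lead whose pool is thinner than
n_sets/10 has its tolerances doubled with a warning, at most twice; an
empty pool after widening is an error. The one-tailed permutation p uses
the add-one convention (1 + #{null ≥ observed})/(1 + n_sets), which avoids
p = 0 and makes the smallest achievable p at 10,000 sets equal 1.0×10⁻⁴.

## Polygenic score and epidemiology

The score is Σ β·dosage(effect allele) over lead SNPs. When the stated
effect allele is the panel's other allele the dosage is flipped to 2 − d;
an allele matching neither panel allele is an error. Standardization is to
the scored cohort's own mean and SD (the discovery cohort's SD is not, in
general, available), so "per SD" always means per SD in the analyzed
sample.

PheWAS fits one logistic regression per binary phenotype (covariates: age
at enrollment, sex, genotyping array, five PCs), excludes phenotypes below
a 200-case floor before testing — mirroring the screened design rather
than fit-and-flag — and reports Bonferroni thresholds of 0.05/(scores ×
phenotypes); 7 scores × 96 curated phenotypes gives 7.4×10⁻⁵. Separated or
non-converged fits are reported with a flag, never dropped silently.

The incident-disease model is Cox proportional hazards with Efron tie
handling (ties are common with year-granular follow-up), adjusted for sex,
array, five PCs and a natural cubic spline of age at enrollment with
interior knots at the age quartiles (natural = linear beyond the boundary
knots; hand-rolled closed form, no formula machinery). Per-trait
significance is 0.05/7 = 0.007. Cumulative incidence is 1 − the
Kaplan–Meier estimate per score stratum (bottom 10% / middle 80% / top
10% by default; explicit labels supported), with confidence bands from the
Greenwood-type SE of the cumulative hazard mapped to the incidence scale as
1 − exp(−(H ± z·se)), which keeps the bands inside [0, 1].

The carrier-modifier analysis restricts a linear regression of each LV
trait on the score to rare-variant carriers (≥ 20 required; error if fewer
carriers than parameters), Bonferroni-corrected over the three traits. The
score is used exactly as passed, so callers provide the cohort-standardized
score and effects read as trait units per full-cohort SD.

## Replication concordance

Harmonization aligns replication betas to the discovery effect allele
through direct match, allele swap, strand complement, or both; palindromic
(A/T, C/G) SNPs are resolved by allele frequency only when both cohorts are
clearly away from 0.5 (|EAF − 0.5| > 0.08, this package's default) and
dropped otherwise; incompatible allele sets are dropped with a reason.
Harmonization is an involution: re-harmonizing an aligned table is a
no-op.

The two binomial tests use the exact two-tailed minimum-likelihood
convention (sum of all outcome probabilities ≤ the observed outcome's) —
the dominant statistical-software default. Test 1 compares the
same-direction count to 50%; test 2 compares the count of same-direction
effects with replication p < 0.05 to 5%, with the full aligned site count
as the trials denominator (the alternative reading — conditioning on the
nominally significant subset — is noted but not used).

## Synthetic cohort

The generator exists so every downstream stage is testable with known
truth. Genotypes come from a Gaussian copula: per haplotype, a latent
normal with equicorrelated blocks (default 20 variants at latent r = 0.6)
is thresholded at the allele-frequency quantile and the two haplotypes
summed. Thresholding attenuates correlation, so realized dosage r within a
block is below the latent target (roughly 0.3–0.5 at these defaults); the
r = 0 case is exact. A ±0.04 uniform jitter with clipping emulates
imputation dosage noise, and INFO is recorded as the assigned (not
realized) quality so INFO filtering is deterministic. One master seed fans
out to fixed per-component child seeds, so enabling one component never
perturbs another, and identical seeds give bit-identical output.

Phenotype defaults reproduce the cohort the pipeline targets: mean MRI age
64, majority female (52.9%), female/male mean LVEDV 120/150 mL and LVESV
41/58 mL, residual trait SDs of 21/12 mL, SNP-heritability target 0.40 on
the baseline-removed scale, genetic correlation 0.65 between the two
volumes (configurable — observational and genetic correlations are similar
in this setting but no canonical value exists), a 2 mL scanner batch SD,
and mild age slopes. Samples violating LVESV < LVEDV have their noise
redrawn until fewer than 0.1% remain. Outcomes follow a proportional-
hazards model with log-hazard log(1.58)·z by default and administrative
censoring at the empirical quantile that yields the configured censored
fraction (default 98%, ≈ 400 events per 20,000). Comorbidities are
logistic with configurable loadings, including zero-loading null
phenotypes for calibration. Rare carriers are Bernoulli(0.005) with +11.8
mL LVEDV and +7.7 mL LVESV offsets; at typical female volumes these induce
≈ −2.8 percentage points of LVEF through the derived-trait identities, so
no separate LVEF offset is applied.

What the generator does *not* emulate: realistic recombination maps or
coalescent LD decay (blocks are exchangeable and equicorrelated), allele-
frequency/effect-size coupling, relatedness and population structure
(PCs are pure noise), X-chromosome inheritance, informative censoring, or
PheCode hierarchies. Passing tests therefore demonstrate statistical
correctness of the machinery under its stated model, not robustness to
every artifact of real biobank data.

## Problem sizes and numerical conventions

The test suite and the acceptance script run at desk scale, chosen so each
statistical check has adequate power while the whole suite stays fast:
null-scan calibration at 2,000 samples × 10,000 variants; Haseman–Elston
recovery at 2,000 × 1,000; Cox recovery at 10,000–20,000 samples with ~400
events; enrichment calibration over 200 replicates of 99 null sets.
Coordinates are 1-based inclusive internally (VCF convention); BED-like
gene maps are converted on read/write and the conversion is tested in both
directions. All on-disk artifacts are plain-text TSV/VCF; reruns with the
same configuration and seed are byte-identical. p-values are floored at
the smallest positive double rather than reported as 0.
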