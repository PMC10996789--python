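# Methods

This note records the models the package implements, the conventions chosen
where the standard method leaves room, and what the synthetic-data tests do
and do not establish.

## Data model and preprocessing

The unit of analysis is a complete log2 abundance matrix, proteins ×
samples, from a single-platform CSF proteomics run (aptamer- or
PEA-style).  Values are assumed already scale-normalised by the platform
pipeline; the package deliberately starts *after* vendor normalisation and
accepts plain TSV/CSV.

**Sample outliers.**  A sample's network connectivity is
`k_i = Σ_{j≠i} cor(sample_i, sample_j)`, Pearson over protein-z-scored
data, standardised to `Z.k`.  Samples with `Z.k < −cutoff` (default 3) are
dropped and the statistic recomputed until stable.  The rule is one-sided:
only low-connectivity samples are suspect — a sample can be an outlier by
failing to correlate with the cohort, not by correlating too well.  If all
pairwise sample correlations are exactly equal (degenerate data) nothing is
flagged.  A guard refuses to drop more than 20% of samples, which signals a
data problem rather than a few bad collections.

**Covariate adjustment.**  Age and sex act on most CSF proteins and would
otherwise dominate co-expression.  Per protein, `abundance ~ 1 + (age −
mean_age) + (sex − mean_sex)` is fit by OLS in controls; a nonparametric
bootstrap (default B = 1,000, whole samples resampled with replacement, the
*same* resample for all proteins to preserve cross-protein dependence)
yields the median coefficient, which is then subtracted from every sample,
cases included.  Covariates are centred at control means so adjustment does
not shift the grand location.  Residual age correlation after adjustment is
bounded below by chance (`median |cor| ≈ 0.674/√n`) plus coefficient noise
(`∝ 1/√n_controls`); verification runs therefore use a control-rich design
(600 samples, 60% controls) so the 0.05 bound being checked is not masked
by the measurement itself.

## Network construction

* **Correlation**: biweight midcorrelation.  With `m = median(x)`,
  `u_i = (x_i − m)/(9·MAD(x))`, `w_i = (1 − u_i²)²·1{|u_i|<1}` and
  `x̃ = (x − m)·w`, `bicor(x,y) = Σx̃ỹ/(‖x̃‖‖ỹ‖)`.  Rows with MAD = 0
  cannot be biweighted and enter mean-centred (Pearson-style); the event is
  logged.  kME uses the same correlation as the network so module
  membership strength is measured on the scale the network was built on.
* **Adjacency**: signed, `A_ij = ((1 + cor_ij)/2)^β`, β = 12.  β is a fixed
  analysis parameter; scale-free-fit R² is reported as a diagnostic but
  never used to pick β.
* **TOM**: `TOM_ij = (L_ij + A_ij)/(D_ij + 1 − A_ij)` with
  `L_ij = Σ_{u≠i,j} A_iu A_uj` and `D_ij` the mean (default) or minimum of
  the two connectivities.  The vectorised implementation is tested
  elementwise against a triple-loop evaluation.
* **Clustering**: average linkage on `1 − TOM`, single block.

## Hybrid tree cut

Modules are dendrogram branches satisfying four criteria:

1. size ≥ `min_module_size` (default 30);
2. **core scatter**: the mean height of the merges forming the branch core
   (core size `min_module_size/2 + 1 + √(size − …)`) at or below
   `q05 + maxCoreScatter·(cut − q05)`, with `maxCoreScatter` from the
   deepSplit level (0.64, 0.73, 0.82, 0.91, 0.95 for levels 0–4);
3. **gap**: the branch's attach height exceeds the 90th percentile of its
   internal merge heights by `(1 − maxCoreScatter)·¾·(cut − q05)` — the
   trimmed top tolerates a few members that join late;
4. **coherence**: mean within-branch dissimilarity at least 2 − 0.25·deepSplit
   pairwise SDs below the all-pairs mean.

Criterion 4 is this package's addition and deserves explanation.  A
dendrogram of unstructured data is statistically self-similar: every
height-derived statistic (scatter, gaps) scales with the height range, so
at the permissive deepSplit-4 settings noise branches satisfy the classic
criteria and whole-noise matrices would come out as one or two giant
modules.  The coherence criterion is scale-free — it asks whether the
branch's members are actually closer to each other than random protein
pairs, in units of the pairwise-dissimilarity SD.  On planted data module
branches sit 2–6 SDs below the mean while noise branches sit within 0.7
SDs, so the criterion separates them with a wide margin; a pure-noise
matrix yields an entirely grey assignment.

The search takes the *deepest qualifying partition*: sub-branches win over
their union, so two modules merged high in the tree split apart, while a
genuine module does not over-split because its halves fail the gap
criterion (within-module merge heights are continuous).  The cut height
defaults to the maximum merge height; with average linkage on realistic
noise levels the last members of a fuzzy module join within a percent of
the tree top, and separation is already enforced by gap and coherence.

The PAM-like stage assigns each leftover object to the cluster with the
smallest mean dissimilarity, restricted (when `pam_respects_dendro`) to
clusters in the object's own branch, and only when that mean sits at least
half the coherence cut below the all-pairs mean — objects no closer to a
module than a random pair stay grey.

## Eigenproteins, kME, merging, reassignment

The eigenprotein is the first right singular vector of the z-scored member
matrix, z-scored and sign-oriented so the mean member correlation is
positive; the proportion of variance explained is reported.  Modules whose
eigenproteins are closer than `1 − cor = 0.07` merge iteratively.

kME-consistency reassignment repeats until a fixed point (cap 30
iterations): an assigned protein whose maximal kME points elsewhere (test
p below threshold) moves there; a grey protein with significant maximal
kME is rescued; an assigned protein significant nowhere turns grey.
Correlation-test p-values are Bonferroni-scaled by the number of modules
before the comparison, because each protein shops across every module
eigenprotein — with k modules and a raw per-test threshold α the chance
rescue rate of a genuinely unassigned protein would be `1 − (1−α)^k`
(≈ 34% at k = 8, α = 0.05), which would flood modules with background.
The threshold itself stays a config key (`kme_p_threshold`, default 0.05,
familywise per protein).

## Annotation and hubs

Over-representation is computed at gene-symbol level (several analytes per
gene count once) with a one-tailed Fisher/hypergeometric test against the
measured background; the over-representation Z uses the hypergeometric
mean and variance; BH-FDR runs over the full module × set table.  Hubs are
the top `⌈0.2·m⌉` members by own-module kME, ties at the cutoff included.

## Associations

Group comparisons residualise the eigenprotein on age and sex, then apply
one-way ANOVA with Tukey HSD (Tukey–Kramer on unbalanced groups, via the
studentized range distribution).  Residualisation (rather than covariate
terms in the ANOVA) was chosen because it keeps the post-hoc machinery
exact; the two coincide in balanced designs.  Severity/NfL relationships
use Spearman's ρ; BH-FDR is applied within full-sample families and
withheld (flagged) in gene-stratified runs, whose sample sizes differ too
much for a shared FDR family to be meaningful.  Differential abundance
reports the mean log2 difference and Tukey-adjusted p per contrast, with
module labels attached for volcano colouring; module DA proportions rank
non-grey modules but report grey too.

Cognitive slopes come from `global_z ~ time + baseline age + sex +
education` with random intercept and slope per subject (unstructured 2×2
covariance), REML; the per-subject slope is the fixed time effect plus the
empirical-Bayes deviation.  Single-visit subjects are excluded and counted.
On non-convergence the model falls back to per-subject OLS slopes, flagged
in the result.

## Cross-cohort validation

**Module preservation.**  Eight statistics per module, observed in the
target cohort under the reference assignment.  Density (within the module,
in the target): proportion of variance explained, mean signed kME, mean
signed correlation, mean adjacency.  Connectivity (between cohorts): the
correlations of the module's kIM, kME, correlation and adjacency
*footprints* — its pattern over a fixed random panel of ≤ 200 probe
proteins — between reference and target.  Footprints rather than
within-module-only vectors were chosen because with compact, internally
homogeneous modules the within-module connectivity pattern carries almost
no signal (all entries are similar), while the module's position in the
whole network is exactly what preservation asks about; the probe panel
also keeps the permutation loop inexpensive.  The null redraws same-size
protein sets uniformly from the whole cohort overlap — grey included,
mirroring a permutation of the full label vector.  `Z = (obs − perm
mean)/perm SD`; statistics with zero permutation SD (degenerate, e.g. in a
self-comparison) are dropped with a warning.  `Z_density` and
`Z_connectivity` are medians of their four members, `Z_summary` their
mean; < 2 no evidence, 2–10 moderate, > 10 high.

**Synthetic eigenproteins** re-express reference modules in a target
cohort: overlapping proteins (shared id, or uppercase symbol with
duplicates collapsed to the highest-variance analyte) with missing
frequency below 75% (exactly complete when the threshold is 0), median
imputation of remaining gaps, then the usual sign-oriented first PC.
Modules with fewer than two eligible proteins are omitted and flagged.
Contrasts between target groups use two-sided t tests with BH-FDR across
modules within each contrast.

**Cross-network ORA** compares two assignments at symbol level against
their platform intersection, Fisher one-tailed per module pair, BH over
all pairs, with a −log10(FDR) matrix for heatmaps.

## Synthetic data: what it emulates, what it does not

Module proteins follow `x_pj = λ_p f_{m(p),j} + α_p age_j + γ_p sex_j +
ε_pj`: standard-normal latent factors per module (shifted per
status × gene group), loadings uniform in the configured range, iid
Gaussian noise; background proteins are noise plus covariates.  Defaults
are the package's study conditions: 800 proteins × 140 samples, 8 modules
of 40–80 proteins, loadings 0.6–0.9, noise SD 1, 25% controls, carriers
split evenly over three gene groups and two stages, age uniform 30–75,
age slopes up to ±0.03 log2-units/yr, sex offsets up to ±0.2, and
disease shifts of 0.5–1 z on a few modules — magnitudes in line with
strongly affected CSF modules.  Replication cohorts reuse loadings with
fresh factors (preserved modules) or scatter loadings onto random proteins
(non-preserved, destroying the original member sets' co-expression);
platform subsetting keeps a random protein fraction and injects
missing-at-random cells per protein; cognition follows per-subject linear
trajectories whose slopes track the first module's factor.

Not emulated: aptamer cross-reactivity, batch/plate structure, heavy-tailed
or correlated noise, informative missingness, nonlinear covariate effects,
and module overlap (each protein belongs to at most one community).
Passing the recovery tests therefore shows the pipeline is correct and
well-calibrated under its own assumptions — not that real CSF data meet
those assumptions.

## Numerical conventions and problem sizes

Module labels are M1..Mk by descending size, ties broken by the smallest
member id; grey is reserved for unassigned.  Correlations are clipped to
[−1, 1]; symmetric matrices are symmetrised before use; eigenprotein signs
follow the member majority.  All generators and permutation procedures are
pure functions of their parameters and a seed.

Verification runs use desk-scale problem sizes chosen so each check's
sampling error is small relative to the property verified: the 800 × 140
discovery cohort for recovery, 70-sample replication cohorts with 500
permutations for preservation, 1,000 simulations for error calibration,
120 subjects × 4 visits for slope recovery, and 20 cohort draws for the
replication-pattern check.  The full acceptance run completes in about two
minutes on one CPU.

## Known limitations

* The hybrid cut's coherence criterion is a deliberate departure from the
  classic height-only hybrid algorithm; on data whose modules are weak
  *and* whose background is strongly dependent, its pairwise-SD scale may
  be inflated and small modules missed (raise `deep_split` leniency or
  lower `min_module_size` to compensate).
* Preservation probe panels introduce a seeded random element into the
  connectivity statistics; with fewer than ~50 overlap proteins the
  footprints get noisy and density statistics dominate.
* The LMM uses a diagonal-free unstructured 2×2 random-effects covariance
  and can fail to converge on tiny or degenerate designs; the OLS fallback
  is flagged rather than silent.
* FDR families follow the analysis design (full-sample vs stratified);
  users pooling tables across strata must re-correct themselves.
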