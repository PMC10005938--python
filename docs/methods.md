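# Methods

This note records the models implemented in `dtimega`, their
assumptions, the defaults and why they were chosen, and what the
synthetic cohort does and does not emulate.

## Synthetic cohort

The generator (`dtimega.synthetic_cohort`) produces a participant table
and a long ROI-measure table with the structure of a nine-site
adolescent case-control DTI study. One `numpy.random.Generator` seeded
from `CohortConfig.seed` drives everything; identical configs yield
byte-identical tables.

**Sample structure.** `default_study_config()` fixes 321 cases (180
early-onset schizophrenia, 95 affective psychosis, 46 other psychosis)
and 265 controls across nine sites of unequal size. Four sites have
fewer than 10 participants in one diagnostic group and therefore drop
out of the meta-analysis under the default inclusion rule; exactly one
site (81 participants) contributes FA only, so diffusivity metrics
cover 505 subjects. Subgroup labels are shuffled globally and
partitioned over sites, so each cohort draw has a different (but
deterministic) site-by-subgroup mix. Sex is assigned with exact female
counts per subgroup (CTR 57.7%, EOS 38.9%, AFP 56.8%, OTP 54.3%);
females are coded 1 throughout.

**Ages** follow a truncated normal, mean 16.3, SD 1.4, on [12, 18] —
chosen to approximate the reported medians/IQRs of an adolescent
sample where only median and IQR are available.

**ROI values.** For subject *j*, ROI *r*, metric *m*:

    y = baseline(r, m) + β1·age_c + β2·age_c² + βs·female
        + effect(subgroup, r, m)·σ_m + shift(site, m)
        + scale(site, m)·σ_m·(√ρ·u_j + √(1−ρ)·ε_jr)

with σ_m the metric's noise SD (FA 0.025; MD 0.035; RD 0.040; AD 0.050
on the 10⁻³ mm²/s scale), u_j a subject-level latent factor and ε
idiosyncratic noise. The latent-factor correlation ρ = 0.5 is a
modelling choice, not an empirical claim: the within-subject
correlation structure across tracts is not reported for real data, and
a single shared factor is the simplest mechanism that makes ROI
p-values positively dependent, as they are in practice. Diffusivity
draws that land non-positive (or FA outside (0, 1)) are resampled with
a warning and error out if they persist — with the default parameters
this never triggers.

**Site effects** are drawn once per configuration (additive shifts
N(0, (0.6σ_m)²), scale factors log-normal(0, 0.15)) and stored
explicitly on each `SiteSpec` so harmonization tests have ground truth.

**Injected effects** are standardized case shifts per (subgroup, ROI,
metric), in control-SD units. The default matrix concentrates FA
deficits and RD elevations in the EOS subgroup with a mild global AFP
component and nothing for OTP, including a "Periphery" entry so the
skeleton summaries carry a global component. Note an important
consequence for recovery checks: because subgroup composition
correlates with sex (EOS is majority male), the covariate-adjusted
binary case-control contrast is a partially sex-absorbed version of
the naive subgroup-weighted mixture — the estimated cohort-level d for
a tract is therefore systematically a little below
`Σ n_g·effect_g / n_cases`. Clean parameter-recovery claims use
uniform injections (`with_injected_effect`) or the vectorized
Monte-Carlo in `dtimega.validation`, where the injected and estimated
quantities coincide.

**Skeleton summaries.** The core is the unweighted mean of the 24
tract values (a proxy for the voxel-weighted mean over atlas labels);
the periphery is generated as its own feature; the skeleton average is
derived exactly from the voxel-count identity
`Average·112,889 = Core·31,742 + Periphery·81,147`. The 25 regional
outcomes entering every battery are the 24 tracts plus this Average.

**Clinical covariates** exist for cases only: illness duration is
log-normal with subgroup-specific medians (EOS 1.00, AFP 0.21, OTP
0.62 years), onset = age − duration (so chronology is coherent by
construction), PANSS sub-scores are shifted log-normals, CPZ is
log-normal (median 200 mg-eq), and medication flags are Bernoulli with
subgroup-specific rates. Two sites carry no PANSS (mirroring cohorts
that used other instruments) and CPZ has 12% sporadic missingness.

**What the generator does not emulate:** voxel-level data and the
image-processing chain, non-Gaussian measurement error, site-specific
age ranges or inclusion criteria, longitudinal structure, and any
genuine clinical-DTI coupling (clinical variables are independent of
ROI values unless a test injects a link). Passing tests therefore
establish the correctness and calibration of the statistical pipeline
under its own assumptions, not the biological findings themselves.

## ComBat harmonization

Parametric empirical-Bayes ComBat, fitted per metric on the sites that
provide that metric. Standardization uses least squares with all site
indicators plus covariates; the grand intercept is the size-weighted
mean of site intercepts, which enforces the sum-to-zero identifiability
constraint on the raw site locations. Hyperparameters are
method-of-moments per site across features; the conditional posterior
means for location and scale are iterated to a relative tolerance of
1e-4 (cap 1000 iterations; the default cohort converges in ~4). These
numerical choices match common reference implementations of the
method. The biological design preserves age, sex and the 4-level
diagnostic subgroup (one-hot, controls as reference): "diagnostic
group" is ambiguous between binary and subgroup coding, and the
subgroup coding preserves strictly more structure. Only those three
terms enter the harmonization design; the quadratic and interaction
terms appear downstream in the regression battery only.

`fit_combat(..., eb=False)` switches off the shrinkage and adjusts
with the raw per-site location/scale estimates. This is the exact
removal oracle used in tests; the EB adjustment deliberately leaves a
small shrinkage residue (posterior means lie between the raw estimate
and the site prior mean), which is the price of stability for small
sites. Applying a fit requires the subjects to have been present at
fit time: their standardization means are stored in the fit, which
keeps `apply` free of covariate look-ups and makes unseen sites or
subjects a hard error rather than a silent extrapolation.

The harmonization report quantifies both promises numerically: η², the
between-site share of variance in covariate-adjusted residuals, before
and after (it must not increase); and the absolute drift of each
biological coefficient against its pre-fit SE.

## Regression battery and effect sizes

All models are OLS per (ROI, metric). Continuous covariates are
mean-centered within the analysis sample and age² is the square of
centered age; centering leaves the group contrast invariant (verified
to 1e-10) but keeps the polynomial terms well-conditioned. The main
covariate set is age, age², sex, age×sex, age²×sex. Sex-stratified
models use age and age² only. The age-at-onset clinical model adjusts
for sex only, because onset and age at scan are strongly collinear in
an adolescent window; all other clinical models use the full set.

Cohen's d = t·(n₁+n₂)/(√(n₁n₂)·√df) with residual df, and
SE(d) = √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))). This is the standard
consortium convention for converting a covariate-adjusted t to a
standardized mean difference; it reduces to the classical two-sample d
as df → n₁+n₂. The group regressor is 1 for controls, so positive d
means higher values in controls and FA deficits in cases print as
positive d. Bonferroni is applied per metric across the 25 regional
outcomes (0.05/25 = 0.002), not across metrics — matching how such
studies state their threshold. Medication contrasts are oriented
non-user-minus-user; continuous clinical slopes report coefficient, t
and p with d left as NaN (a standardized mean difference is not
defined for them).

Degenerate designs fail loudly: rank-deficient matrices name the
collinear columns, strata must be non-empty, contrasts need at least 3
subjects per group, and per-cell failures in a battery are warned
about while the remaining cells continue.

ROI inputs are assumed hemisphere-combined (the generator produces
combined tracts directly); a lateralized analysis would simply use a
vocabulary with side-suffixed labels and is out of scope here.

## Meta-analysis

Sites enter the complementary meta-analysis only with ≥10 cases and
≥10 controls (boundary inclusive). Per-site d uses the same
full-covariate model as the mega-analysis. Pooling is inverse-variance
with the DerSimonian–Laird moment estimator for τ² (the conventional
default when the estimator is otherwise unspecified; an iterative REML
option is exposed), I² = max(0, (Q−(k−1))/Q), and normal-quantile 95%
CIs without the Knapp–Hartung adjustment. With one site the pooled
estimate is the site estimate and τ² = 0. Leave-one-out re-pools k−1
sites k times and flags a site as influential when dropping it flips
the pooled estimate's significance at the working α.

## Cross-study comparison

The z-difference test is computed exactly as printed in the field:
Diff = M_B − M_A, SE_Diff = √(V_MA + V_MB), Z = Diff/SE_Diff,
p = 2[1 − Φ(|Z|)]. The survival function implements 1 − Φ, and p is
floored at the smallest positive float so the invariant p ∈ (0, 1]
survives extreme Z. Comparator values (e.g., an adult-disorder
reference) are user-supplied as a CSV of (roi, d, se); nothing is
bundled. Tract matching is by canonical abbreviation, order-
insensitive, with an optional subset, and the number of matched tracts
is always reported alongside r because published correlations of this
kind depend on whether the skeleton average is included.

## Demographics

Shapiro–Wilk at α = 0.05 decides summary style and test choice for
continuous variables; the implemented tables use Kruskal–Wallis
(tie-corrected, χ² approximation) for continuous and χ² for
categorical variables. The Yates continuity correction is applied to
2×2 tables only — this choice is forced by the published p-values,
which are reproduced with the correction and not without it. Pairwise
subgroup contrasts report raw p-values without multiplicity
adjustment, as such tables conventionally do.

## Monte-Carlo validation

`dtimega.validation` re-runs the exact design construction and d
conversion of the battery, but solves all replicates of a
noise-redrawn outcome in one least-squares call. Covariates are drawn
once per experiment and held fixed, so the reported mean and MC
standard error describe the estimator over residual noise at a
representative design. At n = 321/265 with 500 replicates this costs
well under a second and gives MCSE(d̄) ≈ 0.004; the known small-sample
inflation of the t→d conversion (factor √(n/df)(1+3/(4df)) ≈ 1.007)
is visible but within two MCSE of the injected values.

## Problem sizes and determinism

The shipped defaults are the study conditions themselves: 586 subjects,
9 sites, 25 outcomes × 4 metrics, 500 Monte-Carlo replicates, 5
replicate cohorts in the acceptance script. The full test suite runs
in well under a minute on one CPU. All randomness flows from explicit
seeds; the CLI fans a single global seed into per-stage substreams via
hashing, so skipping one stage does not shift another stage's draws.

## Known limitations

- EB ComBat does not remove site effects exactly (shrinkage residue of
  a few percent of the injected offset); `eb=False` exists for exact
  removal but forfeits the small-site stability the EB pooling buys.
- Harmonizing the Average summary as its own feature breaks the
  voxel-count identity by a (tiny) amount after adjustment; the
  identity is exact in generated data.
- Mixed-effects site modelling is intentionally absent: the design is
  harmonize-then-pool, with site heterogeneity surfaced by the
  meta-analysis instead.
- The robust small-sample ComBat variant alluded to in the literature
  is not specified there; the standard parametric EB form is
  implemented and this choice is documented rather than guessed at.
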