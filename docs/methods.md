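# Methods

## Scope and data model

`pubsem` analyses cross-sectional multi-method pubertal data from early
adolescent girls: seven ordinal self-report items (PDS1 growth, PDS2 body
hair, PDS3 skin, PDS4 breasts, all 1–4; PDS6 menarche 0/1; LD1 breast and
LD2 pubic-hair line drawings, 1–5), up to four saliva samples per hormone
(DHEA, testosterone, estradiol) with a collection-day index, one hair
concentration per hormone, age in years, and per-participant cortical
thickness for the 68 Desikan-Killiany regions.  Social-comparison PDS item
5 and hair-survey covariates are excluded by design; subcortical volumes,
nonlinear trajectories and longitudinal modelling are out of scope.

## Preprocessing

Hormones are natural-log transformed (raw concentrations are positively
skewed and kurtotic) and then winsorized **on the log scale**: values
beyond mean ± 3 sample SD are replaced by the cut value plus (above) or
minus (below) 0.01·j for the j-th ranked outlier, preserving the complete
rank order.  The order — log first, winsorize second — follows the
described cleaning sequence; the increment unit is therefore log-units by
default and both the cut (`k_sd`) and increment are configurable.
The saliva window keeps the last four dated samples on or before the
second session, padding shorter series with missing placeholders.

Composites map each item to a common 1–5 scale (4-point PDS items
linearly, menarche 0→1/1→5) and average: adrenarche over {PDS2, PDS3,
LD2}, gonadarche over {PDS1, PDS4, PDS6, LD1}, overall puberty as the mean
of the two.  PDS1 (height growth) sits on the gonadal composite by
convention but is the item most debatable, so the mapping is a parameter.
The PDS stage (1–5, Tanner-approximating) uses a category table on the sum
of body hair and breast growth gated by menarche; the published scheme is
cited but not printed in the source literature, so the shipped table is an
explicit reconstruction and overrideable.  MRI QC excludes opt-outs,
worst-rated (3) images, and rating-2 images failed on motion re-review;
with the study-scale counts (174 enrolled, 10 opt-outs, 25 rated 3, 27
motion exclusions) this retains 112 participants.

## SEM engine

The engine uses the LISREL-style parameterization
`Σ = Λ(I−B)⁻¹Ψ(I−B)⁻ᵀΛᵀ + Θ` with an optional saturated mean structure
(free intercepts).  Observed covariates (age) and outcome variables
(regional thickness) enter as *phantom* latents — unit fixed loading, zero
residual, free variance — so they can covary with or predict latent
factors.

**Identification.**  The default "unit" rule fixes every non-phantom
latent's *residual* variance to 1 (marker-indicator identification is
available).  Fixing residual rather than total variances is what makes
both second-order loadings of hierarchical models separately identifiable.
Local identification is verified at build time by the column rank of the
Jacobian of vech(Σ) at jittered start values; under-identified variants
raise with a diagnostic rather than fitting to a ridge.  Two findings from
this check shaped the model catalogue: (i) a top factor with only two
latent indicators (a hormone factor and a self-report factor) is not
identified, so the one-factor multi-method scheme loads PUB directly on
{saliva-DHEA, saliva-T, saliva-E2, self-report-PUB}; (ii) a full
within-questionnaire correlated-uniqueness block over the five PDS items
has a null direction trading a uniform method covariance against the
loadings, so the CU variant frees only the same-questionnaire pairs that
span the adrenal/gonadal item sets (six PDS pairs plus LD1–LD2).

**Estimation.**  `F_ML` is minimized by L-BFGS-B with analytic gradients
derived from `dF = tr(M dΣ)`, where M chains through Λ, B, Ψ, Θ; a
non-positive-definite Σ (tested by Cholesky, not by determinant sign)
returns a large finite barrier so the line search backtracks.  Start
values: loadings 0.7·SD(indicator), residual variances half the observed
variance, latent covariances 0.3 (0 when a phantom is involved), directed
paths 0.3.  Convergence requires the optimizer's own criteria or gradient
max-norm < 1e-4; non-convergence is reported, never silently accepted.
Negative variance estimates (Heywood cases) are flagged with a warning,
not truncated.  χ² = n·F_ML with n the analyzed cases (the n-vs-(n−1)
convention is stated here because MFI and ECVI inherit it).

**FIML** groups rows by missingness pattern and sums the Gaussian
log-density of each row's observed subvector; its χ² is
2(ℓ_saturated − ℓ_model), with the saturated MLE obtained by an EM
algorithm for the unrestricted multivariate normal.  The independence
baseline under FIML has a closed form (per-variable observed-case
mean/variance).  On complete data FIML reproduces the ML log-likelihood to
1e-8 (tested).

**PML** treats each ordinal item as a standard-normal latent response cut
at free, strictly increasing thresholds (internally reparameterized as
first threshold plus log-gaps), with total latent-response variance fixed
to 1 (delta parameterization).  The objective sums over variable pairs:
rectangle probabilities for ordinal–ordinal pairs, bivariate normal
log-densities for continuous–continuous, and density × conditional
interval probability for mixed pairs; pairs with a missing member drop
casewise.  Bivariate normal CDFs use Genz's Gauss–Legendre algorithm
(20-point, with the |ρ| > 0.925 singular expansion), vectorized, accurate
to ~1e-15 against `scipy.stats.multivariate_normal` (tested); rectangle
probabilities are floored at 1e-300 before logging.  PML reports the
pairwise log-likelihood, estimates and standardized solution; χ²-based
indices are not defined for this estimator and are left unset.

**Robust statistics.**  Sandwich standard errors use numerically
differentiated casewise scores (B) and the observed information from the
analytic gradient (A).  The mean-scaled χ² divides by
c = tr(UΓ)/df with Γ the empirical fourth-moment covariance of vech(S)
and U the normal-theory residual weight; under multivariate normal data
c → 1 (property-tested).

**Fit indices.**  CFI = 1 − max(χ²−df,0)/max(χ²_B−df_B, χ²−df, 0) against
an independence baseline with free variances (and means when modelled);
MFI = exp(−(χ²−df)/2n); ECVI = (χ²+2q)/n; SRMR is the RMS of
(s_ij − σ̂_ij)/√(s_ii s_jj) over unique elements including the diagonal
(normalizing both matrices by the sample SDs is what makes the diagonal
informative).

**Standardization.**  The standardized solution rescales all latents and
observables to unit variance; each latent's sign is made canonical (sum of
its standardized loadings non-negative, resolved bottom-up through the
hierarchy) so factor orientation — and hence the sign of brain
correlations — is deterministic across fits.

## Model catalogue

First-order factors: sDHEA, sT, sE2 over their four saliva samples (plus
the hair indicator when included; the hair-DHEA loading can be fixed to
0), and self-report srADR {PDS2, PDS3, LD2} / srGON {PDS1, PDS4, PDS6,
LD1}, or a single srPUB over all seven items.  Second order: ADR over
{sDHEA, sT, srADR} and GON over {sE2, srGON}, freely correlated; the
one-factor scheme is PUB over {sDHEA, sT, sE2, srPUB}.  Saliva-only
hormone models collapse the gonadal side to the E2 factor itself (a single
first-order indicator cannot support its own second-order factor), which
is why the one- and two-factor hormone-only models are equivalent.
Same-day residual covariances link the three hormones' sample k (k =
1..4; 12 parameters).  Age enters either correlated with the top-level
factors or as their exogenous predictor.  PDS6 is a 2-category ordinal
under PML and 0/1 numeric under ML/FIML.

The estimator ladder assigns PML to ordinal-only (self-report) models,
ML/MLR to continuous-only hormone models, and FIML (items as numeric) to
the full multi-method models; `run_model_series` applies it and tabulates
χ², df, CFI, MFI, ECVI, SRMR with nested Δχ² tests.  Stratified fits
(PDS stage ≥ 3 vs < 3) refit the same spec per stratum.

## Brain maps

Each region model adds one thickness column to the chosen measurement
model (multi-method, self-report-only, or saliva-hormone) as a phantom
latent covarying with the top-level factor(s); the reported r is the
standardized latent–thickness correlation, fitted by ML on the
listwise-complete covariance.  "Controlling for age" regresses the
thickness phantom on age while the factors correlate freely with age; the
adjusted r is the correlation between the factor and the age-residualized
thickness, which reproduces the stage-vs-timing contract: when thickness
depends on the factors only through age, the adjusted r attenuates to ~0
while the unadjusted one does not (tested).  Standard errors on r use the
Fisher large-sample approximation (1−r²)/√(n−3) — an explicit
approximation, adequate for effect-size banding.  Effect bands label |r|
as weak < 0.1 ≤ small < 0.3 ≤ medium < 0.5 ≤ large, boundary values going
up; no multiple-comparison correction is applied, by design.  A failed
region fit yields a flagged row, never a crashed sweep.

## Synthetic cohort generator

The generator draws the truth exactly as a path model: top-level ADR, GON
and age-z from their 3×3 correlation (defaults 0.95, 0.58, 0.70; verified
positive semi-definite, rejection names the offending eigenvalue),
first-order factors as γ·parent + residual (defaults: sDHEA 0.85, sT 0.80,
srADR 0.90 on ADR; sE2 0.80, srGON 0.90 on GON), and observables as
λ·factor + residual with same-day saliva residual blocks (default residual
correlation 0.30).  Default loadings (saliva DHEA 0.90, T/E2 0.80, items
0.55–0.85 with PDS1 lowest, hair ≤ 0.3) mirror the reported ranges.
Hormone observables exponentiate the log-scale draws, with (m, s) solved
from the raw-scale Table-1 marginals via the log-normal moment map, so raw
values are positively skewed; outliers add `outlier_magnitude` (default 4)
latent SDs to randomly selected cells at rate 0.01.  Ordinal items
threshold their latent responses at configurable cut-points; the defaults
are symmetric spreads (PDS −1/0/+1; LD −1.5/−0.5/+0.5/+1.5; menarche
0.25), chosen to populate all categories — the source reports no
item-level frequencies, so these are deliberately neutral.  Thickness is
ρ_r·PUBc + β_r·age-z + residual in z-units, scaled to mm marginals
(default 2.6 ± 0.15 mm), where PUBc is the normalized ADR+GON composite;
ρ_r defaults to −0.3 in seven posterior regions per hemisphere
(cuneus, lateral occipital, lingual, pericalcarine, inferior/superior
parietal, precuneus) and 0 elsewhere, and β_r (default 0) supports
age-mediation scenarios.  Age is N(11.55, 0.81²) clipped to [10, 13]; the
clipping touches ~6% of draws and attenuates age correlations by well
under the testing tolerance.

`implied_population_covariance` assembles the same structure by path
tracing into the covariance over all continuous/latent-response variables
(hormones on the log scale, items as latent responses) and is the oracle
for the generator tests: the sample correlation matrix of a 100 000-record
draw matches it within 0.02 everywhere.  One global seed expands into
fixed named substreams (factors, saliva, hair, items, thickness, outliers,
missingness), so enabling or resizing one block never perturbs another.
Missingness is injected per block, missing-completely-at-random
(defaults: self-report 2%, saliva 5%, hair 10%).

What the generator does **not** emulate: circadian/menstrual hormone
dynamics beyond day-level residual covariance, MAR/MNAR missingness,
non-normal latent distributions, measurement non-invariance across
maturation, and spatial correlation among cortical regions beyond their
shared pubertal/age dependence.  Passing recovery tests therefore show
the estimators are correct under the assumed data-generating process, not
that the substantive findings generalize to real cohorts.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script use cohorts of n = 2000
(complete data, no outliers) for parameter recovery — large enough that
sampling error is well inside the stated tolerances (loadings ±0.05,
ADR–GON ±0.03, age correlations ±0.05, planted thickness effects ±0.05 on
the posterior-region mean) — and n = 174 with full missingness/outlier
defaults for pipeline-level checks; the Monte-Carlo covariance oracle uses
n = 100 000.  Optimizer tolerances: L-BFGS-B gtol 1e-6, ftol 1e-12; EM
stops at relative log-likelihood change 1e-8; identification rank uses SVD
tolerance 1e-8.  Ties in winsorization are broken by original order
(stable sort); effect-band boundaries go to the upper band.

## Known limitations

* PML standard errors and scaled test statistics (Godambe information) are
  not implemented; PML reports estimates and the pairwise log-likelihood.
* The robust χ² implements mean scaling only (no mean-and-variance
  adjustment).
* The brain sweep refits the measurement model jointly per region (a
  fixed-measurement mode is not yet provided); with 68 regions this costs
  about a minute at n = 2000.
* FIML treats ordinal items as numeric, as in the estimator ladder it
  implements; a full ordinal-FIML hybrid is out of scope.
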