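# Methods

This note documents the models implemented in `onca`, the assumptions they
make, the defaults and why, what the synthetic-data generator does and does
not emulate, and the numerical choices that a maintainer would otherwise
have to reverse-engineer from the code.

## Maximum-entropy suitability model

The presence-only model is the Gibbs distribution over background cells,

    raw(x) = exp(Σⱼ λⱼ fⱼ(x)) / Z(λ),

fitted by maximizing the penalized presence log-likelihood
(1/m) Σᵢ λ·f(xᵢ) − log Z(λ) − Σⱼ βⱼ|λⱼ|. The L1 penalty makes the fit
equivalent to relaxed moment matching: at the optimum,
|E_raw[fⱼ] − presence mean fⱼ| ≤ βⱼ for every retained feature (this is
asserted as a test invariant).

*Features.* Each continuous layer is min–max rescaled to [0,1] over valid
cells and contributes a linear and a quadratic feature; each categorical
layer contributes one indicator per observed class. Constant layers are
dropped with a warning. Hinge/product/threshold features are deliberately
out of scope.

*Regularization.* βⱼ = reg · max(sⱼ, 0.05)/√m with sⱼ the presence-sample
standard deviation of feature j and m the presence count; reg defaults
to 1.0. The 0.05 floor (on [0,1]-scaled features) keeps βⱼ > 0 when a
feature is degenerate in the presence sample, which would otherwise let
|λⱼ| diverge; reg = 0 disables the penalty exactly, which the fitting tests
use to compare against brute-force likelihood search.

*Optimizer.* Deterministic bound-constrained L-BFGS on the split
λ = u − v, u,v ≥ 0; the convergence threshold (default 1.0e−5) bounds both
the projected gradient and the recorded final max weight update, and the
iteration cap defaults to 5000. Non-convergence sets a flag rather than
raising.

*Logistic output.* Suitability is e^H·raw/(1 + e^H·raw) with H the entropy
of the fitted raw distribution — the entropy-based transform with implicit
prevalence 0.5. It is strictly increasing in raw, so cell rankings are
identical on both scales.

*Background and bias.* Training background defaults to the cells carrying
observer effort (the sampling mask), which operationalizes bias-restricted
learning; projection covers the full valid mask. All valid cells are used
when ≤ 20,000, otherwise a seeded uniform subsample of 10,000.

*Evaluation.* A seeded uniform 75/25 split of presence cells; AUC is the
normalized Mann–Whitney statistic (ties 0.5) of test presences against
background. The null model fits 99 replicates to presences drawn uniformly
without replacement from the study mask with the identical
split-fit-score protocol; the observed model is significant when its AUC
exceeds the 95th-ranked null AUC, and the reported p-value uses the +1
permutation convention, p = (1 + #{null ≥ obs})/100. Because observed and
null replicates are exchangeable under the null, the type-I error is 5% by
construction; the test suite measures it at 200 outer replicates and
requires [0.02, 0.09].

*Bootstrap.* Optional presence-resampling replicates (pipeline default 10);
reported suitability is the replicate mean, each replicate scored with its
own normalizer and entropy.

## Closed-population capture–recapture

*Encounter histories.* Detection nights are grouped into consecutive
occasions of configurable length (pipeline default: 10 occasions); the last
occasion may be short. Closure is assumed — no births, deaths, or
migration over the ~3-month survey.

*M0.* Joint MLE over (N, p) with p profiled as p̂ = total/(t·N); N is
optimized continuously (integer relaxation) with an adaptively expanded
upper bound, and the SE comes from the observed information (numerical
second derivative of the profile likelihood, with the standard closed-form
fallback on flat likelihoods). Two boundary cases are explicit: everyone
captured every occasion → N̂ = M_{t+1}, p̂ = 1; zero recaptures → the
likelihood increases in N without bound, and N̂ = ∞ is returned with a
boundary flag rather than a spurious finite number.

*Mh.* Burnham–Overton jackknife orders 1–5 from capture frequencies,
N̂_Jk = Σᵢ a_ik fᵢ, with the published coefficient table (verified in the
tests against an independent leave-d-occasions-out generalized-jackknife
enumeration), Var(N̂_Jk) = Σ a_ik² fᵢ − N̂_Jk, and order selection by the
sequential test on successive differences at α = 0.05 (first
non-significant increment wins; all significant → highest order;
interpolation between orders is not implemented). Raw jackknife
combinations can fall below M_{t+1} on pathological frequency vectors, so
reported estimates are clamped at the observed count.

*MMDM and area.* An individual qualifies for MMDM when detected at ≥ 2
distinct stations (station-based criterion); its contribution is the
maximum pairwise distance among its stations. The effective area is the
station convex hull dilated by the buffer via the exact Steiner formula
A + P·b + πb², avoiding discretized circles entirely. Distances are planar
Euclidean on projected km; the CLI refuses lon/lat input.

*Calibration.* On simulated 16-station surveys (N = 60, σ = 2 km,
g0 = 0.3, heterogeneity SD 0.75), the MMDM-buffered density is calibrated:
median within 25% of the true density over the activity-centre region. The
½MMDM buffer overestimates by roughly 50% under the same conditions — the
known bias of the narrow buffer, and the reason the wider buffer is the
recommended design — so the calibration test asserts the MMDM band and the
½MMDM overestimation *direction*, not a ½MMDM band.

*Reporting.* Densities are rounded half-away-from-zero to one decimal;
intervals are 100·(N̂ ± SE)/A. One published-table cell (N̂ = 10 over
194 km²) computes to 5.155 → 5.2 under this rule while the source table
prints 5.1; the discrepancy is treated as a source rounding anomaly and the
implementation does not force agreement.

## Line transects

KI = contacts/km, or Σ group sizes/km for gregarious species; biomass
index = KI × mean adult mass, additive over species. No detection function
is fitted — these are raw encounter-rate indices, not distance-sampling
densities.

Effort sufficiency truncates each survey to its first d km and correlates
the truncated KI with the full-effort KI across surveys. For homogeneous
Poisson encounters the correlation is exactly √(d/L) (Poisson thinning),
independent of the encounter rate; the suite verifies the mean empirical
curve against this closed form. The field-relevant ordering — rarer
species need longer transects — only appears when true rates vary between
sites: with site rates λᵢ of mean m and variance V,
r(d) = √((V + m/L)/(V + m/d)), which at fixed coefficient of variation
gives larger sufficient d for smaller m. The ordering test therefore uses
log-normally varying site rates (SD 0.5 on the log scale, matching the
generator's footprint-driven rate variation) and checks the medians against
this closed form; under strictly homogeneous rates the ordering provably
vanishes, so a homogeneous ordering test would be meaningless.

## Habitat structure

Roughness is the 3×3 focal standard deviation of the DEM with the sample
(n−1) denominator (the population/sample choice is undocumented upstream;
sample SD was chosen and is pinned by tests). The input is centred before
the moment subtraction, which keeps the result numerically
translation-invariant (asserted to 1e−5 in the worst adversarial case —
the square root of a cancelled variance bounds the attainable agreement);
border cells with incomplete windows are masked rather than padded.

Waveform extent estimates the noise floor from the first and last 10% of
samples and takes signal begin/end as the first/last run of two consecutive
samples above mean + k·SD (k = 3.0 default). The two-sample run condition
rejects isolated noise spikes that a single-sample threshold crossing
admits. The synthetic waveform generator produces a boxcar-plus-two-peaks
return spanning exactly canopy height + slope spread, so the extent
estimator can be checked against generator truth to within two sampling
steps. Canopy-height rasters, when simulated, carry 3.6 m Gaussian noise —
the nominal precision of spaceborne-LiDAR height retrieval — but the
height-retrieval regression itself is out of scope, as is parsing any
binary LiDAR product.

## Associations

Pairwise correlations default to product–moment with two-sided uncorrected
p-values from the t reference distribution; a rank option and a Holm
adjustment exist behind flags but are off by default, matching the
uncorrected-reporting convention of the field workflow this mirrors. The
"ensemble regression" association is a random-forest regression scored as
the Pearson correlation between out-of-bag predictions and the observed
response — the only construction of a forest "r" that does not reward
overfitting (resubstitution correlations approach 1 regardless of signal).
It is bit-reproducible under a fixed seed and tree count. No spatial
autocorrelation correction is applied to any p-value; with ~30 sites on one
landscape this overstates independence and is a known limitation.

The priority overlay is the conjunction HFI < 15 ∧ roughness > 12 (both
cuts configurable), reported with the masked-area fraction over valid
cells.

## Synthetic landscapes: what they emulate, and what they do not

Continuous layers are Gaussian-smoothed white noise, affinely mapped to
realistic ranges (rainfall ~1500–4500 mm/yr, altitude 0–800 m, AGB
~120–550 Mg/ha); categorical layers are quantile-binned smooth fields
(5 vegetation, 4 biogeographic, 5 geology classes); the human footprint
decays exponentially (5-km scale) from random access lines, and the
sampling mask covers the 40% of cells nearest those lines — observer effort
concentrates near access, which is what makes the bias-restricted
background meaningful. The true suitability surface is a logistic
linear+quadratic response to rescaled rainfall and altitude with a negative
footprint term.

Sightings are distinct cells drawn with probability proportional to true
suitability (one record per 0.5-km cell); the default 302 records mirror a
realistic opportunistic collation. Camera-trap truth places activity
centres uniformly on the station hull buffered by 2σ and detects with
p = g0·exp(−d²/2σ²) shifted on the logit scale by an individual N(0, 0.75²)
effect — the minimal mechanism that makes Mh the right estimator. Transect
contacts are Poisson with log-rate a + b·HFI per species (b < 0, steeper
for the two large birds than for the five mammals) at 30 sites × 97 km,
with 1 + Poisson group sizes for gregarious species.

Not emulated: animal movement trajectories (detections are exchangeable
given the activity centre), open-population dynamics, spatial correlation
of transect counts beyond their HFI dependence, imperfect individual
identification, and real-landscape covariate structure (collinearity among
layers is weaker than in real terrain). Passing recovery tests therefore
demonstrates estimator correctness under the stated generating model, not
robustness to field pathologies such as trap shyness or misidentification.

## Problem sizes

Defaults were chosen so a full test run and the acceptance script each
complete in minutes on a single core while keeping Monte-Carlo error well
inside the asserted bands: 64×64 landscapes for SDM work, 200 outer ×
99-null replicates for type-I calibration, 500 replicates for estimator
recovery, 100 replicates for the end-to-end sign-recovery experiment
(48×48 landscapes, two camera-trap sites with N = 32 vs 8 — abundance
proportional to suitability 0.8 vs 0.2, a deliberately clear contrast so
the ordering probe measures estimator behaviour, not generator ambiguity).
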