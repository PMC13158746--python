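# Methods

This note records the statistical procedures implemented in `rfeq`, the
assumptions behind them, the defaults and why, and what the synthetic-data
tests do and do not establish about real survey data.

## Index construction

The three indices are binary food-group counts, by design: presence or
absence of a group at an outlet, never quantities, prices or facings.
HRFES sums one point per healthy group present (max 9). URFES sums one
point per unhealthy group, two for processed meats (max 9; the double
weight reflects the strength of the processed-meat/NCD association).
RFEQI = HRFES − URFES + 9 maps the difference onto 0–18 so that the index
is never negative; 9 is the balance point where healthy and unhealthy
variety cancel. All scores are integers; a missing presence flag is an
error rather than an implicit zero, because silent zeros would bias every
score downward in exactly the records with data problems.

## Neighborhood buffers

An outlet's retail neighborhood at radius r is the set of outlets within r
meters (closed ball, focal outlet included — the natural convention, since
the focal outlet is at distance 0). Presence is pooled by logical union
and re-scored, so buffer HRFES/URFES are non-decreasing in r and dominate
the retailer-level score; RFEQI at the buffer level need not be monotone
because both components grow. Defaults: 50, 100 and 200 m, pedestrian
scales for dense retail environments. Buffers are not clipped at the
study-window boundary: the survey design enumerates all outlets inside the
ward, so an edge outlet pools exactly the outlets that exist. Neighbor
search uses exact pairwise distances up to 10^4 points and a KD-tree above
that, with identical results by contract.

## Coordinates

Input coordinates are WGS84 lon/lat. All metric computation happens in a
local tangent plane: geodetic → ECEF on the WGS84 ellipsoid → East/North
coordinates about the centroid of the point set. At ward scale (≤ ~30 km)
the planar distances agree with ellipsoidal geodesics to well within 0.1%;
point sets spanning more than 3° of longitude are rejected with advice to
project upstream. The transformation is deterministic given the record
set.

## Contrasts

Index scores are compared between rural and urban strata with Welch
two-sample t tests (no equal-variance assumption; the survey strata differ
in both spread and size) and Kruskal–Wallis rank tests, reporting group
means ± SD. Categorical characteristics are compared with Fisher's exact
test; 2×2 tables exactly, larger tables by Monte Carlo: 10^5 tables drawn
with fixed margins (Patefield sampling), p = (#{tables at least as
unlikely as observed} + 1)/(reps + 1), with the simulation standard error
and seed reported. Full r×c enumeration is combinatorially explosive at
survey sizes, and the Monte Carlo p is within simulation error of the
enumerated value (verified against full enumeration on small tables).

## Count regression and IRRs

Associations between an index and retailer characteristics are estimated
with a single-level log-link count GLM ("fixed effects" in the sense of
categorical covariates, no random effects):

    log E[Y_i] = β0 + Σ_j β1j TYPE_ij + Σ_g β2g GENDER_ig
               + Σ_l β3l SPACE_il + β4 LOC_i

Reference levels: mobile retailers, female, 100% food space, rural.
Exponentiated coefficients are incidence rate ratios; intervals are Wald
95% CIs on the log scale, exponentiated — the standard presentation for
IRRs. The default family is Poisson: it is the minimal model producing
IRRs, the indices are small bounded counts, and for a single binary factor
the Poisson MLE equals the sample rate ratio exactly (a property the tests
use as an analytic oracle). Because a bounded sum of Bernoullis is
under-dispersed relative to Poisson, Poisson-based CIs tend to be mildly
conservative here. A negative-binomial option (moment-estimated
dispersion) is provided for genuinely overdispersed outcomes. Model fit is
summarized by McFadden pseudo-R² (1 − ll/ll_null) and AIC.

A covariate level whose outcomes are all zero (e.g. a typology stocking no
unhealthy group) separates the likelihood; its log-rate diverges. Such
rows are detected up front and reported with IRR 0 and a flagged,
unbounded interval instead of a spurious finite CI.

## Subsampling robustness

Index stability is probed by drawing floor(0.7·n) records without
replacement (a subset, not a bootstrap — the procedure asks how the mean
behaves on smaller surveys, not about resampling variance), recomputing
the mean, and repeating. The replicate mean is unbiased for the
full-sample mean with finite-population-corrected standard error
√((1−f)/(f·n))·s, and its distribution is asymptotically normal; skewness
and excess kurtosis near zero are the practical normality criterion, since
at 10^4–10^5 replicates any formal test rejects trivially. Desk default is
10^4 replicates (the estimand is identical at 10^5, only the Monte Carlo
error changes); stratified subsampling is available as an option, pooled
is the default.

## Spatial weights, Moran's I, LISA

Because autocorrelation inference needs a neighbor graph and survey wards
are irregular, the default weights are k-nearest (k = 8), row-standardized
— k-NN cannot produce isolates, and the scheme is recorded alongside every
result so outputs are labeled with their weights. Distance-band weights
are available; an isolated unit under a band is an error suggesting a
wider band. Ties in k-NN are broken by index order for determinism.

Global Moran's I = (n/S0)·Σ w_ij z_i z_j / Σ z_i², with null expectation
−1/(n−1). Inference is by conditional permutation (value shuffles over
locations), one-sided toward the observed sign, p = (exceedances +
1)/(permutations + 1); 999 permutations by default. z-scoring makes the
statistic affine-invariant in the attribute.

Local Moran I_i = z_i·lag_i/m2 decomposes I (Σ I_i = n·I for
row-standardized weights — a numerical identity the tests enforce at
1e-10 relative). Quadrants come from the signs of (z_i, lag_i): HH, HL,
LH, LL; labels are assigned only where the per-unit conditional
permutation p ≤ α, else "ns". Default α = 0.05 with no multiple-testing
correction — pointwise significance is what hot/cold-spot maps
conventionally display — with an optional Benjamini–Hochberg flag.

## Ripley's K

K̂(r) = (|W|/n²)·Σ_{i≠j} e_ij·1[d_ij ≤ r] with the isotropic edge
correction: e_ij is the reciprocal of the fraction of the circle of radius
d_ij centered at i lying inside the window. The fraction is computed by
arc sampling at 1° resolution (360 points), which handles non-convex
windows and is within 0.5% of the exact fraction on convex ones; circles
entirely inside the window (d_ij ≤ distance to boundary) shortcut to 1.
With the 1/n² normalization E[K̂] carries a (n−1)/n factor relative to
πr², about 1–2% at the point counts used in the tests — well inside the
calibration tolerance, and irrelevant to envelope inference, where
observed and simulated patterns share the estimator.

Envelopes condition on the observed n: m CSR simulations (uniform in the
window), pointwise bounds at order-statistic rank k, two-sided pointwise
level 2k/(m+1). Survey-scale settings are m = 499, k = 2 (≈ 99% envelope
at the 1% pointwise level); the desk default is m = 199, k = 1. The
standardized deviation z(r) = (K̂_obs − mean K̂_sim)/sd K̂_sim is summarized
by z_max = max|z| and r_peak = argmax|z|, the dominant clustering scale.
Radii are truncated (with a warning) at a quarter of the window diameter,
beyond which the estimator is unreliable.

## Synthetic environments

The generator emulates the structures the analysis assumes:

* **Locations**: a Thomas cluster process — uniform parents (sampled in a
  3σ-padded bounding box to avoid edge bias), Poisson offspring counts,
  isotropic Gaussian offspring dispersion σ — clipped to the window and
  thinned to exactly n outlets (thinning preserves the Thomas class). σ
  controls the dominant clustering scale that Ripley's K should recover.
* **Categories**: typology, gender and shelf space are drawn from closed
  mixtures; the presets use the surveyed ward compositions (e.g. ~71%
  female retailers; stalls ≈ 25–28%, kiosks 27–39% by ward). An optional
  typology-by-cluster mode assigns typologies per parent cluster,
  inducing attribute autocorrelation that Moran/LISA should detect —
  separating attribute clustering from point clustering in tests.
* **Stocking**: per-group Bernoulli presence conditional on typology.
  True stocking probabilities are not published, so the default matrix
  encodes the qualitative ordering of the fitted associations: stalls
  healthy-heavy with mobile retailers at exactly one third of the stall
  probabilities (designed stall-vs-mobile HRFES rate ratio 3.0, which the
  regression-recovery tests target), kiosks/supermarkets/restaurants/home
  vendors unhealthy-heavy, butchers dominated by red meat, farmgate
  sellers stocking nothing unhealthy (exercising the regression's
  separation handling). The rural preset scales healthy stocking by 1.12,
  reproducing the observed pattern of rural outlets individually
  out-scoring urban ones while denser urban neighborhoods overtake them
  at buffer level.
* **Presets**: `rural` — ~446.2 km² square ward, n = 894, σ = 170 m;
  `urban` — ~5.0 km² square ward, n = 1192, σ = 70 m. The rural pattern
  therefore exhibits a broader K-deviation scale, matching the observed
  ordering of dominant clustering scales.

What passing tests show: the pipeline's estimators recover designed
parameters (rate ratios, clustering scales, autocorrelation) from data
generated under its own assumptions. What they do not show: robustness to
road-network geometry, inhomogeneous background intensity, enumeration
gaps, or item→group mapping errors in real surveys — none of which the
generator models.

## Numerical and design choices

* Projection origin = mean lon/lat of the record set (deterministic).
* Closed-ball (≤ r) inclusion everywhere a distance threshold appears.
* k-NN ties broken by index; all permutation/simulation procedures take
  explicit seeds and record them in their results; the pipeline spawns
  per-stage seeds from the run seed, so same-seed runs are byte-identical.
* Fisher Monte Carlo uses a fixed tolerance (1e-9 in log-probability) to
  classify ties.
* Degenerate inputs fail loudly: constant attributes for Moran/LISA, zero
  margins in contingency tables (dropped with a warning), subsamples
  smaller than 2, empty neighbor pools, non-integer outcomes for the
  count model.
* Desk-scale defaults throughout (199 simulations, 999 permutations, 10^4
  replicates, a few hundred outlets in examples) are the package's chosen
  problem sizes; every procedure accepts survey-scale settings through
  the same parameters.

## Known limitations

* Euclidean distances only; no road-network or population-weighted
  catchments.
* Single-level GLMs; no spatial-error or mixed models, so IRRs inherit
  whatever spatial confounding the covariates miss.
* The LISA permutation loop is per-unit Python; comfortable to a few
  thousand units, not designed for tens of thousands.
* Arc-sampled edge correction is approximate (≤ 0.5% on convex windows);
  exact polygon–circle geometry is not implemented.
* Published ward-level survey values depend on the deposited dataset and
  on modeling choices (GLM family, weight scheme) their source does not
  state; the package reproduces the procedures, not those printed numbers.
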