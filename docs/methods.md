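# Methods

## The P/E curve

Given a suitability surface `hs` over valid grid cells and a set of
validation presence records, the range [0, 1] is partitioned into
`b = 1/W` contiguous classes of width `W`. Per class `i`, `p_i` counts
presence records (per record, not per unique cell — the record is the
sampling unit), `a_i` counts valid cells, and

    P_i = p_i / Σ p_j ,   E_i = a_i / Σ a_j ,   F_i = P_i / E_i .

`F_i` is the density of presences in class `i` relative to a uniform
random placement over the landscape; `F ≈ 1` everywhere means the model is
uninformative.

Conventions, fixed because the quantities are otherwise ambiguous:

* Bins are half-open `[lo, hi)` with the final bin closed so `hs = 1` is
  counted; assignment is exhaustive and exclusive (`Σ a_i = n_valid`,
  `Σ p_i = n_points`).
* `W` must divide 1 into an integer number of classes; the default
  `W = 0.01` (100 classes) is the customary curve resolution.
* Classes with `a_i = 0` have no defined `F` and are dropped from the
  retained curve; classes with area but no presences keep `F_i = 0` — an
  informative zero, not a missing value. Empty classes are not
  interpolated.
* The abscissa of a class is the mean suitability of its cells, not the
  bin midpoint; across retained bins this is strictly increasing by
  construction.

The per-class frequencies always normalise (`Σ P = Σ E = 1` over retained
classes, since presences can only fall in classes with area); this is
enforced by property tests to 1e-9.

## Two-region threshold regression

The regression observations are the retained curve points
`(hs_mean_i, F_i)`, so `T ≈ 1/W`. The model is piecewise proportional:

    pe_t = hs_t δ1 + ε_t  (0 < hs_t ≤ γ),
    pe_t = hs_t δ2 + ε_t  (γ < hs_t ≤ hs_max),

estimated by grid search: the candidate set Γ is the distinct observed
`hs` values between the empirical 10th and 90th percentiles (trimming
fraction 0.10, configurable), quantiles taken by nearest rank with
inclusive bounds — the lower bound is the sorted value at 0-based rank
`floor(q·n)`, the upper at rank `ceil((1−q)·n) − 1`. For each candidate
the two regions are fitted separately and

    γ̂ = argmin_γ S(γ),   S(γ) = Σ (pe_t − fitted_t)² .

Numerical and design choices:

* **No intercepts by default.** The model is proportional through the
  origin; the per-region least-squares slope has the closed form
  `δ = Σ hs·pe / Σ hs²`. Per-region intercepts are available behind
  `intercept=True` (then each region needs ≥ 2 points) as the standard
  threshold-regression variant, but they change the estimator and are
  deliberately non-default.
* **Least squares by default.** A quantile-loss mode (`loss="quantile"`,
  τ configurable, solved as a linear program) is provided for robustness
  studies; the default estimator is SSR-based.
* **Feasibility.** A candidate must leave ≥ 1 point in each region;
  infeasible candidates are skipped and excluded from the SSR profile. If
  no candidate is feasible, or fewer than 5 classes are retained, or fewer
  than 2 distinct candidates survive trimming (e.g. a constant grid), the
  fit raises rather than guessing.
* **Ties.** Equal-SSR candidates resolve to the smallest γ (the more
  inclusive habitat map). Because an exactly proportional curve produces
  SSRs at rounding level (~1e-30) rather than exact zeros, SSRs within
  `1e-12 · Σ pe²` of the minimum count as tied.
* The full `(γ, SSR)` profile is kept on the fit object so the search
  surface can be inspected or plotted.

The grid search is exact by construction (the criterion only changes at
observed values); tests verify it against an independently written
exhaustive enumeration on random curves, and breakpoint recovery on noisy
two-slope curves (slopes 0.3/4, break 0.5, Gaussian noise σ = 0.05):
within ±0.05 in ≥ 90% of seeds.

## Comparator rules

All comparators classify with the inclusive rule *prediction ≥ threshold →
habitat*. For the optimiser family (MSS, ESS, MaxKappa, MinROC) the
criterion is a step function changing only at observed prediction values,
so the search space is the sorted unique union of presence and
pseudo-absence predictions plus {0, 1}, searched exhaustively; ties go to
the smallest threshold, and because equal rational criteria (ratios of
integer counts) can round differently at different thresholds, an
improvement must exceed 1e-12 to displace an earlier candidate.

* MSS maximises sensitivity + specificity; ESS minimises
  |sensitivity − specificity| (argmin over candidates, not root-finding);
  MaxKappa maximises Cohen's kappa; MinROC minimises the Euclidean
  distance of (1−spec, sens) from the ROC ideal (0, 1).
* EqualPrev minimises |fraction(grid ≥ t) − observed prevalence|. The
  observed prevalence must be supplied by the caller — for virtual species
  the realized truth-map prevalence is the natural choice; there is no
  defensible silent default for real presence-only data.
* MeanProb returns the mean prediction. The default semantics is the mean
  over the whole valid study area; what to average over is genuinely
  underdetermined in the literature, so the benchmark can switch to the
  pooled validation predictions (see below).
* Se_s returns the largest candidate threshold with sensitivity ≥ s — the
  nearest-rank (1−s) quantile of presence predictions under the ≥ rule.
  With fewer than 1/(1−s) presences the quantile is unresolvable; the
  nearest-rank value is still returned, with a warning.

Cohen's kappa uses the closed form
`κ = (p_o − p_e)/(1 − p_e)`; a degenerate table with `p_e = 1` yields
κ = 0 with a warning (agreement indistinguishable from chance).

## Virtual species

The generator emulates a presence-only study with known truth:

1. **Environment.** `n_layers` (default 3) smooth fields: Gaussian white
   noise low-pass filtered at σ = `smoothness` cells (default 5 on a
   100×100 landscape, periodic boundaries), standardized to mean 0 / sd 1.
   They stand in for orthogonal climate/terrain principal components; they
   are stationary and isotropic, which real environmental gradients are
   not.
2. **Suitability.** One response function per layer — gaussian
   (unimodal preference), linear, or logistic (saturating) — summed and
   min-max rescaled to [0, 1]. A constant raw sum (degenerate species) is
   an error. The default species uses two gaussian responses and one
   linear, giving a realistic right-skewed suitability histogram.
3. **Occurrence probability.** `Pr = 1/(1 + exp((hs − β)/α))` with
   α = −0.05 (the sign makes Pr increase with suitability; the magnitude
   sets a transition width of ~0.2 suitability units). β — the suitability
   at which Pr = 0.5 — is calibrated by Brent root-finding on the bracket
   [−1, 2] so the landscape-mean probability hits a target prevalence to
   1e-4; the study levels are 0.1, 0.25, 0.5 and 0.75. The mean
   probability is continuous and strictly monotone in β, so the root is
   unique.
4. **Truth.** Cellwise independent Bernoulli draws. Realized prevalence
   therefore fluctuates around the target with binomial noise
   √(p(1−p)/n); tests allow 3 standard errors.

Validation presences are drawn uniformly without replacement from truth
presence cells, background (pseudo-absence) points uniformly from all
valid cells excluding the drawn presences. All randomness flows through
`numpy.random.default_rng` seeded per run; derived seeds are spawned from
the master seed.

What passing tests on this generator do **not** show: robustness to
spatially biased sampling, detection error, non-stationary environments,
or SDM miscalibration — the benchmark's "model" is the true suitability
surface itself (a perfect model), which isolates the threshold-selection
question from model-fitting error.

## Evaluation

* **Accuracy**: Cohen's kappa between the binarised suitability map and
  the realized truth map, over valid cells. The default compares the full
  landscape exhaustively (synthetic grids are small); a stratified-sample
  mode (1000 cells split by prevalence, 1/50 of the classical
  50,000-point design) is available.
* **Prevalence recovery**: fraction of valid cells ≥ threshold vs. the
  species' true prevalence.
* **Consistency**: one-way ANOVA F = MSB/MSW across validation-size
  groups of thresholds, df (k−1, N−k), p from the upper F tail. Groups are
  defined by validation size with equal replicate counts, so F values are
  directly comparable between methods. Degenerate conventions: zero
  within-group variance with unequal means → (F = ∞, p = 0); no variance
  at all → (F = 0, p = 1); group means are compared with a 1e-12 relative
  tolerance so that identical thresholds never register spurious
  between-group variance through last-ulp rounding.

`run_benchmark` crosses methods × validation sizes × repeats on one
virtual species. Its default validation ladder (250, 500, 1000, 2000
presences with 2500 background) is a quarter-scale version of the
1000–8000 (+10,000 background) design appropriate to a 100×100 landscape,
keeping the full benchmark under half a minute.

A subtlety in the consistency experiment: with the library-default
comparator semantics (area-wide MeanProb, caller-supplied true prevalence
for EqualPrev), those two thresholds are constants of the landscape and
their consistency F is trivially 0. The question the experiment asks is
how rules behave when driven by the validation data, so the benchmark's
default mode (`comparator_inputs="validation"`) feeds MeanProb and
EqualPrev the pooled validation predictions, with the validation set's
presence fraction as observed prevalence. Under that mode their thresholds
track the validation composition (F in the hundreds to thousands) while
the threshold-regression estimate, which reads only the shape of the P/E
curve, keeps F near 1. `comparator_inputs="area"` restores the constant
behaviour.

## Known limitations

* The estimated threshold is always a retained class mean, so its
  resolution is one class width (~W); with few validation presences
  (≲ 2–3 per class on average) the selected class can jitter by one or
  two classes between draws.
* Exactly two regions; species whose P/E curve is concave downward (seen
  with some tree-ensemble SDMs at high prevalence) violate the model's
  premise and the selected point is not meaningful.
* No inference on γ̂ — no confidence intervals or structural-break tests;
  the point estimate is the deliverable.
* Raster I/O is plain text (ESRI ASCII grid / bare matrix); the package
  addresses threshold selection, not GIS plumbing.
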