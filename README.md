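# btqr — presence-only threshold selection for species distribution models

Species distribution models (SDMs) output a continuous habitat-suitability
surface, but conservation planning, prevalence estimation and many
downstream analyses need a binary habitat / non-habitat map. With
presence-absence data the binarisation threshold can be tuned against a
confusion matrix; with **presence-only** data — the common case — the usual
workarounds either invent pseudo-absences or pick a sensitivity level by
fiat.

This package selects the threshold objectively from presences alone, using
the shape of the **Boyce predicted-to-expected (P/E) curve**. The
suitability range [0, 1] is split into `1/W` classes (default `W = 0.01`);
for class *i* with `p_i` validation presences and `a_i` grid cells,

```
P_i = p_i / Σ_j p_j      E_i = a_i / Σ_j a_j      F_i = P_i / E_i
```

so `F_i > 1` marks suitability classes where presences concentrate beyond
chance. Empirically the P/E curve is concave upward with an abrupt slope
change — a *mutation point* — which source-sink ecology interprets as the
transition from sink habitat (occupancy sustained only by immigration) to
source habitat (positive natural growth). That point is a defensible
binarisation threshold.

The mutation point is located by **two-region threshold regression** on the
curve points `(hs_t, pe_t)` (class mean suitability vs. P/E ratio):

```
pe_t = hs_t δ1 + ε_t   if 0 < hs_t ≤ γ
pe_t = hs_t δ2 + ε_t   if γ < hs_t ≤ hs_max
```

Every observed class mean between the 10th and 90th percentile (10%
trimming) is a tentative threshold; each region is fitted by no-intercept
least squares and the candidate minimising the total sum of squared
residuals is the estimate γ̂.

Also included:

* the nine traditional threshold rules used as comparators — MSS, ESS,
  MaxKappa, MinROC (need pseudo-absences), EqualPrev, MeanProb,
  Se0.5/0.75/0.9 — with shared confusion-matrix machinery;
* a virtual-species simulator (smooth environmental layers → additive
  response functions → logistic occurrence probability with calibrated
  prevalence → Bernoulli truth map) so every classification can be scored
  against a known truth;
* an evaluation harness: Cohen's kappa against the truth map, prevalence
  recovery, and a one-way ANOVA F-test for threshold consistency across
  validation sets of different sizes.

## Worked example

```python
from btqr import (compute_pe_curve, extract_suitability, fit_btqr,
                  make_virtual_species, sample_points, estimate_prevalence)

species = make_virtual_species(target_prevalence=0.25, seed=7)
pres_cells, _ = sample_points(species.pa_map, n_presence=1000,
                              seed=8, mask=species.suitability.mask)
presences = extract_suitability(species.suitability, pres_cells)
curve = compute_pe_curve(species.suitability, presences, window_width=0.01)
fit = fit_btqr(curve, trimming=0.10)
print(fit.gamma_hat, fit.delta1, fit.delta2)
print(estimate_prevalence(species.suitability, fit.gamma_hat))
```

prints

```
0.615  0.66  4.38
0.275
```

i.e. the estimated threshold 0.615 sits at the foot of the steep region of
the P/E curve (region slopes 0.66 vs 4.38) right next to the species'
logistic inflection point (0.645 for this seed), and binarising at it
recovers a landscape prevalence of 0.275 against a true prevalence of
0.249. The scripts in `examples/` walk through each capability — P/E
curves, the regression fit, all ten rules side by side, prevalence
calibration, and the consistency benchmark — and print commented output.

A thin CLI mirrors the library for shell use:

```sh
btqr simulate --prevalence 0.25 --seed 3 --outdir sim/
btqr fit --raster sim/suitability.txt --presences sim/presences.csv --nodata -9999
btqr threshold --method mss --raster pred.asc --presences pts.csv --absences bg.csv
```

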