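"""Compare all ten threshold-selection rules on one validation dataset.

The optimiser family (MSS, ESS, MaxKappa, MinROC) needs pseudo-absences;
the prevalence family (EqualPrev, MeanProb) needs area-wide predictions;
the fixed-sensitivity family (Se0.5/0.75/0.9) and the threshold-regression
method need presences only.
"""

import numpy as np

from btqr import (apply_threshold, btqr_threshold, extract_suitability,
                  kappa_vs_truth, make_virtual_species, sample_points,
                  select_threshold)

species = make_virtual_species(target_prevalence=0.25, seed=7)
suit = species.suitability
pres_cells, bg_cells = sample_points(species.pa_map, n_presence=1000,
                                     n_background=2500, seed=8,
                                     mask=suit.mask)
presences = extract_suitability(suit, pres_cells)
p = presences.suitabilities
a = suit.values[bg_cells[:, 0], bg_cells[:, 1]]

thresholds = {}
for m in ("MSS", "ESS", "MaxKappa", "MinROC"):
    thresholds[m] = select_threshold(m, presence_preds=p,
                                     absence_preds=a).threshold
thresholds["EqualPrev"] = select_threshold(
    "EqualPrev", grid_preds=suit.valid_values,
    observed_prevalence=species.realized_prevalence).threshold
thresholds["MeanProb"] = select_threshold(
    "MeanProb", grid_preds=suit.valid_values).threshold
for s in (0.5, 0.75, 0.9):
    thresholds[f"Se{s}"] = select_threshold(f"Se{s}",
                                            presence_preds=p).threshold
thresholds["BTQR"] = btqr_threshold(suit, presences)

print("method      threshold   kappa vs truth")
for m, t in thresholds.items():
    kap = kappa_vs_truth(apply_threshold(suit, t), species.pa_map, suit.mask)
    print(f"{m:<10s}  {t:9.3f}   {kap:6.3f}")

# Higher kappa = binary map closer to the realized truth map.  The
# pseudo-absence optimisers see background points, not true absences, so
# their thresholds are biased; fixed sensitivities are arbitrary choices.
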