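"""Scoring threshold methods: kappa accuracy, prevalence, F-test consistency.

Three complementary views of a threshold method's quality:

* **Accuracy** — Cohen's kappa between the binarised suitability map and a
  truth map (for virtual species, the realized presence-absence map).
* **Prevalence recovery** — the fraction of the landscape classified as
  habitat, compared with the species' true prevalence.
* **Consistency** — a one-way ANOVA F-test on the thresholds produced under
  validation sets of different sizes: a method whose threshold drifts with
  the amount of validation data has a large F; a consistent method an F
  near (or below) one.

:func:`run_benchmark` orchestrates the full design — methods x validation
sizes x repeats on one virtual species — and returns tidy tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .comparators import (ConfusionMatrix, apply_threshold, cohen_kappa,
                          select_threshold)
from .grid import SuitabilityGrid
from .pe_curve import extract_suitability
from .regression import btqr_threshold
from .virtual_species import VirtualSpecies, sample_points

__all__ = [
    "EvaluationReport",
    "kappa_vs_truth",
    "estimate_prevalence",
    "anova_f_consistency",
    "run_benchmark",
]


@dataclass
class EvaluationReport:
    """Per-method evaluation summary."""

    method: str
    kappa: float
    estimated_prevalence: float
    thresholds_by_group: dict = field(default_factory=dict)
    f_value: float = np.nan
    p_value: float = np.nan


def _confusion_from_maps(binary_map, truth_map, mask=None) -> ConfusionMatrix:
    b = np.asarray(binary_map)
    t = np.asarray(truth_map)
    if b.shape != t.shape:
        raise ValueError(f"map shapes differ: {b.shape} vs {t.shape}")
    if mask is None:
        mask = np.ones(b.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != b.shape:
            raise ValueError("mask shape differs from map shape")
    b, t = b[mask].astype(bool), t[mask].astype(bool)
    return ConfusionMatrix(
        tp=int(np.sum(b & t)), fp=int(np.sum(b & ~t)),
        fn=int(np.sum(~b & t)), tn=int(np.sum(~b & ~t)),
    )


def kappa_vs_truth(binary_map, truth_map, mask=None) -> float:
    """Cohen's kappa between a classified map and a truth map, over valid cells."""
    return cohen_kappa(_confusion_from_maps(binary_map, truth_map, mask))


def kappa_vs_truth_sampled(binary_map, truth_map, n_total: int,
                           prevalence: float, seed: int = 0,
                           mask=None) -> float:
    """Kappa on a stratified cell sample instead of the full map.

    Draws ``n_total * prevalence`` presence cells and the remainder from
    absence cells of the truth map and scores the classification on those
    cells only — a scaled-down version of test designs that subsample the
    landscape rather than compare it exhaustively.
    """
    b = np.asarray(binary_map)
    t = np.asarray(truth_map)
    if mask is None:
        mask = np.ones(b.shape, dtype=bool)
    rng = np.random.default_rng(seed)
    pres = np.argwhere((t == 1) & mask)
    absc = np.argwhere((t == 0) & mask)
    n_p = min(int(round(n_total * prevalence)), pres.shape[0])
    n_a = min(n_total - n_p, absc.shape[0])
    pi = pres[rng.choice(pres.shape[0], n_p, replace=False)]
    ai = absc[rng.choice(absc.shape[0], n_a, replace=False)]
    tp = int(np.sum(b[pi[:, 0], pi[:, 1]] == 1))
    fp = int(np.sum(b[ai[:, 0], ai[:, 1]] == 1))
    cm = ConfusionMatrix(tp=tp, fp=fp, fn=n_p - tp, tn=n_a - fp)
    return cohen_kappa(cm)


def estimate_prevalence(grid: SuitabilityGrid, threshold: float) -> float:
    """Fraction of valid cells classified habitat at a threshold (>= rule)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return float(np.mean(grid.valid_values >= threshold))


def anova_f_consistency(thresholds_by_group: dict) -> tuple[float, float]:
    """One-way ANOVA F-test on thresholds grouped by validation set.

    F = MSB / MSW with degrees of freedom (k - 1, N - k).  Conventions for
    degenerate inputs: zero within-group variance with unequal group means
    gives (inf, 0); zero variance everywhere gives (0, 1).
    """
    groups = [np.asarray(v, dtype=float) for v in thresholds_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0.0:
        # distinguish truly unequal means from last-ulp rounding noise
        means = np.array([g.mean() for g in groups])
        scale = max(1.0, float(np.abs(means).max()))
        if np.ptp(means) <= 1e-12 * scale:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


_NEEDS_ABSENCES = {"MSS", "ESS", "MaxKappa", "MinROC"}


def _threshold_for(method: str, suitability: SuitabilityGrid,
                   pres_vals, abs_vals, grid_vals, observed_prevalence,
                   presences, window_width, trimming) -> float:
    if method == "BTQR":
        return btqr_threshold(suitability, presences,
                              window_width=window_width, trimming=trimming)
    return select_threshold(
        method,
        presence_preds=pres_vals,
        absence_preds=abs_vals if method in _NEEDS_ABSENCES else None,
        grid_preds=grid_vals if method in ("EqualPrev", "MeanProb") else None,
        observed_prevalence=(observed_prevalence if method == "EqualPrev"
                             else None),
    ).threshold


def run_benchmark(species: VirtualSpecies,
                  methods=("BTQR", "MeanProb", "EqualPrev"),
                  validation_sizes=(250, 500, 1000, 2000),
                  n_background: int = 2500,
                  repeats: int = 5,
                  window_width: float = 0.01,
                  trimming: float = 0.10,
                  seed: int = 0,
                  kappa_mode: str = "cells",
                  comparator_inputs: str = "validation"
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Methods x validation-size x repeat benchmark on one virtual species.

    For every combination a fresh validation set is drawn from the realized
    presence-absence map, each method produces a threshold, and the
    binarised suitability map is scored against the truth map.  Returns two
    tidy tables: per-run results (method, validation_size, repeat,
    threshold, kappa, est_prevalence) and the per-method consistency F-test
    across validation-size groups.

    ``kappa_mode``: ``"cells"`` compares the full landscape exhaustively;
    ``"sampled"`` scores a stratified cell sample (1/50 of the classical
    50,000-point design).

    ``comparator_inputs`` controls what the prevalence-family rules see.
    ``"validation"`` (default) feeds MeanProb/EqualPrev the pooled
    validation predictions with the validation set's presence fraction as
    observed prevalence — the usage under study when asking how thresholds
    react to the validation set.  ``"area"`` feeds them the whole-landscape
    predictions and the species' realized prevalence, which makes their
    thresholds independent of the validation draw.
    """
    if comparator_inputs not in ("validation", "area"):
        raise ValueError("comparator_inputs must be 'validation' or 'area'")
    suit = species.suitability
    truth = species.pa_map
    area_vals = suit.valid_values
    rng = np.random.default_rng(seed)

    rows = []
    for size in validation_sizes:
        for rep in range(repeats):
            s_pts = int(rng.integers(2 ** 31))
            pres_cells, bg_cells = sample_points(
                truth, n_presence=size, n_background=n_background,
                seed=s_pts, mask=suit.mask)
            presences = extract_suitability(suit, pres_cells)
            pres_vals = presences.suitabilities
            abs_vals = suit.values[bg_cells[:, 0], bg_cells[:, 1]]
            if comparator_inputs == "validation":
                grid_vals = np.concatenate([pres_vals, abs_vals])
                observed_prev = size / (size + n_background)
            else:
                grid_vals = area_vals
                observed_prev = species.realized_prevalence
            for method in methods:
                t = _threshold_for(method, suit, pres_vals, abs_vals,
                                   grid_vals, observed_prev, presences,
                                   window_width, trimming)
                bmap = apply_threshold(suit, t)
                if kappa_mode == "cells":
                    kap = kappa_vs_truth(bmap, truth, suit.mask)
                else:
                    kap = kappa_vs_truth_sampled(
                        bmap, truth, n_total=1000,
                        prevalence=species.target_prevalence,
                        seed=s_pts, mask=suit.mask)
                rows.append({
                    "prevalence": species.target_prevalence,
                    "method": method,
                    "validation_size": size,
                    "repeat": rep,
                    "threshold": t,
                    "kappa": kap,
                    "est_prevalence": estimate_prevalence(suit, t),
                })
    results = pd.DataFrame(rows)

    frows = []
    for method in methods:
        sub = results[results.method == method]
        groups = {s: sub[sub.validation_size == s].threshold.to_numpy()
                  for s in validation_sizes}
        if repeats < 2:
            warnings.warn("F-test skipped: needs >= 2 repeats per group",
                          stacklevel=2)
            f, p = np.nan, np.nan
        else:
            f, p = anova_f_consistency(groups)
        frows.append({"method": method, "f_value": f, "p_value": p})
    ftable = pd.DataFrame(frows)
    return results, ftable
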