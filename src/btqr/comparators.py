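"""Traditional threshold-selection rules and confusion-matrix machinery.

Nine comparator rules are implemented alongside the threshold-regression
method, covering the three families found in practice:

* sensitivity/specificity optimisers needing pseudo-absences — MSS
  (maximise sens + spec), ESS (equalise sens and spec), MaxKappa, MinROC
  (closest ROC point to (0, 1));
* prevalence/trait rules — EqualPrev (match predicted to observed
  prevalence), MeanProb (mean prediction over the study area);
* fixed-sensitivity rules needing presences only — Se0.5, Se0.75, Se0.9.

Classification rule: a prediction **>= threshold** is classified presence.
Criterion functions are step functions of the threshold that change only at
observed prediction values, so the optimisers search the sorted unique
observed values (plus 0 and 1) exhaustively — brute force is exact here.
Ties go to the smallest threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import SuitabilityGrid

__all__ = [
    "ConfusionMatrix",
    "ThresholdResult",
    "confusion_at",
    "cohen_kappa",
    "sensitivity",
    "specificity",
    "select_threshold",
    "apply_threshold",
    "METHODS",
]

METHODS = ("MSS", "ESS", "MaxKappa", "EqualPrev", "MeanProb", "MinROC",
           "Se0.5", "Se0.75", "Se0.9", "BTQR")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.fp + self.tn)


@dataclass(frozen=True)
class ThresholdResult:
    method: str
    threshold: float
    criterion_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError(f"threshold {self.threshold} outside [0, 1]")


def confusion_at(threshold: float, presence_preds, absence_preds) -> ConfusionMatrix:
    """Confusion matrix at a threshold under the >= classification rule."""
    p = np.asarray(presence_preds, dtype=float)
    a = np.asarray(absence_preds, dtype=float)
    if p.size == 0:
        raise ValueError("presence_preds must be non-empty")
    tp = int(np.sum(p >= threshold))
    fp = int(np.sum(a >= threshold))
    return ConfusionMatrix(tp=tp, fp=fp, fn=p.size - tp, tn=a.size - fp)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement of a 2x2 confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement
    p_o = (tp+tn)/n and chance agreement
    p_e = ((tp+fp)(tp+fn) + (fn+tn)(fp+tn)) / n^2.  When p_e = 1 (all mass
    in one marginal cell) agreement is indistinguishable from chance and
    kappa is defined as 0, with a warning.
    """
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
           + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n ** 2
    if p_e >= 1.0:
        warnings.warn("degenerate marginals (p_e = 1); kappa defined as 0",
                      stacklevel=2)
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def sensitivity(threshold: float, presence_preds) -> float:
    p = np.asarray(presence_preds, dtype=float)
    return float(np.mean(p >= threshold))


def specificity(threshold: float, absence_preds) -> float:
    a = np.asarray(absence_preds, dtype=float)
    return float(np.mean(a < threshold))


def _candidates(*arrays) -> np.ndarray:
    vals = np.concatenate([np.asarray(a, dtype=float).ravel() for a in arrays]
                          + [np.array([0.0, 1.0])])
    return np.unique(vals)


def _optimize(cands, score, maximize: bool) -> tuple[float, float]:
    """Exhaustive search over candidate thresholds; ties -> smallest t.

    Criterion values are ratios of integer counts; equal rationals can
    round differently in floating point depending on the threshold, so an
    improvement only counts beyond a small absolute tolerance — otherwise
    the earlier (smaller) threshold is kept.
    """
    tol = 1e-12
    best_t, best_v = None, None
    for t in cands:  # ascending, strict improvement keeps smallest tie
        v = score(t)
        if best_v is None or (v > best_v + tol if maximize else v < best_v - tol):
            best_t, best_v = t, v
    return float(best_t), float(best_v)


def select_threshold(method: str, presence_preds=None, absence_preds=None,
                     grid_preds=None, observed_prevalence: float | None = None,
                     sens_target: float | None = None) -> ThresholdResult:
    """Select a binarisation threshold by one of the comparator rules.

    Parameters
    ----------
    method
        One of ``MSS, ESS, MaxKappa, MinROC`` (need presences and
        pseudo-absences), ``EqualPrev`` (needs grid predictions and the
        observed prevalence), ``MeanProb`` (needs grid predictions),
        ``Se0.5 / Se0.75 / Se0.9`` or ``Se`` with ``sens_target`` (need
        presences only).
    grid_preds
        Predictions over the whole (valid) study area, used by the
        prevalence-based rules.
    observed_prevalence
        Caller-supplied prevalence for ``EqualPrev`` — for virtual species
        the known realized prevalence; never defaulted silently.
    """
    name = method
    if method.startswith("Se"):
        if sens_target is None:
            if len(method) <= 2:
                raise ValueError("method 'Se' requires sens_target")
            sens_target = float(method[2:])
        if not (0.0 < sens_target < 1.0):
            raise ValueError("sensitivity target must lie in (0, 1)")
        method = "Se"

    def need(arg, argname):
        if arg is None:
            raise ValueError(f"method {name} requires {argname}")
        return arg

    if method in ("MSS", "ESS", "MaxKappa", "MinROC"):
        p = np.asarray(need(presence_preds, "presence_preds"), dtype=float)
        a = np.asarray(need(absence_preds, "absence_preds"), dtype=float)
        cands = _candidates(p, a)

        if method == "MSS":
            t, v = _optimize(cands, lambda t: sensitivity(t, p) + specificity(t, a),
                             maximize=True)
        elif method == "ESS":
            t, v = _optimize(cands,
                             lambda t: abs(sensitivity(t, p) - specificity(t, a)),
                             maximize=False)
        elif method == "MaxKappa":
            t, v = _optimize(cands, lambda t: cohen_kappa(confusion_at(t, p, a)),
                             maximize=True)
        else:  # MinROC
            t, v = _optimize(
                cands,
                lambda t: float(np.hypot(1 - sensitivity(t, p),
                                         1 - specificity(t, a))),
                maximize=False)
        return ThresholdResult(name, t, v)

    if method == "EqualPrev":
        g = np.asarray(need(grid_preds, "grid_preds"), dtype=float)
        prev = need(observed_prevalence, "observed_prevalence")
        cands = _candidates(g)
        t, v = _optimize(cands, lambda t: abs(float(np.mean(g >= t)) - prev),
                         maximize=False)
        return ThresholdResult(name, t, v)

    if method == "MeanProb":
        g = np.asarray(need(grid_preds, "grid_preds"), dtype=float)
        t = float(np.mean(g))
        return ThresholdResult(name, t, t)

    if method == "Se":
        p = np.asarray(need(presence_preds, "presence_preds"), dtype=float)
        if p.size < 1.0 / (1.0 - sens_target):
            warnings.warn(
                f"{p.size} presence points cannot resolve sensitivity "
                f"{sens_target}; nearest-rank quantile returned",
                stacklevel=2)
        cands = _candidates(p)
        # largest threshold keeping sensitivity >= target
        feas = [t for t in cands if sensitivity(t, p) >= sens_target]
        t = float(max(feas))
        return ThresholdResult(name, t, sensitivity(t, p))

    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def apply_threshold(grid: SuitabilityGrid, threshold: float) -> np.ndarray:
    """Binarise a suitability grid; nodata cells are 0 in the returned map.

    Returns an integer 0/1 array of the grid's shape.  Use the grid's mask
    to distinguish true absences from nodata.
    """
    out = np.zeros(grid.shape, dtype=int)
    out[grid.mask] = (grid.values[grid.mask] >= threshold).astype(int)
    return out
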