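"""Two-region threshold regression locating the mutation point of a P/E curve.

The P/E curve of a well-behaved species distribution model is concave
upward: flat where suitability is low (sink habitat, occupancy sustained by
immigration only) and steep above some suitability value (source habitat,
positive natural growth).  The transition — the mutation point — is an
objective, presence-only choice of binarisation threshold.

It is located by a piecewise no-intercept regression on the curve points
(hs_t, pe_t):

    pe_t = hs_t * delta1 + eps_t   if 0 < hs_t <= gamma
    pe_t = hs_t * delta2 + eps_t   if gamma < hs_t <= hs_max

with the threshold gamma estimated by grid search: every observed hs value
between the 10th and 90th percentile (the trimming bounds) is a tentative
threshold, the two regions are fitted by least squares for each, and the
candidate minimising the total sum of squared residuals wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .pe_curve import PECurve

__all__ = [
    "InfeasibleThreshold",
    "ThresholdFit",
    "candidate_thresholds",
    "two_region_ssr",
    "fit_btqr",
    "btqr_threshold",
]


class InfeasibleThreshold(ValueError):
    """A candidate threshold leaves one region without enough points."""


@dataclass(frozen=True)
class ThresholdFit:
    """Result of the grid-searched two-region fit.

    ``gamma_hat`` is the selected threshold (always one of ``candidates``),
    ``delta1``/``delta2`` the per-region slopes at the optimum, and
    ``ssr_profile`` the (candidate, SSR) pairs over all feasible candidates,
    retained so the search surface can be inspected.
    """

    gamma_hat: float
    delta1: float
    delta2: float
    ssr_profile: np.ndarray  # (k, 2) columns: candidate gamma, SSR
    candidates: np.ndarray
    trimming: float
    hs_max: float
    window_width: float | None = None
    intercepts: tuple[float, float] | None = None
    loss: str = "ls"

    def to_dict(self) -> dict:
        d = {
            "gamma_hat": self.gamma_hat,
            "delta1": self.delta1,
            "delta2": self.delta2,
            "trimming": self.trimming,
            "hs_max": self.hs_max,
            "window_width": self.window_width,
            "loss": self.loss,
            "ssr_profile": [[float(g), float(s)] for g, s in self.ssr_profile],
        }
        if self.intercepts is not None:
            d["intercepts"] = list(self.intercepts)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def candidate_thresholds(hs, trimming: float = 0.10) -> np.ndarray:
    """Tentative thresholds: observed hs values inside the trimming bounds.

    With trimming fraction ``q`` the candidates are the distinct observed
    values between the empirical q-th and (1-q)-th quantiles, bounds
    inclusive, under the nearest-rank convention: the lower bound is the
    value at 0-based rank ``floor(q*n)`` of the sorted sample and the upper
    bound the value at rank ``ceil((1-q)*n) - 1``.

    Raises
    ------
    ValueError
        If fewer than two distinct candidates survive — the curve cannot
        support a two-region split.
    """
    hs = np.sort(np.asarray(hs, dtype=float))
    n = hs.size
    if n < 5:
        raise ValueError(f"need at least 5 observations, got {n}")
    if not (0.0 <= trimming < 0.5):
        raise ValueError("trimming must lie in [0, 0.5)")
    i_lo = int(np.floor(trimming * n))
    i_hi = int(np.ceil((1.0 - trimming) * n)) - 1
    lo_val, hi_val = hs[i_lo], hs[i_hi]
    cands = np.unique(hs[(hs >= lo_val) & (hs <= hi_val)])
    if cands.size < 2:
        raise ValueError(
            "insufficient curve support: fewer than 2 distinct candidate "
            "thresholds survive trimming"
        )
    return cands


def _fit_region(hs: np.ndarray, pe: np.ndarray, intercept: bool,
                loss: str, tau: float) -> tuple[float, float, np.ndarray]:
    """Fit pe ~ hs in one region; returns (slope, intercept, residuals)."""
    if loss == "ls":
        if intercept:
            X = np.column_stack([hs, np.ones_like(hs)])
            coef, *_ = np.linalg.lstsq(X, pe, rcond=None)
            slope, icept = float(coef[0]), float(coef[1])
        else:
            denom = float(np.sum(hs * hs))
            if denom == 0.0:
                raise InfeasibleThreshold("sum of hs^2 is zero in a region")
            slope = float(np.sum(hs * pe) / denom)
            icept = 0.0
    elif loss == "quantile":
        slope, icept = _quantile_fit(hs, pe, intercept, tau)
    else:  # pragma: no cover
        raise ValueError(f"unknown loss {loss!r}")
    resid = pe - (hs * slope + icept)
    return slope, icept, resid


def _quantile_fit(hs: np.ndarray, pe: np.ndarray, intercept: bool,
                  tau: float) -> tuple[float, float]:
    """Quantile-loss fit of pe ~ hs via linear programming.

    Minimises sum of check-function losses rho_tau(pe - hs*b [- a]).
    Standard LP formulation with positive/negative residual parts.
    """
    from scipy.optimize import linprog

    n = hs.size
    if intercept:
        X = np.column_stack([hs, np.ones(n)])
    else:
        X = hs[:, None]
    p = X.shape[1]
    # variables: beta (free, split +/-), u >= 0, v >= 0 ; Xb + u - v = pe
    c = np.concatenate([np.zeros(2 * p), tau * np.ones(n), (1 - tau) * np.ones(n)])
    A_eq = np.hstack([X, -X, np.eye(n), -np.eye(n)])
    res = linprog(c, A_eq=A_eq, b_eq=pe, bounds=[(0, None)] * (2 * p + 2 * n),
                  method="highs")
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"quantile fit failed: {res.message}")
    beta = res.x[:p] - res.x[p:2 * p]
    if intercept:
        return float(beta[0]), float(beta[1])
    return float(beta[0]), 0.0


def two_region_ssr(curve_hs, curve_pe, gamma: float, *,
                   intercept: bool = False, loss: str = "ls",
                   tau: float = 0.5):
    """Total squared residual of the two-region fit at a tentative threshold.

    Region 1 holds the curve points with ``0 < hs <= gamma``, region 2
    those with ``gamma < hs <= hs_max``; each is fitted separately
    (no-intercept least squares by default, slope ``sum(hs*pe)/sum(hs^2)``).

    Returns ``(ssr, delta1, delta2)`` or, with ``intercept=True``,
    ``(ssr, delta1, delta2, (a1, a2))``.

    Raises
    ------
    InfeasibleThreshold
        If either region has too few points (1 per region, 2 when
        intercepts are fitted).
    """
    hs = np.asarray(curve_hs, dtype=float)
    pe = np.asarray(curve_pe, dtype=float)
    in1 = (hs > 0) & (hs <= gamma)
    in2 = hs > gamma
    min_pts = 2 if intercept else 1
    if in1.sum() < min_pts or in2.sum() < min_pts:
        raise InfeasibleThreshold(
            f"gamma={gamma:.6g} leaves a region with fewer than "
            f"{min_pts} point(s)"
        )
    d1, a1, r1 = _fit_region(hs[in1], pe[in1], intercept, loss, tau)
    d2, a2, r2 = _fit_region(hs[in2], pe[in2], intercept, loss, tau)
    ssr = float(np.sum(r1 ** 2) + np.sum(r2 ** 2))
    if intercept:
        return ssr, d1, d2, (a1, a2)
    return ssr, d1, d2


def fit_btqr(curve: PECurve, trimming: float = 0.10, *,
             intercept: bool = False, loss: str = "ls",
             tau: float = 0.5) -> ThresholdFit:
    """Grid-search the threshold over the curve's trimmed candidate set.

    The regression observations are the retained curve classes
    ``(hs_mean_i, F_i)``.  Every candidate threshold is evaluated with
    :func:`two_region_ssr`; infeasible candidates are skipped; ties in SSR
    go to the smallest candidate (the more inclusive habitat map).
    """
    if loss not in ("ls", "quantile"):
        raise ValueError("loss must be 'ls' or 'quantile'")
    hs = np.asarray(curve.hs_mean, dtype=float)
    pe = np.asarray(curve.F, dtype=float)
    if hs.size < 5:
        raise ValueError(
            f"curve has {hs.size} retained classes; at least 5 are required"
        )
    if np.any(np.diff(hs) <= 0):
        raise ValueError("curve hs_mean is not strictly increasing")

    cands = candidate_thresholds(hs, trimming)
    profile = []
    fits = []
    for g in cands:
        try:
            out = two_region_ssr(hs, pe, g, intercept=intercept,
                                 loss=loss, tau=tau)
        except InfeasibleThreshold:
            continue
        profile.append((g, out[0]))
        fits.append((g, out))
    if not fits:
        raise ValueError("no feasible candidate threshold")
    # ties at the minimum go to the smallest candidate; SSRs within floating
    # noise of the minimum (relative to the curve's total sum of squares)
    # count as tied
    ssrs = np.array([s for _, s in profile])
    tol = 1e-12 * max(float(np.sum(pe ** 2)), 1.0)
    tied = np.flatnonzero(ssrs <= ssrs.min() + tol)
    g, out = fits[tied[0]]
    icepts = out[3] if intercept else None
    return ThresholdFit(
        gamma_hat=float(g),
        delta1=float(out[1]),
        delta2=float(out[2]),
        ssr_profile=np.array(profile, dtype=float),
        candidates=cands,
        trimming=trimming,
        hs_max=float(hs.max()),
        window_width=curve.window_width,
        intercepts=icepts,
        loss=loss,
    )


def btqr_threshold(grid, presences, window_width: float = 0.01,
                   trimming: float = 0.10, **fit_kwargs) -> float:
    """Presence-only threshold for a suitability grid: curve + fit in one call."""
    from .pe_curve import compute_pe_curve

    curve = compute_pe_curve(grid, presences, window_width)
    fit = fit_btqr(curve, trimming, **fit_kwargs)
    return fit.gamma_hat
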