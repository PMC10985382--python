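"""Virtual species with known suitability, occurrence probability and truth.

A virtual species gives the one thing real occurrence data never can: a
known truth map against which binary classifications can be scored.  The
construction follows the standard three-step recipe of the virtual-species
literature:

1. **Suitability.**  Smooth synthetic environmental layers (stand-ins for
   climate/terrain principal components) are passed through per-layer
   response functions — gaussian, linear or logistic — summed, and min-max
   rescaled to [0, 1].
2. **Occurrence probability.**  The suitability surface is converted with a
   logistic transformation ``Pr = 1 / (1 + exp((hs - beta) / alpha))``;
   with the conventional ``alpha = -0.05`` the curve rises steeply with
   suitability and ``beta`` is the inflection point.  ``beta`` is
   calibrated by bisection so the expected prevalence (the landscape mean
   of Pr) hits a target — the study levels are 0.1, 0.25, 0.5 and 0.75.
3. **Realisation.**  Each cell gets an independent Bernoulli draw: presence
   where a uniform random number falls below Pr.

Sampling helpers draw validation presences from the realized map and
background (pseudo-absence) points from the whole landscape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .grid import SuitabilityGrid

__all__ = [
    "ResponseFunction",
    "VirtualSpecies",
    "generate_environment",
    "build_suitability",
    "logistic_probability",
    "calibrate_beta",
    "realize_presence_absence",
    "sample_points",
    "make_virtual_species",
]

DEFAULT_ALPHA = -0.05


@dataclass(frozen=True)
class ResponseFunction:
    """Response of suitability to one environmental layer.

    kinds and params:
      - ``gaussian``: (mean, sd), sd > 0 — unimodal preference.
      - ``linear``: (slope, intercept).
      - ``logistic``: (alpha, beta), alpha != 0 — saturating response,
        same parameterisation as the occurrence-probability transform.
    """

    kind: str
    params: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "linear", "logistic"):
            raise ValueError(f"unknown response kind {self.kind!r}")
        if len(self.params) != 2:
            raise ValueError(f"{self.kind} response takes 2 parameters")
        if self.kind == "gaussian" and self.params[1] <= 0:
            raise ValueError("gaussian sd must be > 0")
        if self.kind == "logistic" and self.params[0] == 0:
            raise ValueError("logistic alpha must be nonzero")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        a, b = self.params
        if self.kind == "gaussian":
            return np.exp(-0.5 * ((x - a) / b) ** 2)
        if self.kind == "linear":
            return a * x + b
        return _logistic(x, a, b)


def _logistic(x: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    z = np.clip((x - beta) / alpha, -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(z))


@dataclass(frozen=True)
class VirtualSpecies:
    """A fully realized virtual species and the parameters that made it."""

    env_layers: list
    suitability: SuitabilityGrid
    alpha: float
    beta: float
    prob: np.ndarray
    pa_map: np.ndarray
    target_prevalence: float
    seed: int

    @property
    def realized_prevalence(self) -> float:
        m = self.suitability.mask
        return float(self.pa_map[m].mean())

    @property
    def expected_prevalence(self) -> float:
        m = self.suitability.mask
        return float(self.prob[m].mean())


def generate_environment(n_layers: int, shape: tuple[int, int],
                         smoothness: float = 5.0, seed: int = 0) -> list[np.ndarray]:
    """Smooth standardized random fields standing in for environmental PCs.

    Gaussian white noise is low-pass filtered (Gaussian kernel with sigma =
    ``smoothness`` cells) and standardized to zero mean, unit variance.
    Larger smoothness gives stronger spatial autocorrelation.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if min(shape) < 10:
        raise ValueError("shape must be at least 10x10")
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    rng = np.random.default_rng(seed)
    layers = []
    for _ in range(n_layers):
        field = ndimage.gaussian_filter(rng.standard_normal(shape), smoothness,
                                        mode="wrap")
        field = (field - field.mean()) / field.std()
        layers.append(field)
    return layers


def build_suitability(layers, responses) -> SuitabilityGrid:
    """Additive response model min-max rescaled to [0, 1].

    raw = sum_k f_k(layer_k); suitability = (raw - min) / (max - min).
    A constant raw field (degenerate species) is an error.
    """
    if len(layers) != len(responses):
        raise ValueError("need exactly one response per layer")
    raw = np.zeros_like(np.asarray(layers[0], dtype=float))
    for layer, resp in zip(layers, responses):
        raw = raw + resp(np.asarray(layer, dtype=float))
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        raise ValueError("degenerate species: raw suitability is constant")
    return SuitabilityGrid((raw - lo) / (hi - lo))


def logistic_probability(suitability: SuitabilityGrid, alpha: float = DEFAULT_ALPHA,
                         beta: float = 0.5) -> np.ndarray:
    """Occurrence probability Pr = 1 / (1 + exp((hs - beta) / alpha)).

    With ``alpha < 0`` Pr increases with suitability; ``beta`` is the
    suitability at which Pr = 0.5.  Nodata cells get Pr = 0.
    """
    if alpha == 0:
        raise ValueError("alpha must be nonzero")
    prob = np.zeros(suitability.shape, dtype=float)
    prob[suitability.mask] = _logistic(suitability.values[suitability.mask],
                                       alpha, beta)
    return prob


def calibrate_beta(suitability: SuitabilityGrid, alpha: float = DEFAULT_ALPHA,
                   target_prevalence: float = 0.25, tol: float = 1e-4,
                   bracket: tuple[float, float] = (-1.0, 2.0)) -> float:
    """Solve for the beta giving a target expected prevalence.

    The expected prevalence g(beta) — the mean occurrence probability over
    valid cells — is continuous and strictly monotone in beta (decreasing
    for alpha < 0), so bisection on the bracket finds the root of
    g(beta) - target to within ``tol`` on the prevalence scale.
    """
    if not (0.0 < target_prevalence < 1.0):
        raise ValueError("target_prevalence must lie in (0, 1)")
    hs = suitability.valid_values

    def g(beta: float) -> float:
        return float(_logistic(hs, alpha, beta).mean())

    lo, hi = bracket
    f_lo, f_hi = g(lo) - target_prevalence, g(hi) - target_prevalence
    if f_lo * f_hi > 0:
        raise ValueError(
            f"target prevalence {target_prevalence} unreachable for beta in "
            f"[{lo}, {hi}] (g({lo})={f_lo + target_prevalence:.4g}, "
            f"g({hi})={f_hi + target_prevalence:.4g})"
        )
    beta = optimize.brentq(lambda b: g(b) - target_prevalence, lo, hi,
                           xtol=1e-12)
    if abs(g(beta) - target_prevalence) > tol:  # pragma: no cover
        raise RuntimeError("beta calibration did not reach tolerance")
    return float(beta)


def realize_presence_absence(prob: np.ndarray, seed: int = 0,
                             mask: np.ndarray | None = None) -> np.ndarray:
    """Cellwise Bernoulli realisation: presence where uniform draw < Pr."""
    prob = np.asarray(prob, dtype=float)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    x = rng.random(prob.shape)
    pa = (x < prob).astype(int)
    if mask is not None:
        pa[~np.asarray(mask, dtype=bool)] = 0
    return pa


def sample_points(pa_map: np.ndarray, n_presence: int, n_background: int = 0,
                  exclude=None, seed: int = 0,
                  mask: np.ndarray | None = None):
    """Draw validation presences and background pseudo-absence points.

    Presences are drawn uniformly without replacement from cells with
    ``pa_map == 1`` (minus ``exclude``); background points uniformly from
    all valid cells excluding the drawn presences.  Returns two (n, 2)
    arrays of (row, col) indices.
    """
    pa_map = np.asarray(pa_map)
    if mask is None:
        mask = np.ones(pa_map.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    rng = np.random.default_rng(seed)

    excl = set()
    if exclude is not None:
        excl = {tuple(p) for p in np.atleast_2d(np.asarray(exclude, dtype=int))}

    pres_cells = np.argwhere((pa_map == 1) & mask)
    if excl:
        keep = [i for i, c in enumerate(map(tuple, pres_cells)) if c not in excl]
        pres_cells = pres_cells[keep]
    if pres_cells.shape[0] < n_presence:
        raise ValueError(
            f"only {pres_cells.shape[0]} presence cells available, "
            f"{n_presence} requested"
        )
    idx = rng.choice(pres_cells.shape[0], size=n_presence, replace=False)
    presences = pres_cells[idx]

    background = np.empty((0, 2), dtype=int)
    if n_background > 0:
        taken = {tuple(p) for p in presences} | excl
        all_cells = np.argwhere(mask)
        keep = [i for i, c in enumerate(map(tuple, all_cells)) if c not in taken]
        all_cells = all_cells[keep]
        if all_cells.shape[0] < n_background:
            raise ValueError("not enough valid cells for background sample")
        idx = rng.choice(all_cells.shape[0], size=n_background, replace=False)
        background = all_cells[idx]
    return presences, background


def make_virtual_species(shape: tuple[int, int] = (100, 100), n_layers: int = 3,
                         responses=None, smoothness: float = 5.0,
                         alpha: float = DEFAULT_ALPHA,
                         target_prevalence: float = 0.25,
                         seed: int = 0) -> VirtualSpecies:
    """End-to-end virtual species construction with calibrated prevalence.

    Defaults mirror the study conditions: a 100x100 landscape, three
    smooth environmental layers with mixed gaussian/linear responses,
    alpha = -0.05, and beta calibrated to the target prevalence.
    """
    rng = np.random.default_rng(seed)
    env_seed, pa_seed = rng.integers(2 ** 31, size=2)
    layers = generate_environment(n_layers, shape, smoothness, int(env_seed))
    if responses is None:
        base = [ResponseFunction("gaussian", (0.0, 1.0)),
                ResponseFunction("linear", (0.5, 0.0)),
                ResponseFunction("gaussian", (0.5, 1.5))]
        responses = [base[i % 3] for i in range(n_layers)]
    suit = build_suitability(layers, responses)
    beta = calibrate_beta(suit, alpha, target_prevalence)
    prob = logistic_probability(suit, alpha, beta)
    pa = realize_presence_absence(prob, int(pa_seed), mask=suit.mask)
    return VirtualSpecies(
        env_layers=layers, suitability=suit, alpha=alpha, beta=beta,
        prob=prob, pa_map=pa, target_prevalence=target_prevalence, seed=seed,
    )
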