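import numpy as np
import pytest

from btqr import PECurve, SuitabilityGrid


@pytest.fixture
def two_level_grid():
    """10-cell grid: five cells at 0.1 and five at 0.9."""
    return SuitabilityGrid(np.array([[0.1] * 5 + [0.9] * 5]))


@pytest.fixture
def uniform_grid():
    rng = np.random.default_rng(42)
    return SuitabilityGrid(rng.random((100, 100)))


def curve_from_F(hs, F, window_width=0.01):
    """Assemble a PECurve directly from (hs_mean, F) points for fit tests."""
    hs = np.asarray(hs, dtype=float)
    F = np.asarray(F, dtype=float)
    n = hs.size
    w = window_width
    return PECurve(
        class_edges=np.column_stack([hs - w / 2, hs + w / 2]),
        hs_mean=hs,
        p_counts=np.ones(n, dtype=int),
        a_counts=np.ones(n, dtype=int),
        P=np.full(n, 1.0 / n),
        E=np.full(n, 1.0 / n),
        F=F,
        n_classes=int(round(1.0 / w)),
        window_width=w,
    )


@pytest.fixture
def piecewise_curve_factory():
    """Noisy two-slope P/E curves: F = 0.3*hs below 0.5, 4*hs above."""

    def make(sigma=0.0, seed=None, n=100):
        hs = np.arange(n) / n + 0.5 / n
        F = np.where(hs <= 0.5, 0.3 * hs, 4.0 * hs)
        if sigma > 0:
            rng = np.random.default_rng(seed)
            F = np.clip(F + rng.normal(0, sigma, n), 0.0, None)
        return curve_from_F(hs, F, 1.0 / n)

    return make
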