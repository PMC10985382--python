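"""Virtual species construction: layers, suitability, prevalence control."""

import numpy as np
import pytest

from btqr import (ResponseFunction, SuitabilityGrid, build_suitability,
                  calibrate_beta, generate_environment, logistic_probability,
                  make_virtual_species, realize_presence_absence,
                  sample_points)


def lag1_autocorr(field):
    a = field - field.mean()
    return float(np.sum(a[:, :-1] * a[:, 1:]) / np.sum(a * a))


class TestGenerateEnvironment:
    def test_deterministic_given_seed(self):
        a = generate_environment(2, (20, 20), 3.0, seed=9)
        b = generate_environment(2, (20, 20), 3.0, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_standardized(self):
        layers = generate_environment(3, (100, 100), 5.0, seed=0)
        assert len(layers) == 3
        for lay in layers:
            assert abs(lay.mean()) < 1e-6
            assert abs(lay.std() - 1.0) < 1e-6

    def test_smoothness_increases_autocorrelation(self):
        # large domain so the lag-1 statistic can resolve sigma=25
        acs = [lag1_autocorr(generate_environment(1, (200, 200), s, seed=1)[0])
               for s in (1, 5, 25)]
        assert acs[0] < acs[1] < acs[2]

    def test_invalid_smoothness(self):
        with pytest.raises(ValueError, match="smoothness"):
            generate_environment(1, (20, 20), 0.0)


class TestResponsesAndSuitability:
    def test_linear_response_is_rescaled_identity(self):
        layer = np.linspace(-2, 2, 100).reshape(10, 10)
        suit = build_suitability([layer], [ResponseFunction("linear", (1.0, 0.0))])
        expect = (layer - layer.min()) / (layer.max() - layer.min())
        assert np.allclose(suit.values, expect)

    def test_gaussian_mode_attains_maximum(self):
        layer = np.linspace(-2, 2, 100).reshape(10, 10)
        suit = build_suitability([layer], [ResponseFunction("gaussian", (0.5, 1.0))])
        peak = np.unravel_index(np.argmax(suit.values), suit.shape)
        assert abs(layer[peak] - 0.5) == pytest.approx(
            np.min(np.abs(layer - 0.5)))

    def test_cancellation_is_degenerate(self):
        layer = np.linspace(-1, 1, 100).reshape(10, 10)
        with pytest.raises(ValueError, match="degenerate"):
            build_suitability([layer, -layer],
                              [ResponseFunction("linear", (1.0, 0.0))] * 2)

    def test_rescaling_idempotent(self):
        rng = np.random.default_rng(4)
        layer = rng.standard_normal((10, 10))
        suit = build_suitability([layer], [ResponseFunction("linear", (2.0, 1.0))])
        v = suit.values
        again = (v - v.min()) / (v.max() - v.min())
        assert np.allclose(again, v)

    def test_invalid_response_parameters(self):
        with pytest.raises(ValueError, match="sd"):
            ResponseFunction("gaussian", (0.0, -1.0))
        with pytest.raises(ValueError, match="alpha"):
            ResponseFunction("logistic", (0.0, 0.5))
        with pytest.raises(ValueError, match="unknown"):
            ResponseFunction("quadratic", (1.0, 1.0))


class TestLogisticProbability:
    def test_midpoint_is_half(self):
        g = SuitabilityGrid(np.full((10, 10), 0.3))
        prob = logistic_probability(g, alpha=-0.05, beta=0.3)
        assert np.allclose(prob, 0.5)

    def test_one_alpha_above_beta(self):
        g = SuitabilityGrid(np.full((10, 10), 0.35))
        prob = logistic_probability(g, alpha=-0.05, beta=0.3)
        assert np.allclose(prob, 1.0 / (1.0 + np.exp(-1.0)))

    def test_steep_alpha_approaches_step(self):
        g = SuitabilityGrid(np.array([[0.2, 0.8]]))
        prob = logistic_probability(g, alpha=-1e-8, beta=0.5)
        assert prob[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert prob[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_suitability(self):
        rng = np.random.default_rng(0)
        g = SuitabilityGrid(rng.random((30, 30)))
        prob = logistic_probability(g, alpha=-0.05, beta=0.5)
        order = np.argsort(g.values.ravel())
        assert np.all(np.diff(prob.ravel()[order]) >= 0)


class TestCalibrateBeta:
    def test_symmetric_uniform_gives_half(self):
        g = SuitabilityGrid(np.linspace(0, 1, 10000).reshape(100, 100))
        beta = calibrate_beta(g, alpha=-0.05, target_prevalence=0.5)
        assert beta == pytest.approx(0.5, abs=1e-3)

    @pytest.mark.parametrize("target", [0.1, 0.25, 0.5, 0.75])
    def test_hits_study_prevalence_levels(self, target):
        rng = np.random.default_rng(8)
        g = SuitabilityGrid(rng.random((100, 100)))
        beta = calibrate_beta(g, alpha=-0.05, target_prevalence=target)
        got = float(logistic_probability(g, -0.05, beta).mean())
        assert abs(got - target) <= 1e-4

    def test_beta_decreasing_in_target(self):
        rng = np.random.default_rng(8)
        g = SuitabilityGrid(rng.random((50, 50)))
        b_low = calibrate_beta(g, target_prevalence=0.1)
        b_high = calibrate_beta(g, target_prevalence=0.75)
        assert b_low > b_high

    def test_unreachable_target_rejected(self):
        g = SuitabilityGrid(np.full((10, 10), 0.5))
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_beta(g, alpha=-0.05, target_prevalence=0.999,
                           bracket=(0.4, 0.6))


class TestRealization:
    def test_certain_presence_and_absence(self):
        assert realize_presence_absence(np.ones((5, 5))).all()
        assert not realize_presence_absence(np.zeros((5, 5))).any()

    def test_binomial_rate(self):
        pa = realize_presence_absence(np.full((100, 100), 0.3), seed=13)
        se = np.sqrt(0.3 * 0.7 / 10000)
        assert abs(pa.mean() - 0.3) <= 3 * se

    def test_deterministic(self):
        p = np.full((20, 20), 0.4)
        assert np.array_equal(realize_presence_absence(p, 7),
                              realize_presence_absence(p, 7))


class TestSamplePoints:
    def test_exhaustive_draw_returns_all(self):
        pa = np.zeros((10, 10), dtype=int)
        pa[2, 3] = pa[5, 5] = pa[7, 1] = 1
        pres, _ = sample_points(pa, 3)
        assert {tuple(p) for p in pres} == {(2, 3), (5, 5), (7, 1)}

    def test_background_excludes_presences(self):
        rng = np.random.default_rng(0)
        pa = (rng.random((30, 30)) < 0.5).astype(int)
        pres, bg = sample_points(pa, 100, 200, seed=2)
        assert not ({tuple(p) for p in pres} & {tuple(b) for b in bg})

    def test_seed_controls_sample(self):
        pa = np.ones((20, 20), dtype=int)
        a1, _ = sample_points(pa, 50, seed=1)
        a2, _ = sample_points(pa, 50, seed=1)
        b, _ = sample_points(pa, 50, seed=2)
        assert np.array_equal(a1, a2)
        assert not np.array_equal(a1, b)

    def test_insufficient_presences(self):
        with pytest.raises(ValueError, match="presence cells"):
            sample_points(np.zeros((5, 5), dtype=int), 1)

    def test_exclude_respected(self):
        pa = np.ones((5, 5), dtype=int)
        excl = [(0, 0), (0, 1)]
        pres, _ = sample_points(pa, 23, exclude=excl, seed=0)
        assert not ({tuple(p) for p in pres} & set(excl))


class TestEndToEnd:
    @pytest.mark.parametrize("target", [0.1, 0.25, 0.5, 0.75])
    def test_prevalence_control(self, target):
        sp = make_virtual_species(target_prevalence=target, seed=3)
        n = sp.suitability.n_valid
        se = np.sqrt(target * (1 - target) / n)
        assert abs(sp.realized_prevalence - target) <= 3 * se
        assert sp.suitability.valid_values.min() == 0.0
        assert sp.suitability.valid_values.max() == 1.0

    def test_reproducible(self):
        a = make_virtual_species(seed=6)
        b = make_virtual_species(seed=6)
        assert np.array_equal(a.pa_map, b.pa_map)
        assert a.beta == b.beta
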