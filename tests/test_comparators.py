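"""Comparator threshold rules and confusion-matrix machinery."""

import numpy as np
import pytest

from btqr import (apply_threshold, cohen_kappa, confusion_at,
                  select_threshold, sensitivity, specificity,
                  ConfusionMatrix, SuitabilityGrid)


def brute_criterion(method, t, p, a, g=None, prev=None):
    """Direct evaluation of each method's criterion at a threshold."""
    sens = np.mean(p >= t)
    if method == "MSS":
        return sens + np.mean(a < t)
    if method == "ESS":
        return abs(sens - np.mean(a < t))
    if method == "MaxKappa":
        return cohen_kappa(confusion_at(t, p, a))
    if method == "MinROC":
        return np.hypot(1 - sens, 1 - np.mean(a < t))
    if method == "EqualPrev":
        return abs(np.mean(g >= t) - prev)
    raise AssertionError(method)


class TestConfusion:
    def test_zero_threshold_classifies_everything_presence(self):
        cm = confusion_at(0.0, [0.2, 0.8], [0.3, 0.6])
        assert (cm.fn, cm.tn) == (0, 0)
        assert (cm.tp, cm.fp) == (2, 2)

    def test_direct_count(self):
        cm = confusion_at(0.5, [0.2, 0.8], [0.3, 0.6])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)

    def test_threshold_one_keeps_exact_ones(self):
        cm = confusion_at(1.0, [1.0, 0.99], [0.5])
        assert (cm.tp, cm.fn) == (1, 1)

    def test_empty_presences_rejected(self):
        with pytest.raises(ValueError, match="presence"):
            confusion_at(0.5, [], [0.1])


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(ConfusionMatrix(50, 0, 0, 50)) == pytest.approx(1.0)

    def test_hand_computed_closed_form(self):
        assert cohen_kappa(ConfusionMatrix(40, 10, 10, 40)) == pytest.approx(0.6)

    def test_chance_agreement(self):
        assert cohen_kappa(ConfusionMatrix(25, 25, 25, 25)) == pytest.approx(0.0)

    def test_degenerate_marginals_warn_and_zero(self):
        with pytest.warns(UserWarning, match="p_e = 1"):
            assert cohen_kappa(ConfusionMatrix(10, 0, 0, 0)) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_on_random_tables(self, seed):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(seed)
        tp, fp, fn, tn = rng.integers(1, 50, 4)
        truth = np.array([1] * (tp + fn) + [0] * (fp + tn))
        pred = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn)
        assert cohen_kappa(ConfusionMatrix(tp, fp, fn, tn)) == pytest.approx(
            cohen_kappa_score(truth, pred))


class TestSelectThreshold:
    def test_se05_nearest_rank(self):
        res = select_threshold("Se0.5", presence_preds=[0.2, 0.4, 0.6, 0.8])
        assert res.threshold == pytest.approx(0.6)
        assert res.criterion_value == pytest.approx(0.5)

    def test_meanprob_is_arithmetic_mean(self):
        res = select_threshold("MeanProb", grid_preds=[0.0, 0.5, 1.0])
        assert res.threshold == pytest.approx(0.5)

    def test_perfectly_separated_data(self):
        p, a = [0.9] * 5, [0.1] * 5
        for m in ("MSS", "ESS", "MaxKappa", "MinROC"):
            t = select_threshold(m, presence_preds=p, absence_preds=a).threshold
            assert 0.1 < t <= 0.9
            assert sensitivity(t, p) == 1.0 and specificity(t, a) == 1.0

    def test_equalprev_hits_exact_quantile(self):
        rng = np.random.default_rng(0)
        g = np.concatenate([rng.uniform(0, 0.7, 75), rng.uniform(0.7, 1, 25)])
        res = select_threshold("EqualPrev", grid_preds=g,
                               observed_prevalence=0.25)
        assert np.mean(g >= res.threshold) == pytest.approx(0.25)

    def test_missing_inputs_named(self):
        with pytest.raises(ValueError, match="absence_preds"):
            select_threshold("MSS", presence_preds=[0.5])
        with pytest.raises(ValueError, match="observed_prevalence"):
            select_threshold("EqualPrev", grid_preds=[0.5])
        with pytest.raises(ValueError, match="grid_preds"):
            select_threshold("MeanProb")

    def test_bad_sensitivity_target(self):
        with pytest.raises(ValueError, match="sensitivity target"):
            select_threshold("Se", presence_preds=[0.5], sens_target=1.5)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown method"):
            select_threshold("TSS", presence_preds=[0.5])

    @pytest.mark.parametrize("method", ["MSS", "ESS", "MaxKappa", "MinROC"])
    @pytest.mark.parametrize("seed", range(5))
    def test_optimizers_match_brute_force(self, method, seed):
        rng = np.random.default_rng(seed)
        p = rng.beta(3, 2, 40)
        a = rng.beta(2, 3, 60)
        res = select_threshold(method, presence_preds=p, absence_preds=a)
        cands = np.unique(np.concatenate([p, a, [0.0, 1.0]]))
        vals = [brute_criterion(method, t, p, a) for t in cands]
        best = max(vals) if method in ("MSS", "MaxKappa") else min(vals)
        assert res.criterion_value == pytest.approx(best)
        # smallest threshold attaining the optimum (exact-rational ties)
        opt_ts = [t for t, v in zip(cands, vals) if abs(v - best) < 1e-9]
        assert res.threshold == pytest.approx(min(opt_ts))

    def test_se_is_largest_feasible_threshold(self):
        rng = np.random.default_rng(1)
        p = rng.random(200)
        for s in (0.5, 0.75, 0.9):
            t = select_threshold(f"Se{s}", presence_preds=p).threshold
            assert sensitivity(t, p) >= s
            above = np.unique(p[p > t])
            if above.size:
                assert sensitivity(above.min(), p) < s

    def test_se_resolution_warning(self):
        with pytest.warns(UserWarning, match="cannot resolve"):
            select_threshold("Se0.9", presence_preds=[0.3, 0.7])

    def test_sensitivity_monotone_specificity_antitone(self):
        rng = np.random.default_rng(2)
        p, a = rng.random(50), rng.random(50)
        ts = np.linspace(0, 1, 21)
        sens = [sensitivity(t, p) for t in ts]
        spec = [specificity(t, a) for t in ts]
        assert np.all(np.diff(sens) <= 0)
        assert np.all(np.diff(spec) >= 0)

    def test_maxkappa_dominates_other_methods(self):
        rng = np.random.default_rng(3)
        p = rng.beta(4, 2, 100)
        a = rng.beta(2, 4, 100)
        kmax = select_threshold("MaxKappa", presence_preds=p, absence_preds=a)
        best = cohen_kappa(confusion_at(kmax.threshold, p, a))
        for m in ("MSS", "ESS", "MinROC"):
            t = select_threshold(m, presence_preds=p, absence_preds=a).threshold
            assert cohen_kappa(confusion_at(t, p, a)) <= best + 1e-12


class TestApplyThreshold:
    def test_binarises_and_preserves_nodata(self):
        vals = np.array([[0.2, 0.8], [0.6, 0.1]])
        mask = np.array([[True, True], [True, False]])
        g = SuitabilityGrid(vals, mask)
        out = apply_threshold(g, 0.6)
        assert out.tolist() == [[0, 1], [1, 0]]
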