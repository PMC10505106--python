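"""Bayes-risk losses: analytic spot values, MC oracle agreement, structure."""

import math

import autograd.numpy as anp
import numpy as np
import pytest
from autograd import grad

from edlseg import (
    AnnealingSchedule,
    ClassWeights,
    LossConfig,
    TheoremGrid,
    annealing_lambda,
    check_theorems,
    class_weights_from_labels,
    loss_ce,
    loss_dice,
    loss_edl,
    loss_kl,
    loss_ml,
    loss_mse,
    loss_wdice,
    mc_bayes_risk,
    mc_dirichlet_moments,
)
from edlseg.losses import edl_total

A11 = np.array([[1.0], [1.0]])
Y10 = np.array([[1.0], [0.0]])


def _random_instance(rng, k=None, n_voxels=None, alpha_max=8.0):
    k = int(k or rng.integers(2, 5))
    n_voxels = int(n_voxels or rng.integers(1, 5))
    alpha = rng.uniform(1.0, alpha_max, size=(k, n_voxels))
    labels = np.eye(k)[rng.integers(0, k, size=n_voxels)].T
    return alpha, labels


class TestClosedForms:
    def test_marginal_likelihood_spot_value(self):
        assert loss_ml(A11, Y10)[0] == pytest.approx(math.log(2), abs=1e-12)

    def test_cross_entropy_spot_value(self):
        # psi(2) - psi(1) = 1 by the digamma recurrence
        assert loss_ce(A11, Y10)[0] == pytest.approx(1.0, abs=1e-12)

    def test_mse_spot_value(self):
        assert loss_mse(A11, Y10)[0] == pytest.approx(2.0 / 3.0, abs=1e-12)

    @pytest.mark.parametrize("fn", [loss_ml, loss_ce, loss_mse])
    def test_perfect_evidence_limit(self, fn):
        a = np.array([[1e7], [1.0]])
        assert fn(a, Y10)[0] < 1e-5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            loss_ce(np.ones((2, 3)), np.ones((3, 3)))

    def test_losses_nonnegative_on_random_inputs(self, rng):
        for _ in range(20):
            a, y = _random_instance(rng)
            assert (loss_ml(a, y) >= -1e-12).all()
            assert (loss_ce(a, y) >= -1e-12).all()
            per_voxel_mse = loss_mse(a, y)
            assert (per_voxel_mse >= -1e-12).all()
            assert (per_voxel_mse <= 2.0).all()
            assert loss_dice(a, y) >= -1e-12


class TestRegionDice:
    def test_two_voxel_worked_example(self):
        # 2 voxels, K=2, all alpha=1, labels on opposite classes:
        # per class num=2*0.5, den=1+2*(0.25)+2*(1/12)=5/3 -> loss 0.4
        alpha = np.ones((2, 2))
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert loss_dice(alpha, y) == pytest.approx(0.4, abs=1e-4)

    def test_perfect_concentration_drives_loss_to_zero(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        alpha = np.where(y > 0, 1e7, 1.0)
        assert loss_dice(alpha, y) < 1e-4

    def test_empty_voxel_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            loss_dice(np.ones((2, 0)), np.ones((2, 0)))

    def test_moments_match_monte_carlo(self, rng):
        alpha, _ = _random_instance(rng, k=3, n_voxels=2)
        m1, m2, se1, se2 = mc_dirichlet_moments(alpha, n_samples=100_000, seed=11)
        s = alpha.sum(axis=0)
        p = alpha / s
        closed_m2 = p**2 + p * (1 - p) / (s + 1)
        assert (np.abs(m1 - p) <= 3 * se1).all()
        assert (np.abs(m2 - closed_m2) <= 3 * se2).all()

    def test_mc_sdice_mode_quantifies_expectation_gap(self):
        alpha = np.array([[4.0, 1.0], [1.0, 4.0]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        est = mc_bayes_risk(alpha, y, "sdice", n_samples=20_000, seed=5)
        # the ratio-of-expectations closed form approximates, but need not
        # equal, the expectation of the ratio
        assert abs(est.mean - loss_dice(alpha, y)) < 0.1
        again = mc_bayes_risk(alpha, y, "sdice", n_samples=20_000, seed=5)
        assert est.mean == again.mean


class TestClassWeights:
    def test_ratio_formula(self):
        y = np.zeros((2, 110))
        y[1, :10] = 1
        y[0] = 1 - y[1]
        w = class_weights_from_labels(y)
        assert w.weights[1] == pytest.approx(0.9)  # 1 - 10/100
        assert w.weights[0] == pytest.approx(1e-3)  # 1 - 100/10 clamped

    def test_zero_foreground_gives_weight_one(self):
        y = np.zeros((3, 10))
        y[0, :5] = 1
        y[2, 5:] = 1  # class 1 has no foreground anywhere
        assert class_weights_from_labels(y).weights[1] == pytest.approx(1.0)

    def test_equal_split_hits_clamp(self):
        y = np.zeros((2, 10))
        y[1, :5] = 1
        y[0] = 1 - y[1]
        assert (class_weights_from_labels(y).weights == 1e-3).all()

    def test_no_background_rejected(self):
        y = np.ones((2, 4))  # overlapping-style labels covering every voxel
        with pytest.raises(ValueError, match="zero background"):
            class_weights_from_labels(y)


class TestWeightedDice:
    def test_uniform_weights_reduce_to_dice(self, rng):
        a, y = _random_instance(rng, k=3, n_voxels=4)
        w = ClassWeights(np.ones(3))
        assert loss_wdice(a, y, w) == loss_dice(a, y)

    def test_two_voxel_example_with_unit_weights(self):
        alpha = np.ones((2, 2))
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert loss_wdice(alpha, y, ClassWeights(np.ones(2))) == pytest.approx(
            0.4, abs=1e-4
        )

    def test_upweighting_moves_loss_toward_that_class(self):
        alpha = np.array([[8.0, 1.0], [1.0, 1.5]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        from edlseg.losses import _dice_class_terms

        terms = _dice_class_terms(alpha, y, 1e-5)
        heavy0 = loss_wdice(alpha, y, ClassWeights(np.array([5.0, 1.0])))
        heavy1 = loss_wdice(alpha, y, ClassWeights(np.array([1.0, 5.0])))
        # the weighted loss is 1 - convex combination of class terms
        assert heavy0 == pytest.approx(1 - (5 * terms[0] + terms[1]) / 6)
        assert heavy1 == pytest.approx(1 - (terms[0] + 5 * terms[1]) / 6)


class TestKLRegularizer:
    def test_no_misleading_evidence_is_zero(self):
        y = np.array([[1.0], [0.0], [0.0]])
        alpha = np.array([[9.0], [1.0], [1.0]])  # adjusted params all ones
        assert loss_kl(alpha, y)[0] == pytest.approx(0.0, abs=1e-12)

    def test_binary_spot_value(self):
        # adjusted (1, 2): log 2 - 1/2
        alpha = np.array([[3.0], [2.0]])
        assert loss_kl(alpha, Y10)[0] == pytest.approx(math.log(2) - 0.5, abs=1e-12)

    def test_binary_monotone_in_wrong_evidence(self):
        values = []
        for t in (1.0, 2.0, 4.0, 8.0, 16.0):
            alpha = np.array([[1.0], [t]])
            values.append(loss_kl(alpha, Y10)[0])
        assert all(b > a for a, b in zip(values, values[1:]))


class TestAnnealing:
    @pytest.mark.parametrize("epoch, expected", [(0, 0.0), (50, 0.025), (100, 0.1), (250, 0.1)])
    def test_schedule_values(self, epoch, expected):
        assert annealing_lambda(epoch) == pytest.approx(expected)

    def test_monotone_and_capped(self):
        lams = [annealing_lambda(n) for n in range(0, 150, 5)]
        assert all(b >= a for a, b in zip(lams, lams[1:]))
        assert max(lams) == pytest.approx(0.1)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            annealing_lambda(-1)


class TestTotalObjective:
    def test_epoch_zero_is_pure_region_term(self, rng):
        a, y = _random_instance(rng)
        b = loss_edl(a, y, epoch=0)
        assert b.lambda_used == 0.0
        assert b.total == pytest.approx(loss_dice(a, y))

    def test_breakdown_recomposes(self, rng):
        for _ in range(5):
            a, y = _random_instance(rng)
            b = loss_edl(a, y, epoch=37)
            assert b.total == pytest.approx(
                b.dice_term + b.lambda_used * b.kl_term, rel=1e-12
            )
            assert b.dice_term == pytest.approx(loss_dice(a, y))
            assert b.kl_term == pytest.approx(float(np.mean(loss_kl(a, y))))

    def test_perfect_prediction_vanishes_at_any_epoch(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        alpha = np.where(y > 0, 1e7, 1.0)
        for epoch in (0, 50, 200):
            assert loss_edl(alpha, y, epoch).total < 1e-4


class TestMonteCarloOracle:
    def test_ce_spot_value(self):
        est = mc_bayes_risk(A11, Y10, "ce", n_samples=100_000, seed=2)
        assert abs(est.mean - 1.0) <= 3 * est.stderr

    def test_mse_spot_value(self):
        est = mc_bayes_risk(A11, Y10, "mse", n_samples=100_000, seed=2)
        assert abs(est.mean - 2.0 / 3.0) <= 3 * est.stderr

    def test_same_seed_is_deterministic(self):
        a = mc_bayes_risk(A11, Y10, "ce", n_samples=2_000, seed=9)
        b = mc_bayes_risk(A11, Y10, "ce", n_samples=2_000, seed=9)
        assert a.mean == b.mean and a.stderr == b.stderr

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            mc_bayes_risk(A11, Y10, "ce", n_samples=10)

    def test_unknown_base_loss_rejected(self):
        with pytest.raises(ValueError, match="unknown base loss"):
            mc_bayes_risk(A11, Y10, "hinge")


class TestTheoremSweep:
    def test_single_point_denominator_dominance(self):
        # alpha=(1,1): sDiceDen >= 1 + 0.25 > Var = 1/12
        rep = check_theorems(TheoremGrid(alpha_values=(1.0,), n_classes=(2,),
                                         voxel_counts=(1,)))
        assert rep.violations["T1"] == 0

    def test_grid_below_one_rejected(self):
        with pytest.raises(ValueError, match="alpha >= 1"):
            TheoremGrid(alpha_values=(0.5, 1.0))

    def test_data_fit_spot_check(self):
        # adding correct-class evidence lowers the region loss
        y = np.array([[1.0], [0.0]])
        l2 = loss_dice(np.array([[2.0], [1.0]]), y, smoothing=0.0)
        l3 = loss_dice(np.array([[3.0], [1.0]]), y, smoothing=0.0)
        assert l3 < l2

    def test_default_grid_oracle_result(self):
        """Frozen brute-force result: T1-T3 hold everywhere; the KL
        per-coordinate monotonicity (T4) holds for binary segmentation but
        fails for K >= 3 once another wrong-class parameter is large."""
        rep = check_theorems()
        assert rep.violations["T1"] == 0
        assert rep.violations["T2"] == 0
        assert rep.violations["T3"] == 0
        binary = check_theorems(TheoremGrid(n_classes=(2,)))
        assert binary.passed
        multi = check_theorems(TheoremGrid(n_classes=(3,)))
        assert multi.violations["T4"] > 0

    def test_kl_coordinate_nonmonotonicity_counterexample(self):
        """KL(Dir(1,64,b) || Dir(1,1,1)) dips as b grows from 1 to 16: the
        wrong-class KL penalty is not coordinate-monotone for K=3."""
        y = np.array([[1.0], [0.0], [0.0]])
        vals = [
            loss_kl(np.array([[1.0], [64.0], [b]]), y)[0]
            for b in (1.0, 2.0, 8.0, 16.0)
        ]
        assert vals[0] > vals[1] > vals[2] > vals[3]


class TestDifferentiability:
    def _fd_grad(self, f, x, eps=1e-6):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            g[i] = (f(xp) - f(xm)) / (2 * eps)
        return g

    @pytest.mark.parametrize(
        "name, make_f",
        [
            ("ml", lambda y: lambda a: anp.mean(loss_ml(a, y))),
            ("ce", lambda y: lambda a: anp.mean(loss_ce(a, y))),
            ("mse", lambda y: lambda a: anp.mean(loss_mse(a, y))),
            ("dice", lambda y: lambda a: loss_dice(a, y)),
            ("kl", lambda y: lambda a: anp.mean(loss_kl(a, y))),
            ("edl", lambda y: lambda a: edl_total(a, y, 37)),
        ],
    )
    def test_autodiff_matches_finite_differences(self, name, make_f, rng):
        alpha, y = _random_instance(rng, k=3, n_voxels=4, alpha_max=6.0)
        alpha += 0.2  # keep clear of the alpha=1 boundary
        f = make_f(y)
        g = grad(f)(alpha)
        g_fd = self._fd_grad(f, alpha)
        rel = np.abs(g - g_fd) / np.maximum(np.abs(g_fd), 1e-8)
        assert rel.max() < 1e-4
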