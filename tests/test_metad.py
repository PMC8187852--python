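"""Metadynamics: hill heights, deposition, PB combination, reweighting."""
import numpy as np
import pytest

from mmkit.dynamics import IntegratorConfig, run_trajectory
from mmkit.metad import (BiasState, MetaDConfig, deposit_hill, evaluate_bias,
                         final_bias_weights, pb_deposit, pb_total_bias,
                         run_metad, wt_hill_height)
from mmkit.systems import double_well_1d, three_well_2d

from conftest import metad_config_for


class TestWTHillHeight:
    def test_zero_bias_gives_h0(self):
        assert wt_hill_height(0.5, 0.0, 10.0, 2.83) == pytest.approx(0.5)

    def test_large_biasfactor_limit(self):
        assert wt_hill_height(1.0, 5.0, 1e9, 1.0) == pytest.approx(1.0, rel=1e-6)

    def test_hand_value(self):
        # v = 1 kT, gamma = 10: h = h0 exp(-1/9)
        assert wt_hill_height(1.0, 1.0, 10.0, 1.0) == pytest.approx(
            np.exp(-1 / 9), rel=1e-12)
        assert wt_hill_height(1.0, 1.0, 10.0, 1.0) == pytest.approx(0.8948,
                                                                    abs=1e-4)

    def test_invalid_biasfactor(self):
        with pytest.raises(ValueError):
            wt_hill_height(1.0, 0.0, 1.0, 1.0)


def joint_bias_1d(sigma=0.1, height=1.0, lo=-2.0, hi=2.0):
    sys = double_well_1d()
    cfg = MetaDConfig(cvs=(sys.cv("x"),), sigma=(sigma,), grid_min=(lo,),
                      grid_max=(hi,), mode="joint", height=height,
                      biasfactor=10.0)
    return BiasState(cfg, kT=1.0), cfg


class TestDepositAndEvaluate:
    def test_first_hill_has_height_h0(self):
        bias, cfg = joint_bias_1d(height=0.7)
        hill = deposit_hill(bias, [0.3])
        assert hill.height == pytest.approx(0.7)

    def test_bias_at_center_equals_height(self):
        # within grid-interpolation tolerance
        bias, cfg = joint_bias_1d()
        hill = deposit_hill(bias, [0.0])
        v, _ = evaluate_bias(bias, np.array([0.0]))
        assert v == pytest.approx(hill.height, rel=5e-3)

    def test_two_hills_sum_linearly(self):
        pts = np.random.default_rng(0).uniform(-1, 1, (50, 1))
        b1, _ = joint_bias_1d()
        deposit_hill(b1, [-0.5])
        v1 = evaluate_bias(b1, pts)[0]
        b2, _ = joint_bias_1d()
        deposit_hill(b2, [0.5])
        v2 = evaluate_bias(b2, pts)[0]
        both, _ = joint_bias_1d()
        deposit_hill(both, [-0.5])
        deposit_hill(both, [0.5])
        # second hill's well-tempered height differs from the fresh one only
        # through the bias at its center, which is tiny 10 sigma away
        vb = evaluate_bias(both, pts)[0]
        np.testing.assert_allclose(vb, v1 + v2, atol=1e-4)

    def test_no_hills_zero_bias_and_gradient(self):
        bias, cfg = joint_bias_1d()
        v, g = evaluate_bias(bias, np.array([0.2]))
        assert v == 0.0 and np.all(g == 0.0)

    def test_gaussian_closed_form(self):
        bias, cfg = joint_bias_1d(sigma=0.2)
        hill = deposit_hill(bias, [0.0])
        delta = 0.3
        expected = hill.height * np.exp(-delta**2 / (2 * 0.2**2))
        # direct hill summation is exact; the grid cache is exact to the
        # documented interpolation tolerance
        assert bias.direct(np.array([[delta]]))[0] == pytest.approx(
            expected, rel=1e-12)
        v, _ = evaluate_bias(bias, np.array([delta]))
        assert v == pytest.approx(expected, rel=1e-2)

    def test_gradient_consistent_with_finite_differences(self):
        # cached gradient vs finite differences of the exact hill sum:
        # agreement to the quadratic interpolation tolerance of the grid
        bias, cfg = joint_bias_1d(sigma=0.15)
        rng = np.random.default_rng(1)
        for c in rng.uniform(-1, 1, 5):
            deposit_hill(bias, [c])
        for s in rng.uniform(-0.9, 0.9, 20):
            _, g = evaluate_bias(bias, np.array([s]))
            eps = 1e-6
            fd = (bias.direct(np.array([[s + eps]]))[0]
                  - bias.direct(np.array([[s - eps]]))[0]) / (2 * eps)
            # absolute tolerance: the interpolation error of the gradient
            # cache scales with h/sigma, not with the local gradient value
            assert g[0] == pytest.approx(fd, abs=0.05)

    def test_center_outside_grid_rejected(self):
        bias, cfg = joint_bias_1d(lo=-1.0, hi=1.0)
        with pytest.raises(ValueError, match="outside grid"):
            deposit_hill(bias, [1.5])

    def test_grid_cache_equals_direct_summation_at_nodes(self):
        bias, cfg = joint_bias_1d(sigma=0.25)
        rng = np.random.default_rng(2)
        for c in rng.uniform(-1.5, 1.5, 20):
            deposit_hill(bias, [c])
        nodes = bias.joint_grid.nodes[::37][:, None]
        v_grid, _ = evaluate_bias(bias, nodes)
        v_direct = bias.direct(nodes)
        np.testing.assert_allclose(v_grid, v_direct, atol=1e-6 * cfg.height)

    def test_wt_heights_nonincreasing_at_fixed_location(self):
        bias, cfg = joint_bias_1d()
        heights = [deposit_hill(bias, [0.0]).height for _ in range(10)]
        assert all(a >= b for a, b in zip(heights, heights[1:]))


def pb_bias_2cv(kT=1.0):
    sys = three_well_2d()
    cfg = metad_config_for(sys, ["x1", "x2"], mode="pb", sigma=0.15)
    return BiasState(cfg, kT=kT), cfg


class TestParallelBias:
    def test_single_cv_reduces_to_plain_bias(self):
        sys = double_well_1d()
        cfg = MetaDConfig(cvs=(sys.cv("x"),), sigma=(0.1,), grid_min=(-2.0,),
                          grid_max=(2.0,), mode="pb", height=1.0,
                          biasfactor=10.0)
        bias = BiasState(cfg, kT=1.0)
        hills = pb_deposit(bias, [0.0])
        assert len(hills) == 1
        assert hills[0].height == pytest.approx(1.0)   # full h0, softmax = 1
        v = pb_total_bias(bias, np.array([0.3]))
        vi, _ = bias.per_cv_values(np.array([[0.3]]))
        assert v == pytest.approx(vi[0, 0], rel=1e-9)

    def test_zero_bias_two_cvs_gives_minus_kT_ln2(self):
        bias, cfg = pb_bias_2cv(kT=1.3)
        v = pb_total_bias(bias, np.array([0.0, 0.0]))
        assert v == pytest.approx(-1.3 * np.log(2.0), rel=1e-12)

    def test_total_bias_bounded_by_min_component(self):
        bias, cfg = pb_bias_2cv()
        rng = np.random.default_rng(3)
        for _ in range(15):
            pb_deposit(bias, rng.uniform(0.0, 2.0, 2))
        pts = rng.uniform(0.0, 2.0, (40, 2))
        v = pb_total_bias(bias, pts)
        Vi, _ = bias.per_cv_values(pts)
        assert np.all(v <= Vi.min(axis=1) + 1e-12)

    def test_uniform_softmax_shares_height_equally(self):
        bias, cfg = pb_bias_2cv()
        hills = pb_deposit(bias, [0.5, 0.5])
        assert hills[0].height == pytest.approx(cfg.height / 2, rel=1e-12)
        assert hills[1].height == pytest.approx(cfg.height / 2, rel=1e-12)

    def test_heavily_biased_cv_gets_smaller_share(self):
        bias, cfg = pb_bias_2cv()
        for _ in range(20):
            pb_deposit(bias, [0.5, 0.5])
        # bias on CV1 at 0.5 now exceeds bias on CV2 at a fresh location
        hills = pb_deposit(bias, [0.5, 2.5])
        assert hills[0].height < hills[1].height

    def test_softmax_shares_sum_to_one_each_deposition(self):
        bias, cfg = pb_bias_2cv()
        rng = np.random.default_rng(4)
        for _ in range(20):
            s = rng.uniform(0.2, 2.4, 2)
            Vi, _ = bias.per_cv_values(s[None, :])
            hills = pb_deposit(bias, s)
            wt = [wt_hill_height(cfg.height, Vi[0, i], cfg.biasfactor, bias.kT)
                  for i in range(2)]
            shares = [h.height / w for h, w in zip(hills, wt)]
            assert sum(shares) == pytest.approx(1.0, rel=1e-9)


class TestRunMetaD:
    def test_zero_height_reproduces_unbiased_run(self, double_well):
        cfg = metad_config_for(double_well, ["x"], mode="joint", height=0.0)
        integ = IntegratorConfig(dt=0.004, n_steps=2000, seed=9, save_stride=10)
        run = run_metad(double_well.spec, cfg, integ, n_walkers=1,
                        x0=double_well.spec.centers[0])
        ref = run_trajectory(double_well.spec, integ,
                             x0=double_well.spec.centers[0][None, :])
        np.testing.assert_allclose(run.trajectories[0].coords,
                                   ref.coords[:, 0, :], atol=1e-12)

    def test_bias_crosses_barrier_where_unbiased_does_not(self):
        # a 14 kT barrier is effectively uncrossable unbiased on this time
        # scale, while the well-tempered bias fills the well and escapes
        tall = double_well_1d(barrier_kT=14.0)
        start = tall.spec.centers[0]          # left well bottom
        integ = IntegratorConfig(dt=0.004, n_steps=60_000, seed=12,
                                 save_stride=10)
        ref = run_trajectory(tall.spec, integ, x0=start[None, :])
        assert ref.coords.max() < 0.5    # never crosses unbiased

        cfg = metad_config_for(tall, ["x"], mode="joint", sigma=0.12,
                               height=1.2, pace=100)
        run = run_metad(tall.spec, cfg, integ, n_walkers=1, x0=start)
        x = run.trajectories[0].cv_values["x"]
        assert x.max() > 0.5 and x.min() < -0.5   # visits both wells

    def test_hills_bookkeeping(self, short_dw_metad_run):
        run = short_dw_metad_run
        expected = (run.integ_cfg.n_steps // run.metad_cfg.pace) * run.n_walkers
        assert len(run.bias.hills) == expected

    def test_deposition_order_by_time_then_walker(self, short_dw_metad_run):
        times = [h.time for h in short_dw_metad_run.bias.hills]
        assert times == sorted(times)


class TestFinalBiasWeights:
    def test_constant_bias_gives_uniform_weights(self):
        bias, cfg = joint_bias_1d()
        w = final_bias_weights(np.zeros((10, 1)), bias)
        np.testing.assert_allclose(w, 0.1)

    def test_kT_ln2_difference_doubles_weight(self):
        bias, cfg = joint_bias_1d(sigma=0.3)
        # build a bias with a known value difference via direct deposit
        deposit_hill(bias, [0.0])
        sA, sB = 0.0, 3.0 * 0.3 * np.sqrt(2 * np.log(2))   # not exact; compute
        vA, _ = evaluate_bias(bias, np.array([0.0]))
        # find a point where V = vA - kT ln 2 by bisection on the Gaussian
        target = vA - np.log(2.0)
        lo_s, hi_s = 0.0, 2.0
        for _ in range(60):
            mid = 0.5 * (lo_s + hi_s)
            v, _ = evaluate_bias(bias, np.array([mid]))
            if v > target:
                lo_s = mid
            else:
                hi_s = mid
        w = final_bias_weights(np.array([[0.0], [lo_s]]), bias)
        assert w[0] / w[1] == pytest.approx(2.0, rel=1e-5)

    def test_weights_sum_to_one(self):
        bias, cfg = joint_bias_1d()
        rng = np.random.default_rng(5)
        for c in rng.uniform(-1, 1, 10):
            deposit_hill(bias, [c])
        w = final_bias_weights(rng.uniform(-1.5, 1.5, (200, 1)), bias)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w >= 0)


def test_nreff_series_uniform_when_unbiased(double_well):
    cfg = metad_config_for(double_well, ["x"], mode="joint", height=0.0)
    integ = IntegratorConfig(dt=0.004, n_steps=1000, seed=1, save_stride=10)
    run = run_metad(double_well.spec, cfg, integ, n_walkers=4)
    _, nreff = run.nreff_series()
    np.testing.assert_allclose(nreff, 4.0)
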