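"""Metainference: weights, NR_eff, sigma machinery, energies and forces."""
import numpy as np
import pytest

from mmkit.cvs import CoordinateCV, LinearCV
from mmkit.dynamics import IntegratorConfig
from mmkit.metainference import (AveragingWindow, GuinierModel, LinearCVModel,
                                 MIConfig, ObservableSet, SigmaState,
                                 effective_replicas, mc_update_sigma,
                                 mi_energy, mi_forces, relative_sem_error,
                                 replica_average, replica_weights_from_bias,
                                 run_mm, sigma_cap, sigma_sem)
from mmkit.systems import two_state_1d

from conftest import metad_config_for


class TestReplicaWeights:
    def test_equal_biases_uniform(self):
        w = replica_weights_from_bias(np.zeros(5))
        np.testing.assert_allclose(w, 0.2)

    def test_hand_value(self):
        w = replica_weights_from_bias(np.array([0.0, np.log(2.0)]), kT=1.0)
        np.testing.assert_allclose(w, [1 / 3, 2 / 3], rtol=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        V = rng.uniform(-3, 3, 8)
        np.testing.assert_allclose(replica_weights_from_bias(V),
                                   replica_weights_from_bias(V + 17.0),
                                   rtol=1e-12)

    def test_window_history_averaged(self):
        hist = np.array([[0.0, 2.0], [1.0, 1.0]])   # (NR=2, window m=2)
        w = replica_weights_from_bias(hist, kT=1.0)
        np.testing.assert_allclose(w, 0.5)           # equal window means


class TestEffectiveReplicas:
    def test_hand_values(self):
        assert effective_replicas(np.full(10, 0.1)) == pytest.approx(10.0)
        assert effective_replicas([1 / 3, 2 / 3]) == pytest.approx(1.8)
        assert effective_replicas([0.0, 0.7, 0.0]) == pytest.approx(1.0)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            w = rng.uniform(0, 1, rng.integers(2, 20))
            nr = effective_replicas(w)
            assert 1.0 - 1e-12 <= nr <= len(w) + 1e-12


class TestReplicaAverage:
    def test_uniform_weights_arithmetic_mean(self):
        f = np.array([[1.0], [2.0], [3.0]])
        assert replica_average(f, np.ones(3))[0] == pytest.approx(2.0)

    def test_degenerate_weight(self):
        f = np.array([[3.0], [7.0]])
        assert replica_average(f, [1.0, 0.0])[0] == pytest.approx(3.0)

    def test_constant_values(self):
        f = np.full((4, 3), 2.5)
        rng = np.random.default_rng(2)
        np.testing.assert_allclose(replica_average(f, rng.uniform(0, 1, 4)),
                                   2.5)


class TestSigmaSEM:
    def test_identical_replicas_zero(self):
        f = np.full((5, 2), 1.0)
        np.testing.assert_allclose(sigma_sem(f, np.ones(5)), 0.0)

    def test_two_replica_hand_value(self):
        f = np.array([[0.0], [2.0]])
        assert sigma_sem(f, np.ones(2))[0] == pytest.approx(1.0)

    def test_nreff_of_one_rejected(self):
        f = np.array([[0.0], [2.0]])
        with pytest.raises(ValueError, match="NR_eff"):
            sigma_sem(f, [1.0, 0.0])

    def test_window_max_dominates_instantaneous(self):
        win = AveragingWindow(length=5, n_replicas=3, n_data=2)
        rng = np.random.default_rng(3)
        sems = rng.uniform(0, 1, (5, 2))
        for s in sems:
            win.push(np.zeros(3), s)
        np.testing.assert_array_equal(win.max_sem(), sems.max(axis=0))
        assert np.all(win.max_sem()[None, :] >= sems - 1e-15)


class TestSigmaCap:
    def test_hand_value(self):
        assert sigma_cap(1.0, 4) == pytest.approx(2.0)

    def test_single_replica_cap_equals_sem(self):
        assert sigma_cap(0.7, 1) == pytest.approx(0.7)

    def test_linear_in_sem(self):
        np.testing.assert_allclose(sigma_cap(np.array([1.0, 2.0]), 9),
                                   [3.0, 6.0])


class TestMIEnergy:
    def test_zero_residual_zero_data_term(self):
        e = mi_energy(f_avg=[1.0], d=[1.0], lam=1.0, sigma_b=[[0.5]],
                      sem=[0.1], include_esigma=False)
        assert e.data == pytest.approx(0.0)

    def test_hand_value(self):
        # kT=1, one replica, one datum, residual 1, sigma_B=1, sigma_SEM=0
        e = mi_energy(f_avg=[0.0], d=[1.0], lam=1.0, sigma_b=[[1.0]],
                      sem=[0.0], include_esigma=False)
        assert e.data == pytest.approx(0.5)

    def test_decreasing_in_sigma_b(self):
        vals = [mi_energy([0.0], [1.0], 1.0, [[s]], [0.0],
                          include_esigma=False).data
                for s in (0.5, 1.0, 2.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_replica_permutation_invariance(self):
        rng = np.random.default_rng(4)
        sb = rng.uniform(0.5, 2.0, (4, 3))
        e1 = mi_energy([0.2, 0.4, 0.6], [0.3, 0.3, 0.3], 1.0, sb, [0.1, 0.1, 0.1])
        e2 = mi_energy([0.2, 0.4, 0.6], [0.3, 0.3, 0.3], 1.0, sb[::-1],
                       [0.1, 0.1, 0.1])
        assert e1.total == pytest.approx(e2.total)

    def test_total_is_sum_of_parts(self):
        e = mi_energy([0.0], [1.0], 1.0, [[1.0]], [0.5], e_ff=2.0)
        assert e.total == pytest.approx(e.forcefield + e.data + e.esigma)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            mi_energy([0.0], [1.0], 1.0, [[0.0]], [0.0])


class TestMIForces:
    def test_zero_residual_zero_force(self):
        model = LinearCVModel(CoordinateCV(0, name="x"))
        X = np.array([[1.5]])
        F = mi_forces(X, model, d=[1.5], lam=1.0, sigma_b=[[1.0]], sem=[0.0],
                      weights=[1.0])
        np.testing.assert_allclose(F, 0.0, atol=1e-14)

    def test_single_replica_harmonic_form(self):
        # f = x, lambda = 1: force = -kT (x - d)/(sigma_B^2 + sigma_SEM^2)
        model = LinearCVModel(CoordinateCV(0, name="x"))
        x, d, sb, sem, kT = 1.7, 1.0, 0.8, 0.3, 1.3
        F = mi_forces(np.array([[x]]), model, [d], 1.0, [[sb]], [sem], [1.0],
                      kT=kT)
        assert F[0, 0] == pytest.approx(-kT * (x - d) / (sb**2 + sem**2))

    @pytest.mark.parametrize("seed", range(4))
    def test_finite_difference_agreement(self, seed):
        # gradient of the data term through <f> and the forward model, with
        # replica weights held constant
        rng = np.random.default_rng(seed)
        NR, dim = 3, 2
        size_cv = LinearCV([0.3, -0.2], intercept=1.2, name="size")
        model = GuinierModel(np.linspace(0.1, 1.2, 5), size_cv)
        X = rng.uniform(-1, 1, (NR, dim))
        d = rng.uniform(0.3, 0.9, 5)
        sb = rng.uniform(0.3, 1.0, (NR, 5))
        sem = rng.uniform(0.05, 0.2, 5)
        w = rng.uniform(0.2, 1.0, NR)
        lam, kT = 1.0, 1.0
        F = mi_forces(X, model, d, lam, sb, sem, w, kT=kT)

        def data_term(Xp):
            favg = replica_average(model.values(Xp), w)
            return mi_energy(favg, d, lam, sb, sem, kT=kT,
                             include_esigma=False).data

        eps = 1e-6
        for r in range(NR):
            for c in range(dim):
                Xp = X.copy(); Xp[r, c] += eps
                Xm = X.copy(); Xm[r, c] -= eps
                fd = -(data_term(Xp) - data_term(Xm)) / (2 * eps)
                assert F[r, c] == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestMCUpdateSigma:
    def make_state(self, NR=2, Nd=3, val=0.5):
        return SigmaState(sigma_b=np.full((NR, Nd), val),
                          sigma_sem=np.full(Nd, 0.4),
                          sigma_min=np.full(Nd, 1e-4),
                          step_size=np.full(Nd, 0.2))

    def test_proposals_outside_bounds_rejected(self):
        state = self.make_state()
        cap = sigma_cap(state.sigma_sem, state.n_replicas)
        rng = np.random.default_rng(5)
        for _ in range(200):
            mc_update_sigma(state, np.zeros(3), 1.0, rng)
        assert np.all(state.sigma_b > 1e-4)
        assert np.all(state.sigma_b <= cap[None, :] + 1e-15)

    def test_zero_residual_drifts_to_lower_bound(self):
        # data term vanishes; likelihood normalization + Jeffreys prior
        # favor small sigma
        state = self.make_state(val=0.5)
        rng = np.random.default_rng(6)
        for _ in range(3000):
            mc_update_sigma(state, np.zeros(3), 1.0, rng)
        assert np.median(state.sigma_b) < 0.05

    def test_fixed_seed_reproducible(self):
        s1 = self.make_state()
        s2 = self.make_state()
        r1 = np.random.default_rng(7)
        r2 = np.random.default_rng(7)
        for _ in range(50):
            mc_update_sigma(s1, np.full(3, 0.3), 1.0, r1)
            mc_update_sigma(s2, np.full(3, 0.3), 1.0, r2)
        np.testing.assert_array_equal(s1.sigma_b, s2.sigma_b)
        assert s1.n_accept == s2.n_accept


class TestRelativeSEMError:
    def test_values_and_flags(self):
        rel, flags = relative_sem_error([0.0, 0.05, 0.099, 0.101],
                                        [1.0, 1.0, 1.0, 1.0])
        np.testing.assert_allclose(rel, [0.0, 5.0, 9.9, 10.1])
        np.testing.assert_array_equal(flags, [False, False, False, True])

    def test_zero_datum_excluded_and_flagged(self):
        rel, flags = relative_sem_error([0.1], [0.0])
        assert np.isnan(rel[0]) and flags[0]


@pytest.fixture(scope="module")
def mm_setup():
    ref = two_state_1d((0.5, 0.5))
    prior = two_state_1d((0.8, 0.2))
    model = GuinierModel(np.linspace(0.05, 1.39, 8), ref.size_cv)
    from mmkit.potentials import make_reference_dataset

    refdata = make_reference_dataset(ref.spec, model,
                                     partition_cv=ref.partition_cv,
                                     partition=ref.partition)
    obs = ObservableSet(ids=model.ids, d=refdata.d, model=model, stride=2)
    cfg = metad_config_for(prior, ["x"], mode="pb", sigma=0.12, pace=250)
    return prior, cfg, obs


class TestRunMM:
    def test_no_bias_gives_uniform_replica_weights(self, mm_setup):
        prior, cfg, obs = mm_setup
        from dataclasses import replace

        cfg0 = replace(cfg, height=0.0)
        integ = IntegratorConfig(dt=0.004, n_steps=3000, seed=3, save_stride=10)
        mi = MIConfig(n_replicas=4, averaging=250)
        run = run_mm(prior.spec, cfg0, integ, obs, mi)
        np.testing.assert_allclose(run.nreff, 4.0)

    def test_restraint_pulls_average_toward_targets(self, mm_setup):
        prior, cfg, obs = mm_setup
        integ = IntegratorConfig(dt=0.004, n_steps=40_000, seed=4,
                                 save_stride=20)
        mi = MIConfig(n_replicas=8, averaging=250)
        rng = np.random.default_rng(4)
        x0 = prior.start_points(8, rng, populations=(0.8, 0.2))
        run = run_mm(prior.spec, cfg, integ, obs, mi, x0=x0)
        favg = run.restrained_average(discard_frac=0.3)
        # restrained replica-average profile close to target within the
        # model-error scale
        tol = 3 * np.sqrt(run.final_sem() ** 2 + run.sigma.sigma_b.mean() ** 2)
        assert np.all(np.abs(favg - obs.d) <= tol + 0.05)

    def test_sigma_b_capped_by_sem_times_sqrt_nr(self, mm_setup):
        prior, cfg, obs = mm_setup
        integ = IntegratorConfig(dt=0.004, n_steps=5000, seed=5, save_stride=20)
        mi = MIConfig(n_replicas=4, averaging=250)
        run = run_mm(prior.spec, cfg, integ, obs, mi)
        cap = sigma_cap(run.sigma.sigma_sem, 4)
        assert np.all(run.sigma.sigma_b <= cap[None, :] * (1 + 1e-9))

    def test_more_replicas_give_smaller_relative_sem_error(self, mm_setup):
        prior, cfg, obs = mm_setup
        errs = {}
        for NR in (2, 12):
            integ = IntegratorConfig(dt=0.004, n_steps=30_000, seed=6,
                                     save_stride=20)
            mi = MIConfig(n_replicas=NR, averaging=250)
            rng = np.random.default_rng(6)
            x0 = prior.start_points(NR, rng, populations=(0.8, 0.2))
            run = run_mm(prior.spec, cfg, integ, obs, mi, x0=x0)
            errs[NR] = run.mean_relative_sem_error()
        assert errs[12] < errs[2]
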