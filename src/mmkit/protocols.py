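"""End-to-end study protocols: the package's headline experiments.

Each function runs one self-contained experiment from scratch — building the
toy system, sampling, analyzing — and returns a dict of the numbers a study
would report.  `scripts/acceptance.py` and the validation test suite both
call these, so the reported values and the tested values are produced by the
same code path.  All randomness derives from the `seed` argument.

Default problem sizes are the package's study conditions (see
docs/methods.md): large enough to resolve each effect comfortably on a
single core.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import binomtest

from . import systems
from .cvopt import StateSummary, optimize_weights, psi_score_multistate
from .dynamics import IntegratorConfig
from .metad import MetaDConfig, default_grid_range, run_metad
from .metainference import GuinierModel, MIConfig, ObservableSet, run_mm
from .potentials import (analytic_marginal_fes, make_reference_dataset,
                         quadrature_state_populations)
from .stats import (block_error_curve, replicate_average_populations, rfactor,
                    state_populations, weighted_block_error, weighted_fes)

__all__ = [
    "fes_recovery",
    "triplicate_populations",
    "cv_optimizer_benchmark",
    "block_error_calibration",
    "mm_correction",
    "pb_vs_joint_ordering",
]


def _metad_cfg(system, cv_names, mode, sigma, height, pace, biasfactor=10.0):
    cvs = tuple(system.cv(n) for n in cv_names)
    ranges = [default_grid_range(system.spec, cv) for cv in cvs]
    return MetaDConfig(
        cvs=cvs, sigma=tuple(np.broadcast_to(sigma, len(cvs))),
        grid_min=tuple(r[0] for r in ranges),
        grid_max=tuple(r[1] for r in ranges),
        mode=mode, height=height, pace=pace, biasfactor=biasfactor,
    )


def fes_recovery(seed: int, n_steps: int = 2_000_000) -> dict:
    """Well-tempered MetaD free-energy recovery on the 8 kT double well.

    One walker, bias factor 10, final-bias reweighting; the recovered
    profile is compared with the quadrature truth on all bins below 5 kT.

    The accuracy of this estimate at a fixed step count is limited by the
    number of independent traversals of the bias-flattened landscape, so the
    protocol maximizes simulated time per step: a large time step under the
    predictor-corrector (Heun) scheme, whose stationary-density error is
    second order and stays negligible at k·dt ~ 0.1, with small frequent
    hills (h0 = 0.2 kT, sigma = 0.2, every 30 steps) keeping the deposition
    gentle.
    """
    dw = systems.double_well_1d(barrier_kT=8.0)
    x = dw.cv("x")
    cfg = _metad_cfg(dw, ["x"], "joint", sigma=0.2, height=0.2, pace=30)
    integ = IntegratorConfig(dt=0.012, n_steps=n_steps, seed=seed,
                             save_stride=20, scheme="heun")
    run = run_metad(dw.spec, cfg, integ, n_walkers=1)
    edges = np.linspace(-3.2, 3.2, 49)
    truth = analytic_marginal_fes(dw.spec, x, edges)
    w = run.frame_weights(discard_frac=0.25)
    vals = run.cv_series()[:, 0]
    keep = w > 0
    fes = weighted_fes(vals[keep], w[keep], edges, n_blocks=10)
    err = np.abs(fes.free_energy - truth.free_energy)
    mask = truth.free_energy < 5.0
    err[~mask] = np.nan
    return {
        "max_abs_error_kT": float(np.nanmax(err)),
        "n_bins_checked": int(mask.sum()),
        "nf_eff_fraction": run.nf_eff_fraction(0.25),
        "n_steps": n_steps,
    }


def triplicate_populations(seed: int, n_steps: int = 150_000,
                           n_walkers: int = 4) -> dict:
    """Three seeded PBMetaD runs of the 2D three-well system.

    Each run yields reweighted state populations with block errors; the
    triplicate average is compared with the quadrature truth using the
    combined (replicate + block) uncertainty per state.
    """
    tw = systems.three_well_2d()
    truth = quadrature_state_populations(tw.spec, tw.partition_cv, tw.partition)
    cfg = _metad_cfg(tw, ["x1", "x2"], "pb", sigma=0.15, height=1.0, pace=250)
    pops_runs, errs_runs = [], []
    for rep in range(3):
        integ = IntegratorConfig(dt=0.003, n_steps=n_steps, seed=seed + rep,
                                 save_stride=20)
        rng = np.random.default_rng(seed + rep)
        run = run_metad(tw.spec, cfg, integ, n_walkers=n_walkers,
                        x0=tw.start_points(n_walkers, rng))
        w = run.frame_weights(discard_frac=0.25)
        keep = w > 0
        vals = run.observable(tw.partition_cv)
        df = state_populations(vals[keep], w[keep], tw.partition, n_blocks=10)
        pops_runs.append(df.population.to_numpy())
        errs_runs.append(df.error.to_numpy())
    avg = replicate_average_populations(pops_runs)
    block_mean = np.mean(errs_runs, axis=0)
    combined = np.sqrt(avg.error.to_numpy() ** 2 + (block_mean / np.sqrt(3)) ** 2)
    combined = np.maximum(combined, 1e-6)
    truth_vec = np.array([truth[l] for l in tw.partition.labels])
    dev = np.abs(avg.population.to_numpy() - truth_vec) / combined
    return {
        "labels": list(tw.partition.labels),
        "per_run_populations": [p.tolist() for p in pops_runs],
        "per_run_block_errors": [e.tolist() for e in errs_runs],
        "average_populations": avg.population.to_numpy().tolist(),
        "combined_errors": combined.tolist(),
        "truth": truth_vec.tolist(),
        "max_deviation_sigmas": float(dev.max()),
        "n_frames_per_run": n_walkers * (n_steps // 20),
    }


def cv_optimizer_benchmark(seed: int, n_instances: int = 20) -> dict:
    """The combination-CV optimizer against closed form and grid search.

    The closed-form instance (state means 4 apart on CV1, unit covariance)
    has its stationary point at a1² = 1/(1+e⁻⁸); random two-state N = 2
    instances are checked against a dense scan of the unit circle.
    """
    s1 = StateSummary("1", np.zeros(2), np.eye(2), 100)
    s2 = StateSummary("2", np.array([4.0, 0.0]), np.eye(2), 100)
    w, _ = optimize_weights([s1, s2], n_starts=12, seed=seed)
    a1sq = float(w.a[0] ** 2)

    rng = np.random.default_rng(seed)
    thetas = np.linspace(0, np.pi, 31416, endpoint=False)
    circle = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
    max_dtheta = 0.0
    for _ in range(n_instances):
        def rand_cov():
            A = rng.standard_normal((2, 2))
            return A @ A.T + 0.3 * np.eye(2)

        t1 = StateSummary("1", rng.uniform(-2, 2, 2), rand_cov(), 100)
        t2 = StateSummary("2", rng.uniform(-2, 2, 2), rand_cov(), 100)
        wi, sc = optimize_weights([t1, t2], n_starts=12, seed=seed)
        vals = np.array([psi_score_multistate(a, [t1, t2]).total
                         for a in circle])
        t_best = thetas[np.argmin(vals)]
        t_w = np.arctan2(wi.a[1], wi.a[0]) % np.pi
        d = abs(t_w - t_best)
        max_dtheta = max(max_dtheta, min(d, np.pi - d))
    return {
        "closed_form_a1_sq": a1sq,
        "closed_form_expected": 1.0 / (1.0 + np.exp(-8.0)),
        "max_angle_deviation_rad": float(max_dtheta),
        "n_instances": n_instances,
    }


def block_error_calibration(seed: int, n_iid: int = 10_000,
                            n_ar1: int = 500_000) -> dict:
    """Weighted block errors against analytic standard errors of the mean.

    i.i.d. unit normals with equal weights should match sigma/sqrt(N); an
    AR(1) series with phi = 0.9 should plateau at the tau-inflated SEM
    sqrt((1+phi)/(1-phi))/sqrt(N); and substituting NB for NB_eff on an
    unbalanced-weight fixture must shrink the estimate.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_iid)
    iid_est = weighted_block_error(x, np.ones(n_iid), 100)
    iid_true = 1.0 / np.sqrt(n_iid)

    phi = 0.9
    eps = rng.standard_normal(n_ar1)
    y = np.empty(n_ar1)
    y[0] = eps[0]
    for i in range(1, n_ar1):
        y[i] = phi * y[i - 1] + eps[i]
    y *= np.sqrt(1 - phi**2)
    curve = block_error_curve(y, np.ones(n_ar1), [10, 100, 1000, 5000, 10_000])
    ar1_true = np.sqrt((1 + phi) / (1 - phi)) / np.sqrt(n_ar1)

    z = rng.standard_normal(1000)
    wz = np.ones(1000)
    wz[:100] = 50.0
    nb = 10
    err_nbeff = weighted_block_error(z, wz, nb)
    W = np.array([wz[i * 100:(i + 1) * 100].sum() for i in range(nb)])
    means = np.array([np.average(z[i * 100:(i + 1) * 100],
                                 weights=wz[i * 100:(i + 1) * 100])
                      for i in range(nb)])
    grand = np.average(means, weights=W)
    err_nb = np.sqrt(np.sum(W * (means - grand) ** 2) / W.sum() / (nb - 1))

    return {
        "iid_ratio": float(iid_est / iid_true),
        "ar1_plateau_ratio": float(curve.plateau_value / ar1_true),
        "nb_underestimates": bool(err_nb < err_nbeff),
        "nb_over_nbeff_ratio": float(err_nb / err_nbeff),
        "n_iid": n_iid,
        "n_ar1": n_ar1,
    }


def mm_correction(seed: int, n_steps: int = 200_000,
                  replica_counts=(16, 2)) -> dict:
    """Metainference correction of a biased prior toward reference data.

    Prior: two-state system at 80/20.  Targets: 24 Guinier-like intensities
    of the 50/50 reference ensemble (quadrature).  A prior-only PBMetaD run
    (10 walkers) sets the baseline R-factor; M&M runs with each replica
    count measure the corrected populations, the mean relative sigma_SEM
    error and the restrained R-factor.
    """
    ref_sys = systems.two_state_1d((0.5, 0.5))
    prior_sys = systems.two_state_1d((0.8, 0.2))
    model = GuinierModel(systems.saxs_q_grid(), ref_sys.size_cv)
    ref = make_reference_dataset(ref_sys.spec, model,
                                 partition_cv=ref_sys.partition_cv,
                                 partition=ref_sys.partition)
    obs = ObservableSet(ids=model.ids, d=ref.d, model=model, stride=2)
    cfg = _metad_cfg(prior_sys, ["x"], "pb", sigma=0.15, height=1.0, pace=250)

    integ = IntegratorConfig(dt=0.004, n_steps=n_steps, seed=seed,
                             save_stride=20)
    rng = np.random.default_rng(seed)
    prior = run_metad(prior_sys.spec, cfg, integ, n_walkers=10,
                      x0=prior_sys.start_points(10, rng, populations=(0.8, 0.2)))
    w = prior.frame_weights(discard_frac=0.25)
    keep = w > 0
    vals = prior.observable(prior_sys.partition_cv)
    prior_pops = state_populations(vals[keep], w[keep], prior_sys.partition)
    I_prior = w @ model.values(prior.coords())
    out = {
        "target_folded_pct": 100.0 * ref.populations["folded"],
        "prior_folded_pct": 100.0 * float(prior_pops.population[0]),
        "rfactor_prior_pct": rfactor(I_prior, ref.d),
        "n_steps": n_steps,
        "runs": {},
    }
    for NR in replica_counts:
        mi = MIConfig(n_replicas=NR, averaging=cfg.pace)
        integ_r = IntegratorConfig(dt=0.004, n_steps=n_steps,
                                   seed=seed + 100 + NR, save_stride=20)
        rng_r = np.random.default_rng(seed + 100 + NR)
        x0 = prior_sys.start_points(NR, rng_r, populations=(0.8, 0.2))
        mm = run_mm(prior_sys.spec, cfg, integ_r, obs, mi, x0=x0)
        wr = mm.frame_weights(discard_frac=0.25)
        keepr = wr > 0
        valsr = mm.observable(prior_sys.partition_cv)
        pops = state_populations(valsr[keepr], wr[keepr], prior_sys.partition)
        out["runs"][NR] = {
            "folded_pct": 100.0 * float(pops.population[0]),
            "mean_relative_sem_error_pct": mm.mean_relative_sem_error(),
            "nreff_cumavg": float(mm.nreff_cumulative()[-1]),
            "rfactor_pct": rfactor(mm.restrained_average(), ref.d),
        }
    return out


def pb_vs_joint_ordering(seed: int, n_pairs: int = 8,
                         n_steps: int = 50_000) -> dict:
    """Parallel-bias vs joint-CV MetaD: effective-statistics ordering.

    Matched seed pairs on the three-well system, both modes biasing
    (x1, x2) at equal bias factor.  The joint 2D bias explores more of the
    CV plane and spreads the frame/replica weights further, so PB should
    win on both NF_eff fraction and mean NR_eff; one-sided sign tests
    quantify that.
    """
    tw = systems.three_well_2d()
    wins_nf = wins_nr = 0
    nf = {"pb": [], "joint": []}
    nr = {"pb": [], "joint": []}
    for k in range(n_pairs):
        res = {}
        for mode in ("pb", "joint"):
            cfg = _metad_cfg(tw, ["x1", "x2"], mode, sigma=0.15, height=1.0,
                             pace=250)
            integ = IntegratorConfig(dt=0.003, n_steps=n_steps,
                                     seed=seed + 1000 + k, save_stride=20)
            rng = np.random.default_rng(seed + 1000 + k)
            run = run_metad(tw.spec, cfg, integ, n_walkers=4,
                            x0=tw.start_points(4, rng))
            _, nreff = run.nreff_series()
            res[mode] = (run.nf_eff_fraction(0.25),
                         float(nreff[len(nreff) // 2:].mean()))
            nf[mode].append(res[mode][0])
            nr[mode].append(res[mode][1])
        wins_nf += res["pb"][0] > res["joint"][0]
        wins_nr += res["pb"][1] > res["joint"][1]
    return {
        "n_pairs": n_pairs,
        "nf_eff_wins": int(wins_nf),
        "nr_eff_wins": int(wins_nr),
        "nf_eff_sign_p": float(binomtest(wins_nf, n_pairs,
                                         alternative="greater").pvalue),
        "nr_eff_sign_p": float(binomtest(wins_nr, n_pairs,
                                         alternative="greater").pvalue),
        "mean_nf_eff_fraction_pb": float(np.mean(nf["pb"])),
        "mean_nf_eff_fraction_joint": float(np.mean(nf["joint"])),
        "mean_nr_eff_pb": float(np.mean(nr["pb"])),
        "mean_nr_eff_joint": float(np.mean(nr["joint"])),
    }
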