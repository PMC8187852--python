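"""Gaussian-noise metainference over weighted replicas, coupled to MetaD.

Metainference restrains an ensemble of NR replicas against Nd experimental
(or synthetic) data d by comparing them with replica-averaged forward-model
predictions.  The restraint energy is

    E_MI = E_FF + (kT/2) Σ_i Σ_r (d_i - λ⟨f_i(X)⟩)² / ((σ_B[r,i])² + (σ_SEM[i])²) + E_σ

where ⟨f_i(X)⟩ = Σ_r w_r f_i(X_r) / Σ_r w_r is the weighted replica average,
σ_B[r,i] are sampled uncertainty parameters (random/systematic errors),
σ_SEM[i] is the standard error of the mean from conformational averaging,
λ an optional scaling (fixed at 1 by default), and E_σ collects the Gaussian
likelihood normalization plus a Jeffreys prior on σ_B.

When the replicas double as metadynamics walkers (M&M), each replica r
carries an on-the-fly weight w_r ∝ exp(V̄_G(CV(X_r))/kT) with V̄ a moving
average of the bias over an AVERAGING window; the effective replica count is
NR_eff = (Σ w_r)²/Σ w_r².  σ_SEM is the weighted SEM over replicas, reported
as its maximum over the same window, and σ_B is capped at σ_SEM·√NR (the
cap that converts a standard error of the mean back to a single-replica
scale).  The relative error 100·σ_SEM/|d_i| diagnoses whether NR_eff is
large enough to capture the conformational heterogeneity behind datum i.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import IntegratorConfig, Trajectory, default_start
from .metad import (BiasState, MetaDConfig, MetaDRun, _NOISE_CHUNK, _CVMap,
                    _ForceField, _clip_to_grid, _warn_if_clamped,
                    deposit_hill, pb_deposit)
from .potentials import PotentialSpec

__all__ = [
    "ObservableSet",
    "SigmaState",
    "AveragingWindow",
    "MIEnergyBreakdown",
    "MIConfig",
    "MMRun",
    "GuinierModel",
    "LinearCVModel",
    "replica_weights_from_bias",
    "effective_replicas",
    "replica_average",
    "sigma_sem",
    "sigma_cap",
    "mi_energy",
    "mi_forces",
    "mc_update_sigma",
    "relative_sem_error",
    "run_mm",
]

logger = logging.getLogger(__name__)

SIGMA_MIN_FRAC = 1e-6   # sigma_B lower bound as a fraction of |d_i|


# ---------------------------------------------------------------------------
# forward models


class GuinierModel:
    """Guinier-like intensity f_q(X) = exp(-q² s(X)²/3) on a size CV s.

    The stand-in for small-angle scattering intensities: sensitive to the
    overall size of the conformation, evaluated on a grid of scattering
    angles q.
    """

    def __init__(self, q, size_cv):
        self.q = np.atleast_1d(np.asarray(q, dtype=float))
        self.size_cv = size_cv
        self.ids = tuple(f"q_{qi:.4f}" for qi in self.q)

    @property
    def n_data(self) -> int:
        return len(self.q)

    def values(self, x) -> np.ndarray:
        """(n, dim) -> (n, Nd)."""
        s = np.atleast_1d(self.size_cv.value(x))
        return np.exp(-np.outer(s**2, self.q**2) / 3.0)

    def grads(self, x) -> np.ndarray:
        """(n, dim) -> (n, Nd, dim)."""
        x2 = np.atleast_2d(np.asarray(x, dtype=float))
        s = np.atleast_1d(self.size_cv.value(x2))
        f = np.exp(-np.outer(s**2, self.q**2) / 3.0)
        ds = np.atleast_2d(self.size_cv.gradient(x2))
        pref = f * (-2.0 / 3.0) * np.outer(s, self.q**2)
        return pref[:, :, None] * ds[:, None, :]


class LinearCVModel:
    """Identity/linear forward model f(X) = coeff · cv(X) + offset (Nd = 1)."""

    def __init__(self, cv, coeff: float = 1.0, offset: float = 0.0):
        self.cv = cv
        self.coeff = float(coeff)
        self.offset = float(offset)
        self.ids = (cv.name,)

    @property
    def n_data(self) -> int:
        return 1

    def values(self, x) -> np.ndarray:
        v = np.atleast_1d(self.cv.value(x))
        return (self.coeff * v + self.offset)[:, None]

    def grads(self, x) -> np.ndarray:
        g = np.atleast_2d(self.cv.gradient(x))
        return self.coeff * g[:, None, :]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class ObservableSet:
    """Target data d_i with their forward model and restraint stride."""

    ids: tuple
    d: np.ndarray
    model: object
    stride: int = 2   # restraint applied every `stride` MD steps

    def __post_init__(self):
        d = np.atleast_1d(np.asarray(self.d, dtype=float))
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "ids", tuple(self.ids))
        if len(self.ids) != len(d) or len(d) < 1:
            raise ValueError("need one id per datum and at least one datum")
        if self.stride < 1:
            raise ValueError("restraint stride must be >= 1")

    @property
    def n_data(self) -> int:
        return len(self.d)


@dataclass
class SigmaState:
    """Per-(replica, datum) σ_B with caps, MC step sizes and counters."""

    sigma_b: np.ndarray          # (NR, Nd)
    sigma_sem: np.ndarray        # (Nd,)
    lam: float = 1.0
    sigma_min: np.ndarray | None = None
    step_size: np.ndarray | None = None   # (Nd,), MC proposal half-widths
    n_accept: int = 0
    n_trial: int = 0

    def __post_init__(self):
        self.sigma_b = np.atleast_2d(np.asarray(self.sigma_b, dtype=float))
        self.sigma_sem = np.atleast_1d(np.asarray(self.sigma_sem, dtype=float))
        if self.lam <= 0:
            raise ValueError("scaling parameter lambda must be positive")
        if np.any(self.sigma_b <= 0):
            raise ValueError("sigma_B must be positive")
        if np.any(self.sigma_sem < 0):
            raise ValueError("sigma_SEM must be non-negative")

    @property
    def n_replicas(self) -> int:
        return self.sigma_b.shape[0]

    @property
    def acceptance_rate(self) -> float:
        return self.n_accept / self.n_trial if self.n_trial else float("nan")


class AveragingWindow:
    """Ring buffers for the AVERAGING window: bias history and σ_SEM history.

    Replica weights use the moving average of the bias over the window;
    the reported σ_SEM is the maximum instantaneous value over the window.
    """

    def __init__(self, length: int, n_replicas: int, n_data: int):
        if length < 1:
            raise ValueError("window length must be >= 1")
        self.length = int(length)
        self._bias = np.zeros((self.length, n_replicas))
        self._sem = np.zeros((self.length, n_data))
        self._n = 0
        self._i = 0

    @property
    def n_filled(self) -> int:
        return min(self._n, self.length)

    def push(self, bias_values: np.ndarray, sem_values: np.ndarray | None = None):
        self._bias[self._i] = bias_values
        if sem_values is not None:
            self._sem[self._i] = sem_values
        self._i = (self._i + 1) % self.length
        self._n += 1

    def mean_bias(self) -> np.ndarray:
        k = self.n_filled
        if k == 0:
            raise ValueError("averaging window is empty")
        return self._bias[:k].mean(axis=0)

    def max_sem(self) -> np.ndarray:
        k = self.n_filled
        if k == 0:
            raise ValueError("averaging window is empty")
        return self._sem[:k].max(axis=0)


@dataclass(frozen=True)
class MIEnergyBreakdown:
    """E_MI = E_FF + data term + E_σ."""

    forcefield: float
    data: float
    esigma: float

    @property
    def total(self) -> float:
        return self.forcefield + self.data + self.esigma


# ---------------------------------------------------------------------------
# core formulas


def replica_weights_from_bias(bias_history, kT: float = 1.0) -> np.ndarray:
    """Normalized replica weights w_r ∝ exp(V̄_r/kT).

    ``bias_history`` is either a (NR,) vector of window-averaged bias values
    or an (NR, m) array of per-replica bias samples over the window, which is
    averaged along the window axis first.  Overflow-shifted; invariant to a
    constant added to all biases.
    """
    V = np.asarray(bias_history, dtype=float)
    if V.ndim == 2:
        if V.shape[1] == 0:
            raise ValueError("empty averaging window")
        V = V.mean(axis=1)
    a = V / kT
    a = a - a.max()
    w = np.exp(a)
    return w / w.sum()


def effective_replicas(weights) -> float:
    """NR_eff = (Σ w_r)² / Σ w_r²; lies in [1, NR]."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(w > 0):
        raise ValueError("weights must not all be zero")
    w = w / w.max()   # scale-invariant; keeps squares away from under/overflow
    s = w.sum()
    return float(s * s / np.sum(w * w))


def replica_average(f_values, weights) -> np.ndarray:
    """⟨f_i(X)⟩ = Σ_r w_r f_i(X_r) / Σ_r w_r per datum."""
    f = np.atleast_2d(np.asarray(f_values, dtype=float))   # (NR, Nd)
    w = np.asarray(weights, dtype=float)
    s = w.sum()
    if s <= 0:
        raise ValueError("weights must not all be zero")
    return (w @ f) / s


def sigma_sem(f_values, weights, nreff_floor: float = 0.0) -> np.ndarray:
    """Instantaneous σ_SEM per datum:

        σ_SEM,i = sqrt[ 1/(NR_eff - 1) · Σ_r w_r (f_i(X_r) - ⟨f_i⟩)² / Σ_r w_r ]

    Raises if NR_eff ≤ 1 (the restraint is undefined) unless a positive
    ``nreff_floor`` is given, in which case NR_eff - 1 is floored to it
    (run-time guard for transiently degenerate weights).
    """
    f = np.atleast_2d(np.asarray(f_values, dtype=float))
    w = np.asarray(weights, dtype=float)
    nreff = effective_replicas(w)
    denom = nreff - 1.0
    if denom <= 0:
        if nreff_floor > 0:
            denom = nreff_floor
        else:
            raise ValueError("sigma_SEM undefined for NR_eff <= 1")
    favg = replica_average(f, w)
    var = (w @ (f - favg) ** 2) / w.sum()
    return np.sqrt(var / denom)


def sigma_cap(sem, n_replicas: int) -> np.ndarray:
    """Maximum σ_B that may be sampled: σ_SEM · √NR."""
    if n_replicas < 1:
        raise ValueError("need at least one replica")
    return np.asarray(sem, dtype=float) * np.sqrt(n_replicas)


def mi_energy(f_avg, d, lam, sigma_b, sem, kT: float = 1.0,
              e_ff: float = 0.0, include_esigma: bool = True,
              jeffreys: bool = True) -> MIEnergyBreakdown:
    """Metainference energy breakdown for the current state.

    data term = (kT/2) Σ_i Σ_r (d_i - λ⟨f_i⟩)² / (σ_B[r,i]² + σ_SEM[i]²);
    E_σ = (kT/2) Σ_{r,i} log(2π(σ_B² + σ_SEM²)) + kT Σ_{r,i} log σ_B
    (Gaussian-likelihood normalization plus Jeffreys prior p(σ_B) ∝ 1/σ_B).
    """
    f_avg = np.atleast_1d(np.asarray(f_avg, dtype=float))
    d = np.atleast_1d(np.asarray(d, dtype=float))
    sigma_b = np.atleast_2d(np.asarray(sigma_b, dtype=float))
    sem = np.atleast_1d(np.asarray(sem, dtype=float))
    denom = sigma_b**2 + sem[None, :] ** 2
    if np.any(denom <= 0):
        raise ValueError("sigma denominators must be positive")
    res = d - lam * f_avg
    data = 0.5 * kT * float(np.sum(res[None, :] ** 2 / denom))
    esig = 0.0
    if include_esigma:
        esig = 0.5 * kT * float(np.sum(np.log(2 * np.pi * denom)))
        if jeffreys:
            esig += kT * float(np.sum(np.log(sigma_b)))
    return MIEnergyBreakdown(forcefield=float(e_ff), data=data, esigma=esig)


def mi_forces(coords, model, d, lam, sigma_b, sem, weights,
              kT: float = 1.0) -> np.ndarray:
    """Restraint forces -∂E_MI/∂X_r, treating replica weights as constants.

    F_r = kT λ (w_r/Σw) Σ_i S_i (d_i - λ⟨f_i⟩) ∇f_i(X_r)
    with S_i = Σ_r' 1/(σ_B[r',i]² + σ_SEM[i]²).
    """
    X = np.atleast_2d(np.asarray(coords, dtype=float))
    w = np.asarray(weights, dtype=float)
    sigma_b = np.atleast_2d(np.asarray(sigma_b, dtype=float))
    sem = np.atleast_1d(np.asarray(sem, dtype=float))
    f = model.values(X)                      # (NR, Nd)
    favg = replica_average(f, w)
    res = np.asarray(d, dtype=float) - lam * favg        # (Nd,)
    S = np.sum(1.0 / (sigma_b**2 + sem[None, :] ** 2), axis=0)   # (Nd,)
    grads = model.grads(X)                   # (NR, Nd, dim)
    coef = kT * lam * (w / w.sum())          # (NR,)
    return coef[:, None] * np.einsum("i,rid->rd", res * S, grads)


def mc_update_sigma(state: SigmaState, residuals, kT: float,
                    rng: np.random.Generator,
                    cap: np.ndarray | None = None) -> SigmaState:
    """One sweep of single-site Metropolis updates of every σ_B[r,i].

    Target density per site: Gaussian data likelihood
    exp(-res²/(2(σ²+σ_SEM²))) / sqrt(2π(σ²+σ_SEM²)) times the Jeffreys prior
    1/σ, on the interval (σ_min, cap].  Symmetric uniform proposals; values
    outside the interval are rejected outright.  Updates are in place.
    """
    res = np.atleast_1d(np.asarray(residuals, dtype=float))
    sem = state.sigma_sem
    if cap is None:
        cap = sigma_cap(sem, state.n_replicas)
    cap = np.broadcast_to(np.asarray(cap, dtype=float), sem.shape)
    smin = state.sigma_min
    if smin is None:
        smin = np.full_like(sem, 1e-12)
    step = state.step_size
    if step is None:
        step = 0.1 * np.maximum(cap - smin, 1e-12)

    sb = state.sigma_b
    prop = sb + step[None, :] * rng.uniform(-1.0, 1.0, size=sb.shape)
    inside = (prop > smin[None, :]) & (prop <= cap[None, :])

    def site_energy(sig):
        den = sig**2 + sem[None, :] ** 2
        return (0.5 * res[None, :] ** 2 / den + 0.5 * np.log(2 * np.pi * den)
                + np.log(sig))

    dE = site_energy(np.where(inside, prop, sb)) - site_energy(sb)
    accept = inside & (rng.uniform(size=sb.shape) < np.exp(np.minimum(-dE, 0.0)))
    sb[accept] = prop[accept]
    state.n_trial += sb.size
    state.n_accept += int(np.count_nonzero(accept))
    return state


def relative_sem_error(sem, d, threshold: float = 10.0):
    """Per-datum relative error 100·σ_SEM/|d| with above-threshold flags.

    Data points with d = 0 are excluded (NaN) and flagged.  The default 10%
    threshold marks data whose conformational-averaging error suggests too
    few effective replicas.
    """
    sem = np.atleast_1d(np.asarray(sem, dtype=float))
    d = np.atleast_1d(np.asarray(d, dtype=float))
    zero = d == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(zero, np.nan, 100.0 * sem / np.abs(np.where(zero, 1.0, d)))
    flags = zero | (rel > threshold)
    return rel, flags


# ---------------------------------------------------------------------------
# the combined M&M run


@dataclass(frozen=True)
class MIConfig:
    """Metainference run parameters."""

    n_replicas: int
    averaging: int = 250          # window length in MD steps (default = pace)
    lam: float = 1.0
    mc_seed_offset: int = 7919    # decorrelate the σ MC stream from the noise
    record_stride: int = 50       # record diagnostics every this many restraint steps
    nreff_floor: float = 1e-3     # floor for NR_eff - 1 in sigma_sem

    def __post_init__(self):
        if self.n_replicas < 2:
            raise ValueError("metainference needs at least 2 replicas")
        if self.averaging < 1:
            raise ValueError("averaging window must be >= 1 step")


@dataclass
class MMRun(MetaDRun):
    """MetaD run augmented with metainference diagnostics."""

    observables: ObservableSet = None
    sigma: SigmaState = None
    diag_times: np.ndarray = None
    nreff: np.ndarray = None
    sem_history: np.ndarray = None       # (n_records, Nd)
    sigma_b_mean: np.ndarray = None      # (n_records,)

    def nreff_cumulative(self) -> np.ndarray:
        return np.cumsum(self.nreff) / np.arange(1, len(self.nreff) + 1)

    def final_sem(self, tail_frac: float = 0.25) -> np.ndarray:
        """σ_SEM per datum averaged over the trailing fraction of the run."""
        k = max(1, int(tail_frac * len(self.diag_times)))
        return self.sem_history[-k:].mean(axis=0)

    def mean_relative_sem_error(self, tail_frac: float = 0.25) -> float:
        rel, _ = relative_sem_error(self.final_sem(tail_frac), self.observables.d)
        return float(np.nanmean(rel))

    def restrained_average(self, discard_frac: float = 0.25) -> np.ndarray:
        """Back-calculated profile ⟨f⟩ over the reweighted restrained ensemble."""
        w = self.frame_weights(discard_frac)
        f = self.observables.model.values(self.coords())
        return (w @ f) / w.sum()

    def diagnostics_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.diag_times, "nreff": self.nreff,
                           "nreff_cumavg": self.nreff_cumulative(),
                           "sigma_b_mean": self.sigma_b_mean})
        rel, _ = relative_sem_error(self.sem_history[-1], self.observables.d)
        for j, oid in enumerate(self.observables.ids):
            df[f"sem_{oid}"] = self.sem_history[:, j]
        return df


def run_mm(spec: PotentialSpec, metad_cfg: MetaDConfig,
           integ_cfg: IntegratorConfig, observables: ObservableSet,
           mi_cfg: MIConfig, x0=None) -> MMRun:
    """Metadynamics-metainference: NR replicas share the bias as walkers.

    Every ``observables.stride`` steps the replica weights (window-averaged
    bias), ⟨f⟩, σ_SEM (window max), the σ_B Monte-Carlo state and the
    restraint forces are refreshed; hills are deposited every ``pace`` steps
    exactly as in a plain run.  Aborts if NR_eff stays at ≤ 1 over a full
    averaging window.
    """
    NR = mi_cfg.n_replicas
    if x0 is None:
        x0 = np.tile(default_start(spec), (NR, 1))
    X = np.array(x0, dtype=float)
    if X.shape != (NR, spec.dim):
        raise ValueError("x0 must have shape (n_replicas, dim)")
    model = observables.model
    Nd = observables.n_data
    d = observables.d
    kT = integ_cfg.kT

    bias = BiasState(metad_cfg, kT=kT)
    cvs = metad_cfg.cvs
    rng = np.random.default_rng(integ_cfg.seed)
    mc_rng = np.random.default_rng(integ_cfg.seed + mi_cfg.mc_seed_offset)
    dt_over_g = integ_cfg.dt / integ_cfg.friction
    noise_scale = np.sqrt(2.0 * kT * integ_cfg.dt / integ_cfg.friction)

    stride = observables.stride
    window = AveragingWindow(max(1, mi_cfg.averaging // stride), NR, Nd)
    sigma_min = SIGMA_MIN_FRAC * np.abs(d)
    sigma_min[sigma_min == 0] = 1e-12

    # bootstrap the error model from the starting replicas (uniform weights)
    f0 = model.values(X)
    sem0 = sigma_sem(f0, np.ones(NR), nreff_floor=mi_cfg.nreff_floor)
    sem0 = np.maximum(sem0, sigma_min)
    cap0 = sigma_cap(sem0, NR)
    sigma = SigmaState(
        sigma_b=np.tile(0.5 * cap0, (NR, 1)),
        sigma_sem=sem0, lam=mi_cfg.lam, sigma_min=sigma_min,
    )

    n_save = integ_cfg.n_steps // integ_cfg.save_stride
    frames = np.empty((n_save, NR, spec.dim))
    s_frames = np.empty((n_save, NR, len(cvs)))
    v_frames = np.empty((n_save, NR))
    times = np.empty(n_save)

    n_events = integ_cfg.n_steps // stride
    diag_times, nreff_rec, sem_rec, sb_rec = [], [], [], []
    ext_force = np.zeros((NR, spec.dim))
    degenerate_events = 0
    isave = 0
    noise = None
    noise_i = 0

    def draw_noise():
        nonlocal noise, noise_i
        noise = rng.standard_normal((_NOISE_CHUNK, NR, spec.dim))
        noise_i = 0

    ff = _ForceField(spec)
    cvmap = _CVMap(cvs, spec.dim)
    heun = integ_cfg.scheme == "heun"

    def total_force(Y):
        f = ff(Y)
        _, dV = bias._evaluate2(cvmap.values(Y))
        return f + cvmap.pull_back(Y, dV) + ext_force

    for step in range(integ_cfg.n_steps):
        force = total_force(X)
        if noise_scale > 0:
            if noise is None or noise_i >= _NOISE_CHUNK:
                draw_noise()
            eta = noise_scale * noise[noise_i]
            noise_i += 1
        else:
            eta = 0.0
        if heun:
            Xp = X + dt_over_g * force + eta
            X = X + 0.5 * dt_over_g * (force + total_force(Xp)) + eta
        else:
            X = X + dt_over_g * force + eta
        t_now = (step + 1) * integ_cfg.dt

        sstep = step + 1
        deposit = metad_cfg.height > 0 and sstep % metad_cfg.pace == 0
        restrain = sstep % stride == 0
        record = sstep % integ_cfg.save_stride == 0

        if deposit or restrain or record:
            if not np.all(np.isfinite(X)):
                raise RuntimeError(f"non-finite coordinates at step {sstep}")
            s_now = _clip_to_grid(cvmap.values(X), metad_cfg)
            v_now, _ = bias._evaluate2(s_now)

        if deposit:
            for k in range(NR):
                if metad_cfg.mode == "joint":
                    deposit_hill(bias, s_now[k], time=t_now)
                else:
                    pb_deposit(bias, s_now[k], time=t_now)
            v_now, _ = bias._evaluate2(s_now)

        if restrain:
            f = model.values(X)
            w_inst = replica_weights_from_bias(v_now, kT)
            sem_inst = sigma_sem(f, w_inst, nreff_floor=mi_cfg.nreff_floor)
            window.push(v_now, sem_inst)
            w = replica_weights_from_bias(window.mean_bias(), kT)
            nreff = effective_replicas(w)
            if nreff <= 1.0 + 1e-9:
                degenerate_events += 1
                if degenerate_events * stride >= mi_cfg.averaging:
                    raise RuntimeError(
                        "NR_eff <= 1 persisted over a full averaging window; "
                        "the replica ensemble has collapsed onto one replica"
                    )
            else:
                degenerate_events = 0
            sem = np.maximum(window.max_sem(), sigma_min)
            sigma.sigma_sem = sem
            cap = np.maximum(sigma_cap(sem, NR), sigma_min * (1 + 1e-9))
            np.clip(sigma.sigma_b, sigma_min[None, :], cap[None, :],
                    out=sigma.sigma_b)
            favg = replica_average(f, w)
            mc_update_sigma(sigma, d - sigma.lam * favg, kT, mc_rng, cap=cap)
            ext_force = mi_forces(X, model, d, sigma.lam, sigma.sigma_b,
                                  sem, w, kT=kT)
            event = sstep // stride
            if event % mi_cfg.record_stride == 0 or event == n_events:
                diag_times.append(t_now)
                nreff_rec.append(nreff)
                sem_rec.append(sem.copy())
                sb_rec.append(float(sigma.sigma_b.mean()))

        if record:
            times[isave] = t_now
            frames[isave] = X
            s_frames[isave] = s_now
            v_frames[isave] = v_now
            isave += 1

    _warn_if_clamped(bias)
    trajectories = []
    for k in range(NR):
        cv_cols = {cv.name: s_frames[:, k, j] for j, cv in enumerate(cvs)}
        cv_cols["metad.bias"] = v_frames[:, k]
        trajectories.append(Trajectory(times=times.copy(), coords=frames[:, k, :],
                                       cv_values=cv_cols, walker=k))
    return MMRun(
        spec=spec, metad_cfg=metad_cfg, integ_cfg=integ_cfg, bias=bias,
        trajectories=trajectories, observables=observables, sigma=sigma,
        diag_times=np.array(diag_times), nreff=np.array(nreff_rec),
        sem_history=np.array(sem_rec), sigma_b_mean=np.array(sb_rec),
    )
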