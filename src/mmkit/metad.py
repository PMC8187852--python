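"""Well-tempered and parallel-bias metadynamics with multiple walkers.

Two bias modes are supported:

* ``joint`` — conventional metadynamics: one Gaussian hill over the joint
  space of all biased CVs per deposition, with the well-tempered height
  h = h₀ exp(-V(s)/((γ-1) kT)).
* ``pb`` — parallel-bias metadynamics: one one-dimensional bias V_i per CV,
  combined into the total bias V_PB(s) = -kT log Σ_i exp(-V_i(s_i)/kT).
  Each deposition adds a 1D Gaussian per CV whose height carries both the
  well-tempered damping and a softmax share exp(-V_i/kT)/Σ_j exp(-V_j/kT)
  (the shares sum to one).

All walkers read and write a single shared bias; deposition events at a
common pace step are ordered by ascending walker index.  Biases are
accumulated on regular grids (value and gradient nodes filled analytically
per hill, linear interpolation in between); the cached grid is exact at the
nodes, and off-node interpolation error is quadratic in the grid spacing —
negligible at the default of ≥8 nodes per Gaussian width.

Frames are reweighted with the final bias, w_i ∝ exp(V_final(s_i)/kT),
assuming a constant bias over the whole run (no time-dependent correction).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

from .cvs import CombinationCV, CoordinateCV, LinearCV
from .dynamics import IntegratorConfig, Trajectory, default_start
from .potentials import PotentialSpec, domain_bounds, potential_gradient
from .stats import effective_frames

__all__ = [
    "Hill",
    "MetaDConfig",
    "BiasState",
    "MetaDRun",
    "wt_hill_height",
    "deposit_hill",
    "pb_deposit",
    "evaluate_bias",
    "pb_total_bias",
    "run_metad",
    "final_bias_weights",
    "default_grid_range",
]

logger = logging.getLogger(__name__)

_NOISE_CHUNK = 8192  # matches dynamics.run_trajectory so h0=0 reproduces it
_HILL_CUTOFF = 7.0   # Gaussians truncated beyond this many widths (e^{-24.5})


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian."""

    time: float
    center: np.ndarray       # (ncv,) for joint; (1,) for a per-CV 1D hill
    sigma: np.ndarray
    height: float
    cv_name: str | None = None   # which 1D bias (pb mode); None = joint

    def __post_init__(self):
        object.__setattr__(self, "center", np.atleast_1d(np.asarray(self.center, float)))
        object.__setattr__(self, "sigma", np.atleast_1d(np.asarray(self.sigma, float)))
        if np.any(self.sigma <= 0):
            raise ValueError("hill widths must be positive")
        if self.height < 0:
            raise ValueError("hill height must be non-negative")


@dataclass(frozen=True)
class MetaDConfig:
    """Metadynamics parameters: mode, biased CVs, h₀, pace, γ, widths, grids.

    ``sigma``, ``grid_min``, ``grid_max`` and ``grid_bins`` are per biased CV.
    Fixed Gaussian widths are used (with PLUMED-style per-CV minima as
    natural defaults in configs) rather than an adaptive-width scheme.
    """

    cvs: tuple                      # CollectiveVariable objects
    sigma: tuple
    grid_min: tuple
    grid_max: tuple
    mode: str = "pb"
    height: float = 1.0             # h0, energy units
    pace: int = 250                 # steps between depositions
    biasfactor: float = 10.0
    grid_bins: tuple | None = None

    def __post_init__(self):
        ncv = len(self.cvs)
        object.__setattr__(self, "cvs", tuple(self.cvs))
        for name in ("sigma", "grid_min", "grid_max"):
            vals = tuple(float(v) for v in np.atleast_1d(getattr(self, name)))
            if len(vals) != ncv:
                raise ValueError(f"{name} must have one entry per biased CV")
            object.__setattr__(self, name, vals)
        bins = self.grid_bins
        if bins is None:
            # >= 8 nodes per Gaussian width
            bins = tuple(
                max(64, int(np.ceil(8 * (hi - lo) / sig)))
                for lo, hi, sig in zip(self.grid_min, self.grid_max, self.sigma)
            )
        else:
            bins = tuple(int(b) for b in np.atleast_1d(bins))
            if len(bins) != ncv:
                raise ValueError("grid_bins must have one entry per biased CV")
        object.__setattr__(self, "grid_bins", bins)
        if self.mode not in ("pb", "joint"):
            raise ValueError(f"unknown metadynamics mode {self.mode!r}")
        if self.mode == "joint" and ncv > 2:
            raise ValueError("joint mode supports at most 2 biased CVs")
        if self.biasfactor <= 1:
            raise ValueError("well-tempered bias factor must exceed 1")
        if self.pace < 1:
            raise ValueError("deposition pace must be >= 1")
        if self.height < 0:
            raise ValueError("initial hill height must be non-negative")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("Gaussian widths must be positive")
        if any(hi <= lo for lo, hi in zip(self.grid_min, self.grid_max)):
            raise ValueError("grid_max must exceed grid_min")

    @property
    def cv_names(self) -> tuple:
        return tuple(cv.name for cv in self.cvs)


class _Grid1D:
    """Regular 1D grid caching bias values and gradients."""

    def __init__(self, lo: float, hi: float, n: int):
        self.lo, self.hi, self.n = float(lo), float(hi), int(n)
        self.nodes = np.linspace(lo, hi, n)
        self.dx = self.nodes[1] - self.nodes[0]
        self.vals = np.zeros(n)
        self.dvals = np.zeros(n)
        self.n_clamped = 0

    def add_gaussian(self, center: float, sigma: float, height: float):
        # update only nodes within the truncation window (tail < e^{-24.5})
        i0 = max(0, int((center - _HILL_CUTOFF * sigma - self.lo) / self.dx))
        i1 = min(self.n, int((center + _HILL_CUTOFF * sigma - self.lo) / self.dx) + 2)
        z = (self.nodes[i0:i1] - center) / sigma
        g = height * np.exp(-0.5 * z * z)
        self.vals[i0:i1] += g
        self.dvals[i0:i1] += -g * z / sigma

    def lookup(self, s):
        s = np.asarray(s, dtype=float)
        out = (s < self.lo) | (s > self.hi)
        if np.any(out):
            self.n_clamped += int(np.count_nonzero(out))
        sc = np.clip(s, self.lo, self.hi)
        f = (sc - self.lo) / self.dx
        i = np.minimum(f.astype(int), self.n - 2)
        t = f - i
        v = self.vals[i] * (1 - t) + self.vals[i + 1] * t
        dv = self.dvals[i] * (1 - t) + self.dvals[i + 1] * t
        dv = np.where(out, 0.0, dv)
        return v, dv


class _Grid2D:
    """Regular 2D grid caching joint bias values and gradients."""

    def __init__(self, lo, hi, n):
        self.lo = np.asarray(lo, float)
        self.hi = np.asarray(hi, float)
        self.n = np.asarray(n, int)
        self.ax = [np.linspace(self.lo[d], self.hi[d], self.n[d]) for d in range(2)]
        self.dx = np.array([a[1] - a[0] for a in self.ax])
        shape = tuple(self.n)
        self.vals = np.zeros(shape)
        self.d1 = np.zeros(shape)
        self.d2 = np.zeros(shape)
        self.n_clamped = 0

    def add_gaussian(self, center, sigma, height: float):
        # windowed update: nodes within the truncation cutoff of the center
        w0, w1 = [], []
        for d in range(2):
            w0.append(max(0, int((center[d] - _HILL_CUTOFF * sigma[d]
                                  - self.lo[d]) / self.dx[d])))
            w1.append(min(self.n[d], int((center[d] + _HILL_CUTOFF * sigma[d]
                                          - self.lo[d]) / self.dx[d]) + 2))
        z1 = (self.ax[0][w0[0]:w1[0]] - center[0]) / sigma[0]
        z2 = (self.ax[1][w0[1]:w1[1]] - center[1]) / sigma[1]
        g1 = np.exp(-0.5 * z1 * z1)
        g2 = np.exp(-0.5 * z2 * z2)
        G = height * np.outer(g1, g2)
        sl = (slice(w0[0], w1[0]), slice(w0[1], w1[1]))
        self.vals[sl] += G
        self.d1[sl] += G * (-z1 / sigma[0])[:, None]
        self.d2[sl] += G * (-z2 / sigma[1])[None, :]

    def lookup(self, s):
        s = np.atleast_2d(np.asarray(s, dtype=float))
        out = np.any((s < self.lo) | (s > self.hi), axis=1)
        if np.any(out):
            self.n_clamped += int(np.count_nonzero(out))
        sc = np.clip(s, self.lo, self.hi)
        f = (sc - self.lo) / self.dx
        i = np.minimum(f.astype(int), self.n - 2)
        t = f - i
        i1, i2 = i[:, 0], i[:, 1]
        t1, t2 = t[:, 0], t[:, 1]

        def bilin(A):
            return ((A[i1, i2] * (1 - t1) + A[i1 + 1, i2] * t1) * (1 - t2)
                    + (A[i1, i2 + 1] * (1 - t1) + A[i1 + 1, i2 + 1] * t1) * t2)

        v = bilin(self.vals)
        dv = np.stack([bilin(self.d1), bilin(self.d2)], axis=1)
        dv[out] = 0.0
        return v, dv


class BiasState:
    """Accumulated metadynamics bias: hills plus cached grids.

    In pb mode one 1D grid per CV; in joint mode a single 1D or 2D grid.
    """

    def __init__(self, cfg: MetaDConfig, kT: float):
        self.cfg = cfg
        self.kT = float(kT)
        self.mode = cfg.mode
        self.hills: list[Hill] = []
        if cfg.mode == "pb" or len(cfg.cvs) == 1:
            self.grids = [
                _Grid1D(lo, hi, n)
                for lo, hi, n in zip(cfg.grid_min, cfg.grid_max, cfg.grid_bins)
            ]
            self.joint_grid = self.grids[0] if cfg.mode == "joint" else None
        else:
            self.joint_grid = _Grid2D(cfg.grid_min, cfg.grid_max, cfg.grid_bins)
            self.grids = []

    @property
    def n_cvs(self) -> int:
        return len(self.cfg.cvs)

    # -- evaluation -----------------------------------------------------

    def per_cv_values(self, s):
        """pb mode: (V_i, dV_i/ds_i) arrays of shape (n, ncv)."""
        s = np.atleast_2d(np.asarray(s, dtype=float))
        V = np.empty(s.shape)
        dV = np.empty(s.shape)
        for i, g in enumerate(self.grids):
            V[:, i], dV[:, i] = g.lookup(s[:, i])
        return V, dV

    def evaluate(self, s):
        """Total bias and gradient w.r.t. the CVs; vectorized over frames."""
        s = np.asarray(s, dtype=float)
        squeeze = s.ndim == 1
        v, dv = self._evaluate2(np.atleast_2d(s))
        return (v[0], dv[0]) if squeeze else (v, dv)

    def _evaluate2(self, s2: np.ndarray):
        """As :meth:`evaluate` but strictly (n, ncv) in — hot path."""
        if self.mode == "joint":
            if self.n_cvs == 1:
                v, dv = self.joint_grid.lookup(s2[:, 0])
                dv = dv[:, None]
            else:
                v, dv = self.joint_grid.lookup(s2)
            return v, dv
        Vi, dVi = self.per_cv_values(s2)
        a = Vi * (-1.0 / self.kT)
        m = a.max(axis=1, keepdims=True)
        e = np.exp(a - m)
        tot = e.sum(axis=1)
        v = -self.kT * (np.log(tot) + m[:, 0])
        dv = (e / tot[:, None]) * dVi
        return v, dv

    def direct(self, s):
        """Bias by direct summation over the hill list (no grid cache)."""
        s = np.atleast_2d(np.asarray(s, dtype=float))
        if self.mode == "joint":
            v = np.zeros(len(s))
            for h in self.hills:
                z = (s - h.center) / h.sigma
                v += h.height * np.exp(-0.5 * np.sum(z * z, axis=1))
            return v
        Vi = np.zeros(s.shape)
        for h in self.hills:
            i = self.cfg.cv_names.index(h.cv_name)
            z = (s[:, i] - h.center[0]) / h.sigma[0]
            Vi[:, i] += h.height * np.exp(-0.5 * z * z)
        return -self.kT * logsumexp(-Vi / self.kT, axis=1)


def wt_hill_height(h0: float, v_at_s: float, biasfactor: float, kT: float) -> float:
    """Well-tempered hill height h = h₀ exp(-V(s)/((γ-1) kT))."""
    if biasfactor <= 1:
        raise ValueError("well-tempered bias factor must exceed 1")
    return float(h0 * np.exp(-np.asarray(v_at_s) / ((biasfactor - 1.0) * kT)))


def deposit_hill(bias: BiasState, center, cfg: MetaDConfig | None = None,
                 time: float = 0.0, v_at_center: float | None = None) -> Hill:
    """Deposit one joint (multi-dimensional) well-tempered Gaussian."""
    cfg = cfg or bias.cfg
    if bias.mode != "joint":
        raise ValueError("deposit_hill applies to joint mode; use pb_deposit")
    center = np.atleast_1d(np.asarray(center, dtype=float))
    for c, lo, hi in zip(center, cfg.grid_min, cfg.grid_max):
        if not (lo <= c <= hi):
            raise ValueError(f"hill center {c} outside grid bounds [{lo}, {hi}]")
    if v_at_center is None:
        v_at_center = bias.evaluate(center)[0]
    h = wt_hill_height(cfg.height, v_at_center, cfg.biasfactor, bias.kT)
    hill = Hill(time=time, center=center, sigma=np.array(cfg.sigma), height=h)
    bias.hills.append(hill)
    if bias.n_cvs == 1:
        bias.joint_grid.add_gaussian(center[0], cfg.sigma[0], h)
    else:
        bias.joint_grid.add_gaussian(center, np.array(cfg.sigma), h)
    return hill


def pb_deposit(bias: BiasState, s, cfg: MetaDConfig | None = None,
               time: float = 0.0) -> list[Hill]:
    """Deposit one 1D Gaussian per CV with softmax-partitioned heights.

    Height of the hill on CV i: h₀ · exp(-V_i(s_i)/((γ-1) kT)) ·
    exp(-V_i(s_i)/kT)/Σ_j exp(-V_j(s_j)/kT); the softmax shares sum to 1.
    """
    cfg = cfg or bias.cfg
    if bias.mode != "pb":
        raise ValueError("pb_deposit applies to parallel-bias mode")
    s = np.atleast_1d(np.asarray(s, dtype=float))
    for c, lo, hi in zip(s, cfg.grid_min, cfg.grid_max):
        if not (lo <= c <= hi):
            raise ValueError(f"hill center {c} outside grid bounds [{lo}, {hi}]")
    Vi, _ = bias.per_cv_values(s[None, :])
    Vi = Vi[0]
    share = softmax(-Vi / bias.kT)
    hills = []
    for i, name in enumerate(cfg.cv_names):
        h = wt_hill_height(cfg.height, Vi[i], cfg.biasfactor, bias.kT) * share[i]
        hill = Hill(time=time, center=np.array([s[i]]),
                    sigma=np.array([cfg.sigma[i]]), height=h, cv_name=name)
        bias.hills.append(hill)
        bias.grids[i].add_gaussian(s[i], cfg.sigma[i], h)
        hills.append(hill)
    return hills


def evaluate_bias(bias: BiasState, s):
    """Total bias energy and gradient w.r.t. the CV values."""
    return bias.evaluate(s)


def pb_total_bias(bias: BiasState, s):
    """V_PB(s) = -kT log Σ_i exp(-V_i(s_i)/kT)."""
    if bias.mode != "pb":
        raise ValueError("pb_total_bias applies to parallel-bias mode")
    s = np.asarray(s, dtype=float)
    squeeze = s.ndim == 1
    Vi, _ = bias.per_cv_values(np.atleast_2d(s))
    v = -bias.kT * logsumexp(-Vi / bias.kT, axis=1)
    return float(v[0]) if squeeze else v


def final_bias_weights(cv_series, bias: BiasState, kT: float | None = None) -> np.ndarray:
    """Per-frame weights w_i ∝ exp(V_final(s_i)/kT), normalized to sum 1."""
    kT = bias.kT if kT is None else float(kT)
    s = np.atleast_2d(np.asarray(cv_series, dtype=float))
    v, _ = bias.evaluate(s)
    a = v / kT
    a -= a.max()
    w = np.exp(a)
    return w / w.sum()


def default_grid_range(spec: PotentialSpec, cv, margin: float = 0.05,
                       n_scan: int = 33) -> tuple[float, float]:
    """CV range over the potential's quadrature domain, padded by ``margin``."""
    bounds = domain_bounds(spec)
    axes = [np.linspace(lo, hi, n_scan) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    v = cv.value(pts)
    lo, hi = float(v.min()), float(v.max())
    pad = margin * (hi - lo)
    return lo - pad, hi + pad


@dataclass
class MetaDRun:
    """Result of a multiple-walker metadynamics run."""

    spec: PotentialSpec
    metad_cfg: MetaDConfig
    integ_cfg: IntegratorConfig
    bias: BiasState
    trajectories: list

    @property
    def n_walkers(self) -> int:
        return len(self.trajectories)

    @property
    def times(self) -> np.ndarray:
        return self.trajectories[0].times

    @property
    def total_time(self) -> float:
        return self.n_walkers * self.integ_cfg.n_steps * self.integ_cfg.dt

    def coords(self) -> np.ndarray:
        """Concatenated coordinates over walkers, (NF, dim)."""
        return np.concatenate([t.coords for t in self.trajectories], axis=0)

    def cv_series(self) -> np.ndarray:
        """Concatenated biased-CV values, (NF, ncv)."""
        cols = []
        for t in self.trajectories:
            cols.append(np.stack(
                [t.cv_values[name] for name in self.metad_cfg.cv_names], axis=1))
        return np.concatenate(cols, axis=0)

    def frame_weights(self, discard_frac: float = 0.0) -> np.ndarray:
        """Final-bias frame weights over all walkers (optionally discarding an
        initial fraction of each walker's frames)."""
        keep = self._keep_mask(discard_frac)
        w = np.zeros(keep.size)
        w[keep] = final_bias_weights(self.cv_series()[keep], self.bias)
        return w / w.sum()

    def _keep_mask(self, discard_frac: float) -> np.ndarray:
        nf = self.trajectories[0].n_frames
        skip = int(discard_frac * nf)
        mask = np.zeros(self.n_walkers * nf, dtype=bool)
        for k in range(self.n_walkers):
            mask[k * nf + skip:(k + 1) * nf] = True
        return mask

    def observable(self, cv) -> np.ndarray:
        """An analysis CV evaluated on every concatenated frame."""
        return cv.value(self.coords())

    def nf_eff_fraction(self, discard_frac: float = 0.0) -> float:
        w = self.frame_weights(discard_frac)
        w = w[w > 0]
        return effective_frames(w) / w.size

    def nreff_series(self) -> tuple[np.ndarray, np.ndarray]:
        """Instantaneous effective-replica count from per-frame bias values."""
        V = np.stack([t.cv_values["metad.bias"] for t in self.trajectories])
        a = V / self.bias.kT
        a -= a.max(axis=0, keepdims=True)
        w = np.exp(a)
        nreff = w.sum(axis=0) ** 2 / np.sum(w * w, axis=0)
        return self.times, nreff


def _affine_map(cvs, dim: int):
    """(A, b) with s = A x + b if every CV is affine in x, else None."""
    rows, offs = [], []
    for cv in cvs:
        if isinstance(cv, CoordinateCV):
            r = np.zeros(dim)
            r[cv.index] = 1.0
            rows.append(r)
            offs.append(0.0)
        elif isinstance(cv, LinearCV):
            rows.append(np.asarray(cv.coeffs, dtype=float))
            offs.append(cv.intercept)
        elif isinstance(cv, CombinationCV):
            sub = _affine_map(cv.cvs, dim)
            if sub is None:
                return None
            A, b = sub
            rows.append(cv.weights @ A)
            offs.append(float(cv.weights @ b))
        else:
            return None
    return np.array(rows), np.array(offs)


class _ForceField:
    """Precomputed fast evaluator of -∇U for the run loops."""

    def __init__(self, spec: PotentialSpec):
        self.spec = spec
        self.mixture = spec.form == "multiwell"
        if self.mixture:
            self.centers = spec.centers
            self.depths = spec.depths
            self.inv2w2 = 1.0 / (2.0 * spec.widths**2)
            self.winv = 1.0 / spec.widths**2

    def __call__(self, X: np.ndarray) -> np.ndarray:
        if not self.mixture:
            return -potential_gradient(self.spec, X)
        diff = X[:, None, :] - self.centers
        d2 = np.einsum("nkd,nkd->nk", diff, diff)
        a = self.depths - d2 * self.inv2w2
        a -= a.max(axis=1, keepdims=True)
        np.exp(a, out=a)
        a /= a.sum(axis=1, keepdims=True)
        return -np.einsum("nk,nkd->nd", a * self.winv, diff)


class _CVMap:
    """Biased-CV values and chain-rule pullback, with an affine fast path."""

    def __init__(self, cvs, dim: int):
        self.cvs = cvs
        self.aff = _affine_map(cvs, dim)
        if self.aff is not None:
            self.A, self.b = self.aff
            self.AT = self.A.T.copy()

    def values(self, X: np.ndarray) -> np.ndarray:
        if self.aff is not None:
            return X @ self.AT + self.b
        return np.stack([cv.value(X) for cv in self.cvs], axis=1)

    def pull_back(self, X: np.ndarray, dVds: np.ndarray) -> np.ndarray:
        """-∇_x V from dV/ds (bias force on the coordinates)."""
        if self.aff is not None:
            return -(dVds @ self.A)
        f = np.zeros_like(X)
        for j, cv in enumerate(self.cvs):
            f -= dVds[:, j, None] * cv.gradient(X)
        return f


def run_metad(spec: PotentialSpec, metad_cfg: MetaDConfig,
              integ_cfg: IntegratorConfig, n_walkers: int = 1,
              x0=None) -> MetaDRun:
    """Multiple-walker (PB)MetaD on a toy potential.

    All walkers advance synchronously under the shared bias; every ``pace``
    steps each walker deposits at its current CV position (ascending walker
    index).  Saved frames record coordinates, biased CV values and the
    instantaneous bias (column ``metad.bias``) for reweighting.
    """
    if x0 is None:
        x0 = np.tile(default_start(spec), (n_walkers, 1))
    X = np.array(x0, dtype=float)
    if X.ndim == 1:
        X = np.tile(X, (n_walkers, 1))
    if X.shape != (n_walkers, spec.dim):
        raise ValueError("x0 must have shape (n_walkers, dim)")

    bias = BiasState(metad_cfg, kT=integ_cfg.kT)
    cvs = metad_cfg.cvs
    ff = _ForceField(spec)
    cvmap = _CVMap(cvs, spec.dim)
    rng = np.random.default_rng(integ_cfg.seed)
    dt_over_g = integ_cfg.dt / integ_cfg.friction
    noise_scale = np.sqrt(2.0 * integ_cfg.kT * integ_cfg.dt / integ_cfg.friction)
    heun = integ_cfg.scheme == "heun"

    n_save = integ_cfg.n_steps // integ_cfg.save_stride
    frames = np.empty((n_save, n_walkers, spec.dim))
    s_frames = np.empty((n_save, n_walkers, len(cvs)))
    v_frames = np.empty((n_save, n_walkers))
    times = np.empty(n_save)

    isave = 0
    step = 0
    while step < integ_cfg.n_steps:
        chunk = min(_NOISE_CHUNK, integ_cfg.n_steps - step)
        noise = rng.standard_normal((chunk, n_walkers, spec.dim)) if noise_scale > 0 else None
        for i in range(chunk):
            force = ff(X)
            _, dVds = bias._evaluate2(cvmap.values(X))
            force += cvmap.pull_back(X, dVds)
            eta = noise_scale * noise[i] if noise is not None else 0.0
            if heun:
                Xp = X + dt_over_g * force + eta
                fp = ff(Xp)
                _, dVp = bias._evaluate2(cvmap.values(Xp))
                fp += cvmap.pull_back(Xp, dVp)
                X = X + 0.5 * dt_over_g * (force + fp) + eta
            else:
                X = X + dt_over_g * force + eta
            t_now = (step + i + 1) * integ_cfg.dt
            deposit = metad_cfg.height > 0 and (step + i + 1) % metad_cfg.pace == 0
            record = (step + i + 1) % integ_cfg.save_stride == 0
            if deposit or record:
                if not np.all(np.isfinite(X)):
                    raise RuntimeError(
                        f"non-finite coordinates at step {step + i + 1}")
                s_now = _clip_to_grid(cvmap.values(X), metad_cfg)
            if deposit:
                for k in range(n_walkers):
                    if metad_cfg.mode == "joint":
                        deposit_hill(bias, s_now[k], time=t_now)
                    else:
                        pb_deposit(bias, s_now[k], time=t_now)
            if record:
                v_now, _ = bias._evaluate2(s_now)
                times[isave] = t_now
                frames[isave] = X
                s_frames[isave] = s_now
                v_frames[isave] = v_now
                isave += 1
        step += chunk

    _warn_if_clamped(bias)
    trajectories = []
    for k in range(n_walkers):
        cv_cols = {cv.name: s_frames[:, k, j] for j, cv in enumerate(cvs)}
        cv_cols["metad.bias"] = v_frames[:, k]
        trajectories.append(Trajectory(times=times.copy(), coords=frames[:, k, :],
                                       cv_values=cv_cols, walker=k))
    return MetaDRun(spec=spec, metad_cfg=metad_cfg, integ_cfg=integ_cfg,
                    bias=bias, trajectories=trajectories)


def _clip_to_grid(s: np.ndarray, cfg: MetaDConfig) -> np.ndarray:
    lo = np.asarray(cfg.grid_min)
    hi = np.asarray(cfg.grid_max)
    return np.clip(s, lo, hi)


def _warn_if_clamped(bias: BiasState):
    grids = bias.grids if bias.grids else [bias.joint_grid]
    clamped = sum(g.n_clamped for g in grids)
    if clamped:
        logger.warning("bias evaluated outside the grid %d times (clamped)", clamped)
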