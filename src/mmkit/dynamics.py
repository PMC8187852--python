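"""Overdamped Langevin (Brownian) dynamics on the toy potentials.

Update rule per step:

    x' = x - (Δt/γ) ∇U(x) + sqrt(2 kT Δt / γ) ξ,   ξ ~ N(0, 1)

with friction γ in inverse time units.  The integrator is the simplest
ergodic sampler for the analytic toy landscapes; for kT → 0 it reduces to
gradient descent.  Runs are bit-reproducible under a fixed seed
(numpy Generator, PCG64).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .potentials import PotentialSpec, potential_gradient

__all__ = ["IntegratorConfig", "Trajectory", "run_trajectory"]

_NOISE_CHUNK = 8192  # steps of pre-generated noise per draw


@dataclass(frozen=True)
class IntegratorConfig:
    """Time step, temperature (kT), friction, length, seed, save stride.

    ``scheme`` selects the drift integrator: ``"euler"`` is the plain
    first-order update above; ``"heun"`` is its predictor-corrector
    refinement (drift averaged between the current and predicted point,
    same noise), which removes the O(k·Δt) bias of the sampled stationary
    density at twice the force-evaluation cost.
    """

    dt: float
    n_steps: int
    kT: float = 1.0
    friction: float = 1.0
    seed: int = 0
    save_stride: int = 10
    scheme: str = "euler"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        if self.kT < 0:
            raise ValueError("kT must be non-negative")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")
        if self.scheme not in ("euler", "heun"):
            raise ValueError(f"unknown integrator scheme {self.scheme!r}")


@dataclass
class Trajectory:
    """Saved frames of one walker: times, coordinates and CV columns."""

    times: np.ndarray
    coords: np.ndarray
    cv_values: dict = field(default_factory=dict)
    walker: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 1:
            self.coords = self.coords[:, None]
        if len(self.times) != len(self.coords):
            raise ValueError("times and coordinates must be aligned")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        for name, col in self.cv_values.items():
            if len(col) != len(self.times):
                raise ValueError(f"CV column {name!r} not aligned with frames")

    @property
    def n_frames(self) -> int:
        return len(self.times)


def default_start(spec: PotentialSpec) -> np.ndarray:
    """First well center — a deterministic default starting point."""
    return spec.centers[0].copy()


def run_trajectory(spec: PotentialSpec, cfg: IntegratorConfig,
                   external_force=None, x0=None, cvs=()) -> Trajectory:
    """Integrate one walker (or a batch) of overdamped Langevin dynamics.

    ``external_force(x, t)`` — if given — must accept the current (n, dim)
    coordinates and time and return a force array of the same shape, added
    to -∇U.  ``x0`` may be a single point (dim,) or a batch (n, dim); a
    batch returns a Trajectory whose coords have shape (frames, n, dim).
    Aborts with a diagnostic if coordinates become non-finite.
    """
    if x0 is None:
        x0 = default_start(spec)
    X = np.array(x0, dtype=float)
    batched = X.ndim == 2
    if not batched:
        X = X[None, :]
    if X.shape[1] != spec.dim:
        raise ValueError("x0 dimensionality does not match the potential")

    rng = np.random.default_rng(cfg.seed)
    dt_over_g = cfg.dt / cfg.friction
    noise_scale = np.sqrt(2.0 * cfg.kT * cfg.dt / cfg.friction)

    n_save = cfg.n_steps // cfg.save_stride
    frames = np.empty((n_save,) + X.shape)
    times = np.empty(n_save)

    isave = 0
    step = 0
    while step < cfg.n_steps:
        chunk = min(_NOISE_CHUNK, cfg.n_steps - step)
        noise = rng.standard_normal((chunk,) + X.shape) if noise_scale > 0 else None
        for i in range(chunk):
            t_next = (step + i + 1) * cfg.dt

            def total_force(Y):
                f = -potential_gradient(spec, Y)
                if external_force is not None:
                    f = f + external_force(Y, t_next)
                return f

            force = total_force(X)
            eta = noise_scale * noise[i] if noise is not None else 0.0
            if cfg.scheme == "heun":
                Xp = X + dt_over_g * force + eta
                X = X + 0.5 * dt_over_g * (force + total_force(Xp)) + eta
            else:
                X = X + dt_over_g * force + eta
            if (step + i + 1) % cfg.save_stride == 0:
                if not np.all(np.isfinite(X)):
                    raise RuntimeError(
                        f"non-finite coordinates at step {step + i + 1}; "
                        "reduce the time step"
                    )
                times[isave] = (step + i + 1) * cfg.dt
                frames[isave] = X
                isave += 1
        step += chunk
    if not np.all(np.isfinite(X)):
        raise RuntimeError("non-finite coordinates at end of run")

    coords = frames if batched else frames[:, 0, :]
    cv_cols = {}
    for cv in cvs:
        flat = coords.reshape(-1, spec.dim) if batched else coords
        vals = cv.value(flat)
        cv_cols[cv.name] = vals.reshape(coords.shape[:-1]) if batched else vals
    return Trajectory(times=times, coords=coords, cv_values=cv_cols)
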