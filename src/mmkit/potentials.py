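"""Analytic multi-well toy potentials and their exact ensemble properties.

The workhorse functional form is a log-sum-exp Gaussian mixture,

    U(x) = -log Σ_k exp( D_k - |x - c_k|² / (2 w_k²) )        [kT units]

so the Boltzmann weight e^{-U} is exactly a sum of Gaussian bumps: well k
carries mass e^{D_k} (2π w_k²)^{dim/2} up to negligible overlap between
well-separated wells.  This makes state populations, marginal free-energy
profiles and ensemble-averaged observables computable to quadrature accuracy
— the independent truth against which sampled, biased and restrained
ensembles are checked.  A single harmonic well (form="harmonic",
U = |x-c|²/(2w²), i.e. spring constant 1/w²) is also supported for
closed-form checks.

Quadrature is performed on a rectangle covering every well center ± 6 widths;
the neglected tail mass is below e^{-18} of a well's total and is documented
rather than corrected for.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .stats import FESProfile, StatePartition

__all__ = [
    "PotentialSpec",
    "ReferenceEnsemble",
    "potential_energy",
    "potential_gradient",
    "domain_bounds",
    "boltzmann_grid",
    "analytic_marginal_fes",
    "quadrature_state_populations",
    "make_reference_dataset",
    "perturb_potential",
]

DOMAIN_PAD_WIDTHS = 6.0   # quadrature rectangle: wells ± this many widths


@dataclass(frozen=True)
class PotentialSpec:
    """Multi-well (or harmonic) analytic potential in kT units.

    centers: (n_wells, dim) well minima; depths: (n_wells,) log-Boltzmann
    prefactors D_k (deepening a well by 1 kT multiplies its population by e);
    widths: (n_wells,) Gaussian widths.
    """

    form: str
    centers: np.ndarray
    depths: np.ndarray
    widths: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        depths = np.atleast_1d(np.asarray(self.depths, dtype=float))
        widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "widths", widths)
        if self.form not in ("multiwell", "harmonic"):
            raise ValueError(f"unknown potential form {self.form!r}")
        n = centers.shape[0]
        if depths.shape != (n,) or widths.shape != (n,):
            raise ValueError("centers, depths and widths must be aligned")
        if self.form == "multiwell" and n < 2:
            raise ValueError("a multiwell potential needs at least 2 wells")
        if self.form == "harmonic" and n != 1:
            raise ValueError("a harmonic potential has exactly one well")
        if np.any(widths <= 0):
            raise ValueError("well widths must be positive")
        if not (np.all(np.isfinite(centers)) and np.all(np.isfinite(depths))):
            raise ValueError("well parameters must be finite")
        if self.labels and len(self.labels) != n:
            raise ValueError("one label per well")

    @property
    def dim(self) -> int:
        return self.centers.shape[1]

    @property
    def n_wells(self) -> int:
        return self.centers.shape[0]


@dataclass(frozen=True)
class ReferenceEnsemble:
    """Target observables d_i and true state populations of an ensemble."""

    observable_ids: tuple
    d: np.ndarray
    populations: dict
    provenance: str

    def __post_init__(self):
        d = np.atleast_1d(np.asarray(self.d, dtype=float))
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "observable_ids", tuple(self.observable_ids))
        if len(self.observable_ids) != len(d):
            raise ValueError("one datum per observable definition")
        pops = np.array(list(self.populations.values()), dtype=float)
        if np.any(pops < 0) or np.any(pops > 1) or abs(pops.sum() - 1) > 1e-9:
            raise ValueError("populations must lie in [0,1] and sum to 1")


def _check_x(spec: PotentialSpec, x) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 0:
        x = x[None]
    if x.ndim == 1:
        if x.shape[0] != spec.dim:
            raise ValueError(f"coordinate has dim {x.shape[0]}, potential has {spec.dim}")
        return x[None, :], True
    if x.shape[1] != spec.dim:
        raise ValueError(f"coordinates have dim {x.shape[1]}, potential has {spec.dim}")
    return x, False


def _mixture_exponents(spec: PotentialSpec, x2: np.ndarray) -> np.ndarray:
    diff = x2[:, None, :] - spec.centers[None, :, :]
    d2 = np.einsum("nkd,nkd->nk", diff, diff)
    return spec.depths[None, :] - d2 / (2.0 * spec.widths[None, :] ** 2)


def potential_energy(spec: PotentialSpec, x) -> float | np.ndarray:
    """U(x) in kT units; vectorized over a leading frame axis."""
    x2, squeeze = _check_x(spec, x)
    if spec.form == "harmonic":
        d2 = np.sum((x2 - spec.centers[0]) ** 2, axis=1)
        u = d2 / (2.0 * spec.widths[0] ** 2)
    else:
        u = -logsumexp(_mixture_exponents(spec, x2), axis=1)
    return float(u[0]) if squeeze else u


def potential_gradient(spec: PotentialSpec, x) -> np.ndarray:
    """∇U(x); for the mixture, a softmax-weighted sum of per-well springs."""
    x2, squeeze = _check_x(spec, x)
    if spec.form == "harmonic":
        g = (x2 - spec.centers[0]) / spec.widths[0] ** 2
    else:
        a = _mixture_exponents(spec, x2)
        a = a - a.max(axis=1, keepdims=True)
        s = np.exp(a)
        s /= s.sum(axis=1, keepdims=True)
        diff = x2[:, None, :] - spec.centers[None, :, :]
        g = np.einsum("nk,nkd->nd", s / spec.widths[None, :] ** 2, diff)
    return g[0] if squeeze else g


def domain_bounds(spec: PotentialSpec, pad: float = DOMAIN_PAD_WIDTHS) -> np.ndarray:
    """(dim, 2) bounding rectangle covering all wells ± pad·width."""
    lo = (spec.centers - pad * spec.widths[:, None]).min(axis=0)
    hi = (spec.centers + pad * spec.widths[:, None]).max(axis=0)
    return np.stack([lo, hi], axis=1)


def boltzmann_grid(spec: PotentialSpec, kT: float = 1.0,
                   n_quad: int | None = None):
    """Quadrature nodes (m, dim) and Boltzmann weights e^{-U/kT}·dV.

    Midpoint rule on a regular grid over :func:`domain_bounds`.  The default
    resolution (4000 nodes per axis in 1D, 500 in 2D) keeps the node spacing
    well below both the well widths and typical analysis bin widths.
    """
    if n_quad is None:
        n_quad = 4000 if spec.dim == 1 else 500
    bounds = domain_bounds(spec)
    axes, cell = [], 1.0
    for lo, hi in bounds:
        step = (hi - lo) / n_quad
        axes.append(lo + step * (np.arange(n_quad) + 0.5))
        cell *= step
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    u = potential_energy(spec, pts)
    wt = np.exp(-(u - u.min()) / kT) * cell
    return pts, wt


def analytic_marginal_fes(spec: PotentialSpec, cv, edges, kT: float = 1.0,
                          n_quad: int | None = None) -> FESProfile:
    """Quadrature free-energy profile along a CV: F(b) = -kT log ∫_b e^{-U/kT}.

    The profile is shifted so its minimum is 0.  Probability falling outside
    the binning range is dropped (the profile is normalized over the covered
    range); empty bins get NaN.
    """
    pts, wt = boltzmann_grid(spec, kT=kT, n_quad=n_quad)
    s = cv.value(pts)
    edges = np.asarray(edges, dtype=float)
    p, _ = np.histogram(s, bins=edges, weights=wt)
    tot = p.sum()
    if tot <= 0:
        raise ValueError("no Boltzmann weight falls inside the binning range")
    p = p / tot
    with np.errstate(divide="ignore"):
        F = np.where(p > 0, -kT * np.log(np.maximum(p, 1e-300)), np.nan)
    F = F - np.nanmin(F)
    return FESProfile(edges=edges, free_energy=F, errors=None, probabilities=p)


def quadrature_state_populations(spec: PotentialSpec, cv,
                                 partition: StatePartition,
                                 kT: float = 1.0, n_quad: int | None = None) -> dict:
    """Exact (quadrature) populations of the partition's states."""
    pts, wt = boltzmann_grid(spec, kT=kT, n_quad=n_quad)
    codes = partition.assign(cv.value(pts))
    tot = wt.sum()
    return {
        label: float(wt[codes == k].sum() / tot)
        for k, label in enumerate(partition.labels)
    }


def make_reference_dataset(spec: PotentialSpec, model, partition_cv=None,
                           partition: StatePartition | None = None,
                           method: str = "quadrature", kT: float = 1.0,
                           n_quad: int | None = None, integrator=None) -> ReferenceEnsemble:
    """Synthetic target data: Boltzmann-ensemble averages of a forward model.

    d_i = ⟨f_i(X)⟩ over the ensemble of ``spec`` — the stand-in for target
    intensities computed from a trusted reference ensemble.  ``method`` is
    either exact quadrature or a long unbiased run (``integrator`` required).
    """
    if method == "quadrature":
        pts, wt = boltzmann_grid(spec, kT=kT, n_quad=n_quad)
        F = model.values(pts)
        d = wt @ F / wt.sum()
        provenance = "quadrature"
        if partition is not None and partition_cv is not None:
            pops = quadrature_state_populations(spec, partition_cv, partition,
                                                kT=kT, n_quad=n_quad)
        else:
            pops = {"all": 1.0}
    elif method == "long-run":
        if integrator is None:
            raise ValueError("method='long-run' requires an integrator config")
        from .dynamics import run_trajectory

        traj = run_trajectory(spec, integrator)
        F = model.values(traj.coords)
        d = F.mean(axis=0)
        provenance = "long-run"
        if partition is not None and partition_cv is not None:
            codes = partition.assign(partition_cv.value(traj.coords))
            pops = {
                label: float(np.mean(codes == k))
                for k, label in enumerate(partition.labels)
            }
        else:
            pops = {"all": 1.0}
    else:
        raise ValueError(f"unknown method {method!r}")
    return ReferenceEnsemble(
        observable_ids=tuple(model.ids),
        d=np.atleast_1d(d),
        populations=pops,
        provenance=provenance,
    )


def perturb_potential(spec: PotentialSpec, depth_shifts) -> PotentialSpec:
    """Shift per-well depths — the toy analogue of swapping the force field.

    With the log-sum-exp mixture form, deepening well k by ΔD multiplies its
    Boltzmann population by e^{ΔD} exactly (up to well overlap).
    """
    shifts = np.atleast_1d(np.asarray(depth_shifts, dtype=float))
    if shifts.shape != spec.depths.shape:
        raise ValueError("one depth shift per well")
    if not np.all(np.isfinite(shifts)):
        raise ValueError("depth shifts must be finite")
    return replace(spec, depths=spec.depths + shifts)
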