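"""Ready-made toy systems emulating a three-state folder probed by SAXS.

The defaults mirror a small peptide that populates folded, misfolded and
unfolded states with different compactness: a 2D three-well landscape with a
size-like CV s(x) that grows from the folded to the unfolded basin, a
distance-from-folded CV standing in for an RMSD from the native structure,
and a Guinier-like intensity grid of 24 scattering angles between 0.01 and
1.39 (inverse length) as the synthetic target observable.

Well depths are solved from requested state populations: for the
log-sum-exp mixture, well k carries Boltzmann mass e^{D_k} (2π w_k²)^{dim/2},
so D_k = log p_k - (dim/2) log(2π w_k²) gives the target populations exactly
up to well overlap.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cvs import CollectiveVariable, CoordinateCV, DistanceCV, LinearCV
from .potentials import PotentialSpec
from .stats import StatePartition

__all__ = [
    "ToySystem",
    "depths_for_populations",
    "double_well_1d",
    "two_state_1d",
    "three_well_2d",
    "saxs_q_grid",
]

N_SAXS_POINTS = 24
Q_MIN, Q_MAX = 0.01, 1.39


def saxs_q_grid() -> np.ndarray:
    """24 equally spaced scattering angles between 0.01 and 1.39."""
    return np.linspace(Q_MIN, Q_MAX, N_SAXS_POINTS)


@dataclass(frozen=True)
class ToySystem:
    """A potential plus the CVs and state partition used to analyze it."""

    spec: PotentialSpec
    cvs: tuple
    size_cv: CollectiveVariable
    partition_cv: CollectiveVariable
    partition: StatePartition

    def cv(self, name: str) -> CollectiveVariable:
        for cv in self.cvs:
            if cv.name == name:
                return cv
        raise KeyError(f"no CV named {name!r}")

    def start_points(self, n: int, rng: np.random.Generator,
                     populations=None, jitter: float = 0.5) -> np.ndarray:
        """n starting points drawn from the wells.

        Wells are chosen with the given probabilities (default: proportional
        to the spec's own well masses) and jittered by ``jitter`` well widths.
        Emulates seeding walkers from a pool of prior conformations.
        """
        spec = self.spec
        if populations is None:
            dim = spec.dim
            mass = spec.depths + 0.5 * dim * np.log(2 * np.pi * spec.widths**2)
            populations = np.exp(mass - mass.max())
        populations = np.asarray(populations, dtype=float)
        populations = populations / populations.sum()
        wells = rng.choice(spec.n_wells, size=n, p=populations)
        pts = spec.centers[wells]
        pts = pts + jitter * spec.widths[wells, None] * rng.standard_normal(pts.shape)
        return pts


def depths_for_populations(populations, widths, dim: int) -> np.ndarray:
    """Well depths D_k giving the requested populations in the mixture form."""
    p = np.asarray(populations, dtype=float)
    w = np.asarray(widths, dtype=float)
    if np.any(p <= 0) or abs(p.sum() - 1) > 1e-9:
        raise ValueError("populations must be positive and sum to 1")
    return np.log(p) - 0.5 * dim * np.log(2 * np.pi * w**2)


def double_well_1d(barrier_kT: float = 8.0, half_separation: float = 2.0,
                   ) -> ToySystem:
    """Symmetric 1D double well with a prescribed barrier height.

    For wells at ±a with equal depths and width w the barrier is
    a²/(2w²) - ln 2 (the log-sum-exp saddle at the midpoint), so
    w = a / sqrt(2 (B + ln 2)).  The default separation keeps the curvature
    at the barrier top (≈ 2B/w²) small enough that first-order Langevin
    discretization does not distort the stationary density at usual time
    steps.
    """
    a = float(half_separation)
    w = a / np.sqrt(2.0 * (barrier_kT + np.log(2.0)))
    spec = PotentialSpec(
        form="multiwell",
        centers=np.array([[-a], [a]]),
        depths=np.zeros(2),
        widths=np.full(2, w),
        labels=("left", "right"),
    )
    x = CoordinateCV(0, name="x")
    size = LinearCV([0.2], intercept=1.2, name="size")
    dist = DistanceCV([-a], name="dist")
    partition = StatePartition(thresholds=(a,), labels=("left", "right"))
    return ToySystem(spec=spec, cvs=(x, size, dist), size_cv=size,
                     partition_cv=dist, partition=partition)


def two_state_1d(populations=(0.5, 0.5), centers=(-1.2, 1.2),
                 width: float = 0.45) -> ToySystem:
    """Two-state 1D system (folded/unfolded) with tunable populations.

    The size CV s(x) = 1.2 + 0.2 x puts the folded state at s ≈ 0.96 and the
    unfolded one at s ≈ 1.44, the compaction contrast a small peptide shows
    between native and unfolded ensembles.  Well width and separation keep
    the inter-well barrier a few kT with mild curvature everywhere (gentle
    on first-order Langevin discretization).
    """
    widths = np.full(2, float(width))
    depths = depths_for_populations(populations, widths, dim=1)
    spec = PotentialSpec(
        form="multiwell",
        centers=np.array([[centers[0]], [centers[1]]]),
        depths=depths,
        widths=widths,
        labels=("folded", "unfolded"),
    )
    x = CoordinateCV(0, name="x")
    size = LinearCV([0.2], intercept=1.2, name="size")
    dist = DistanceCV([centers[0]], name="dist")
    half = 0.5 * abs(centers[1] - centers[0])
    partition = StatePartition(thresholds=(half,), labels=("folded", "unfolded"))
    return ToySystem(spec=spec, cvs=(x, size, dist), size_cv=size,
                     partition_cv=dist, partition=partition)


def three_well_2d(populations=(0.55, 0.15, 0.30)) -> ToySystem:
    """2D three-well landscape: folded, misfolded and unfolded analogues.

    Geometry: folded at the origin, misfolded at (2.6, 0), unfolded at
    (3.4, 3.4) (broadest well — the entropic, expanded state).  The distance
    from the folded center is the RMSD analogue partitioning the states at
    1.5 and 3.6; the size CV s = 1 + 0.12 (x₁ + x₂) rises from ≈1.0 (folded)
    to ≈1.8 (unfolded) so the Guinier-like intensities discriminate the
    states.  Well widths are broad enough that barrier-top curvature stays
    mild for first-order Langevin stepping.
    """
    centers = np.array([[0.0, 0.0], [2.6, 0.0], [3.4, 3.4]])
    widths = np.array([0.45, 0.50, 0.62])
    depths = depths_for_populations(populations, widths, dim=2)
    spec = PotentialSpec(
        form="multiwell",
        centers=centers,
        depths=depths,
        widths=widths,
        labels=("folded", "misfolded", "unfolded"),
    )
    x1, x2 = CoordinateCV(0), CoordinateCV(1)
    size = LinearCV([0.12, 0.12], intercept=1.0, name="size")
    dist = DistanceCV([0.0, 0.0], name="dist")
    partition = StatePartition(
        thresholds=(1.5, 3.6), labels=("folded", "misfolded", "unfolded")
    )
    return ToySystem(spec=spec, cvs=(x1, x2, size, dist), size_cv=size,
                     partition_cv=dist, partition=partition)
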