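"""Optimized linear combinations of simple collective variables.

Given N input CVs φ and two or more labeled states, build a single
discriminating CV(a, φ) = Σ_i a_i φ_i with a normalized weight vector
(Σ a_i² = 1) by minimizing the scoring function

    ψ(a) = - (⟨CV₁⟩ - ⟨CV₂⟩)² / (σ²_CV1 + σ²_CV2)
           + max(σ_CV1, σ_CV2) / min(σ_CV1, σ_CV2)
           + Σ_i a_i² log( a_i² / (1/N) )

whose three terms respectively maximize state discrimination, keep the
widths of the two minima comparable (important for Gaussian-hill methods),
and keep the weights as uniform as possible (a KL divergence of {a_i²} from
uniform, ≥ 0 with equality iff uniform).  Per-state CV means and variances
come from the state's mean vector μ and full covariance C of the inputs:
⟨CV⟩ = a·μ and σ²_CV = aᵀ C a.

For more than two states the discrimination and width-ratio terms are
summed over all unordered state pairs and the entropy term enters once.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "StateSummary",
    "CombinationWeights",
    "PsiScore",
    "state_summary",
    "evaluate_cv",
    "psi_score",
    "psi_score_multistate",
    "optimize_weights",
]


@dataclass(frozen=True)
class StateSummary:
    """Mean vector and covariance of the input CVs within one labeled state."""

    label: str
    mean: np.ndarray
    cov: np.ndarray
    count: int

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        n = mean.shape[0]
        if cov.shape != (n, n):
            raise ValueError("covariance shape must match the mean vector")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if self.count < 2:
            raise ValueError("a state summary needs at least 2 samples")

    @property
    def n_cvs(self) -> int:
        return self.mean.shape[0]


@dataclass(frozen=True)
class CombinationWeights:
    """Normalized weight vector a (Σ a_i² = 1, first nonzero entry > 0)."""

    a: np.ndarray
    cv_names: tuple = ()

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        object.__setattr__(self, "a", a)
        if abs(np.sum(a**2) - 1.0) > 1e-9:
            raise ValueError("weights must satisfy sum a_i^2 = 1")
        nz = np.nonzero(a)[0]
        if nz.size and a[nz[0]] < 0:
            raise ValueError("sign convention: first nonzero component positive")
        if self.cv_names and len(self.cv_names) != len(a):
            raise ValueError("one name per weight")

    @property
    def n(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class PsiScore:
    """Breakdown of ψ(a): discrimination (≤0), width ratio (≥1), entropy (≥0)."""

    discrimination: float
    width_ratio: float
    entropy: float

    @property
    def total(self) -> float:
        return self.discrimination + self.width_ratio + self.entropy


def state_summary(samples, label: str = "state") -> StateSummary:
    """Unbiased mean/covariance summary of per-frame CV samples (n, N)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 2:
        raise ValueError("need at least 2 samples per state")
    mean = samples.mean(axis=0)
    cov = np.cov(samples, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return StateSummary(label=label, mean=mean, cov=cov, count=samples.shape[0])


def evaluate_cv(weights: CombinationWeights | np.ndarray, phi) -> float | np.ndarray:
    """CV(a, φ) = Σ_i a_i φ_i; vectorized over a leading frame axis."""
    a = np.asarray(getattr(weights, "a", weights), dtype=float)
    phi = np.asarray(phi, dtype=float)
    if phi.shape[-1] != len(a):
        raise ValueError("phi length does not match the weight vector")
    return phi @ a


def _entropy_term(a2: np.ndarray) -> float:
    n = len(a2)
    mask = a2 > 0
    return float(np.sum(a2[mask] * np.log(a2[mask] * n)))  # 0·log 0 := 0


def _pair_terms(a: np.ndarray, s1: StateSummary, s2: StateSummary):
    m1, m2 = a @ s1.mean, a @ s2.mean
    v1 = float(a @ s1.cov @ a)
    v2 = float(a @ s2.cov @ a)
    if v1 <= 0 or v2 <= 0:
        raise ValueError(
            f"zero CV variance in state {s1.label!r} or {s2.label!r}; "
            "width ratio undefined"
        )
    disc = -((m1 - m2) ** 2) / (v1 + v2)
    sd1, sd2 = np.sqrt(v1), np.sqrt(v2)
    width = max(sd1, sd2) / min(sd1, sd2)
    return disc, width


def psi_score(weights, s1: StateSummary, s2: StateSummary) -> PsiScore:
    """Two-state ψ(a) with its per-term breakdown."""
    a = np.asarray(getattr(weights, "a", weights), dtype=float)
    if s1.n_cvs != len(a) or s2.n_cvs != len(a):
        raise ValueError("state summaries and weights must share N")
    disc, width = _pair_terms(a, s1, s2)
    return PsiScore(discrimination=disc, width_ratio=width,
                    entropy=_entropy_term(a**2))


def psi_score_multistate(weights, summaries) -> PsiScore:
    """ψ over ≥2 states: pairwise discrimination/width sums + one entropy."""
    summaries = list(summaries)
    if len(summaries) < 2:
        raise ValueError("need at least 2 states")
    a = np.asarray(getattr(weights, "a", weights), dtype=float)
    disc = width = 0.0
    for s1, s2 in combinations(summaries, 2):
        d, w = _pair_terms(a, s1, s2)
        disc += d
        width += w
    return PsiScore(discrimination=disc, width_ratio=width,
                    entropy=_entropy_term(a**2))


def _canonical(a: np.ndarray) -> np.ndarray:
    a = a / np.linalg.norm(a)
    nz = np.nonzero(np.abs(a) > 1e-12)[0]
    if nz.size and a[nz[0]] < 0:
        a = -a
    return a


def optimize_weights(summaries, n_starts: int = 16, seed: int = 0,
                     tol: float = 1e-12,
                     cv_names: tuple = ()) -> tuple[CombinationWeights, PsiScore]:
    """Minimize ψ(a) on the unit sphere by seeded multi-start local search.

    Starts are the uniform vector plus ``n_starts`` random unit vectors;
    ψ is invariant under a → -a and only depends on the direction of a, so
    the optimization runs over an unconstrained vector normalized inside the
    objective.  Nelder-Mead handles the kink where the max/min width switch
    crosses.  Returns the best weights (sign convention applied) with the
    score breakdown.
    """
    summaries = list(summaries)
    if len(summaries) < 2:
        raise ValueError("need at least 2 states")
    n = summaries[0].n_cvs
    if n < 2:
        raise ValueError("need at least 2 input CVs to combine")

    def objective(v):
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            return np.inf
        return psi_score_multistate(v / nv, summaries).total

    rng = np.random.default_rng(seed)
    starts = [np.full(n, 1.0 / np.sqrt(n))]
    for _ in range(n_starts):
        v = rng.standard_normal(n)
        starts.append(v / np.linalg.norm(v))

    best_a, best_val = None, np.inf
    n_converged = 0
    for v0 in starts:
        res = minimize(objective, v0, method="Nelder-Mead",
                       options={"xatol": tol, "fatol": tol, "maxiter": 2000})
        if not np.isfinite(res.fun):
            continue
        n_converged += 1
        if res.fun < best_val:
            best_val = res.fun
            best_a = _canonical(res.x)
    if best_a is None:
        raise RuntimeError("no optimization start converged to a finite score")
    weights = CombinationWeights(a=best_a, cv_names=tuple(cv_names))
    return weights, psi_score_multistate(best_a, summaries)
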