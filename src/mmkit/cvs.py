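"""Collective variables (CVs) on toy coordinates.

A CV is a scalar function s(x) of the microscopic coordinates together with
its gradient; biasing and forward models only ever touch coordinates through
CVs.  All implementations are vectorized over a leading frame axis: ``value``
maps an (n, dim) array to (n,) and ``gradient`` to (n, dim).
"""
from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np

__all__ = [
    "CollectiveVariable",
    "CoordinateCV",
    "LinearCV",
    "DistanceCV",
    "CombinationCV",
]


def _atleast_2d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


class CollectiveVariable(ABC):
    """Scalar function of coordinates with an analytic gradient."""

    name: str

    @abstractmethod
    def value(self, x: np.ndarray) -> np.ndarray:
        """CV value per frame; (n, dim) -> (n,) (scalar in, scalar out)."""

    @abstractmethod
    def gradient(self, x: np.ndarray) -> np.ndarray:
        """d s / d x per frame; (n, dim) -> (n, dim)."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}({self.name!r})"


class CoordinateCV(CollectiveVariable):
    """One Cartesian component of the coordinates."""

    def __init__(self, index: int, name: str | None = None):
        self.index = int(index)
        self.name = name if name is not None else f"x{self.index + 1}"

    def value(self, x):
        x2, squeeze = _atleast_2d(x)
        v = x2[:, self.index].copy()
        return v[0] if squeeze else v

    def gradient(self, x):
        x2, squeeze = _atleast_2d(x)
        g = np.zeros_like(x2)
        g[:, self.index] = 1.0
        return g[0] if squeeze else g


class LinearCV(CollectiveVariable):
    """Affine function c·x + b, e.g. the size-like CV of the toy systems."""

    def __init__(self, coeffs, intercept: float = 0.0, name: str = "linear"):
        self.coeffs = np.asarray(coeffs, dtype=float)
        self.intercept = float(intercept)
        self.name = name

    def value(self, x):
        x2, squeeze = _atleast_2d(x)
        v = x2 @ self.coeffs + self.intercept
        return v[0] if squeeze else v

    def gradient(self, x):
        x2, squeeze = _atleast_2d(x)
        g = np.broadcast_to(self.coeffs, x2.shape).copy()
        return g[0] if squeeze else g


class DistanceCV(CollectiveVariable):
    """Euclidean distance from a reference point.

    Plays the role of an RMSD from a reference (folded) structure: the
    three-state partition of the toy systems is defined on this CV.
    """

    def __init__(self, center, name: str = "dist"):
        self.center = np.atleast_1d(np.asarray(center, dtype=float))
        self.name = name

    def value(self, x):
        x2, squeeze = _atleast_2d(x)
        r = np.linalg.norm(x2 - self.center, axis=1)
        return r[0] if squeeze else r

    def gradient(self, x):
        x2, squeeze = _atleast_2d(x)
        d = x2 - self.center
        r = np.linalg.norm(d, axis=1)
        # direction undefined at the center; return 0 there
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(r[:, None] > 0, d / np.maximum(r, 1e-300)[:, None], 0.0)
        return g[0] if squeeze else g


class CombinationCV(CollectiveVariable):
    """Normalized linear combination CV(a, phi) = sum_i a_i phi_i(x)."""

    def __init__(self, weights, cvs: list[CollectiveVariable], name: str = "combo"):
        weights = np.asarray(getattr(weights, "a", weights), dtype=float)
        if len(weights) != len(cvs):
            raise ValueError(
                f"{len(weights)} weights for {len(cvs)} input CVs"
            )
        self.weights = weights
        self.cvs = list(cvs)
        self.name = name

    def value(self, x):
        x2, squeeze = _atleast_2d(x)
        v = sum(a * cv.value(x2) for a, cv in zip(self.weights, self.cvs))
        return v[0] if squeeze else v

    def gradient(self, x):
        x2, squeeze = _atleast_2d(x)
        g = sum(a * cv.gradient(x2) for a, cv in zip(self.weights, self.cvs))
        return g[0] if squeeze else g
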