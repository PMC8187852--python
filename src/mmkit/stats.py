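"""Weighted-ensemble statistics for reweighted trajectories.

Frames coming out of a metadynamics run carry statistical weights
w_i ∝ exp(V_final(s_i)/kT).  Everything here therefore works on weighted
series: Kish effective sample sizes, weighted block-average errors with the
effective number of blocks NB_eff = (Σ W_b)² / Σ W_b², free-energy profiles
F_b = -kT log p_b, three-state populations, folded↔unfolded transition
counts, replicate averaging, and the R-factor agreement measure between
intensity profiles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WeightedSeries",
    "StatePartition",
    "FESProfile",
    "BlockErrorCurve",
    "effective_frames",
    "weighted_block_error",
    "block_error_curve",
    "weighted_fes",
    "state_populations",
    "count_transitions",
    "replicate_average_populations",
    "replicate_average_fes",
    "rfactor",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class WeightedSeries:
    """Observable time series with per-frame statistical weights.

    Weights are normalized to sum to one on construction.
    """

    times: np.ndarray
    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if not (len(self.times) == len(self.values) == len(w)):
            raise ValueError("times, values and weights must be aligned")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        tot = w.sum()
        if tot <= 0:
            raise ValueError("weights must not all be zero")
        self.weights = w / tot

    @property
    def n_frames(self) -> int:
        return len(self.values)

    def effective_frames(self) -> float:
        return effective_frames(self.weights)


@dataclass(frozen=True)
class StatePartition:
    """Ordered thresholds on a reference-distance CV defining labeled states.

    Intervals are half-open on the left: state 0 is (-inf, t1], state 1 is
    (t1, t2], ... so a frame exactly at a threshold belongs to the lower
    state (deterministic assignment).
    """

    thresholds: tuple
    labels: tuple

    def __post_init__(self):
        thr = tuple(float(t) for t in self.thresholds)
        object.__setattr__(self, "thresholds", thr)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != len(thr) + 1:
            raise ValueError("need exactly one more label than thresholds")
        if any(a >= b for a, b in zip(thr, thr[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def assign(self, values) -> np.ndarray:
        """Integer state codes per frame (0 .. n_states-1)."""
        values = np.asarray(values, dtype=float)
        return np.searchsorted(np.asarray(self.thresholds), values, side="left")


@dataclass
class FESProfile:
    """Binned free-energy profile, shifted so its minimum is zero."""

    edges: np.ndarray
    free_energy: np.ndarray          # kT units; NaN on empty bins
    errors: np.ndarray | None
    probabilities: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self) -> pd.DataFrame:
        d = {
            "bin_center": self.centers,
            "free_energy": self.free_energy,
            "probability": self.probabilities,
        }
        if self.errors is not None:
            d["error"] = self.errors
        return pd.DataFrame(d)


@dataclass
class BlockErrorCurve:
    block_lengths: np.ndarray
    n_blocks: np.ndarray
    errors: np.ndarray
    nb_eff: np.ndarray
    plateau: bool
    plateau_value: float


# ---------------------------------------------------------------------------
# effective sample size


def effective_frames(weights) -> float:
    """Kish effective sample size NF_eff = (Σ w_i)² / Σ w_i²."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(w > 0):
        raise ValueError("weights must not all be zero")
    w = w / w.max()   # scale-invariant; keeps squares away from under/overflow
    s = w.sum()
    return float(s * s / np.sum(w * w))


# ---------------------------------------------------------------------------
# block averaging


def _block_slices(n: int, n_blocks: int) -> list[slice]:
    """Contiguous equal-frame-count blocks; trailing remainder merged into
    the last block."""
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    length = n // n_blocks
    if length < 1:
        raise ValueError(f"cannot split {n} frames into {n_blocks} blocks")
    slices = [slice(b * length, (b + 1) * length) for b in range(n_blocks)]
    slices[-1] = slice((n_blocks - 1) * length, n)
    return slices


def weighted_block_error(values, weights, n_blocks: int) -> float:
    """Weighted block-average error of the mean of a correlated series.

    The series is split into NB contiguous blocks with weights
    W_b = Σ_{i∈b} w_i and block averages Ō_b.  The error estimate is

        err(O) = sqrt[ 1/(NB_eff - 1) · Σ_b W_b (Ō_b - Ō)² / Σ_b W_b ]

    with NB_eff = (Σ W_b)²/Σ W_b² the effective number of blocks and Ō the
    weight-grand mean.  Using NB in place of NB_eff underestimates the error
    when block weights are unbalanced.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must be aligned")
    slices = _block_slices(len(values), n_blocks)
    W = np.array([weights[s].sum() for s in slices])
    empty = np.nonzero(W <= 0)[0]
    if empty.size:
        raise ValueError(f"blocks with zero total weight: {empty.tolist()}")
    means = np.array([np.average(values[s], weights=weights[s]) for s in slices])
    grand = np.average(means, weights=W)
    nb_eff = W.sum() ** 2 / np.sum(W**2)
    var = np.sum(W * (means - grand) ** 2) / W.sum()
    return float(np.sqrt(var / (nb_eff - 1.0))) if nb_eff > 1.0 else float("inf")


def block_error_curve(values, weights, block_lengths) -> BlockErrorCurve:
    """Block error as a function of block length, with plateau detection.

    The error of a correlated series grows with block length until blocks
    decorrelate; a plateau (relative change < 10% across the two largest
    lengths) signals convergence of the estimate.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    lengths = np.asarray(sorted(int(L) for L in block_lengths))
    if len(lengths) < 2:
        raise ValueError("need at least 2 block lengths")
    n = len(values)
    errs, nbs, nbeffs = [], [], []
    for L in lengths:
        nb = n // L
        if nb < 2:
            raise ValueError(f"block length {L} leaves fewer than 2 blocks")
        err = weighted_block_error(values, weights, nb)
        slices = _block_slices(n, nb)
        W = np.array([weights[s].sum() for s in slices])
        errs.append(err)
        nbs.append(nb)
        nbeffs.append(W.sum() ** 2 / np.sum(W**2))
    errs = np.array(errs)
    top, prev = errs[-1], errs[-2]
    denom = max(abs(top), abs(prev), 1e-300)
    plateau = bool(abs(top - prev) / denom < 0.10)
    return BlockErrorCurve(
        block_lengths=lengths,
        n_blocks=np.array(nbs),
        errors=errs,
        nb_eff=np.array(nbeffs),
        plateau=plateau,
        plateau_value=float(top),
    )


# ---------------------------------------------------------------------------
# free-energy profiles and populations


def weighted_fes(values, weights, edges, kT: float = 1.0,
                 n_blocks: int = 10) -> FESProfile:
    """Free-energy profile F_b = -kT log p_b from a weighted series.

    p_b is the total weight in bin b; the profile is shifted so its minimum
    is zero, and per-bin errors come from a weighted block-average error on
    the bin indicator series propagated as kT · err_p / p_b.  Empty bins get
    NaN free energy.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    edges = np.asarray(edges, dtype=float)
    w = weights / weights.sum()
    p, _ = np.histogram(values, bins=edges, weights=w)
    inside = p.sum()
    if inside <= 0:
        raise ValueError("no weight falls inside the binning range")
    p = p / inside
    with np.errstate(divide="ignore"):
        F = np.where(p > 0, -kT * np.log(np.maximum(p, 1e-300)), np.nan)
    F = F - np.nanmin(F)
    errors = np.full(len(p), np.nan)
    if n_blocks and n_blocks >= 2:
        idx = np.digitize(values, edges[1:-1], right=False)
        for b in range(len(p)):
            if p[b] <= 0:
                continue
            indicator = (idx == b).astype(float)
            try:
                err_p = weighted_block_error(indicator, w, n_blocks)
            except ValueError:
                continue
            errors[b] = kT * err_p / (p[b] * inside)
    return FESProfile(edges=edges, free_energy=F, errors=errors, probabilities=p)


def state_populations(values, weights, partition: StatePartition,
                      n_blocks: int = 10) -> pd.DataFrame:
    """Per-state weighted populations with block-average errors."""
    values = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    codes = partition.assign(values)
    rows = []
    for k, label in enumerate(partition.labels):
        indicator = (codes == k).astype(float)
        pop = float(np.sum(w * indicator))
        err = np.nan
        if n_blocks and n_blocks >= 2:
            try:
                err = weighted_block_error(indicator, w, n_blocks)
            except ValueError:
                pass
        rows.append({"state": label, "population": pop, "error": err})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# transitions


def count_transitions(label_series, partition: StatePartition,
                      total_time: float) -> pd.DataFrame:
    """Transitions between the two extreme states of the partition.

    A transition folded→unfolded is counted when a walker whose last
    extreme-state visit was the folded state enters the unfolded one;
    excursions into intermediate states neither count nor reset.  Rates are
    counts per unit time with Poisson (√count) uncertainties.
    """
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    if isinstance(label_series, np.ndarray) and label_series.ndim == 1:
        label_series = [label_series]
    lo, hi = 0, partition.n_states - 1
    lo_lab, hi_lab = partition.labels[lo], partition.labels[hi]
    counts = {(lo_lab, hi_lab): 0, (hi_lab, lo_lab): 0}
    for series in label_series:
        codes = np.asarray(series)
        if codes.dtype.kind in "UO":  # label strings -> codes
            lut = {lab: k for k, lab in enumerate(partition.labels)}
            codes = np.array([lut[v] for v in codes])
        pole = None
        for c in codes:
            if c == lo or c == hi:
                if pole is not None and c != pole:
                    src = lo_lab if pole == lo else hi_lab
                    dst = lo_lab if c == lo else hi_lab
                    counts[(src, dst)] += 1
                pole = c
    rows = []
    for (src, dst), n in counts.items():
        rows.append({
            "direction": f"{src}->{dst}",
            "count": n,
            "rate": n / total_time,
            "rate_error": np.sqrt(n) / total_time,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# replicate averaging


def replicate_average_populations(population_sets) -> pd.DataFrame:
    """Mean and standard error of state populations over replicate runs."""
    arr = np.asarray(population_sets, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 replicates of aligned population vectors")
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    std = arr.std(axis=0, ddof=1)
    return pd.DataFrame({
        "population": mean,
        "error": std / np.sqrt(n),
    })


def replicate_average_fes(profiles: list[FESProfile], kT: float = 1.0) -> FESProfile:
    """Average replicate FES profiles on the probability scale.

    F̄_b = -kT log p̄_b with p̄_b the mean bin probability over n replicates
    and err(F̄_b) = kT σ_p / (p̄_b √n) — for triplicates the 1/√3 factor.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 replicate profiles")
    edges = profiles[0].edges
    for pr in profiles[1:]:
        if pr.edges.shape != edges.shape or not np.allclose(pr.edges, edges):
            raise ValueError("replicate profiles must share identical binning")
    P = np.stack([pr.probabilities for pr in profiles])
    n = P.shape[0]
    pbar = P.mean(axis=0)
    sp = P.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(pbar > 0, -kT * np.log(np.maximum(pbar, 1e-300)), np.nan)
        err = np.where(pbar > 0, kT * sp / np.maximum(pbar, 1e-300) / np.sqrt(n), np.nan)
    F = F - np.nanmin(F)
    return FESProfile(edges=edges, free_energy=F, errors=err, probabilities=pbar)


# ---------------------------------------------------------------------------
# intensity agreement


def rfactor(intensity, intensity_ref) -> float:
    """Mean relative deviation (%) between calculated and target profiles:
    R = mean_q |I_q - I_ref,q| / I_ref,q × 100."""
    I = np.asarray(intensity, dtype=float)
    Iref = np.asarray(intensity_ref, dtype=float)
    if I.shape != Iref.shape:
        raise ValueError("profiles must share the same grid")
    if np.any(Iref <= 0):
        raise ValueError("reference intensities must be positive")
    return float(np.mean(np.abs(I - Iref) / Iref) * 100.0)
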