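"""Vincentized quantile binning of epoched ERP amplitudes.

Each epoch is cut into equal-width time bins (twelve 100 ms bins over
-200..+1000 ms by default).  Within every (subject, condition, electrode,
bin) cell the amplitude samples are sorted and read off at mid-point
probabilities -- the left-continuous generalized inverse of the empirical
CDF -- and the per-subject quantile functions are then Vincent-averaged
(pointwise weighted mean of quantile functions) across subjects.  Because
quantile averaging preserves distribution shape for location-scale families,
the resulting bin values are robust to latency and shape differences between
individual subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "QuantileFunction",
    "BinTable",
    "empirical_quantile",
    "quantile_midpoints",
    "vincent_average",
    "vincentize_epochs",
]


@dataclass(frozen=True, eq=False)
class QuantileFunction:
    """Ordered (alpha, value) pairs with alpha in (0, 1), non-decreasing."""

    alphas: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if a.shape != v.shape or a.ndim != 1 or a.size == 0:
            raise ValueError("alphas and values must be matching 1-D arrays")
        if np.any(a <= 0) or np.any(a >= 1):
            raise ValueError("alphas must lie strictly inside (0, 1)")
        if np.any(np.diff(a) <= 0):
            raise ValueError("alphas must be strictly increasing")
        if np.any(np.diff(v) < -1e-12):
            raise ValueError("quantile values must be non-decreasing")
        object.__setattr__(self, "alphas", a)
        object.__setattr__(self, "values", v)

    def standardized(self) -> np.ndarray:
        """Values centered and scaled to zero mean, unit sd (shape check)."""
        v = self.values
        sd = v.std()
        if sd == 0:
            return np.zeros_like(v)
        return (v - v.mean()) / sd


def empirical_quantile(values: Sequence[float], alpha: float) -> float:
    """Left-continuous inverse empirical CDF.

    Returns the smallest sample value ``v`` such that ``F(v) >= alpha``,
    i.e. the ``ceil(n*alpha)``-th order statistic.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("empty sample")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    k = math.ceil(arr.size * alpha)
    return float(arr[max(k - 1, 0)])


def quantile_midpoints(values: Sequence[float], q: int | None = None) -> QuantileFunction:
    """Quantile function of a sample evaluated at the mid-points of ``q``
    equal-probability bins (``alpha = (k - 1/2)/q``).

    With ``q`` equal to the sample size (the default) this is exactly the
    sorted sample.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("empty sample")
    if q is None:
        q = arr.size
    if q < 1:
        raise ValueError("q must be >= 1")
    alphas = (np.arange(q) + 0.5) / q
    idx = np.ceil(arr.size * alphas).astype(int) - 1
    return QuantileFunction(alphas, arr[np.clip(idx, 0, arr.size - 1)])


def vincent_average(
    fns: Sequence[QuantileFunction], weights: Sequence[float] | None = None
) -> QuantileFunction:
    """Pointwise weighted average of quantile functions on a shared grid.

    Weights default to 1/n; they must be non-negative and sum to one within
    1e-9.
    """
    if not fns:
        raise ValueError("need at least one quantile function")
    base = fns[0].alphas
    for f in fns[1:]:
        if f.alphas.shape != base.shape or not np.allclose(f.alphas, base):
            raise ValueError("quantile functions must share one alpha grid")
    n = len(fns)
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("one weight per quantile function required")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
    stacked = np.stack([f.values for f in fns])
    return QuantileFunction(base.copy(), w @ stacked)


@dataclass(eq=False)
class BinTable:
    """Vincentized bin amplitudes.

    ``per_subject`` has shape ``(n_subjects, n_conditions, n_electrodes,
    n_bins)``; ``values`` is its subject mean (equal Vincent weights).
    ``bin_edges`` holds the ``n_bins + 1`` half-open edges in ms.
    """

    subjects: list[str]
    conditions: list[str]
    electrodes: list[str]
    bin_edges: np.ndarray
    per_subject: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.per_subject = np.asarray(self.per_subject, dtype=float)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.subjects),):
                raise ValueError("one Vincent weight per subject required")
        expected = (
            len(self.subjects),
            len(self.conditions),
            len(self.electrodes),
            self.bin_edges.size - 1,
        )
        if self.per_subject.shape != expected:
            raise ValueError(
                f"per_subject shape {self.per_subject.shape} != {expected}"
            )
        if not np.all(np.isfinite(self.per_subject)):
            raise ValueError("bin table contains non-finite values")

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def values(self) -> np.ndarray:
        """(n_conditions, n_electrodes, n_bins) group-level bin values
        (Vincent average across subjects; equal weights by default)."""
        if self.weights is None:
            return self.per_subject.mean(axis=0)
        return np.tensordot(self.weights, self.per_subject, axes=(0, 0))

    def condition_index(self, condition: str) -> int:
        try:
            return self.conditions.index(condition)
        except ValueError:
            raise KeyError(f"unknown condition {condition!r}") from None

    def differences(
        self, minuend: str = "target", subtrahend: str = "distractor"
    ) -> np.ndarray:
        """(n_electrodes, n_bins) signed difference of group bin values."""
        v = self.values
        return v[self.condition_index(minuend)] - v[self.condition_index(subtrahend)]

    def window(self, start_ms: float, end_ms: float) -> "BinTable":
        """Restrict to bins fully inside [start_ms, end_ms]."""
        keep = np.flatnonzero(
            (self.bin_edges[:-1] >= start_ms - 1e-9)
            & (self.bin_edges[1:] <= end_ms + 1e-9)
        )
        if keep.size == 0:
            raise ValueError(f"no bins inside [{start_ms}, {end_ms}] ms")
        edges = np.append(self.bin_edges[keep], self.bin_edges[keep[-1] + 1])
        return BinTable(
            subjects=list(self.subjects),
            conditions=list(self.conditions),
            electrodes=list(self.electrodes),
            bin_edges=edges,
            per_subject=self.per_subject[..., keep],
            weights=None if self.weights is None else self.weights.copy(),
        )


def vincentize_epochs(epochs, n_bins: int = 12, weights=None) -> BinTable:
    """Vincentize an epoch set into ``n_bins`` equal-width time bins.

    For every (subject, condition, electrode, bin) cell the within-bin
    amplitude sample is sorted and read at bin mid-point probabilities; the
    per-subject cell value is the mean of those mid-point quantiles, and the
    group value is the (weighted) Vincent average across subjects.  The
    distractor condition is binned identically to the target by
    construction, since the grid is shared.
    """
    data = epochs.data
    n_sub, n_cond, n_elec, n_time = data.shape
    if n_time % n_bins != 0:
        raise ValueError(
            f"epoch length {n_time} is not divisible into {n_bins} bins"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError("epoch grid is incomplete or non-finite")
    per_bin = n_time // n_bins
    # sort within bins: quantile mid-points at q = per-bin sample count are
    # exactly the sorted sample
    shaped = data.reshape(n_sub, n_cond, n_elec, n_bins, per_bin)
    quantiles = np.sort(shaped, axis=-1)
    if weights is None:
        w = np.full(n_sub, 1.0 / n_sub)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n_sub,):
            raise ValueError("one Vincent weight per subject required")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("Vincent weights must be non-negative and sum to 1")
    per_subject = quantiles.mean(axis=-1)
    edges = np.linspace(epochs.times[0], epochs.times[-1] + epochs.dt, n_bins + 1)
    return BinTable(
        subjects=list(epochs.subjects),
        conditions=list(epochs.conditions),
        electrodes=list(epochs.electrodes),
        bin_edges=edges,
        per_subject=per_subject,
        weights=None if weights is None else w,
    )
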