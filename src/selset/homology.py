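"""Structural and functional homology tests.

Structural: z-scores of grey-matter localization search ranges (mm) are
compared between the child-derived and simulated source sets.  Functional:
observed per-bin topographic maps are regressed on the simulated maps and
the fit summarized by the coefficient of determination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .actr import TopoMap

__all__ = [
    "ZRangeComparison",
    "TopoFit",
    "HomologyReport",
    "z_ranges",
    "compare_z_ranges",
    "topo_fit",
    "homology_report",
    "recovery_protocol",
]


def z_ranges(ranges) -> tuple[np.ndarray, bool]:
    """Standardize localization ranges: (x - mean) / sample sd.

    Returns ``(z_scores, degenerate)``; a spread-free input yields all
    zeros flagged degenerate.
    """
    arr = np.asarray(ranges, dtype=float)
    if arr.size == 0:
        raise ValueError("empty range list")
    if arr.size < 2:
        return np.zeros_like(arr), True
    sd = arr.std(ddof=1)
    if sd == 0:
        return np.zeros_like(arr), True
    return (arr - arr.mean()) / sd, False


@dataclass(frozen=True)
class ZRangeComparison:
    statistic: float
    p: float
    significant: bool
    method: str


def compare_z_ranges(
    child, simulated, alpha: float = 0.05, method: str = "welch"
) -> ZRangeComparison:
    """Two-sample comparison of localization z-scores (Welch t by default,
    Mann-Whitney behind a flag)."""
    a = np.asarray(child, dtype=float)
    b = np.asarray(simulated, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least two values")
    if method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):  # identical zero-variance groups
        stat, p = 0.0, 1.0
    return ZRangeComparison(stat, p, p < alpha, method)


@dataclass(frozen=True)
class TopoFit:
    condition: str
    time_ms: float
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p: float
    n: int


def topo_fit(actual: TopoMap, simulated: TopoMap) -> TopoFit:
    """OLS of the actual map on the simulated map over shared electrodes."""
    if actual.electrodes != simulated.electrodes:
        raise ValueError("maps must share one electrode set, in order")
    if actual.time_ms != simulated.time_ms or actual.condition != simulated.condition:
        raise ValueError("maps must describe the same bin and condition")
    x = simulated.values
    y = actual.values
    if np.allclose(x.std(), 0):
        raise ValueError("simulated map has zero variance; fit undefined")
    n = x.size
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    df = (1, n - 2)
    if r2 >= 1.0:
        f = float("inf")
    else:
        f = r2 * (n - 2) / (1.0 - r2)
    p = float(stats.f.sf(f, *df)) if np.isfinite(f) else 0.0
    return TopoFit(
        condition=actual.condition,
        time_ms=actual.time_ms,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        f_statistic=f,
        df=df,
        p=p,
        n=n,
    )


@dataclass(eq=False)
class HomologyReport:
    z_comparisons: dict[str, ZRangeComparison]
    fits: list[TopoFit]

    @property
    def min_r_squared(self) -> float:
        return min(f.r_squared for f in self.fits)

    @property
    def max_r_squared(self) -> float:
        return max(f.r_squared for f in self.fits)

    def fits_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(f) for f in self.fits])

    def structural_significant(self) -> bool:
        return any(c.significant for c in self.z_comparisons.values())


def homology_report(
    actual_maps: list[TopoMap],
    simulated_maps: list[TopoMap],
    child_ranges: pd.DataFrame | None = None,
    simulated_ranges: pd.DataFrame | None = None,
    alpha: float = 0.05,
    method: str = "welch",
) -> HomologyReport:
    """Aggregate per-bin regressions and per-condition z-range comparisons.

    Maps are matched on (condition, time); a simulated map without an
    actual counterpart (or vice versa) is an error.  Range tables need
    ``range_mm`` and ``condition`` columns.
    """
    sim_by_key = {(m.condition, m.time_ms): m for m in simulated_maps}
    act_by_key = {(m.condition, m.time_ms): m for m in actual_maps}
    if set(sim_by_key) != set(act_by_key):
        missing = set(sim_by_key) ^ set(act_by_key)
        raise ValueError(f"mismatched map bins: {sorted(missing)}")
    fits = [
        topo_fit(act_by_key[key], sim_by_key[key]) for key in sorted(act_by_key)
    ]
    z_comparisons: dict[str, ZRangeComparison] = {}
    if child_ranges is not None and simulated_ranges is not None:
        conds = sorted(set(child_ranges["condition"]) | set(simulated_ranges["condition"]))
        for cond in conds:
            child_vals = child_ranges.loc[
                child_ranges["condition"] == cond, "range_mm"
            ].to_numpy(dtype=float)
            sim_vals = simulated_ranges.loc[
                simulated_ranges["condition"] == cond, "range_mm"
            ].to_numpy(dtype=float)
            zc, _ = z_ranges(child_vals)
            zs, _ = z_ranges(sim_vals)
            z_comparisons[cond] = compare_z_ranges(zc, zs, alpha=alpha, method=method)
    return HomologyReport(z_comparisons=z_comparisons, fits=fits)


def recovery_protocol(
    seed: int = 0,
    noise_fraction: float = 0.1,
    conditions=("target", "distractor"),
    alpha: float = 0.05,
) -> HomologyReport:
    """Scaled-down functional/structural homology stand-in.

    Forward-simulate both condition dipole schedules, create synthetic
    observed maps by adding seeded Gaussian noise with sd equal to
    ``noise_fraction`` of each map's sd, and regress observed on simulated
    per bin; the packaged localization-range tables feed the structural
    comparison.
    """
    from .actr import simulate_condition
    from .fixtures import localization_ranges

    rng = np.random.default_rng(seed)
    actual, simulated = [], []
    for cond in conditions:
        _, _, maps = simulate_condition(cond)
        for m in maps:
            simulated.append(m)
            sd = float(m.values.std())
            noisy = m.values + rng.normal(0.0, noise_fraction * sd, size=m.values.shape)
            actual.append(
                TopoMap(
                    time_ms=m.time_ms,
                    condition=m.condition,
                    provenance="actual",
                    electrodes=list(m.electrodes),
                    values=noisy,
                )
            )
    ranges = localization_ranges()
    ranges = ranges[ranges["condition"].isin(conditions)]
    return homology_report(
        actual,
        simulated,
        child_ranges=ranges[ranges["source"] == "child"],
        simulated_ranges=ranges[ranges["source"] == "simulated"],
        alpha=alpha,
    )
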