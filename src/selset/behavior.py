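"""Behavioral summaries for the go/no-go detection block.

Accuracy, signal-detection sensitivity (d') and criterion (c), reaction-time
statistics, and the +/-2 SD response window used to bound motor confounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BehaviorSummary",
    "sdt_metrics",
    "response_window",
    "accuracy_summary",
    "summarize",
]


@dataclass(frozen=True)
class BehaviorSummary:
    accuracy_pct: float
    accuracy_se_pct: float
    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion: float
    mean_rt_ms: float
    se_rt_ms: float
    sd_rt_ms: float
    window_low_ms: float
    window_high_ms: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def _corrected_rate(rate: float, n: int | None, what: str) -> float:
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"{what} must lie in [0, 1], got {rate!r}")
    if rate in (0.0, 1.0):
        if n is None:
            raise ValueError(
                f"{what} of {rate} is degenerate; supply the trial count so "
                "the 1/(2N) extreme-rate correction can be applied"
            )
        half = 1.0 / (2.0 * n)
        return half if rate == 0.0 else 1.0 - half
    return rate


def sdt_metrics(
    hit: float,
    fa: float,
    n_signal: int | None = None,
    n_noise: int | None = None,
) -> tuple[float, float]:
    """Signal-detection sensitivity and criterion from hit/false-alarm rates.

    d' = z(hit) - z(fa);  c = -(z(hit) + z(fa)) / 2.

    Rates of exactly 0 or 1 are replaced by the standard 1/(2N) correction,
    which requires the corresponding trial count.
    """
    hit = _corrected_rate(hit, n_signal, "hit rate")
    fa = _corrected_rate(fa, n_noise, "false-alarm rate")
    zh, zf = stats.norm.ppf(hit), stats.norm.ppf(fa)
    return float(zh - zf), float(-(zh + zf) / 2.0)


def response_window(mean_rt: float, sd_rt: float) -> tuple[float, float]:
    """(mean - 2*sd, mean + 2*sd) bounds in ms."""
    if sd_rt < 0:
        raise ValueError("sd_rt must be >= 0")
    return (mean_rt - 2.0 * sd_rt, mean_rt + 2.0 * sd_rt)


def accuracy_summary(records: pd.DataFrame) -> tuple[float, float]:
    """Mean and standard error (over subjects) of percent correct.

    ``records`` needs ``subject`` and boolean ``correct`` columns.
    """
    if records.empty:
        raise ValueError("no behavior records")
    per = records.groupby("subject")["correct"].mean() * 100.0
    n = per.size
    se = 0.0 if n < 2 else float(per.std(ddof=1) / np.sqrt(n))
    return float(per.mean()), se


def summarize(records: pd.DataFrame) -> BehaviorSummary:
    """Full behavioral summary from a trial-level table.

    Expects columns ``subject, stimulus, responded, rt_ms, correct`` where
    ``stimulus`` is 'target' or 'distractor' and ``rt_ms`` is NaN for
    withheld responses.
    """
    acc, acc_se = accuracy_summary(records)
    targets = records[records["stimulus"] == "target"]
    lures = records[records["stimulus"] == "distractor"]
    if targets.empty or lures.empty:
        raise ValueError("need both target and distractor trials")
    hit = float(targets["responded"].mean())
    fa = float(lures["responded"].mean())
    d, c = sdt_metrics(hit, fa, n_signal=len(targets), n_noise=len(lures))
    rts = records["rt_ms"].dropna()
    if rts.empty:
        mean_rt = se_rt = sd_rt = float("nan")
        low = high = float("nan")
    else:
        mean_rt = float(rts.mean())
        sd_rt = float(rts.std(ddof=1)) if rts.size > 1 else 0.0
        se_rt = sd_rt / np.sqrt(rts.size) if rts.size > 1 else 0.0
        low, high = response_window(mean_rt, sd_rt)
    return BehaviorSummary(
        accuracy_pct=acc,
        accuracy_se_pct=acc_se,
        hit_rate=hit,
        fa_rate=fa,
        d_prime=d,
        criterion=c,
        mean_rt_ms=mean_rt,
        se_rt_ms=float(se_rt),
        sd_rt_ms=sd_rt,
        window_low_ms=low,
        window_high_ms=high,
    )
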