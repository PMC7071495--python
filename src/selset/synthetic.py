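"""Seeded generators for trial sequences, behavior and multi-subject epochs.

Everything downstream of raw acquisition is testable against this module:
it produces a fixed-composition trial block, Bernoulli/ex-Gaussian behavior,
and epoched amplitude grids whose condition structure is either (a) smooth
per-bin offsets taken from a configurable enhancement table or (b) a
forward-projected dipole field, both on top of AR(1) Gaussian noise with a
per-subject offset.  All randomness flows through explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

from . import head_model
from .fixtures import enhancement_differences, enhancement_polarity

__all__ = ["GeneratorConfig", "EpochSet", "generate_trials", "generate_behavior",
           "generate_study_behavior", "generate_epochs"]

CONDITIONS = ("target", "distractor")


@dataclass(eq=False)
class EpochSet:
    """Complete (subject, condition, electrode, time) amplitude grid in uV."""

    subjects: list[str]
    conditions: list[str]
    electrodes: list[str]
    times: np.ndarray
    data: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        expected = (
            len(self.subjects),
            len(self.conditions),
            len(self.electrodes),
            self.times.size,
        )
        if self.data.shape != expected:
            raise ValueError(f"data shape {self.data.shape} != {expected}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch amplitudes must be finite")
        if self.times.size < 2 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be a strictly increasing grid")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def sampling_rate(self) -> float:
        return 1000.0 / self.dt


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic study.

    RT parameters are ex-Gaussian (mu + sigma Gaussian plus tau exponential;
    mean = mu + tau = 685 ms at defaults).  ``enhancement`` is an
    (electrode x 7 post-stimulus bins) table of signed target-minus-
    distractor offsets in uV; the shipped default qualitatively mirrors the
    worked-example significance table and is synthetic, not measured data.
    """

    n_subjects: int = 13
    n_trials: int = 150
    n_targets: int = 37
    hit_rate: float = 0.775
    fa_rate: float = 0.0607
    rt_mu: float = 485.0
    rt_sigma: float = 50.0
    rt_tau: float = 200.0
    noise_sd: float = 1.0
    noise_phi: float = 0.7
    subject_sd: float = 1.0
    sampling_rate: float = 1000.0
    epoch_start_ms: float = -200.0
    epoch_end_ms: float = 1000.0
    electrodes: tuple[str, ...] = head_model.DEFAULT_LABELS
    enhancement: np.ndarray | None = None
    polarity: np.ndarray | None = None
    condition_base: float = 0.3
    rejection_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_targets > self.n_trials:
            raise ValueError("n_targets cannot exceed n_trials")
        for name in ("hit_rate", "fa_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if not (0.0 <= self.rejection_fraction < 1.0):
            raise ValueError("rejection_fraction must lie in [0, 1)")
        if self.enhancement is None:
            self.enhancement = enhancement_differences(self.electrodes)
        self.enhancement = np.asarray(self.enhancement, dtype=float)
        if self.enhancement.shape[0] != len(self.electrodes):
            raise ValueError("enhancement table needs one row per electrode")
        if self.polarity is None:
            if self.enhancement.shape == (
                len(self.electrodes),
                enhancement_differences(self.electrodes).shape[1],
            ) and np.allclose(
                self.enhancement, enhancement_differences(self.electrodes)
            ):
                self.polarity = enhancement_polarity(self.electrodes)
            else:
                self.polarity = np.where(self.enhancement >= 0, 1.0, -1.0)
        self.polarity = np.asarray(self.polarity, dtype=float)
        if self.polarity.shape != self.enhancement.shape:
            raise ValueError("polarity grid must match the enhancement table")

    @property
    def times(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate
        return np.arange(self.epoch_start_ms, self.epoch_end_ms, step)


def generate_trials(cfg: GeneratorConfig, seed: int = 0) -> pd.DataFrame:
    """Pseudo-random trial order with exact per-type counts.

    Columns: trial, stimulus, onset_ms, stimulus_duration_ms,
    fixation_duration_ms.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    kinds = np.array(
        ["target"] * cfg.n_targets
        + ["distractor"] * (cfg.n_trials - cfg.n_targets)
    )
    rng.shuffle(kinds)
    trial_ms = 500.0 + 500.0  # stimulus + fixation
    return pd.DataFrame(
        {
            "trial": np.arange(cfg.n_trials),
            "stimulus": kinds,
            "onset_ms": np.arange(cfg.n_trials) * trial_ms,
            "stimulus_duration_ms": 500.0,
            "fixation_duration_ms": 500.0,
        }
    )


def _ex_gaussian(rng: np.random.Generator, n: int, cfg: GeneratorConfig) -> np.ndarray:
    gauss = rng.normal(cfg.rt_mu, cfg.rt_sigma, size=n)
    expo = rng.exponential(cfg.rt_tau, size=n) if cfg.rt_tau > 0 else 0.0
    return np.maximum(gauss + expo, 1.0)


def generate_behavior(
    trials: pd.DataFrame, cfg: GeneratorConfig, seed: int = 0
) -> pd.DataFrame:
    """Bernoulli responses at the configured hit/false-alarm rates with
    ex-Gaussian RTs on responded trials."""
    rng = np.random.default_rng(seed)
    is_target = (trials["stimulus"] == "target").to_numpy()
    p = np.where(is_target, cfg.hit_rate, cfg.fa_rate)
    responded = rng.random(len(trials)) < p
    rts = np.full(len(trials), np.nan)
    rts[responded] = _ex_gaussian(rng, int(responded.sum()), cfg)
    correct = np.where(is_target, responded, ~responded)
    out = trials[["trial", "stimulus"]].copy()
    out["responded"] = responded
    out["rt_ms"] = rts
    out["correct"] = correct
    return out


def generate_study_behavior(cfg: GeneratorConfig, seed: int = 0) -> pd.DataFrame:
    """Trial-level behavior for every subject (adds a ``subject`` column).

    A nonzero ``rejection_fraction`` drops that share of trials at random
    per subject, mimicking artifact rejection."""
    frames = []
    for i in range(cfg.n_subjects):
        trials = generate_trials(cfg, seed=seed * 1000 + i)
        beh = generate_behavior(trials, cfg, seed=seed * 1000 + 500 + i)
        if cfg.rejection_fraction > 0:
            rng = np.random.default_rng(seed * 1000 + 750 + i)
            n_keep = len(beh) - int(round(cfg.rejection_fraction * len(beh)))
            keep = np.sort(rng.choice(len(beh), size=n_keep, replace=False))
            beh = beh.iloc[keep].reset_index(drop=True)
        beh.insert(0, "subject", f"S{i+1:02d}")
        frames.append(beh)
    return pd.concat(frames, ignore_index=True)


def _ar1(rng: np.random.Generator, shape: tuple[int, ...], sd: float, phi: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    innovations = rng.normal(0.0, sd, size=shape)
    if phi == 0:
        return innovations
    return _signal.lfilter([1.0], [1.0, -phi], innovations, axis=-1)


def _bump_signal(cfg: GeneratorConfig, condition: str) -> np.ndarray:
    """(electrode, time) condition waveform for 'bumps' mode.

    Each post-stimulus 100 ms cell carries a peak of sign ``polarity``; the
    advantaged condition (target when ``diff * polarity >= 0``, distractor
    otherwise) gets the larger magnitude, so the signed per-bin mean
    target-distractor difference equals the configured enhancement value
    exactly while the dominant-amplitude condition matches the intended
    advantage.  Offsets are piecewise constant over bins.
    """
    times = cfg.times
    sig = np.zeros((len(cfg.electrodes), times.size))
    diff = cfg.enhancement
    pol = cfg.polarity
    target_adv = diff * pol >= 0
    mag = np.abs(diff)
    if condition == "target":
        amp = pol * (cfg.condition_base + np.where(target_adv, mag, 0.0))
    else:
        amp = pol * (cfg.condition_base + np.where(target_adv, 0.0, mag))
    n_bins = diff.shape[1]
    for b in range(n_bins):
        lo, hi = b * 100.0, (b + 1) * 100.0
        mask = (times >= lo) & (times < hi)
        sig[:, mask] += amp[:, [b]]
    return sig


def generate_epochs(
    cfg: GeneratorConfig,
    seed: int = 0,
    mode: str = "bumps",
    dipoles=None,
    montage=None,
    projection_scale: float = 1.0,
) -> EpochSet:
    """Synthesize a complete epoch grid.

    ``mode='bumps'`` adds the enhancement-table offsets to the target
    condition; ``mode='forward'`` instead projects condition-specific
    dipoles through the spherical head model (``dipoles``/``montage``
    required).  Noise is per-subject AR(1) plus a subject random offset;
    with ``noise_sd=subject_sd=0`` the output is exactly the deterministic
    condition signal.
    """
    rng = np.random.default_rng(seed)
    times = cfg.times
    n_s, n_e, n_t = cfg.n_subjects, len(cfg.electrodes), times.size

    if mode == "bumps":
        cond_sig = np.stack([_bump_signal(cfg, c) for c in CONDITIONS])
    elif mode == "forward":
        if dipoles is None:
            raise ValueError("forward mode requires a dipole list")
        if montage is None:
            montage = head_model.standard_montage(cfg.electrodes)
        cond_sig = np.stack(
            [
                projection_scale
                * head_model.scalp_projection(
                    [d for d in dipoles if d.condition == c], montage, times
                )
                for c in CONDITIONS
            ]
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    offsets = (
        rng.normal(0.0, cfg.subject_sd, size=n_s) if cfg.subject_sd > 0 else np.zeros(n_s)
    )
    noise = _ar1(rng, (n_s, len(CONDITIONS), n_e, n_t), cfg.noise_sd, cfg.noise_phi)
    data = cond_sig[None, :, :, :] + offsets[:, None, None, None] + noise
    return EpochSet(
        subjects=[f"S{i+1:02d}" for i in range(n_s)],
        conditions=list(CONDITIONS),
        electrodes=list(cfg.electrodes),
        times=times,
        data=data,
    )
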