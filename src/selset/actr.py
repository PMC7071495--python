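"""A minimal production-system forward simulator over module/buffer/chunk
semantics, driving the dipole field model.

Six modules fire one production each on a fixed schedule (k * bin + cycle
ms).  A production fires when its if-pattern matches the buffer contents,
places a chunk in its module's buffer, and -- when the schedule ties it to a
source -- emits a dipole spike.  Per-electrode polyspiking aggregates, at
every production time, the task-level field of the currently firing source
with the resting/decaying background of the others; coarse coding quantizes
the aggregated amplitudes onto an ordered intensity scale mapped to a
relative +/-6 uV range, from which per-bin topographic maps are assembled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from . import head_model
from .head_model import Dipole, Electrode

__all__ = [
    "Chunk",
    "Buffer",
    "Production",
    "ActivationProfile",
    "Firing",
    "Trace",
    "SpikePattern",
    "TopoMap",
    "StallError",
    "DEFAULT_MODULES",
    "build_schedule",
    "run_model",
    "polyspike",
    "coarse_code",
    "simulate_condition",
]

WILDCARD = "*"

#: (function, brain region) in default firing order.
DEFAULT_MODULES: tuple[tuple[str, str], ...] = (
    ("visual", "occipital"),
    ("spatial-attention", "parietal"),
    ("declarative", "temporal"),
    ("executive", "frontal"),
    ("procedural", "basal-ganglia"),
    ("manual", "parietal"),
)


class StallError(RuntimeError):
    """No production matches the current buffer contents."""


@dataclass(frozen=True)
class Chunk:
    """An ordered slot:value record."""

    slots: tuple[tuple[str, object], ...]

    def __init__(self, **slots: object) -> None:
        object.__setattr__(self, "slots", tuple(slots.items()))

    def get(self, slot: str, default=None):
        for k, v in self.slots:
            if k == slot:
                return v
        return default

    def matches(self, pattern: dict[str, object]) -> bool:
        for slot, want in pattern.items():
            have = self.get(slot, _MISSING)
            if have is _MISSING:
                return False
            if want != WILDCARD and have != want:
                return False
        return True


_MISSING = object()


@dataclass
class Buffer:
    """One-chunk holding slot owned by a module."""

    module: str
    content: Chunk | None = None

    def set(self, chunk: Chunk | None) -> None:
        if chunk is not None and not isinstance(chunk, Chunk):
            raise TypeError("buffers hold Chunk instances")
        self.content = chunk


@dataclass(frozen=True)
class Production:
    """An if/then rule bound to a module, region and completion time."""

    name: str
    module: str
    region: str
    completion_ms: float
    requires: tuple[tuple[str, tuple[tuple[str, object], ...]], ...]
    effect: Callable[[dict[str, Buffer], str], None]
    duration_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.completion_ms <= 0:
            raise ValueError("completion_ms must be > 0")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be > 0")

    def pattern(self) -> dict[str, dict[str, object]]:
        return {buf: dict(slots) for buf, slots in self.requires}

    def matches(self, buffers: dict[str, Buffer]) -> bool:
        for buf_name, slots in self.pattern().items():
            buf = buffers.get(buf_name)
            if buf is None or buf.content is None:
                return False
            if not buf.content.matches(slots):
                return False
        return True


@dataclass(frozen=True)
class ActivationProfile:
    """Rest/task activation levels and rise/decay dynamics.

    The rise toward a production's completion follows a normalized
    ex-Gaussian cumulative envelope with parameters (mu, sigma, tau); after
    firing the level decays exponentially with the given half-life.  The
    resting level is a fraction of the task level.  Faster productions are
    made more intense (intensity scales with the reference duration over the
    production duration) and decay proportionally faster.
    """

    task_level: float = 1.0
    rest_fraction: float = 0.1
    rise_mu: float = 30.0
    rise_sigma: float = 10.0
    rise_tau: float = 40.0
    decay_half_life_ms: float = 50.0
    reference_duration_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.task_level < 0 or self.rest_fraction < 0:
            raise ValueError("activation levels must be >= 0")
        if self.rise_sigma < 0 or self.rise_tau < 0:
            raise ValueError("sigma and tau must be >= 0")
        if self.decay_half_life_ms <= 0:
            raise ValueError("decay half-life must be > 0")

    def intensity(self, duration_ms: float) -> float:
        return self.task_level * self.reference_duration_ms / duration_ms

    def decay_rate(self, duration_ms: float) -> float:
        base = math.log(2.0) / self.decay_half_life_ms
        if self.task_level == 0:
            return base
        return base * self.intensity(duration_ms) / self.task_level

    def _rise_cdf(self, x: float) -> float:
        sigma = max(self.rise_sigma, 1e-9)
        if self.rise_tau <= 1e-12:
            return float(stats.norm.cdf(x, loc=self.rise_mu, scale=sigma))
        k = self.rise_tau / sigma
        return float(stats.exponnorm.cdf(x, k, loc=self.rise_mu, scale=sigma))

    def level(self, dt: float, duration_ms: float) -> float:
        """Activation at ``dt`` ms relative to the firing completion."""
        peak = self.intensity(duration_ms)
        rest = self.rest_fraction * peak
        if dt > 0:
            return peak * math.exp(-self.decay_rate(duration_ms) * dt)
        if dt == 0:
            return peak
        span = self.rise_mu + self.rise_tau
        denom = self._rise_cdf(span)
        if denom <= 0:
            return rest
        frac = self._rise_cdf(dt + span) / denom
        return rest + (peak - rest) * min(frac, 1.0)


DEFAULT_PROFILE = ActivationProfile()


def _chain_effect(module: str, is_last: bool) -> Callable[[dict[str, Buffer], str], None]:
    def effect(buffers: dict[str, Buffer], stimulus: str) -> None:
        upstream = None
        for buf in buffers.values():
            if buf.content is not None and buf.content.get("identity") is not None:
                upstream = buf.content
        identity = upstream.get("identity") if upstream else stimulus
        slots: dict[str, object] = {"stage": module, "identity": identity}
        if module == "declarative":
            slots["action"] = "press" if identity == "target" else "withhold"
        else:
            prior = upstream.get("action") if upstream else None
            if prior is not None:
                slots["action"] = prior
        if is_last:
            slots["response"] = (
                "release" if slots.get("action") == "press" else "withhold"
            )
        buffers.setdefault(module, Buffer(module)).set(Chunk(**slots))

    return effect


def build_schedule(
    bin_ms: float = 100.0,
    cycle_ms: float = 50.0,
    modules: Sequence[tuple[str, str]] = DEFAULT_MODULES,
) -> list[Production]:
    """Default production chain: production ``k`` (1-based) completes at
    ``k * bin_ms + cycle_ms`` and requires the previous module's buffer."""
    if not modules:
        raise ValueError("module list must be non-empty")
    if bin_ms <= 0 or cycle_ms < 0:
        raise ValueError("durations must be positive")
    productions = []
    prev_buffer = "visual-location"
    prev_slots: tuple[tuple[str, object], ...] = (("stimulus", WILDCARD),)
    for k, (module, region) in enumerate(modules, start=1):
        productions.append(
            Production(
                name=f"{module}-step",
                module=module,
                region=region,
                completion_ms=k * bin_ms + cycle_ms,
                requires=((prev_buffer, prev_slots),),
                effect=_chain_effect(module, is_last=(k == len(modules))),
                duration_ms=bin_ms,
            )
        )
        prev_buffer = module
        prev_slots = (("stage", module),)
    return productions


@dataclass(frozen=True)
class Firing:
    time_ms: float
    production: str
    module: str
    region: str
    dipole: str | None
    activation: float
    duration_ms: float


@dataclass
class Trace:
    """Ordered firings, final buffer snapshot and the response decision."""

    stimulus: str
    firings: list[Firing]
    buffers: dict[str, Buffer]
    response: str

    @property
    def times(self) -> list[float]:
        return [f.time_ms for f in self.firings]


def run_model(
    stimulus: str,
    schedule: Sequence[Production] | None = None,
    profile: ActivationProfile = DEFAULT_PROFILE,
    dipoles: Sequence[Dipole] | None = None,
) -> Trace:
    """Run the serial production cycle for one stimulus.

    Productions fire one at a time in completion order; each firing is
    stamped with its completion time, activation intensity and -- when a
    dipole in ``dipoles`` shares its condition and peak time -- the source
    it drives.  Target runs end with the motor program released, distractor
    runs with the response withheld.  A step at which no production matches
    raises :class:`StallError`.
    """
    if stimulus not in ("target", "distractor"):
        raise ValueError("stimulus must be 'target' or 'distractor'")
    if schedule is None:
        schedule = build_schedule()
    if dipoles is None:
        from .fixtures import default_dipoles

        dipoles = default_dipoles()
    by_time = {
        (d.condition, d.peak_time): d.label
        for d in dipoles
    }
    buffers: dict[str, Buffer] = {
        "visual-location": Buffer("visual-location", Chunk(stimulus=stimulus, identity=stimulus))
    }
    pending = sorted(schedule, key=lambda p: p.completion_ms)
    times = [p.completion_ms for p in pending]
    if len(set(times)) != len(times):
        raise ValueError("serial firing requires distinct completion times")
    firings: list[Firing] = []
    while pending:
        fired = None
        for prod in pending:
            if prod.matches(buffers):
                fired = prod
                break
        if fired is None:
            raise StallError(
                f"no production matches at t={pending[0].completion_ms} ms "
                f"(pending: {[p.name for p in pending]})"
            )
        pending.remove(fired)
        fired.effect(buffers, stimulus)
        firings.append(
            Firing(
                time_ms=fired.completion_ms,
                production=fired.name,
                module=fired.module,
                region=fired.region,
                dipole=by_time.get((stimulus, fired.completion_ms)),
                activation=profile.intensity(fired.duration_ms),
                duration_ms=fired.duration_ms,
            )
        )
    response = "withhold"
    for buf in buffers.values():
        if buf.content is not None and buf.content.get("response") is not None:
            response = str(buf.content.get("response"))
    return Trace(stimulus=stimulus, firings=sorted(firings, key=lambda f: f.time_ms),
                 buffers=buffers, response=response)


@dataclass(eq=False)
class SpikePattern:
    """Aggregated spike series at one electrode.

    One spike per production time; ``sources`` names the dipole firing at
    each time (None for background-only spikes).  ``codes`` and
    ``scaled_uv`` are filled by :func:`coarse_code`.
    """

    electrode: str
    times: np.ndarray
    amplitudes: np.ndarray
    sources: list[str | None]
    codes: np.ndarray | None = None
    scaled_uv: np.ndarray | None = None
    clipped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must align")
        if len(self.sources) != self.times.size:
            raise ValueError("one source entry per spike required")


@dataclass(eq=False)
class TopoMap:
    """Per-electrode values at one bin midpoint, on the relative uV scale."""

    time_ms: float
    condition: str
    provenance: str
    electrodes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.electrodes),):
            raise ValueError("one value per electrode required")
        if self.provenance not in ("actual", "simulated"):
            raise ValueError("provenance must be 'actual' or 'simulated'")


def polyspike(
    trace: Trace,
    dipoles: Sequence[Dipole],
    montage: Sequence[Electrode],
    profile: ActivationProfile = DEFAULT_PROFILE,
) -> list[SpikePattern]:
    """Per-electrode spike series over the trace's production times.

    At each production time the source tied to that firing contributes at
    its task level while every other source of the run's condition
    contributes its resting (before firing) or exponentially decaying
    (after firing) background, each weighted by its forward-field gain at
    the electrode.
    """
    cond_dipoles = [d for d in dipoles if d.condition == trace.stimulus]
    by_label = {d.label: d for d in cond_dipoles}
    for f in trace.firings:
        if f.dipole is not None and f.dipole not in by_label:
            raise ValueError(
                f"firing at {f.time_ms} ms references unmapped dipole {f.dipole!r}"
            )
    spike_times = np.array([f.time_ms for f in trace.firings])
    # firing time and duration per source, from the trace
    events = {
        f.dipole: (f.time_ms, f.duration_ms)
        for f in trace.firings
        if f.dipole is not None
    }
    patterns = []
    for e in montage:
        amps = np.zeros(spike_times.size)
        for d in cond_dipoles:
            gain = head_model.dipole_potential(d, e)
            fire_time, duration = events.get(d.label, (None, None))
            for i, t in enumerate(spike_times):
                if fire_time is None:
                    dur = d.width
                    level = profile.rest_fraction * profile.intensity(dur)
                else:
                    level = profile.level(t - fire_time, duration)
                amps[i] += gain * level * d.strength
        sources = [f.dipole for f in trace.firings]
        patterns.append(
            SpikePattern(
                electrode=e.label,
                times=spike_times.copy(),
                amplitudes=amps,
                sources=sources,
            )
        )
    return patterns


def coarse_code(
    patterns: Sequence[SpikePattern],
    scale: tuple[float, float] = (-6.0, 6.0),
    n_levels: int = 13,
    condition: str = "target",
    quantize_maps: bool = False,
) -> list[TopoMap]:
    """Quantize spike amplitudes onto ``n_levels`` ordered categories and
    assemble per-bin topographic maps.

    Relative amplitudes are mapped linearly onto the scale (the global
    absolute maximum lands on the scale bound); category codes are written
    back onto each pattern along with the scaled uV values and a clipping
    record.  Maps take the continuous scaled values by default; pass
    ``quantize_maps=True`` to build them from the decoded categories.
    """
    lo, hi = scale
    if not hi > lo:
        raise ValueError("degenerate scale: need hi > lo")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    patterns = list(patterns)
    if not patterns:
        raise ValueError("no spike patterns to code")
    amax = max(float(np.max(np.abs(p.amplitudes))) for p in patterns)
    half_span = (hi - lo) / 2.0
    mid = (hi + lo) / 2.0
    step = (hi - lo) / (n_levels - 1)
    for p in patterns:
        if amax == 0:
            uv = np.full_like(p.amplitudes, mid)
        else:
            uv = mid + p.amplitudes / amax * half_span
        clipped = (uv < lo) | (uv > hi)
        uv = np.clip(uv, lo, hi)
        codes = np.rint((uv - lo) / step).astype(int)
        p.codes = codes
        p.scaled_uv = uv
        p.clipped = clipped
    times = patterns[0].times
    maps = []
    for i, t in enumerate(times):
        if quantize_maps:
            values = np.array([lo + p.codes[i] * step for p in patterns])
        else:
            values = np.array([p.scaled_uv[i] for p in patterns])
        maps.append(
            TopoMap(
                time_ms=float(t),
                condition=condition,
                provenance="simulated",
                electrodes=[p.electrode for p in patterns],
                values=values,
            )
        )
    return maps


def simulate_condition(
    condition: str,
    dipoles: Sequence[Dipole] | None = None,
    montage: Sequence[Electrode] | None = None,
    schedule: Sequence[Production] | None = None,
    profile: ActivationProfile = DEFAULT_PROFILE,
    scale: tuple[float, float] = (-6.0, 6.0),
    n_levels: int = 13,
) -> tuple[Trace, list[SpikePattern], list[TopoMap]]:
    """End-to-end forward run: trace, polyspike patterns and bin maps."""
    if dipoles is None:
        from .fixtures import default_dipoles

        dipoles = default_dipoles()
    if montage is None:
        montage = head_model.standard_montage()
    trace = run_model(condition, schedule=schedule, profile=profile, dipoles=dipoles)
    patterns = polyspike(trace, dipoles, montage, profile=profile)
    maps = coarse_code(patterns, scale=scale, n_levels=n_levels, condition=condition)
    return trace, patterns, maps
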