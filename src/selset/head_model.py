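"""Electrode geometry on a unit sphere and the dipole -> scalp forward field.

The head is a unit-radius sphere in dimensionless coordinates (x toward the
right ear, y toward the nose, z toward the vertex).  Sources are point
dipoles strictly inside the sphere; sensors are points on it.  The potential
a dipole induces at a sensor is ``k * p * cos(theta) / r**2`` where ``r`` is
the straight-line source-sensor distance and ``theta`` the angle between the
dipole moment and the source-to-sensor direction.  Each source emits its
energy as a triangular spike in time, and the scalp field is the
superposition of the per-source contributions.  Only relative magnitudes are
meaningful; ``k`` defaults to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Electrode",
    "Dipole",
    "MONTAGE_POSITIONS",
    "DEFAULT_LABELS",
    "standard_montage",
    "dipole_potential",
    "triangular_spike",
    "scalp_projection",
]

_UNIT_TOL = 1e-9


def _as_vec(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(frozen=True, eq=False)
class Electrode:
    """A named sensor on the unit sphere."""

    label: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = _as_vec(self.position, "position")
        if abs(np.linalg.norm(pos) - 1.0) > _UNIT_TOL:
            raise ValueError(
                f"electrode {self.label!r} position must lie on the unit "
                f"sphere (|position| = {np.linalg.norm(pos):.12f})"
            )
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True, eq=False)
class Dipole:
    """A point current source inside the unit sphere.

    ``moment`` is normalized to unit length on construction; ``strength``
    carries the (relative) magnitude.  ``peak_time`` and ``width`` place the
    triangular spike this source emits.
    """

    label: str
    position: np.ndarray
    moment: np.ndarray
    strength: float = 1.0
    peak_time: float = 0.0
    width: float = 100.0
    condition: str = "target"

    def __post_init__(self) -> None:
        pos = _as_vec(self.position, "position")
        if np.linalg.norm(pos) >= 1.0:
            raise ValueError(
                f"dipole {self.label!r} must sit strictly inside the unit "
                f"sphere (|position| = {np.linalg.norm(pos):.6f})"
            )
        mom = _as_vec(self.moment, "moment")
        norm = np.linalg.norm(mom)
        if norm == 0.0:
            raise ValueError(f"dipole {self.label!r} has a zero moment")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "moment", mom / norm)

    @classmethod
    def radial(cls, label, position, **kwargs) -> "Dipole":
        """Dipole whose moment points outward along its own position."""
        pos = _as_vec(position, "position")
        if np.linalg.norm(pos) == 0:
            raise ValueError("radial moment undefined at the origin")
        return cls(label=label, position=pos, moment=pos.copy(), **kwargs)


def _grid_point(x: float, y: float) -> tuple[float, float, float]:
    z2 = 1.0 - x * x - y * y
    if z2 < 0:
        raise ValueError("grid point falls off the sphere")
    return (x, y, math.sqrt(z2))


# Built-in sensor table: an idealized symmetric spherical grid with the
# vertex sensor at the pole, left/right pairs mirrored in x and the
# frontal/occipital rows mirrored in y.  Any fixed convention works here
# because the forward model is only used on a relative scale.
MONTAGE_POSITIONS: dict[str, tuple[float, float, float]] = {
    "F3": _grid_point(-0.5, 0.75),
    "Fz": _grid_point(0.0, 0.75),
    "F4": _grid_point(0.5, 0.75),
    "T7": (-1.0, 0.0, 0.0),
    "Cz": (0.0, 0.0, 1.0),
    "T8": (1.0, 0.0, 0.0),
    "P7": _grid_point(-0.6, -0.45),
    "Pz": _grid_point(0.0, -0.45),
    "P8": _grid_point(0.6, -0.45),
    "O1": _grid_point(-0.5, -0.75),
    "Oz": _grid_point(0.0, -0.75),
    "O2": _grid_point(0.5, -0.75),
}

#: The 12-channel montage used throughout, in row-major scalp order.
DEFAULT_LABELS: tuple[str, ...] = (
    "F3", "Fz", "F4", "Cz", "T7", "T8", "P7", "Pz", "P8", "O1", "Oz", "O2",
)


def standard_montage(labels: Sequence[str] = DEFAULT_LABELS) -> list[Electrode]:
    """Build electrodes at the built-in unit-sphere positions.

    Parameters
    ----------
    labels
        Channel names drawn from the built-in table.  Order is preserved.

    Raises
    ------
    ValueError
        If a label is unknown or repeated.
    """
    seen: set[str] = set()
    out: list[Electrode] = []
    for label in labels:
        if label not in MONTAGE_POSITIONS:
            raise ValueError(
                f"unknown electrode label {label!r}; known labels: "
                f"{sorted(MONTAGE_POSITIONS)}"
            )
        if label in seen:
            raise ValueError(f"duplicate electrode label {label!r}")
        seen.add(label)
        out.append(Electrode(label, np.asarray(MONTAGE_POSITIONS[label])))
    return out


def dipole_potential(dipole: Dipole, electrode: Electrode, k: float = 1.0) -> float:
    """Relative potential of one dipole at one sensor: k*p*cos(theta)/r**2."""
    rvec = electrode.position - dipole.position
    r = float(np.linalg.norm(rvec))
    if r == 0.0:
        raise ValueError(
            f"degenerate geometry: electrode {electrode.label!r} coincides "
            f"with dipole {dipole.label!r}"
        )
    cos_theta = float(np.dot(dipole.moment, rvec)) / r
    return k * dipole.strength * cos_theta / r**2


def triangular_spike(
    t, peak_time: float, width: float, amplitude: float = 1.0
):
    """Triangular pulse: ``amplitude`` at ``peak_time``, zero at and beyond
    ``peak_time +/- width/2``, linear in between.  Vectorized over ``t``."""
    if width <= 0:
        raise ValueError("width must be > 0")
    t_arr = np.asarray(t, dtype=float)
    out = amplitude * np.clip(1.0 - np.abs(t_arr - peak_time) / (width / 2.0), 0.0, None)
    if np.ndim(t) == 0:
        return float(out)
    return out


def _check_disjoint(dipoles: Sequence[Dipole]) -> None:
    for i, a in enumerate(dipoles):
        for b in dipoles[i + 1:]:
            if abs(a.peak_time - b.peak_time) < (a.width + b.width) / 2.0 - 1e-12:
                raise ValueError(
                    f"spike supports of {a.label!r} and {b.label!r} overlap "
                    f"(peaks {a.peak_time} and {b.peak_time} ms)"
                )


def scalp_projection(
    dipoles: Iterable[Dipole],
    montage: Sequence[Electrode],
    times,
    k: float = 1.0,
    require_disjoint: bool = False,
) -> np.ndarray:
    """Project a dipole set onto a montage over a time grid.

    Returns an ``(n_electrodes, n_times)`` array where entry ``(e, t)`` is
    the superposition of every dipole's potential at electrode ``e`` scaled
    by that dipole's triangular spike at time ``t``.

    With ``require_disjoint=True`` the call asserts that no two spikes
    overlap in time (the schedule regime where at most one source is active
    at any instant).
    """
    montage = list(montage)
    if not montage:
        raise ValueError("montage must be non-empty")
    t_arr = np.asarray(times, dtype=float)
    if t_arr.ndim != 1:
        raise ValueError("times must be a 1-D grid")
    if t_arr.size > 1 and np.any(np.diff(t_arr) <= 0):
        raise ValueError("times must be strictly increasing")
    dipoles = list(dipoles)
    if require_disjoint:
        _check_disjoint(dipoles)
    out = np.zeros((len(montage), t_arr.size))
    for d in dipoles:
        spike = triangular_spike(t_arr, d.peak_time, d.width, 1.0)
        gains = np.array([dipole_potential(d, e, k=k) for e in montage])
        out += np.outer(gains, spike)
    return out
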