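"""Activity paths: per-bin maxima, simultaneity grouping and least-path
ordering under wiring-minimization movement constraints.

The 12-channel montage is read as a 4 x 3 scalp grid (frontal, central,
parietal, occipital rows; left, midline, right columns).  Movement rules:
occipital-row activity may only move forward (toward the frontal row) or
laterally; frontal-row activity only backward or laterally; a lateral
(within-row) move from a left-column electrode must go rightward and from a
right-column electrode leftward; midline lateral moves are unrestricted.
Within a bin, electrodes tied at the maximum difference are ordered by
exhaustive search over constraint-legal permutations, minimizing total
scalp distance, with a deterministic posterior-first/left-first tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd

from .contrasts import SignificanceTable
from .head_model import Electrode

__all__ = [
    "ROWS",
    "PathStep",
    "grid_coords",
    "move_legal",
    "max_diff_electrodes",
    "order_simultaneous",
    "build_paths",
    "path_edges",
    "narrate",
]

ROWS: tuple[tuple[str, ...], ...] = (
    ("F3", "Fz", "F4"),
    ("T7", "Cz", "T8"),
    ("P7", "Pz", "P8"),
    ("O1", "Oz", "O2"),
)
_GRID = {lab: (r, c) for r, row in enumerate(ROWS) for c, lab in enumerate(row)}
_FRONTAL_ROW, _OCCIPITAL_ROW = 0, len(ROWS) - 1


def grid_coords(label: str) -> tuple[int, int]:
    """(row, column) of an electrode in the scalp grid; row 0 is frontal."""
    try:
        return _GRID[label]
    except KeyError:
        raise ValueError(f"electrode {label!r} is not on the 4x3 scalp grid") from None


def move_legal(src: str, dst: str) -> bool:
    """Is a single activation move from ``src`` to ``dst`` allowed?"""
    (r1, c1), (r2, c2) = grid_coords(src), grid_coords(dst)
    if r1 == r2:  # lateral move
        if c1 == 1:
            return True  # midline unrestricted
        return c2 > c1 if c1 == 0 else c2 < c1
    if r1 == _OCCIPITAL_ROW:  # may only move forward
        return r2 < r1
    if r1 == _FRONTAL_ROW:  # may only move backward
        return r2 > r1
    return True


@dataclass(frozen=True)
class PathStep:
    """One bin of a path: the ordered simultaneous electrode set."""

    bin_index: int
    electrodes: tuple[str, ...]
    condition: str
    legal: bool = True

    def __post_init__(self) -> None:
        if not self.electrodes:
            raise ValueError("a path step needs at least one electrode")
        if len(set(self.electrodes)) != len(self.electrodes):
            raise ValueError("electrodes within a step must be distinct")
        if len(self.electrodes) > 3:
            raise ValueError("at most three simultaneous electrodes per step")


def max_diff_electrodes(
    sig: SignificanceTable,
    bin_index: int,
    condition: str,
    tolerance: float,
) -> list[str]:
    """Electrodes whose flagged |difference| is within ``tolerance`` of the
    bin maximum for the given advantage condition ('T' or 'D').

    Sorted by decreasing |difference| and capped at three; empty when the
    bin has no flagged cell for that condition.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    flag = {"target": "T", "distractor": "D"}.get(condition, condition)
    if flag not in ("T", "D"):
        raise ValueError(f"unknown condition {condition!r}")
    if not (1 <= bin_index <= sig.n_bins):
        raise ValueError(f"bin index {bin_index} outside 1..{sig.n_bins}")
    col = bin_index - 1
    hits = [
        (abs(sig.differences[i, col]), e)
        for i, e in enumerate(sig.electrodes)
        if sig.flags[i, col] == flag
    ]
    if not hits:
        return []
    top = max(v for v, _ in hits)
    keep = sorted(
        [(v, e) for v, e in hits if v >= top - tolerance], reverse=True
    )
    return [e for _, e in keep[:3]]


def _sort_key(label: str) -> tuple[int, int, str]:
    r, c = grid_coords(label)
    return (-r, c, label)  # posterior rows first, then left to right


def order_simultaneous(
    electrodes: Sequence[str], montage: Sequence[Electrode]
) -> tuple[list[str], bool]:
    """Least-distance constraint-legal visiting order of 1-3 electrodes.

    All permutations are enumerated; among those whose every consecutive
    move is legal the one with minimal total Euclidean scalp distance wins,
    ties broken by the posterior-first grid order.  If no permutation is
    legal the distance-minimal ordering is returned flagged ``False`` rather
    than silently dropped.
    """
    electrodes = list(electrodes)
    if not (1 <= len(electrodes) <= 3):
        raise ValueError("simultaneous sets hold one to three electrodes")
    pos = {e.label: e.position for e in montage}
    for lab in electrodes:
        if lab not in pos:
            raise ValueError(f"electrode {lab!r} missing from montage")

    def total_dist(order: tuple[str, ...]) -> float:
        return float(
            sum(
                np.linalg.norm(pos[a] - pos[b])
                for a, b in zip(order, order[1:])
            )
        )

    def rank(order: tuple[str, ...]):
        return (round(total_dist(order), 12), [_sort_key(lab) for lab in order])

    legal, illegal = [], []
    for order in permutations(electrodes):
        ok = all(move_legal(a, b) for a, b in zip(order, order[1:]))
        (legal if ok else illegal).append(order)
    pool = legal if legal else illegal
    best = min(pool, key=rank)
    return list(best), bool(legal)


def build_paths(
    sig: SignificanceTable,
    montage: Sequence[Electrode],
    tolerance: float,
    conditions: Sequence[str] = ("target", "distractor"),
) -> dict[str, list[PathStep]]:
    """Per-condition ordered path steps over all bins of ``sig``."""
    paths: dict[str, list[PathStep]] = {}
    for cond in conditions:
        steps = []
        for b in range(1, sig.n_bins + 1):
            members = max_diff_electrodes(sig, b, cond, tolerance)
            if not members:
                continue
            ordered, ok = order_simultaneous(members, montage)
            steps.append(
                PathStep(bin_index=b, electrodes=tuple(ordered), condition=cond, legal=ok)
            )
        paths[cond] = steps
    return paths


def path_edges(paths: dict[str, list[PathStep]]) -> pd.DataFrame:
    """Edge list (condition, bin, from, to, within_step, legal)."""
    recs = []
    for cond, steps in paths.items():
        prev_last: str | None = None
        for step in steps:
            if prev_last is not None:
                recs.append(
                    {
                        "condition": cond,
                        "bin": step.bin_index,
                        "from_electrode": prev_last,
                        "to_electrode": step.electrodes[0],
                        "within_step": False,
                        "legal": move_legal(prev_last, step.electrodes[0]),
                    }
                )
            for a, b in zip(step.electrodes, step.electrodes[1:]):
                recs.append(
                    {
                        "condition": cond,
                        "bin": step.bin_index,
                        "from_electrode": a,
                        "to_electrode": b,
                        "within_step": True,
                        "legal": move_legal(a, b),
                    }
                )
            prev_last = step.electrodes[-1]
    return pd.DataFrame(
        recs,
        columns=["condition", "bin", "from_electrode", "to_electrode", "within_step", "legal"],
    )


def narrate(paths: dict[str, list[PathStep]], bin_edges=None) -> str:
    """Human-readable narration of each condition's path."""
    lines = []
    for cond, steps in paths.items():
        if not steps:
            lines.append(f"{cond}: no significant activity in the analysis window.")
            continue
        parts = []
        for step in steps:
            span = f"bin {step.bin_index}"
            if bin_edges is not None:
                span += (
                    f" ({bin_edges[step.bin_index - 1]:.0f}-"
                    f"{bin_edges[step.bin_index]:.0f} ms)"
                )
            joined = " -> ".join(step.electrodes)
            note = "" if step.legal else " [constraint-violating]"
            parts.append(f"{span}: {joined}{note}")
        lines.append(f"{cond}: " + "; ".join(parts) + ".")
    return "\n".join(lines)
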