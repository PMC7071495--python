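"""Packaged configuration tables.

Three small delimited tables ship with the package:

``enhancement_table.csv``
    The worked-example grid of signed target-minus-distractor bin
    differences (uV) with advantage labels and dominant-peak polarities for
    the 0-700 ms window.  Doubles as the default effect table for the
    synthetic generator.
``dipoles.csv``
    Approximate normalized source coordinates, radial moments and spike
    schedule for the two condition-specific dipole sequences.  These are
    editable inputs, not derived quantities.
``localization_ranges.csv``
    Grey-matter search ranges (mm) per source for the child and simulated
    datasets, used by the structural homology comparison.
"""

from __future__ import annotations

from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from . import head_model

__all__ = [
    "enhancement_table",
    "enhancement_differences",
    "enhancement_polarity",
    "default_dipoles",
    "localization_ranges",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("selset.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def enhancement_table() -> pd.DataFrame:
    """Long-format worked-example table: electrode, bin, diff_uv, label,
    polarity."""
    df = _read("enhancement_table.csv")
    df["label"] = df["label"].fillna("")
    return df


def _pivot(df: pd.DataFrame, column: str, electrodes: Sequence[str]) -> np.ndarray:
    wide = df.pivot(index="electrode", columns="bin", values=column)
    return wide.loc[list(electrodes)].to_numpy(dtype=float)


def enhancement_differences(
    electrodes: Sequence[str] = head_model.DEFAULT_LABELS,
) -> np.ndarray:
    """(electrode x 7 bins) signed difference grid from the packaged table."""
    return _pivot(enhancement_table(), "diff_uv", electrodes)


def enhancement_polarity(
    electrodes: Sequence[str] = head_model.DEFAULT_LABELS,
) -> np.ndarray:
    """(electrode x 7 bins) dominant-peak signs from the packaged table."""
    return _pivot(enhancement_table(), "polarity", electrodes)


def default_dipoles(condition: str | None = None) -> list[head_model.Dipole]:
    """Dipole objects from the packaged configuration table."""
    df = _read("dipoles.csv")
    if condition is not None:
        df = df[df["condition"] == condition]
    return [
        head_model.Dipole(
            label=row.label,
            position=np.array([row.x, row.y, row.z]),
            moment=np.array([row.mx, row.my, row.mz]),
            strength=float(row.p),
            peak_time=float(row.peak_ms),
            width=float(row.width_ms),
            condition=row.condition,
        )
        for row in df.itertuples(index=False)
    ]


def localization_ranges() -> pd.DataFrame:
    """label, range_mm, source, condition rows for the homology tests."""
    return _read("localization_ranges.csv")
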