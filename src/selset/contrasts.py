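"""Omnibus mixed ANOVA, focused-contrast thresholding and cell classification.

The omnibus design treats each (subject, time-bin) observation vector as a
unit grouped by bin (the between-unit factor), with electrode and condition
as fully-crossed within-unit factors.  The classical balanced sums-of-squares
decomposition is computed from first principles; the electrode-by-condition
error mean square feeds the focused-contrast minimum-significant-difference
threshold

    amp_diff = t_crit * sqrt(MSE_within * sum(lambda_i**2 / n_i))

which, with a Bonferroni-corrected two-tailed t critical value, converts the
family-wise alpha into a microvolt threshold applied cell-by-cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .vincent import BinTable

__all__ = [
    "AnovaResult",
    "SignificanceTable",
    "omnibus_anova",
    "t_critical",
    "bonferroni_tcrit",
    "min_sig_diff",
    "classify_cells",
    "infer_polarity",
    "enhancement_test",
]

ERROR_WITHIN = "electrode:condition:subject(bin)"


@dataclass(eq=False)
class AnovaResult:
    """Effect table of the balanced split-plot decomposition.

    ``table`` is indexed by effect name with columns ``ss, df, ms, F, p,
    partial_eta_sq, error_term``.
    """

    table: pd.DataFrame

    @property
    def mse_within(self) -> float:
        """Error mean square for the electrode x condition interaction."""
        return float(self.table.loc[ERROR_WITHIN, "ms"])

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]


def _ss(arr: np.ndarray, scale: float) -> float:
    return float(scale * np.sum(np.square(arr)))


def omnibus_anova(bins: BinTable) -> AnovaResult:
    """Balanced split-plot ANOVA of per-subject vincentized bin values.

    Units are (subject, bin) pairs grouped by bin; electrode and condition
    are within-unit factors.  Raises on incomplete (unbalanced) input --
    the per-subject grid must be full and finite.
    """
    y = bins.per_subject
    if not np.all(np.isfinite(y)):
        raise ValueError("unbalanced input: bin table has missing cells")
    # reorder (subject, condition, electrode, bin) -> (bin, subject,
    # electrode, condition) = (group, unit, A, C)
    y = np.transpose(y, (3, 0, 2, 1)).astype(float)
    g, n, a, c = y.shape
    if n < 2:
        raise ValueError("need at least two subjects")

    m = y.mean()
    mg = y.mean(axis=(1, 2, 3))
    mgu = y.mean(axis=(2, 3))
    ma = y.mean(axis=(0, 1, 3))
    mc = y.mean(axis=(0, 1, 2))
    mga = y.mean(axis=(1, 3))
    mgc = y.mean(axis=(1, 2))
    mac = y.mean(axis=(0, 1))
    mgac = y.mean(axis=1)
    mgua = y.mean(axis=3)
    mguc = y.mean(axis=2)

    rows: list[tuple[str, float, int, str | None]] = [
        ("bin", _ss(mg - m, n * a * c), g - 1, "subject(bin)"),
        ("subject(bin)", _ss(mgu - mg[:, None], a * c), g * (n - 1), None),
        ("electrode", _ss(ma - m, g * n * c), a - 1, "electrode:subject(bin)"),
        (
            "bin:electrode",
            _ss(mga - mg[:, None] - ma[None, :] + m, n * c),
            (g - 1) * (a - 1),
            "electrode:subject(bin)",
        ),
        (
            "electrode:subject(bin)",
            _ss(mgua - mgu[:, :, None] - mga[:, None, :] + mg[:, None, None], c),
            g * (n - 1) * (a - 1),
            None,
        ),
        ("condition", _ss(mc - m, g * n * a), c - 1, "condition:subject(bin)"),
        (
            "bin:condition",
            _ss(mgc - mg[:, None] - mc[None, :] + m, n * a),
            (g - 1) * (c - 1),
            "condition:subject(bin)",
        ),
        (
            "condition:subject(bin)",
            _ss(mguc - mgu[:, :, None] - mgc[:, None, :] + mg[:, None, None], a),
            g * (n - 1) * (c - 1),
            None,
        ),
        (
            "electrode:condition",
            _ss(mac - ma[:, None] - mc[None, :] + m, g * n),
            (a - 1) * (c - 1),
            ERROR_WITHIN,
        ),
        (
            "bin:electrode:condition",
            _ss(
                mgac
                - mga[:, :, None]
                - mgc[:, None, :]
                - mac[None, :, :]
                + mg[:, None, None]
                + ma[None, :, None]
                + mc[None, None, :]
                - m,
                n,
            ),
            (g - 1) * (a - 1) * (c - 1),
            ERROR_WITHIN,
        ),
        (
            ERROR_WITHIN,
            _ss(
                y
                - mgua[:, :, :, None]
                - mguc[:, :, None, :]
                - mgac[:, None, :, :]
                + mgu[:, :, None, None]
                + mga[:, None, :, None]
                + mgc[:, None, None, :]
                - mg[:, None, None, None],
                1,
            ),
            g * (n - 1) * (a - 1) * (c - 1),
            None,
        ),
    ]

    tbl = pd.DataFrame(rows, columns=["effect", "ss", "df", "error_term"])
    tbl = tbl.set_index("effect")
    tbl["ms"] = np.where(tbl["df"] > 0, tbl["ss"] / tbl["df"].replace(0, np.nan), np.nan)
    f_vals, p_vals, eta = [], [], []
    for name, row in tbl.iterrows():
        err = row["error_term"]
        if err is None or row["df"] < 1:
            f_vals.append(np.nan)
            p_vals.append(np.nan)
            eta.append(np.nan)
            continue
        ms_err = tbl.loc[err, "ms"]
        df_err = tbl.loc[err, "df"]
        if not np.isfinite(ms_err) or ms_err == 0 or df_err < 1:
            f_vals.append(np.nan)
            p_vals.append(np.nan)
        else:
            f = row["ms"] / ms_err
            f_vals.append(f)
            p_vals.append(stats.f.sf(f, row["df"], df_err))
        denom = row["ss"] + tbl.loc[err, "ss"]
        eta.append(row["ss"] / denom if denom > 0 else np.nan)
    tbl["F"] = f_vals
    tbl["p"] = p_vals
    tbl["partial_eta_sq"] = eta
    return AnovaResult(tbl[["ss", "df", "ms", "F", "p", "partial_eta_sq", "error_term"]])


def t_critical(p_two_tailed: float, df: int) -> float:
    """Two-tailed Student-t critical value at the given p."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not (0.0 < p_two_tailed < 1.0):
        raise ValueError("p must lie in (0, 1)")
    return float(stats.t.isf(p_two_tailed / 2.0, df))


def bonferroni_tcrit(family_alpha: float = 0.05, m: int = 12, df: int = 12) -> float:
    """Two-tailed t critical value after dividing the family alpha by ``m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return t_critical(family_alpha / m, df)


def min_sig_diff(t_crit: float, mse_within: float, lam=(1.0, -1.0), n=13) -> float:
    """Minimum significant contrast: t_crit * sqrt(MSE * sum(lam_i^2/n_i))."""
    lam = np.asarray(lam, dtype=float)
    n_arr = np.broadcast_to(np.asarray(n, dtype=float), lam.shape)
    if np.any(n_arr < 1):
        raise ValueError("cell sizes must be >= 1")
    if abs(lam.sum()) > 1e-9:
        raise ValueError("contrast weights must sum to 0")
    if mse_within < 0:
        raise ValueError("MSE must be >= 0")
    return float(t_crit * np.sqrt(mse_within * np.sum(lam**2 / n_arr)))


@dataclass(eq=False)
class SignificanceTable:
    """Per electrode x bin: signed target-distractor difference and flag.

    ``flags`` entries are 'T' (target advantage), 'D' (distractor advantage)
    or '' (below threshold).
    """

    electrodes: list[str]
    bin_edges: np.ndarray
    differences: np.ndarray
    flags: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.differences = np.asarray(self.differences, dtype=float)
        self.flags = np.asarray(self.flags, dtype=object)
        shape = (len(self.electrodes), self.bin_edges.size - 1)
        if self.differences.shape != shape or self.flags.shape != shape:
            raise ValueError("differences/flags shape mismatch")

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    def counts(self) -> tuple[int, int]:
        """(#target-advantage, #distractor-advantage) significant cells."""
        return int(np.sum(self.flags == "T")), int(np.sum(self.flags == "D"))

    def as_frame(self) -> pd.DataFrame:
        recs = []
        for i, e in enumerate(self.electrodes):
            for b in range(self.n_bins):
                recs.append(
                    {
                        "electrode": e,
                        "bin": b + 1,
                        "bin_start_ms": self.bin_edges[b],
                        "bin_end_ms": self.bin_edges[b + 1],
                        "diff_uv": self.differences[i, b],
                        "flag": self.flags[i, b],
                    }
                )
        return pd.DataFrame(recs)


def infer_polarity(bins: BinTable, minuend="target", subtrahend="distractor") -> np.ndarray:
    """Dominant-peak sign per electrode x bin cell.

    The sign of whichever condition has the larger absolute vincentized
    amplitude; this is the polarity under which a signed difference is
    interpreted (at negative-going peaks a more negative value is the larger
    response).
    """
    v = bins.values
    t = v[bins.condition_index(minuend)]
    d = v[bins.condition_index(subtrahend)]
    dominant = np.where(np.abs(t) >= np.abs(d), t, d)
    return np.where(dominant >= 0, 1.0, -1.0)


def classify_cells(
    differences: np.ndarray | BinTable,
    threshold: float,
    polarity: np.ndarray,
    electrodes: list[str] | None = None,
    bin_edges: np.ndarray | None = None,
    window_ms: tuple[float, float] = (0.0, 700.0),
) -> SignificanceTable:
    """Flag cells whose |difference| reaches the threshold.

    ``differences`` is either an (electrode, bin) array of signed
    target-minus-distractor values or a :class:`BinTable` (restricted to the
    analysis window first).  ``polarity`` gives the dominant peak sign per
    cell; a significant cell with zero/NaN polarity raises, because the
    advantage cannot be assigned without it.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if isinstance(differences, BinTable):
        table = differences.window(*window_ms)
        diffs = table.differences()
        electrodes = list(table.electrodes)
        bin_edges = table.bin_edges
    else:
        diffs = np.asarray(differences, dtype=float)
        if electrodes is None:
            electrodes = [f"E{i+1}" for i in range(diffs.shape[0])]
        if bin_edges is None:
            bin_edges = np.linspace(
                window_ms[0], window_ms[1], diffs.shape[1] + 1
            )
    pol = np.asarray(polarity, dtype=float)
    if pol.shape != diffs.shape:
        raise ValueError("polarity must match the difference grid")
    sig = np.abs(diffs) >= threshold
    bad = sig & (~np.isfinite(pol) | (pol == 0))
    if np.any(bad):
        i, b = np.argwhere(bad)[0]
        raise ValueError(
            f"missing polarity for significant cell ({electrodes[i]}, bin {b + 1})"
        )
    flags = np.full(diffs.shape, "", dtype=object)
    flags[sig & (diffs * pol > 0)] = "T"
    flags[sig & (diffs * pol < 0)] = "D"
    return SignificanceTable(
        electrodes=electrodes,
        bin_edges=np.asarray(bin_edges, dtype=float),
        differences=diffs,
        flags=flags,
        threshold=float(threshold),
    )


def enhancement_test(n_t: int, n_d: int, n_cells: int) -> tuple[float, float]:
    """Continuity-corrected chi-square (1 df) comparing the proportion of
    target-advantage cells with the proportion of distractor-advantage cells
    out of ``n_cells`` comparisons each.

    Returns (chi2, p).  The |ad - bc| - N/2 term is clamped at zero.
    """
    if min(n_t, n_d, n_cells) < 0:
        raise ValueError("counts must be >= 0")
    if n_t > n_cells or n_d > n_cells:
        raise ValueError("counts cannot exceed the number of comparisons")
    a, b = n_t, n_cells - n_t
    c, d = n_d, n_cells - n_d
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if any(mm == 0 for mm in margins):
        raise ValueError("degenerate 2x2 table: zero margin")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    chi2 = n * num**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(chi2), float(stats.chi2.sf(chi2, 1))
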