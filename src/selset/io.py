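"""Delimited-text readers/writers and the end-to-end pipeline runner.

Every artifact is plain CSV with a header; writer/reader pairs round-trip at
full float precision (values are written with ``repr``-level precision).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import actr, behavior, contrasts, head_model, homology, paths, synthetic, vincent

__all__ = [
    "PipelineConfig",
    "read_epochs",
    "write_epochs",
    "read_montage",
    "write_montage",
    "read_dipoles",
    "write_dipoles",
    "write_bin_table",
    "write_topomaps",
    "read_topomaps",
    "run_pipeline",
]

log = logging.getLogger("selset")

_FLOAT_FMT = "%.17g"


def write_epochs(epochs: synthetic.EpochSet, path) -> None:
    """Long-format epochs: subject, condition, electrode, time_ms,
    amplitude_uV."""
    n_s, n_c, n_e, n_t = epochs.data.shape
    idx = pd.MultiIndex.from_product(
        [epochs.subjects, epochs.conditions, epochs.electrodes, epochs.times],
        names=["subject", "condition", "electrode", "time_ms"],
    )
    df = pd.DataFrame({"amplitude_uV": epochs.data.ravel()}, index=idx).reset_index()
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_epochs(path) -> synthetic.EpochSet:
    """Read and validate a long-format epoch file; the (subject, condition,
    electrode, time) grid must be complete and unique."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"subject", "condition", "electrode", "time_ms", "amplitude_uV"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"epoch file missing columns: {sorted(missing)}")
    if not np.issubdtype(df["amplitude_uV"].dtype, np.number):
        raise ValueError("non-numeric amplitude values in epoch file")
    subjects = list(pd.unique(df["subject"]))
    conditions = list(pd.unique(df["condition"]))
    electrodes = list(pd.unique(df["electrode"]))
    times = np.sort(pd.unique(df["time_ms"]))
    expected = len(subjects) * len(conditions) * len(electrodes) * times.size
    if len(df) != expected:
        raise ValueError(
            f"epoch grid incomplete or duplicated: {len(df)} rows, expected {expected}"
        )
    pivot = df.set_index(["subject", "condition", "electrode", "time_ms"])
    if pivot.index.has_duplicates:
        dup = pivot.index[pivot.index.duplicated()][0]
        raise ValueError(f"duplicate epoch cell: {dup}")
    data = (
        pivot["amplitude_uV"]
        .unstack("time_ms")
        .reindex(
            pd.MultiIndex.from_product([subjects, conditions, electrodes]),
        )
        .to_numpy()
        .reshape(len(subjects), len(conditions), len(electrodes), times.size)
    )
    if np.any(np.isnan(data)):
        flat = np.argwhere(np.isnan(data))[0]
        cell = (subjects[flat[0]], conditions[flat[1]], electrodes[flat[2]], times[flat[3]])
        raise ValueError(f"epoch grid missing cell {cell}")
    return synthetic.EpochSet(
        subjects=subjects,
        conditions=conditions,
        electrodes=electrodes,
        times=times,
        data=data,
    )


def write_montage(montage, path) -> None:
    df = pd.DataFrame(
        [
            {"label": e.label, "x": e.position[0], "y": e.position[1], "z": e.position[2]}
            for e in montage
        ]
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_montage(path) -> list[head_model.Electrode]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        head_model.Electrode(row.label, np.array([row.x, row.y, row.z]))
        for row in df.itertuples(index=False)
    ]


def write_dipoles(dipoles, path) -> None:
    df = pd.DataFrame(
        [
            {
                "label": d.label,
                "x": d.position[0], "y": d.position[1], "z": d.position[2],
                "mx": d.moment[0], "my": d.moment[1], "mz": d.moment[2],
                "p": d.strength,
                "peak_ms": d.peak_time,
                "width_ms": d.width,
                "condition": d.condition,
            }
            for d in dipoles
        ]
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_dipoles(path) -> list[head_model.Dipole]:
    df = pd.read_csv(path, float_precision="round_trip")
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


def write_bin_table(table: vincent.BinTable, path) -> None:
    """Wide per-cell rows with one value column per subject."""
    recs = []
    values = table.values
    for ci, cond in enumerate(table.conditions):
        for ei, elec in enumerate(table.electrodes):
            for b in range(table.n_bins):
                rec = {
                    "condition": cond,
                    "electrode": elec,
                    "bin": b + 1,
                    "bin_start_ms": table.bin_edges[b],
                    "bin_end_ms": table.bin_edges[b + 1],
                    "value_uV": values[ci, ei, b],
                }
                for si, sub in enumerate(table.subjects):
                    rec[f"value_{sub}"] = table.per_subject[si, ci, ei, b]
                recs.append(rec)
    pd.DataFrame(recs).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_topomaps(maps, path) -> None:
    recs = []
    for m in maps:
        for e, v in zip(m.electrodes, m.values):
            recs.append(
                {
                    "condition": m.condition,
                    "time_ms": m.time_ms,
                    "provenance": m.provenance,
                    "electrode": e,
                    "value_uV": v,
                }
            )
    pd.DataFrame(recs).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_topomaps(path) -> list[actr.TopoMap]:
    df = pd.read_csv(path, float_precision="round_trip")
    maps = []
    for (cond, t, prov), grp in df.groupby(
        ["condition", "time_ms", "provenance"], sort=True
    ):
        maps.append(
            actr.TopoMap(
                time_ms=float(t),
                condition=cond,
                provenance=prov,
                electrodes=list(grp["electrode"]),
                values=grp["value_uV"].to_numpy(dtype=float),
            )
        )
    return maps


@dataclass
class PipelineConfig:
    """All knobs for the seeded end-to-end run."""

    seed: int = 0
    out_dir: str = "selset-out"
    n_subjects: int = 13
    sampling_rate: float = 1000.0
    noise_sd: float = 1.0
    noise_phi: float = 0.7
    family_alpha: float = 0.05
    n_electrode_family: int = 12
    tcrit_df: int = 12
    path_tolerance: float | None = None
    noise_fraction: float = 0.1
    write_epoch_file: bool = True

    def config_hash(self) -> str:
        """Hash of the numeric parameterization (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Synthesize, vincentize, test, classify, trace paths, simulate and
    compare -- writing every artifact under ``cfg.out_dir``.

    Returns a summary dict echoing seeds, the config hash and headline
    numbers.  Any stage failure propagates with a stage-tagged message.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "init"
    t0 = time.time()
    try:
        stage = "synthesize"
        gen_cfg = synthetic.GeneratorConfig(
            n_subjects=cfg.n_subjects,
            sampling_rate=cfg.sampling_rate,
            noise_sd=cfg.noise_sd,
            noise_phi=cfg.noise_phi,
        )
        beh = synthetic.generate_study_behavior(gen_cfg, seed=cfg.seed)
        beh.to_csv(out / "behavior.csv", index=False, float_format=_FLOAT_FMT)
        summary = behavior.summarize(beh)
        summary.as_frame().to_csv(out / "behavior_summary.csv", index=False)
        epochs = synthetic.generate_epochs(gen_cfg, seed=cfg.seed + 1)
        if cfg.write_epoch_file:
            write_epochs(epochs, out / "epochs.csv")

        stage = "vincentize"
        bins = vincent.vincentize_epochs(epochs)
        write_bin_table(bins, out / "bins.csv")

        stage = "contrasts"
        anova = contrasts.omnibus_anova(bins)
        anova.table.to_csv(out / "anova.csv")
        tcrit = contrasts.bonferroni_tcrit(
            cfg.family_alpha, cfg.n_electrode_family, cfg.tcrit_df
        )
        threshold = contrasts.min_sig_diff(
            tcrit, anova.mse_within, (1.0, -1.0), cfg.n_subjects
        )
        window = bins.window(0.0, 700.0)
        sig = contrasts.classify_cells(
            bins, threshold, contrasts.infer_polarity(window)
        )
        sig.as_frame().to_csv(out / "significance.csv", index=False)
        n_t, n_d = sig.counts()
        n_cells = len(sig.electrodes) * sig.n_bins
        if n_t + n_d > 0:
            chi2, chi2_p = contrasts.enhancement_test(n_t, n_d, n_cells)
        else:
            chi2, chi2_p = float("nan"), float("nan")

        stage = "paths"
        montage = head_model.standard_montage(epochs.electrodes)
        tol = threshold if cfg.path_tolerance is None else cfg.path_tolerance
        act_paths = paths.build_paths(sig, montage, tol)
        paths.path_edges(act_paths).to_csv(out / "paths.csv", index=False)
        (out / "paths.txt").write_text(paths.narrate(act_paths, sig.bin_edges) + "\n")

        stage = "simulate"
        sim_maps = []
        for cond in ("target", "distractor"):
            trace, patterns, maps = actr.simulate_condition(cond)
            sim_maps.extend(maps)
            pd.DataFrame(
                [
                    {
                        "time_ms": f.time_ms,
                        "production": f.production,
                        "module": f.module,
                        "region": f.region,
                        "dipole": f.dipole,
                        "activation": f.activation,
                        "response": trace.response,
                    }
                    for f in trace.firings
                ]
            ).to_csv(out / f"trace_{cond}.csv", index=False)
            spike_recs = [
                {
                    "condition": cond,
                    "electrode": p.electrode,
                    "time_ms": t,
                    "amplitude": a,
                    "source": s,
                    "code": c,
                    "scaled_uV": u,
                }
                for p in patterns
                for t, a, s, c, u in zip(
                    p.times, p.amplitudes, p.sources, p.codes, p.scaled_uv
                )
            ]
            pd.DataFrame(spike_recs).to_csv(
                out / f"spikes_{cond}.csv", index=False, float_format=_FLOAT_FMT
            )
        write_topomaps(sim_maps, out / "topomaps_simulated.csv")

        stage = "homology"
        report = homology.recovery_protocol(
            seed=cfg.seed + 2, noise_fraction=cfg.noise_fraction
        )
        report.fits_frame().to_csv(out / "homology_fits.csv", index=False)

        result = {
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "elapsed_s": round(time.time() - t0, 3),
            "behavior": {
                "accuracy_pct": summary.accuracy_pct,
                "d_prime": summary.d_prime,
                "criterion": summary.criterion,
                "mean_rt_ms": summary.mean_rt_ms,
            },
            "threshold_uV": threshold,
            "t_critical": tcrit,
            "mse_within": anova.mse_within,
            "n_target_cells": n_t,
            "n_distractor_cells": n_d,
            "chi2": chi2,
            "chi2_p": chi2_p,
            "min_r_squared": report.min_r_squared,
            "max_r_squared": report.max_r_squared,
            "structural_significant": report.structural_significant(),
        }
        (out / "run.json").write_text(json.dumps(result, indent=2, default=float) + "\n")
        log.info("pipeline finished in %.1fs", time.time() - t0)
        return result
    except Exception as exc:  # noqa: BLE001 - re-raise with stage tag
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
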