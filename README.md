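# selset

Selective-set ERP analysis and forward simulation for a 12-channel go/no-go
target-detection study design: vincentized quantile-bin statistics with
focused-contrast thresholding, scalp activity paths under wiring-minimization
constraints, a minimal production-system (module/buffer/chunk) simulator
driving a spherical-head dipole field model, and structural/functional
homology comparisons between observed and simulated topographic maps.
A seeded synthetic-data module emulates the 13-subject, 150-trial study
structure so the whole pipeline runs end to end with no external data.

## Layout

| module | what it does |
| --- | --- |
| `selset.head_model` | unit-sphere electrode geometry, dipole -> scalp forward field (`k·p·cosθ/r²`), triangular spikes, superposed projections |
| `selset.synthetic` | seeded trial sequences, Bernoulli/ex-Gaussian behavior, AR(1) epoch grids with configurable enhancement structure |
| `selset.behavior` | accuracy, d′/criterion signal-detection metrics, ±2 SD response window |
| `selset.vincent` | empirical quantiles, Vincent averaging, 12×100 ms bin tables |
| `selset.contrasts` | balanced split-plot ANOVA (from first principles), Bonferroni t-critical, minimum-significant-difference threshold, T/D cell classification, continuity-corrected χ² |
| `selset.paths` | per-bin maximum-difference electrode sets, simultaneity grouping, least-path ordering with movement-rule replay |
| `selset.actr` | production schedule (k·100 + 50 ms), serial firing engine, per-electrode polyspiking, coarse coding, topographic bin maps |
| `selset.homology` | localization z-ranges (Welch/Mann–Whitney comparison) and per-bin map regressions (R²) |
| `selset.io` / `selset.cli` | CSV readers/writers, pipeline runner, `selset` subcommand CLI |
| `selset.fixtures` | packaged tables: worked-example difference grid, dipole configuration, localization ranges |

All file formats are plain delimited text; writer/reader pairs round-trip at
full float precision.

## CLI

```sh
selset synth --seed 1 --out epochs.csv              # synthetic epoch grid
selset vincentize epochs.csv --out bins.csv          # 12-bin vincentized table
selset contrasts epochs.csv --out significance.csv   # ANOVA + threshold + flags
selset paths significance.csv --tolerance 0.8 --out paths.csv
selset simulate --condition target --maps-out sim.csv
selset homology actual.csv sim.csv                   # per-bin R² + z-ranges
selset run-all --seed 1 --out-dir out/               # everything, seeded
```

`selset run-all` accepts `--config cfg.yaml` with any `PipelineConfig`
field; outputs carry the seed and a config hash so re-runs are reproducible.

## Notes

- The packaged enhancement table and dipole/localization coordinates are
  editable configuration fixtures, not measured data; electrode positions
  use a fixed idealized spherical convention because the forward model is
  only ever used on a relative scale.
- The synthetic generator is deterministic under explicit seeds everywhere;
  no hidden global RNG state.
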