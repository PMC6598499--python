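# thermoniche

Thermal-niche analysis pipeline for microalgal growth experiments: estimate
growth rates from fluorescence time series, fit a Blanchard-type thermal
performance curve per strain, derive the thermal optimum / maximum / 80%
performance range, and quantify phylogenetic signal (Pagel's λ, Blomberg's K)
and genetic–geographic distance structure (Mantel test) in the resulting
trait data. A seeded synthetic-data generator produces trees,
phylogenetically structured thermal optima, and noisy multi-temperature
growth experiments so every stage is testable end to end.

## Modules

| module | contents |
| --- | --- |
| `thermoniche.growth_kinetics` | log2-F0 growth-rate regression, replicate averaging, viability fractions |
| `thermoniche.thermal_response` | Blanchard curve, multistart NLS fit with delta-method SEs, performance range, correlation/regression helper |
| `thermoniche.phylo_comparative` | penalized-likelihood rate smoothing, BM covariance, Pagel's λ (ML + LR test), Blomberg's K (+ permutation test), p-distances, haversine distances, Mantel test |
| `thermoniche.synthetic_data` | Yule tree simulator, λ-BM trait simulator, strain-panel and growth-experiment generators |
| `thermoniche.pipeline` / `thermoniche.cli` | `run_all` orchestration, YAML config, SST summary, click CLI |

## CLI

```bash
# generate a synthetic 24-strain panel
thermoniche simulate --seed 1 --out panel/

# stage by stage
thermoniche growth-rates --f0 panel/f0.csv --out rates.csv
thermoniche fit-tpc --rates rates.csv --out tpc.csv
thermoniche niche --tpc tpc.csv --fraction 0.8
thermoniche phylosignal --tree panel/tree.nwk --trait topt.csv --n-perm 999 --seed 1
thermoniche mantel --alignment aln.fasta --coords panel/strains.csv --n-perm 999 --seed 1
thermoniche sst 10 12 14 16

# everything at once (flags override config-file values)
thermoniche run-all --f0 panel/f0.csv --tree panel/tree.nwk \
    --strains panel/strains.csv --out out/ --seed 1
thermoniche run-all --config run.yaml
```

`run-all` writes `rates.csv`, `tpc_fits.csv` and a `report.json` containing
the effective configuration, the phylogenetic-signal block, the Mantel result
(when an alignment is given), and the trait/environment regressions
(μmax–Topt observed and predicted, Topt–SST yearly and per season,
width–Topt, width–SST-sd, width–μmax). Reports are byte-identical across
runs with the same config and seed.

### Input formats

- **f0.csv** — long format, columns `strain_id, temperature_c, replicate,
  time_days, f0`.
- **tree.nwk** — rooted newick; non-ultrametric trees are converted by
  penalized-likelihood rate smoothing (default smoothing 0.1).
- **strains.csv** — `strain_id, lat_dd, lon_dd, climate_zone, sst_winter,
  sst_spring, sst_summer, sst_autumn, sst_mean, sst_sd` (decimal degrees,
  S/W negative).
- **alignment** — aligned FASTA; p-distances use pairwise deletion of gaps
  and ambiguity codes.

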