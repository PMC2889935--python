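# refselect

Selection of optimal reference-gene subsets for qRT-PCR normalization.

The normalizing factor (NF) for a set of reference genes is the geometric
mean of their expression levels; the log NF is the arithmetic mean of the
log expressions. `refselect` estimates the full (unstructured) covariance
matrix **V** of the candidate genes' log expression, computes the log-NF
variance **C'VC**/L² for every one of the 2^J−1 nonempty gene subsets, and
ranks subsets robustly by bootstrapping the samples: per subset it reports
the 95% upper confidence limit (UCL) of the variance and the average
bootstrap rank. Subsets are then selected by one of three criteria:

- **A** — minimize the 95% UCL of the log-NF variance;
- **B** — minimize the number of genes subject to the UCL (SD scale)
  staying under an acceptable threshold;
- **C** — minimize the average bootstrap rank.

Unlike stability rankings of individual genes, this evaluates whole
subsets and accounts for correlation among the candidates' innate
variation. Baseline comparators are included for head-to-head evaluation:
the geNorm pairwise-variation stability ranking and an
independence-assuming (diagonal-covariance) subset scorer. A simulation
engine generates datasets from configurable covariance scenarios and
measures each method's sensitivity to the true optimal subset.

## Package layout

| module | contents |
| --- | --- |
| `refselect.data_io` | wide/long table IO, Ct → relative-expression transform, replicate averaging, log transform |
| `refselect.covariance` | unstructured covariance estimation (OLS closed form), fixed-sample-effect residuals, residual correlations |
| `refselect.subsets` | subset enumeration, log geometric means, quadratic-form variances, ranking |
| `refselect.bootstrap` | bootstrap resampling of samples, UCL/mean-rank summaries, criteria A/B/C, UCL-vs-rank plot data |
| `refselect.baselines` | geNorm ranking, diagonal-model comparator (total / innate / REML-weighted innate variances) |
| `refselect.simulation` | scenario specs, synthetic data, true-optimum tables, sensitivity experiment |
| `refselect.cli` | `refselect` command-line front end |

## CLI

```sh
# bootstrap selection on a samples x genes table of log expression
refselect select --input expr.csv -B 1000 --seed 7 --criterion A --out-dir out/

# raw-Ct analysis (no transform), criterion B with an SD threshold
refselect select --input ct.csv --scale ct --no-transform \
    --criterion B --sd-threshold 0.55 --out-dir out_ct/

# per-size minima table for a named scenario (no simulation)
refselect simulate --scenario s1_uncorrelated --sizes-only --out-dir sim/

# full sensitivity experiment, all five scenarios
refselect simulate --all --n 80 --reps 400 --seed 7 --out-dir sens/

# geNorm stability ranking; synthetic fixture generation
refselect genorm --input expr.csv --out genorm.csv
refselect fixtures --scenario s3_mixed02 --n 40 --seed 2 --out fixture.csv
```

`select` writes the estimated covariance, the per-subset variance table,
the bootstrap summary, top-per-size and top-10-by-rank reports, the
UCL-vs-rank scatter data and a `selection.json` that echoes the full
configuration (seed, B, ...) so any run is reproducible byte-for-byte.
A YAML file passed via `--config` supplies defaults; explicit flags win.

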