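# reefsync

Community synchrony and portfolio-effect statistics for benthic
percent-cover time series.

Long-term reef monitoring produces annual percent-cover estimates for many
coral taxa at many fixed plots. A central question for such data is whether
total community cover is stabilised by *asynchrony* among populations (the
portfolio effect) and, when synchrony is observed, whether it reflects
consistent positive or negative covariation among taxa or just random,
uncoupled fluctuation. `reefsync` implements the full inferential toolkit
for that question, plus a synthetic community generator so every stage can
be exercised and calibrated without field data.

## The statistics

**Synchrony index.** For one site (or the cross-site mean), with `v` the
temporal covariance matrix of the taxa over the years of a phase,

```
phi = sum_ij v_ij / ( sum_i sqrt(v_ii) )^2
```

The numerator equals the temporal variance of total community cover, so
`phi = 1` when populations fluctuate perfectly synchronously and `phi = 0`
when the community total does not fluctuate (perfect compensation).

**Variance-preserving permutation null.** Each taxon's covers are
independently permuted among years and phi recomputed; permutation leaves
every population's variance (and hence phi's denominator) untouched, so the
null isolates covariation. An observed phi below the central 95% quantile
range of 10,000 replicates indicates net negative covariation, above it net
positive covariation.

**Bootstrapped repeated-measures ANOVA.** Year effects on total cover are
tested by comparing the observed within-subjects F ratio (df `(Y-1,
(Y-1)(S-1))`) to a null built by permuting year labels within each site,
with bootstrap post hoc year-pair contrasts.

**Covariance-sign consistency.** For each taxon pair, an exact two-tailed
binomial test at p = 1/2 asks whether the sign of the pair's temporal
covariance is the same across more sites than a fair coin allows.

## Worked example

Simulate a 15-site, 2013–2021 survey of 12 focal taxa plus an "other
corals" class, with a cumulative predator-outbreak decline from 2018, then
analyse it:

```bash
reefsync simulate --scenario reef-decline --seed 7 --out survey.csv
cat > config.yaml <<EOF
input:
  csv: survey.csv
seed: 7
resampling:
  n_reps: 10000
EOF
reefsync analyze --config config.yaml --out-dir results
```

`results/synchrony_table.csv` then contains one row per site x phase plus
island-mean rows, e.g.:

```
       site  phase   observed_si  null_quantile_low  null_quantile_high  classification
island_mean phase1      0.160654           0.026456            0.358468  not_significant
island_mean phase2      0.980920           0.017838            0.381172  positive_covariation
```

In phase 1 (stable, independently fluctuating populations) the island-mean
synchrony index is 0.16 and indistinguishable from randomly fluctuating
communities; in phase 2 the shared decline drives it to 0.98, far above the
null's 95% quantile range — significant positive covariation. The
accompanying ANOVA table shows no year effect on total cover in phase 1
(`F(4, 56) = 1.14, p = 0.34`) and a strong one in phase 2
(`F(3, 42) = 222.3, p = 0.0001`), and `pair_consistency.csv` flags 75 of 78
pairs as consistently positively covarying in phase 2 versus 3 in phase 1.

The same pipeline runs on real data: any CSV with columns
`site, year, taxon, cover` works as `input.csv`.

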