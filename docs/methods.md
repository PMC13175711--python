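# Methods

## Data model

The exchange object is a dense site × year × taxon tensor of percent cover
(fraction of plot area × 100). Taxa are mutually exclusive substrate
classes, so covers are in [0, 100] and sum to ≤ 100 per site-year, leaving
an implicit non-coral remainder. Long-format CSV
(`site, year, taxon, cover`) is canonical on disk; wide matrices exist only
internally. Missing (site, year, taxon) combinations are zero-filled with a
logged warning: under point-intercept sampling, a taxon absent from a
year's sample genuinely has estimated cover 0. Reading uses pandas'
round-trip float parsing so read → write → read is the identity.

Phases are a priori year windows (defaults: 2013–2017 and 2018–2021). Each
window must contain at least three survey years: a temporal variance needs
two points, and a permutation null over year shuffles is degenerate below
three. Island (cross-site) means weight every site equally; the survey
design samples a fixed number of points per plot, so equal weighting is the
natural choice and plot area does not vary.

Focal-group selection keeps taxa whose across-site mean cover exceeds a
threshold (default 0.5%) in at least one year and which occur at a minimum
number of sites (default 4); selection is monotone in both knobs and an
empty result is a warning, not an error.

## Synchrony index

For a years × taxa matrix with temporal covariance matrix `v`,
`phi = Σ_ij v_ij / (Σ_i √v_ii)²`. The numerator equals the variance of the
community-total series (an identity the test suite checks to 1e-9 relative
tolerance over randomized matrices). All variances and covariances use the
sample (n − 1) normalisation, applied consistently; `phi` is invariant to
that choice, which only fixes the scale of reported covariances. Zero-
variance taxa contribute 0 to both numerator terms and the denominator and
are retained rather than dropped, so taxon sets remain comparable across
sites. A community in which every taxon is constant has an undefined index
and raises an error. Tiny negative numerators from floating cancellation
(a constant-total community) are reported as exactly 0. Pearson r is
emitted alongside each pairwise covariance for visual comparability (it is
bounded in [−1, 1]); the covariance *sign* is the inferential quantity in
the consistency test.

## Permutation null for the synchrony index

Each replicate independently permutes (without replacement) each taxon's
covers among years within a site and recomputes `phi`. A permutation leaves
each taxon's multiset of values — hence its temporal variance and the
index's denominator — exactly unchanged; only the covariance structure
varies, which is precisely the component the null is meant to isolate. The
total-community variance is therefore *not* held fixed across replicates,
only its population-level components are. Implementation-wise the
denominator is computed once from the observed matrix and each replicate
recomputes only the variance of its permuted community totals; the two
routes are mathematically identical and this one makes denominator
constancy exact by construction.

Classification uses the central 95% quantile range of the null (2.5% and
97.5% empirical quantiles, linear interpolation of order statistics /
type 7): observed `phi` strictly below the lower bound is evidence of net
negative covariation, strictly above the upper bound of net positive
covariation; equality with a bound is conservatively not significant.
Default 10,000 replicates; tests and quick runs reduce this via config.

Validity note: the permutation null assumes years are exchangeable within
each taxon. The calibration checks in the acceptance tests therefore use
noise-free independent-dynamics series, where exchangeability holds
exactly; multinomial observation noise adds a small negative within-year
coupling among taxa (points assigned to one class are unavailable to
another) that is negligible at realistic covers but formally violates
independence.

## Bootstrapped repeated-measures ANOVA

Year effects on total cover use the one-way within-subjects decomposition
`SS_total = SS_sites + SS_year + SS_error`, F = MS_year / MS_error with df
`(Y − 1, (Y − 1)(S − 1))` (15 sites × 5 years → df (4, 56)); the observed F
is checked against `statsmodels` in the test suite. Because cover data are
typically non-normal and heteroscedastic, significance comes from a
permutation null: year labels are shuffled within each site (preserving the
repeated-measures blocking) and F recomputed; a global shuffle across the
full site × year pool is available behind `shuffle="global"` for users who
prefer the unblocked reading. `p = (1 + #{F_null ≥ F_obs}) / (n_reps + 1)`,
so finite resampling never reports p = 0. A matrix with no within-site
variation has an undefined F, reported as F = 0 with p = 1 by convention.
Post hoc year-pair contrasts resample group assignments with replacement
from the pooled pair values and report raw two-sided bootstrap p-values
(no multiplicity correction, matching per-contrast α = 0.05 reporting).

## Covariance-sign consistency

For each taxon pair, a site "occurrence" requires both taxa to have
positive temporal variance in the phase (a constant taxon has no covariance
sign); zero covariances count toward occurrences but toward neither sign.
With n occurrences and k = max(positives, negatives), the two-tailed exact
binomial probability at p = 1/2 sums P(X = j) over all outcomes no likelier
than the observed one, capped at 1 — at p = 1/2 this equals doubling the
tail beyond max(k, n − k). Significance is p < 0.05 per pair; a Holm
step-down adjustment across pairs is available behind a flag but off by
default, matching per-pair α reporting. Pairs occurring at no site are
omitted with a warning.

## Synthetic community generator

The generator emulates a fixed-plot annual survey: 15 sites, nine annual
surveys (2013–2021), 12 focal taxa plus an "other corals" remainder with
baselines summing to ≈33% cover, and virtual-point-intercept observation
noise (2,500 multinomial point classifications per plot-year, the density
of 25 points/m² on a 10 m × 10 m plot). On the log scale,

```
log cover[s, t, i] = log baseline_i + lambda_i · u[s, t] + eps[s, t, i]
```

with `u` a shared site-year effect (sd `sigma_shared`, default =
`sigma_log`) and `eps` independent Gaussian (sd `sigma_log`, default 0.25,
giving population CVs around 0.25). Modes: *independent* (λ = 0),
*common_forcing* (λ_i = `rho_shared` for all taxa), and *compensatory*
(per-year taxon deviations from an equicorrelated Gaussian with negative
pairwise correlation `rho_shared`, feasible only for `rho ≥ −1/(k−1)`,
constructed exactly from centered/mean components so the boundary
`rho = −1` with two taxa yields perfectly opposed deviations). Multiplicative
lognormal fluctuations were chosen because cover is positive and CV-based
stability measures are scale-free. Because fluctuations are multiplicative,
a two-taxon `rho = −1` community has a constant *log-scale* sum, not a
constant cover sum; its synchrony index approaches 0 in the small-noise
limit rather than vanishing exactly.

The phase-2 decline is a cumulative per-year survival multiplier per taxon
from a start year (default 0.72/yr from 2018, roughly halving cover within
two years as a predator outbreak would); the analysis consumes only
abundance trajectories, so no predator agent model is attempted. Covers
whose sum exceeds 100 are proportionally renormalised (logged). Point
placement is exchangeable multinomial, not spatially explicit; spatial
autocorrelation of colonies is out of scope. Consequently, passing tests
demonstrate the statistical machinery under the stated generative
assumptions (lognormal fluctuations, exchangeable years, multinomial
observation) and say nothing about spatial structure, observer error, or
taxonomic misclassification in real surveys.

## Determinism and problem sizes

All resampling flows through `numpy.random.Generator`; the pipeline spawns
per-stage child streams from one root seed, so identical config + seed
produces byte-identical report CSVs. Monte-Carlo checks in the acceptance
tests use 500 simulated site-phases (500 null replicates each) for the 95%
coverage of the classification rule, 500 datasets for the ANOVA type-I
rate, and 200 simulations per power scenario — sizes at which the
two-standard-error Monte-Carlo bands are ±2% and the checks complete in
seconds.

## Known limitations

- The permutation null tests exchangeability of years within taxa; trends
  within a phase register as covariation (that is the intended reading of
  the phase-2 decline, but it means the null is not a trend-removal tool).
- No sphericity-corrected parametric ANOVA, mixed models, detrending, or
  alternative synchrony metrics (variance ratio, Gross index).
- The consistency test treats sites as independent coin flips; spatial
  correlation among nearby sites would make it anti-conservative.
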