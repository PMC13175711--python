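"""Resampling inference: synchrony nulls, bootstrap RM-ANOVA, sign tests.

Three procedures:

1. A variance-preserving permutation null for the synchrony index: each
   taxon's cover values are independently permuted among years, which leaves
   every population's temporal variance (and hence the SI denominator)
   unchanged and isolates the contribution of covariation. Observed SI below
   the central 95% quantile range of the null is evidence of net negative
   covariation, above it of net positive covariation.

2. A bootstrapped repeated-measures ANOVA for year effects on total cover:
   the observed F ratio from the one-way within-subjects decomposition is
   compared with a null F distribution built by permuting year labels within
   each site, plus bootstrap post hoc year-pair contrasts.

3. An exact two-tailed binomial test for whether a taxon pair's covariance
   sign is consistent across sites more often than a fair coin allows.

All procedures are bit-reproducible under a fixed seed. Monte-Carlo p-values
use the (1 + exceedances) / (n_reps + 1) convention so that finite
resampling never yields p = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DataValidationError, DegenerateCommunityError
from .synchrony import PairCovariance, SiteYearMatrix, synchrony_index

logger = logging.getLogger(__name__)

NOT_SIGNIFICANT = "not_significant"
POSITIVE_COVARIATION = "positive_covariation"
NEGATIVE_COVARIATION = "negative_covariation"


def _as_rng(seed: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ------------------------------------------------------------ SI null model

def permute_within_taxa(
    values: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One null replicate: independently permute each taxon column among years."""
    out = np.empty_like(values)
    for k in range(values.shape[1]):
        out[:, k] = rng.permutation(values[:, k])
    return out


def si_null_distribution(
    m: SiteYearMatrix,
    n_reps: int = 10_000,
    seed: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Null SI distribution under within-taxon year permutation.

    Each replicate independently permutes (without replacement) each taxon's
    values across years and recomputes the SI. Because a permutation leaves
    each taxon's multiset of values — hence its temporal variance — exactly
    unchanged, the SI denominator is identical in every replicate and only
    the covariance structure (the numerator) varies.
    """
    if n_reps < 1:
        raise DataValidationError("n_reps must be >= 1")
    values = m.values
    var_taxa = values.var(axis=0, ddof=1)
    denom = np.sqrt(var_taxa).sum() ** 2
    if denom == 0.0:
        raise DegenerateCommunityError(
            "degenerate community: all taxa temporally constant"
        )
    rng = _as_rng(seed)
    Y, K = values.shape
    keys = rng.random((n_reps, Y, K))
    idx = np.argsort(keys, axis=1)                      # independent column perms
    permuted = values[idx, np.arange(K)[None, None, :]]  # (n_reps, Y, K)
    num = permuted.sum(axis=2).var(axis=1, ddof=1)       # var of community totals
    null = num / denom
    return np.clip(null, 0.0, None)


@dataclass(frozen=True)
class SynchronyResult:
    """Observed SI, null quantile range and covariation classification."""

    site: str
    phase: str
    observed_si: float
    null_quantile_low: float
    null_quantile_high: float
    n_reps: int
    classification: str
    seed: int | None = None
    is_island_mean: bool = False


def classify_si(
    observed: float, null_values: Sequence[float], level: float = 0.95
) -> tuple[str, float, float]:
    """Classify an observed SI against an empirical null distribution.

    Bounds are the central ``level`` quantile range (2.5% and 97.5% for the
    default), computed by linear interpolation of order statistics (type 7).
    Strict inequalities decide significance; an observed value exactly equal
    to a bound is not significant (conservative tie rule).
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise DataValidationError("null distribution is empty")
    tail = (1.0 - level) / 2.0
    low, high = np.quantile(null, [tail, 1.0 - tail], method="linear")
    if observed < low:
        cls = NEGATIVE_COVARIATION
    elif observed > high:
        cls = POSITIVE_COVARIATION
    else:
        cls = NOT_SIGNIFICANT
    return cls, float(low), float(high)


def synchrony_with_null(
    m: SiteYearMatrix,
    site: str,
    phase: str,
    n_reps: int = 10_000,
    seed: np.random.Generator | int | None = None,
    level: float = 0.95,
    is_island_mean: bool = False,
) -> SynchronyResult:
    """Observed SI plus its permutation-null quantile range for one site x phase."""
    observed = synchrony_index(m)
    seed_val = seed if isinstance(seed, (int, type(None))) else None
    null = si_null_distribution(m, n_reps=n_reps, seed=seed)
    cls, low, high = classify_si(observed, null, level=level)
    return SynchronyResult(
        site=site,
        phase=phase,
        observed_si=observed,
        null_quantile_low=low,
        null_quantile_high=high,
        n_reps=n_reps,
        classification=cls,
        seed=seed_val,
        is_island_mean=is_island_mean,
    )


# --------------------------------------------------- bootstrapped RM-ANOVA

@dataclass(frozen=True)
class AnovaResult:
    """Bootstrapped repeated-measures ANOVA for a year effect on total cover."""

    f_observed: float
    df_between: int
    df_error: int
    p_boot: float
    n_reps: int
    posthoc: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)


def _rm_anova_decomposition(X: np.ndarray) -> tuple[float, float, float, float]:
    """(ss_sites, ss_year, ss_error, ss_total) of the within-subjects design."""
    S, Y = X.shape
    grand = X.mean()
    ss_total = float(((X - grand) ** 2).sum())
    ss_sites = float(Y * ((X.mean(axis=1) - grand) ** 2).sum())
    ss_year = float(S * ((X.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_sites - ss_year
    return ss_sites, ss_year, ss_error, ss_total


def bootstrap_rm_anova(
    totals: np.ndarray,
    years: Sequence[int] | None = None,
    n_reps: int = 10_000,
    seed: np.random.Generator | int | None = None,
    shuffle: str = "within_site",
    with_posthoc: bool = False,
) -> AnovaResult:
    """Permutation-null repeated-measures ANOVA on a sites x years matrix.

    The observed F = MS_year / MS_error comes from the one-way
    within-subjects decomposition SS_total = SS_sites + SS_year + SS_error
    with df (Y-1, (Y-1)(S-1)). Null replicates permute year labels within
    each site (``shuffle="within_site"``, the default, preserving the
    repeated-measures blocking) or across the whole site x year pool
    (``shuffle="global"``). p = (1 + #{F_null >= F_obs}) / (n_reps + 1).

    A matrix with zero year and error sums of squares (identical values
    every year within each site) has an undefined F; by convention F = 0 and
    p = 1.
    """
    X = np.asarray(totals, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise DataValidationError("totals must be a (>=2 sites) x (>=2 years) matrix")
    if not np.all(np.isfinite(X)):
        raise DataValidationError("missing cells: the design must be balanced")
    if shuffle not in ("within_site", "global"):
        raise DataValidationError(f"unknown shuffle mode {shuffle!r}")
    S, Y = X.shape
    df_between, df_error = Y - 1, (Y - 1) * (S - 1)
    ss_sites, ss_year, ss_error, ss_total = _rm_anova_decomposition(X)

    if ss_year == 0.0 and ss_error <= 0.0:
        return AnovaResult(0.0, df_between, df_error, 1.0, n_reps)
    if ss_error <= 0.0:
        f_obs = np.inf
    else:
        f_obs = (ss_year / df_between) / (ss_error / df_error)

    rng = _as_rng(seed)
    if shuffle == "within_site":
        keys = rng.random((n_reps, S, Y))
        idx = np.argsort(keys, axis=2)
        Xp = np.take_along_axis(np.broadcast_to(X, (n_reps, S, Y)), idx, axis=2)
        # row means are permutation-invariant, so SS_sites is fixed
        grand = X.mean()
        colmeans = Xp.mean(axis=1)                                  # (n_reps, Y)
        ss_year_r = S * ((colmeans - grand) ** 2).sum(axis=1)
        ss_error_r = (ss_total - ss_sites) - ss_year_r
    else:
        flat = X.ravel()
        keys = rng.random((n_reps, S * Y))
        idx = np.argsort(keys, axis=1)
        Xp = flat[idx].reshape(n_reps, S, Y)
        grand = X.mean()
        rowmeans = Xp.mean(axis=2)
        colmeans = Xp.mean(axis=1)
        ss_sites_r = Y * ((rowmeans - grand) ** 2).sum(axis=1)
        ss_year_r = S * ((colmeans - grand) ** 2).sum(axis=1)
        ss_error_r = ss_total - ss_sites_r - ss_year_r

    with np.errstate(divide="ignore", invalid="ignore"):
        f_null = (ss_year_r / df_between) / (ss_error_r / df_error)
    f_null = np.nan_to_num(f_null, nan=0.0, posinf=np.inf)
    p = (1 + int((f_null >= f_obs).sum())) / (n_reps + 1)

    posthoc: dict[tuple[int, int], tuple[float, float]] = {}
    if with_posthoc:
        yrs = list(years) if years is not None else list(range(Y))
        posthoc = posthoc_year_differences(X, yrs, n_reps=n_reps, seed=rng)
    return AnovaResult(float(f_obs), df_between, df_error, float(p), n_reps, posthoc)


def posthoc_year_differences(
    totals: np.ndarray,
    years: Sequence[int] | None = None,
    n_reps: int = 10_000,
    seed: np.random.Generator | int | None = None,
) -> dict[tuple[int, int], tuple[float, float]]:
    """Bootstrap post hoc contrasts between every pair of years.

    For each year pair the observed statistic is the difference of
    across-site means. The null resamples group assignments with replacement
    from the pooled 2S values of that pair; the two-sided p-value is
    (1 + #{|d_null| >= |d_obs|}) / (n_reps + 1). Raw p-values are reported
    (no multiplicity correction, matching per-contrast alpha reporting).
    """
    X = np.asarray(totals, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise DataValidationError("totals must be a (>=2 sites) x (>=2 years) matrix")
    if not np.all(np.isfinite(X)):
        raise DataValidationError("missing cells: the design must be balanced")
    S, Y = X.shape
    yrs = list(years) if years is not None else list(range(Y))
    if len(yrs) != Y:
        raise DataValidationError("years labels do not match matrix width")
    rng = _as_rng(seed)
    out: dict[tuple[int, int], tuple[float, float]] = {}
    for a, b in combinations(range(Y), 2):
        pooled = np.concatenate([X[:, a], X[:, b]])
        d_obs = X[:, a].mean() - X[:, b].mean()
        g1 = pooled[rng.integers(0, 2 * S, size=(n_reps, S))].mean(axis=1)
        g2 = pooled[rng.integers(0, 2 * S, size=(n_reps, S))].mean(axis=1)
        d_null = g1 - g2
        p = (1 + int((np.abs(d_null) >= abs(d_obs)).sum())) / (n_reps + 1)
        out[(yrs[a], yrs[b])] = (float(d_obs), float(p))
    return out


# ---------------------------------------------- covariance-sign consistency

@dataclass(frozen=True)
class PairConsistency:
    """Cross-site covariance-sign consistency for one taxon pair x phase."""

    taxon_i: str
    taxon_j: str
    phase: str
    n_sites_present: int
    n_positive: int
    n_negative: int
    p_binomial: float
    significant: bool


def two_tailed_binomial_p(k: int, n: int) -> float:
    """Exact two-tailed binomial probability at success probability 1/2.

    Sums P(X = j) over every outcome j whose point probability does not
    exceed P(X = k), capped at 1. At p = 1/2 the distribution is symmetric,
    so this equals min(1, 2 x tail beyond max(k, n - k)).
    """
    if not (0 <= k <= n):
        raise DataValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    pmf = stats.binom.pmf(np.arange(n + 1), n, 0.5)
    p = float(pmf[pmf <= pmf[k] * (1 + 1e-12)].sum())
    return min(1.0, p)


def covariance_sign_consistency(
    pairs_by_site: Mapping[str, Sequence[PairCovariance]],
    phase: str = "",
    alpha: float = 0.05,
    holm: bool = False,
) -> list[PairConsistency]:
    """Binomial test of covariance-sign consistency across sites per pair.

    A pair "occurs" at a site when both taxa have positive temporal variance
    there (sign is not "undefined"); zero-covariance occurrences count
    toward ``n_sites_present`` but to neither sign. With n occurrences and
    k = max(n_positive, n_negative), the two-tailed exact binomial
    probability at 1/2 tests whether the sign is more consistent than chance
    (significant iff p < ``alpha``; optional Holm step-down adjustment
    across pairs when ``holm=True``). Pairs occurring at no site are omitted
    with a warning.
    """
    tally: dict[tuple[str, str], dict[str, int]] = {}
    for site, records in pairs_by_site.items():
        for rec in records:
            key = (rec.taxon_i, rec.taxon_j)
            t = tally.setdefault(key, {"n": 0, "pos": 0, "neg": 0})
            if rec.sign == "undefined":
                continue
            t["n"] += 1
            if rec.sign == "+":
                t["pos"] += 1
            elif rec.sign == "-":
                t["neg"] += 1

    keys, pvals, rows = [], [], []
    for (ti, tj), t in tally.items():
        if t["n"] == 0:
            logger.warning(
                "pair (%s, %s) occurs at no site in phase %s; omitted", ti, tj, phase
            )
            continue
        k = max(t["pos"], t["neg"])
        p = two_tailed_binomial_p(k, t["n"])
        keys.append((ti, tj))
        pvals.append(p)
        rows.append((ti, tj, t))

    if holm and pvals:
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
        pvals = list(p_adj)
        signif = list(reject)
    else:
        signif = [p < alpha for p in pvals]

    return [
        PairConsistency(
            taxon_i=ti,
            taxon_j=tj,
            phase=phase,
            n_sites_present=t["n"],
            n_positive=t["pos"],
            n_negative=t["neg"],
            p_binomial=float(p),
            significant=bool(sig),
        )
        for (ti, tj, t), p, sig in zip(rows, pvals, signif)
    ]
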