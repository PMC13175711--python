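"""Synchrony index, coefficients of variation and pairwise covariation.

The community synchrony index phi (Loreau & de Mazancourt sense) is

    phi = sum_ij(v_ij) / (sum_i sqrt(v_ii))^2

where v is the temporal covariance matrix of the taxa. The numerator equals
the temporal variance of total community cover, so phi = 1 when all
populations fluctuate perfectly synchronously and phi = 0 when total cover
does not fluctuate at all (perfect compensation). All variances and
covariances use the sample (n-1) normalisation, applied consistently; phi is
invariant to that choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataValidationError, DegenerateCommunityError


@dataclass(frozen=True)
class SiteYearMatrix:
    """Years x taxa percent-cover matrix for one site (or the island mean)."""

    years: tuple[int, ...]
    taxa: tuple[str, ...]
    values: np.ndarray  # shape (n_years, n_taxa)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2 or self.values.shape != (len(self.years), len(self.taxa)):
            raise DataValidationError("values must be (n_years, n_taxa)")
        if len(self.years) < 3:
            raise DataValidationError("need >= 3 years")
        if len(self.taxa) < 1:
            raise DataValidationError("need >= 1 taxon")
        if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
            raise DataValidationError("values must be finite and non-negative")

    @classmethod
    def from_series(cls, series, site: str) -> "SiteYearMatrix":
        return cls(
            years=tuple(series.years),
            taxa=tuple(series.taxa),
            values=series.site_matrix(site),
        )


@dataclass(frozen=True)
class PairCovariance:
    """Temporal covariance of one unordered taxon pair at one site.

    ``pearson_r`` is NaN (undefined) iff either taxon has zero temporal
    variance, in which case ``sign`` is ``"undefined"``; otherwise sign is
    "+", "-" or "0" according to the covariance.
    """

    taxon_i: str
    taxon_j: str
    covariance: float
    pearson_r: float
    sign: str


def _covariance_matrix(values: np.ndarray) -> np.ndarray:
    """Sample (ddof=1) temporal covariance matrix of the taxon columns."""
    return np.atleast_2d(np.cov(values, rowvar=False, ddof=1))


def synchrony_index(m: SiteYearMatrix) -> float:
    """Community synchrony index phi in [0, 1].

    Raises
    ------
    DegenerateCommunityError
        If every taxon is temporally constant (zero denominator).
    """
    v = _covariance_matrix(m.values)
    denom = np.sqrt(np.diag(v)).sum() ** 2
    if denom == 0.0:
        raise DegenerateCommunityError(
            "degenerate community: all taxa temporally constant"
        )
    num = v.sum()
    if num <= 0.0:
        # var(total) >= 0 mathematically; trim float cancellation noise
        return 0.0
    return float(num / denom)


@dataclass(frozen=True)
class CVResult:
    """Coefficient of variation and its inverse (the stability measure).

    ``zero_variance`` flags a constant series: cv = 0 and the inverse is
    reported as +inf.
    """

    cv: float
    inverse_cv: float
    zero_variance: bool


def coefficient_of_variation(x: Sequence[float]) -> CVResult:
    """CV = sample sd / mean of an abundance series; mean must be positive."""
    arr = np.asarray(x, dtype=float)
    mean = arr.mean()
    if mean <= 0:
        raise DataValidationError(f"mean must be positive, got {mean}")
    sd = arr.std(ddof=1)
    if sd == 0.0:
        return CVResult(cv=0.0, inverse_cv=np.inf, zero_variance=True)
    cv = float(sd / mean)
    return CVResult(cv=cv, inverse_cv=1.0 / cv, zero_variance=False)


def pairwise_covariances(m: SiteYearMatrix) -> list[PairCovariance]:
    """One record per unordered taxon pair (k taxa -> k(k-1)/2 records).

    Covariances use the same (n-1) normalisation as the synchrony index.
    Pairs involving a zero-variance taxon get covariance 0, NaN Pearson r
    and sign "undefined".
    """
    v = _covariance_matrix(m.values)
    var = np.diag(v)
    out: list[PairCovariance] = []
    k = len(m.taxa)
    for i in range(k):
        for j in range(i + 1, k):
            if var[i] == 0.0 or var[j] == 0.0:
                out.append(
                    PairCovariance(m.taxa[i], m.taxa[j], 0.0, float("nan"), "undefined")
                )
                continue
            cov = float(v[i, j])
            r = cov / float(np.sqrt(var[i] * var[j]))
            sign = "+" if cov > 0 else "-" if cov < 0 else "0"
            out.append(PairCovariance(m.taxa[i], m.taxa[j], cov, r, sign))
    return out
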