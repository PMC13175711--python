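"""Abundance data model and long-format table I/O.

The canonical interchange object is :class:`AbundanceTimeSeries`, a dense
site x year x taxon tensor of percent cover (fraction of plot area x 100).
Long-format CSV with columns ``site, year, taxon, cover`` is the on-disk
representation; wide matrices are internal only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError

logger = logging.getLogger(__name__)

#: Sum of taxon covers per (site, year) may exceed 100 by at most this much
#: (taxa are mutually exclusive substrate classes; slack absorbs float error).
_SUM_TOL = 1e-6


@dataclass(frozen=True)
class PhaseConfig:
    """Named, non-overlapping year windows used to slice every analysis.

    Each phase is ``(name, first_year, last_year)`` with inclusive bounds and
    must span at least 3 survey years: variances need >= 2 points and
    permutation nulls over year shuffles are degenerate below 3.
    """

    phases: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        seen: list[tuple[int, int]] = []
        for name, first, last in self.phases:
            if last - first + 1 < 3:
                raise DataValidationError(
                    f"phase {name!r} spans {last - first + 1} years; need >= 3"
                )
            for lo, hi in seen:
                if first <= hi and last >= lo:
                    raise DataValidationError(f"phase {name!r} overlaps another window")
            seen.append((first, last))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.phases)

    @classmethod
    def from_dict(cls, entries: Sequence[Mapping]) -> "PhaseConfig":
        return cls(
            tuple(
                (str(e["name"]), int(e["first_year"]), int(e["last_year"]))
                for e in entries
            )
        )


#: Pre/post predator-outbreak windows of the 2013-2021 survey design.
DEFAULT_PHASES = PhaseConfig((("phase1", 2013, 2017), ("phase2", 2018, 2021)))


@dataclass
class AbundanceTimeSeries:
    """Dense site x year x taxon percent-cover tensor with optional metadata.

    Parameters
    ----------
    sites, years, taxa
        Ordered axis labels; ``years`` strictly increasing integers.
    cover
        Array of shape ``(n_sites, n_years, n_taxa)``; percent cover in
        [0, 100]; per (site, year) the taxon covers sum to <= 100.
    taxon_meta
        Optional map ``taxon -> {"life_history": ..., "species_level": ...}``,
        carried through untouched (pass-through metadata only).
    """

    sites: list[str]
    years: list[int]
    taxa: list[str]
    cover: np.ndarray
    taxon_meta: dict[str, dict] | None = None

    def __post_init__(self) -> None:
        self.cover = np.asarray(self.cover, dtype=float)
        self.validate()

    # ------------------------------------------------------------------ api
    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.sites), len(self.years), len(self.taxa))

    def validate(self) -> None:
        s, y, k = self.shape
        if self.cover.shape != (s, y, k):
            raise DataValidationError(
                f"cover shape {self.cover.shape} != (sites, years, taxa) {(s, y, k)}"
            )
        if len(set(self.sites)) != s or len(set(self.taxa)) != k:
            raise DataValidationError("duplicate site or taxon labels")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise DataValidationError("years must be strictly increasing")
        if not np.all(np.isfinite(self.cover)):
            raise DataValidationError("cover contains non-finite values")
        if self.cover.min() < 0 or self.cover.max() > 100:
            raise DataValidationError("cover outside [0, 100]")
        totals = self.cover.sum(axis=2)
        if totals.max() > 100 + _SUM_TOL:
            si, yi = np.unravel_index(np.argmax(totals), totals.shape)
            raise DataValidationError(
                f"taxon covers sum to {totals[si, yi]:.4f} > 100 at "
                f"(site={self.sites[si]}, year={self.years[yi]})"
            )

    def site_matrix(self, site: str) -> np.ndarray:
        """Year x taxon cover matrix for one site."""
        return self.cover[self.sites.index(site)]

    def subset_taxa(self, taxa: Sequence[str]) -> "AbundanceTimeSeries":
        idx = [self.taxa.index(t) for t in taxa]
        meta = (
            {t: self.taxon_meta[t] for t in taxa if t in self.taxon_meta}
            if self.taxon_meta
            else None
        )
        return AbundanceTimeSeries(
            sites=list(self.sites),
            years=list(self.years),
            taxa=list(taxa),
            cover=self.cover[:, :, idx].copy(),
            taxon_meta=meta,
        )

    def subset_years(self, years: Sequence[int]) -> "AbundanceTimeSeries":
        idx = [self.years.index(y) for y in years]
        return AbundanceTimeSeries(
            sites=list(self.sites),
            years=list(years),
            taxa=list(self.taxa),
            cover=self.cover[:, idx, :].copy(),
            taxon_meta=self.taxon_meta,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with columns site, year, taxon, cover."""
        s, y, k = self.shape
        idx = pd.MultiIndex.from_product(
            [self.sites, self.years, self.taxa], names=["site", "year", "taxon"]
        )
        return (
            pd.DataFrame({"cover": self.cover.reshape(s * y * k)}, index=idx)
            .reset_index()
        )


# ---------------------------------------------------------------------- I/O

def read_abundance_table(
    path: str | Path, percent_scale: bool = True
) -> AbundanceTimeSeries:
    """Read a long-format delimited table into a validated series.

    Missing (site, year, taxon) combinations are filled with 0 cover — under
    point-intercept sampling absence from a year's sample is a true zero —
    and each fill is logged as a warning. Duplicate records are a hard error.

    Parameters
    ----------
    path
        CSV with columns ``site, year, taxon, cover`` (UTF-8).
    percent_scale
        If True (default) cover is on [0, 100]; if False the file carries
        proportions on [0, 1] which are rescaled to percent on ingest.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = {"site", "year", "taxon", "cover"} - set(df.columns)
    if missing_cols:
        raise DataValidationError(f"missing columns: {sorted(missing_cols)}")
    df = df.astype({"site": str, "year": int, "taxon": str, "cover": float})

    dup = df.duplicated(["site", "year", "taxon"], keep=False)
    if dup.any():
        first = df.loc[dup, ["site", "year", "taxon"]].iloc[0]
        raise DataValidationError(
            "duplicate record for (site=%s, year=%s, taxon=%s)"
            % (first["site"], first["year"], first["taxon"])
        )

    hi = 100.0 if percent_scale else 1.0
    bad = df[(df["cover"] < 0) | (df["cover"] > hi)]
    if not bad.empty:
        r = bad.iloc[0]
        raise DataValidationError(
            f"cover {r['cover']} outside [0, {hi:g}] at "
            f"(site={r['site']}, year={r['year']}, taxon={r['taxon']})"
        )
    if not percent_scale:
        df = df.assign(cover=df["cover"] * 100.0)

    sites = sorted(df["site"].unique())
    years = sorted(df["year"].unique())
    taxa = sorted(df["taxon"].unique())
    wide = df.set_index(["site", "year", "taxon"])["cover"]
    full = pd.MultiIndex.from_product([sites, years, taxa], names=wide.index.names)
    filled = wide.reindex(full)
    for site, year, taxon in filled.index[filled.isna()]:
        logger.warning(
            "missing record (site=%s, year=%s, taxon=%s) filled with 0 cover",
            site, year, taxon,
        )
    cover = (
        filled.fillna(0.0)
        .to_numpy()
        .reshape(len(sites), len(years), len(taxa))
    )
    return AbundanceTimeSeries(sites=sites, years=years, taxa=taxa, cover=cover)


def write_abundance_table(series: AbundanceTimeSeries, path: str | Path) -> None:
    """Write the series as a long-format CSV (site, year, taxon, cover)."""
    series.to_frame().to_csv(path, index=False)


def read_taxon_metadata(path: str | Path) -> dict[str, dict]:
    """Read the optional taxon metadata sidecar (taxon, life_history, species_level)."""
    df = pd.read_csv(path)
    if "taxon" not in df.columns:
        raise DataValidationError("metadata sidecar needs a 'taxon' column")
    return {
        str(r["taxon"]): {
            k: r[k] for k in ("life_history", "species_level") if k in df.columns
        }
        for _, r in df.iterrows()
    }


# ------------------------------------------------------------- operations

def select_focal_groups(
    series: AbundanceTimeSeries,
    mean_cover_threshold: float = 0.5,
    min_sites: int = 4,
) -> list[str]:
    """Select focal taxa by island-wide mean cover and site occupancy.

    A taxon is focal when its across-site mean cover exceeds
    ``mean_cover_threshold`` percent in at least one year AND it is present
    (cover > 0 in any year) at at least ``min_sites`` sites. Returned in
    descending order of overall mean cover. An empty result is a warning,
    not an error.
    """
    island = series.cover.mean(axis=0)           # (years, taxa)
    exceeds = (island > mean_cover_threshold).any(axis=0)
    n_sites_present = (series.cover > 0).any(axis=1).sum(axis=0)   # per taxon
    keep = exceeds & (n_sites_present >= min_sites)
    overall = series.cover.mean(axis=(0, 1))
    order = np.argsort(-overall, kind="stable")
    focal = [series.taxa[i] for i in order if keep[i]]
    if not focal:
        logger.warning("no taxa passed focal-group selection")
    return focal


def split_phases(
    series: AbundanceTimeSeries, phases: PhaseConfig = DEFAULT_PHASES
) -> dict[str, AbundanceTimeSeries]:
    """Slice the series into one sub-series per phase window.

    Each phase keeps exactly the survey years inside its inclusive window;
    sites and taxa are unchanged. A window containing fewer than 3 survey
    years is a hard error (downstream variances and permutation nulls would
    be degenerate).
    """
    out: dict[str, AbundanceTimeSeries] = {}
    for name, first, last in phases.phases:
        inside = [y for y in series.years if first <= y <= last]
        if len(inside) < 3:
            raise DataValidationError(
                f"phase {name!r} ({first}-{last}) contains {len(inside)} survey "
                "years; need >= 3"
            )
        out[name] = series.subset_years(inside)
    return out


ISLAND_MEAN_SITE = "island_mean"


def island_mean_series(series: AbundanceTimeSeries) -> AbundanceTimeSeries:
    """Collapse sites to their unweighted mean, returning a 1-site series.

    All sites weigh equally regardless of how many points were sampled.
    """
    if not series.sites:
        raise DataValidationError("need at least one site")
    mean = series.cover.mean(axis=0, keepdims=True)
    return AbundanceTimeSeries(
        sites=[ISLAND_MEAN_SITE],
        years=list(series.years),
        taxa=list(series.taxa),
        cover=mean,
        taxon_meta=series.taxon_meta,
    )
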