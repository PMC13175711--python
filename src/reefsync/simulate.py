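"""Synthetic benthic-community generator.

Emulates the statistical structure of an annual fixed-plot percent-cover
survey: multiple sites, ~a decade of yearly visits, a dozen focal coral taxa
plus an "other corals" remainder, lognormal multiplicative cover
fluctuations with configurable shared / independent / compensatory
structure, an optional systematic second-phase decline (predator outbreak),
and multinomial virtual-point-intercept (VPI) observation noise.

The generative model on the log scale is

    log cover[s, t, i] = log baseline_i + lambda_i * u[s, t] + eps[s, t, i]

with u a shared site-year effect and eps independent Gaussian noise:

* ``independent``    — lambda = 0; eps iid N(0, sigma_log^2).
* ``common_forcing`` — lambda_i = rho_shared for all taxa;
  u ~ N(0, sigma_shared^2), eps iid N(0, sigma_log^2).
* ``compensatory``   — the per-year taxon deviation vector is mean-zero
  Gaussian with sd sigma_log and constant pairwise correlation
  rho_shared < 0 (feasible only for rho_shared >= -1/(k-1)).

Cover is positive and CVs are scale-free, so multiplicative lognormal
fluctuations are the natural noise family; the generator stands in for field
data and makes no claim to mechanism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datamodel import AbundanceTimeSeries
from .errors import DataValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeclineConfig:
    """Systematic decline: cumulative per-year survival from ``start_year``.

    ``survival`` is a single multiplier applied to every taxon, or a map
    taxon -> multiplier. A year y >= start_year has its cover multiplied by
    survival ** (y - start_year + 1).
    """

    start_year: int
    survival: float | Mapping[str, float]

    def factor(self, taxon: str, year: int) -> float:
        if year < self.start_year:
            return 1.0
        s = (
            self.survival[taxon]
            if isinstance(self.survival, Mapping)
            else self.survival
        )
        return float(s) ** (year - self.start_year + 1)


@dataclass(frozen=True)
class CommunityScenario:
    """Full parameterisation of one synthetic community draw.

    Parameters
    ----------
    taxa
        Map taxon name -> baseline mean cover (percent). Baselines must sum
        to <= 100, leaving an implicit non-coral remainder class.
    dynamics_mode
        "independent", "common_forcing" or "compensatory".
    sigma_log
        Sd of the independent log-cover fluctuations (>= 0; 0 is the
        noise-free limit used in tests).
    rho_shared
        Loading of the shared year effect in [0, 1] (common_forcing) or the
        target negative pairwise correlation in [-1, 0) (compensatory).
    sigma_shared
        Sd of the shared year effect u; defaults to sigma_log.
    n_points
        VPI points per plot; 2500 matches a 10 m x 10 m plot sampled at
        25 points / m^2.
    """

    n_sites: int = 15
    years: tuple[int, ...] = tuple(range(2013, 2022))
    taxa: Mapping[str, float] = field(default_factory=dict)
    dynamics_mode: str = "independent"
    sigma_log: float = 0.25
    rho_shared: float = 0.0
    sigma_shared: float | None = None
    decline: DeclineConfig | None = None
    n_points: int = 2500
    seed: int | None = None
    taxon_meta: Mapping[str, Mapping] | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_points < 1 or len(self.years) < 1:
            raise DataValidationError("n_sites, n_points and years must be positive")
        if not self.taxa:
            raise DataValidationError("scenario needs at least one taxon")
        if any(b <= 0 for b in self.taxa.values()):
            raise DataValidationError("baseline covers must be positive")
        if sum(self.taxa.values()) > 100:
            raise DataValidationError("baseline covers must sum to <= 100")
        if self.sigma_log < 0:
            raise DataValidationError("sigma_log must be >= 0")
        if self.dynamics_mode not in ("independent", "common_forcing", "compensatory"):
            raise DataValidationError(f"unknown dynamics_mode {self.dynamics_mode!r}")
        k = len(self.taxa)
        if self.dynamics_mode == "compensatory":
            if not (-1.0 <= self.rho_shared < 0.0):
                raise DataValidationError(
                    "compensatory mode needs rho_shared in [-1, 0)"
                )
            bound = -1.0 / (k - 1) if k > 1 else 0.0
            if self.rho_shared < bound - 1e-12:
                raise DataValidationError(
                    f"rho_shared={self.rho_shared} infeasible for {k} taxa: "
                    f"a constant pairwise correlation must be >= {bound:.4f}"
                )
        elif self.dynamics_mode == "common_forcing":
            if not (0.0 <= self.rho_shared <= 1.0):
                raise DataValidationError(
                    "common_forcing mode needs rho_shared in [0, 1]"
                )

    @property
    def sigma_u(self) -> float:
        return self.sigma_log if self.sigma_shared is None else self.sigma_shared

    def to_dict(self) -> dict:
        d = {
            "n_sites": self.n_sites,
            "years": list(self.years),
            "taxa": dict(self.taxa),
            "dynamics_mode": self.dynamics_mode,
            "sigma_log": self.sigma_log,
            "rho_shared": self.rho_shared,
            "sigma_shared": self.sigma_shared,
            "n_points": self.n_points,
            "seed": self.seed,
        }
        if self.decline is not None:
            d["decline"] = {
                "start_year": self.decline.start_year,
                "survival": (
                    dict(self.decline.survival)
                    if isinstance(self.decline.survival, Mapping)
                    else self.decline.survival
                ),
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CommunityScenario":
        d = dict(d)
        if "years" in d:
            d["years"] = tuple(int(y) for y in d["years"])
        if d.get("decline") is not None:
            dec = d["decline"]
            d["decline"] = DeclineConfig(
                start_year=int(dec["start_year"]), survival=dec["survival"]
            )
        return cls(**d)


def simulate_true_cover(
    scenario: CommunityScenario, rng: np.random.Generator | None = None
) -> AbundanceTimeSeries:
    """Noise-free (pre-observation) cover under the scenario's dynamics.

    If per-(site, year) covers exceed 100 after the lognormal fluctuation
    they are proportionally renormalised to 100 (logged when triggered).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    taxa = list(scenario.taxa)
    baselines = np.array([scenario.taxa[t] for t in taxa], dtype=float)
    S, T, K = scenario.n_sites, len(scenario.years), len(taxa)

    if scenario.dynamics_mode == "independent":
        eta = rng.normal(0.0, 1.0, (S, T, K)) * scenario.sigma_log
    elif scenario.dynamics_mode == "common_forcing":
        u = rng.normal(0.0, 1.0, (S, T)) * scenario.sigma_u
        eps = rng.normal(0.0, 1.0, (S, T, K)) * scenario.sigma_log
        eta = scenario.rho_shared * u[:, :, None] + eps
    else:  # compensatory: equicorrelated mean-zero deviations, rho < 0
        rho = scenario.rho_shared
        z = rng.normal(0.0, 1.0, (S, T, K))
        zbar = z.mean(axis=2, keepdims=True)
        alpha = scenario.sigma_log * np.sqrt(1.0 - rho)
        beta = scenario.sigma_log * np.sqrt(max(0.0, 1.0 + (K - 1) * rho))
        eta = alpha * (z - zbar) + beta * zbar

    cover = baselines[None, None, :] * np.exp(eta)

    if scenario.decline is not None:
        fac = np.array(
            [
                [scenario.decline.factor(t, y) for t in taxa]
                for y in scenario.years
            ]
        )  # (T, K)
        cover = cover * fac[None, :, :]

    totals = cover.sum(axis=2)
    over = totals > 100.0
    if over.any():
        logger.info(
            "renormalising %d site-years whose covers exceeded 100%%", over.sum()
        )
        scale = np.where(over, 100.0 / totals, 1.0)
        cover = cover * scale[:, :, None]

    sites = [f"S{i + 1:02d}" for i in range(S)]
    return AbundanceTimeSeries(
        sites=sites,
        years=list(scenario.years),
        taxa=taxa,
        cover=cover,
        taxon_meta=dict(scenario.taxon_meta) if scenario.taxon_meta else None,
    )


def vpi_sample(
    true_series: AbundanceTimeSeries,
    n_points: int = 2500,
    rng: np.random.Generator | int | None = None,
) -> AbundanceTimeSeries:
    """Virtual-point-intercept observation of a true-cover series.

    Each (site, year) classifies ``n_points`` points into the taxa plus the
    implicit non-coral remainder with probabilities cover / 100; observed
    cover is 100 x count / n_points. Stratified-random point placement is
    approximated as exchangeable multinomial sampling (spatial
    autocorrelation is out of scope); counts plus remainder always sum to
    ``n_points`` exactly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    S, T, K = true_series.shape
    p = true_series.cover.reshape(S * T, K) / 100.0
    remainder = np.clip(1.0 - p.sum(axis=1, keepdims=True), 0.0, 1.0)
    probs = np.hstack([p, remainder])
    probs = probs / probs.sum(axis=1, keepdims=True)
    counts = rng.multinomial(n_points, probs)  # (S*T, K+1)
    observed = counts[:, :K].reshape(S, T, K) * 100.0 / n_points
    return AbundanceTimeSeries(
        sites=list(true_series.sites),
        years=list(true_series.years),
        taxa=list(true_series.taxa),
        cover=observed,
        taxon_meta=true_series.taxon_meta,
    )


def make_fixture(
    scenario: CommunityScenario, rng: np.random.Generator | None = None
) -> AbundanceTimeSeries:
    """Simulate true cover, then observe it by VPI: a pipeline-ready series."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    true = simulate_true_cover(scenario, rng)
    return vpi_sample(true, scenario.n_points, rng)


# --------------------------------------------------------------- presets

#: Baseline percent covers loosely shaped like a Pacific fore-reef coral
#: assemblage: one dominant massive taxon, a mid-abundance branching taxon,
#: a tail of minor groups, and an "other corals" remainder. Phase-1 total
#: ~30%.
DEFAULT_TAXA: dict[str, float] = {
    "porites_massive": 9.0,
    "pocillopora_spp": 5.0,
    "montipora_encrusting": 3.5,
    "pavona_submassive": 2.5,
    "fungia_spp": 2.0,
    "acropora_branching": 1.5,
    "pavona_massive": 1.5,
    "hydnophora": 1.2,
    "pavona_encrusting": 1.0,
    "goniastrea": 0.8,
    "turbinaria": 0.7,
    "acropora_table": 0.6,
    "other_corals": 4.0,
}

DEFAULT_TAXON_META: dict[str, dict] = {
    "porites_massive": {"life_history": "stress_tolerant", "species_level": True},
    "pocillopora_spp": {"life_history": "competitive", "species_level": False},
    "montipora_encrusting": {"life_history": "weedy", "species_level": False},
    "pavona_submassive": {"life_history": "stress_tolerant", "species_level": True},
    "fungia_spp": {"life_history": "generalist", "species_level": False},
    "acropora_branching": {"life_history": "competitive", "species_level": False},
    "pavona_massive": {"life_history": "stress_tolerant", "species_level": True},
    "hydnophora": {"life_history": "stress_tolerant", "species_level": True},
    "pavona_encrusting": {"life_history": "weedy", "species_level": True},
    "goniastrea": {"life_history": "stress_tolerant", "species_level": True},
    "turbinaria": {"life_history": "stress_tolerant", "species_level": True},
    "acropora_table": {"life_history": "competitive", "species_level": False},
    "other_corals": {"life_history": "mixed", "species_level": False},
}


def scenario_preset(name: str, seed: int | None = None) -> CommunityScenario:
    """Named scenario presets.

    * ``independent``   — random, uncoupled population fluctuations.
    * ``common-forcing``— a strong shared year effect (synchrony).
    * ``compensatory``  — two taxa with perfectly opposed fluctuations.
    * ``reef-decline``  — the default survey-like design: 15 sites,
      2013-2021, 12 focal taxa + other corals, independent fluctuations and
      a cumulative 0.72/yr survival decline from 2018 that roughly halves
      cover within two years, mimicking a predator outbreak.
    """
    key = name.replace("_", "-").lower()
    if key == "independent":
        return CommunityScenario(
            taxa=dict(DEFAULT_TAXA), taxon_meta=DEFAULT_TAXON_META, seed=seed
        )
    if key == "common-forcing":
        return CommunityScenario(
            taxa=dict(DEFAULT_TAXA),
            taxon_meta=DEFAULT_TAXON_META,
            dynamics_mode="common_forcing",
            rho_shared=1.0,
            sigma_shared=0.3,
            sigma_log=0.1,
            seed=seed,
        )
    if key == "compensatory":
        return CommunityScenario(
            taxa={"taxon_a": 15.0, "taxon_b": 15.0},
            dynamics_mode="compensatory",
            rho_shared=-1.0,
            sigma_log=0.3,
            seed=seed,
        )
    if key == "reef-decline":
        return CommunityScenario(
            taxa=dict(DEFAULT_TAXA),
            taxon_meta=DEFAULT_TAXON_META,
            decline=DeclineConfig(start_year=2018, survival=0.72),
            seed=seed,
        )
    raise DataValidationError(f"unknown scenario preset {name!r}")
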