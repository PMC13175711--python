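"""End-to-end analysis orchestration.

``run_analysis`` composes the full pipeline: ingest (or simulate) ->
focal-group selection -> phase split -> per-site and island-mean synchrony
with permutation nulls -> bootstrapped RM-ANOVA on total cover -> pairwise
covariances and cross-site sign-consistency tests -> tabular reports.
Everything is a pure function of (input, config, seed); running the same
config twice writes byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import (
    DEFAULT_PHASES,
    ISLAND_MEAN_SITE,
    AbundanceTimeSeries,
    PhaseConfig,
    island_mean_series,
    read_abundance_table,
    select_focal_groups,
    split_phases,
)
from .errors import DataValidationError
from .resampling import (
    SynchronyResult,
    bootstrap_rm_anova,
    covariance_sign_consistency,
    posthoc_year_differences,
    synchrony_with_null,
)
from .simulate import CommunityScenario, make_fixture, scenario_preset
from .synchrony import SiteYearMatrix, coefficient_of_variation, pairwise_covariances

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "phases": [
        {"name": "phase1", "first_year": 2013, "last_year": 2017},
        {"name": "phase2", "first_year": 2018, "last_year": 2021},
    ],
    "focal": {"mean_cover_threshold": 0.5, "min_sites": 4},
    "resampling": {
        "n_reps": 10_000,
        "level": 0.95,
        "alpha": 0.05,
        "anova_shuffle": "within_site",
        "holm": False,
    },
    "seed": 0,
}


@dataclass
class AnalysisReport:
    """All tabular outputs of one pipeline run.

    ``synchrony_table`` has one row per site x phase plus one island-mean
    row per phase, flagged by ``is_island_mean``.
    """

    synchrony_table: pd.DataFrame
    cv_table: pd.DataFrame
    pair_table: pd.DataFrame
    pair_consistency: pd.DataFrame
    anova_table: pd.DataFrame
    posthoc_table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    _FILES = {
        "synchrony_table": "synchrony_table.csv",
        "cv_table": "cv_table.csv",
        "pair_table": "pair_table.csv",
        "pair_consistency": "pair_consistency.csv",
        "anova_table": "anova_table.csv",
        "posthoc_table": "posthoc_table.csv",
    }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for attr, fname in self._FILES.items():
            getattr(self, attr).to_csv(out / fname, index=False)
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True, default=str) + "\n"
        )
        (out / "summary.txt").write_text(self.summary())

    def summary(self) -> str:
        lines = ["reefsync analysis summary", "=" * 25, ""]
        lines.append("Synchrony index by site and phase:")
        lines.append(self.synchrony_table.to_string(index=False))
        lines.append("")
        lines.append("Year effect on total cover (bootstrapped RM-ANOVA):")
        lines.append(self.anova_table.to_string(index=False))
        lines.append("")
        n_sig = int(self.pair_consistency["significant"].sum())
        lines.append(
            f"Taxon pairs with cross-site consistent covariance sign: "
            f"{n_sig} of {len(self.pair_consistency)} pair x phase tests"
        )
        return "\n".join(lines) + "\n"


def _merge_config(user: Mapping[str, Any]) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, Mapping):
        raise DataValidationError("config must be a mapping")
    return _merge_config(user)


def _load_input(cfg: Mapping[str, Any], rng: np.random.Generator) -> AbundanceTimeSeries:
    inp = cfg.get("input") or {}
    if "csv" in inp:
        return read_abundance_table(
            inp["csv"], percent_scale=inp.get("percent_scale", True)
        )
    if "scenario" in inp:
        spec = inp["scenario"]
        if isinstance(spec, str):
            scenario = scenario_preset(spec)
        else:
            spec = dict(spec)
            preset = spec.pop("preset", None)
            if preset is not None:
                base = scenario_preset(preset).to_dict()
                base.pop("seed", None)
                base.update(spec)
                spec = base
            scenario = CommunityScenario.from_dict(spec)
        return make_fixture(scenario, rng)
    raise DataValidationError("config must provide input.csv or input.scenario")


def run_analysis(
    config: Mapping[str, Any] | str | Path, out_dir: str | Path | None = None
) -> AnalysisReport:
    """Run the full synchrony analysis described by ``config``.

    ``config`` is a mapping (or path to a YAML file) with keys ``input``
    (``csv`` path or ``scenario``), ``phases``, ``focal``, ``resampling``
    and ``seed``. Deterministic under a fixed seed. When ``out_dir`` is
    given all report CSVs, a provenance JSON and a text summary are written.
    """
    cfg = (
        load_config(config)
        if isinstance(config, (str, Path))
        else _merge_config(config)
    )
    seed = int(cfg.get("seed", 0))
    n_reps = int(cfg["resampling"]["n_reps"])
    level = float(cfg["resampling"]["level"])
    alpha = float(cfg["resampling"]["alpha"])
    holm = bool(cfg["resampling"]["holm"])
    shuffle = str(cfg["resampling"]["anova_shuffle"])
    phases = PhaseConfig.from_dict(cfg["phases"])

    root_ss = np.random.SeedSequence(seed)
    input_rng = np.random.default_rng(root_ss.spawn(1)[0])
    series = _load_input(cfg, input_rng)
    logger.info("loaded series: %d sites x %d years x %d taxa", *series.shape)

    focal = select_focal_groups(
        series,
        mean_cover_threshold=float(cfg["focal"]["mean_cover_threshold"]),
        min_sites=int(cfg["focal"]["min_sites"]),
    )
    logger.info("focal groups (%d): %s", len(focal), ", ".join(focal))
    focal_series = series.subset_taxa(focal) if focal else series

    by_phase = split_phases(focal_series, phases)
    totals_by_phase = split_phases(series, phases)  # totals use all taxa

    # one child seed stream per deterministic stage key
    stage_rng = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["synchrony", "anova", "posthoc"], root_ss.spawn(3)
        )
    }

    sync_rows: list[dict] = []
    cv_rows: list[dict] = []
    pair_rows: list[dict] = []
    consistency_rows: list[dict] = []
    anova_rows: list[dict] = []
    posthoc_rows: list[dict] = []

    for phase_name, phase_series in by_phase.items():
        pairs_by_site: dict[str, list] = {}
        island = island_mean_series(phase_series)
        targets = [
            (site, SiteYearMatrix.from_series(phase_series, site), False)
            for site in phase_series.sites
        ] + [(ISLAND_MEAN_SITE, SiteYearMatrix.from_series(island, ISLAND_MEAN_SITE), True)]

        for site, matrix, is_island in targets:
            res = synchrony_with_null(
                matrix,
                site=site,
                phase=phase_name,
                n_reps=n_reps,
                seed=stage_rng["synchrony"],
                level=level,
                is_island_mean=is_island,
            )
            sync_rows.append(
                {
                    "site": res.site,
                    "phase": res.phase,
                    "is_island_mean": res.is_island_mean,
                    "observed_si": res.observed_si,
                    "null_quantile_low": res.null_quantile_low,
                    "null_quantile_high": res.null_quantile_high,
                    "n_reps": res.n_reps,
                    "classification": res.classification,
                }
            )
            if not is_island:
                pairs = pairwise_covariances(matrix)
                pairs_by_site[site] = pairs
                for rec in pairs:
                    pair_rows.append(
                        {
                            "site": site,
                            "phase": phase_name,
                            "taxon_i": rec.taxon_i,
                            "taxon_j": rec.taxon_j,
                            "covariance": rec.covariance,
                            "pearson_r": rec.pearson_r,
                            "sign": rec.sign,
                        }
                    )

            for k, taxon in enumerate(matrix.taxa):
                x = matrix.values[:, k]
                if x.mean() <= 0:
                    cv_rows.append(
                        {"site": site, "phase": phase_name, "taxon": taxon,
                         "cv": np.nan, "inverse_cv": np.nan, "zero_variance": False}
                    )
                    continue
                r = coefficient_of_variation(x)
                cv_rows.append(
                    {"site": site, "phase": phase_name, "taxon": taxon,
                     "cv": r.cv, "inverse_cv": r.inverse_cv,
                     "zero_variance": r.zero_variance}
                )
            if not is_island:
                tot = matrix.values.sum(axis=1)
                if tot.mean() > 0:
                    r = coefficient_of_variation(tot)
                    cv_rows.append(
                        {"site": site, "phase": phase_name, "taxon": "total_coral",
                         "cv": r.cv, "inverse_cv": r.inverse_cv,
                         "zero_variance": r.zero_variance}
                    )

        for rec in covariance_sign_consistency(
            pairs_by_site, phase=phase_name, alpha=alpha, holm=holm
        ):
            consistency_rows.append(
                {
                    "taxon_i": rec.taxon_i,
                    "taxon_j": rec.taxon_j,
                    "phase": rec.phase,
                    "n_sites_present": rec.n_sites_present,
                    "n_positive": rec.n_positive,
                    "n_negative": rec.n_negative,
                    "prop_positive": rec.n_positive / rec.n_sites_present,
                    "prop_negative": rec.n_negative / rec.n_sites_present,
                    "p_binomial": rec.p_binomial,
                    "significant": rec.significant,
                }
            )

        # ANOVA on total coral cover (all taxa, not just focal)
        tot_series = totals_by_phase[phase_name]
        totals = tot_series.cover.sum(axis=2)  # (sites, years)
        if totals.shape[0] < 2:
            logger.warning(
                "phase %s has %d site(s); RM-ANOVA needs >= 2, skipping",
                phase_name, totals.shape[0],
            )
            continue
        anova = bootstrap_rm_anova(
            totals, n_reps=n_reps, seed=stage_rng["anova"], shuffle=shuffle
        )
        anova_rows.append(
            {
                "phase": phase_name,
                "f_observed": anova.f_observed,
                "df_between": anova.df_between,
                "df_error": anova.df_error,
                "p_boot": anova.p_boot,
                "n_reps": anova.n_reps,
            }
        )
        for (ya, yb), (diff, p) in posthoc_year_differences(
            totals, tot_series.years, n_reps=n_reps, seed=stage_rng["posthoc"]
        ).items():
            posthoc_rows.append(
                {"phase": phase_name, "year_a": ya, "year_b": yb,
                 "mean_difference": diff, "p_boot": p}
            )

    report = AnalysisReport(
        synchrony_table=pd.DataFrame(sync_rows),
        cv_table=pd.DataFrame(cv_rows),
        pair_table=pd.DataFrame(pair_rows),
        pair_consistency=pd.DataFrame(consistency_rows),
        anova_table=pd.DataFrame(anova_rows),
        posthoc_table=pd.DataFrame(posthoc_rows),
        provenance={
            "config": cfg,
            "seed": seed,
            "focal_groups": focal,
            "n_sites": len(series.sites),
            "years": series.years,
            "reefsync_version": __version__,
        },
    )
    if out_dir is not None:
        report.write(out_dir)
        logger.info("report written to %s", out_dir)
    return report
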