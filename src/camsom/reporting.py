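"""Record-count summaries, effect tables, and the end-to-end pipeline driver.

The effect tables mirror how community camera-trap studies present covariate
effects: one row per species plus one community-level ("All.sp") row per
coefficient, colour-coded by whether the 95% credible interval excludes zero,
with a weaker "marginal" flag at a configurable level, species ordered by
body mass.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .derived import site_summaries
from .histories import augment_history, build_history
from .lmm import LMMConfig, effect_support, fit_lmm, prepare_lmm_data
from .msom import MCMCConfig, ModelSpec, PosteriorDraws, fit_msom
from .synthetic import SimulationScenario, simulate_dataset

__all__ = [
    "count_summary",
    "coefficient_summaries",
    "build_effect_table",
    "PipelineConfig",
    "run_pipeline",
]

ALL_SPECIES_LABEL = "All.sp"


def count_summary(records: pd.DataFrame, stations: pd.DataFrame) -> dict:
    """Stratified focal-record counts and the percent difference between strata.

    Returns counts for the no-dogs and dogs strata, their total, and the
    percent increase of the no-dogs count over the dogs count, truncated to
    an integer percent (100 * (a - b) / b). With an empty dogs stratum the
    percentage is undefined and flagged instead of raising.
    """
    strat = records.merge(
        stations[["station_id", "dogs_allowed"]], on="station_id", how="left"
    )
    if strat["dogs_allowed"].isna().any():
        bad = strat.loc[strat["dogs_allowed"].isna(), "station_id"].unique()
        raise ValueError(f"records at unknown stations: {list(bad)[:5]}")
    n_dogs = int((strat["dogs_allowed"] == 1).sum())
    n_no_dogs = int((strat["dogs_allowed"] == 0).sum())
    out = {
        "records_no_dogs": n_no_dogs,
        "records_dogs": n_dogs,
        "records_total": n_no_dogs + n_dogs,
        "percent_increase_no_dogs": None,
        "undefined_percent": False,
    }
    if n_dogs == 0:
        out["undefined_percent"] = True
    else:
        out["percent_increase_no_dogs"] = int(100 * (n_no_dogs - n_dogs) / n_dogs)
    return out


def coefficient_summaries(
    draws: PosteriorDraws, marginal_level: float = 0.90
) -> pd.DataFrame:
    """Per-species and community-level interval summaries of the covariate
    coefficients, in the shape :func:`build_effect_table` consumes."""
    a95 = 0.025
    am = (1.0 - marginal_level) / 2.0
    rows = []

    def add(species, coefficient, flat):
        rows.append(
            {
                "species": species,
                "coefficient": coefficient,
                "mean": flat.mean(),
                "lo95": np.quantile(flat, a95),
                "hi95": np.quantile(flat, 1 - a95),
                "lo_marginal": np.quantile(flat, am),
                "hi_marginal": np.quantile(flat, 1 - am),
            }
        )

    for k, name in enumerate(draws.coef_names):
        add(ALL_SPECIES_LABEL, name, draws.hyper[f"mu_{name}"].reshape(-1))
        for s, code in enumerate(draws.species):
            if draws.augmented[s]:
                continue
            add(code, name, draws.coef[:, :, s, k].reshape(-1))
    return pd.DataFrame(rows)


def build_effect_table(
    posterior_summaries: pd.DataFrame,
    traits: pd.DataFrame,
    marginal_level: float = 0.90,
) -> pd.DataFrame:
    """Attach effect direction, marginal flags and body-mass ordering.

    ``direction`` is positive/negative when the 95% interval excludes zero,
    otherwise none; ``marginal`` flags rows whose 95% interval includes zero
    but whose ``marginal_level`` interval does not. The community row comes
    first, then species by descending mass; species missing from the trait
    table sort last and are flagged.
    """
    df = posterior_summaries.copy()
    df["direction"] = "none"
    df.loc[df["lo95"] > 0, "direction"] = "positive"
    df.loc[df["hi95"] < 0, "direction"] = "negative"
    df["marginal"] = (
        (df["direction"] == "none")
        & ((df["lo_marginal"] > 0) | (df["hi_marginal"] < 0))
    )
    df["marginal_level"] = marginal_level

    mass = dict(zip(traits["code"], traits["mass_kg"]))
    df["mass_kg"] = df["species"].map(mass)
    df["missing_mass"] = df["mass_kg"].isna() & (df["species"] != ALL_SPECIES_LABEL)
    df["_rank"] = np.where(
        df["species"] == ALL_SPECIES_LABEL,
        np.inf,
        df["mass_kg"].fillna(-np.inf),
    )
    df = (
        df.sort_values(["coefficient", "_rank"], ascending=[True, False], kind="stable")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return df


@dataclass
class PipelineConfig:
    """Settings for a full synthetic-data pipeline run."""

    scenario: SimulationScenario = field(default_factory=SimulationScenario)
    n_aug: int = 10
    z_max: int = 50
    msom_mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    lmm_config: LMMConfig = field(default_factory=LMMConfig)
    draws_per_site: int = 100
    marginal_level: float = 0.90
    partial_policy: str = "keep"
    rhat_bound: float = 1.1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "scenario" in raw:
            sc = dict(raw["scenario"])
            if "hyperparams" in sc:
                from .synthetic import CommunityHyperparams

                hp = dict(sc["hyperparams"])
                for key in ("mu_beta", "sigma_beta"):
                    if key in hp:
                        hp[key] = tuple(hp[key])
                sc["hyperparams"] = CommunityHyperparams(**hp)
            if "distance_range_km" in sc:
                sc["distance_range_km"] = tuple(sc["distance_range_km"])
            kw["scenario"] = SimulationScenario(**sc)
        if "msom_mcmc" in raw:
            kw["msom_mcmc"] = MCMCConfig(**raw["msom_mcmc"])
        if "lmm_config" in raw:
            kw["lmm_config"] = LMMConfig(**raw["lmm_config"])
        for key in ("n_aug", "z_max", "draws_per_site", "marginal_level",
                    "partial_policy", "rhat_bound"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Simulate, rebuild histories from records, fit both model variants,
    derive site summaries, fit the three mixed models, and write all tables
    plus a JSON run manifest.

    Returns the manifest dict. Any monitored community-hyperparameter Rhat
    above ``config.rhat_bound`` marks the run non-converged in the manifest
    (the artifacts are still written).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.scenario.seed,
        "stages": {},
        "converged": True,
        "max_rhat": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done():
            manifest["stages"][name] = round(time.perf_counter() - t0, 3)

        return done

    done = stage("simulate")
    ds = simulate_dataset(config.scenario)
    ds.records.to_csv(outdir / "records.csv", index=False)
    ds.stations.to_csv(outdir / "stations.csv", index=False)
    ds.traits.to_csv(outdir / "species_traits.csv", index=False)
    done()

    done = stage("build_history")
    calendar = config.scenario.calendar()
    history = build_history(
        ds.records,
        ds.stations,
        ds.traits,
        calendar,
        partial_policy=config.partial_policy,
        survey_start=config.scenario.start_date,
    )
    history.to_frame().to_csv(outdir / "detection_history_Y.csv")
    history_aug = augment_history(history, config.n_aug)
    done()

    fits = {}
    for variant in ("abundance", "detection"):
        done = stage(f"fit_{variant}")
        spec = ModelSpec(variant=variant, n_aug=config.n_aug, z_max=config.z_max)
        draws = fit_msom(history_aug, ds.stations, spec, config.msom_mcmc)
        fits[variant] = draws
        summ = draws.summary()
        summ.to_csv(outdir / f"msom_{variant}_summary.csv")
        draws.to_flat_frame().to_csv(outdir / f"msom_{variant}_draws.csv", index=False)
        draws.save(outdir / f"msom_{variant}_draws.npz")
        rhats = draws.hyper_rhat()
        manifest["max_rhat"][f"msom_{variant}"] = max(rhats.values())
        if max(rhats.values()) > config.rhat_bound:
            manifest["converged"] = False
        table = build_effect_table(
            coefficient_summaries(draws, config.marginal_level),
            ds.traits,
            config.marginal_level,
        )
        table.to_csv(outdir / f"effects_{variant}.csv", index=False)
        done()

    done = stage("derive")
    summaries = site_summaries(fits["abundance"], ds.traits)
    summaries.to_csv(outdir / "site_summaries.csv", index=False)
    done()

    for response in ("richness", "abundance", "biomass"):
        done = stage(f"lmm_{response}")
        data = prepare_lmm_data(
            summaries,
            ds.stations,
            response,
            draws_per_site=config.draws_per_site,
            seed=config.scenario.seed + 1,
        )
        post = fit_lmm(data, config.lmm_config)
        post.summary().to_csv(outdir / f"lmm_{response}.csv")
        manifest["max_rhat"][f"lmm_{response}"] = post.max_rhat()
        if post.max_rhat() > config.rhat_bound:
            manifest["converged"] = False
        done()

    done = stage("counts")
    manifest["counts"] = count_summary(ds.records, ds.stations)
    done()

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
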