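"""Synthetic camera-trap communities with the generative structure the
multispecies Royle-Nichols model assumes.

The generator emulates the study design this package targets: 20 stations
split over two river-bank strata (hunting with dogs allowed vs not), station
distances to the human community drawn on a fixed range, a 49-day continuous
deployment binned into 5-day occasions, and a community of species whose
abundance coefficients and per-individual detection are drawn from shared
normal hyperdistributions. Because every dataset is simulated from known
parameters, inference can be validated by parameter recovery.

Links are log for expected abundance lambda and logit for per-individual
detection r, so species coefficients live on an unbounded scale and are
exchangeable draws from the community distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .histories import (
    DetectionHistory,
    OccasionCalendar,
    build_occasions,
    load_focal_species,
    scale_distances,
)

__all__ = [
    "CommunityHyperparams",
    "SimulationScenario",
    "SimulatedDataset",
    "COEF_NAMES",
    "simulate_stations",
    "draw_species_params",
    "simulate_abundance",
    "simulate_histories",
    "simulate_records",
    "simulate_dataset",
]

#: Covariate order used everywhere: intercept, standardized distance,
#: hunting-with-dogs stratum dummy, and their product.
COEF_NAMES = ("intercept", "distance", "dogs", "dist_x_dogs")


@dataclass(frozen=True)
class CommunityHyperparams:
    """Community-level means and SDs of species parameters.

    ``mu_beta``/``sigma_beta`` govern the four abundance coefficients
    (log link, ordered as :data:`COEF_NAMES`); ``mu_detect``/``sigma_detect``
    govern the species baseline per-individual detection on the logit scale;
    ``omega`` is the inclusion probability of an augmented species.

    Defaults describe a moderately detectable Amazonian community in which
    habitat use rises away from the settlement and is depressed on the bank
    where hunting with dogs is practised.
    """

    mu_beta: tuple = (0.0, 0.5, -0.6, 0.0)
    sigma_beta: tuple = (0.8, 0.4, 0.4, 0.25)
    mu_detect: float = -1.5
    sigma_detect: float = 0.6
    omega: float = 0.75

    def __post_init__(self):
        mu = np.asarray(self.mu_beta, dtype=float)
        sd = np.asarray(self.sigma_beta, dtype=float)
        if mu.shape != (4,) or sd.shape != (4,):
            raise ValueError("mu_beta and sigma_beta must have 4 entries")
        if np.any(sd < 0) or self.sigma_detect < 0:
            raise ValueError("community SDs must be non-negative")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")
        object.__setattr__(self, "mu_beta", tuple(mu))
        object.__setattr__(self, "sigma_beta", tuple(sd))


@dataclass(frozen=True)
class SimulationScenario:
    """Survey layout and community settings for one simulated dataset."""

    n_stations_per_stratum: int = 10
    distance_range_km: tuple = (0.54, 5.1)
    n_species: int = 29
    n_days: int = 49
    occasion_length_days: int = 5
    seed: int = 0
    hyperparams: CommunityHyperparams = field(default_factory=CommunityHyperparams)
    start_date: str = "2018-06-01"

    def __post_init__(self):
        if self.n_stations_per_stratum < 1:
            raise ValueError("need at least one station per stratum")
        lo, hi = self.distance_range_km
        if not 0 < lo < hi:
            raise ValueError("distance range must satisfy 0 < min < max")
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if self.n_days < self.occasion_length_days or self.occasion_length_days < 1:
            raise ValueError("need n_days >= occasion_length_days >= 1")

    def calendar(self) -> OccasionCalendar:
        return build_occasions(0, self.n_days, self.occasion_length_days)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_stations(scenario: SimulationScenario, rng=None) -> pd.DataFrame:
    """Lay out 2 x n_stations_per_stratum stations.

    Distances are uniform on the scenario range; exactly half the stations
    sit on the dogs-allowed bank. Returns a station table with raw and
    standardized distances.
    """
    rng = _rng(scenario.seed if rng is None else rng)
    lo, hi = scenario.distance_range_km
    n = 2 * scenario.n_stations_per_stratum
    dist = rng.uniform(lo, hi, size=n)
    dogs = np.repeat([0, 1], scenario.n_stations_per_stratum)
    df = pd.DataFrame(
        {
            "station_id": [f"CT{k + 1:02d}" for k in range(n)],
            "dogs_allowed": dogs,
            "distance_km": dist,
        }
    )
    df["distance_scaled"] = scale_distances(df["distance_km"].to_numpy())
    return df


def draw_species_params(
    hyperparams: CommunityHyperparams, n_species: int, seed_or_rng=0
) -> pd.DataFrame:
    """Draw species-level parameters from the community hyperdistributions.

    Each species' abundance coefficient vector is Normal(mu_beta, sigma_beta)
    componentwise and its baseline detection is Normal(mu_detect,
    sigma_detect) on the logit scale. Zero SDs collapse the community to
    identical species.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = _rng(seed_or_rng)
    mu = np.asarray(hyperparams.mu_beta)
    sd = np.asarray(hyperparams.sigma_beta)
    beta = rng.normal(mu, sd, size=(n_species, 4))
    logit_r = rng.normal(hyperparams.mu_detect, hyperparams.sigma_detect, size=n_species)
    df = pd.DataFrame(beta, columns=[f"beta_{c}" for c in COEF_NAMES])
    df.insert(0, "species", [f"Sp{k + 1:02d}" for k in range(n_species)])
    df["logit_r"] = logit_r
    df["r"] = expit(logit_r)
    return df


def _design(stations: pd.DataFrame) -> np.ndarray:
    d = stations["distance_scaled"].to_numpy(dtype=float)
    g = stations["dogs_allowed"].to_numpy(dtype=float)
    return np.column_stack([np.ones_like(d), d, g, d * g])


def simulate_abundance(
    species_params: pd.DataFrame, stations: pd.DataFrame, seed_or_rng=0
) -> np.ndarray:
    """Draw the latent abundance matrix Z ~ Poisson(lambda).

    log lambda_ij = beta0_i + beta1_i * dist_j + beta2_i * dogs_j
    + beta3_i * dist_j * dogs_j.
    """
    rng = _rng(seed_or_rng)
    beta = species_params[[f"beta_{c}" for c in COEF_NAMES]].to_numpy(dtype=float)
    lam = np.exp(beta @ _design(stations).T)
    return rng.poisson(lam)


def simulate_histories(
    Z: np.ndarray, species_params: pd.DataFrame, V, seed_or_rng=0
) -> DetectionHistory:
    """Draw occasion-detection counts Y ~ Binomial(V, 1 - (1 - r)^Z).

    ``V`` may be a scalar or a per-station vector. Cells with Z = 0 are
    structural zeros: nothing is there to detect.
    """
    rng = _rng(seed_or_rng)
    Z = np.asarray(Z, dtype=int)
    r = species_params["r"].to_numpy(dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("per-individual detection r must lie in [0, 1]")
    V = np.broadcast_to(np.asarray(V, dtype=int), (Z.shape[1],)).copy()
    p = 1.0 - (1.0 - r[:, None]) ** Z
    Y = rng.binomial(V[None, :], p)
    species = list(species_params["species"])
    stations = [f"CT{j + 1:02d}" for j in range(Z.shape[1])]
    return DetectionHistory(Y=Y, V=V, species=species, stations=stations)


def simulate_records(
    Z: np.ndarray,
    species_params: pd.DataFrame,
    stations: pd.DataFrame,
    calendar: OccasionCalendar,
    seed_or_rng=0,
    start_date: str = "2018-06-01",
    max_photos_per_occasion: int = 3,
):
    """Simulate a timestamped record table plus the detection history it encodes.

    For every occasion, species i is detected at station j with probability
    1 - (1 - r_i)^Z_ij; each detected occasion yields 1 to
    ``max_photos_per_occasion`` records at uniform times inside the window.
    Collapsing the records by occasion reproduces the returned Y exactly,
    which is what makes the record builder testable end to end.

    Returns ``(records, history)`` where records has columns ``station_id``,
    ``species_code``, ``datetime``.
    """
    rng = _rng(seed_or_rng)
    Z = np.asarray(Z, dtype=int)
    r = species_params["r"].to_numpy(dtype=float)
    station_ids = list(stations["station_id"])
    S, J = Z.shape
    K = calendar.n_occasions
    p = 1.0 - (1.0 - r[:, None]) ** Z  # (S, J)
    detected = rng.random((S, J, K)) < p[:, :, None]

    origin = pd.Timestamp(start_date)
    rows = []
    codes = list(species_params["species"])
    for i, j, k in zip(*np.nonzero(detected)):
        n_photos = int(rng.integers(1, max_photos_per_occasion + 1))
        lo, hi = calendar.starts[k], calendar.ends[k]
        for t in np.sort(rng.uniform(lo, hi, size=n_photos)):
            rows.append((station_ids[j], codes[i], origin + pd.to_timedelta(t, unit="D")))
    records = pd.DataFrame(rows, columns=["station_id", "species_code", "datetime"])
    if len(records):
        records = records.sort_values("datetime", kind="stable").reset_index(drop=True)
        records["datetime"] = records["datetime"].dt.strftime("%Y-%m-%dT%H:%M:%S")

    Y = detected.sum(axis=2).astype(int)
    history = DetectionHistory(
        Y=Y,
        V=np.full(J, K, dtype=int),
        species=codes,
        stations=station_ids,
        calendar=calendar,
    )
    return records, history


@dataclass
class SimulatedDataset:
    """Bundle of everything one simulation produced, truth included."""

    scenario: SimulationScenario
    stations: pd.DataFrame
    traits: pd.DataFrame
    species_params: pd.DataFrame
    Z: np.ndarray
    records: pd.DataFrame
    history: DetectionHistory


def _traits_for(codes: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Trait rows for simulated species: the bundled focal table where it
    reaches, lognormal masses for any surplus synthetic species."""
    focal = load_focal_species()
    n = len(codes)
    rows = focal.iloc[: min(n, len(focal))][["code", "english_name", "game", "mass_kg"]].copy()
    extra = n - len(rows)
    if extra > 0:
        rows = pd.concat(
            [
                rows,
                pd.DataFrame(
                    {
                        "code": [f"Syn{k + 1:02d}" for k in range(extra)],
                        "english_name": [f"Synthetic species {k + 1}" for k in range(extra)],
                        "game": (np.arange(extra) % 2).astype(int),
                        "mass_kg": np.exp(rng.normal(1.0, 1.0, size=extra)),
                    }
                ),
            ],
            ignore_index=True,
        )
    rows = rows.reset_index(drop=True)
    rows["code"] = codes  # simulated species inherit trait rows positionally
    return rows


def simulate_dataset(scenario: SimulationScenario) -> SimulatedDataset:
    """Run the full generator for one scenario, deterministically in the seed.

    Species codes reuse the bundled focal-species table (masses included) up
    to 29 species; larger communities get extra synthetic trait rows.
    """
    root = np.random.SeedSequence(scenario.seed)
    ss = root.spawn(5)
    stations = simulate_stations(scenario, rng=np.random.default_rng(ss[0]))
    params = draw_species_params(
        scenario.hyperparams, scenario.n_species, np.random.default_rng(ss[1])
    )
    rng_traits = np.random.default_rng(ss[2])
    focal = load_focal_species()
    codes = list(focal["code"][: min(scenario.n_species, len(focal))])
    codes += [f"Syn{k + 1:02d}" for k in range(scenario.n_species - len(codes))]
    params = params.assign(species=codes)
    traits = _traits_for(codes, rng_traits)
    Z = simulate_abundance(params, stations, np.random.default_rng(ss[3]))
    records, history = simulate_records(
        Z,
        params,
        stations,
        scenario.calendar(),
        np.random.default_rng(ss[4]),
        start_date=scenario.start_date,
    )
    return SimulatedDataset(
        scenario=scenario,
        stations=stations,
        traits=traits,
        species_params=params,
        Z=Z,
        records=records,
        history=history,
    )
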