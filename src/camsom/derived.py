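"""Per-draw, per-site community summaries derived from the fitted model.

Richness, aggregated abundance, and aggregated biomass are deterministic
functions of each retained posterior draw of the latent abundances Z and
inclusion indicators w, so their posteriors propagate the full estimation
uncertainty into the downstream mixed-model stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .msom import PosteriorDraws

__all__ = ["site_richness", "site_abundance", "site_biomass", "site_summaries"]


def site_richness(Z_draw, w_draw) -> np.ndarray:
    """Number of included species with at least one individual per site:
    richness_j = #{i : w_i = 1 and Z_ij >= 1}."""
    Z = np.asarray(Z_draw)
    w = np.asarray(w_draw)
    return ((Z >= 1) & (w[:, None] == 1)).sum(axis=0)


def site_abundance(Z_draw, w_draw) -> np.ndarray:
    """Summed latent abundance of included species per site."""
    Z = np.asarray(Z_draw)
    w = np.asarray(w_draw)
    return (w[:, None] * Z).sum(axis=0)


def site_biomass(Z_draw, w_draw, mass_kg, observed=None) -> np.ndarray:
    """Mass-weighted summed abundance per site, in kg.

    Augmented species have no body mass and contribute nothing; pass
    ``observed`` as a boolean mask over species rows (default: rows with a
    finite mass). A missing mass for an observed species is an error.
    """
    Z = np.asarray(Z_draw)
    w = np.asarray(w_draw)
    mass = np.asarray(mass_kg, dtype=float)
    if observed is None:
        observed = np.isfinite(mass)
    observed = np.asarray(observed, dtype=bool)
    if np.any(observed & ~np.isfinite(mass)):
        raise ValueError("observed species with missing body mass")
    m = np.where(observed, mass, 0.0)
    return (w[:, None] * Z * m[:, None]).sum(axis=0)


def site_summaries(draws: PosteriorDraws, traits: pd.DataFrame) -> pd.DataFrame:
    """Long-format table of the three site summaries for every retained draw.

    ``traits`` must supply a mass for every non-augmented species row in
    ``draws`` (matched by code). Output columns: chain, draw, station_id,
    richness, abundance, biomass_kg.
    """
    mass_by_code = dict(zip(traits["code"], traits["mass_kg"]))
    mass = np.array(
        [
            np.nan if aug else mass_by_code.get(code, np.nan)
            for code, aug in zip(draws.species, draws.augmented)
        ]
    )
    missing = [
        code
        for code, aug, m in zip(draws.species, draws.augmented, mass)
        if not aug and not np.isfinite(m)
    ]
    if missing:
        raise ValueError(f"no body mass for observed species: {missing}")

    observed = ~draws.augmented
    C, D, S, J = draws.Z.shape
    w = draws.w  # (C, D, S)
    Z = draws.Z
    present = (Z >= 1) & (w[..., None] == 1)
    rich = present.sum(axis=2)  # (C, D, J)
    abund = (w[..., None] * Z).sum(axis=2)
    m = np.where(observed, mass, 0.0)
    biom = (w[..., None] * Z * m[None, None, :, None]).sum(axis=2)

    chain_idx = np.repeat(np.arange(C), D * J)
    draw_idx = np.tile(np.repeat(np.arange(D), J), C)
    station_idx = np.tile(np.arange(J), C * D)
    return pd.DataFrame(
        {
            "chain": chain_idx,
            "draw": draw_idx,
            "station_id": np.asarray(draws.stations)[station_idx],
            "richness": rich.reshape(-1),
            "abundance": abund.reshape(-1),
            "biomass_kg": biom.reshape(-1),
        }
    )
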