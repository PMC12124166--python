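"""Bayesian Gaussian linear mixed models via a conjugate Gibbs sampler.

The downstream stage of the pipeline regresses a derived site summary
(richness, abundance or biomass, one row per retained posterior draw per
station) on standardized distance and the hunting stratum, with a station
random intercept absorbing the repeated draws per site:

    y_i = x_i' beta + u_{station(i)} + eps_i,
    u_j ~ Normal(0, tau^2),  eps_i ~ Normal(0, sigma^2).

Priors: improper flat on the fixed effects, inverse-gamma(0.001, 0.001) on
both variance components. All full conditionals are conjugate (normal for
beta and u, inverse gamma for the variances), so the sampler is a plain
Gibbs cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostics import gelman_rubin

__all__ = [
    "LMMData",
    "LMMConfig",
    "LMMPosterior",
    "prepare_lmm_data",
    "fit_lmm",
    "effect_support",
]

_IG_SHAPE = 0.001
_IG_RATE = 0.001


@dataclass(frozen=True)
class LMMData:
    """Response vector, fixed-effect design and station grouping."""

    y: np.ndarray
    X: np.ndarray
    groups: np.ndarray  # integer station codes, 0..J-1
    station_ids: list[str]
    effect_names: tuple = ("intercept", "distance", "dogs")

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        X = np.asarray(self.X, dtype=float)
        g = np.asarray(self.groups, dtype=int)
        if y.ndim != 1 or X.shape[0] != y.size or g.shape != y.shape:
            raise ValueError("y, X and groups must align row-wise")
        if y.size < 2:
            raise ValueError("need at least 2 response rows")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")
        if len(np.unique(g)) < 2:
            raise ValueError("need at least 2 stations for a station random effect")
        if np.var(y) == 0:
            raise ValueError("response has zero variance; nothing to model")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "groups", g)


@dataclass(frozen=True)
class LMMConfig:
    n_chains: int = 3
    n_iter: int = 4000
    burn_in: int = 2000
    thin: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1 or (self.n_iter - self.burn_in) // self.thin < 1:
            raise ValueError("no draws would be retained")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def prepare_lmm_data(
    summaries: pd.DataFrame,
    stations: pd.DataFrame,
    response: str,
    draws_per_site: int = 100,
    seed: int = 0,
) -> LMMData:
    """Assemble mixed-model data from the derived-summary table.

    Subsamples (without replacement where possible) ``draws_per_site``
    posterior draws per station, so the response carries the estimation
    uncertainty of the upstream model while staying a manageable size.
    """
    if response not in ("richness", "abundance", "biomass"):
        raise ValueError("response must be richness, abundance or biomass")
    col = "biomass_kg" if response == "biomass" else response
    rng = np.random.default_rng(seed)
    station_ids = list(stations["station_id"])
    idx = {s: j for j, s in enumerate(station_ids)}
    cov = stations.set_index("station_id")

    rows = []
    for sid, grp in summaries.groupby("station_id", sort=False):
        take = min(draws_per_site, len(grp))
        sel = grp.iloc[rng.choice(len(grp), size=take, replace=False)]
        for val in sel[col]:
            rows.append((idx[sid], val))
    g = np.array([r[0] for r in rows], dtype=int)
    y = np.array([r[1] for r in rows], dtype=float)
    d = cov["distance_scaled"].to_numpy(dtype=float)[g]
    dogs = cov["dogs_allowed"].to_numpy(dtype=float)[g]
    X = np.column_stack([np.ones_like(d), d, dogs])
    return LMMData(y=y, X=X, groups=g, station_ids=station_ids)


def _run_lmm_chain(data: LMMData, cfg: LMMConfig, seed):
    # (beta, u) are drawn as ONE joint Gaussian block given the variances:
    # with station-level covariates in X the fixed effects are identified
    # only through the shrinkage of u, and one-at-a-time updates of beta and
    # u random-walk along that ridge instead of crossing it.
    rng = np.random.default_rng(seed)
    y, X, g = data.y, data.X, data.groups
    n, P = X.shape
    J = g.max() + 1
    counts = np.bincount(g, minlength=J).astype(float)

    XtX = X.T @ X
    Xty = X.T @ y
    XtZ = np.zeros((P, J))
    for k in range(P):
        XtZ[k] = np.bincount(g, weights=X[:, k], minlength=J)
    ysum_g = np.bincount(g, weights=y, minlength=J)

    beta = np.linalg.solve(XtX, Xty) + rng.normal(0, 0.5, size=P)
    u = rng.normal(0, 0.5, size=J)
    sigma2 = np.var(y - X @ beta) + 1e-6
    tau2 = max(np.var(u), 1e-6)

    M = np.empty((P + J, P + J))
    b = np.empty(P + J)
    nd = cfg.n_draws
    out = {
        "beta": np.empty((nd, P)),
        "u": np.empty((nd, J)),
        "sigma_e": np.empty(nd),
        "sigma_u": np.empty(nd),
    }
    d_idx = 0
    for t in range(1, cfg.n_iter + 1):
        # (beta, u) | variances ~ N(M^{-1} b, M^{-1}) with block precision
        M[:P, :P] = XtX / sigma2
        M[:P, P:] = XtZ / sigma2
        M[P:, :P] = XtZ.T / sigma2
        M[P:, P:] = np.diag(counts / sigma2 + 1.0 / tau2)
        b[:P] = Xty / sigma2
        b[P:] = ysum_g / sigma2
        L = np.linalg.cholesky(M)
        mean = np.linalg.solve(M, b)
        theta = mean + np.linalg.solve(L.T, rng.normal(size=P + J))
        beta, u = theta[:P], theta[P:]
        # variances | rest
        resid = y - X @ beta - u[g]
        sigma2 = 1.0 / rng.gamma(_IG_SHAPE + n / 2.0, 1.0 / (_IG_RATE + 0.5 * resid @ resid))
        tau2 = 1.0 / rng.gamma(_IG_SHAPE + J / 2.0, 1.0 / (_IG_RATE + 0.5 * u @ u))
        if t > cfg.burn_in and (t - cfg.burn_in) % cfg.thin == 0:
            out["beta"][d_idx] = beta
            out["u"][d_idx] = u
            out["sigma_e"][d_idx] = np.sqrt(sigma2)
            out["sigma_u"][d_idx] = np.sqrt(tau2)
            d_idx += 1
    return out


@dataclass
class LMMPosterior:
    """Posterior draws and summaries for one mixed-model fit."""

    effect_names: tuple
    station_ids: list[str]
    beta: np.ndarray  # (C, D, P)
    u: np.ndarray  # (C, D, J)
    sigma_e: np.ndarray  # (C, D)
    sigma_u: np.ndarray  # (C, D)

    def summary(self) -> pd.DataFrame:
        """Fixed-effect table: mean, 95% credible interval, Rhat, support."""
        rows = []
        for k, name in enumerate(self.effect_names):
            arr = self.beta[:, :, k]
            support, lo, hi = effect_support(arr.reshape(-1))
            rows.append(
                {
                    "effect": name,
                    "mean": arr.mean(),
                    "sd": arr.std(ddof=1),
                    "lo95": lo,
                    "hi95": hi,
                    "rhat": gelman_rubin(arr),
                    "support": support,
                }
            )
        return pd.DataFrame(rows).set_index("effect")

    def max_rhat(self) -> float:
        vals = [gelman_rubin(self.beta[:, :, k]) for k in range(self.beta.shape[2])]
        vals += [gelman_rubin(self.sigma_e), gelman_rubin(self.sigma_u)]
        return max(vals)


def fit_lmm(data: LMMData, config: LMMConfig = None) -> LMMPosterior:
    """Fit the random-intercept model by Gibbs sampling, one chain per
    substream of ``config.seed``, with overdispersed starts."""
    config = config or LMMConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [_run_lmm_chain(data, config, s) for s in seeds]
    return LMMPosterior(
        effect_names=data.effect_names,
        station_ids=data.station_ids,
        beta=np.stack([c["beta"] for c in chains]),
        u=np.stack([c["u"] for c in chains]),
        sigma_e=np.stack([c["sigma_e"] for c in chains]),
        sigma_u=np.stack([c["sigma_u"] for c in chains]),
    )


def effect_support(coefficient_draws, level: float = 0.95):
    """Classify an effect by whether its central credible interval excludes 0.

    Returns ``(support, lo, hi)`` with support in {"positive", "negative",
    "none"} based on the ``level`` central interval of the pooled draws.
    """
    draws = np.asarray(coefficient_draws, dtype=float).reshape(-1)
    if draws.size < 100:
        raise ValueError("need at least 100 draws for a stable interval")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    if lo > 0:
        return "positive", float(lo), float(hi)
    if hi < 0:
        return "negative", float(lo), float(hi)
    return "none", float(lo), float(hi)
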