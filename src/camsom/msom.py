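"""Hierarchical multispecies Royle-Nichols model fit by Metropolis-within-Gibbs.

The observation model ties per-occasion detection to latent local abundance:
an individual of species i is detected at station j with probability r_ij per
occasion, so with Z_ij individuals present the occasion-level detection
probability is

    p_ij = 1 - (1 - r_ij)^Z_ij,

Y_ij ~ Binomial(V_j, p_ij) counts detected occasions, and Z_ij ~ Poisson(lambda_ij)
is the number of individuals available for detection (habitat-use intensity,
not density). Species parameters are exchangeable draws from community-level
normal hyperdistributions, and all-zero augmented rows with Bernoulli(omega)
inclusion indicators let posterior richness exceed the observed species count.

Two variants mirror a small-sample parameterization strategy: the
``abundance`` variant (Model 1) puts the intercept/distance/stratum/interaction
covariates on log lambda with species-constant r; the ``detection`` variant
(Model 2) puts them on logit r with species-constant lambda.

The sampler is purpose-built: latent Z by exact enumeration over a truncated
support, inclusion indicators and omega by their conjugate full conditionals,
community means by conjugate normal updates, and species coefficients and
community SDs by adaptive random-walk Metropolis (adaptation during burn-in
only, so detailed balance holds for retained draws).

Priors (vague on the link scale, proper): hypermeans Normal(0, 10),
hyper-SDs Uniform(0, 5), omega Uniform(0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import binom as binom_dist
from scipy.stats import poisson as poisson_dist

from .diagnostics import gelman_rubin
from .histories import DetectionHistory, augment_history
from .synthetic import COEF_NAMES

__all__ = [
    "ModelSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "detection_prob",
    "cell_loglik",
    "marginal_cell_loglik",
    "latent_abundance_pmf",
    "fit_msom",
]

_HYPERMEAN_PRIOR_SD = 10.0
_HYPERSD_PRIOR_UPPER = 5.0


# ---------------------------------------------------------------------------
# elementary model quantities


def detection_prob(r, Z):
    """Occasion-level detection probability p = 1 - (1 - r)^Z.

    Non-decreasing in both arguments; exactly 0 iff Z = 0 or r = 0, and 1
    when r = 1 and Z >= 1.
    """
    r = np.asarray(r, dtype=float)
    Z = np.asarray(Z)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("r must lie in [0, 1]")
    if np.any(Z < 0) or np.any(Z != np.floor(Z)):
        raise ValueError("Z must be a non-negative integer")
    return 1.0 - (1.0 - r) ** np.asarray(Z, dtype=float)


def cell_loglik(Y, V, r, Z):
    """log Binomial(Y | V, p) with p induced by abundance Z.

    Impossible configurations (e.g. Y > 0 with Z = 0) return -inf rather
    than raising; r outside [0, 1] or Y outside [0, V] is a domain error.
    """
    Y = np.asarray(Y)
    V = np.asarray(V)
    if np.any((Y < 0) | (Y > V)):
        raise ValueError("need 0 <= Y <= V")
    p = detection_prob(r, Z)
    return binom_dist.logpmf(Y, V, p)


def marginal_cell_loglik(Y, V, r, lam, z_max=50):
    """log P(Y | V, r, lambda) with the latent abundance summed out.

    Computes log sum_{Z=0}^{z_max} Poisson(Z | lambda) Binomial(Y | V, p(Z))
    in log space. Warns when the truncated Poisson tail beyond ``z_max``
    exceeds 1e-8, since the sum is then visibly short.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if z_max < 1:
        raise ValueError("z_max must be >= 1")
    tail = poisson_dist.sf(z_max, lam)
    if tail > 1e-8:
        warnings.warn(
            f"Poisson tail mass beyond z_max={z_max} is {tail:.2e}; increase z_max",
            stacklevel=2,
        )
    z = np.arange(z_max + 1)
    terms = poisson_dist.logpmf(z, lam) + cell_loglik(Y, V, r, z)
    return float(logsumexp(terms))


def latent_abundance_pmf(Y, V, r, lam, z_max):
    """Normalized full-conditional pmf of Z on {0..z_max}.

    P(Z = z | Y) proportional to Poisson(z | lambda) Binomial(Y | V, p(z));
    this is the exact enumeration the Gibbs update for Z samples from.
    """
    z = np.arange(z_max + 1)
    logw = poisson_dist.logpmf(z, lam) + cell_loglik(Y, V, r, z)
    logw -= logsumexp(logw)
    return np.exp(logw)


# ---------------------------------------------------------------------------
# model and sampler configuration


@dataclass(frozen=True)
class ModelSpec:
    """Which side of the model carries the station covariates.

    ``variant="abundance"`` models log lambda_ij on intercept, standardized
    distance, stratum and their interaction with species-constant r;
    ``variant="detection"`` models logit r_ij the same way with
    species-constant lambda. ``n_aug`` all-zero rows are appended for
    undetected species; ``z_max`` truncates the latent-abundance support
    (raised automatically during burn-in if draws pile up at the bound).
    """

    variant: str = "abundance"
    n_aug: int = 10
    z_max: int = 50
    adapt_z_max: bool = True
    z_max_cap: int = 400

    def __post_init__(self):
        if self.variant not in ("abundance", "detection"):
            raise ValueError("variant must be 'abundance' or 'detection'")
        if self.n_aug < 0:
            raise ValueError("n_aug must be >= 0")
        if not 1 <= self.z_max <= self.z_max_cap:
            raise ValueError("need 1 <= z_max <= z_max_cap")


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 3
    n_iter: int = 100_000
    burn_in: int = 50_000
    thin: int = 100
    seed: int = 0
    target_accept: float = 0.35
    init_scale: float = 0.3

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.n_iter - self.burn_in) // self.thin < 1:
            raise ValueError("no draws would be retained")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws, grouped by chain.

    ``hyper`` maps each community-level parameter name to a
    ``(n_chains, n_draws)`` array; ``coef`` holds species coefficients for
    the covariate-carrying side, ``const`` the species-constant parameter of
    the other side (both on link scale), ``w`` the inclusion indicators and
    ``Z`` the latent abundances.
    """

    variant: str
    species: list[str]
    stations: list[str]
    augmented: np.ndarray
    coef_names: tuple
    hyper: dict
    coef: np.ndarray  # (C, D, S, 4)
    const: np.ndarray  # (C, D, S)
    w: np.ndarray  # (C, D, S)
    Z: np.ndarray  # (C, D, S, J)
    const_name: str = "detect"

    def hyper_rhat(self) -> dict:
        return {k: gelman_rubin(v) for k, v in self.hyper.items()}

    def max_hyper_rhat(self) -> float:
        return max(self.hyper_rhat().values())

    def _species_param_arrays(self) -> dict:
        out = {}
        for k, name in enumerate(self.coef_names):
            for s, code in enumerate(self.species):
                out[f"beta_{name}[{code}]"] = self.coef[:, :, s, k]
        for s, code in enumerate(self.species):
            out[f"{self.const_name}[{code}]"] = self.const[:, :, s]
        return out

    def summary(self, include_species: bool = True) -> pd.DataFrame:
        """Posterior mean, SD, central quantiles and Rhat per parameter."""
        params = dict(self.hyper)
        if include_species:
            params.update(self._species_param_arrays())
        rows = []
        for name, arr in params.items():
            flat = arr.reshape(-1)
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "q2.5": np.quantile(flat, 0.025),
                    "q50": np.quantile(flat, 0.5),
                    "q97.5": np.quantile(flat, 0.975),
                    "rhat": gelman_rubin(arr),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def save(self, path) -> None:
        """Serialize every draw (including latent Z and w) to a compressed
        npz so derived summaries can be recomputed without refitting."""
        hyper_arrays = {f"hyper_{k}": v for k, v in self.hyper.items()}
        np.savez_compressed(
            path,
            variant=np.array(self.variant),
            const_name=np.array(self.const_name),
            species=np.array(self.species),
            stations=np.array(self.stations),
            augmented=self.augmented,
            coef_names=np.array(self.coef_names),
            coef=self.coef,
            const=self.const,
            w=self.w,
            Z=self.Z,
            **hyper_arrays,
        )

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        with np.load(path, allow_pickle=False) as z:
            hyper = {
                k[len("hyper_"):]: z[k] for k in z.files if k.startswith("hyper_")
            }
            return cls(
                variant=str(z["variant"]),
                species=[str(s) for s in z["species"]],
                stations=[str(s) for s in z["stations"]],
                augmented=z["augmented"],
                coef_names=tuple(str(c) for c in z["coef_names"]),
                hyper=hyper,
                coef=z["coef"],
                const=z["const"],
                w=z["w"],
                Z=z["Z"],
                const_name=str(z["const_name"]),
            )

    def to_flat_frame(self) -> pd.DataFrame:
        """Long format (chain, draw, parameter, value) for hyperparameters
        and species-level parameters."""
        params = dict(self.hyper)
        params.update(self._species_param_arrays())
        frames = []
        C, D = self.w.shape[:2]
        chain_idx = np.repeat(np.arange(C), D)
        draw_idx = np.tile(np.arange(D), C)
        for name, arr in params.items():
            frames.append(
                pd.DataFrame(
                    {
                        "chain": chain_idx,
                        "draw": draw_idx,
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# the sampler


class _ChainState:
    __slots__ = ("coef", "const", "mu_coef", "sigma_coef", "mu_const",
                 "sigma_const", "w", "omega", "Z")


def _binom_ll_given_z(Y, V, Z, log1mr, logp):
    """Binomial log-likelihood per cell given latent Z; cells with Z = 0
    contribute 0 (their Y is necessarily 0)."""
    out = np.where(Y > 0, Y * logp, 0.0) + (V - Y) * Z * log1mr
    return np.where(Z > 0, out, 0.0)


# -inf and 0*inf arise by construction in impossible branches that np.where
# discards; state finiteness is checked explicitly at the end of each sweep.
@np.errstate(divide="ignore", invalid="ignore")
def _run_chain(Y, V, X, spec, cfg, seed):
    rng = np.random.default_rng(seed)
    S, J = Y.shape
    K = X.shape[1]
    abundance_model = spec.variant == "abundance"
    ever_detected = Y.sum(axis=1) > 0

    st = _ChainState()
    st.mu_coef = rng.normal(0, cfg.init_scale, size=K)
    st.sigma_coef = np.exp(rng.normal(0, 0.3, size=K)) * 0.8
    st.mu_const = rng.normal(-1.0 if abundance_model else 0.0, cfg.init_scale)
    st.sigma_const = np.exp(rng.normal(0, 0.3)) * 0.8
    st.coef = st.mu_coef + rng.normal(0, 0.2, size=(S, K))
    st.const = st.mu_const + rng.normal(0, 0.2, size=S)
    st.w = np.ones(S, dtype=np.int8)
    st.omega = rng.uniform(0.3, 0.9)
    st.Z = np.where(Y > 0, np.maximum(Y, 1), 0).astype(np.int64)

    scales = {
        "coef": np.full(K, 0.2),
        "const": 0.2,
        "sigma_coef": np.full(K, 0.3),
        "sigma_const": 0.3,
    }

    z_max = spec.z_max
    zgrid = np.arange(z_max + 1, dtype=float)
    lgam = gammaln(zgrid + 1.0)

    n_draws = cfg.n_draws
    draws = {
        "coef": np.empty((n_draws, S, K)),
        "const": np.empty((n_draws, S)),
        "mu_coef": np.empty((n_draws, K)),
        "sigma_coef": np.empty((n_draws, K)),
        "mu_const": np.empty(n_draws),
        "sigma_const": np.empty(n_draws),
        "w": np.empty((n_draws, S), dtype=np.int8),
        "omega": np.empty(n_draws),
        "Z": np.empty((n_draws, S, J), dtype=np.int16),
    }

    Vf = V[None, :].astype(float)
    Yf = Y.astype(float)
    top_hits_post = 0
    top_hits_burn = 0
    cell_draws_burn = 0

    def linpred():
        # (S, J) linear predictor on the covariate side
        return st.coef @ X.T

    d_idx = 0
    for t in range(1, cfg.n_iter + 1):
        adapting = t <= cfg.burn_in

        # --- latent abundance Z | rest, by exact enumeration over 0..z_max
        if abundance_model:
            log_lam = linpred()  # (S, J)
            r = expit(st.const)[:, None]  # (S, 1)
        else:
            log_lam = st.const[:, None] * np.ones((1, J))
            r = expit(linpred())  # (S, J)
        lam = np.exp(log_lam)
        log1mr = np.log1p(-np.clip(r, 0.0, 1.0 - 1e-15))
        # logits over the z grid: z*log lam - lgamma(z+1) + Y log p(z) + (V-Y) z log(1-r)
        A = zgrid[:, None, None] * log1mr[None, :, :]  # (G, S, J) = log(1-p)
        logp = np.log(-np.expm1(A))
        logits = (
            zgrid[:, None, None] * log_lam[None, :, :]
            - lgam[:, None, None]
            + np.where(Yf[None, :, :] > 0, Yf[None, :, :] * logp, 0.0)
            + (Vf - Yf)[None, :, :] * A
        )
        logits -= logits.max(axis=0, keepdims=True)
        pz = np.exp(logits)
        cz = np.cumsum(pz, axis=0)
        u = rng.random((S, J)) * cz[-1]
        Znew = (cz < u[None, :, :]).sum(axis=0)
        Znew[st.w == 0, :] = 0
        st.Z = Znew
        if adapting:
            # grow the truncated support only when the running estimate of
            # posterior mass in the top bin exceeds ~1e-6 per cell-draw
            top_hits_burn += int((Znew == z_max).sum())
            cell_draws_burn += S * J
            if (
                spec.adapt_z_max
                and z_max < spec.z_max_cap
                and top_hits_burn >= 3
                and top_hits_burn > 1e-6 * cell_draws_burn
            ):
                z_max = min(int(z_max * 1.5) + 5, spec.z_max_cap)
                zgrid = np.arange(z_max + 1, dtype=float)
                lgam = gammaln(zgrid + 1.0)
                top_hits_burn = 0
                cell_draws_burn = 0
        elif Znew.max() >= z_max:
            top_hits_post += 1

        Zf = st.Z.astype(float)
        wmask = st.w.astype(float)[:, None]

        # --- species coefficients (covariate side), per-coordinate RW Metropolis
        def cov_side_ll(eta):
            if abundance_model:
                lam_ = np.exp(eta)
                return (wmask * (Zf * eta - lam_)).sum(axis=1)
            r_ = expit(eta)
            l1mr = np.log1p(-np.clip(r_, 0.0, 1.0 - 1e-15))
            lp = np.log(-np.expm1(Zf * l1mr))
            return (wmask * _binom_ll_given_z(Yf, Vf, Zf, l1mr, lp)).sum(axis=1)

        eta = linpred()
        ll_cur = cov_side_ll(eta)
        for k in range(K):
            step = rng.normal(0, scales["coef"][k], size=S)
            eta_prop = eta + step[:, None] * X[:, k][None, :]
            ll_prop = cov_side_ll(eta_prop)
            lp_cur = -0.5 * ((st.coef[:, k] - st.mu_coef[k]) / st.sigma_coef[k]) ** 2
            lp_prop = -0.5 * ((st.coef[:, k] + step - st.mu_coef[k]) / st.sigma_coef[k]) ** 2
            log_acc = ll_prop - ll_cur + lp_prop - lp_cur
            accept = np.log(rng.random(S)) < log_acc
            # inactive species carry no likelihood: refresh from the community
            flat = st.w == 0
            st.coef[accept, k] += step[accept]
            st.coef[flat, k] = rng.normal(st.mu_coef[k], st.sigma_coef[k], size=int(flat.sum()))
            eta = st.coef @ X.T
            ll_cur = cov_side_ll(eta)
            if adapting:
                gamma = min(0.1, t**-0.6)
                frac = accept[~flat].mean() if (~flat).any() else cfg.target_accept
                scales["coef"][k] *= np.exp(gamma * (frac - cfg.target_accept))

        # --- species-constant side, RW Metropolis
        if abundance_model:
            def const_ll(c):
                r_ = expit(c)[:, None]
                l1mr = np.log1p(-np.clip(r_, 0.0, 1.0 - 1e-15))
                lp = np.log(-np.expm1(Zf * l1mr))
                return (wmask * _binom_ll_given_z(Yf, Vf, Zf, l1mr, lp)).sum(axis=1)
            flat_const = (st.w == 0) | (st.Z.sum(axis=1) == 0)
        else:
            def const_ll(c):
                lam_ = np.exp(c)[:, None]
                return (wmask * (Zf * c[:, None] - lam_)).sum(axis=1)
            flat_const = st.w == 0

        step = rng.normal(0, scales["const"], size=S)
        ll_cur = const_ll(st.const)
        ll_prop = const_ll(st.const + step)
        lp_cur = -0.5 * ((st.const - st.mu_const) / st.sigma_const) ** 2
        lp_prop = -0.5 * ((st.const + step - st.mu_const) / st.sigma_const) ** 2
        accept = np.log(rng.random(S)) < ll_prop - ll_cur + lp_prop - lp_cur
        st.const[accept] += step[accept]
        st.const[flat_const] = rng.normal(
            st.mu_const, st.sigma_const, size=int(flat_const.sum())
        )
        if adapting:
            gamma = min(0.1, t**-0.6)
            frac = accept[~flat_const].mean() if (~flat_const).any() else cfg.target_accept
            scales["const"] *= np.exp(gamma * (frac - cfg.target_accept))

        # --- community hypermeans: conjugate normal updates
        prior_prec = 1.0 / _HYPERMEAN_PRIOR_SD**2
        for k in range(K):
            prec = S / st.sigma_coef[k] ** 2 + prior_prec
            mean = st.coef[:, k].sum() / st.sigma_coef[k] ** 2 / prec
            st.mu_coef[k] = rng.normal(mean, 1.0 / np.sqrt(prec))
        prec = S / st.sigma_const**2 + prior_prec
        mean = st.const.sum() / st.sigma_const**2 / prec
        st.mu_const = rng.normal(mean, 1.0 / np.sqrt(prec))

        # --- community SDs, two complementary moves per sweep:
        # (1) centered exact draw: with Uniform(0, 5) prior on sigma the full
        #     conditional of sigma^2 given the species values is
        #     inverse-gamma((S-1)/2, sum(dev^2)/2) truncated at 25;
        # (2) an interweaved non-centered rescaling (sufficiency/ancillarity
        #     interweaving): holding the standardized residuals eta fixed,
        #     propose sigma on the log scale and move all species values with
        #     it, accepting on the data likelihood. The pair breaks the
        #     funnel-shaped coupling that makes centered-only updates mix
        #     slowly when a community SD is small.
        def draw_sigma_centered(values, mu, current):
            a = 0.5 * np.sum((values - mu) ** 2)
            if a <= 0 or len(values) < 2:  # sigma unidentified from one species
                return current
            for _ in range(50):
                s2 = a / rng.gamma((len(values) - 1) / 2.0)
                if s2 < _HYPERSD_PRIOR_UPPER**2:
                    return np.sqrt(s2)
            return current

        for k in range(K):
            st.sigma_coef[k] = draw_sigma_centered(
                st.coef[:, k], st.mu_coef[k], st.sigma_coef[k]
            )
        st.sigma_const = draw_sigma_centered(st.const, st.mu_const, st.sigma_const)

        ll_cur_tot = cov_side_ll(st.coef @ X.T).sum()
        for k in range(K):
            prop = st.sigma_coef[k] * np.exp(rng.normal(0, scales["sigma_coef"][k]))
            accepted = False
            if prop < _HYPERSD_PRIOR_UPPER:
                eta_sp = (st.coef[:, k] - st.mu_coef[k]) / st.sigma_coef[k]
                coef_prop = st.coef.copy()
                coef_prop[:, k] = st.mu_coef[k] + prop * eta_sp
                ll_prop_tot = cov_side_ll(coef_prop @ X.T).sum()
                log_acc = (ll_prop_tot - ll_cur_tot
                           + np.log(prop) - np.log(st.sigma_coef[k]))
                if np.log(rng.random()) < log_acc:
                    accepted = True
                    st.coef = coef_prop
                    st.sigma_coef[k] = prop
                    ll_cur_tot = ll_prop_tot
            if adapting:
                gamma = min(0.1, t**-0.6)
                scales["sigma_coef"][k] *= np.exp(
                    gamma * (float(accepted) - cfg.target_accept)
                )

        prop = st.sigma_const * np.exp(rng.normal(0, scales["sigma_const"]))
        accepted = False
        if prop < _HYPERSD_PRIOR_UPPER:
            eta_sp = (st.const - st.mu_const) / st.sigma_const
            const_prop = st.mu_const + prop * eta_sp
            ll_c = const_ll(st.const).sum()
            ll_p = const_ll(const_prop).sum()
            log_acc = ll_p - ll_c + np.log(prop) - np.log(st.sigma_const)
            if np.log(rng.random()) < log_acc:
                accepted = True
                st.const = const_prop
                st.sigma_const = prop
        if adapting:
            gamma = min(0.1, t**-0.6)
            scales["sigma_const"] *= np.exp(
                gamma * (float(accepted) - cfg.target_accept)
            )

        # --- inclusion indicators and omega
        if abundance_model:
            lam_rows = np.exp(st.coef @ X.T).sum(axis=1)
        else:
            lam_rows = np.exp(st.const) * J
        zero_Z = st.Z.sum(axis=1) == 0
        can_flip = zero_Z & ~ever_detected
        log_odds = np.log(st.omega) - np.log1p(-st.omega) - lam_rows
        p1 = expit(log_odds)
        st.w = np.ones(S, dtype=np.int8)
        st.w[can_flip] = (rng.random(int(can_flip.sum())) < p1[can_flip]).astype(np.int8)
        st.w[~zero_Z] = 1
        st.omega = rng.beta(1 + st.w.sum(), 1 + S - st.w.sum())

        if not (np.isfinite(st.mu_coef).all() and np.isfinite(st.const).all()):
            raise FloatingPointError(
                f"non-finite sampler state at iteration {t}: mu_coef={st.mu_coef}"
            )

        # --- store
        if t > cfg.burn_in and (t - cfg.burn_in) % cfg.thin == 0:
            draws["coef"][d_idx] = st.coef
            draws["const"][d_idx] = st.const
            draws["mu_coef"][d_idx] = st.mu_coef
            draws["sigma_coef"][d_idx] = st.sigma_coef
            draws["mu_const"][d_idx] = st.mu_const
            draws["sigma_const"][d_idx] = st.sigma_const
            draws["w"][d_idx] = st.w
            draws["omega"][d_idx] = st.omega
            draws["Z"][d_idx] = st.Z
            d_idx += 1

    if top_hits_post > 0:
        warnings.warn(
            f"latent abundance hit the truncation bound z_max={z_max} in "
            f"{top_hits_post} post-burn-in iterations; consider a larger z_max",
            stacklevel=2,
        )
    return draws


def fit_msom(
    history: DetectionHistory,
    stations: pd.DataFrame,
    model_spec: ModelSpec = None,
    mcmc_config: MCMCConfig = None,
) -> PosteriorDraws:
    """Fit the hierarchical community model to a detection history.

    If the history carries no augmented rows yet, ``model_spec.n_aug``
    all-zero rows are appended first. Chains run sequentially with
    independent substreams of ``mcmc_config.seed`` and overdispersed random
    initial states, so Rhat is a meaningful check.
    """
    model_spec = model_spec or ModelSpec()
    mcmc_config = mcmc_config or MCMCConfig()

    if history.augmented.sum() == 0 and model_spec.n_aug > 0:
        history = augment_history(history, model_spec.n_aug)
    elif history.augmented.sum() not in (0, model_spec.n_aug):
        raise ValueError(
            f"history has {int(history.augmented.sum())} augmented rows but "
            f"model_spec.n_aug={model_spec.n_aug}"
        )

    if list(stations["station_id"]) != list(history.stations):
        raise ValueError("station table and history columns must align")

    d = stations["distance_scaled"].to_numpy(dtype=float)
    g = stations["dogs_allowed"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(d), d, g, d * g])

    seeds = np.random.SeedSequence(mcmc_config.seed).spawn(mcmc_config.n_chains)
    per_chain = [
        _run_chain(history.Y, history.V, X, model_spec, mcmc_config, s)
        for s in seeds
    ]

    C = mcmc_config.n_chains
    stack = lambda key: np.stack([pc[key] for pc in per_chain])
    coef = stack("coef")
    const = stack("const")
    const_name = "detect" if model_spec.variant == "abundance" else "abund"
    hyper = {}
    mu_coef = stack("mu_coef")
    sigma_coef = stack("sigma_coef")
    for k, name in enumerate(COEF_NAMES):
        hyper[f"mu_{name}"] = mu_coef[:, :, k]
        hyper[f"sigma_{name}"] = sigma_coef[:, :, k]
    hyper[f"mu_{const_name}"] = stack("mu_const")
    hyper[f"sigma_{const_name}"] = stack("sigma_const")
    hyper["omega"] = stack("omega")

    return PosteriorDraws(
        variant=model_spec.variant,
        species=list(history.species),
        stations=list(history.stations),
        augmented=history.augmented.copy(),
        coef_names=COEF_NAMES,
        hyper=hyper,
        coef=coef,
        const=const,
        w=stack("w"),
        Z=stack("Z"),
        const_name=const_name,
    )
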