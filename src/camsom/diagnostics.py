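"""Convergence diagnostics for multi-chain MCMC output."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["gelman_rubin"]


def gelman_rubin(draws_by_chain) -> float:
    """Potential scale reduction factor (Rhat), Brooks-Gelman corrected form.

    Parameters
    ----------
    draws_by_chain
        Array of shape ``(m_chains, n_draws)`` with m >= 2 and n >= 10.

    Returns
    -------
    float
        ``sqrt((m+1)/m * Vhat/W - (n-1)/(m*n))`` where ``W`` is the mean
        within-chain variance, ``B/n`` the variance of chain means, and
        ``Vhat = (n-1)/n W + B/n``. Values near 1 indicate the chains are
        sampling the same distribution; the conventional bound used here
        downstream is 1.1.

    Chains with zero within-chain variance are flagged with a warning
    rather than propagating NaN: the result is 1.0 if the chains also agree
    in mean (a degenerate but consistent posterior) and +inf otherwise.
    """
    x = np.asarray(draws_by_chain, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (m_chains >= 2, n_draws) array")
    m, n = x.shape
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = x.mean(axis=1).var(ddof=1)
    if W == 0.0:
        warnings.warn("zero within-chain variance; Rhat degenerate", stacklevel=2)
        return 1.0 if B_over_n == 0.0 else np.inf
    vhat = (n - 1) / n * W + B_over_n
    psrf_sq = (m + 1) / m * vhat / W - (n - 1) / (m * n)
    return float(np.sqrt(psrf_sq))
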