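"""Brute-force exact posterior for small GO-activity instances.

Integrates the Beta variables (P, Pi_0, Pi_1) analytically and sums the
joint weight over every binary configuration of the term states G and
gene indicators I.  Feasible only for a handful of terms and gene slots
(2^(K + S) configurations); used as the correctness oracle for the
variational fit, never for real inference.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, logsumexp

from .types import ModelData, PriorSpec

__all__ = ["exact_term_posterior", "exact_log_marginal", "MAX_CONFIGS"]

MAX_CONFIGS = 1 << 18  # 2^(K + S) enumeration bound (~260k configurations)


def _check_bounds(data: ModelData) -> None:
    if data.n_terms > 4:
        raise ValueError(f"enumeration supports at most 4 terms, got {data.n_terms}")
    if 2 ** (data.n_terms + data.n_slots) > MAX_CONFIGS:
        raise ValueError(
            f"instance too large for enumeration: K={data.n_terms}, "
            f"S={data.n_slots} exceeds {MAX_CONFIGS} configurations"
        )


def _config_log_weights(
    data: ModelData, priors: PriorSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Log weight of every (G, I) configuration, Beta variables integrated.

    Returns (g_configs, logw) where g_configs has shape (2^K, K) and
    logw[j] = logsumexp over all I of the joint weight under G config j:

        B(dP1 + n1, dP0 + n0) / B(dP1, dP0)
        * prod_l B(dPi[l,1] + c_l1, dPi[l,0] + c_l0) / B(dPi[l,1], dPi[l,0])
        * prod_s lik[I_s]

    with n_l the number of terms in state l and c_lm the indicator counts
    within each state.  All sums are in log space.
    """
    _check_bounds(data)
    K, S = data.n_terms, data.n_slots
    dP, dPi = priors.delta_P, priors.delta_Pi

    g_configs = (
        (np.arange(1 << K)[:, None] >> np.arange(K)) & 1
    ).astype(bool)
    i_configs = (
        (np.arange(1 << S)[:, None] >> np.arange(S)) & 1
    ).astype(bool) if S else np.zeros((1, 0), dtype=bool)

    loglik_I = i_configs @ data.log_lik[:, 1] + (~i_configs) @ data.log_lik[:, 0]

    logw = np.empty(1 << K)
    for j, g in enumerate(g_configs):
        n1 = int(g.sum())
        logw_P = betaln(dP[1] + n1, dP[0] + (K - n1)) - betaln(dP[1], dP[0])
        slot_active = g[data.slot_term] if S else np.zeros(0, dtype=bool)
        total = np.full(1 << S, logw_P) + loglik_I
        for l in (0, 1):
            mask = slot_active == bool(l)
            c1 = i_configs[:, mask].sum(axis=1)
            c0 = int(mask.sum()) - c1
            total += betaln(dPi[l, 1] + c1, dPi[l, 0] + c0) - betaln(
                dPi[l, 1], dPi[l, 0]
            )
        logw[j] = logsumexp(total)
    return g_configs, logw


def exact_term_posterior(data: ModelData, priors: PriorSpec) -> np.ndarray:
    """Exact marginal P(G_k = 1 | D) per term, by full enumeration."""
    g_configs, logw = _config_log_weights(data, priors)
    log_total = logsumexp(logw)
    post = np.empty(data.n_terms)
    for k in range(data.n_terms):
        post[k] = np.exp(logsumexp(logw[g_configs[:, k]]) - log_total)
    return post


def exact_log_marginal(data: ModelData, priors: PriorSpec) -> float:
    """Exact log marginal likelihood ln p(D); upper-bounds any converged
    negative free energy from the variational fit (Jensen)."""
    _, logw = _config_log_weights(data, priors)
    return float(logsumexp(logw))
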