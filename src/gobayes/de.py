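"""Per-gene posterior probabilities of activity from two-group expression.

A conjugate Bayesian two-model comparison stands in for a first-level
variational ANOVA: per gene, the marginal likelihood of a single common
mean (M0) is compared with that of group-specific means (M1), both
under a Normal-Inverse-Gamma prior with shared variance, and combined
with a prior activity probability into P(I_g = 1 | D_g).  Any external
per-gene posterior file can bypass this module entirely; it exists so
the full pipeline runs end-to-end from a log-expression matrix.

Each gene is grand-mean centred before the marginals are computed, which
makes the posterior exactly invariant to adding a constant to all of a
gene's samples (the location carries no information about differential
expression).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

__all__ = ["de_posterior", "DEFAULT_KAPPA0", "DEFAULT_A0", "DEFAULT_B0"]

#: Prior precision of each mean relative to the data precision.
DEFAULT_KAPPA0 = 0.01
#: Inverse-Gamma shape and rate of the shared noise variance.
DEFAULT_A0 = 0.1
DEFAULT_B0 = 0.1


def _nig_suffstats(y: np.ndarray, kappa0: float) -> tuple[np.ndarray, int]:
    """Posterior rate increment for one block sharing a mean ~ N(0, s2/k0).

    Returns (0.5 * (SS + k0*n*ybar^2/(k0+n)), n) vectorised over rows.
    """
    n = y.shape[1]
    ybar = y.mean(axis=1)
    ss = ((y - ybar[:, None]) ** 2).sum(axis=1)
    return 0.5 * (ss + kappa0 * n * ybar**2 / (kappa0 + n)), n


def de_posterior(
    data,
    groups,
    prior_active: float = 0.5,
    kappa0: float = DEFAULT_KAPPA0,
    a0: float = DEFAULT_A0,
    b0: float = DEFAULT_B0,
):
    """Posterior probability of group-specific means, per gene.

    Parameters
    ----------
    data
        Genes x samples matrix of log expression (DataFrame or array);
        no missing values.
    groups
        Two-level factor of length n_samples, each level with >= 2
        samples.
    prior_active
        Prior probability of differential expression, in (0, 1).

    Returns
    -------
    Per-gene probabilities; a Series indexed like ``data`` when a
    DataFrame is given, else an ndarray.
    """
    if not 0.0 < prior_active < 1.0:
        raise ValueError("prior_active must be in (0, 1)")
    is_frame = isinstance(data, pd.DataFrame)
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D genes x samples matrix")
    if np.isnan(X).any():
        raise ValueError("data contains missing values")
    groups = np.asarray(groups)
    if groups.shape[0] != X.shape[1]:
        raise ValueError("groups length must match the number of samples")
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"exactly two groups required, got {levels.size}")
    masks = [groups == lv for lv in levels]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("each group needs at least 2 samples")

    X = X - X.mean(axis=1, keepdims=True)  # location is uninformative
    n = X.shape[1]
    an = a0 + 0.5 * n
    const = gammaln(an) - gammaln(a0) + a0 * np.log(b0) - 0.5 * n * np.log(2 * np.pi)

    r_all, _ = _nig_suffstats(X, kappa0)
    log_m0 = (
        const
        + 0.5 * np.log(kappa0 / (kappa0 + n))
        - an * np.log(b0 + r_all)
    )

    occam = 0.0
    rate = np.zeros(X.shape[0])
    for m in masks:
        r_j, n_j = _nig_suffstats(X[:, m], kappa0)
        occam += 0.5 * np.log(kappa0 / (kappa0 + n_j))
        rate += r_j
    log_m1 = const + occam - an * np.log(b0 + rate)

    logit_prior = np.log(prior_active) - np.log1p(-prior_active)
    probs = expit(logit_prior + log_m1 - log_m0)
    if is_frame:
        return pd.Series(probs, index=data.index, name="posterior")
    return probs
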