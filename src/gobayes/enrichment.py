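"""Counts-based GO enrichment baseline: threshold, Fisher's exact test, BH.

Genes are dichotomised into active/inactive at a probability threshold
and each term's 2x2 table (in-term vs rest-of-universe, active vs
inactive) is tested exactly.  The universe is the union of all annotated
genes that have a probability; unobserved genes are excluded rather than
imputed.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .annotations import AnnotationTable

__all__ = ["call_active", "fisher_enrichment", "bh_adjust"]


def call_active(gene_probs: Mapping[str, float], threshold: float = 0.5) -> dict[str, bool]:
    """Dichotomise activity probabilities: active iff prob > threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return {g: p > threshold for g, p in gene_probs.items()}


def fisher_enrichment(
    table: AnnotationTable,
    calls: Mapping[str, bool],
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-term Fisher exact test of enrichment with active genes.

    Returns a frame with columns term_id, a (in-term active), b (in-term
    inactive), p — one row per term with at least one called gene.  The
    default one-sided alternative tests over-representation (the exact
    hypergeometric upper tail); 'two-sided' is also available.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    universe = {
        g for genes in table.terms.values() for g in genes if g in calls
    }
    if not universe:
        raise ValueError("no annotated gene has an activity call")
    n_active = sum(calls[g] for g in universe)
    n_universe = len(universe)

    rows = []
    for term in sorted(table.terms):
        genes = [g for g in table.terms[term] if g in calls]
        if not genes:
            continue
        a = sum(calls[g] for g in genes)
        b = len(genes) - a
        c = n_active - a
        d = (n_universe - len(genes)) - c
        _, p = fisher_exact([[a, b], [c, d]], alternative=alternative)
        rows.append((term, a, b, float(p)))
    return pd.DataFrame(rows, columns=["term_id", "a", "b", "p"])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
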