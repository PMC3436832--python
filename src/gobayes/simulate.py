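"""Synthetic benchmarks with known GO-term activity.

Two generators: a deterministic four-term scenario contrasting
probability-aware inference with counts-based testing, and a full
simulated GO study in which hypothetical terms recruit differentially
expressed (DE) genes at state-dependent rates and log expression is
Gaussian around group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import AnnotationTable
from .types import TermAnnotation

__all__ = ["FourTermScenario", "SimulationTruth", "make_four_term_scenario", "simulate_go_study"]

#: Per-term gene activity probabilities of the four-term scenario.
#: A: large majority highly active; B: half highly active, half just not
#: active; C: majority just above 0.5 with two confidently inactive;
#: D: majority confidently inactive.
FOUR_TERM_PROBS: dict[str, list[float]] = {
    "A": [0.90] * 10 + [0.40] * 2,
    "B": [0.90] * 6 + [0.45] * 6,
    "C": [0.55] * 10 + [0.05] * 2,
    "D": [0.60] * 2 + [0.10] * 10,
}


@dataclass(frozen=True)
class FourTermScenario:
    """The deterministic four-term scenario (terms A-D, 12 genes each)."""

    terms: tuple[TermAnnotation, ...]
    gene_probs: dict[str, float]

    @property
    def term_probs(self) -> dict[str, list[float]]:
        return {
            t.term_id: [self.gene_probs[g] for g in sorted(t.gene_ids)]
            for t in self.terms
        }


def make_four_term_scenario() -> FourTermScenario:
    """Build the four-term scenario with distinct genes per term.

    Thresholding the probabilities at 0.5 gives active/inactive counts
    A 10/2, B 6/6, C 10/2, D 2/10 — so A and C are indistinguishable to
    any counts-based test while their probability profiles differ
    sharply.
    """
    terms = []
    gene_probs: dict[str, float] = {}
    for term_id, probs in FOUR_TERM_PROBS.items():
        gene_ids = []
        for i, p in enumerate(probs):
            gid = f"{term_id}:g{i:03d}"
            gene_ids.append(gid)
            gene_probs[gid] = p
        terms.append(TermAnnotation(term_id, gene_ids))
    return FourTermScenario(terms=tuple(terms), gene_probs=gene_probs)


@dataclass
class SimulationTruth:
    """Ground truth and parameters of a simulated GO study."""

    term_ids: list[str]
    term_active: np.ndarray
    gene_ids: list[str]
    gene_de: np.ndarray
    term_genes: dict[str, set[str]]
    params: dict = field(default_factory=dict)
    seed: int = 0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term_id": self.term_ids, "active": self.term_active.astype(int)}
        )


def _n_de(gamma: int, rate: float, rng: np.random.Generator) -> int:
    """DE genes to recruit for a term of size gamma at the given rate.

    Binomial(gamma, rate): each annotated gene is independently DE with
    the state-dependent chance, matching the Bernoulli emission the
    activity model itself assumes.
    """
    return int(rng.binomial(gamma, rate))


def simulate_go_study(
    n_terms: int = 2000,
    genes_per_term: tuple[int, int] = (1, 100),
    p_active: float = 0.2,
    p_de_active: float = 0.8,
    p_de_inactive: float = 0.2,
    n_genes: int = 20000,
    n_per_group: int = 8,
    de_mean: float = 1.0,
    sd: float = 0.6,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, AnnotationTable, SimulationTruth]:
    """Simulate a GO study with known term activity states.

    Each of ``n_terms`` hypothetical terms is annotated with between
    ``genes_per_term[0]`` and ``genes_per_term[1]`` genes and is active
    with probability ``p_active``.  Active terms recruit DE genes at
    rate ``p_de_active``, inactive terms at ``p_de_inactive``.  Because
    terms share one pool of ``n_genes`` genes, a single global DE flag
    is drawn first (pool fraction = the marginal DE rate implied by the
    term-level rates) and each term then samples its quota from the DE
    and null pools — without replacement within a term, with sharing
    across terms — so every recruitment is consistent with one per-gene
    truth.

    Log expression mimics a two-level design with ``n_per_group``
    samples per level: DE genes get group means ``+de_mean``/``-de_mean``
    (orientation random per gene), null genes mean zero, i.i.d. Gaussian
    noise with standard deviation ``sd``.

    Returns (expression matrix genes x samples, group labels,
    annotation table, truth).
    """
    if not 0.0 <= p_active <= 1.0:
        raise ValueError("p_active must be in [0, 1]")
    lo, hi = genes_per_term
    if not 1 <= lo <= hi:
        raise ValueError("genes_per_term must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(seed)

    term_ids = [f"GO:SIM{k:05d}" for k in range(n_terms)]
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    term_active = rng.random(n_terms) < p_active

    pool_frac = p_active * p_de_active + (1.0 - p_active) * p_de_inactive
    n_de_pool = round(pool_frac * n_genes)
    gene_de = np.zeros(n_genes, dtype=bool)
    gene_de[rng.permutation(n_genes)[:n_de_pool]] = True
    de_pool = np.flatnonzero(gene_de)
    null_pool = np.flatnonzero(~gene_de)

    gammas = rng.integers(lo, hi + 1, size=n_terms)
    table = AnnotationTable()
    term_genes: dict[str, set[str]] = {}
    for k, term in enumerate(term_ids):
        gamma = int(gammas[k])
        rate = p_de_active if term_active[k] else p_de_inactive
        n_de = _n_de(gamma, rate, rng)
        n_null = gamma - n_de
        if n_de > de_pool.size or n_null > null_pool.size:
            raise RuntimeError("gene pool exhausted; increase n_genes")
        picks = np.concatenate(
            [
                rng.choice(de_pool, size=n_de, replace=False),
                rng.choice(null_pool, size=n_null, replace=False),
            ]
        )
        genes = {gene_ids[i] for i in picks}
        term_genes[term] = genes
        for g in genes:
            table.add(term, g, "direct")

    n_samples = 2 * n_per_group
    groups = np.array(["a"] * n_per_group + ["b"] * n_per_group)
    means = np.zeros((n_genes, n_samples))
    sign = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    means[gene_de, :n_per_group] = (de_mean * sign[gene_de])[:, None]
    means[gene_de, n_per_group:] = (-de_mean * sign[gene_de])[:, None]
    X = means + rng.normal(0.0, sd, size=(n_genes, n_samples))
    expr = pd.DataFrame(
        X,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"{g}{j}" for g in ("a", "b") for j in range(n_per_group)],
    )

    truth = SimulationTruth(
        term_ids=term_ids,
        term_active=term_active,
        gene_ids=gene_ids,
        gene_de=gene_de,
        term_genes=term_genes,
        params=dict(
            n_terms=n_terms,
            genes_per_term=genes_per_term,
            p_active=p_active,
            p_de_active=p_de_active,
            p_de_inactive=p_de_inactive,
            n_genes=n_genes,
            n_per_group=n_per_group,
            de_mean=de_mean,
            sd=sd,
        ),
        seed=seed,
    )
    return expr, groups, table, truth
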