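"""Shared domain types for GO-term activity inference.

The model views each annotated GO term k as a binary latent state G_k
(1 = active, 0 = dormant) and each gene slot (g, k) as a binary latent
indicator I_gk whose evidence is carried by a pair of marginal
likelihoods.  Beta priors over the global activity rate P and the
emission probabilities Pi_0, Pi_1 complete the hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GeneEvidence",
    "TermAnnotation",
    "PriorSpec",
    "VariationalState",
    "TermPosterior",
    "ModelData",
]


@dataclass(frozen=True)
class GeneEvidence:
    """Per gene-slot evidence: likelihoods proportional to p(D_gk | I_gk).

    Only the ratio lik1/lik0 matters; rescaling both by any c > 0 leaves
    every posterior unchanged.
    """

    gene_id: str
    lik0: float
    lik1: float

    def __post_init__(self) -> None:
        if not (self.lik0 > 0 and np.isfinite(self.lik0)):
            raise ValueError(f"lik0 must be positive and finite, got {self.lik0}")
        if not (self.lik1 > 0 and np.isfinite(self.lik1)):
            raise ValueError(f"lik1 must be positive and finite, got {self.lik1}")


@dataclass(frozen=True)
class TermAnnotation:
    """A GO term together with the set of gene ids annotated to it."""

    term_id: str
    gene_ids: frozenset[str]

    def __init__(self, term_id: str, gene_ids: Iterable[str]) -> None:
        genes = frozenset(gene_ids)
        if not genes:
            raise ValueError(f"term {term_id!r} has no annotated genes")
        object.__setattr__(self, "term_id", term_id)
        object.__setattr__(self, "gene_ids", genes)

    @property
    def gamma(self) -> int:
        """Number of genes annotated to the term."""
        return len(self.gene_ids)


@dataclass(frozen=True)
class PriorSpec:
    """Beta prior counts for the activity rate P and emissions Pi.

    ``delta_P[m]`` is the prior count for G = m; ``delta_Pi[l, m]`` the
    prior count for I = m given G = l.  All-ones counts are the
    uninformative default.  A small identification bonus ``epsilon`` on
    the matched states (delta_Pi[1,1] and delta_Pi[0,0]) breaks the
    label-swap symmetry of the otherwise exchangeable two-component model.
    """

    delta_P: np.ndarray
    delta_Pi: np.ndarray

    def __post_init__(self) -> None:
        dP = np.asarray(self.delta_P, dtype=float)
        dPi = np.asarray(self.delta_Pi, dtype=float)
        if dP.shape != (2,) or dPi.shape != (2, 2):
            raise ValueError("delta_P must have shape (2,), delta_Pi shape (2, 2)")
        if not (np.all(dP > 0) and np.all(dPi > 0)):
            raise ValueError("all prior counts must be strictly positive")
        object.__setattr__(self, "delta_P", dP)
        object.__setattr__(self, "delta_Pi", dPi)

    @classmethod
    def uniform(cls, epsilon: float = 0.0) -> "PriorSpec":
        """All-ones prior counts, optionally with an identification bonus."""
        if epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        dPi = np.ones((2, 2))
        dPi[1, 1] += epsilon
        dPi[0, 0] += epsilon
        return cls(np.ones(2), dPi)


@dataclass
class VariationalState:
    """All factors of the mean-field posterior plus the bound trace.

    ``qP`` and ``qPi`` hold Beta counts in the same [state-0, state-1]
    layout as :class:`PriorSpec`; ``qG[k]`` is Q(G_k = 1) and ``qI[s]``
    is Q(I_s = 1) over flattened gene slots.
    """

    qP: np.ndarray
    qPi: np.ndarray
    qG: np.ndarray
    qI: np.ndarray
    free_energy_trace: list[float] = field(default_factory=list)
    identified: bool = False
    converged: bool = False

    def copy(self) -> "VariationalState":
        return VariationalState(
            qP=self.qP.copy(),
            qPi=self.qPi.copy(),
            qG=self.qG.copy(),
            qI=self.qI.copy(),
            free_energy_trace=list(self.free_energy_trace),
            identified=self.identified,
            converged=self.converged,
        )


@dataclass(frozen=True)
class TermPosterior:
    """Approximate posterior activity of one GO term with its decision."""

    term_id: str
    prob_active: float
    n_genes: int
    decision: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_active <= 1.0:
            raise ValueError("prob_active must lie in [0, 1]")
        if self.decision not in ("active", "inactive"):
            raise ValueError("decision must be 'active' or 'inactive'")


class ModelData:
    """Flattened (term, gene-slot) layout consumed by inference.

    A gene annotated to several terms contributes an independent slot per
    term; indicators are never shared across terms.  Slots within a term
    are ordered by gene id so the layout is reproducible, and all
    posteriors are invariant to that ordering.
    """

    def __init__(
        self,
        term_ids: Sequence[str],
        slot_term: np.ndarray,
        slot_gene: Sequence[str],
        log_lik: np.ndarray,
    ) -> None:
        self.term_ids = list(term_ids)
        self.slot_term = np.asarray(slot_term, dtype=np.intp)
        self.slot_gene = list(slot_gene)
        self.log_lik = np.asarray(log_lik, dtype=float)
        self.n_terms = len(self.term_ids)
        self.n_slots = len(self.slot_gene)
        if self.log_lik.shape != (self.n_slots, 2):
            raise ValueError("log_lik must have shape (n_slots, 2)")
        self.gamma = np.bincount(self.slot_term, minlength=self.n_terms)
        if self.n_terms and self.gamma.min() < 1:
            empty = self.term_ids[int(np.argmin(self.gamma))]
            raise ValueError(f"term {empty!r} has no gene slots")

    @classmethod
    def from_terms(
        cls,
        terms: Sequence[TermAnnotation],
        evidence: Mapping[str, GeneEvidence],
    ) -> "ModelData":
        """Build the slot layout from annotations and per-gene evidence.

        Genes without evidence are dropped from their terms; a term whose
        genes all lack evidence raises.
        """
        term_ids: list[str] = []
        slot_term: list[int] = []
        slot_gene: list[str] = []
        log_lik: list[tuple[float, float]] = []
        for k, term in enumerate(terms):
            observed = sorted(g for g in term.gene_ids if g in evidence)
            if not observed:
                raise ValueError(
                    f"term {term.term_id!r} has no gene with evidence"
                )
            term_ids.append(term.term_id)
            for g in observed:
                ev = evidence[g]
                slot_term.append(k)
                slot_gene.append(g)
                log_lik.append((np.log(ev.lik0), np.log(ev.lik1)))
        return cls(
            term_ids,
            np.asarray(slot_term, dtype=np.intp),
            slot_gene,
            np.asarray(log_lik, dtype=float).reshape(len(slot_gene), 2),
        )
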