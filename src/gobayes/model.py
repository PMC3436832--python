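"""Hierarchical Beta-Bernoulli model of GO-term activity, fitted by
mean-field variational Bayes.

The generative model: a global activity rate P ~ Beta(delta_P) draws a
binary state G_k per term; given G_k = l, each gene slot's indicator
I_gk ~ Bernoulli(Pi_l) with Pi_l ~ Beta(delta_Pi[l]); the expression
data enter only through per-slot marginal likelihoods p(D_gk | I_gk),
supplied up to a constant.  Inference approximates the joint posterior
by a fully factorised Q-distribution optimised by coordinate ascent on
the negative free energy (the ELBO), which lower-bounds the log marginal
likelihood and is non-decreasing across sweeps.

With symmetric prior counts the two labelings of G are exchangeable, so
a converged solution is identified once post hoc: G = 1 is anchored to
the component whose emission probability of active genes is larger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, digamma, expit, xlogy

from .types import (
    GeneEvidence,
    ModelData,
    PriorSpec,
    TermAnnotation,
    TermPosterior,
    VariationalState,
)

__all__ = [
    "GOActivityModel",
    "GOActivityResults",
    "evidence_from_posterior",
    "vb_sweep",
    "free_energy",
    "identify",
    "vb_fit",
    "decide",
    "expected_fdr",
]

DEFAULT_CLIP = 1e-12


def evidence_from_posterior(
    post1: float,
    prior1: float = 0.5,
    clip: float = DEFAULT_CLIP,
    gene_id: str = "",
) -> GeneEvidence:
    """Convert a first-level posterior activity probability to evidence.

    By Bayes' theorem, p(D|I=m) is proportional to P(I=m|D) / P(I=m); the
    dropped constant p(D) cancels in all downstream posteriors.  The
    posterior is clipped into [clip, 1-clip] so that degenerate 0/1
    probabilities do not produce infinite log-likelihood ratios.
    """
    if not 0.0 < prior1 < 1.0:
        raise ValueError(f"prior activity probability must be in (0, 1), got {prior1}")
    if not 0.0 <= post1 <= 1.0:
        raise ValueError(f"posterior probability must be in [0, 1], got {post1}")
    if not 0.0 < clip < 0.5:
        raise ValueError(f"clip must be in (0, 0.5), got {clip}")
    p = min(max(post1, clip), 1.0 - clip)
    return GeneEvidence(gene_id=gene_id, lik0=(1.0 - p) / (1.0 - prior1), lik1=p / prior1)


def _eln_beta(counts: np.ndarray) -> np.ndarray:
    """E[ln x_m] under Beta with counts[..., m]; last axis is the state."""
    return digamma(counts) - digamma(counts.sum(axis=-1, keepdims=True))


def init_state(
    data: ModelData, priors: PriorSpec, rng: np.random.Generator | None = None
) -> VariationalState:
    """Initial Q: qI from normalised evidence, qG random in (0.1, 0.9).

    The Beta factors start at the counts implied by the initial qG and
    qI (i.e. their own update applied once to the random start) rather
    than at the bare priors: a symmetric Q(Pi) would make the first
    I- and G-updates erase the random initialisation and trap every
    restart at the saddle point qG = 1/2 of the label-exchangeable
    model.  With rng=None, qG starts at 0.5 and the Beta factors stay
    at the priors (the neutral state whose free energy is zero on empty
    data).
    """
    lik = np.exp(data.log_lik - data.log_lik.max(axis=1, keepdims=True))
    qI = lik[:, 1] / lik.sum(axis=1)
    if rng is None:
        return VariationalState(
            qP=priors.delta_P.copy(),
            qPi=priors.delta_Pi.copy(),
            qG=np.full(data.n_terms, 0.5),
            qI=qI,
        )
    qG = rng.uniform(0.1, 0.9, size=data.n_terms)
    qP = priors.delta_P + np.array([data.n_terms - qG.sum(), qG.sum()])
    qPi = priors.delta_Pi.copy()
    wg = qG[data.slot_term]
    for l, w in ((0, 1.0 - wg), (1, wg)):
        qPi[l] = priors.delta_Pi[l] + np.array(
            [float(np.sum(w * (1.0 - qI))), float(np.sum(w * qI))]
        )
    return VariationalState(qP=qP, qPi=qPi, qG=qG, qI=qI)


def vb_sweep(
    state: VariationalState, data: ModelData, priors: PriorSpec
) -> VariationalState:
    """One full coordinate-ascent pass: I -> G -> P -> Pi, in place.

    Each factor update is the exponentiated expectation of the log joint
    under the remaining factors; Beta expectations use
    E[ln x] = psi(a) - psi(a + b).  Appends the new negative free energy
    to the trace and returns the state.
    """
    k = data.slot_term
    elnPi = _eln_beta(state.qPi)  # [l, m]

    # Q(I_s = 1): evidence log-ratio plus mixture-weighted emission log-ratio
    w1 = state.qG[k]
    logit_I = (
        data.log_lik[:, 1]
        - data.log_lik[:, 0]
        + w1 * (elnPi[1, 1] - elnPi[1, 0])
        + (1.0 - w1) * (elnPi[0, 1] - elnPi[0, 0])
    )
    state.qI = expit(logit_I)

    # Q(G_k = 1): prior log-ratio plus per-term summed emission log-ratios
    elnP = _eln_beta(state.qP)
    per_slot = np.empty((data.n_slots, 2))
    for l in (0, 1):
        per_slot[:, l] = state.qI * elnPi[l, 1] + (1.0 - state.qI) * elnPi[l, 0]
    s0 = np.bincount(k, weights=per_slot[:, 0], minlength=data.n_terms)
    s1 = np.bincount(k, weights=per_slot[:, 1], minlength=data.n_terms)
    state.qG = expit((elnP[1] - elnP[0]) + (s1 - s0))

    # Q(P): prior counts plus expected state occupancies
    state.qP = priors.delta_P + np.array(
        [data.n_terms - state.qG.sum(), state.qG.sum()]
    )

    # Q(Pi_l): prior counts plus responsibility-weighted indicator counts
    wg = state.qG[k]
    for l, w in ((0, 1.0 - wg), (1, wg)):
        c1 = float(np.sum(w * state.qI))
        c0 = float(np.sum(w * (1.0 - state.qI)))
        state.qPi[l] = priors.delta_Pi[l] + np.array([c0, c1])

    if not (
        np.all(np.isfinite(state.qI))
        and np.all(np.isfinite(state.qG))
        and np.all(np.isfinite(state.qP))
        and np.all(np.isfinite(state.qPi))
    ):
        bad = ~np.isfinite(state.qG)
        term = data.term_ids[int(np.argmax(bad))] if bad.any() else "<global factor>"
        raise FloatingPointError(f"non-finite variational update at term {term!r}")

    state.free_energy_trace.append(free_energy(state, data, priors))
    return state


def _kl_beta(q: np.ndarray, p: np.ndarray) -> float:
    """KL(Beta(q) || Beta(p)) with counts in [state-0, state-1] layout."""
    return float(
        betaln(p[1], p[0])
        - betaln(q[1], q[0])
        + (q[1] - p[1]) * digamma(q[1])
        + (q[0] - p[0]) * digamma(q[0])
        + (p.sum() - q.sum()) * digamma(q.sum())
    )


def _bernoulli_entropy(q: np.ndarray) -> float:
    return float(-np.sum(xlogy(q, q) + xlogy(1.0 - q, 1.0 - q)))


def free_energy(
    state: VariationalState, data: ModelData, priors: PriorSpec
) -> float:
    """Negative free energy E_Q[ln p(theta, D)] - E_Q[ln Q(theta)].

    Lower-bounds the log marginal likelihood (Jensen); used to assess
    convergence and to rank restarts.  Zero for an empty model whose
    Beta factors sit at their priors.
    """
    k = data.slot_term
    elnP = _eln_beta(state.qP)
    elnPi = _eln_beta(state.qPi)
    qG, qI = state.qG, state.qI

    data_term = float(np.sum(qI * data.log_lik[:, 1] + (1.0 - qI) * data.log_lik[:, 0]))

    wg = qG[k] if data.n_slots else np.zeros(0)
    emission = 0.0
    for l, w in ((0, 1.0 - wg), (1, wg)):
        emission += float(
            np.sum(w * (qI * elnPi[l, 1] + (1.0 - qI) * elnPi[l, 0]))
        )

    state_term = float(np.sum(qG * elnP[1] + (1.0 - qG) * elnP[0]))

    return (
        data_term
        + emission
        + state_term
        - _kl_beta(state.qP, priors.delta_P)
        - _kl_beta(state.qPi[0], priors.delta_Pi[0])
        - _kl_beta(state.qPi[1], priors.delta_Pi[1])
        + _bernoulli_entropy(qG)
        + _bernoulli_entropy(qI)
    )


def identify(state: VariationalState) -> VariationalState:
    """Anchor G = 1 to the component emitting active genes more often.

    If E[Pi_11] < E[Pi_01] the labels are exchanged in place: qG is
    flipped, the Pi factors and the P counts are swapped.  An exact tie
    (degenerate symmetric data) keeps the current labeling with a warning.
    """
    mean_active = state.qPi[:, 1] / state.qPi.sum(axis=1)
    if mean_active[1] < mean_active[0]:
        state.qG = 1.0 - state.qG
        state.qPi = state.qPi[::-1].copy()
        state.qP = state.qP[::-1].copy()
    elif mean_active[1] == mean_active[0]:
        warnings.warn(
            "identification tie: E[Pi_11] == E[Pi_01]; labeling kept as is",
            RuntimeWarning,
            stacklevel=2,
        )
    state.identified = True
    return state


def _fit_single(
    data: ModelData,
    priors: PriorSpec,
    max_iter: int,
    tol: float,
    rng: np.random.Generator | None,
) -> VariationalState:
    state = init_state(data, priors, rng)
    prev = None
    for _ in range(max_iter):
        vb_sweep(state, data, priors)
        cur = state.free_energy_trace[-1]
        if prev is not None and abs(cur - prev) <= tol * max(1.0, abs(prev)):
            state.converged = True
            break
        prev = cur
    return state


def vb_fit(
    data: ModelData,
    priors: PriorSpec | None = None,
    n_restarts: int = 10,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[list[TermPosterior], VariationalState]:
    """Run ``n_restarts`` random-restart optimisations, keep the best.

    Restart r uses its own generator seeded ``seed + r``; the solution
    with the largest converged negative free energy wins and is
    identified before posteriors are read off.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    priors = priors if priors is not None else PriorSpec.uniform()
    best: VariationalState | None = None
    any_converged = False
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        state = _fit_single(data, priors, max_iter, tol, rng)
        any_converged = any_converged or state.converged
        if best is None or (
            state.free_energy_trace
            and state.free_energy_trace[-1] > best.free_energy_trace[-1]
        ):
            best = state
    assert best is not None
    if data.n_terms and not any_converged:
        warnings.warn(
            f"no restart converged within {max_iter} sweeps", RuntimeWarning,
            stacklevel=2,
        )
    identify(best)
    posteriors = [
        TermPosterior(
            term_id=data.term_ids[i],
            prob_active=float(best.qG[i]),
            n_genes=int(data.gamma[i]),
            decision="active" if best.qG[i] > threshold else "inactive",
        )
        for i in range(data.n_terms)
    ]
    return posteriors, best


def decide(
    posteriors: Sequence[TermPosterior], threshold: float = 0.5
) -> list[TermPosterior]:
    """Re-threshold decisions: active iff prob_active strictly exceeds
    ``threshold`` (the Bayes rule at equal error costs when 0.5)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [
        TermPosterior(
            term_id=p.term_id,
            prob_active=p.prob_active,
            n_genes=p.n_genes,
            decision="active" if p.prob_active > threshold else "inactive",
        )
        for p in posteriors
    ]


def expected_fdr(
    posteriors: Sequence[TermPosterior], threshold: float = 0.5
) -> float:
    """Expected FDR of the selection at ``threshold``: the mean posterior
    probability of inactivity among selected terms, valid when term
    activities are independent."""
    selected = [p.prob_active for p in posteriors if p.prob_active > threshold]
    if not selected:
        raise ValueError(f"no term selected at threshold {threshold}")
    return float(np.mean([1.0 - p for p in selected]))


class GOActivityModel:
    """GO-term activity model over annotated terms and per-gene evidence.

    Parameters
    ----------
    terms
        Annotated GO terms; genes without evidence are dropped per term
        and fully unobserved terms are dropped with a warning.
    evidence
        Mapping gene id -> :class:`GeneEvidence`.
    priors
        Beta prior counts; defaults to all ones (uninformative).
    epsilon_identification
        Optional symmetry-breaking bonus on the matched emission counts;
        ignored when ``priors`` is given explicitly.
    """

    def __init__(
        self,
        terms: Sequence[TermAnnotation],
        evidence: Mapping[str, GeneEvidence],
        priors: PriorSpec | None = None,
        epsilon_identification: float = 0.0,
    ) -> None:
        kept: list[TermAnnotation] = []
        dropped: list[str] = []
        for t in terms:
            if any(g in evidence for g in t.gene_ids):
                kept.append(t)
            else:
                dropped.append(t.term_id)
        if dropped:
            warnings.warn(
                f"dropped {len(dropped)} term(s) with no observed gene: "
                + ", ".join(sorted(dropped)[:5])
                + ("..." if len(dropped) > 5 else ""),
                RuntimeWarning,
                stacklevel=2,
            )
        if not kept:
            raise ValueError("no annotated term overlaps the evidence genes")
        self.terms = kept
        self.evidence = dict(evidence)
        self.dropped_terms = dropped
        self.priors = (
            priors
            if priors is not None
            else PriorSpec.uniform(epsilon_identification)
        )
        self.data = ModelData.from_terms(kept, self.evidence)

    @classmethod
    def from_probabilities(
        cls,
        term_probs: Mapping[str, Sequence[float]],
        prior1: float = 0.5,
        clip: float = DEFAULT_CLIP,
        **kwargs,
    ) -> "GOActivityModel":
        """Build from per-term lists of gene activity probabilities.

        Convenience constructor for synthetic scenarios: gene ids are
        generated as ``<term>:g<i>`` so each slot is independent.
        """
        terms: list[TermAnnotation] = []
        evidence: dict[str, GeneEvidence] = {}
        for term_id, probs in term_probs.items():
            gene_ids = []
            for i, p in enumerate(probs):
                gid = f"{term_id}:g{i:03d}"
                gene_ids.append(gid)
                evidence[gid] = evidence_from_posterior(p, prior1, clip, gene_id=gid)
            terms.append(TermAnnotation(term_id, gene_ids))
        return cls(terms, evidence, **kwargs)

    @classmethod
    def from_files(
        cls,
        annotations_path,
        evidence_path,
        clip: float = DEFAULT_CLIP,
        **kwargs,
    ) -> "GOActivityModel":
        """Build from the tab-delimited annotation and evidence files."""
        from .annotations import read_annotation_file
        from .io import read_evidence

        table = read_annotation_file(annotations_path)
        ev_frame = read_evidence(evidence_path)
        evidence = {
            row.gene_id: evidence_from_posterior(
                row.posterior, row.prior, clip, gene_id=row.gene_id
            )
            for row in ev_frame.itertuples(index=False)
        }
        terms = [
            TermAnnotation(t, genes)
            for t, genes in table.terms.items()
            if genes
        ]
        return cls(terms, evidence, **kwargs)

    def fit(
        self,
        n_restarts: int = 10,
        max_iter: int = 1000,
        tol: float = 1e-6,
        seed: int = 0,
        threshold: float = 0.5,
    ) -> "GOActivityResults":
        restarts: list[VariationalState] = []
        for r in range(n_restarts):
            rng = np.random.default_rng(seed + r)
            restarts.append(
                _fit_single(self.data, self.priors, max_iter, tol, rng)
            )
        finals = [s.free_energy_trace[-1] for s in restarts]
        best_idx = int(np.argmax(finals))
        best = restarts[best_idx]
        if not any(s.converged for s in restarts):
            warnings.warn(
                f"no restart converged within {max_iter} sweeps",
                RuntimeWarning,
                stacklevel=2,
            )
        identify(best)
        posteriors = [
            TermPosterior(
                term_id=self.data.term_ids[i],
                prob_active=float(best.qG[i]),
                n_genes=int(self.data.gamma[i]),
                decision="active" if best.qG[i] > threshold else "inactive",
            )
            for i in range(self.data.n_terms)
        ]
        return GOActivityResults(
            model=self,
            state=best,
            posteriors=posteriors,
            restart_free_energies=finals,
            best_restart=best_idx,
            threshold=threshold,
            seed=seed,
        )


@dataclass
class GOActivityResults:
    """Fitted GO-term activity posteriors with diagnostics."""

    model: GOActivityModel
    state: VariationalState
    posteriors: list[TermPosterior]
    restart_free_energies: list[float]
    best_restart: int
    threshold: float
    seed: int

    @property
    def prob_active(self) -> pd.Series:
        return pd.Series(
            {p.term_id: p.prob_active for p in self.posteriors}, name="prob_active"
        )

    @property
    def free_energy(self) -> float:
        """Converged negative free energy of the selected restart."""
        return self.state.free_energy_trace[-1]

    def decide(self, threshold: float = 0.5) -> list[TermPosterior]:
        return decide(self.posteriors, threshold)

    def expected_fdr(self, threshold: float = 0.5) -> float:
        return expected_fdr(self.posteriors, threshold)

    def frame(self) -> pd.DataFrame:
        """Posterior table sorted by activity probability, descending."""
        df = pd.DataFrame(
            [
                (p.term_id, p.prob_active, p.n_genes, p.decision)
                for p in self.posteriors
            ],
            columns=["term_id", "prob_active", "n_genes", "decision"],
        )
        return df.sort_values(
            ["prob_active", "term_id"], ascending=[False, True]
        ).reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    def summary(self) -> str:
        df = self.frame()
        n_active = int((df["prob_active"] > self.threshold).sum())
        lines = [
            "GO-term activity model (mean-field variational Bayes)",
            f"  terms: {len(self.posteriors)}   gene slots: {self.model.data.n_slots}",
            f"  restarts: {len(self.restart_free_energies)}   "
            f"best: #{self.best_restart} "
            f"(F = {self.free_energy:.4f}, "
            f"{'converged' if self.state.converged else 'not converged'})",
            f"  active at threshold {self.threshold}: {n_active}",
        ]
        try:
            lines.append(f"  expected FDR at {self.threshold}: {self.expected_fdr(self.threshold):.4f}")
        except ValueError:
            lines.append(f"  expected FDR at {self.threshold}: undefined (no selection)")
        with pd.option_context("display.max_rows", 20):
            lines.append(df.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
        return "\n".join(lines)
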