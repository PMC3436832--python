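"""Method comparison on simulated studies: per-group ROC AUCs.

Terms are stratified by annotation size (sparsely annotated terms are
where probability-aware inference should help most) and each method's
term scores are summarised as the area under the ROC curve against the
known activity states.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

from .enrichment import call_active, fisher_enrichment
from .model import GOActivityModel, evidence_from_posterior
from .simulate import SimulationTruth
from .types import TermAnnotation

__all__ = [
    "DEFAULT_GAMMA_THRESHOLDS",
    "group_terms",
    "roc_auc",
    "fisher_rank_scores",
    "score_terms",
    "compare_methods",
    "plot_comparison",
]

#: Annotation-size strata boundaries; four thresholds give five groups.
DEFAULT_GAMMA_THRESHOLDS = (16, 37, 63, 84)


def group_terms(gamma, thresholds=DEFAULT_GAMMA_THRESHOLDS) -> np.ndarray:
    """Stratum index per term: the number of thresholds strictly below
    its annotation count (a count equal to a threshold stays in the
    lower group)."""
    t = np.asarray(thresholds)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    return np.searchsorted(t, np.asarray(gamma), side="left")


def roc_auc(scores, truth) -> float:
    """Rank-based (Mann-Whitney) AUC with ties averaged; larger score
    must mean more active."""
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("both truth classes must be present to define AUC")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


def fisher_rank_scores(p_values, a_counts) -> np.ndarray:
    """ROC orientation of Fisher results: rank by 1 - p, ties broken by
    the active in-term count.  Returned scores are ranks, so any
    strictly monotone transform of p gives the same AUC."""
    p = np.asarray(p_values, dtype=float)
    a = np.asarray(a_counts, dtype=float)
    # lexicographic key: smaller p first, then larger a; dense-rank the
    # primary key so the secondary can never cross a primary boundary
    primary = rankdata(-p, method="dense")
    secondary = rankdata(a, method="dense")
    combined = primary * (secondary.max() + 1.0) + secondary
    return rankdata(combined, method="average")


def score_terms(
    expr,
    groups,
    table,
    n_restarts: int = 10,
    seed: int = 0,
    call_threshold: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Score every annotated term with both methods on identical inputs.

    Runs the gene-level posterior analysis, then (a) the variational
    GO-activity fit and (b) threshold calls plus Fisher's exact test.
    Returns a frame with term_id, gamma, bayes (posterior activity) and
    fisher (rank score, larger = more active) columns.
    """
    from .de import de_posterior

    probs = de_posterior(expr, groups)
    gene_probs = dict(zip(expr.index, np.asarray(probs)))

    terms = [
        TermAnnotation(t, genes)
        for t, genes in sorted(table.nonempty_terms().items())
    ]
    evidence = {
        g: evidence_from_posterior(p, 0.5, gene_id=g)
        for g, p in gene_probs.items()
    }
    model = GOActivityModel(terms, evidence)
    res = model.fit(n_restarts=n_restarts, seed=seed, tol=tol, max_iter=max_iter)
    bayes = res.prob_active

    calls = call_active(gene_probs, call_threshold)
    fisher = fisher_enrichment(table, calls).set_index("term_id")

    out = pd.DataFrame(
        {
            "term_id": bayes.index,
            "gamma": [model.data.gamma[i] for i in range(model.data.n_terms)],
            "bayes": bayes.values,
            "p_fisher": fisher.loc[bayes.index, "p"].values,
            "a_fisher": fisher.loc[bayes.index, "a"].values,
        }
    )
    out["fisher"] = fisher_rank_scores(out["p_fisher"], out["a_fisher"])
    return out


def compare_methods(
    scores: pd.DataFrame,
    truth: SimulationTruth,
    thresholds=DEFAULT_GAMMA_THRESHOLDS,
) -> pd.DataFrame:
    """Per-stratum AUC of each method against the known term states.

    A stratum missing one truth class is skipped with a warning.
    Returns a tidy frame (group, method, auc, n_terms, n_active).
    """
    active = dict(zip(truth.term_ids, truth.term_active))
    df = scores.copy()
    df["truth"] = [bool(active[t]) for t in df["term_id"]]
    df["group"] = group_terms(df["gamma"], thresholds)

    rows = []
    for g, sub in df.groupby("group"):
        for method in ("bayes", "fisher"):
            try:
                auc = roc_auc(sub[method], sub["truth"])
            except ValueError:
                warnings.warn(
                    f"group {g}: one truth class absent, AUC undefined",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            rows.append((int(g), method, auc, len(sub), int(sub["truth"].sum())))
    return pd.DataFrame(
        rows, columns=["group", "method", "auc", "n_terms", "n_active"]
    )


def plot_comparison(auc_tables: dict[float, pd.DataFrame], path=None):
    """Bar panel of per-group AUCs, one panel per noise level."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, len(auc_tables), figsize=(5 * len(auc_tables), 4), squeeze=False
    )
    for ax, (sd, table) in zip(axes[0], sorted(auc_tables.items())):
        pivot = table.pivot(index="group", columns="method", values="auc")
        pivot.plot.bar(ax=ax, ylim=(0.4, 1.0))
        ax.set_title(f"sd = {sd}")
        ax.set_ylabel("AUC")
        ax.set_xlabel("annotation-size group")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
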