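# gobayes

Bayesian assignment of Gene Ontology (GO) terms to gene-expression
experiments.

Classical GO enrichment dichotomises genes into "active" and "inactive"
at a probability or significance threshold and tests each term's 2×2
contingency table (Fisher's exact test, hypergeometric tail). That
discards everything a Bayesian first-level analysis knows about *how
certain* each gene call is, and it systematically favours well-studied
terms with many annotated genes. `gobayes` instead treats term activity
itself as a latent variable and combines the per-gene posterior
probabilities in a probabilistically consistent way, so that sparsely
annotated terms and borderline genes contribute exactly the evidence
they carry.

## The model

Each annotated GO term *k* carries a binary state G_k (1 = active,
0 = dormant) drawn with probability P, itself given a Beta(δ^P) prior.
Given G_k = l, every gene slot annotated to the term has a binary
indicator I_gk ~ Bernoulli(Π_l), with Beta(δ^Π_l) priors on the two
emission probabilities — a two-component Beta–Bernoulli mixture. The
expression data D_gk enter only through marginal likelihoods
p(D_gk | I_gk), recovered up to an irrelevant constant from any
first-level Bayesian analysis via

    p(D | I=m) ∝ P(I=m | D) / P(I=m).

Inference is mean-field variational Bayes: the joint posterior is
approximated by a fully factorised Q-distribution optimised by
coordinate ascent on the negative free energy (ELBO), a lower bound on
the log marginal likelihood that is non-decreasing across sweeps. The
fit is repeated from several random starting points and the solution
with the largest bound is kept. Because symmetric priors make the two
labelings of G exchangeable, the winning solution is identified once
post hoc: G = 1 is anchored to the component that emits active genes
more often. The headline output is Q(G_k = 1) ≈ P(G_k = 1 | D) per
term; terms are called active when this exceeds 0.5 (the Bayes rule at
equal error costs) or a conservative 0.995, and the mean posterior
probability of inactivity among selected terms estimates the FDR of the
selection under independence.

The package also ships:

- `gobayes.exact` — exact posterior by enumeration for small instances
  (the correctness oracle for the variational fit);
- `gobayes.de` — a conjugate Bayesian two-group comparison producing
  per-gene activity posteriors from a log-expression matrix;
- `gobayes.annotations` — OBO/GAF parsing and upward annotation
  propagation that stops at the highest manually curated ancestor;
- `gobayes.enrichment` — the Fisher's-exact-test baseline;
- `gobayes.simulate` / `gobayes.evaluation` — synthetic benchmarks with
  known term activity and ROC-based method comparison.

## Worked example

Four hypothetical GO terms, twelve genes each, with gene activity
probabilities: term A has ten genes at 0.90 and two at 0.40; B six at
0.90 and six at 0.45; C ten at 0.55 and two at 0.05; D two at 0.60 and
ten at 0.10.

```python
from gobayes import GOActivityModel, make_four_term_scenario

fixture = make_four_term_scenario()
model = GOActivityModel.from_probabilities(fixture.term_probs)
results = model.fit(n_restarts=10, seed=1)
print(results.summary())
```

```
GO-term activity model (mean-field variational Bayes)
  terms: 4   gene slots: 48
  restarts: 10   best: #5 (F = 5.1004, converged)
  active at threshold 0.5: 2
  expected FDR at 0.5: 0.0000
term_id  prob_active  n_genes decision
      A       1.0000       12   active
      B       1.0000       12   active
      C       0.0000       12 inactive
      D       0.0000       12 inactive
```

A and C are indistinguishable to a counts-based test — both threshold
to 10 active / 2 inactive genes, hence identical Fisher p-values — yet
the model activates A (whose majority genes are confidently active) and
deactivates C (whose majority barely clears 0.5 while two genes are
confidently inactive). B's six borderline genes leave enough combined
evidence to call the term active even though Fisher sees an unremarkable
6/6 split.

The same workflow from files, via the CLI:

```sh
gobayes prepare-annotations --obo go.obo --assoc assoc.gaf --format gaf \
    --namespace biological_process --out annotations.tsv
gobayes infer --annotations annotations.tsv --evidence evidence.tsv \
    --out posteriors.tsv --report report.json --seed 1
gobayes enrich-fisher --annotations annotations.tsv --evidence evidence.tsv \
    --out fisher.tsv
```

`evidence.tsv` is tab-delimited `gene_id / posterior / prior` (prior
optional, default 0.5), as produced by any Bayesian first-level
analysis; `gobayes.de.de_posterior` provides one from a two-group
log-expression matrix.

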