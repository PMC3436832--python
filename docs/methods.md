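# Methods

## Model

`gobayes` infers which Gene Ontology terms are engaged in an expression
experiment from per-gene posterior probabilities of activity. The
generative model is a hierarchical Beta–Bernoulli mixture:

- P ~ Beta(δ^P) — the global prior probability that a term is active;
- G_k | P ~ Bernoulli(P) — the binary activity state of term k;
- Π_l ~ Beta(δ^Π_l), l ∈ {0, 1} — the probability that a gene annotated
  to a dormant (l = 0) or active (l = 1) term is itself active;
- I_gk | G_k = l ~ Bernoulli(Π_l) — the activity indicator of gene slot
  (g, k);
- D_gk | I_gk — the expression data, entering only through the marginal
  likelihoods p(D_gk | I_gk = m).

A gene annotated to several terms contributes an independent indicator
per term; indicators are never shared across terms. This mirrors the
plate structure of the model and keeps every term's evidence
self-contained, at the cost of treating a multiply annotated gene's data
as independent replicates — a known simplification that slightly
overcounts shared evidence in densely overlapping annotation tables.

Evidence is supplied as posterior/prior ratios: by Bayes' theorem
p(D | I=m) ∝ P(I=m | D) / P(I=m), and the dropped constant p(D) cancels
from every posterior. Posteriors are clipped to [1e−12, 1 − 1e−12]
before conversion so degenerate 0/1 inputs cannot produce infinite
log-likelihood ratios. When no gene-level prior is supplied, 0.5 is
assumed and the ratio reduces to the posterior itself (the constant 2
cancels). All downstream results are invariant to rescaling both
likelihoods of a gene by any positive constant.

## Inference

The joint posterior over {P, Π, G, I} is approximated by a fully
factorised mean-field family. One sweep updates, in order, all Q(I_gk),
all Q(G_k), Q(P), Q(Π_0), Q(Π_1); each update is the exponentiated
expected log joint under the other factors, with Beta expectations
E[ln x] = ψ(a) − ψ(a + b). The negative free energy (ELBO)
E_Q[ln p(θ, D)] − E_Q[ln Q] is recomputed after every sweep; coordinate
ascent makes it non-decreasing, which the test suite enforces at
relative tolerance 1e−8, and Jensen's inequality bounds it by the log
marginal likelihood, which the suite verifies against the enumeration
oracle.

Parameters that matter:

- `n_restarts` (default 10): independent optimisations from random
  starting points; the final state with the largest bound wins. The
  landscape is multimodal (the model is mixture-like), so single runs
  can stall in poor labelings.
- `tol` (default 1e−6) and `max_iter` (default 1000): a run stops when
  |F_t − F_{t−1}| ≤ tol · max(1, |F_{t−1}|). The max(1, ·) guard keeps
  the criterion meaningful when the bound is near zero. Because the
  criterion measures the bound, which shifts by an additive constant
  under evidence rescaling, exact scale invariance holds per sweep
  rather than at the stopping point; the invariance test therefore
  compares fixed-sweep trajectories.
- `threshold` (default 0.5) and `conservative_threshold` (default
  0.995): decisions are strict inequalities, `prob_active > threshold`.
- `epsilon_identification` (default 0): optional bonus on the matched
  emission prior counts (δ^Π_{1,1} = δ^Π_{0,0} = 1 + ε). The default
  keeps the priors fully uninformative; ε = 0.5 is used in the oracle
  tests, where the symmetric model's exact marginals are provably 0.5
  for all data and could not discriminate a correct implementation from
  a broken one.

Initialisation: Q(I) starts at the normalised evidence
lik1/(lik0 + lik1); Q(G_k) is drawn i.i.d. Uniform(0.1, 0.9) per restart
from a generator seeded `seed + restart`; Q(P) and Q(Π) start at the
counts implied by those initial values (their own update applied once to
the random start). Starting the Beta factors at the bare priors instead
would be fatal: a symmetric Q(Π) zeroes the emission log-ratios, so the
first I- and G-updates would map every q(G_k) to exactly 1/2 and all
restarts would sit at the label-symmetric saddle point forever. The
chosen initialisation preserves the sweep order, the monotone bound, and
the invariant that every Beta parameter is at least its prior count.

Identification: with symmetric priors the model cannot decide whether
G = 1 codes activity — flipping all G labels, swapping the Π factors and
reversing Q(P) yields an equally good solution (a property the test
suite asserts). After selecting the best restart, labels are exchanged
once if E[Π_{1,1}] < E[Π_{0,1}], anchoring G = 1 to the component that
emits active genes more often. An exact tie (only possible on degenerate
symmetric data) keeps the current labeling and emits a warning. The
free-energy trace is frozen before the swap, so bound comparisons always
refer to the converged, pre-identification state.

## Exact oracle

`gobayes.exact` integrates P and Π analytically (Beta-function ratios)
and sums the joint weight over all 2^(K+S) binary configurations in log
space. It is restricted to K ≤ 4 terms and ~2^18 configurations and
serves three purposes: validating the variational updates (decisions at
threshold 0.5 agree wherever the exact posterior is outside [0.4, 0.6];
mean |Q(G) − exact| stays below 0.15 over randomised small instances),
verifying the Jensen bound, and demonstrating that symmetric priors make
the exact posterior exactly 0.5 for every term on any data — the formal
statement of the identification problem.

## Gene-level evidence

`gobayes.de.de_posterior` is a conjugate Bayesian two-model comparison
standing in for a first-level variational ANOVA: per gene, the marginal
likelihood of one common mean (M0) is compared against group-specific
means (M1), both under a Normal–Inverse-Gamma prior with shared
variance (prior mean 0, mean precision κ0 = 0.01 relative to the data
precision, variance shape and rate a0 = b0 = 0.1), and combined with a
prior activity probability (default 0.5). Genes are grand-mean centred
first, making the result exactly invariant to location shifts. The
closed forms are validated against nested numerical quadrature. The
module is deliberately an adapter: any external per-gene posterior file
can replace it, and its hyperparameters are a pragmatic default rather
than a calibrated reconstruction of any particular first-level tool. A
unit-information prior (κ0 = 1) was considered and rejected: it
compresses the per-gene Bayes factors and measurably degrades term-level
discrimination on the synthetic benchmark.

## Annotation preparation

Associations are propagated upward through is_a and part_of edges only
(regulates is excluded; the standard true-path set). Along every upward
path from a gene's direct term, the gene is added to each ancestor at or
below the highest ancestor on that path possessing at least one direct
manual annotation; ancestors above that term receive nothing. "Manual"
means any evidence code other than IEA/ND; two-column TSV input carries
no codes, so every direct annotation counts as manual there. The
per-path rule means a term reachable on one qualifying path is annotated
even if another path stops earlier. Propagation stops at curated levels
so the resulting table stays at a level of abstraction biologists have
actively used, rather than flooding near-root terms. The default
namespace is biological_process.

## Synthetic benchmarks

`make_four_term_scenario` builds a deterministic four-term scenario (12 genes
each): A — ten genes at 0.90, two at 0.40; B — six at 0.90, six at 0.45;
C — ten at 0.55, two at 0.05; D — two at 0.60, ten at 0.10. Thresholded
at 0.5 the counts are A 10/2, B 6/6, C 10/2, D 2/10, so A and C are
identical to any counts-based test while their probability profiles
differ sharply; the fitted model activates A and B and deactivates C and
D. The minority probabilities are a reconstruction from a verbal
description of a graphical figure, chosen so that A and C threshold
identically (A's two minority genes sit at 0.40, "just not active", for
that reason).

`simulate_go_study` generates a study with known truth: by default 2000
hypothetical terms annotated with 1–100 genes each from a shared pool of
20000 genes, 20% of terms active, and differential expression observed
with chance 80% in active and 20% in inactive terms. Because terms share
the gene pool, independent per-term DE draws would contradict each other
at shared genes; instead a single global DE flag is drawn first (pool
fraction 0.32, the marginal implied by the term-level rates) and each
term samples Binomial(γ, rate) genes from the DE pool and the remainder
from the null pool — without replacement within a term, with sharing
across terms — so every recruitment is consistent with one per-gene
truth while preserving the per-term rates. Binomial recruitment (rather
than a fixed quota per term) matches the Bernoulli emission the activity
model assumes. Expression mimics a two-level design with 8 samples per
group: DE genes get group means +1/−1 (orientation random per gene),
null genes mean 0, i.i.d. Gaussian noise of standard deviation 0.6
(low-noise condition) or 1.2 (high-noise condition). Identical seeds and
parameters give bit-identical outputs.

What the generator does *not* emulate: array-level artifacts
(background, probe effects, normalisation), correlated noise between
genes, multi-factor or time-course designs, and the long-tailed
annotation-size distribution of the real GO. Passing benchmarks
therefore demonstrate correct combination of gene-level evidence under
the model's own assumptions, not robustness to real-data pathologies.

## Method comparison

Terms are stratified by annotation count at thresholds 16/37/63/84
(a count equal to a threshold falls in the lower stratum), giving five
groups, and each method's scores are summarised as rank-based ROC AUC
against the known states. The Bayesian score is Q(G_k = 1); the Fisher
baseline is scored by 1 − p with exact-p ties broken by the in-term
active count, encoded as ranks so any strictly monotone transform of p
gives the same AUC. A stratum missing one truth class is skipped with a
warning.

On the full simulated design the Bayesian method's advantage
concentrates in the sparsest stratum (≤ 16 genes) at the higher noise
level, where per-gene uncertainty is largest and counts are most
granular; in the remaining strata the two methods are practically
equivalent. The margin in the sparsest stratum is modest (of the order
of a few hundredths of AUC) and the stratum holds only ~320 of the 2000
terms, so the orderings fluctuate across simulation seeds; the
acceptance test runs the full 2000-term design at the package-default
seed 0. At a scaled-down 500 terms the sparsest stratum (~80 terms) is
too small for the ordering to be a stable property at all, which is why
the test uses the full design — the fit itself takes a few seconds
either way.

## Numerical choices

- All mixture and enumeration arithmetic is in log space
  (log-sum-exp, Beta functions via log-gamma).
- Decisions use strict inequalities; a posterior exactly at the
  threshold is inactive.
- Expected FDR of a selection is the mean of 1 − prob_active over
  selected terms and is undefined (an error) for an empty selection.
- Terms with no observed gene are dropped with a warning before
  fitting; an empty overlap between evidence and annotations is fatal.
- The empty model has free energy exactly 0 (all KL terms vanish at the
  prior), which anchors the bound computation.

## Known limitations

- Mean-field Q(G) is systematically overconfident relative to the exact
  posterior (deviations up to ~0.4 on adversarial small instances, mean
  ≤ 0.15); decisions are nonetheless reliable wherever the exact
  posterior is decisive.
- The independence assumption behind the expected-FDR estimate ignores
  correlation between nested GO terms.
- Upward propagation enumerates ancestor paths; on pathological DAGs
  with exponentially many paths it would be slow (the real GO is fine).
- The first-level module assumes exactly two groups, equal variance and
  no missing values.
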