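# Methods

This note documents the statistical model, the algorithmic choices, the
synthetic-data generator, and the known limitations of the package.

## Model

### Conditional linear Gaussian network

Every species' dataset is modeled jointly over one discrete binary class
node (disease = 1, control = 0) and one continuous node per feature
(transcript-level probes, or genes after naive summarization).  The class
node is restricted to be a root: in a conditional linear Gaussian (CLG)
network a discrete node may not have continuous parents, so every
class–gene relationship is oriented class → gene.  A gene node with
continuous parents **u** follows a Gaussian linear regression on **u**,
with a separate (intercept, weights, residual variance) triple per class
state when the class node is a parent.

Parameters are maximum-likelihood: per-family OLS with the residual
variance estimated as RSS/n (the ML convention, so that the saturated-fit
log-likelihood identity −(n/2)(log 2πσ̂² + 1) holds exactly).  Two
numerical guards apply: residual variances are floored at 1e−6 and singular
design matrices fall back to ridge regression with λ = 1e−6 (both warn).
If a class stratum holds fewer than `n_parents + 2` samples, that family is
fitted pooled across classes (with a warning) — small disease arms at
fold level make this unavoidable, and a pooled fit is preferable to a
degenerate per-class one.

Feature-level standardization everywhere uses the sample standard
deviation (n − 1 denominator).

### Scoring

Structures are scored by the BIC in "higher is better" orientation:
penalized log-likelihood with k/2·ln n, where k counts every intercept,
weight and residual variance plus |classes| − 1 prior parameters.  The
score decomposes over node families; a search move therefore re-scores
only the families whose parent sets changed, and family scores are cached
by (child, parent set, class-parent flag).

### Prediction

*Expression*: the per-class joint Gaussian over all gene nodes is
assembled from the structural system x = Wx + b_c + ε (mean via a linear
solve, covariance via A⁻¹DA⁻ᵀ with A = I − W).  The target node's
posterior mean given all other gene nodes is a mixture over class states,
weighted by the class posterior given the observed nodes; the class node
is marginalized by default.  Conditioning on the observed label instead is
available as `condition_on_class=True` but is off by default, since a
held-out sample's label should not inform its expression prediction.

*Class*: the posterior over class states given (possibly partial) gene
evidence, computed through the same per-class joint Gaussian; missing
evidence is marginalized exactly, which is what makes the model tolerant
of missing data.  The classification rule is argmax posterior with ties
broken toward control (the majority class in case/control designs).  The
"class SSE" reported alongside the confusion counts is the Brier-style
squared shortfall Σ(1 − P(true class))², a continuous error for a
discrete node.

## Structure search

Simulated annealing from the empty DAG.  One proposal per iteration:
the operator (add / remove / reverse) is drawn uniformly, then an instance
of it uniformly; draws that are illegal (cycle, duplicate edge, class-node
parent, or — in translation mode — a gene-level projection outside the
candidate set) are re-drawn, up to 50 attempts before the neighborhood is
declared exhausted for that iteration.  Edge lists are ordered by node
*position* rather than name during sampling, so runs are independent of
label spelling (and a gene-level run replays a transcript-level run
exactly when every gene has one transcript).

Cooling is geometric, tᵢ = t₀·r^i with r = (tₙ/t₀)^(1/maxfc); the
endpoints t₀ = 10 and tₙ = 0.001 and the budgets (1000 proposals for
training, 500 during translation) follow the published run constants.
Improving moves are always accepted, worsening moves with probability
exp(Δ/t), and exact ties are rejected (incumbent wins).  The returned
structure is the best ever visited, not the final one.  `maxfc` counts
proposals (not accepted moves) — the alternative reading is not
recoverable from the available description, and proposals give the more
conservative budget.

With ~30–40 nodes and a uniform proposal distribution, a specific edge is
proposed only about once per 1000-proposal run, so individual fold
networks are sparse, stochastic samples of the high-scoring region rather
than converged optima.  This is by design the regime the confidence
machinery addresses: reproducibility across folds and species, not
single-run optimality, is the unit of evidence.

## Translation

Network maps are **undirected** gene-level link sets: re-learning in the
target species re-orients every edge anyway, and confidence counting
operates on relationships rather than arrows.  Transcript edges within one
gene are dropped at collapse (they have no gene-level meaning).  Orthology
expansion maps each link endpoint to all target-species members of its
ortholog groups (one-to-many expands to all combinations); links touching
a gene with no target ortholog are dropped and returned in a loss report.

Link occurrences are counted in the **ortholog-group namespace**, so that
one biological relationship accumulates counts across species.  A gene
belonging to several groups projects to its lexicographically smallest
group id for counting purposes (candidate generation still expands to all
groups); with curated one-group-per-gene tables this is exact.

Confidence for a link in a species is found/max over that species'
networks in the run plan: k_train cross-validation networks for the
training species and k_train × k_test translated networks for each test
species.  The consensus keeps links whose confidence clears the threshold
in **every** species in scope — the all-species intersection is what makes
even a 0.1 threshold restrictive.  The disease domain takes directions
from a representative structure (by convention the training fold-network
with the most edges or the highest score), computes the class node's
Markov blanket on its gene-level projection, and keeps the consensus links
inside blanket ∪ {class}; if no consensus link touches the class node the
domain is empty (with a warning) — the collapse mode of the naive variant.

## Synthetic data generator

The generator emulates the study design the method targets: several
species sharing one ground-truth disease network, observed through
species-specific obstacles.

* **Truth**: a linear Gaussian system over genes (acyclic weighted edges,
  unit innovation variance) plus a Bernoulli class root that shifts a
  subset of genes ("class children") by a stated number of sd units.
* **Species privacy**: each species adds its own spurious edges (random
  acyclic placements, |weight| ∈ [0.4, 0.8]) emulating model-system
  artifacts, and may drop genes from its orthology rows (dropout), though
  they remain in the expression matrix.
* **Isoforms**: gene g expands to transcripts tᵢ = ρᵢ·g̃ + √(1−ρᵢ²)·ηᵢ
  (g̃ the standardized gene signal, ηᵢ fresh noise) — an equicorrelated
  model in which fidelity ρᵢ is the transcript–gene correlation; optional
  measurement noise is added on top.  This is the simplest model that
  exhibits the isoform-selection problem the exhaustive variant solves.
* Output matrices are quantile-normalized (optional) and standardized;
  each species draws its class labels Bernoulli(balance), re-drawn until
  both classes appear.

The default study conditions (`dandelion.harness.demo_truth_spec`) are
three species of 40 samples; 15 module genes with 8 chain edges of weight
0.9 and 4 class children at effect 1.5 sd; 10 unconnected random control
genes; two private spurious edges per species; a second isoform on each
class child.  Class children carry no outgoing edges so that they are the
only class-associated genes and recovered class links can be scored
against the truth unambiguously.  The harnesses use 4 folds per species, a
design matched to ~40 samples.

Two deliberate departures from the defaults apply inside the desk-scale
harnesses.  First, they sample with `quantile_norm=False`: quantile
normalization equalizes each sample's value distribution, and with only
~25 features of which 4 are class-shifted, the class difference *is* a
distributional difference — QN at this panel size removes a large part of
the signal, an artifact that does not occur at array scale where a small
module is a negligible fraction of ~50k probes.  Second, effect sizes are
generative shifts; after standardization against total (between-class
included) variance and isoform attenuation, a nominal 1.5 sd effect is an
observed ~1.1 sd shift, which at fold-level n ≈ 30 sits near the BIC
detection boundary.  That marginality is intentional: it reproduces the
regime in which single-species networks are unstable and the cross-species
consensus demonstrates its value.  A consequence worth knowing: the
naive-versus-exhaustive class-link comparison hovers around a factor of
two and individual RNG realizations can land on either side of it.

What passing these harnesses does *not* show: performance under realistic
microarray error models (dye bias, batch effects), annotation noise in the
orthology table, unbalanced designs as extreme as 4 cases / 18 controls,
or modules whose genes overlap several pathways.  The generator's
obstacles are idealized, one-mechanism-at-a-time versions of those
problems.

## Evaluation conventions

* Confusion metrics return `None` (not 0) when a denominator is empty.
* Pooled confusion counts across networks are the primary summary;
  per-network values remain available.
* ROC points are per-network (one confusion matrix each), not threshold
  sweeps.
* Translatability is the fraction of training-species links whose
  confidence in a target species clears the threshold; it is undefined
  (raises) for an empty trained set.

## Parameters at a glance

| parameter | default | meaning |
| --- | --- | --- |
| t0 / tn | 10 / 0.001 | annealing temperature endpoints (score units) |
| maxfc_train / maxfc_test | 1000 / 500 | proposals per search run |
| threshold | 0.1 | consensus confidence threshold (fraction of networks) |
| variance floor / ridge λ | 1e−6 / 1e−6 | numerical guards in fitting |
| folds | 4–6 | per-species cross-validation folds (≥ minority class size) |

## Known limitations

* Binary class states only; no latent variables; static networks.
* The class node must be a root (CLG restriction); gene → class causality
  is not representable.
* Uniform proposal sampling makes single runs coverage-limited on large
  node sets; confidences, not single structures, are the interpretable
  output.
* The group-namespace projection for counting collapses multi-group genes
  to one id (see Translation above).
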