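# Methods

This note records the models, numerical choices, and open design decisions
behind `swcnet`, in the order the pipeline runs.

## Source scoring

**Iterative AdjustCD.** Observed interactions start at weight 1; at each
iteration k the weight of a pair (u, v) is

    w_k(u,v) = Σ_{x ∈ N_u ∩ N_v} [w_{k−1}(u,x) + w_{k−1}(v,x)]
               ───────────────────────────────────────────────
               max(deg_w(u), λ) + max(deg_w(v), λ)

where N are the *observed* neighborhoods, deg_w the weighted degree under
w_{k−1}, and λ the mean weighted degree over all vertices — a penalty that
keeps sparsely connected proteins from scoring high by accident. Updates
are simultaneous (Jacobi-style) and run for two iterations by default.
Imputed level-2 candidates (non-interacting pairs at distance two) are
scored on the final iteration only; they never feed back into the
neighborhoods, because level-2 pairs are outputs of the scoring, not
observations. Interactions whose endpoints share no neighbor are discarded
as unreliable; level-2 pairs are kept above a 0.1 score threshold and
emitted as a separate source. Scores are symmetric and lie in [0, 1]
(the numerator is a sub-sum of the denominator). No further cap is placed
on level-2 candidates beyond the score threshold.

**Literature co-occurrence** is the Jaccard similarity of the two proteins'
document sets; pairs sharing no document are omitted. A `min_docs` knob
(default 1 — the reference behavior) exists only to bound memory on dense
incidences. Functional-association scores are consumed as given, keeping
pairs with score strictly greater than 0.5.

**Composite assembly** takes the union of all sources' pairs; an edge
exists iff at least one source relates the pair, and absent sources
contribute feature value 0. Assembly is order-independent.

## Supervised weighting

Labeling is existential: an edge is co-complex iff *some* training complex
contains both endpoints. All training complexes participate, including
those of size 2–3 — the cross-validation protocol holds out only large
complexes, and small ones still carry co-membership information.

**Discretization** follows the classic recursive entropy-minimization with
the MDL stopping rule: a cut T on segment S (N points, k classes) is
accepted iff

    Gain(T;S) > [log2(N−1) + log2(3^k − 2) − k·Ent(S) + k1·Ent(S1) + k2·Ent(S2)] / N.

Candidate cuts are midpoints between consecutive distinct sorted values;
the minimum-entropy candidate is taken, ties broken toward the smallest
cut value for determinism. A feature with no accepted top-level cut is
dropped (this doubles as feature selection). Zero is an ordinary value:
absent-source edges land in the lowest bin, no special missing-data bin.
The equivalence of this implementation with an independent exhaustive
search is asserted on small inputs in the test suite.

**Estimation.** Conditionals are (count + α) / (class total + α·#bins)
with pseudocount α = 1 by default, applied to conditionals only so that
likelihood ratios stay finite on empty bins; priors are raw class
frequencies over the composite network's edges (the maximum-likelihood
choice — the posterior formula references P(co-comp) without prescribing
an estimator). Only composite-network edges are data instances; protein
pairs with no source support are not.

**Posterior weighting** accumulates log conditionals for both classes and
normalizes once, so the complement posterior is exactly 1 − w. Raising a
feature to a bin with a larger likelihood ratio can only raise the
posterior. Top-k selection breaks weight ties by canonical (lexicographic)
edge key so the output size is exactly min(k, |E|) and runs are
reproducible.

## Clustering

**MCL** builds a column-stochastic matrix from the edge weights plus unit
self-loops and alternates expansion (matrix power, default 2) with
inflation (element-wise power, default 2; grid 2/3/4), pruning entries
below 1e−5 after inflation and renormalizing, until the maximum
element-wise change drops below 1e−6 or 200 iterations pass
(non-convergence returns the current state with a warning). Clusters are
the connected components of the attractor's non-zero structure; singletons
are discarded.

**CMC** enumerates maximal cliques (pivoting Bron–Kerbosch via networkx),
drops those below `min_size` (default 4), and ranks the rest by weighted
density. For each ordered pair with overlap |A∩B|/min(|A|,|B|) strictly
above `overlap_thres` (default 0.5), the two clusters are merged when
their inter-connectivity reaches `merge_thres`, else the lower-density one
is removed; passes repeat to a fixed point. Inter-connectivity is defined
here as the mean edge weight over all pairs between the lower-density
cluster's non-shared members and the other cluster (absent edges count 0);
the reference method defers this formula to its own source, so this is the
package's definition, chosen because it reduces to weighted density on the
merged set when information is complete. `min_deg_ratio` screens candidate
cliques by presence degree (every member must touch at least
ratio·(|C|−1) others); within a clique this holds by construction at the
default ratio 1, and merged clusters are exempt because `merge_thres`
already gates their quality — a ratio against the *average weighted*
degree would be degenerate (on any non-uniformly weighted clique some
member sits below average, so the default would discard nearly every
clique).

**COMBINED** pools clusters from all algorithms (minimum size 4
throughout, matching the evaluation's size floor), links clusters with
Jaccard ≥ 0.75, and treats connected components of that graph as groups —
the reference description ("two or more clusters similar to each other")
does not define transitive grouping, and components are deterministic and
order-independent. Each group keeps its densest member (ties:
lexicographically smallest member set) scored density × number of
*distinct algorithm names* voting for the group; parameter variants of one
algorithm do not count twice.

## Evaluation

A cluster matches a complex when their Jaccard similarity reaches the
match threshold (0.5, or 0.75 for the strict setting). Precision excludes
clusters that match only training complexes, removing the supervised
methods' advantage of re-predicting their own supervision. Curves sweep
the distinct cluster scores descending — COMBINED scores (density ×
votes) are the thresholding score where they exist, since that is the
cluster's score by definition. AUC is the trapezoid over (recall,
precision) anchored at (0, first precision); thresholds where the
precision denominator is empty record precision 1 with zero recall span,
hence zero area. Edge-level evaluation mirrors the training exclusion:
edges co-resident in a training complex leave both numerator and
denominator (configurable in principle; the reference text is silent), and
each point reports the fraction of test complexes covered by at least one
retained edge.

Cross-validation holds out t = 90% of the complexes larger than three
proteins per round (ten rounds by default), training on everything else.
The test-set size is round-half-away-from-zero of t × #candidates, which
reproduces the familiar 149 → 134/274 and 714 → 643/1186 splits. Seeds
derive from (seed, round), so rounds are independent and reruns identical.
Calibration pools (combined-cluster score, matched-a-test-complex)
outcomes across rounds, excluding train-only matches, bins scores by
quantiles, and flattens bin precisions with pool-adjacent-violators so the
estimate is monotone in the score. Novel-complex filtering runs three
passes in order: greedy dedup at Jaccard ≥ 0.5 keeping the higher score,
removal of anything matching a reference complex at 0.5, and removal of
clusters whose calibrated precision falls strictly below the confidence
threshold (presets 0.5 and 0.4).

## GO coherence

Term information content is −log2 of the fraction of annotated proteins
covered by the term or its descendants, computed against the user-supplied
annotation corpus itself (no external frequency tables). Pair similarity
is the maximum IC over common ancestors of the two proteins' annotated
terms; complex coherence is the mean over computable member pairs, with
pairs involving unannotated proteins *skipped* and reported via a coverage
fraction rather than scored 0 — scoring 0 would conflate missing
annotation with dissimilarity. High-level annotation assigns every
candidate term that covers the maximum number of members, provided that
count is a strict majority. A rank-sum utility is exposed for comparing
coherence distributions; no attempt is made to reproduce any particular
published p-value, since the underlying test there is unnamed.

## Synthetic benchmark

The generator plants complexes (sizes uniform 4–12, members drawn
independently, occasional overlap allowed) among 2000 proteins, 200
complexes by default. Each source relates a surviving co-complex pair with
probability 0.7 and scores it Beta(5, 2); background pairs are sampled to
a per-source target (15 000, putting the default composite network at
about 50 000 edges) and scored Beta(2, 5). Class-conditional Beta
distributions are the natural choice for scores in [0, 1] with
stochastically ordered classes, which is what monotone likelihood-ratio
curves require. Two structured noise regimes are modeled: a 10% whole-pair
dropout (a co-complex pair missing from *every* source), and 20 transient
hubs — complex-free proteins of degree 20–50 whose edges score like
co-complex pairs in the interaction source only, the failure mode
supervised integration should suppress. `true_likelihood_ratios`
integrates these generative distributions over a discretization scheme,
conditioning on edge existence, to give the exact per-bin ratios a learner
should recover; bins with no background mass are reported as infinite
(their empirical counterparts are bounded only by smoothing).

What the generator does not emulate: real degree distributions,
correlated evidence between sources, annotation biases of literature
corpora, or organism-scale complex-size distributions. Passing recovery
tests therefore demonstrates correctness of the learning and clustering
machinery under the model's own assumptions, not performance on any real
interactome.

## Problem sizes and tolerances

The recovery benchmarks run at the generator's default scale (about
50 000 edges), where likelihood ratios in bins with expected support of at
least 200 instances per class recover the generative values within 15%
relative error and the full pipeline (weight → top-10000 → MCL + CMC →
COMBINED) reaches cluster-level PR AUC ≥ 0.6 at match threshold 0.5,
beating the unweighted all-edges baseline across seeds. Support-poor bins
are judged through a support-weighted mean instead, since their empirical
ratios are dominated by sampling noise and smoothing (a bin with expected
count c has relative sampling noise ≈ 1/√c). Unit tests pin the worked
examples (AdjustCD toy values, MDL acceptance arithmetic, posterior
arithmetic, PR-curve hand counts) and property tests cover the invariants;
all randomized tests are seeded.
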