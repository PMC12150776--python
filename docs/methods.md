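# Methods

This note records how `kglink` models its problem, the parameters that
matter, the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Graph model

A knowledge graph is typed, undirected and unweighted.  Node ids are opaque
strings; all numerics run over a dense integer index obtained by sorting the
ids, so the index is reproducible from the node set alone.  Every undirected
edge is stored canonically (smaller dense index first); all edge-set algebra
(holdouts, negative rejection, false-negative audits) uses this form, which
makes intersections and differences well defined.

Parallel typed relations are common in biomedical KGs, so a node pair may
carry several typed edges: one edge per `(pair, edge_type)` is kept.
Topological operations (degree, components, walks, embedding) see the pair
once; type-filtered operations see the typed multiplicities.  Self-loops are
dropped at load time with a log line — the undirected, unweighted reading of
the graph gives them no role.  Duplicate rows and both orientations of a
pair collapse silently; an edge referencing an unknown node id is a hard
error naming the row.

## Synthetic generator

The generator is a stochastic block model (SBM) over node types: types are
drawn i.i.d. from a frequency vector, and each unordered pair with types
`(s, t)` is an edge independently with probability `block_density[s, t]`.
This parameterization (probability rather than target mean degree) was
chosen because it gives exact binomial/multinomial moments, which the tests
use as closed-form oracles; a helper converts target within-type mean
degrees into densities when that is the more natural input.  Edge types are
a deterministic function of the endpoint type pair; several pairs may share
one label, which is how sub-community structure is planted inside a single
typed prediction task.  When `ensure_connected` is set, components are
merged by uniformly random inter-component edges, each flagged in the
planted-truth record so block-count checks can exclude them.

The `rnakg_like_preset` emulates, at 5,000 (small) or 50,000 (medium) nodes,
the statistical shape of a large RNA-centric KG: 81 node types with
frequencies proportional to `rank^-1.5` (the top 7 types hold ~74% of
nodes), within-type densities chosen so expected mean degrees span more than
an order of magnitude across types, and background cross-type blocks kept at
least 20x sparser than the within-type blocks of their endpoints so that
types remain topologically separable.  A planted `miRNA-disease` edge type
spans three matched miRNA/disease sub-community pairs (matched density 0.3,
mismatched 0.001): a classifier that recovers the sub-communities from the
embedding can predict which typed pairs are plausible edges.  Densities are
calibrated at 5,000 nodes and scaled by `5000/n` so expected degrees are
size-invariant.

Two auxiliary configurations support the leakage study: `dense_target_spec`
(one dense typed block, density 0.3) and `contrastive_target_spec` (two
matched sub-community pairs at density 0.6 with near-empty mismatched
blocks, which maximizes the contrast between biased and unbiased sampling
while leaving enough non-edges to sample).

## Embeddings

**node2vec.**  Second-order walks use the standard weight rule — return
weight for stepping back, 1 for a candidate adjacent to the previous node,
explore weight otherwise — with on-the-fly neighbor scanning (O(deg) per
step) rather than per-edge alias tables, which desk-scale graphs do not
need.  The named presets BFS (5, 0.2), DFS (0.2, 5) and Balanced (1, 1)
are exposed as constructors.  Walks feed a skip-gram model with negative
sampling; the noise distribution is the corpus unigram frequency to the 3/4
power.  No frequency subsampling is applied: walk corpora have controlled
frequencies, unlike natural text.

**LINE.**  First order optimizes `log σ(x_i·x_j)` over uniformly sampled
edges (the graph is unweighted, so uniform edge sampling is exact); second
order uses separate context vectors.  Noise is degree^(3/4); the total
sample budget defaults to `100·|E|`.

Defaults (exposed, not hidden): 10 walks of length 100 per node, window 5,
5 negatives, 10 epochs, learning rate 0.025 with linear decay to a floor of
1e-4 of its initial value.  Preset-scale tests and examples use an
evaluation configuration of 10 walks of length 50 and 3 epochs, at which the
separability results reported by the suite are already saturated.  Training
kernels are single-threaded numba code seeded internally, so a fixed seed
yields bit-identical embeddings; noise sampling uses alias tables and the
sigmoid/log-sigmoid come from a 2048-entry lookup table over [-8, 8]
(scores saturate outside), the standard word2vec-style approximation.  Mean
training loss per epoch is recorded; on small fixed corpora it declines
from first to last epoch, though late in training it can drift up slightly
as cluster-internal negatives become genuinely hard — the contract checked
is the start-to-end decline.

The 2-D t-SNE projection is delegated to scikit-learn with perplexity
`min(30, (n-1)/3)`; it is a reporting utility, not an embedding method.

## Splits and negative sampling

`connected_holdout` draws a random spanning forest (union-find over a
shuffled edge order) that always stays in training, then assigns the
remaining edges at random to hit the requested test fraction as closely as
the forest constraint allows.  One stated step of the original recipe —
"use a spanning tree as the training graph" — would contradict the 70:30
ratio used everywhere else; the forest-plus-random-remainder reading
reconciles the two and is the one implemented.  On a forest the test split
is empty and a warning is raised.

`degree_aware_negative_sample` draws both endpoints independently with
probability proportional to **full-graph** degree (negatives must mimic the
endpoint-degree profile of real positive edges, and a positive edge's
endpoint is degree-biased by construction), then rejects self-pairs, pairs
in the rejection set, exclusions and duplicates.  The rejection budget is
100 attempts per requested sample; exhausting it (e.g. on a near-complete
graph) raises a shortfall error naming the achieved count.

The unbiased specific-edge pipeline: (1) connected holdout of the full
graph; (2) embeddings are computed on the *training* graph — embedding the
full graph would leak test edges into the representation; (3) positives
filtered to the target edge type; (4) negatives rejected against the full
edge set; (5) negatives partitioned into disjoint train/test sets mirroring
the positive 70:30 proportions (the original recipe requires only
disjointness; mirroring keeps class balance comparable across splits);
(6)–(7) training and evaluation are the task layer's job.  Steps 4–5 are
what guarantee FN% = 0.00 exactly, for every graph, type and seed.  The
biased baseline differs in one line — rejection against the filtered
training edges only — so any performance gap on the same seed is
attributable to leakage.

Negatives for a typed task are restricted, by default, to node pairs whose
types form one of the target type's endpoint-type pairs (inferred from the
observed typed edges, overridable).  Without this constraint negatives are
trivially separable by node type and the task degenerates; the flag exists
because the original protocol leaves the point unstated.  The generic-edge
task is type-agnostic by definition and samples without the constraint.

## Tasks, classifiers, metrics

Node-type prediction restricts to the `top_k` most frequent types (ties
broken lexicographically), uses stratified 70:30 node holdouts (types with
a single member go to training with a warning; a type emptied from a test
set is an error), and classifies full-graph embeddings.  Generic- and
specific-edge prediction embed the training graph of each holdout and
featurize edges as the concatenation of endpoint embeddings in canonical
index order.

Classifiers are scikit-learn decision trees and random forests behind a
fixed contract: grid search maximizes inner-CV balanced accuracy (3
stratified folds by default; the original protocol does not state a count),
ties break toward the first-listed grid entry, and everything is
deterministic given the seed.  Default grids are small and standard —
DT: max_depth {5, 10, 20, none} x min_samples_leaf {1, 5, 20};
RF: 100/300 trees x max_depth {10, none} x min_samples_leaf {1, 5} — and
fully overridable; the end-to-end suite uses reduced grids where the full
grid only adds runtime.  Balanced accuracy excludes zero-support classes
with a warning rather than counting them as zero, which would silently
corrupt means; per-class F1 uses the 0 convention when precision + recall
is zero.  A Wilcoxon rank-sum helper is provided for comparing metric
samples across configurations.

## What the benchmarks show — and what they cannot

The suite demonstrates *structural* properties end to end: planted types
are recoverable (top-7 balanced accuracy ≥ 0.9), planted typed edges are
predictable (≥ 0.75 with first-order LINE and a decision tree), the unbiased
pipeline never leaks (FN% = 0.00 across seeds), the biased shortcut leaks
double-digit percentages on dense targets and measurably lowers recall of
true positive edges, and negatives match the positive endpoint-degree
profile (two-sample KS ≤ 0.05).

An SBM carries **no information beyond block membership**: conditional on
the planted types, an edge's presence is independent of everything else, so
within-block link prediction is impossible by design and absolute accuracy
values on real KGs are neither targeted nor reproducible here.  Two
consequences are worth naming.  First, specific-edge accuracy on the preset
is bounded by how well block membership separates positives from sampled
negatives, not by embedding quality.  Second, a 2-D t-SNE of the embeddings
loses essentially nothing on this generator — the cluster map *is* the
signal — so the real-data observation that full embeddings clearly beat 2-D
projections does not transfer to the synthetic benchmark; the suite checks
only that both feature variants are far above chance.  Real KGs additionally
have degree heavy tails within types, transitivity, and ontology-derived
hierarchy, none of which the generator plants.

Problem sizes used by the evaluation suite: the 5,000-node preset for
planted-recovery, degree-matching and leakage checks; the 50,000-node preset
for generation/holdout invariants; 500–600-node focused graphs for the
biased-vs-unbiased contrast, where 5 graph seeds x 3 holdouts give stable
means.

## Known limitations

* Embedding training is single-threaded; at hundreds of thousands of nodes
  the walk corpus and skip-gram pass dominate runtime.
* Walk-window pairs use a fixed window (no word2vec-style window
  subsampling); LINE's sampling schedule follows the canonical method
  description, and any divergence from other implementations' schedules is
  deliberately left as exposed parameters rather than guessed.
* The node-id relabeling invariance of embeddings holds at the level of
  downstream quality, not bitwise, because walk order and RNG consumption
  depend on the dense index.
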