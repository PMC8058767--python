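# Methods

## Model

`dollosa` reconstructs a tumor progression tree from an n × m ternary
single-cell genotype matrix I (0 absent, 1 present, `?`/`2` missing)
under a restricted Dollo-k model: every mutation is gained exactly once;
mutation j may be lost at most k times (loss count c_j ≤ k) and the
whole progression carries at most d losses (Σ_j c_j ≤ d). Dollo-0 is the
perfect phylogeny, Dollo-1 the persistent phylogeny. Biologically, small
k and d encode the observation that back-mutation by deletion happens
but is rare; the d cap also prevents the degenerate use of deletions as
free error correction.

A candidate solution is a rooted tree whose nodes carry gain or loss
labels plus an unlabeled germline root. The root is deliberately
mutation-free so that fully wild-type cells are representable; a
progression whose first event is a single founding mutation is simply a
root with one child. Every loss node must be a strict descendant of its
mutation's gain node, and no two nodes share a label. The genotype
profile D(T, v) marks the mutations gained but not lost on the root → v
path; cells attach to the node whose profile best explains their row.

### Error model and objective

Observed entries are conditionally independent given the corrected
matrix E, with P(I=0|E=1) = α_j (mutation-specific allelic dropout),
P(I=1|E=0) = β (global false positives) and P(I=?|E) = 1 (missing
entries are uninformative). The attachment σ is computed exactly: each
cell scores every node (root, gains and losses alike) and takes the
maximum, with ties broken toward the smallest node id for determinism.
The search objective is the attachment log-likelihood plus a loss-prior
term over the per-mutation loss counts.

Two loss-prior variants are provided because the formulation admits two
readings. The term −c_j·log(1−γ_j) is non-negative and *grows* with
every loss, i.e. it rewards adding deletions until the d cap is hit —
at odds with the premise that losses are rarer than gains. The default
mode therefore uses the standard per-event log-prior penalty
+c_j·log(γ_j), which is ≤ 0 and makes each deletion cost −log γ_j nats;
the reward form remains available as `loss_prior_mode="as-printed"`. Both share the identical
data term, and both are exercised by the test suite. γ_j = 0 declares a
mutation unlosable: in penalty mode any tree that deletes it scores −∞.

With zero-valued rates some entries become impossible (log 0). Scalar
entry likelihoods report −∞ exactly; the vectorized attachment path
substitutes −10¹⁸ per impossible entry so matrix products stay NaN-free,
and a cell whose every attachment falls below −10¹⁷ raises an error
naming the cell (feasible scores are orders of magnitude above this
threshold at any realistic problem size).

## Search

Simulated annealing over four validity-preserving moves:

* **SPR** — prune the subtree at a non-root node u, reattach it under
  any node outside that subtree (root and loss nodes are permitted
  targets; reattaching under the current parent is excluded as a no-op);
* **add deletion** — splice a loss of an ancestral mutation v above u,
  allowed only when c_v < k, total losses < d, and v is not already lost
  on u's root path or inside u's subtree;
* **remove deletion** — delete a loss node, reparenting its children;
* **swap labels** — exchange the mutations of two gain nodes.

Any move that strands a loss (its gain no longer a strict ancestor)
repairs the tree by removing that loss. Proposals draw a move kind
uniformly among the kinds with at least one valid instance, then an
instance uniformly within the kind; pooling all instances instead would
let SPR's O(V²) instances drown out deletion moves. The alternative is a
one-line change inside `propose`.

Cooling is geometric, T_i = T0·(1−cr)^i, with defaults T0 = 10⁴,
cr = 10⁻², Tmin = 10⁻³ and one proposal per temperature step — exactly
1604 proposals per restart. Acceptance is Metropolis, min{e^{Δv/T}, 1}.
Each restart runs an independent chain from a fresh random gain-only
tree (gains attached sequentially to uniformly chosen earlier nodes; no
initial losses, so the start state is valid for any k, d), seeded from
(seed, restart index). The reported tree is the incumbent best across
all restarts, which dominates returning the final state. The default is
3 restarts; because a single 1604-step chain is short relative to the
tree space already at m ≈ 20, accuracy-critical runs should raise it —
the package's own recovery experiments use 20 restarts (~2 minutes at
n = 100, m = 20 on one CPU). Objective evaluation is full recomputation
per proposal (one n × V × m matrix product); incremental updating is a
deliberate non-feature, keeping correctness auditable at desk scale.

## Synthetic data generator

The generator emulates the noisy single-cell protocol end to end and
defines the study conditions for all recovery experiments; defaults are
n = 100 cells, m = 20 mutations, k = 1, d = 3, false-negative rates
α_j ~ Beta(0.3, 0.3), loss priors γ_j ~ Triangular(0, 0.05, 0.1),
false-positive rate 10⁻⁵, 1% missing entries. Beta shapes below one
give the strongly bimodal dropout profile seen in scRNA-seq mutation
calls (spikes near 0.1 and 0.9); the triangular prior is the standard
choice when only a mode and bounds are defensible and makes a loss fire
for roughly one mutation in twenty.

Generation order is fixed and documented: (1) random recursive gain
tree; (2) per mutation j, with probability γ_j one loss is planted at a
location chosen uniformly among placements that keep the tree valid
within k and d (mutations whose gain has no descendants, or whose
trigger fires after the d budget is exhausted, stay unlost); (3) cells
attach uniformly at random over all nodes; (4) per entry, missingness
first (probability `missing_rate`), then 1→0 flips with α_j and 0→1
flips with the false-positive rate on the surviving entries. Flips are
logged exactly, giving the ground truth for the flip-parsimony metric.
Missing-before-flip matters: it makes P(observed 0 | true 1) equal to
(1−q)·α_j rather than α_j·(1−q) + cross terms, and is regression-tested.

What the generator does not emulate: doublet captures, per-cell error
rates, read-count/coverage structure, and clone-size skew (cells attach
uniformly, real clones are far from uniform). Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
declared error model, not robustness to artifacts outside it.

## Evaluation

Ancestor–descendant accuracy is the fraction of ordered gain pairs
(p ancestor of q) in the truth that keep that relation in the inference;
different-lineage accuracy is the analogue for unordered pairs on
separate branches. Both are defined over gain nodes only — loss
placement can be non-identifiable (two losses on sibling branches can be
label-swapped without changing any profile), so losses are excluded from
pair relations; same-node pairs cannot arise since gains are unique.
The false-negative-rate estimator for mutation j is the observed-0
fraction among cells whose corrected genotype carries j (0 when no such
cell exists) — the published evaluations score this quantity without
defining an estimator, so this maximum-likelihood ratio is the package's
choice. The three-gamete conflict counter reports column pairs
exhibiting all of (1,0), (0,1), (1,1), with missing entries treated as
compatible with anything (standard incomplete-perfect-phylogeny
practice).

A practical caveat quantified in the worked example: under
Beta(0.3, 0.3) dropout, mutations with α_j above ~0.7 are close to
unobservable, and ancestor–descendant pairs involving them are
unrecoverable in principle; unrestricted AD accuracy then reflects the
rate profile as much as the search. Under homogeneous α = 0.1 the
recovery experiments reach mean AD ≈ 0.96 and DL ≈ 0.99 over ten seeds.

## Display post-processing

Two transformations affect only how a tree is drawn. Simple-path
collapse merges every non-root unary node with its child, concatenating
label lists (idempotent; the root may stay unary so the germline state
remains visible). Low-support collapse merges any node whose support
s_i — the share of its parent's informative subtree cells falling under
it — is below a threshold into its parent. The denominator is taken
over the parent's subtree, the only choice that keeps s_i in [0,1].
Merges proceed deepest-first with supports recomputed after each merge,
making the operation deterministic and confluent; nodes with a
zero-count denominator get support 1 so structure carrying no cells is
never silently deleted. Both transformations preserve the multiset of
mutation labels and the total cell count, and both are property-tested
for idempotence/fixpoint behavior.

## Numerical and interface conventions

* Matrix files are whitespace-separated over {0, 1, 2, ?}; `2` and `?`
  both mean missing; a transpose switch handles mutations-as-rows
  layouts; labels come from optional side files, one name per line.
* All node/cell/mutation indices are 0-based internally; rendered output
  uses user-supplied names.
* Trees are written as Graphviz DOT with loss nodes styled red and k, d
  recorded as graph attributes; the bundled reader parses exactly this
  emitted subset (used by `dollosa score` and `dollosa viz`).
* Every stochastic component takes an explicit seed or generator;
  identical seeds give bit-identical traces, rate draws and datasets.

## Problem sizes used by the test suite

Exhaustive-enumeration checks run at 4 mutations / 8 cells / k = d = 1
(≈5 700 trees per instance); attachment exactness at 5 mutations over
1000 random tree/row instances; recovery at n = 100, m = 20 over 10
seeds; rate-estimation consistency at n = 500 over 5 seeds; move closure
over 10⁴ proposals. These sizes were chosen so the full suite completes
in a few minutes while each check still exercises the regime it is
about.
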