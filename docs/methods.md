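# Methods

## Model

A directed network G(A) with n nodes stands for the structure of a linear
system x′ = A·x + B·u. Structural controllability asks whether some choice of
nonzero weights makes the Kalman matrix Q_C = [B, AB, …, A^{n−1}B] reach rank
n. The combinatorial reduction used throughout: a maximum matching M of the
digraph — computed on the bipartite split graph where each node v becomes an
out-copy v⁺ and an in-copy v⁻ and a link (u, w) becomes the edge (u⁺, w⁻) —
leaves n − |M| nodes with unmatched in-copies; those are the driver nodes
(N_D = max{n − |M|, 1}; a perfectly matched network still needs one input,
assigned by convention to the lexicographically smallest node). Matched links
give each node at most one successor and one predecessor, so they decompose
the node set into stems (chains starting at drivers) and cycles: the control
paths.

Because maximum matchings are rarely unique, control paths are pooled:
the link-swap random walk starts from one maximum matching, removes a
uniformly chosen matched link, enumerates every maximum matching containing
the remaining links (the removed link's alternative completions: after
deletion exactly one tail and one head are free, so completions are the
network links joining a free tail to a free head), and hops to one uniformly.
Every visited matching is recorded, repeats included. The union of
control-path covers over the collection is the diversified set, and a node's
perturbation influence Pi_i is the union over covers of the nodes reachable
from i along matched links. Pi_i never contains i itself, even when a cycle
returns to it: influence is strictly downstream.

### Known limitation of the single walk

A perfect matching has no alternative completion besides itself, so on dense
networks the walk can freeze in its initial state, and more generally
single-link swaps need not connect all maximum matchings. The package
therefore exposes multi-restart sampling (`sample_mmsets_multistart`,
default 10 walks from differently seeded initial matchings). On sparse
networks — the density regime of curated regulatory maps, about one link per
node — the restarted sampler empirically recovers the exhaustive MMSet set
on every random instance tried (200 instances, ≤ 8 nodes, budget 200·K);
a dedicated test documents the dense-graph freeze. Exhaustive enumeration
(`enumerate_all_mmsets`, backtracking with endpoint-disjointness pruning) is
available up to 20 links as ground truth.

## Similarity and scoring

Term similarity follows Wang's semantic contributions: within a term's
ancestor closure, S(term) = 1 and S(ancestor) = max over closure children of
w_rel·S(child), with contribution factors w(is_a) = 0.8 and
w(part_of) = 0.6 (the method's published defaults; configurable). Two terms
score the summed S-values of shared ancestors over their total semantic
values. Gene similarity is the best-match average over the two annotation
sets; cross-namespace term pairs contribute 0 and unannotated genes score 0
with a logged warning. Set similarity builds the grid of pairwise gene
similarities between two influence sets and returns the **sum** of weights
of a maximum-weight bipartite matching (scipy's assignment solver, which
handles rectangular grids directly). The sum is intentionally unnormalized —
large coherent influence sets should outrank small ones; a normalized
variant (divide by the larger set size) exists but is off by default.

A candidate's disease score is its best set-similarity against any known
disease gene's influence. Ranking is by descending score with ties given the
mean of the tied positions (deterministic and unbiased; integer ranks appear
whenever scores are distinct).

## Cross-validation

LOO-CV withholds each association (d, g), scores g against X_d∖{g}, and ranks
it among all annotated network genes minus the training genes (a pool mode
keeping training genes is available). Recall-at-k% is the fraction of trials
with rank ≤ k%·pool over k = 1..100. k-fold CV partitions associations into
seeded random folds and summarizes ranks by the rank-sum AUC: per trial, the
fraction of pool negatives ranked below the withheld positive (mean ranks
make this the mid-rank Mann–Whitney estimate), averaged over trials.
Perturbation profiles are computed once per network and reused across
trials, since influence does not depend on disease labels.

## Stability (SPi)

SPi at removal fraction f deletes ⌊f·|L|⌋ links uniformly without
replacement, recomputes influence on the reduced network with the same
sampling budget, and averages per-node Jaccard overlap between old and new
influence sets; 0/0 counts as 1 (a node that influenced nothing is perfectly
stable — this inflates SPi on sparse networks and is the declared
convention). Nodes are never removed. Each of the (default 20) repetitions
draws its removal set from a counter-derived seed, while the MMSet walk
reuses the baseline's seed: a paired design under which SPi(0) = 1 exactly
and removal effects are not confounded with sampling noise.

## Kalman oracle and cactus verification

For systems of at most 12 nodes, `kalman_rank_oracle` draws independent
uniform [0.5, 1.5] weights on the nonzero structure of A and B, builds Q_C,
and tests rank n with a singular-value cutoff of 1e-9 relative to the largest
singular value, over 5 trials (generic rank is attained almost surely; trials
guard degenerate draws). `cactus_system` turns a matching into the system
whose A-structure is the matched links with inputs at the drivers; since a
cycle in the cover receives no link from any stem, each cycle also gets an
input at its smallest node, making the full cover controllable. Verification
note: deleting a matched *stem* link always breaks controllability (the
link's head loses its only access), but deleting the link that closes a
cycle into that cycle's input node degrades the bud to a stem, which remains
controllable — so the "any deletion breaks it" property is exact only for
stem-only covers, and the tests draw such instances.

## Synthetic data

`generate_network` produces seeded simple digraphs (uniform link placement,
or preferential attachment on out-degree for hub-dominated regulatory-map
topology); `generate_ontology` builds an is_a tree of configurable depth and
branching with part_of cross-links on 10% of terms, always toward shallower
levels (acyclic by construction).

`generate_disease_benchmark` plants the structure the scoring model assumes.
Per disease: a fresh chain of `module_size` nodes (every chain link has a
unique tail and head, hence belongs to every maximum matching) and
`genes_per_disease` fresh disease genes, each with a single out-link into the
chain head and no in-links. Exactly one disease gene's link into the head is
matched in any maximum matching, and the alternative completions at that link
swap in the others — so the diversified influence of every planted gene is
precisely the module. Disease genes have no in-links so that no background
gene's influence swallows a module wholesale, which would tie it with the
planted genes under the unnormalized score. Module and disease genes draw
`terms_per_gene = 3` annotations from one is_a subtree per disease with an
off-branch noise fraction of 0.2 (informative but not degenerate);
background genes draw uniformly from all terms.

Defaults — 160 background nodes at mean out-degree 2.5, 6 diseases × 3
genes, module size 4, ontology depth 4 / branching 3 — were chosen once so
that the full pipeline (sampling, influence, LOO and k-fold CV) runs in
seconds while the candidate pool stays nontrivial (~200 genes, 18
associations). Construction is verified post hoc with the actual sampling
machinery (default 150 samples × 20 restarts, escalated 4× once if needed;
many short restarts cover the competing module-head links far better than
one long walk), never by assuming a particular matching; generation raises
if any planted gene misses its module.

What the benchmark does *not* emulate: real degree-sequence detail,
feedback-rich signaling loops, annotation bias and shallow/incomplete GO
coverage, overlapping disease modules, or indirect (unmatched-path) disease
mechanisms. Passing tests show the machinery recovers structure of the kind
the model assumes; they do not certify recall on real interactomes.

## Numerical and degenerate-input conventions

- Parallel edges collapse (simple-digraph semantics); self-loops are legal
  and matchable. An undirected edge whose reverse already exists contributes
  only the missing direction.
- Empty networks: the empty matching is the unique MMSet; all influence sets
  are empty; every node is a driver.
- Ties in ranking use mean ranks; the AUC uses mid-ranks, so the two are
  consistent under ties.
- All samplers take explicit integer seeds; identical seeds give bit-identical
  collections, profiles, folds and SPi values.
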