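# Methods

## Problem and data model

The input is a set of k ≥ 2 unweighted undirected PPI networks
G_i = (V_i, E_i) with pairwise-disjoint vertex sets (raw protein ids are
namespaced `network::id` on ingest if they collide), plus a sparse
similarity map sim on cross-network protein pairs. sim is identically 0
inside a network, absent pairs are 0, and only positive scores are stored.
An *alignment* is a set of mutually disjoint match-sets, each with ≥ 2
proteins (any number per network); proteins in no match-set are uncovered.

Two score constructions are provided, both consumed from pre-computed
tables (the package never runs BLAST or Pfam):

* `normalize_blast(xy, xx, yy) = xy / sqrt(xx·yy)` — bit score normalized
  by the geometric mean of the self bit scores, in [0, 1] and
  length-independent;
* `domain_similarity(a, b) = Σ_{d ∈ D} (−ln PV(a,d) − ln PV(b,d))` over
  shared Pfam domains D, 0 when none are shared.

## Pipeline

**Preprocessing.** For each stored pair (v_a, v_b), neighbors of v_a and
v_b are greedily paired: repeatedly take the unused neighbor pair of
maximal similarity and add its score, until either side is exhausted
(zero-similarity pairs are skipped — they contribute nothing). The extra
score is capped at the original score, so the preprocessed score lies in
[original, 2·original] and the support of the matrix never grows. The
greedy rule is implemented exactly as specified (it is *not* replaced by
optimal bipartite matching, which would choose differently in general).
Tie-breaks use the lexicographically smallest unordered pair, which makes
the extra score symmetric and runs reproducible.

**Decision vs. reported scores.** All decisions — clustering, the seed
threshold τ, queue priorities, the merge criterion — use the preprocessed
matrix when preprocessing is enabled. All reported metrics use the raw
matrix. This split is forced by the worked example: expansion order
follows the preprocessed scores while the final average similarity (85/3)
is computed from raw scores.

**Clustering (stage 1).** Proteins with no nonzero similarity are
excluded; the rest are clustered agglomeratively under I1 (default) or I2
into m = max(1, ⌊n_sim/k⌋) clusters (overridable). Each step merges the
connected cluster pair with the greatest criterion gain; gains are
maintained via cross-cluster similarity sums and may go negative near the
end. When no connected pair remains, the two lexicographically smallest
clusters merge. Criterion sums run over unordered distinct pairs — this
convention reproduces the worked example's clustering, whereas
ordered-pair sums would merely double every term. The original
experiments used an external clustering tool with the same criterion
functions; this package re-implements greedy optimization of the criteria
directly, so merge schedules may differ from that tool away from the
validated fixtures.

**Seeding (stage 2).** Every within-cluster cross-network pair with
decision score ≥ τ (inclusive) becomes a seed. Seed count is
non-increasing in τ.

**Expansion and merging (stages 3–4).** Every protein starts as a
singleton match-set with an `aligned` flag set to false. Phase 1 pushes
all seeds keyed by decision score and offers each popped pair to the
merge criterion (return value ignored), so overlapping seeds coalesce
into multi-network seed sets. Phase 2 enqueues, for every multi-member
match-set and every cross-network member pair (v_i, v_j), all
cross-network pairs from N(v_i) × N(v_j), where N(v) is the set of
not-yet-aligned neighbors of v; each successful merge enqueues the new
pair's unaligned neighbors in turn. Queue entries are validated at pop
time: pairs already co-located or with a since-aligned endpoint are
skipped. Match-sets still singleton after stage 3 are dropped from the
alignment only at the end; stage 4 sorts all pairs of still-unaligned
proteins with positive decision score in descending order and offers each
to the merge criterion, so chains of stage-4 merges can build
multi-network match-sets.

**Merge criterion.** Merging S(v_i) and S(v_j) requires, in order:

1. size gate — |S(v_i)| + |S(v_j)| ≤ ω · |Net(S(v_i) ∪ S(v_j))|;
2. maxSim > 0, where maxSim is the maximal decision score over all pairs
   in the union (within-network pairs contribute 0);
3. count · expandRatio ≥ |S(v_i)| · |S(v_j)| · ρ, where count is the
   number of cross-set pairs scoring strictly above maxSim·β and
   expandRatio = |Net(union)| / max(|Net(S(v_i))|, |Net(S(v_j))|).

Exception: during stage 3 two *singleton* sets that pass the size gate
merge unconditionally (flag `merge_zero_sim_singletons`, on by default).
Gate 2 taken literally would contradict both the rule that two singletons
always merge and the worked example's no-preprocessing alignment, which
pairs (A3, B2) at similarity 0 because topology demands it; stage 4 keeps
the strict positive-score requirement, which is explicit for that stage.
Consequences worth knowing: since within-network similarities are 0 and
β > 0, gate 3 caps match-sets at one-to-one pairs whenever ρ > 0.5 and
k = 2 (pairwise mode), which the tests assert.

**Tie-breaks.** The priority queue orders by decision score; batches are
pushed in lexicographic order and equal priorities pop last-in-first-out
("lex-LIFO"). Ties are only consequential among zero-score pairs, where
the worked example's exact no-preprocessing composition (score 80/3)
depends on the rule; its conserved-edge count (2) does not.

## Parameters

| name | default | meaning |
|------|---------|---------|
| τ | — (per run) | seed threshold, in score units (so [0,1]-ish for nBLAST, tens-to-hundreds for bit or domain scores) |
| β | 0.1 | fraction of maxSim a cross-set pair must exceed to count as similar |
| ρ | 0.5 | demanded density of similar cross-set pairs; > 0.5 with k = 2 forces pairwise mode |
| ω | 2.5 | max proteins per spanned network in a match-set (suggested 1.5–2.5) |
| criterion | i1 | clustering criterion; i1 empirically yields higher average similarity than i2 |

Defaults (β, ρ, ω) = (0.1, 0.5, 2.5) are the method's stock settings; the
worked example uses ρ = 0.6 to run in pairwise mode.

## Metrics

Weighted average similarity Σ|S_i|·sim(S_i) / Σ|S_i| with
sim(S_i) = (pair-sum) / C(|S_i|, 2); conserved edges (an edge is conserved
if it maps onto an edge of another network under the alignment, or both
endpoints share a match-set); strictly conserved edges (a conserved edge
with a witness whose two endpoint similarities are positive — one witness
suffices); coverage; conserved edge rate = conserved / edges with both
endpoints covered. GO enrichment uses the upper-tail hypergeometric
p-value with background N = total proteins of all networks (unannotated
proteins count in N − M), a fixed cut of 1e-4 and no multiple-testing
correction. The Hungarian baseline maximizes *total* one-to-one
similarity via `scipy.optimize.linear_sum_assignment`; note that after
dropping zero-score matches its *weighted average* is not necessarily
maximal among all partial matchings — optimality claims and tests are
about the total.

## Synthetic data

`generate_planted(k, n0, p_edge, p_del, sim_signal, sim_noise, seed)`
copies an Erdős–Rényi ancestor G(n0, p_edge) into k networks, deleting
each edge copy independently with probability p_del (all vertices are
kept); same-ancestor cross-network pairs get score `sim_signal`
(optionally jittered), and spurious pairs appear at rate
`sim_noise = (rate, max)` with scores uniform on (0, max]. Defaults —
k = 2, n0 = 50, p_edge = 0.1, p_del = 0.1, signal 100, noise (0.01, 30) —
give sparse graphs of realistic density (mean degree ≈ 5) with a clear
but not degenerate signal/noise margin (spurious scores reach 30% of the
signal). The generator emulates exactly what the aligner assumes — sparse
topology plus block-sparse similarity — and none of what real
interactomes add (heavy-tailed degrees, gene duplication, correlated
noise, assay bias), so recovery results on it demonstrate correctness of
the machinery, not expected field performance. Tests measure
precision/recall/F1 of aligned cross-network pairs against the planted
groups over fixed 10-seed ensembles; full-scale multi-species database
benchmarks are out of desk scope and are replaced by brute-force oracle
equivalence suites (conserved-edge counting, hypergeometric tails,
per-step clustering optimality, Hungarian totals) on hundreds of small
random instances.

## Numerical and degenerate-input choices

* Duplicate similarity rows keep the maximum (BLAST tables often contain
  both orientations); within-network and zero rows are dropped with
  logged counts; unknown proteins warn-and-drop by default, raise in
  strict mode.
* Self-loops are dropped on ingest; the conserved-edge conditions never
  involve them.
* Empty similarity matrix → "no alignable proteins" error; m larger than
  the protein count → all singletons with a warning; empty alignments are
  valid metric inputs except for the average similarity (undefined, and
  an error).
* The hypergeometric tail is computed by `scipy.stats.hypergeom.sf`
  (log-space internally); exhaustive combinatorial sums verify it for all
  parameter tuples with N ≤ 25.
* Everything is deterministic: no stage draws random numbers, and all
  order-dependence is pinned by the documented lexicographic/LIFO
  tie-breaks (the `random_seed` parameter is reserved for future
  stochastic variants and is threaded through but unused).

## Problem sizes

The packaged test and acceptance workloads run on the 7-protein worked
example, random instances of ≤ 30 proteins for oracle suites, and planted
instances of 100–160 proteins for recovery; the algorithm itself is the
O(n² log n) clustering-dominated procedure and preprocessing/clustering
are shared across a τ-sweep, so the same code path scales to
database-sized inputs.

## Known limitations

* The agglomerative schedule is greedy per-merge; it is not guaranteed to
  maximize I1/I2 globally (only stepwise optimality is asserted).
* Stage 3's unconditional singleton-singleton merge can pair proteins
  with zero sequence similarity when topology suggests it; disable
  `merge_zero_sim_singletons` for strictly similarity-gated behavior.
* Edge weights/confidences, GO ontology structure (terms are opaque
  strings) and constrained alignments are unsupported.
* With colliding raw ids across input files, output files use the
  namespaced `network::id` form.
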