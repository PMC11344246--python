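# Methods

This note documents the models, conventions and numerical choices behind
`targetforest`, the defaults and why they were chosen, and what the
synthetic validation does and does not demonstrate.

## Differential co-expression network

Per cohort the adjacency is the soft-thresholded Pearson correlation,
`a_ij = |r_ij|^β` with β = 10 by default. We use the unsigned convention
(the weighted-correlation-network default); a signed variant
`((1 + r)/2)^β` is available via `signed_adjacency` for analyses where the
direction of co-expression matters. Genes with constant expression have
undefined correlations; their adjacencies are set to 0 with a warning and
the genes are flagged rather than dropped, preserving index alignment.

The per-edge differential statistic is `d_ij = |a_case,ij − a_control,ij|`,
which is bounded in [0, 1] and feeds the exact cost transform
`c_ij = 1 − d_ij`. A per-node connectivity-difference variant of the
differential statistic is a recognised alternative; we chose the per-edge
form because the cost transform operates per edge and requires values in
[0, 1]. The differential network keeps all gene pairs by default
(`d_floor = 0`): edge selection is the physical-interaction filter's job,
not a weight threshold's. The filter retains exactly the edges whose
unordered pair carries a case-insensitive "physical interaction" annotation
and is idempotent; analysis then proceeds on the largest connected
component (ties broken by lexicographically smallest member, for
determinism).

Betweenness centrality is computed unnormalized on unweighted shortest
paths; a cost-weighted mode exists (`weighted_betweenness`) but unweighted
is the default because hop-count brokerage is the more robust notion when
most costs are close to 1 (see "Cost concentration" below).

## Variant prizes

The default prize is the per-gene deleterious-mutation frequency: the
fraction of cohort patients with at least one deleterious variant in the
gene. Duplicate (gene, patient) pairs count once; non-deleterious records
never contribute. Frequency is scale-free and bounded in [0, 1], which
makes the prize/cost balance interpretable; `binary` and `count` schemes
are provided, and all three share the same support, so the Direct/Indirect
evidence partition (prize > 0 vs prize = 0) is scheme-invariant.

## Prize-collecting Steiner forest

The objective is the standard prize-collecting form

    f(F) = Σ_{v∈F} b·p_v − Σ_{e∈F} c_e − ω·κ(F),

maximized over forests, with the empty forest (f = 0) admissible and
isolated selected nodes counting as trees. ω defaults to 0.5 at the solver
level (mid-range of the [0, 1] cost scale) and b to 1; both are exposed
everywhere.

**Heuristic.** The solver follows the classic primal–dual moat-growth
scheme on the virtual-root transformation (a root joined to every node at
cost ω): clusters not containing the root grow uniform duals until an edge
goes tight (clusters merge, the edge enters the tentative forest) or a
cluster's prize potential is exhausted (it deactivates). Each resulting
tree is then strongly pruned — a rerooting dynamic program finds the
maximum-net-worth subtree — and kept only if its pruned worth exceeds ω.
Finally a deterministic greedy local search polishes the forest with
single-step moves (add/drop a node, merge/split trees, swap a cycle edge,
reroute around a degree-2 node, and two-step attach/bridge moves through an
outside node). The local search is a standard polish for primal-dual PCSF
heuristics; every move is objective-improving, so the heuristic's objective
can only approach the optimum from below. On random 8-node instances it
reproduces the enumerated optimum in ≥ 99% of cases (measured by the
acceptance script) and by construction never exceeds it.

**Exact oracle.** For small instances the optimum is found by scanning all
node subsets: for a fixed selected set S the cheapest forest covering S is
the minimum spanning tree of S plus the virtual root (each root edge
represents one tree's ω penalty), so 2^|S| MST computations enumerate the
exact optimum. Ties are broken towards the lexicographically smallest node
set then edge set. The oracle is guarded to ≤ 16 nodes / ≤ 20 edges and
exists for testing, not production use.

**Randomized bootstrap.** Each of `n_runs` (default 50) runs multiplies
every edge cost by `1 + u`, `u ~ U(−noise, +noise)` (default noise 0.1,
i.e. 10%), with the generator seeded by (master seed, run index) so runs
are reproducible and independent. Occurrences count per-node membership
across run solutions. The union of run forests can contain cycles; each
union component is reduced to its minimum spanning tree under the original
costs, restoring the property that every reported subgraph is a tree.
Multiplicative noise below 100% can never make costs negative.

## Structural druggability

`drug_score = max(pocket scores)` if strictly more than 40% of the
sequence is structurally modelled and at least one pocket was detected,
else 0. The 40% boundary itself fails (literal strict reading; the
threshold is configurable in the code). Structure coverage is the union of
modelled residue intervals (1-based inclusive, clipped, overlaps counted
once) divided by sequence length. Pocket detection is an external tool:
the module parses fPocket per-structure info text ("Pocket N :" blocks
with a "Druggability Score" line) or consumes precomputed tables; when a
protein has several structures, the intended aggregation is best coverage
first, then the best pocket score among coverage-passing structures.

## Rank product

Each metric (betweenness, occurrences, drug score) is ranked 1..N with the
largest value receiving rank N and tied values sharing the minimum rank of
their block. The combined score is the geometric mean of the three ranks —
the conventional rank-product statistic — so it is invariant under any
strictly increasing transform of a whole metric column; an arithmetic-mean
variant sits behind `rank_combine="arithmetic"`. The ranking universe
defaults to the PCSF union node set (occurrences and cluster membership are
defined there); `ranking_universe="network"` ranks the whole differential
network instead, with absent proteins scoring 0 occurrences and 0 drug
score. The test suite cross-checks the convention against a published
reference target table: every printed rank product must be attainable as
the geometric mean of an integer rank triple in [1, 85]³, and metric-wise
dominance between rows must never invert the rank-product order.

## Synthetic study generator

Planted co-expression uses a single latent factor per module:
`x = sqrt(ρ)·f + sqrt(1−ρ)·ε`, giving exact pairwise correlation ρ in
expectation. Defaults: 300 genes; six modules of eight genes, of which
three are differential (ρ = 0.8 in the case cohort, 0.0 in the control)
and three are shared (ρ = 0.5 in both); remaining genes are independent
noise; 40 case and 40 control samples. PPI annotations cover within-module
pairs with probability 0.9 (10% of those carry only non-physical labels,
to exercise the filter) and background pairs sparsely at 0.01, which also
supplies the inter-module connectivity a real curated PPI network has.
Variants hit differential-module genes at rate 0.3 per patient and
background genes at 0.02, over 40 patients. Druggability assigns 18.4% of
proteins no structure at all; differential-module genes outside that pool
form the planted druggable set (coverage U(0.5, 1), best pocket
U(0.7, 1)), and other structured proteins draw coverage U(0, 1) and
pockets U(0, 0.5). The planted target set is the intersection of the
differential genes with the druggable set, restricted to genes mutated or
physically adjacent to a mutated gene — the adjacency clause keeps the
Steiner/Indirect discovery route meaningful. Every generator is
deterministic given the master seed; per-generator streams are salted so
the same seed can drive all of them without coupling.

**Pipeline prize scale.** With frequency prizes (≤ 1, typically ≈ 0.3
under the default mutation rate) and costs near 1 − d ≈ 0.9 on even the
rewired edges, a unit prize scale would make every non-empty forest
negative and PCSF would always return the empty forest. The pipeline
therefore defaults to `prize_scale = 5`, chosen a priori so that a typical
planted terminal's scaled prize (≈ 1.5) covers an edge plus a share of ω —
the usual way PCSF prize scaling is calibrated against the cost scale. The
solver-level default remains b = 1.

**Cost concentration.** Because β = 10 crushes moderate correlations, the
synthetic differential costs concentrate near 1 (planted edges ≈ 0.65–0.95,
background ≈ 1.0). With ω = 0.5 below every edge cost, the optimal forest
keeps each selected gene as its own tree, so the synthetic subgraph-size
distribution is singleton-heavy — unlike a real study where strong
rewiring produces low-cost edges and multi-protein trees. Raising ω above
the within-module cost (or lowering β) produces larger trees; both are
plain config changes. Steiner-node recruitment does occur whenever two
terminals' connection cost is below ω (see the solver tests and examples).

## Validation scope

The planted-target recovery test runs the full pipeline at the defaults
above over ten seeds and requires the median final rank of the planted
targets to land in the top 20% of the ranking universe in at least eight.
Recovery is evaluated with the full-network ranking universe: the PCSF
union universe consists mostly of the recovered targets themselves, so a
median-within-universe criterion would measure set geometry rather than
recovery. Problem sizes in the tests (300 genes, 50 bootstraps, 10 seeds;
200 random instances against the exact oracle) were chosen so the entire
suite completes in a few minutes on one core.

What passing these tests shows: the statistical machinery (soft
thresholding, differential weighting, PCSF optimization, bootstrap
robustness, the scoring rules and their integration) behaves correctly and
recovers a planted signal of realistic effect size. What it does not show:
performance on real RNA-seq (library-size effects, count dispersion and
normalisation artefacts are not simulated), robustness to PPI curation
bias, or the biological validity of any specific target. The generator
emulates already-normalized expression; upstream alignment and
normalisation are out of scope, as are homology modelling and pocket
detection themselves (their outputs are inputs here).

## Degenerate inputs and numerical conventions

- Floating-point comparisons in the solvers use an absolute tolerance of
  1e-12; the forest invariant |E| = |V| − κ is enforced exactly.
- `d + cost = 1` holds exactly (the cost is computed as `1 − d`, never
  re-derived).
- Empty graphs, empty annotation sets, noise = 0 bootstraps and
  zero-variance metrics warn or raise with explicit messages rather than
  propagating NaNs.
- All orderings (component lists, tie-breaks, table sort) are
  deterministic: size-descending then lexicographic, and rank-product
  descending then gene id.
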