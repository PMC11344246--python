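# targetforest

Network bioinformatics for discovering structurally druggable protein
targets from case-vs-control tumour cohorts. Given two normalized
expression matrices (e.g. mucinous ovarian carcinoma vs benign mucinous
tumours), a curated protein–protein interaction annotation table, a somatic
deleterious-variant table and per-protein structural druggability data,
`targetforest` produces a ranked target table and the prize-collecting
Steiner forest (PCSF) subgraph decomposition behind it.

## Method

1. **Differential co-expression network.** Per cohort, the Pearson
   correlation adjacency is soft-thresholded, `a_ij = |r_ij|^β` (default
   β = 10). The per-edge differential weight is `d_ij = |a_case − a_control|`
   and each edge carries the PCSF cost `c_ij = 1 − d_ij`, so strongly
   rewired gene pairs are cheap to include. Edges are kept only when the
   curated PPI table annotates the pair as a *physical interaction*, and the
   analysis proceeds on the largest connected component.
2. **Variant prizes.** Each gene's node prize is its deleterious somatic
   mutation frequency across the tumour cohort (binary and raw-count schemes
   are available). Genes with a positive prize carry *Direct* genomic
   evidence; genes recruited purely through connectivity are *Indirect*.
3. **PCSF.** A forest F maximizing
   `f(F) = Σ_{v∈F} b·p_v − Σ_{e∈F} c_e − ω·κ(F)` is sought (κ = number of
   trees, ω the per-tree penalty, b the prize scale). The solver is a
   Goemans–Williamson-style primal–dual heuristic with strong pruning and a
   greedy local-search polish; an exact enumeration solver doubles as a test
   oracle on small instances. The solver is rerun 50 times with 10%
   multiplicative edge-cost noise; per-protein *occurrences* count the runs
   selecting it, and the union of runs is reduced per component to its
   minimum spanning tree under the original costs.
4. **Structural druggability.** A protein scores the best per-pocket
   druggability value reported by pocket detection (fPocket output is
   parsed directly), gated by strictly more than 40% of its sequence being
   structurally modelled; otherwise it scores 0.
5. **Rank product.** Betweenness centrality in the differential network,
   PCSF occurrences and drug scores are each ranked 1..N (largest value →
   rank N; ties share the minimum rank of their block) and combined as the
   geometric mean, `RP = (r_btw · r_drug · r_occ)^(1/3)`; larger is more
   important.

A fully synthetic study generator (`targetforest.synthetic`) plants
cohort-specific co-expression modules, module-enriched deleterious
mutations, mixed-type PPI annotations and druggability with a no-structure
fraction, together with the ground-truth target set, so the whole pipeline
can be exercised and validated without controlled-access data.

## Worked example

```bash
python examples/04_full_pipeline.py
```

runs every stage on the default synthetic study (300 genes, three
differential modules of eight genes, 40+40 samples, 50 PCSF bootstraps at
10% noise) and prints, for seed 1:

```
genes in                 : 300
differential edges       : 44850
physical edges kept      : 579
largest component        : 285 nodes / 578 edges
PCSF proteins (union)    : 24
PCSF subgraphs           : 24
...
planted targets            : 18
their rank positions       : [1, 2, ..., 18]
median position            : 9.5 of 285 (top 3.3%)
```

The 18 planted targets (rewired + druggable + mutation-reachable genes)
occupy the top 18 positions of the 285-protein ranking — the pipeline
recovers exactly the genes it was designed to find. The other examples
demonstrate the differential network construction, the PCSF solvers with
Steiner-node recruitment, and the druggability/rank-product rules on small
hand-built inputs.

A thin CLI mirrors the stages (`targetforest simulate | adjacency | diffnet
| prizes | pcsf | drugscore | run | report`); `targetforest run --config
cfg.yaml` executes the full pipeline from a flat YAML config whose defaults
are the published analysis settings.

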