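"""Structural druggability scoring and rank-product prioritisation.

Parses pocket-detection output, applies the >40% structure-coverage gate,
and combines betweenness, bootstrap occurrences and drug scores into a
rank-product ordering on a small hand-built example.
"""

from targetforest.druggability import (
    DruggabilityRecord,
    drug_score,
    parse_fpocket_info,
    structure_coverage,
)
from targetforest.pcsf import OccurrenceTable, PCSFSolution
from targetforest.prizes import PrizeMap
from targetforest.ranking import assemble_rank_table

FPOCKET_TEXT = """\
Pocket 1 :
\tDruggability Score : \t0.21
Pocket 2 :
\tDruggability Score : \t0.88
"""

pockets = parse_fpocket_info(FPOCKET_TEXT)
cov = structure_coverage(500, [(1, 180), (150, 320)])
print(f"pocket scores         : {pockets}")
print(f"coverage (union)      : {cov:.3f}")
print(f"drug score            : {drug_score(cov, pockets)}  (best pocket, gate passed)")
print(f"gate at exactly 40%   : {drug_score(0.40, pockets)}  (strictly >40% required)")

sol = PCSFSolution(
    nodes={"CDK1", "STK11", "DEAF1"}, edges={("CDK1", "STK11")}, objective=1.0,
    node_types={"CDK1": "Steiner", "STK11": "Terminal", "DEAF1": "Terminal"},
)
table = assemble_rank_table(
    betweenness_map={"CDK1": 28660.0, "STK11": 48426.0, "DEAF1": 6916.0},
    druggability_records=[
        DruggabilityRecord("CDK1", 297, 290, [0.81]),
        DruggabilityRecord("STK11", 433, 400, [0.95]),
        DruggabilityRecord("DEAF1", 565, 300, [0.65]),
    ],
    occurrences=OccurrenceTable({"CDK1": 41, "STK11": 50, "DEAF1": 50}, 50, 0.1, 0),
    pcsf_solution=sol,
    prize_map=PrizeMap({"STK11": 0.16, "DEAF1": 0.1}, cohort_size=31),
)
print()
print(table[["gene", "rank_betweenness", "rank_drug", "rank_occurrences",
             "rank_product", "type", "evidence"]].to_string(index=False))
print()
print("Each metric is ranked 1..N (largest value -> rank N, ties take the")
print("minimum rank); the rank product is their geometric mean, so a high")
print("score needs a protein to do well on topology AND druggability.")
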