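"""Small reference datasets bundled with the package.

``MOC_TOP_TARGETS`` is the published top-ranked druggable-target table for
mucinous ovarian carcinoma produced by this style of analysis (betweenness
in the differential interaction network, fPocket drug score, occurrences out
of 50 PCSF bootstraps, combined rank product over a ranking universe of
N = 85 proteins in 19 subgraphs). It is used by the test suite as an
external consistency check of the rank-product convention: every printed
rank product must be realisable as the geometric mean of an integer rank
triple in [1, N]^3, and a row that dominates another on all three metrics
must not carry a smaller rank product.
"""

from __future__ import annotations

import pandas as pd

MOC_UNIVERSE_SIZE = 85
MOC_N_SUBGRAPHS = 19
MOC_BOOTSTRAP_RUNS = 50

_TOP_TARGET_ROWS = [
    # uniprot, gene, betweenness, drug_score, occurrences, rank_product, type, cluster, evidence
    ("Q15831", "STK11", 48426, 0.95, 50, 70.97, "Steiner", 8, "Indirect"),
    ("O43663", "PRC1", 1618, 0.97, 50, 64.97, "Terminal", 6, "Direct"),
    ("P06493", "CDK1", 28660, 0.81, 41, 63.22, "Steiner", 6, "Indirect"),
    ("P31749", "AKT1", 40964, 0.70, 50, 62.82, "Terminal", 8, "Direct"),
    ("P36897", "TGFBR1", 2736, 0.81, 50, 62.16, "Terminal", 15, "Direct"),
    ("Q13363", "CTBP1", 1313, 0.93, 50, 61.96, "Steiner", 8, "Indirect"),
    ("P13497", "BMP1", 2612, 0.79, 50, 61.21, "Steiner", 12, "Indirect"),
    ("P20248", "CCNA2", 5640, 0.73, 50, 60.89, "Terminal", 6, "Direct"),
    ("Q15645", "TRIP13", 657, 0.98, 50, 60.57, "Terminal", 6, "Direct"),
    ("O75398", "DEAF1", 6916, 0.65, 50, 58.91, "Terminal", 7, "Direct"),
    ("Q12834", "CDC20", 4737, 0.99, 4, 34.69, "Steiner", 6, "Indirect"),
]


def moc_top_targets() -> pd.DataFrame:
    """The published reference target table as a DataFrame."""
    return pd.DataFrame(
        _TOP_TARGET_ROWS,
        columns=[
            "uniprot_id", "gene", "betweenness", "drug_score", "occurrences",
            "rank_product", "type", "cluster", "evidence",
        ],
    )
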