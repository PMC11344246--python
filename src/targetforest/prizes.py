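"""Node prizes from somatic variants.

Converts a MAF-like table of somatic variants with predicted deleterious
consequences into per-gene node prizes for the prize-collecting Steiner
forest, and labels genes as carrying Direct (mutated in the cohort) or
Indirect (recruited purely through network connectivity) evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "VariantRecord",
    "PrizeMap",
    "read_variants_tsv",
    "write_variants_tsv",
    "compute_prizes",
    "evidence_labels",
]

SCHEMES = ("frequency", "binary", "count")


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant call in one patient."""

    gene: str
    sample: str
    consequence: str = ""
    deleterious: bool = True

    def __post_init__(self) -> None:
        if not self.gene or not self.sample:
            raise ValueError("variant record needs non-empty gene and sample")


@dataclass
class PrizeMap:
    """gene -> non-negative prize; genes absent from the map have prize 0."""

    prizes: dict[str, float]
    cohort_size: int
    scheme: str = "frequency"
    flagged_genes: list[str] = field(default_factory=list)

    def __getitem__(self, gene: str) -> float:
        return self.prizes.get(gene, 0.0)

    def get(self, gene: str, default: float = 0.0) -> float:
        return self.prizes.get(gene, default)

    def __contains__(self, gene: str) -> bool:
        return gene in self.prizes

    def items(self):
        return self.prizes.items()


def read_variants_tsv(path) -> list[VariantRecord]:
    """MAF-like TSV with columns gene, sample, consequence, deleterious."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            VariantRecord(
                gene=str(row.gene),
                sample=str(row.sample),
                consequence=str(getattr(row, "consequence", "")),
                deleterious=str(getattr(row, "deleterious", "true")).strip().lower()
                in ("true", "1", "yes"),
            )
        )
    return records


def write_variants_tsv(variants: Sequence[VariantRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "gene": v.gene,
                "sample": v.sample,
                "consequence": v.consequence,
                "deleterious": "true" if v.deleterious else "false",
            }
            for v in variants
        ],
        columns=["gene", "sample", "consequence", "deleterious"],
    ).to_csv(path, sep="\t", index=False)


def compute_prizes(
    variants: Iterable[VariantRecord],
    cohort_size: int,
    scheme: str = "frequency",
    network_genes: Iterable[str] | None = None,
) -> PrizeMap:
    """Per-gene prize from deleterious variant recurrence.

    Only records with ``deleterious=True`` contribute, and duplicate
    (gene, sample) pairs count once. Schemes:

    - ``frequency`` (default): fraction of the cohort with >=1 deleterious
      variant in the gene, in [0, 1];
    - ``binary``: 1 if any deleterious variant, else absent;
    - ``count``: raw number of distinct mutated samples.

    If ``network_genes`` is given, prized genes missing from the network are
    kept in the map but flagged with a warning.
    """
    if cohort_size < 1:
        raise ValueError(f"cohort_size must be >=1, got {cohort_size}")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown prize scheme {scheme!r}; choose from {SCHEMES}")
    mutated_samples: dict[str, set[str]] = {}
    for v in variants:
        if v.deleterious:
            mutated_samples.setdefault(v.gene, set()).add(v.sample)
    prizes: dict[str, float] = {}
    for gene, samples in mutated_samples.items():
        n = len(samples)
        if scheme == "frequency":
            prizes[gene] = n / cohort_size
        elif scheme == "binary":
            prizes[gene] = 1.0
        else:
            prizes[gene] = float(n)
    flagged: list[str] = []
    if network_genes is not None:
        known = set(network_genes)
        flagged = sorted(g for g in prizes if g not in known)
        if flagged:
            warnings.warn(
                f"{len(flagged)} mutated gene(s) absent from the network (kept, flagged)",
                UserWarning,
                stacklevel=2,
            )
    return PrizeMap(prizes=prizes, cohort_size=cohort_size, scheme=scheme, flagged_genes=flagged)


def evidence_labels(pm: PrizeMap, nodes: Iterable[str]) -> dict[str, str]:
    """Direct iff the gene carries a positive prize, else Indirect."""
    return {n: ("Direct" if pm.get(n, 0.0) > 0 else "Indirect") for n in nodes}
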