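"""Structural druggability scoring.

A protein is considered structurally tractable when more than 40% of its
sequence could be modelled (SWISS-MODEL/PDB coverage) AND a pocket-detection
run (fPocket) found at least one candidate binding site. Its drug-ability
score is then the best per-pocket druggability score; otherwise the score is
0. Pocket detection and homology modelling themselves are external: this
module consumes their outputs (fPocket info text, coverage tables, or a
precomputed score table).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

__all__ = [
    "DruggabilityRecord",
    "structure_coverage",
    "parse_fpocket_info",
    "drug_score",
    "read_coverage_tsv",
    "read_druggability_tsv",
    "write_druggability_tsv",
    "count_resolved_residues",
]

COVERAGE_THRESHOLD = 0.40  # strict: coverage must exceed this to score


@dataclass
class DruggabilityRecord:
    protein_id: str
    sequence_length: int = 0
    modelled_residues: int = 0
    pocket_scores: list[float] = field(default_factory=list)

    @property
    def coverage(self) -> float:
        if self.sequence_length <= 0:
            return 0.0
        return self.modelled_residues / self.sequence_length

    @property
    def drug_score(self) -> float:
        return drug_score(self.coverage, self.pocket_scores)


def structure_coverage(sequence_length: int, modelled_ranges: Sequence[tuple[int, int]]) -> float:
    """Fraction of the sequence covered by the union of modelled intervals.

    Intervals are 1-based inclusive and are clipped to [1, sequence_length];
    overlaps count once. An empty list gives 0.0.
    """
    if sequence_length < 1:
        raise ValueError(f"sequence_length must be >=1, got {sequence_length}")
    ivals = []
    for lo, hi in modelled_ranges:
        lo, hi = max(1, int(lo)), min(int(sequence_length), int(hi))
        if hi >= lo:
            ivals.append((lo, hi))
    if not ivals:
        return 0.0
    ivals.sort()
    covered = 0
    cur_lo, cur_hi = ivals[0]
    for lo, hi in ivals[1:]:
        if lo <= cur_hi + 1:
            cur_hi = max(cur_hi, hi)
        else:
            covered += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
    covered += cur_hi - cur_lo + 1
    return covered / sequence_length


_POCKET_HEADER = re.compile(r"^\s*Pocket\s+(\d+)\s*:?", re.IGNORECASE)
_DRUG_SCORE = re.compile(r"Druggability Score\s*:\s*([-+0-9.eE]+)")


def parse_fpocket_info(text: str) -> list[float]:
    """Extract the per-pocket druggability scores from an fPocket info file.

    The info-file dialect is a sequence of "Pocket N :" blocks each carrying a
    "Druggability Score : <float>" line. Scores are returned in block order;
    blocks without a parseable score are skipped with a warning.
    """
    scores: list[float] = []
    in_block = False
    block_id = None
    block_done = False
    for line in text.splitlines():
        m = _POCKET_HEADER.match(line)
        if m:
            if in_block and not block_done:
                warnings.warn(f"fPocket block {block_id} has no druggability score; skipped",
                              UserWarning, stacklevel=2)
            in_block, block_id, block_done = True, m.group(1), False
            continue
        if in_block and not block_done:
            s = _DRUG_SCORE.search(line)
            if s:
                try:
                    scores.append(float(s.group(1)))
                    block_done = True
                except ValueError:
                    warnings.warn(f"malformed druggability score in pocket {block_id}; skipped",
                                  UserWarning, stacklevel=2)
                    block_done = True
    if in_block and not block_done:
        warnings.warn(f"fPocket block {block_id} has no druggability score; skipped",
                      UserWarning, stacklevel=2)
    return scores


def drug_score(coverage: float, pocket_scores: Sequence[float]) -> float:
    """Best pocket score, gated by strict >40% structure coverage.

    Returns 0 when coverage <= 0.40 or no pockets were detected; otherwise
    the maximum per-pocket druggability score.
    """
    if not (0.0 <= coverage <= 1.0):
        raise ValueError(f"coverage must be in [0,1], got {coverage}")
    if coverage <= COVERAGE_THRESHOLD or not pocket_scores:
        return 0.0
    return float(max(pocket_scores))


def read_coverage_tsv(path) -> dict[str, tuple[int, int]]:
    """Coverage TSV (protein_id, sequence_length, modelled_residues) -> dict."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.protein_id): (int(r.sequence_length), int(r.modelled_residues))
        for r in df.itertuples(index=False)
    }


def read_druggability_tsv(path) -> list[DruggabilityRecord]:
    """Read a druggability table.

    Two layouts are accepted: the full record layout (protein_id,
    sequence_length, modelled_residues, pocket_scores with semicolon-joined
    floats) and the precomputed layout (protein_id, drug_score), which is
    mapped onto a record with full coverage and a single pocket so that the
    stored score is reproduced exactly.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    if "pocket_scores" in df.columns:
        for r in df.itertuples(index=False):
            records.append(
                DruggabilityRecord(
                    protein_id=str(r.protein_id),
                    sequence_length=int(r.sequence_length),
                    modelled_residues=int(r.modelled_residues),
                    pocket_scores=[float(s) for s in str(r.pocket_scores).split(";") if s],
                )
            )
    elif "drug_score" in df.columns:
        for r in df.itertuples(index=False):
            s = float(r.drug_score)
            records.append(
                DruggabilityRecord(
                    protein_id=str(r.protein_id),
                    sequence_length=1,
                    modelled_residues=1,
                    pocket_scores=[s] if s > 0 else [],
                )
            )
    else:
        raise ValueError("druggability TSV needs either pocket_scores or drug_score column")
    return records


def write_druggability_tsv(records: Sequence[DruggabilityRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "sequence_length": r.sequence_length,
                "modelled_residues": r.modelled_residues,
                "pocket_scores": ";".join(f"{s:g}" for s in r.pocket_scores),
                "drug_score": f"{r.drug_score:g}",
            }
            for r in records
        ],
        columns=["protein_id", "sequence_length", "modelled_residues", "pocket_scores", "drug_score"],
    ).to_csv(path, sep="\t", index=False)


def count_resolved_residues(pdb_path) -> int:
    """Number of residues with resolved coordinates in a PDB-format model.

    Counts standard amino-acid residues across all chains of the first model.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import is_aa

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(pdb_path))
    model = next(iter(structure))
    return sum(1 for chain in model for res in chain if is_aa(res))
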