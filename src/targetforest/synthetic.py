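"""Synthetic study generator with planted ground truth.

Emulates the statistical structure the pipeline assumes, without any
controlled-access data: two cohorts (case and control) of normalized
expression containing planted co-expression modules, a curated PPI
annotation table with mixed interaction types, a somatic-variant table with
deleterious-mutation enrichment in the planted modules, and per-protein
structural druggability with a no-structure fraction.

Planted co-expression follows a single-latent-factor model: gene i in
module k and sample s has expression

    x_is = sqrt(rho_k) * f_ks + sqrt(1 - rho_k) * eps_is

with f and eps standard normal, so any two genes of the module correlate at
exactly rho_k in expectation. Differential modules use ``rho_case`` in the
case cohort and ``rho_control`` in the control cohort; shared modules use
the same ``rho_shared`` in both; background genes are independent noise.

The planted target set — the genes the full pipeline should rank highly —
is the intersection of the differential-module genes with the planted
druggable set, restricted to genes that are mutated or are physical-PPI
neighbours of a mutated gene (the latter exercising the Steiner/Indirect
discovery route).

All generators are deterministic given their seed; each internal stream is
salted so that passing one master seed to every generator keeps the streams
independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .druggability import DruggabilityRecord, write_druggability_tsv
from .networks import (
    ExpressionMatrix,
    PPIAnnotation,
    write_expression_tsv,
    write_ppi_annotations,
)
from .prizes import VariantRecord, write_variants_tsv

__all__ = [
    "SyntheticTruth",
    "SyntheticScenario",
    "simulate_cohorts",
    "simulate_annotations",
    "simulate_variants",
    "simulate_druggability",
    "simulate_all",
]

# salt for per-generator random streams (master seed is shared across generators)
_SALT_COHORTS, _SALT_ANNOT, _SALT_VARIANTS, _SALT_DRUG = 1, 2, 3, 4

DEFAULTS = dict(
    n_genes=300,
    n_modules=6,
    n_differential=3,
    module_size=8,
    n_case=40,
    n_control=40,
    rho_case=0.8,
    rho_control=0.0,
    rho_shared=0.5,
    p_within_physical=0.9,
    p_background_edge=0.01,
    p_nonphysical=0.1,
    n_patients=40,
    rate_target=0.3,
    rate_background=0.02,
    no_structure_fraction=0.184,
)


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    module_of: dict[str, int]  # gene -> module id; background genes absent
    differential_modules: list[int]
    seed: int
    params: dict = field(default_factory=dict)
    mutated_genes: set[str] = field(default_factory=set)
    druggable_genes: set[str] = field(default_factory=set)
    planted_targets: set[str] = field(default_factory=set)

    @property
    def genes(self) -> list[str]:
        return sorted(self.params["gene_ids"])

    @property
    def differential_genes(self) -> set[str]:
        return {g for g, k in self.module_of.items() if k in self.differential_modules}

    def module_genes(self, k: int) -> list[str]:
        return sorted(g for g, kk in self.module_of.items() if kk == k)

    def finalize_targets(self, annotations: list[PPIAnnotation]) -> set[str]:
        """planted targets = differential ∩ druggable ∩ (mutated ∪ PPI-adjacent)."""
        physical_neighbours: set[str] = set()
        for a in annotations:
            if any(t.lower() == "physical interaction" for t in a.interaction_types):
                if a.gene_a in self.mutated_genes:
                    physical_neighbours.add(a.gene_b)
                if a.gene_b in self.mutated_genes:
                    physical_neighbours.add(a.gene_a)
        reachable = self.mutated_genes | physical_neighbours
        self.planted_targets = self.differential_genes & self.druggable_genes & reachable
        return self.planted_targets

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "params": {k: v for k, v in self.params.items() if k != "gene_ids"},
            "gene_ids": self.params.get("gene_ids", []),
            "module_of": self.module_of,
            "differential_modules": self.differential_modules,
            "mutated_genes": sorted(self.mutated_genes),
            "druggable_genes": sorted(self.druggable_genes),
            "planted_targets": sorted(self.planted_targets),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _gene_names(n_genes: int) -> list[str]:
    width = len(str(n_genes))
    return [f"G{i + 1:0{width}d}" for i in range(n_genes)]


def simulate_cohorts(
    n_genes: int = DEFAULTS["n_genes"],
    n_modules: int = DEFAULTS["n_modules"],
    module_size: int = DEFAULTS["module_size"],
    n_case: int = DEFAULTS["n_case"],
    n_control: int = DEFAULTS["n_control"],
    rho_case: float = DEFAULTS["rho_case"],
    rho_control: float = DEFAULTS["rho_control"],
    rho_shared: float = DEFAULTS["rho_shared"],
    n_differential: int = DEFAULTS["n_differential"],
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Two cohorts with planted (partly cohort-specific) co-expression modules.

    Modules 1..n_differential are differential (rho_case vs rho_control);
    modules n_differential+1..n_modules are shared (rho_shared in both).
    """
    if module_size * n_modules > n_genes:
        raise ValueError("module_size * n_modules exceeds n_genes")
    if n_differential > n_modules:
        raise ValueError("n_differential exceeds n_modules")
    for rho in (rho_case, rho_control, rho_shared):
        if not (0.0 <= rho < 1.0):
            raise ValueError(f"rho must be in [0, 1), got {rho}")
    rng = np.random.default_rng([int(seed), _SALT_COHORTS])
    genes = _gene_names(n_genes)
    module_of = {
        genes[i]: i // module_size + 1 for i in range(n_modules * module_size)
    }
    diff_modules = list(range(1, n_differential + 1))

    def cohort(n_samples: int, label: str, rho_diff: float) -> ExpressionMatrix:
        x = rng.standard_normal((n_genes, n_samples))
        for k in range(1, n_modules + 1):
            rho = rho_diff if k in diff_modules else rho_shared
            idx = [i for i, g in enumerate(genes) if module_of.get(g) == k]
            f = rng.standard_normal(n_samples)
            x[idx, :] = np.sqrt(rho) * f + np.sqrt(1.0 - rho) * x[idx, :]
        samples = [f"{label}{s + 1:03d}" for s in range(n_samples)]
        return ExpressionMatrix(genes, samples, x, cohort_label=label)

    expr_case = cohort(n_case, "case", rho_case)
    expr_control = cohort(n_control, "ctrl", rho_control)
    truth = SyntheticTruth(
        module_of=module_of,
        differential_modules=diff_modules,
        seed=int(seed),
        params=dict(
            gene_ids=genes,
            n_genes=n_genes,
            n_modules=n_modules,
            module_size=module_size,
            n_case=n_case,
            n_control=n_control,
            rho_case=rho_case,
            rho_control=rho_control,
            rho_shared=rho_shared,
            n_differential=n_differential,
        ),
    )
    return expr_case, expr_control, truth


def simulate_annotations(
    truth: SyntheticTruth,
    p_within_physical: float = DEFAULTS["p_within_physical"],
    p_background_edge: float = DEFAULTS["p_background_edge"],
    p_nonphysical: float = DEFAULTS["p_nonphysical"],
    seed: int = 0,
) -> list[PPIAnnotation]:
    """Curated-PPI-style annotations with mixed interaction types.

    Within-module pairs are annotated with probability ``p_within_physical``;
    of those, a fraction ``p_nonphysical`` carry only non-physical labels
    (exercising the physical-interaction filter). Background pairs (everything
    else) are annotated sparsely at ``p_background_edge``.
    """
    for p in (p_within_physical, p_background_edge, p_nonphysical):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability out of [0,1]: {p}")
    rng = np.random.default_rng([truth.seed, _SALT_ANNOT, int(seed)])
    genes = truth.params["gene_ids"]
    annotations: list[PPIAnnotation] = []
    methods_pool = ["two-hybrid", "co-ip", "affinity purification", "crosslinking"]
    for ga, gb in combinations(genes, 2):
        same_module = (
            truth.module_of.get(ga) is not None
            and truth.module_of.get(ga) == truth.module_of.get(gb)
        )
        p_edge = p_within_physical if same_module else p_background_edge
        if rng.random() >= p_edge:
            continue
        if same_module and rng.random() < p_nonphysical:
            types = frozenset({"co-expression", "genetic interaction"})
        else:
            types = frozenset({"physical interaction", "co-expression"})
        n_methods = int(rng.integers(1, 3))
        methods = frozenset(rng.choice(methods_pool, size=n_methods, replace=False))
        annotations.append(
            PPIAnnotation(
                gene_a=ga,
                gene_b=gb,
                interaction_types=types,
                methods=methods,
                n_publications=int(rng.integers(1, 20)),
            )
        )
    return annotations


def simulate_variants(
    truth: SyntheticTruth,
    n_patients: int = DEFAULTS["n_patients"],
    rate_target: float = DEFAULTS["rate_target"],
    rate_background: float = DEFAULTS["rate_background"],
    seed: int = 0,
) -> list[VariantRecord]:
    """Somatic deleterious variants enriched in the differential modules.

    Per patient, each differential-module gene is mutated with
    ``rate_target`` and every other gene with ``rate_background``. Updates
    ``truth.mutated_genes``.
    """
    for p in (rate_target, rate_background):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"rate out of [0,1]: {p}")
    rng = np.random.default_rng([truth.seed, _SALT_VARIANTS, int(seed)])
    genes = truth.params["gene_ids"]
    diff_genes = truth.differential_genes
    consequences = ["stop_gained", "missense_deleterious", "frameshift", "splice_donor"]
    variants: list[VariantRecord] = []
    for s in range(n_patients):
        sample = f"P{s + 1:03d}"
        for g in genes:
            rate = rate_target if g in diff_genes else rate_background
            if rng.random() < rate:
                variants.append(
                    VariantRecord(
                        gene=g,
                        sample=sample,
                        consequence=str(rng.choice(consequences)),
                        deleterious=True,
                    )
                )
    truth.mutated_genes = {v.gene for v in variants if v.deleterious}
    truth.params["n_patients"] = n_patients
    truth.params["rate_target"] = rate_target
    truth.params["rate_background"] = rate_background
    return variants


def simulate_druggability(
    truth: SyntheticTruth,
    no_structure_fraction: float = DEFAULTS["no_structure_fraction"],
    seed: int = 0,
) -> list[DruggabilityRecord]:
    """Per-protein structure coverage and pocket scores.

    A genome-wide fraction of proteins has no usable structure (coverage 0,
    no pockets). Differential-module genes outside that pool are the planted
    druggable set: coverage ~ U(0.5, 1) and best pocket ~ U(0.7, 1). Every
    other structured protein draws coverage ~ U(0, 1) and pockets ~ U(0, 0.5).
    Updates ``truth.druggable_genes``.
    """
    if not (0.0 <= no_structure_fraction <= 1.0):
        raise ValueError(f"fraction out of [0,1]: {no_structure_fraction}")
    rng = np.random.default_rng([truth.seed, _SALT_DRUG, int(seed)])
    genes = truth.params["gene_ids"]
    n_nostruct = int(round(no_structure_fraction * len(genes)))
    no_structure = set(rng.choice(genes, size=n_nostruct, replace=False))
    diff_genes = truth.differential_genes
    records: list[DruggabilityRecord] = []
    druggable: set[str] = set()
    for g in genes:
        length = int(rng.integers(200, 1000))
        if g in no_structure:
            records.append(DruggabilityRecord(g, length, 0, []))
            continue
        if g in diff_genes:
            coverage = rng.uniform(0.5, 1.0)
            pockets = [float(rng.uniform(0.7, 1.0))]
            pockets += list(rng.uniform(0.0, 0.7, size=int(rng.integers(0, 3))))
            druggable.add(g)
        else:
            coverage = rng.uniform(0.0, 1.0)
            pockets = list(rng.uniform(0.0, 0.5, size=int(rng.integers(0, 4))))
        records.append(
            DruggabilityRecord(g, length, int(round(coverage * length)), [round(p, 3) for p in pockets])
        )
    truth.druggable_genes = druggable
    truth.params["no_structure_fraction"] = no_structure_fraction
    truth.params["no_structure_genes"] = sorted(no_structure)
    return records


@dataclass
class SyntheticScenario:
    """Everything one run of the pipeline needs, plus the ground truth."""

    expr_case: ExpressionMatrix
    expr_control: ExpressionMatrix
    annotations: list[PPIAnnotation]
    variants: list[VariantRecord]
    druggability: list[DruggabilityRecord]
    truth: SyntheticTruth

    def write(self, outdir) -> dict[str, str]:
        """Write every input format the pipeline readers consume + truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression_case": outdir / "expression_case.tsv",
            "expression_control": outdir / "expression_control.tsv",
            "ppi_annotations": outdir / "ppi_annotations.tsv",
            "variants": outdir / "variants.tsv",
            "druggability": outdir / "druggability.tsv",
            "truth": outdir / "truth.json",
        }
        write_expression_tsv(self.expr_case, paths["expression_case"])
        write_expression_tsv(self.expr_control, paths["expression_control"])
        write_ppi_annotations(self.annotations, paths["ppi_annotations"])
        write_variants_tsv(self.variants, paths["variants"])
        write_druggability_tsv(self.druggability, paths["druggability"])
        self.truth.to_json(paths["truth"])
        return {k: str(v) for k, v in paths.items()}


def simulate_all(seed: int = 0, **overrides) -> SyntheticScenario:
    """Generate a full synthetic study under the default conditions.

    Keyword overrides map onto the individual generators' parameters (see
    ``DEFAULTS``). One master seed drives every generator through salted
    streams.
    """
    params = dict(DEFAULTS)
    unknown = set(overrides) - set(params)
    if unknown:
        raise TypeError(f"unknown synthetic parameters: {sorted(unknown)}")
    params.update(overrides)
    expr_case, expr_control, truth = simulate_cohorts(
        n_genes=params["n_genes"],
        n_modules=params["n_modules"],
        module_size=params["module_size"],
        n_case=params["n_case"],
        n_control=params["n_control"],
        rho_case=params["rho_case"],
        rho_control=params["rho_control"],
        rho_shared=params["rho_shared"],
        n_differential=params["n_differential"],
        seed=seed,
    )
    annotations = simulate_annotations(
        truth,
        p_within_physical=params["p_within_physical"],
        p_background_edge=params["p_background_edge"],
        p_nonphysical=params["p_nonphysical"],
    )
    variants = simulate_variants(
        truth,
        n_patients=params["n_patients"],
        rate_target=params["rate_target"],
        rate_background=params["rate_background"],
    )
    druggability = simulate_druggability(
        truth, no_structure_fraction=params["no_structure_fraction"]
    )
    truth.finalize_targets(annotations)
    return SyntheticScenario(
        expr_case=expr_case,
        expr_control=expr_control,
        annotations=annotations,
        variants=variants,
        druggability=druggability,
        truth=truth,
    )
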