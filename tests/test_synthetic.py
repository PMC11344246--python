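"""Synthetic-study generator: determinism, planted signal, file validity."""

import numpy as np
import pytest

from targetforest.druggability import read_druggability_tsv
from targetforest.networks import (
    compute_adjacency,
    differential_edges,
    read_expression_tsv,
    read_ppi_annotations,
)
from targetforest.prizes import compute_prizes, read_variants_tsv
from targetforest.synthetic import (
    simulate_all,
    simulate_annotations,
    simulate_cohorts,
    simulate_druggability,
    simulate_variants,
)


class TestSimulateCohorts:
    def test_deterministic(self):
        a1, c1, _ = simulate_cohorts(n_genes=40, n_modules=2, n_differential=1,
                                     module_size=5, seed=3, n_case=10, n_control=10)
        a2, c2, _ = simulate_cohorts(n_genes=40, n_modules=2, n_differential=1,
                                     module_size=5, seed=3, n_case=10, n_control=10)
        np.testing.assert_array_equal(a1.values, a2.values)
        np.testing.assert_array_equal(c1.values, c2.values)

    def test_null_when_cohorts_share_rho(self):
        # when both cohorts share the module correlation, per-edge d collapses
        # towards 0 and sits far below the rewired configuration's signal
        def module_mean_d(n_differential, seed):
            case, ctrl, truth = simulate_cohorts(
                n_genes=60, n_modules=2, n_differential=n_differential,
                module_size=6, n_case=40, n_control=40, seed=seed,
            )
            dn = differential_edges(compute_adjacency(case), compute_adjacency(ctrl))
            mod = truth.module_genes(1)
            return np.mean([dn.graph.edges[u, v]["d"]
                            for i, u in enumerate(mod) for v in mod[i + 1:]])

        null = [module_mean_d(0, s) for s in range(5)]
        alt = [module_mean_d(1, s) for s in range(5)]
        assert np.mean(null) < 0.05
        assert np.mean(null) + 3 * np.std(null) < np.mean(alt)

    def test_differential_module_signal(self):
        # planted rewiring beats background in >= 95% of seeds
        wins = 0
        for seed in range(20):
            case, ctrl, truth = simulate_cohorts(
                n_genes=60, n_modules=3, n_differential=1, module_size=8,
                n_case=50, n_control=50, seed=seed,
            )
            dn = differential_edges(compute_adjacency(case), compute_adjacency(ctrl))
            mod = truth.module_genes(1)
            modset = set(mod)
            d_mod = np.mean([dn.graph.edges[u, v]["d"]
                             for i, u in enumerate(mod) for v in mod[i + 1:]])
            d_bg = np.mean([dat["d"] for u, v, dat in dn.edges()
                            if u not in modset and v not in modset])
            wins += d_mod > d_bg
        assert wins >= 19

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            simulate_cohorts(n_genes=10, n_modules=3, module_size=5)
        with pytest.raises(ValueError):
            simulate_cohorts(rho_case=1.0)


class TestSimulateAnnotations:
    def test_complete_within_module_annotation(self):
        _, _, truth = simulate_cohorts(n_genes=20, n_modules=1, n_differential=1, module_size=4, seed=1,
                                       n_case=5, n_control=5)
        ann = simulate_annotations(truth, p_within_physical=1.0, p_background_edge=0.0,
                                   p_nonphysical=0.0)
        assert len(ann) == 6  # C(4,2) pairs, all annotated
        assert all("physical interaction" in a.interaction_types for a in ann)

    def test_no_background_edges(self):
        _, _, truth = simulate_cohorts(n_genes=30, n_modules=2, n_differential=1, module_size=4, seed=2,
                                       n_case=5, n_control=5)
        ann = simulate_annotations(truth, p_within_physical=1.0, p_background_edge=0.0)
        for a in ann:
            assert truth.module_of.get(a.gene_a) == truth.module_of.get(a.gene_b)

    def test_background_count_binomial(self):
        counts, expectations = [], []
        for seed in range(8):
            _, _, truth = simulate_cohorts(n_genes=40, n_modules=0, n_differential=0,
                                           module_size=1, n_case=5, n_control=5, seed=seed)
            ann = simulate_annotations(truth, p_background_edge=0.05)
            counts.append(len(ann))
            expectations.append(0.05 * 40 * 39 / 2)
        n_pairs = 40 * 39 / 2
        se = np.sqrt(0.05 * 0.95 * n_pairs * len(counts))
        assert abs(sum(counts) - sum(expectations)) < 4 * se


class TestSimulateVariants:
    def test_saturated_target_rate(self):
        _, _, truth = simulate_cohorts(n_genes=20, n_modules=1, n_differential=1, module_size=4, seed=4,
                                       n_case=5, n_control=5)
        variants = simulate_variants(truth, n_patients=10, rate_target=1.0,
                                     rate_background=0.0)
        pm = compute_prizes(variants, cohort_size=10)
        for g in truth.differential_genes:
            assert pm[g] == 1.0
        for g in truth.params["gene_ids"]:
            if g not in truth.differential_genes:
                assert pm[g] == 0.0

    def test_empirical_rate_within_ci(self):
        hits = total = 0
        for seed in range(6):
            _, _, truth = simulate_cohorts(n_genes=30, n_modules=1, n_differential=1, module_size=8,
                                           n_case=5, n_control=5, seed=seed)
            variants = simulate_variants(truth, n_patients=30, rate_target=0.3,
                                         rate_background=0.0)
            hits += len(variants)
            total += 30 * 8
        p_hat = hits / total
        se = np.sqrt(0.3 * 0.7 / total)
        assert abs(p_hat - 0.3) < 4 * se


class TestSimulateDruggability:
    def test_all_unmodelled(self):
        _, _, truth = simulate_cohorts(n_genes=20, n_modules=1, n_differential=1, module_size=4, seed=5,
                                       n_case=5, n_control=5)
        records = simulate_druggability(truth, no_structure_fraction=1.0)
        assert all(r.drug_score == 0.0 for r in records)

    def test_planted_druggable_scores(self):
        _, _, truth = simulate_cohorts(n_genes=40, n_modules=2, n_differential=2, module_size=6, seed=6,
                                       n_case=5, n_control=5)
        records = simulate_druggability(truth, no_structure_fraction=0.0)
        by_id = {r.protein_id: r for r in records}
        assert truth.druggable_genes == truth.differential_genes
        for g in truth.druggable_genes:
            assert by_id[g].drug_score >= 0.7
            assert by_id[g].coverage > 0.4

    def test_zero_fraction_accounting(self):
        _, _, truth = simulate_cohorts(n_genes=50, n_modules=2, n_differential=1, module_size=5, seed=7,
                                       n_case=5, n_control=5)
        frac = 0.2
        records = simulate_druggability(truth, no_structure_fraction=frac)
        n_nostruct = len(truth.params["no_structure_genes"])
        assert n_nostruct == round(frac * 50)
        n_zero = sum(1 for r in records if r.drug_score == 0.0)
        assert n_zero >= n_nostruct  # plus the low-coverage / no-pocket fraction


class TestScenarioFiles:
    def test_round_trip_through_all_readers(self, tmp_path, small_scenario):
        paths = small_scenario.write(tmp_path)
        case = read_expression_tsv(paths["expression_case"])
        assert case.gene_ids == small_scenario.expr_case.gene_ids
        np.testing.assert_allclose(case.values, small_scenario.expr_case.values,
                                   rtol=0, atol=1e-9)
        ann = read_ppi_annotations(paths["ppi_annotations"])
        assert {a.pair for a in ann} == {a.pair for a in small_scenario.annotations}
        variants = read_variants_tsv(paths["variants"])
        assert len(variants) == len(small_scenario.variants)
        records = read_druggability_tsv(paths["druggability"])
        want = {r.protein_id: r.drug_score for r in small_scenario.druggability}
        got = {r.protein_id: r.drug_score for r in records}
        assert got == pytest.approx(want)

    def test_truth_invariants(self, small_scenario):
        truth = small_scenario.truth
        assert truth.planted_targets  # non-empty under defaults
        genes = set(truth.params["gene_ids"])
        assert truth.planted_targets <= truth.differential_genes <= genes
        assert truth.planted_targets <= truth.druggable_genes

    def test_same_seed_bit_identical(self):
        s1 = simulate_all(seed=9, n_genes=50, n_modules=2, n_differential=1,
                          module_size=5, n_case=8, n_control=8, n_patients=8)
        s2 = simulate_all(seed=9, n_genes=50, n_modules=2, n_differential=1,
                          module_size=5, n_case=8, n_control=8, n_patients=8)
        np.testing.assert_array_equal(s1.expr_case.values, s2.expr_case.values)
        assert s1.truth.planted_targets == s2.truth.planted_targets
        assert [v.gene for v in s1.variants] == [v.gene for v in s2.variants]
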