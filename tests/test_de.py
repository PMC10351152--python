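"""Normalization, dispersion, the NB test, BH adjustment and the embedding."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from livermet.datatypes import CountMatrix, ValidationError
from livermet.de import (
    PRESETS,
    DECallThresholds,
    adjust_pvalues_bh,
    call_de,
    compute_sample_embedding,
    estimate_dispersion,
    filter_low_expression,
    normalization_factors,
    test_differential_expression as run_de_test,
)
from livermet.simulate import CohortConfig, simulate_cohort


def _cm(array, genes=None, samples=None):
    array = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    samples = samples or [f"s{j}" for j in range(array.shape[1])]
    return CountMatrix(pd.DataFrame(array, index=genes, columns=samples))


class TestLowExpressionFilter:
    def test_threshold_rule_is_strictly_greater_in_ten_percent(self):
        # 2 of 20 samples exceed 10 counts -> exactly the 10% bar
        row_keep = [11, 11] + [0] * 18
        row_drop = [11, 10] + [0] * 18
        row_zero = [0] * 20
        cm = _cm([row_keep, row_drop, row_zero])
        kept = filter_low_expression(cm)
        assert kept.gene_ids == ["g0"]

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        cm = _cm(rng.integers(0, 30, size=(100, 12)))
        kept = set(filter_low_expression(cm).gene_ids)
        need = math.ceil(0.10 * 12)
        oracle = set()
        for g in cm.gene_ids:
            n_over = sum(1 for v in cm.counts.loc[g] if v > 10)
            if n_over >= need:
                oracle.add(g)
        assert kept == oracle


class TestNormalizationFactors:
    def test_pure_depth_difference_gives_unit_factors(self):
        rng = np.random.default_rng(1)
        base = rng.integers(50, 500, size=200)
        cm = _cm(np.column_stack([base, base * 3]))
        f = normalization_factors(cm)
        assert np.allclose(f, 1.0)

    def test_single_sample_factor_is_one(self):
        cm = _cm(np.array([[5], [10], [20]]))
        assert normalization_factors(cm).iloc[0] == 1.0

    def test_matches_edger_tmm_on_toy_matrix(self):
        # frozen oracle: edgeR 4.0 calcNormFactors(method="TMM") on this exact
        # seeded matrix
        rng = np.random.default_rng(42)
        x = rng.negative_binomial(5, 0.01, size=(200, 4))
        x[:, 1] = x[:, 1] * 3
        x[:50, 2] = x[:50, 2] * 4
        cm = _cm(x, samples=list("ABCD"))
        expected = [1.07035180, 1.03314041, 0.83119580, 1.08795459]
        assert np.allclose(normalization_factors(cm), expected, atol=1e-6)

    def test_geometric_mean_is_one(self, toy_counts):
        f = normalization_factors(toy_counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_all_zero_sample_raises_with_name(self):
        cm = _cm([[1, 0], [2, 0]])
        with pytest.raises(ValidationError, match="s1"):
            normalization_factors(cm)

    def test_scaling_one_sample_leaves_other_factor_effects_small(self, toy_counts):
        f0 = normalization_factors(toy_counts)
        scaled = toy_counts.counts.copy()
        scaled["s0"] = scaled["s0"] * 5
        f1 = normalization_factors(CountMatrix(scaled))
        # relative factors among untouched samples move only within trimming noise
        r0 = f0.drop("s0") / f0.drop("s0").iloc[0]
        r1 = f1.drop("s0") / f1.drop("s0").iloc[0]
        assert np.allclose(r0, r1, rtol=0.02)


class TestDispersion:
    def test_constant_gene_has_zero_raw_dispersion(self):
        x = np.full((3, 6), 100)
        cm = _cm(x)
        phi = estimate_dispersion(cm, {f"s{j}": "A" for j in range(6)}, shrink_weight=0.0)
        assert np.allclose(phi, 0.0)

    def test_poisson_counts_estimate_near_zero(self):
        rng = np.random.default_rng(2)
        lib = np.exp(rng.uniform(np.log(1e6), np.log(3e6), 12))
        prop = rng.dirichlet(np.ones(2000))
        x = rng.poisson(prop[:, None] * lib[None, :])
        cm = _cm(x)
        phi = estimate_dispersion(cm, {f"s{j}": "A" for j in range(12)})
        assert np.median(phi) <= 0.02

    def test_recovers_planted_dispersion(self):
        meds = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            lib = np.exp(rng.uniform(np.log(1e6), np.log(5e6), 20))
            prop = rng.dirichlet(np.ones(1000))
            mu = prop[:, None] * lib[None, :]
            size = 1 / 0.2
            x = rng.negative_binomial(size, size / (size + mu))
            cm = _cm(x)
            groups = {f"s{j}": ("A" if j < 10 else "B") for j in range(20)}
            meds.append(np.median(estimate_dispersion(cm, groups)))
        assert 0.1 <= np.median(meds) <= 0.3


class TestBH:
    def test_stepup_worked_example(self):
        assert np.allclose(adjust_pvalues_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_equal_stay_equal(self):
        assert np.allclose(adjust_pvalues_bh([0.2] * 7), 0.2)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        adj = adjust_pvalues_bh(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_matches_bruteforce_stepup_definition(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=1000)
        adj = adjust_pvalues_bh(p)
        n = len(p)
        # independent O(n^2) application of the step-up definition
        oracle = np.empty(n)
        ranks = np.argsort(np.argsort(p, kind="mergesort"), kind="mergesort") + 1
        for i in range(n):
            candidates = [n * p[j] / ranks[j] for j in range(n) if p[j] >= p[i]]
            oracle[i] = min(1.0, min(candidates))
        assert np.allclose(adj, oracle)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            adjust_pvalues_bh([0.5, 1.5])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50), st.randoms(use_true_random=False))
    def test_permutation_invariance(self, p, rnd):
        idx = list(range(len(p)))
        rnd.shuffle(idx)
        adj = adjust_pvalues_bh(p)
        adj_perm = adjust_pvalues_bh([p[i] for i in idx])
        assert np.allclose([adj[i] for i in idx], adj_perm)


class TestDETest:
    def test_swapping_groups_negates_logfc_keeps_p(self, small_cohort):
        cm, meta, _ = small_cohort
        f = filter_low_expression(cm)
        ab = run_de_test(f, meta, ("LM1", "CC"))
        ba = run_de_test(f, meta, ("CC", "LM1"))
        assert np.allclose(ab["logFC"], -ba["logFC"])
        assert np.allclose(ab["PValue"], ba["PValue"])

    def test_absent_class_raises_by_name(self, small_cohort):
        cm, meta, _ = small_cohort
        with pytest.raises(ValidationError, match="NC"):
            run_de_test(cm, meta, ("NC", "CC"))

    def test_planted_effect_recovered_at_paper_thresholds(self):
        cfg = CohortConfig(seed=1, groups={"CC": 8, "LM1": 8})
        cm, meta, truth = simulate_cohort(cfg)
        table = run_de_test(filter_low_expression(cm), meta, ("LM1", "CC"))
        pair = call_de(table, PRESETS["paper"])
        assert len(set(pair.up) & truth.de_up_genes) >= 0.9 * len(truth.de_up_genes)

    def test_self_contrast_p_values_are_uniformish(self):
        from scipy import stats

        cfg = CohortConfig(
            seed=21, mixture_weight=0.0, n_liver_program=0, n_colon_program=0,
            n_genes=1500, groups={"CC": 8, "LM1": 8},
        )
        cm, meta, _ = simulate_cohort(cfg)
        table = run_de_test(filter_low_expression(cm), meta, ("LM1", "CC"))
        assert stats.kstest(table["PValue"], "uniform").pvalue > 1e-3


class TestCallDE:
    def test_boundary_logfc_excluded_by_strict_inequality(self):
        table = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "logFC": [4.0, 4.01, -4.01],
                "PValue": [1e-6, 1e-6, 1e-6],
                "FDR": [1e-5, 1e-5, 1e-5],
            }
        )
        pair = call_de(table, PRESETS["paper"])
        assert pair.up == ("b",) and pair.down == ("c",)

    def test_toy_table_membership(self):
        table = pd.DataFrame(
            {
                "gene_id": list("abcdef"),
                "logFC": [5, -5, 5, -5, 0.5, 6],
                "PValue": [1e-9, 1e-9, 0.5, 1e-9, 1e-9, 1e-9],
                "FDR": [1e-8, 1e-8, 0.6, 0.5, 1e-8, 0.02],
            }
        )
        pair = call_de(table, DECallThresholds(4.0, "adjusted", 0.01))
        assert pair.up == ("a",) and pair.down == ("b",)
        pair_raw = call_de(table, DECallThresholds(4.0, "raw", 0.01))
        assert pair_raw.up == ("a", "f") and pair_raw.down == ("b", "d")


class TestEmbedding:
    def test_duplicated_sample_gets_identical_coordinates(self, toy_counts):
        dup = toy_counts.counts.copy()
        dup["s_dup"] = dup["s0"]
        coords = compute_sample_embedding(CountMatrix(dup), top_n=50)
        assert np.allclose(coords.loc["s0"], coords.loc["s_dup"])

    def test_metastasis_centroid_lies_between_tumor_and_liver(self):
        cfg = CohortConfig(
            seed=13, mixture_weight=0.5, groups={"CC": 6, "LM1": 6, "AL": 6}, n_genes=800
        )
        cm, meta, _ = simulate_cohort(cfg)
        coords = compute_sample_embedding(filter_low_expression(cm))
        cent = coords.join(meta.set_index("sample_id")).groupby("tissue_class")["dim1"].mean()
        assert (cent["CC"] < cent["LM1"] < cent["AL"]) or (cent["AL"] < cent["LM1"] < cent["CC"])

    def test_matches_dense_eigendecomposition(self, toy_counts):
        from livermet.de import effective_library_sizes

        coords = compute_sample_embedding(toy_counts, top_n=100)
        x = toy_counts.counts.to_numpy(dtype=float)
        eff = effective_library_sizes(toy_counts).to_numpy()
        z = np.log2(x / eff * 1e6 + 1.0)
        z = z - z.mean(axis=1, keepdims=True)
        gram = z.T @ z
        w, v = np.linalg.eigh(gram)
        order = np.argsort(w)[::-1]
        oracle = v[:, order[:2]] * np.sqrt(w[order[:2]])
        assert np.allclose(np.abs(coords.to_numpy()), np.abs(oracle), atol=1e-8)
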