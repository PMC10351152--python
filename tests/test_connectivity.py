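"""Query validation, the KS connectivity score, screening and hit selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from livermet.connectivity import (
    QuerySignature,
    connectivity_score,
    screen,
    select_hits,
    summarize_classes,
    validate_query,
)
from livermet.datatypes import SignatureSet, ValidationError
from livermet.signature import core_signature_from_table, load_reference_universe
from livermet.simulate import simulate_perturbation_reference

GENES = [f"g{i:03d}" for i in range(100)]


def _profile(values, genes=GENES):
    return pd.Series(np.asarray(values, dtype=float), index=genes)


def _monotone_profile():
    return _profile(np.arange(len(GENES), 0, -1))


class TestValidateQuery:
    def test_packaged_signature_retains_21_genes(self):
        sig = core_signature_from_table()
        query, dropped = validate_query(
            QuerySignature.from_signature(sig), load_reference_universe()
        )
        assert query.size == 21
        assert dropped == ["SLC13A5"]

    def test_fully_covered_query_unchanged(self, toy_signature):
        ref, _ = simulate_perturbation_reference(toy_signature, seed=0)
        query, dropped = validate_query(QuerySignature.from_signature(toy_signature), ref)
        assert query.up == QuerySignature.from_signature(toy_signature).up
        assert dropped == []

    def test_too_small_after_drop_raises(self):
        sig = QuerySignature(up=tuple(f"ABSENT{i}" for i in range(5)) + tuple(GENES[:9]))
        with pytest.raises(ValidationError, match="9 genes"):
            validate_query(sig, frozenset(g.upper() for g in GENES))


class TestConnectivityScore:
    def test_up_genes_at_top_score_plus_100(self):
        q = QuerySignature(up=tuple(GENES[:15]))
        assert connectivity_score(q, _monotone_profile()) == pytest.approx(100.0)

    def test_up_genes_at_bottom_score_minus_100(self):
        q = QuerySignature(up=tuple(GENES[-15:]))
        assert connectivity_score(q, _monotone_profile()) == pytest.approx(-100.0)

    def test_constant_profile_scores_zero(self):
        q = QuerySignature(up=tuple(GENES[:15]))
        assert connectivity_score(q, _profile(np.ones(100))) == 0.0

    def test_matches_bruteforce_running_sum(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            genes = [f"x{i:02d}" for i in range(n)]
            prof = pd.Series(rng.normal(size=n), index=genes)
            hits = list(rng.choice(genes, int(rng.integers(3, min(8, n - 1))), replace=False))
            q = QuerySignature(up=tuple(hits))
            got = connectivity_score(q, prof)
            # oracle: evaluate the running sum at every prefix length directly
            order = sorted(genes, key=lambda g: (-prof[g], g))
            hit_set = {h.upper() for h in hits}
            best = 0.0
            for i in range(1, n + 1):
                prefix = [g.upper() for g in order[:i]]
                n_hit = sum(1 for g in prefix if g in hit_set)
                n_miss = i - n_hit
                val = n_hit / len(hit_set) - n_miss / (n - len(hit_set))
                if abs(val) > abs(best):
                    best = val
            assert got == pytest.approx(100.0 * best, abs=1e-9)

    def test_negating_profile_negates_score(self):
        rng = np.random.default_rng(11)
        prof = _profile(rng.normal(size=100))
        q = QuerySignature(up=tuple(rng.choice(GENES, 12, replace=False)))
        assert connectivity_score(q, -prof) == pytest.approx(
            -connectivity_score(q, prof), abs=1e-9
        )

    def test_down_only_query_negates_up_only_score(self):
        rng = np.random.default_rng(12)
        prof = _profile(rng.normal(size=100))
        genes = tuple(rng.choice(GENES, 12, replace=False))
        up_score = connectivity_score(QuerySignature(up=genes), prof)
        dn_score = connectivity_score(QuerySignature(up=(), down=genes), prof)
        assert dn_score == pytest.approx(-up_score, abs=1e-9)


class TestScreen:
    def test_single_context_global_equals_context_score(self, toy_signature):
        ref, _ = simulate_perturbation_reference(toy_signature, contexts=["HEPG2"], seed=1)
        q, _ = validate_query(QuerySignature.from_signature(toy_signature), ref)
        res = screen(q, ref)
        wide = res.pivot(index="compound", columns="context", values="score")
        assert np.allclose(wide["global"], wide["HEPG2"])

    def test_planted_reverter_scores_below_minus_95(self, toy_signature):
        ref, truth = simulate_perturbation_reference(toy_signature, n_reverters=2, seed=2)
        q, _ = validate_query(QuerySignature.from_signature(toy_signature), ref)
        res = screen(q, ref)
        glob = res[res["context"] == "global"].set_index("compound")["score"]
        for c in truth.reverter_compounds:
            assert glob[c] < -95

    def test_compound_order_invariance(self, toy_signature):
        ref, _ = simulate_perturbation_reference(toy_signature, n_compounds=10, seed=3)
        q, _ = validate_query(QuerySignature.from_signature(toy_signature), ref)
        res1 = screen(q, ref)
        shuffled = ref.profiles[ref.profiles.columns[::-1]]
        from livermet.datatypes import PerturbationReference

        ref2 = PerturbationReference(shuffled, ref.compound_meta, ref.contexts)
        res2 = screen(q, ref2)
        merged = res1.merge(res2, on=["compound", "context"], suffixes=("_a", "_b"))
        assert np.allclose(merged["score_a"], merged["score_b"])
        assert (merged["rank_a"] == merged["rank_b"]).all()


class TestSelectHits:
    @staticmethod
    def _results(scores):
        rows = [
            {"compound": c, "context": ctx, "score": s}
            for c, ctx_scores in scores.items()
            for ctx, s in ctx_scores.items()
        ]
        return pd.DataFrame(rows)

    def test_boundary_score_excluded_by_strict_inequality(self):
        res = self._results(
            {"a": {"global": -95.0, "c1": -99.0}, "b": {"global": -99.0, "c1": -99.0}}
        )
        assert select_hits(res, cutoff=-95.0) == ["b"]

    def test_cutoff_below_range_yields_empty(self):
        res = self._results({"a": {"global": -100.0}})
        assert select_hits(res, cutoff=-101.0) == []

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(13)
        res = self._results(
            {f"c{i}": {"global": float(rng.uniform(-100, 0))} for i in range(30)}
        )
        h_strict = set(select_hits(res, cutoff=-90))
        h_loose = set(select_hits(res, cutoff=-50))
        assert h_strict <= h_loose

    def test_planted_reverters_and_only_them(self, toy_signature):
        ref, truth = simulate_perturbation_reference(
            toy_signature, n_compounds=50, n_reverters=2, seed=7
        )
        q, _ = validate_query(QuerySignature.from_signature(toy_signature), ref)
        hits = select_hits(screen(q, ref))
        assert set(hits) == set(truth.reverter_compounds)


class TestSummarizeClasses:
    def test_planted_class_counts(self):
        meta = pd.DataFrame(
            {"name": list("abcd"), "mechanism_class": ["A", "A", "A", "B"]},
            index=pd.Index(list("abcd"), name="compound"),
        )
        tab = summarize_classes(list("abcd"), meta)
        out = tab.set_index("mechanism_class")["count"]
        assert out["A"] == 3 and out["B"] == 1
        assert tab["proportion"].sum() == pytest.approx(1.0)

    def test_hit_without_metadata_is_unknown(self):
        meta = pd.DataFrame(
            {"name": ["a"], "mechanism_class": ["A"]},
            index=pd.Index(["a"], name="compound"),
        )
        tab = summarize_classes(["a", "zzz"], meta)
        assert set(tab["mechanism_class"]) == {"A", "unknown"}

    def test_band_filter_excludes_out_of_band_hits(self):
        meta = pd.DataFrame(
            {"name": ["a", "b"], "mechanism_class": ["A", "B"]},
            index=pd.Index(["a", "b"], name="compound"),
        )
        res = pd.DataFrame(
            [
                {"compound": "a", "context": "global", "score": -60.0},
                {"compound": "b", "context": "global", "score": -40.0},
            ]
        )
        tab = summarize_classes(["a", "b"], meta, results=res, score_band=(-100, -50))
        assert list(tab["mechanism_class"]) == ["A"]


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_null_scores_are_bounded(seed):
    rng = np.random.default_rng(seed)
    prof = _profile(rng.normal(size=100))
    q = QuerySignature(up=tuple(rng.choice(GENES, 10, replace=False)))
    s = connectivity_score(q, prof)
    assert -100.0 <= s <= 100.0
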