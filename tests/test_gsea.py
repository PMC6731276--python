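import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathchemo.data_io import Pathway, PathwayCollection
from pathchemo.gsea import (
    EnrichmentResult,
    absolute_signature,
    composite_integration,
    enrich_collection,
    enrichment_score,
    nes_pvalue,
)
from pathchemo.signatures import RankedSignature


def brute_force_es(scores, hit_flags, weight_exp=1.0):
    """Direct O(N) recomputation of the running sum; the oracle the fast
    path is checked against."""
    n, k = len(scores), sum(hit_flags)
    nr = sum(abs(s) ** weight_exp for s, h in zip(scores, hit_flags) if h)
    run, cur = [], 0.0
    for s, h in zip(scores, hit_flags):
        cur += (abs(s) ** weight_exp) / nr if h else -1.0 / (n - k)
        run.append(cur)
    mx, mn = max(run), min(run)
    return mx if mx >= -mn else mn


def _signature(scores):
    return RankedSignature(
        pd.Series(scores, index=[f"g{i}" for i in range(len(scores))]), "welch_t"
    )


class TestEnrichmentScore:
    def test_top_gene_gives_full_score(self, toy_signature):
        es, _, edge = enrichment_score(toy_signature, {"A"})
        assert es == pytest.approx(1.0)
        assert edge == ["A"]

    def test_whole_signature_no_misses(self, toy_signature):
        es, _, _ = enrichment_score(toy_signature, {"A", "B", "C"})
        assert es == pytest.approx(1.0)

    def test_bottom_gene_matches_enumeration(self, toy_signature):
        # scores [3,2,1], set {C}: running sum -1/2, -1, 0 -> ES = -1
        es, running, edge = enrichment_score(toy_signature, {"C"})
        assert es == pytest.approx(
            brute_force_es([3.0, 2.0, 1.0], [False, False, True])
        )
        assert es == pytest.approx(-1.0)
        assert edge == ["C"]

    def test_empty_intersection_is_error(self, toy_signature):
        with pytest.raises(ValueError, match="intersect"):
            enrichment_score(toy_signature, {"Z"})

    def test_zero_hit_weights_is_error(self):
        sig = _signature([1.0, 0.0, -1.0])
        with pytest.raises(ValueError, match="zero"):
            enrichment_score(sig, {"g1"})


class TestNesPvalue:
    def test_deterministic_under_seed(self, toy_signature):
        a = nes_pvalue(toy_signature, {"A"}, n_perm=200, seed=7)
        b = nes_pvalue(toy_signature, {"A"}, n_perm=200, seed=7)
        assert (a.es, a.nes, a.p) == (b.es, b.nes, b.p)

    def test_top_block_of_long_signature_hits_p_floor(self):
        rng = np.random.default_rng(1)
        scores = np.sort(rng.normal(0, 1, 500))[::-1] + 0.0
        scores[:10] += 50.0  # extreme top block
        sig = _signature(scores)
        res = nes_pvalue(sig, {f"g{i}" for i in range(10)}, n_perm=500, seed=3)
        # p sits at its floor: no null beats the observed ES, and the
        # denominator is the same-sign null count (<= n_perm)
        assert res.p <= 1 / 100
        assert res.nes > 1

    def test_p_floor_respected(self, toy_signature):
        res = nes_pvalue(toy_signature, {"A"}, n_perm=200, seed=0)
        assert res.p >= 1 / 201

    def test_small_n_perm_rejected(self, toy_signature):
        with pytest.raises(ValueError):
            nes_pvalue(toy_signature, {"A"}, n_perm=10)


class TestAbsoluteSignature:
    def test_reorders_by_magnitude(self):
        sig = RankedSignature(
            pd.Series({"x": 3.0, "y": -5.0, "z": 1.0}), "welch_t"
        )
        out = absolute_signature(sig)
        assert out.genes == ["y", "x", "z"]
        assert list(out.scores) == [5.0, 3.0, 1.0]

    def test_identity_on_positive_signature(self, toy_signature):
        out = absolute_signature(toy_signature)
        assert out.genes == toy_signature.genes

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(
        st.floats(min_value=-50, max_value=50,
                  allow_nan=False, allow_infinity=False),
        min_size=4, max_size=30, unique=True,
    ))
    def test_sign_flip_invariance(self, scores):
        sig = _signature(scores)
        flipped = RankedSignature(-sig.scores, "welch_t")
        a, b = absolute_signature(sig), absolute_signature(flipped)
        assert list(a.scores.abs().sort_index()) == list(
            b.scores.abs().sort_index()
        )

    def test_absolute_mode_es_invariant_under_global_sign_flip(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 2, 60)
        sig, flipped = _signature(scores), _signature(-scores)
        gs = {f"g{i}" for i in rng.choice(60, 8, replace=False)}
        ea, _, _ = enrichment_score(absolute_signature(sig), gs)
        eb, _, _ = enrichment_score(absolute_signature(flipped), gs)
        assert ea == pytest.approx(eb, abs=1e-12)


class TestEnrichCollection:
    def test_one_result_per_overlapping_pathway(self, toy_signature):
        coll = PathwayCollection([
            Pathway("IN", "", frozenset({"A", "B"})),
            Pathway("OUT", "", frozenset({"Z"})),
        ])
        results, skipped = enrich_collection(toy_signature, coll, n_perm=100)
        assert [r.pathway for r in results] == ["IN"]
        assert skipped == ["OUT"]

    def test_seeded_rerun_identical(self, small_cohort):
        from pathchemo.signatures import welch_signature

        sig = welch_signature(small_cohort.expression, small_cohort.groups)
        r1, _ = enrich_collection(sig, small_cohort.collection, n_perm=100, seed=5)
        r2, _ = enrich_collection(sig, small_cohort.collection, n_perm=100, seed=5)
        assert [(a.nes, a.p) for a in r1] == [(b.nes, b.p) for b in r2]

    def test_nes_sign_matches_es_sign(self, small_cohort):
        from pathchemo.signatures import welch_signature

        sig = welch_signature(small_cohort.expression, small_cohort.groups)
        results, _ = enrich_collection(sig, small_cohort.collection, n_perm=200)
        for r in results:
            if r.es != 0 and r.nes != 0:
                assert np.sign(r.es) == np.sign(r.nes)


def _res(pathway, nes, p, mode):
    return EnrichmentResult(pathway, np.sign(nes) or 1.0, nes, p, ["A"], mode, 100)


class TestCompositeIntegration:
    def test_min_p_prefers_signed(self):
        comp = composite_integration(
            [_res("P", -1.9, 0.004, "signed")], [_res("P", 1.5, 0.2, "absolute")]
        )
        row = comp.table.loc["P"]
        assert (row["composite_nes"], row["composite_p"], row["source_mode"]) == (
            -1.9, 0.004, "signed")

    def test_negative_abs_excluded_even_with_lower_p(self):
        comp = composite_integration(
            [_res("P", 1.1, 0.4, "signed")], [_res("P", -2.0, 0.001, "absolute")]
        )
        assert comp.table.loc["P", "source_mode"] == "signed"
        assert comp.table.loc["P", "composite_p"] == 0.4

    def test_equal_p_tie_goes_signed(self):
        comp = composite_integration(
            [_res("P", 1.2, 0.05, "signed")], [_res("P", 2.0, 0.05, "absolute")]
        )
        assert comp.table.loc["P", "source_mode"] == "signed"

    def test_composite_p_is_min_of_eligible(self):
        rng = np.random.default_rng(9)
        signed, absolute = [], []
        for i in range(50):
            signed.append(_res(f"P{i}", rng.normal(), rng.uniform(), "signed"))
            absolute.append(_res(f"P{i}", rng.normal(), rng.uniform(), "absolute"))
        comp = composite_integration(signed, absolute)
        for s, a in zip(signed, absolute):
            eligible = [s.p] + ([a.p] if a.nes > 0 else [])
            assert comp.table.loc[s.pathway, "composite_p"] == min(eligible)


def test_null_composite_rarely_significant():
    """Fully null signatures: composite p < 0.001 in at most 2 of 100
    pathways for the vast majority of replicate runs."""
    rng = np.random.default_rng(77)
    genes = [f"g{i}" for i in range(400)]
    coll = PathwayCollection([
        Pathway(f"P{j}", "", frozenset(rng.choice(genes, 15, replace=False)))
        for j in range(100)
    ])
    bad_runs = 0
    n_runs = 20
    for run in range(n_runs):
        sig = RankedSignature(
            pd.Series(rng.normal(0, 1, len(genes)), index=genes), "welch_t"
        )
        signed, _ = enrich_collection(sig, coll, "signed", n_perm=1000, seed=run)
        absolute, _ = enrich_collection(sig, coll, "absolute", n_perm=1000,
                                        seed=run + 1)
        comp = composite_integration(signed, absolute)
        if (comp.table["composite_p"] < 0.001).sum() > 2:
            bad_runs += 1
    assert bad_runs <= 1  # >=95% of runs clean
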