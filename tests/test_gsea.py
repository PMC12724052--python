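"""Enrichment-score semantics, permutation p-values, and engine invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adipoproteo.errors import ValidationError
from adipoproteo.gsea import (
    OK,
    SKIPPED_NO_OVERLAP,
    SKIPPED_SIZE,
    RankedList,
    enrichment_score,
    gsea_preranked,
)
from adipoproteo.io_formats import SignatureSet


def naive_es(items, stats, genes, w):
    """Independent running-sum oracle (plain python loop, same tie rule)."""
    hits = [g in genes for g in items]
    n, nh = len(items), sum(hits)
    wsum = sum(abs(s) ** w for s, h in zip(stats, hits) if h)
    rs, best, best_abs = 0.0, 0.0, -1.0
    for s, h in zip(stats, hits):
        if h:
            rs += (abs(s) ** w) / wsum if wsum > 0 else 1.0 / nh
        else:
            rs -= 1.0 / (n - nh)
        if abs(rs) > best_abs:  # first occurrence wins, matching argmax
            best, best_abs = rs, abs(rs)
    return best


TOY = RankedList(["g1", "g2", "g3", "g4", "g5"], [5.0, 4.0, 3.0, 2.0, 1.0])


class TestEnrichmentScore:
    @pytest.mark.parametrize(
        "genes, expected_es, expected_lead",
        [
            ({"g1", "g2"}, 1.0, ["g1", "g2"]),        # top block peaks at +1
            ({"g4", "g5"}, -1.0, ["g4", "g5"]),       # bottom block dips to -1
            ({"g2", "g4"}, -1.0 / 3.0, ["g2", "g4"]),  # hand-computed running sum
        ],
    )
    def test_hand_computed_toy_scores(self, genes, expected_es, expected_lead):
        es, lead = enrichment_score(TOY, SignatureSet("s", frozenset(genes)))
        assert es == pytest.approx(expected_es, abs=1e-12)
        assert lead == expected_lead

    def test_whole_list_set_has_unit_score(self):
        es, lead = enrichment_score(TOY, SignatureSet("all", frozenset(TOY.items)))
        assert es == 1.0
        assert lead == list(TOY.items)

    def test_weight_zero_equals_ks_statistic(self):
        genes = {"g2", "g4"}
        es, _ = enrichment_score(TOY, SignatureSet("s", frozenset(genes)),
                                 weight_exponent=0.0)
        hit = np.array([g in genes for g in TOY.items])
        ks = np.cumsum(hit) / hit.sum() - np.cumsum(~hit) / (~hit).sum()
        expected = ks[np.argmax(np.abs(ks))]
        assert es == pytest.approx(expected, abs=1e-12)

    def test_no_overlap_raises(self):
        with pytest.raises(ValidationError, match="no overlap"):
            enrichment_score(TOY, SignatureSet("s", frozenset({"zz"})))

    def test_exhaustive_oracle_on_six_item_list(self):
        rng = np.random.default_rng(0)
        items = [f"x{i}" for i in range(6)]
        stats_ = np.sort(rng.normal(size=6))[::-1]
        r = RankedList(items, stats_)
        for size in (2, 3):
            for combo in itertools.combinations(items, size):
                for w in (0.0, 1.0, 2.0):
                    es, _ = enrichment_score(r, SignatureSet("s", frozenset(combo)), w)
                    assert es == pytest.approx(
                        naive_es(r.items, r.stats, set(combo), w), abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 100.0))
    def test_positive_scaling_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        stats_ = rng.normal(size=12)
        items = [f"x{i}" for i in range(12)]
        genes = frozenset(rng.choice(items, 4, replace=False))
        for w in (0.0, 1.0):
            es1, _ = enrichment_score(RankedList(items, stats_),
                                      SignatureSet("s", genes), w)
            es2, _ = enrichment_score(RankedList(items, c * stats_),
                                      SignatureSet("s", genes), w)
            assert es2 == pytest.approx(es1, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_sign_flip_under_list_reversal(self, seed):
        from hypothesis import assume

        rng = np.random.default_rng(seed)
        stats_ = rng.normal(size=15)
        items = [f"x{i}" for i in range(15)]
        genes = frozenset(rng.choice(items, 5, replace=False))
        r = RankedList(items, stats_)
        # a run whose maximum and minimum deviations tie in magnitude is
        # degenerate: the extremum (hence the sign) is a tie-break artifact
        hit = np.array([g in genes for g in r.items])
        absw = np.abs(r.stats)
        inc = np.where(hit, absw / absw[hit].sum(), -1.0 / (~hit).sum())
        rs = np.cumsum(inc)
        # near-ties are fragile too: the reversed cumsum rounds differently
        assume(abs(abs(rs.max()) - abs(rs.min())) > 1e-9)
        es, _ = enrichment_score(r, SignatureSet("s", genes))
        es_flip, _ = enrichment_score(RankedList(items, -stats_), SignatureSet("s", genes))
        assert es_flip == pytest.approx(-es, abs=1e-12)


class TestRankedList:
    def test_sorted_descending_with_stable_ties(self):
        r = RankedList(["a", "b", "c"], [1.0, 3.0, 1.0])
        assert list(r.items) == ["b", "a", "c"]

    @pytest.mark.parametrize("items, stats", [
        (["a"], [1.0]),                     # too short
        (["a", "a"], [1.0, 2.0]),           # duplicate symbol
        (["a", "b"], [np.nan, 1.0]),        # non-finite stat
    ])
    def test_invalid_inputs_rejected(self, items, stats):
        with pytest.raises(ValidationError):
            RankedList(items, stats)


@pytest.fixture(scope="module")
def random_ranking():
    rng = np.random.default_rng(42)
    return RankedList([f"x{i}" for i in range(200)], rng.normal(size=200))


class TestGseaPreranked:

    def test_same_seed_reproducible(self, random_ranking):
        sets = [SignatureSet("s", frozenset({f"x{i}" for i in range(10, 25)}))]
        a = gsea_preranked(random_ranking, sets, n_perm=200, seed=9)
        b = gsea_preranked(random_ranking, sets, n_perm=200, seed=9)
        assert a[0].pval == b[0].pval and a[0].nes == b[0].nes and a[0].es == b[0].es

    def test_null_pvalues_approximately_uniform(self, random_ranking):
        rng = np.random.default_rng(7)
        sets = [SignatureSet(f"s{k}",
                             frozenset(rng.choice(random_ranking.items, 15, replace=False)))
                for k in range(200)]
        res = gsea_preranked(random_ranking, sets, n_perm=300, seed=1)
        ps = np.array([r.pval for r in res])
        assert abs((ps <= 0.1).mean() - 0.1) <= 0.05

    def test_top_block_set_attains_extreme_significance(self, random_ranking):
        genes = frozenset(random_ranking.items[:15])
        res = gsea_preranked(random_ranking, [SignatureSet("top", genes)],
                             n_perm=500, min_size=1, seed=2)[0]
        assert res.es > 0.8 and res.nes > 0
        # smallest attainable p is 1/(1 + same-side null count), bounded by
        # the permutation budget; with 500 permutations it cannot be smaller
        # than ~1/500 and should be within a factor ~2 of that floor
        assert 1.0 / 501 <= res.pval <= 0.01

    def test_size_limits_and_overlap_statuses(self, random_ranking):
        sets = [
            SignatureSet("tiny", frozenset({"x1", "x2"})),
            SignatureSet("foreign", frozenset({"nope1", "nope2", "nope3", "nope4", "nope5"})),
            SignatureSet("fine", frozenset({f"x{i}" for i in range(20)})),
        ]
        res = {r.set_name: r for r in
               gsea_preranked(random_ranking, sets, n_perm=100, min_size=5, seed=0)}
        assert res["tiny"].status == SKIPPED_SIZE
        assert res["foreign"].status == SKIPPED_NO_OVERLAP
        assert res["fine"].status == OK
        assert np.isnan(res["tiny"].pval)

    def test_all_sets_skipped_warns_and_returns_empty_ok(self, random_ranking):
        sets = [SignatureSet("foreign", frozenset({"zz1", "zz2", "zz3", "zz4", "zz5"}))]
        with pytest.warns(UserWarning, match="skipped"):
            res = gsea_preranked(random_ranking, sets, n_perm=100, seed=0)
        assert res[0].status == SKIPPED_NO_OVERLAP

    def test_padj_is_bh_over_tested_sets(self, random_ranking):
        rng = np.random.default_rng(3)
        sets = [SignatureSet(f"s{k}",
                             frozenset(rng.choice(random_ranking.items, 12, replace=False)))
                for k in range(25)]
        res = gsea_preranked(random_ranking, sets, n_perm=200, seed=5)
        from statsmodels.stats.multitest import multipletests

        expected = multipletests([r.pval for r in res], method="fdr_bh")[1]
        assert np.allclose([r.padj for r in res], expected)

    def test_leading_edge_subset_of_set_and_list(self, random_ranking):
        genes = frozenset(np.random.default_rng(4).choice(random_ranking.items, 30,
                                                          replace=False))
        res = gsea_preranked(random_ranking, [SignatureSet("s", genes)],
                             n_perm=100, seed=0)[0]
        assert set(res.leading_edge) <= genes
        assert res.size == 30
        assert -1.0 <= res.es <= 1.0
        assert np.sign(res.nes) == np.sign(res.es)


def test_cross_check_against_independent_gsea_implementation():
    """ES of the weighted running sum agrees with gseapy's prerank statistic."""
    gseapy = pytest.importorskip("gseapy")
    import pandas as pd

    rng = np.random.default_rng(11)
    genes = [f"G{i}" for i in range(40)]
    stats_ = np.sort(rng.normal(size=40))[::-1]
    sets = {"A": list(rng.choice(genes, 8, replace=False)),
            "B": list(rng.choice(genes, 12, replace=False))}
    rnk = pd.DataFrame({"gene": genes, "stat": stats_})
    out = gseapy.prerank(rnk=rnk, gene_sets=sets, permutation_num=50,
                         min_size=2, max_size=50, seed=1, outdir=None,
                         no_plot=True, threads=1).res2d
    r = RankedList(genes, stats_)
    for name, members in sets.items():
        es, _ = enrichment_score(r, SignatureSet(name, frozenset(members)))
        theirs = float(out.loc[out["Term"] == name, "ES"].iloc[0])
        assert es == pytest.approx(theirs, abs=1e-6)
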