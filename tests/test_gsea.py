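import dataclasses

import numpy as np
import pandas as pd
import pytest

import trilayer as tl
from oracles import brute_force_es


def _ranked(scores, genes=None):
    scores = np.asarray(scores, dtype=float)
    genes = genes or tuple(f"g{i}" for i in range(len(scores)))
    return tl.RankedList(tuple(genes), scores)


def _random_instance(rng, n_max=50, set_min=2, set_max=20):
    n = int(rng.integers(10, n_max + 1))
    scores = np.sort(rng.normal(size=n))[::-1]
    k = int(rng.integers(set_min, min(set_max, n - 1) + 1))
    members = rng.choice(n, k, replace=False)
    flags = np.zeros(n, dtype=bool)
    flags[members] = True
    return scores, flags


class TestRankGenes:
    def test_orders_by_descending_t(self):
        de = pd.DataFrame({"t": [2.0, -1.0, 0.5]}, index=["g1", "g2", "g3"])
        assert tl.rank_genes(de).genes == ("g1", "g3", "g2")

    def test_tie_breaks_lexically(self):
        de = pd.DataFrame({"t": [1.0, 1.0]}, index=["b", "a"])
        assert tl.rank_genes(de).genes == ("a", "b")

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=30)
        genes = [f"g{i}" for i in range(30)]
        de = pd.DataFrame({"t": t}, index=genes)
        shuffled = de.sample(frac=1.0, random_state=1)
        assert tl.rank_genes(de).genes == tl.rank_genes(shuffled).genes

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tl.rank_genes(pd.DataFrame({"t": []}))


class TestEnrichmentScore:
    def test_hand_computed_running_sum(self):
        ranked = _ranked([2.0, 1.0, 0.5, -0.5, -1.0])
        es, running, leading = tl.enrichment_score(ranked, {"g0", "g1"}, 1.0)
        np.testing.assert_allclose(
            running, [2 / 3, 1.0, 2 / 3, 1 / 3, 0.0], atol=1e-12
        )
        assert es == pytest.approx(1.0)
        assert leading == {"g0", "g1"}

    def test_single_top_gene_unweighted(self):
        ranked = _ranked([3.0, 1.0, -1.0, -2.0])
        es, _, _ = tl.enrichment_score(ranked, {"g0"}, 0.0)
        assert es == pytest.approx(1.0)

    def test_negation_reversal_flips_sign(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            scores, flags = _random_instance(rng)
            genes = tuple(f"g{i}" for i in range(len(scores)))
            members = {g for g, f in zip(genes, flags) if f}
            fwd = tl.RankedList(genes, scores)
            es_f, _, _ = tl.enrichment_score(fwd, members)
            es_r, _, _ = tl.enrichment_score(fwd.reversed(), members)
            assert es_r == pytest.approx(-es_f, abs=1e-12)

    def test_matches_bruteforce_walk(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            scores, flags = _random_instance(rng)
            ranked = _ranked(scores)
            members = {f"g{i}" for i in np.flatnonzero(flags)}
            for p in (0.0, 1.0, 2.0):
                es, running, _ = tl.enrichment_score(ranked, members, p)
                es_ref, running_ref = brute_force_es(scores, flags, p)
                np.testing.assert_allclose(running, running_ref, atol=1e-12)
                assert es == pytest.approx(es_ref, abs=1e-12)

    def test_es_bounded_by_one(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            scores, flags = _random_instance(rng)
            ranked = _ranked(scores)
            members = {f"g{i}" for i in np.flatnonzero(flags)}
            es, _, _ = tl.enrichment_score(ranked, members)
            assert abs(es) <= 1.0 + 1e-12

    def test_whole_universe_rejected(self):
        ranked = _ranked([1.0, -1.0])
        with pytest.raises(ValueError, match="universe"):
            tl.enrichment_score(ranked, {"g0", "g1"})

    def test_disjoint_set_rejected(self):
        ranked = _ranked([1.0, -1.0])
        with pytest.raises(ValueError, match="intersect"):
            tl.enrichment_score(ranked, {"zzz"})


@pytest.fixture(scope="module")
def null_ranked():
    rng = np.random.default_rng(7)
    return _ranked(np.sort(rng.normal(size=300))[::-1])


class TestGseaPreranked:
    def test_size_filter_excludes_small_sets(self, null_ranked):
        collection = {
            "small": [f"g{i}" for i in range(10)],
            "ok": [f"g{i}" for i in range(20)],
        }
        cfg = tl.GseaConfig(min_size=15, max_size=500, n_permutations=100, seed=0)
        res = tl.gsea_preranked(null_ranked, collection, cfg)
        assert list(res["set"]) == ["ok"]

    def test_planted_top_set_is_most_significant(self):
        rng = np.random.default_rng(8)
        scores = np.sort(rng.normal(size=400))[::-1]
        ranked = _ranked(scores)
        collection = {"planted": [f"g{i}" for i in range(20)]}
        collection.update(
            {
                f"rand{j}": [f"g{i}" for i in rng.choice(400, 25, replace=False)]
                for j in range(20)
            }
        )
        res = tl.gsea_preranked(
            ranked, collection, tl.GseaConfig(n_permutations=500, seed=1)
        )
        assert res.iloc[0]["set"] == "planted"
        assert res.iloc[0]["es"] > 0

    def test_deterministic_and_es_stable_across_permutations(self, null_ranked):
        collection = {"s": [f"g{i}" for i in range(0, 60, 3)]}
        cfg = tl.GseaConfig(n_permutations=200, seed=9)
        r1 = tl.gsea_preranked(null_ranked, collection, cfg)
        r2 = tl.gsea_preranked(null_ranked, collection, cfg)
        pd.testing.assert_frame_equal(r1, r2)
        r3 = tl.gsea_preranked(
            null_ranked, collection, dataclasses.replace(cfg, n_permutations=400)
        )
        assert r3["es"].iloc[0] == pytest.approx(r1["es"].iloc[0], abs=1e-15)

    def test_no_surviving_set_warns_and_returns_empty(self, null_ranked):
        with pytest.warns(UserWarning, match="size filter"):
            res = tl.gsea_preranked(
                null_ranked,
                {"tiny": ["g0", "g1"]},
                tl.GseaConfig(n_permutations=100, seed=0),
            )
        assert res.empty


class TestClassifyDirection:
    @staticmethod
    def _records(rows):
        return pd.DataFrame(
            rows, columns=["set", "size", "es", "nes", "p_value", "fdr_q"]
        )

    def test_forward_significant_is_up(self):
        fwd = self._records([("s", 20, 0.6, 2.0, 0.001, 0.01)])
        rev = self._records([("s", 20, 0.1, 0.5, 0.9, 1.0)])
        out = tl.classify_direction(fwd, rev, alpha=0.05)
        assert out.iloc[0]["direction"] == "up"
        assert out.iloc[0]["node_score"] == pytest.approx(3.0)

    def test_reverse_significant_is_down(self):
        fwd = self._records([("s", 20, 0.1, 0.5, 0.8, 1.0)])
        rev = self._records([("s", 20, 0.5, 2.0, 0.01, 0.05)])
        out = tl.classify_direction(fwd, rev, alpha=0.05)
        assert out.iloc[0]["direction"] == "down"
        assert out.iloc[0]["node_score"] == pytest.approx(-2.0)

    def test_bimodal_set_is_both(self):
        # members planted at both extremes of the ranking
        scores = np.linspace(4.0, -4.0, 200)
        ranked = _ranked(scores)
        members = [f"g{i}" for i in range(8)] + [f"g{i}" for i in range(192, 200)]
        rng = np.random.default_rng(10)
        collection = {"bimodal": members}
        collection.update(
            {
                f"rand{j}": [f"g{i}" for i in rng.choice(200, 20, replace=False)]
                for j in range(10)
            }
        )
        cfg = tl.GseaConfig(
            min_size=10, n_permutations=500, seed=2, statistic="pos"
        )
        fwd = tl.gsea_preranked(ranked, collection, cfg)
        rev = tl.gsea_preranked(
            ranked.reversed(), collection, dataclasses.replace(cfg, seed=3)
        )
        out = tl.classify_direction(fwd, rev, alpha=0.05).set_index("set")
        assert out.loc["bimodal", "direction"] == "both"

    def test_mismatched_collections_rejected(self):
        fwd = self._records([("a", 20, 0.5, 1.0, 0.01, 0.1)])
        rev = self._records([("b", 20, 0.5, 1.0, 0.01, 0.1)])
        with pytest.raises(ValueError, match="different sets"):
            tl.classify_direction(fwd, rev)
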