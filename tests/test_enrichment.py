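from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gltdseq.enrichment import enrichment_score, gsea, pi_value, rank_genes
from gltdseq.io import GeneSetCollection


def ranked_frame(scores, ids=None):
    ids = ids or [f"g{i}" for i in range(len(scores))]
    return pd.DataFrame(
        {"gene_id": ids, "pi_value": np.asarray(scores, float),
         "rank": np.arange(1, len(scores) + 1)}
    )


def exhaustive_gsea_p(scores, set_size, observed_es, weight_exponent=1.0):
    """Oracle: exact same-sign tail proportion over every same-size subset.

    This is the quantity the permutation p estimates (its plus-one
    correction vanishes as n_perm grows).
    """
    n = len(scores)
    null = []
    for positions in combinations(range(n), set_size):
        mask = np.zeros(n, dtype=bool)
        mask[list(positions)] = True
        es, _ = enrichment_score(np.asarray(scores, float), mask, weight_exponent)
        null.append(es)
    null = np.asarray(null)
    same = null > 0 if observed_es >= 0 else null < 0
    return int((np.abs(null[same]) >= abs(observed_es) - 1e-12).sum()) / int(same.sum())


class TestPiValue:
    @pytest.mark.parametrize(
        "lfc,padj,expected",
        [(0.5, 0.01, 1.0), (0.7, 1.0, 0.0), (-2.0, 0.1, -2.0)],
    )
    def test_formula(self, lfc, padj, expected):
        assert pi_value(lfc, padj) == pytest.approx(expected)

    def test_zero_padj_clamped_or_rejected(self):
        assert np.isfinite(pi_value(1.0, 0.0))
        with pytest.raises(ValueError):
            pi_value(1.0, 0.0, clamp=False)

    def test_sign_follows_fold_change(self):
        rng = np.random.default_rng(0)
        lfc = rng.normal(size=100)
        padj = rng.uniform(1e-10, 0.99, size=100)
        pi = pi_value(lfc, padj)
        assert np.all(np.sign(pi) == np.sign(lfc))


class TestRankGenes:
    def test_ordering_and_ties(self):
        de = pd.DataFrame(
            {"gene_id": ["b", "a", "c"], "log2fc": [3.0, -1.0, 3.0],
             "padj": [0.1, 0.1, 0.1]}
        )
        ranked = rank_genes(de)
        assert list(ranked["gene_id"]) == ["b", "c", "a"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_all_ties_follow_gene_id(self):
        de = pd.DataFrame(
            {"gene_id": ["z", "m", "a"], "log2fc": [0.0, 0.0, 0.0],
             "padj": [0.5, 0.5, 0.5]}
        )
        assert list(rank_genes(de)["gene_id"]) == ["a", "m", "z"]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        de = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(50)],
             "log2fc": rng.normal(size=50), "padj": rng.uniform(0.001, 1, 50)}
        )
        a = rank_genes(de)
        b = rank_genes(de.sample(frac=1, random_state=2).reset_index(drop=True))
        pd.testing.assert_frame_equal(a, b)

    def test_duplicate_ids_rejected(self):
        de = pd.DataFrame({"gene_id": ["a", "a"], "log2fc": [1, 2],
                           "padj": [0.1, 0.2]})
        with pytest.raises(ValueError):
            rank_genes(de)


class TestEnrichmentScore:
    def test_top_hit_running_sum(self):
        scores = np.array([2.0, 1.0, 1.0, 1.0, 1.0])
        mask = np.array([True, False, False, False, False])
        es, profile = enrichment_score(scores, mask)
        assert np.allclose(profile, [1.0, 0.75, 0.5, 0.25, 0.0])
        assert es == pytest.approx(1.0)

    def test_bottom_hit_running_sum(self):
        scores = np.ones(5)
        mask = np.array([False, False, False, False, True])
        es, profile = enrichment_score(scores, mask)
        assert np.allclose(profile, [-0.25, -0.5, -0.75, -1.0, 0.0])
        assert es == pytest.approx(-1.0)

    def test_zero_exponent_is_classic_ks(self):
        scores = np.array([2.0, 1.0, 1.0, 1.0, 1.0])
        mask = np.array([True, False, False, False, False])
        es_w, _ = enrichment_score(scores, mask, weight_exponent=0.0)
        es_flat, _ = enrichment_score(np.ones(5), mask, weight_exponent=1.0)
        assert es_w == pytest.approx(es_flat)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        n=st.integers(4, 25),
        k=st.integers(1, 6),
        seed=st.integers(0, 10**6),
    )
    def test_bounds_and_antisymmetry(self, n, k, seed):
        if k >= n:
            return
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=n))[::-1]
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=k, replace=False)] = True
        es, profile = enrichment_score(scores, mask)
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
        if abs(profile.max() + profile.min()) < 1e-9:
            return  # exact extremum tie: sign is a convention, not antisymmetric
        es_neg, _ = enrichment_score(-scores[::-1], mask[::-1])
        assert es_neg == pytest.approx(-es, abs=1e-9)

    def test_whole_universe_set_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score(np.ones(4), np.ones(4, dtype=bool))


class TestGsea:
    def test_permutation_p_matches_exhaustive_enumeration(self):
        scores = np.array([3.0, 2.0, 1.5, 1.0, 0.5, -0.5, -1.0, -2.0])
        ranked = ranked_frame(scores)
        sets = GeneSetCollection({"top2": {"g0", "g1"}, "bottom2": {"g6", "g7"}})
        out = gsea(ranked, sets, n_perm=4000, seed=5).set_index("set_name")
        for name in ("top2", "bottom2"):
            es = out.loc[name, "es"]
            exact = exhaustive_gsea_p(scores, 2, es)
            mc_err = 3 * np.sqrt(exact * (1 - exact) / 4000)
            assert abs(out.loc[name, "pvalue"] - exact) <= mc_err + 2 / 4000

    def test_deterministic_and_plus_one_convention(self):
        rng = np.random.default_rng(6)
        ranked = ranked_frame(np.sort(rng.normal(size=60))[::-1])
        sets = GeneSetCollection({"s": set(ranked["gene_id"].iloc[:5])})
        a = gsea(ranked, sets, n_perm=500, seed=7)
        b = gsea(ranked, sets, n_perm=500, seed=7)
        pd.testing.assert_frame_equal(a, b)
        assert (a["pvalue"] >= 1 / 501).all()
        assert (a["padj"] >= a["pvalue"] - 1e-15).all()

    def test_size_filter_and_errors(self):
        ranked = ranked_frame(np.linspace(2, -2, 20))
        sets = GeneSetCollection({"big": set(ranked["gene_id"].iloc[:15]),
                                  "small": {"g0"}})
        out = gsea(ranked, sets, n_perm=200, min_size=1, max_size=10, seed=1)
        assert list(out["set_name"]) == ["small"]  # "big" exceeds max_size
        with pytest.raises(ValueError, match="no gene sets retained"):
            gsea(ranked, sets, n_perm=200, min_size=2, max_size=10, seed=1)
        with pytest.raises(ValueError, match="n_perm"):
            gsea(ranked, sets, n_perm=10, seed=1)

    def test_disjoint_set_skipped_with_warning(self):
        ranked = ranked_frame(np.linspace(1, -1, 10))
        sets = GeneSetCollection({"absent": {"x1", "x2"}, "present": {"g0", "g1"}})
        with pytest.warns(UserWarning, match="absent"):
            out = gsea(ranked, sets, n_perm=200, seed=2)
        assert list(out["set_name"]) == ["present"]

    def test_leading_edge_contains_extreme_hits(self):
        ranked = ranked_frame(np.linspace(3, -3, 30))
        sets = GeneSetCollection({"top": {"g0", "g1", "g2"}})
        out = gsea(ranked, sets, n_perm=200, seed=3)
        assert set(out["leading_edge"].iloc[0]) == {"g0", "g1", "g2"}

    def test_recovery_of_generator_enriched_sets(self):
        from gltdseq.simulate import (
            SimulationConfig,
            assign_true_effects,
            generate_gene_sets,
            generate_gene_universe,
        )

        cfg = SimulationConfig(n_genes=2000, de_fraction=0.3, effect_scale=1.0,
                               gltd_slope=0.0, seed=11)
        u = generate_gene_universe(cfg.n_genes, cfg.seed)
        eff = assign_true_effects(u, cfg)
        coll = generate_gene_sets(u, eff, n_sets=12, n_enriched=3, set_size=60,
                                  enrichment_bias=4.0, seed=11)
        # rank by true effect (perfect DE table) so this isolates the GSEA stage
        de = pd.DataFrame(
            {"gene_id": u.index, "log2fc": eff["true_log2fc"].to_numpy(),
             "padj": np.where(eff["is_de"], 0.01, 0.9)}
        )
        out = gsea(rank_genes(de), coll, n_perm=1000, seed=12)
        enriched = out[out["set_name"].str.startswith("enriched")]
        null = out[out["set_name"].str.startswith("null")]
        assert (enriched["padj"] < 0.05).all()
        assert (null["padj"] < 0.05).mean() <= 0.2
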