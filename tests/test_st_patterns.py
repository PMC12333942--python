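import numpy as np
import pandas as pd
import pytest

from helpers import brute_enrichment_score
from lesionscape.geometry import HexLattice
from lesionscape.st_patterns import (
    SpotMatrix,
    compare_tls_classes,
    filter_spots,
    fit_nmf,
    fractional_expression,
    gsea_preranked,
    label_tls_spots,
    log_transform,
    module_score,
    pattern_marker_scores,
    pattern_vs_module,
)


def toy_spots(counts, composition=None, segments=None, n_cols=40):
    counts = np.asarray(counts)
    G, S = counts.shape
    lat = HexLattice(int(np.ceil(2 * S / n_cols)) + 2, n_cols)
    pos = lat.positions().iloc[:S].reset_index(drop=True)
    return SpotMatrix(
        counts=counts,
        genes=[f"g{i}" for i in range(G)],
        barcodes=[f"s{j}" for j in range(S)],
        positions=pos,
        composition=None if composition is None else pd.DataFrame(composition),
        segment_id=None if segments is None else pd.Series(segments),
    )


class TestFilterSpots:
    def test_predominant_label_rule(self):
        comp = {"ductal": [0.75, 0.5], "collagen": [0.25, 0.5], "non_tissue": [0, 0]}
        spots = toy_spots(np.ones((3, 2)), composition=comp)
        out, _ = filter_spots(spots)
        assert list(out.tissue_label) == ["ductal", "mixed"]

    def test_fat_spots_removed(self):
        comp = {"fat": [0.8, 0.1], "acinar": [0.2, 0.9], "non_tissue": [0, 0]}
        spots = toy_spots(np.ones((3, 2)), composition=comp)
        out, log = filter_spots(spots)
        assert out.n_spots == 1
        assert "fat" in log["reason"].iloc[0]

    def test_non_tissue_spots_removed(self):
        comp = {"acinar": [0.2, 1.0], "non_tissue": [0.8, 0.0]}
        spots = toy_spots(np.ones((3, 2)), composition=comp)
        out, _ = filter_spots(spots)
        assert out.n_spots == 1

    def test_low_umi_segment_removed_rule_by_rule(self):
        rng = np.random.default_rng(0)
        # segment A: median UMI 150; segment B: 400; one fat spot in B
        n = 30
        counts = np.zeros((50, 2 * n), dtype=int)
        for j in range(n):
            counts[:, j] = rng.multinomial(150, np.ones(50) / 50)
            counts[:, n + j] = rng.multinomial(400, np.ones(50) / 50)
        comp = {
            "acinar": [1.0] * (2 * n - 1) + [0.1],
            "fat": [0.0] * (2 * n - 1) + [0.9],
            "non_tissue": [0.0] * 2 * n,
        }
        segments = ["A"] * n + ["B"] * n
        spots = toy_spots(counts, composition=comp, segments=segments)
        out, log = filter_spots(spots, min_segment_median_umi=200)
        # oracle: all of A (30) and the fat spot drop
        assert out.n_spots == n - 1
        assert set(out.segment_id) == {"B"}
        assert len(log) == n + 1

    def test_composition_required(self):
        with pytest.raises(ValueError):
            filter_spots(toy_spots(np.ones((2, 2))))


class TestLabelTlsSpots:
    def test_labels_partition_and_neighbor_count(self):
        lat = HexLattice(20, 21)
        pos = lat.positions()
        spots = SpotMatrix(
            counts=np.ones((3, len(pos)), dtype=int),
            genes=["a", "b", "c"],
            barcodes=[f"s{j}" for j in range(len(pos))],
            positions=pos,
        )
        # hull = a small box around one interior spot
        j = pos.index[(pos.array_row == 10) & (pos.array_col == 10)][0]
        x, y = pos.loc[j, ["x_um", "y_um"]]
        hull = np.array(
            [(x - 20, y - 20), (x + 20, y - 20), (x + 20, y + 20), (x - 20, y + 20)]
        )
        out = label_tls_spots(spots, {"t0": hull}, lat, depth=2)
        counts = out.labels.value_counts()
        assert counts["TLS:t0"] == 1
        assert counts["TLS_neighbor"] == 18
        assert counts.sum() == len(pos)

    def test_depth_validation(self):
        lat = HexLattice(5, 5)
        spots = SpotMatrix(
            counts=np.ones((1, len(lat.positions())), dtype=int),
            genes=["a"],
            barcodes=[f"s{j}" for j in range(len(lat.positions()))],
            positions=lat.positions(),
        )
        with pytest.raises(ValueError):
            label_tls_spots(spots, {}, lat, depth=0)


class TestLogTransform:
    def test_exact_values(self):
        out = log_transform(np.array([[0, 1, 7]]))
        np.testing.assert_allclose(out, [[0.0, 1.0, 3.0]])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(np.array([[-1.0]]))


class TestNMF:
    def test_rank_one_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(0.5, 2, 40)
        v = rng.uniform(0.5, 2, 30)
        D = np.outer(u, v)
        dec = fit_nmf(D, K=1, alpha=0.0, seed=0)
        rel = np.linalg.norm(D - dec.reconstruction) / np.linalg.norm(D)
        assert rel < 1e-3

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(1)
        D = rng.uniform(0, 3, size=(50, 40))
        dec = fit_nmf(D, K=4, seed=1, max_iter=300)
        diffs = np.diff(dec.objective)
        assert (diffs <= 1e-8 * np.abs(dec.objective[:-1]) + 1e-9).all()

    def test_p_rows_rescaled_to_unit_max(self):
        rng = np.random.default_rng(2)
        D = rng.uniform(0, 3, size=(30, 25))
        dec = fit_nmf(D, K=3, seed=0, max_iter=200)
        np.testing.assert_allclose(dec.P.max(axis=1), 1.0, rtol=1e-9)
        assert (dec.A >= 0).all() and (dec.P >= 0).all()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_nmf(np.zeros((5, 5)), K=2)
        with pytest.raises(ValueError):
            fit_nmf(np.ones((5, 5)), K=6)
        with pytest.raises(ValueError):
            fit_nmf(-np.ones((5, 5)), K=2)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        D = rng.uniform(0, 3, size=(30, 20))
        a = fit_nmf(D, K=2, seed=7, max_iter=100)
        b = fit_nmf(D, K=2, seed=7, max_iter=100)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.P, b.P)


class TestFractionalExpression:
    def test_single_pattern_gene(self):
        from lesionscape.st_patterns import PatternDecomposition

        A = np.array([[2.0, 0.0, 0.0]])
        P = np.abs(np.random.default_rng(0).normal(1, 0.1, size=(3, 10)))
        dec = PatternDecomposition(A=A, P=P, K=3, objective=np.array([0.0]), seed=0)
        f, T = fractional_expression(dec)
        np.testing.assert_allclose(f[0], [1.0, 0.0, 0.0])

    def test_hand_computed_shares(self):
        from lesionscape.st_patterns import PatternDecomposition

        A = np.array([[1.0, 1.0]])
        P = np.array([[0.5, 0.5], [1.5, 1.5]])  # r = (1, 3)
        dec = PatternDecomposition(A=A, P=P, K=2, objective=np.array([0.0]), seed=0)
        f, T = fractional_expression(dec)
        np.testing.assert_allclose(f[0], [0.25, 0.75])
        assert T[0] == pytest.approx(4.0)

    def test_rows_sum_to_one(self):
        from lesionscape.st_patterns import PatternDecomposition

        rng = np.random.default_rng(4)
        A = rng.uniform(0, 2, size=(100, 4))
        P = rng.uniform(0, 1, size=(4, 50))
        dec = PatternDecomposition(A=A, P=P, K=4, objective=np.array([0.0]), seed=0)
        f, T = fractional_expression(dec)
        np.testing.assert_allclose(f[T > 0].sum(axis=1), 1.0, rtol=1e-9)


class TestPatternMarkers:
    def test_degenerate_stratum_no_markers(self):
        f = np.tile([1 / 3, 1 / 3, 1 / 3], (60, 1))
        res = pattern_marker_scores(f, np.ones(60))
        assert not res.marker.to_numpy().any()

    def test_exclusive_markers_recovered(self):
        rng = np.random.default_rng(0)
        f_bg = rng.dirichlet([300] * 3, size=300)
        f_mk = np.array(
            [[0.90, 0.05, 0.05]] * 10
            + [[0.05, 0.90, 0.05]] * 10
            + [[0.05, 0.05, 0.90]] * 10
        )
        f = np.vstack([f_bg, f_mk])
        res = pattern_marker_scores(f, rng.lognormal(3, 1, size=len(f)))
        M = res.marker.to_numpy()
        truth = np.zeros_like(M)
        for i in range(30):
            truth[300 + i, i // 10] = True
        tp = (M & truth.astype(bool)).sum()
        fp = (M & ~truth.astype(bool)).sum()
        fn = (~M & truth.astype(bool)).sum()
        assert 2 * tp / (2 * tp + fp + fn) >= 0.9

    def test_dual_pattern_gene_flagged_twice(self):
        rng = np.random.default_rng(1)
        f = np.vstack([rng.dirichlet([200] * 3, size=200), [[0.45, 0.45, 0.10]]])
        res = pattern_marker_scores(f, np.ones(len(f)))
        flags = res.marker.to_numpy()[-1]
        assert flags[0] and flags[1] and not flags[2]

    def test_small_strata_merged(self):
        rng = np.random.default_rng(2)
        f = rng.dirichlet([5, 5], size=8)
        res = pattern_marker_scores(f, rng.lognormal(0, 1, 8), n_strata=3)
        assert res.stratum[res.stratum >= 0].nunique() < 3


class TestModuleScore:
    def test_duplicate_signature_idempotent(self):
        rng = np.random.default_rng(0)
        D = rng.uniform(0, 5, size=(200, 40))
        genes = [f"g{i}" for i in range(200)]
        a = module_score(D, genes, ["g1", "g2", "g3"], seed=1)
        b = module_score(D, genes, ["g1", "g2", "g3", "g2", "g1"], seed=1)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_missing_genes_dropped_empty_rejected(self):
        D = np.ones((5, 4))
        genes = list("abcde")
        res = module_score(D, genes, ["a", "zz"], seed=0)
        assert res.signature == ["a"]
        with pytest.raises(ValueError):
            module_score(D, genes, ["zz"], seed=0)


class TestPatternStats:
    def test_perfect_linearity(self):
        x = np.linspace(0, 1, 50)
        r, r2, p = pattern_vs_module(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pattern_vs_module(np.ones(10), np.arange(10))

    def test_class_comparison_shifted_group(self):
        rng = np.random.default_rng(0)
        w = np.r_[rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(2, 1, 30)]
        cls = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
        (stat, p), pairwise = compare_tls_classes(w, cls)
        assert p < 0.01
        assert len(pairwise) == 3

    def test_singleton_class_dropped(self):
        w = np.r_[np.arange(10), [99.0]]
        cls = ["a"] * 5 + ["b"] * 5 + ["c"]
        (_, _), pairwise = compare_tls_classes(w, cls)
        assert set(pairwise["group_a"]) | set(pairwise["group_b"]) == {"a", "b"}


class TestGsea:
    @staticmethod
    def _scores(n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(
            rng.normal(size=n), index=[f"g{i}" for i in range(n)]
        )

    def test_top_ranked_set_extreme(self):
        scores = self._scores()
        top20 = list(scores.sort_values(ascending=False).index[:20])
        res = gsea_preranked(scores, {"top": top20}, n_perm=200, seed=0)
        assert res["ES"].iloc[0] > 0.9
        assert res["p"].iloc[0] <= 1 / 201 + 1e-12

    def test_reversed_ranking_negates_es(self):
        scores = self._scores(seed=3)
        members = list(scores.index[::7])[:15]
        es_fwd = gsea_preranked(scores, {"s": members}, n_perm=100, seed=0)["ES"].iloc[0]
        es_rev = gsea_preranked(-scores, {"s": members}, n_perm=100, seed=0)["ES"].iloc[0]
        assert es_fwd == pytest.approx(-es_rev, abs=1e-12)

    def test_es_matches_brute_force_loop(self):
        scores = self._scores(seed=5)
        ranked = scores.sort_values(ascending=False)
        rng = np.random.default_rng(1)
        for size in (5, 20, 60):
            members = list(rng.choice(scores.index, size, replace=False))
            res = gsea_preranked(scores, {"s": members}, n_perm=100, seed=0)
            oracle = brute_enrichment_score(
                list(ranked.index), np.abs(ranked.to_numpy()), members
            )
            assert res["ES"].iloc[0] == pytest.approx(oracle, abs=1e-12)

    def test_small_sets_skipped_and_bh_applied(self):
        scores = self._scores()
        sets = {"tiny": ["g0", "g1"], "ok": [f"g{i}" for i in range(10)]}
        res = gsea_preranked(scores, sets, n_perm=100, seed=0)
        assert list(res["set"]) == ["ok"]
        assert "p_adj" in res.columns
        with pytest.raises(ValueError):
            gsea_preranked(scores, sets, n_perm=10, seed=0)
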