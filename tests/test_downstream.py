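import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pseudomics.containers import GeneAnnotation, MotifAnnotation, PeakSet
from pseudomics.downstream import (
    compare_proportions,
    cross_study_fc_correlation,
    hypergeometric_enrichment,
    motif_enrichment,
    pathway_enrichment,
    promoter_peaks,
    spearman_network,
)


def hypergeom_bruteforce(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / math.comb(N, n)


class TestHypergeometric:
    def test_worked_example_76_over_15504(self):
        """N=20, K=5, n=5, k=4: [C(5,4)C(15,1)+C(5,5)] / C(20,5) = 76/15504."""
        universe = [f"g{i}" for i in range(20)]
        selection = universe[:5]
        members = universe[1:5] + [universe[10]]  # overlap k = 4
        out = hypergeometric_enrichment(selection, universe, {"S": members})
        assert out["p_value"].iloc[0] == pytest.approx(76 / 15504, rel=1e-12)
        assert out["overlap"].iloc[0] == 4

    def test_empty_selection_gives_p_one(self):
        universe = ["a", "b", "c"]
        out = hypergeometric_enrichment([], universe, {"S": ["a", "b"]})
        assert (out["p_value"] == 1.0).all()

    def test_set_equal_to_universe_gives_p_one(self):
        universe = ["a", "b", "c", "d"]
        out = hypergeometric_enrichment(["a", "b"], universe, {"S": universe})
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_matches_bruteforce_for_small_universes(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(1, 26))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            universe = [f"g{i}" for i in range(N)]
            members = list(rng.choice(universe, K, replace=False))
            selection = list(rng.choice(universe, n, replace=False))
            out = hypergeometric_enrichment(selection, universe, {"S": members})
            k = len(set(members) & set(selection))
            expected = hypergeom_bruteforce(k, N, K, n) if k > 0 else 1.0
            assert out["p_value"].iloc[0] == pytest.approx(min(expected, 1.0), rel=1e-9)


class TestPathwayEnrichment:
    def _diff(self, genes, lfc, fdr, cell_type="ct"):
        return pd.DataFrame({"gene_id": genes, "log2FC": lfc, "fdr": fdr,
                             "cell_type": cell_type})

    def test_all_up_skips_down_direction(self):
        df = self._diff([f"g{i}" for i in range(30)], np.ones(30),
                        np.linspace(0.01, 0.9, 30))
        with pytest.warns(UserWarning, match="down"):
            out = pathway_enrichment(df, {"S": [f"g{i}" for i in range(5)]}, top_n=10)
        assert set(out["direction"]) == {"up"}

    def test_planted_set_has_lowest_p(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(200)]
        fdr = rng.random(200)
        fdr[:20] = 1e-6  # the top genes
        df = self._diff(genes, np.ones(200), fdr)
        sets = {"planted": genes[:20],
                "random1": list(rng.choice(genes, 20, replace=False)),
                "random2": list(rng.choice(genes, 20, replace=False))}
        out = pathway_enrichment(df, sets, top_n=25)
        best = out.loc[out["p_value"].idxmin(), "set_id"]
        assert best == "planted"

    def test_input_order_invariance(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(60)]
        df = self._diff(genes, rng.choice([-1.0, 1.0], 60), rng.random(60))
        sets = {"S1": genes[:15], "S2": genes[30:50]}
        a = pathway_enrichment(df, sets, top_n=20)
        b = pathway_enrichment(df.sample(frac=1, random_state=3), sets, top_n=20)
        pd.testing.assert_frame_equal(
            a.sort_values(["cell_type", "direction", "set_id"]).reset_index(drop=True),
            b.sort_values(["cell_type", "direction", "set_id"]).reset_index(drop=True),
        )


class TestMotifEnrichment:
    def _fixture(self, n_peaks=100, motif_in=2):
        genes = GeneAnnotation(table=pd.DataFrame(
            {"chrom": ["chr1"], "start": [100_000], "end": [120_000], "strand": ["+"]},
            index=pd.Index(["g"], name="gene_id")))
        starts = [99_000, 99_500] + [200_000 + 1000 * i for i in range(n_peaks - 2)]
        peaks = PeakSet(table=pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": [s + 501 for s in starts]},
            index=pd.Index([f"p{i}" for i in range(n_peaks)], name="peak_id")))
        presence = np.zeros((n_peaks, 1), dtype=int)
        presence[:motif_in, 0] = 1  # motif present in the two promoter peaks only
        motifs = MotifAnnotation(table=pd.DataFrame(
            presence, index=peaks.peak_ids, columns=["M1"]))
        return genes, peaks, motifs

    def test_worked_example_1_over_4950(self):
        """2 promoter peaks, motif in exactly those 2 of 100: C(2,2)/C(100,2)."""
        genes, peaks, motifs = self._fixture()
        out = motif_enrichment("g", genes, peaks, motifs)
        assert out["p_value"].iloc[0] == pytest.approx(1 / 4950, rel=1e-9)

    def test_motif_in_all_peaks_gives_p_one(self):
        genes, peaks, motifs = self._fixture(motif_in=100)
        out = motif_enrichment("g", genes, peaks, motifs)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_gene_without_promoter_peaks_flagged_empty(self):
        genes = GeneAnnotation(table=pd.DataFrame(
            {"chrom": ["chr2"], "start": [5_000], "end": [9_000], "strand": ["-"]},
            index=pd.Index(["lonely"], name="gene_id")))
        _, peaks, motifs = self._fixture()
        out = motif_enrichment("lonely", genes, peaks, motifs)
        assert out.empty and out.attrs["no_promoter_peaks"]

    def test_promoter_window_is_strand_aware(self):
        genes = GeneAnnotation(table=pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [10_000, 10_000],
             "end": [12_000, 12_000], "strand": ["+", "-"]},
            index=pd.Index(["plus", "minus"], name="gene_id")))
        # peak upstream of the plus-strand TSS only
        peaks = PeakSet(table=pd.DataFrame(
            {"chrom": ["chr1"], "start": [8_200], "end": [8_701]},
            index=pd.Index(["p"], name="peak_id")))
        assert promoter_peaks("plus", genes, peaks) == ["p"]
        assert promoter_peaks("minus", genes, peaks) == []


class TestSpearmanNetwork:
    def _meta(self, names, modality="expression"):
        return pd.DataFrame({"modality": modality, "cell_type": "ct"},
                            index=pd.Index(names))

    def test_monotone_transform_gives_rho_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        feats = pd.DataFrame({"x": x, "expx": np.exp(x)})
        g = spearman_network(feats, self._meta(["x", "expx"]), None)
        assert g["x"]["expx"]["rho"] == pytest.approx(1.0)

    def test_p_close_to_permutation_oracle_at_n12(self):
        """The t-approximation p sits within 0.01 of a permutation p."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        feats = pd.DataFrame({"x": x, "y": y})
        g = spearman_network(feats, self._meta(["x", "y"]), None, p_threshold=1.0)
        p_t = g["x"]["y"]["p_value"]
        rho_obs = abs(stats.spearmanr(x, y).statistic)
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            hits += abs(stats.spearmanr(x, rng.permutation(y)).statistic) >= rho_obs - 1e-12
        assert abs(p_t - hits / n_perm) < 0.01

    def test_null_edge_rate_near_alpha(self):
        rng = np.random.default_rng(5)
        n, F = 34, 60
        feats = pd.DataFrame(rng.normal(size=(n, F)),
                             columns=[f"f{i}" for i in range(F)])
        g = spearman_network(feats, self._meta(feats.columns), None)
        n_pairs = F * (F - 1) / 2
        rate = g.number_of_edges() / n_pairs
        assert 0.02 <= rate <= 0.09  # binomial tolerance around 0.05

    def test_edges_shrink_as_threshold_tightens(self):
        rng = np.random.default_rng(6)
        feats = pd.DataFrame(rng.normal(size=(20, 15)),
                             columns=[f"f{i}" for i in range(15)])
        meta = self._meta(feats.columns)
        e = [spearman_network(feats, meta, None, p_threshold=t).number_of_edges()
             for t in (0.2, 0.05, 0.01)]
        assert e[0] >= e[1] >= e[2]

    def test_residualization_removes_covariate_driven_edges(self):
        rng = np.random.default_rng(7)
        cov = rng.normal(size=(40, 1))
        a = 3 * cov[:, 0] + 0.1 * rng.normal(size=40)
        b = 3 * cov[:, 0] + 0.1 * rng.normal(size=40)
        feats = pd.DataFrame({"a": a, "b": b})
        with_cov = spearman_network(feats, self._meta(["a", "b"]), cov, p_threshold=1.0)
        without = spearman_network(feats, self._meta(["a", "b"]), None, p_threshold=1.0)
        assert abs(with_cov["a"]["b"]["rho"]) < abs(without["a"]["b"]["rho"])

    def test_constant_feature_excluded(self):
        feats = pd.DataFrame({"a": np.arange(10.0), "c": np.ones(10)})
        meta = pd.DataFrame({"modality": ["prs", "prs"]}, index=["a", "c"])
        with pytest.warns(UserWarning, match="constant"):
            g = spearman_network(feats, meta, None)
        assert "c" not in g


class TestCrossStudyCorrelation:
    def _table(self, genes, lfc, ct="ct"):
        return pd.DataFrame({"gene_id": genes, "log2FC": lfc, "cell_type": ct})

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(8)
        t = pd.concat([self._table([f"g{i}" for i in range(20)],
                                   rng.normal(size=20), ct) for ct in ("a", "b")])
        corr, shared = cross_study_fc_correlation(t, t)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert (np.diag(shared) == 20).all()

    def test_hand_computed_pearson_on_five_genes(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        corr, _ = cross_study_fc_correlation(
            self._table(list("abcde"), x), self._table(list("abcde"), y)
        )
        assert corr.iloc[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_disjoint_genes_give_nan(self):
        corr, shared = cross_study_fc_correlation(
            self._table(["a", "b", "c"], [1, 2, 3]),
            self._table(["x", "y", "z"], [1, 2, 3]),
        )
        assert np.isnan(corr.iloc[0, 0]) and shared.iloc[0, 0] == 0


def wilcoxon_enumeration(diff: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    ranks = stats.rankdata(np.abs(diff))
    w_obs = ranks[diff > 0].sum()
    n = len(diff)
    total = ranks.sum()
    stat_obs = min(w_obs, total - w_obs)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if min(w, total - w) <= stat_obs + 1e-12:
            count += 1
    return count / 2**n


class TestCompareProportions:
    def _props(self, mat, donors=None):
        donors = donors or [f"d{i}" for i in range(mat.shape[0])]
        df = pd.DataFrame(mat, index=donors,
                          columns=[f"ct{i}" for i in range(mat.shape[1])])
        return df.div(df.sum(axis=1), axis=0)

    def test_identical_tables_give_p_one(self):
        rng = np.random.default_rng(9)
        a = self._props(rng.random((8, 4)) + 0.1)
        table, donor_corr = compare_proportions(a, a.copy())
        assert (table["p_value"] == 1.0).all()
        assert table["all_zero"].all()
        np.testing.assert_allclose(donor_corr, 1.0)

    def test_exact_p_matches_sign_enumeration_at_n6(self):
        rng = np.random.default_rng(10)
        a = self._props(rng.random((6, 3)) + 0.2)
        b = self._props(rng.random((6, 3)) + 0.2, donors=list(a.index))
        table, _ = compare_proportions(a, b)
        for _, row in table.iterrows():
            diff = (a[row["cell_type"]] - b[row["cell_type"]]).to_numpy()
            diff = diff[diff != 0]
            expected = wilcoxon_enumeration(diff)
            assert row["p_value"] == pytest.approx(expected, abs=1e-9)

    def test_shifted_cell_type_detected_after_fdr(self):
        rng = np.random.default_rng(11)
        base = rng.random((40, 4)) + 0.5
        a = self._props(base)
        shifted = base.copy()
        shifted[:, 0] = shifted[:, 0] * 1.6  # systematic shift in ct0
        b = self._props(shifted, donors=list(a.index))
        table, _ = compare_proportions(a, b)
        assert table.set_index("cell_type").loc["ct0", "significant"]
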