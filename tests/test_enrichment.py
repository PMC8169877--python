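"""GSEA running sum, permutation null, KS / rank-sum tests, states, profiles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdyn import (
    ValidationError,
    enrichment_score,
    ks_two_sample,
    metaprofile,
    preranked_gsea,
    rank_from_de,
    rank_sum_compare,
    state_distribution,
)
from .oracles import brute_gsea_es, brute_rank_sum_p, brute_u_statistic


class TestRankFromDe:
    def _de(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2fc", "wald", "padj"])

    def test_deg_thresholds(self):
        de = self._de([("up", 0.678, 5.0, 0.04),      # FC ~ 1.6: up-DEG
                       ("weak", 0.263, 4.0, 0.04),    # FC ~ 1.2: fails gate
                       ("down", -0.8, -5.0, 0.01),    # FC ~ 0.57: down-DEG
                       ("ns", 1.2, 2.0, 0.20)])       # padj fails
        ranked, up, down = rank_from_de(de, fdr=0.05, fc=1.5)
        assert up == {"up"} and down == {"down"}
        assert list(ranked["gene"]) == ["up", "weak", "ns", "down"]

    def test_wald_ties_broken_lexicographically(self):
        de = self._de([("b", 0, 1.0, 1.0), ("a", 0, 1.0, 1.0), ("c", 0, 2.0, 1.0)])
        ranked, _, _ = rank_from_de(de)
        assert list(ranked["gene"]) == ["c", "a", "b"]

    def test_missing_wald_rejected(self):
        de = self._de([("a", 0, np.nan, 1.0)])
        with pytest.raises(ValidationError):
            rank_from_de(de)


class TestEnrichmentScore:
    def test_whole_list_set_scores_one(self):
        assert enrichment_score(np.array([3.0, 2.0, 1.0]), np.array([0, 1, 2])) == 1.0

    def test_five_gene_worked_example(self):
        scores = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        assert enrichment_score(scores, np.array([0, 2]), weight=1.0) == pytest.approx(2 / 3)

    def test_matches_brute_force_on_random_lists(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = rng.integers(3, 30)
            k = rng.integers(1, n)
            hits = np.sort(rng.choice(n, size=k, replace=False))
            scores = np.sort(rng.normal(size=n))[::-1]
            w = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
            assert enrichment_score(scores, hits, w) == pytest.approx(
                brute_gsea_es(n, hits, scores, w), abs=1e-12)

    def test_weight_zero_equals_classical_form_exhaustively(self):
        # for weight 0 the running sum is the classical KS-style statistic;
        # verified against brute force for every hit subset at N = 8
        n = 8
        scores = np.arange(n, 0, -1).astype(float)
        for k in range(1, n):
            for hits in combinations(range(n), k):
                hit_arr = np.asarray(hits)
                assert enrichment_score(scores, hit_arr, 0.0) == pytest.approx(
                    brute_gsea_es(n, hits, scores, 0.0), abs=1e-12)


class TestPrerankedGsea:
    def _ranked(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"gene": [f"g{i:03d}" for i in range(n)],
                             "score": np.sort(rng.normal(size=n))[::-1]})

    def test_determinism_same_seed_same_pvalues(self):
        ranked = self._ranked(100)
        sets = {"A": [f"g{i:03d}" for i in range(0, 30, 3)],
                "B": [f"g{i:03d}" for i in range(50, 80, 2)]}
        r1 = preranked_gsea(ranked, sets, n_perm=200, seed=42)
        r2 = preranked_gsea(ranked, sets, n_perm=200, seed=42)
        pd.testing.assert_frame_equal(r1, r2)
        assert ((r1["p_value"] > 0) & (r1["p_value"] <= 1)).all()

    def test_small_sets_skipped(self):
        ranked = self._ranked(50)
        out = preranked_gsea(ranked, {"tiny": ["g000", "g001"]}, n_perm=50, seed=1)
        assert len(out) == 0

    def test_top_loaded_set_enriched(self):
        ranked = self._ranked(200)
        sets = {"top": [f"g{i:03d}" for i in range(10)],
                "spread": [f"g{i:03d}" for i in range(0, 200, 20)]}
        out = preranked_gsea(ranked, sets, n_perm=500, seed=7).set_index("name")
        assert out.loc["top", "es"] > 0.8
        assert out.loc["top", "p_value"] < 0.05

    def test_bh_adjustment_monotone_and_geq_raw(self):
        ranked = self._ranked(300)
        rng = np.random.default_rng(5)
        sets = {f"s{i}": [f"g{j:03d}" for j in rng.choice(300, 20, replace=False)]
                for i in range(25)}
        out = preranked_gsea(ranked, sets, n_perm=200, seed=3)
        assert (out["p_adjusted"] >= out["p_value"] - 1e-12).all()
        srt = out.sort_values("p_value")
        assert (np.diff(srt["p_adjusted"].to_numpy()) >= -1e-12).all()

    def test_leading_edge_subset_of_set(self):
        ranked = self._ranked(100)
        members = [f"g{i:03d}" for i in range(0, 40, 4)]
        out = preranked_gsea(ranked, {"A": members}, n_perm=100, seed=2)
        le = out.loc[0, "leading_edge"].split("|")
        assert set(le) <= set(members) and len(le) >= 1

    def test_empty_ranked_list_rejected(self):
        with pytest.raises(ValidationError):
            preranked_gsea(pd.DataFrame({"gene": [], "score": []}), {"A": ["x"]})


class TestKs:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2], [3, 4])
        assert d == 1.0

    def test_interleaved_half(self):
        d, _ = ks_two_sample([1, 3], [2, 4])
        assert d == 0.5

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_two_sample([1], [2, 3])


class TestRankSum:
    def test_fully_separated_exact_p(self):
        u, p = rank_sum_compare([1, 2, 3], [4, 5, 6])
        assert u == 0.0 and p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p = rank_sum_compare([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_single_swap_lowers_u(self):
        u_eq = rank_sum_compare([1, 2, 3], [1, 2, 3])[0]
        u_sw = rank_sum_compare([1, 2, 0], [1, 2, 3])[0]
        assert u_sw < u_eq

    def test_large_sample_path_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=40)
        b = rng.normal(0.5, 1, size=35)
        u, p = rank_sum_compare(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_exact_path_with_repeated_values(self):
        # multisets with cross-sample ties exercise the midrank enumeration
        for a, b in (((1, 1, 2), (2, 3, 3)), ((1, 2, 2, 4), (2, 2, 5)), ((5, 5), (5, 6, 7))):
            u, p = rank_sum_compare(a, b)
            assert u == pytest.approx(brute_u_statistic(a, b))
            assert p == pytest.approx(brute_rank_sum_p(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_compare([], [1])


def _pos(pairs):
    return pd.DataFrame(pairs, columns=["chrom", "pos"])


def _states(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


class TestStateDistribution:
    def test_planted_twofold_enrichment(self):
        states = _states([("chr1", 0, 100, "A", "."), ("chr1", 100, 200, "B", ".")])
        background = _pos([("chr1", i) for i in range(50)] + [("chr1", 100 + i) for i in range(50)])
        query = _pos([("chr1", i) for i in range(10)])
        out = state_distribution(query, background, states).set_index("state")
        assert out.loc["A", "log2_enrichment"] == pytest.approx(1.0)
        assert out.loc["A", "query_prop"] == 1.0

    def test_matched_proportions_zero_enrichment(self):
        states = _states([("chr1", 0, 100, "A", "."), ("chr1", 100, 200, "B", ".")])
        sites = _pos([("chr1", 10), ("chr1", 150)])
        out = state_distribution(sites, sites, states)
        assert (out["log2_enrichment"].dropna() == 0).all()

    def test_proportions_sum_to_one_with_unannotated(self):
        states = _states([("chr1", 0, 100, "A", ".")])
        background = _pos([("chr1", 50), ("chr1", 500), ("chr2", 7)])
        query = _pos([("chr1", 60), ("chr1", 300)])
        out = state_distribution(query, background, states)
        assert "unannotated" in set(out["state"])
        assert out["query_prop"].sum() == pytest.approx(1.0, abs=1e-9)
        assert out["background_prop"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_background_state_reported_missing(self):
        states = _states([("chr1", 0, 100, "A", "."), ("chr1", 100, 200, "B", ".")])
        background = _pos([("chr1", 10), ("chr1", 20)])
        query = _pos([("chr1", 150)])
        out = state_distribution(query, background, states).set_index("state")
        assert np.isnan(out.loc["B", "log2_enrichment"])

    def test_overlapping_states_rejected(self):
        states = _states([("chr1", 0, 100, "A", "."), ("chr1", 50, 200, "B", ".")])
        with pytest.raises(ValidationError):
            state_distribution(_pos([("chr1", 1)]), _pos([("chr1", 1)]), states)


class TestMetaprofile:
    def _peaks(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])

    def test_genome_tiling_peaks_give_all_ones(self):
        peaks = self._peaks([("chr1", 0, 10_000_000, "p", ".")])
        out = metaprofile(_pos([("chr1", 5000), ("chr1", 9000)]), peaks, window=1000, bin_size=500)
        assert (out["value"] == 1.0).all()

    def test_no_peaks_give_all_zeros(self):
        out = metaprofile(_pos([("chr1", 5000)]), self._peaks([]), window=1000, bin_size=500)
        assert (out["value"] == 0.0).all()

    def test_half_window_overlap_example(self):
        peaks = self._peaks([("chr1", 5000, 6000, "p", ".")])
        out = metaprofile(_pos([("chr1", 5000)]), peaks, window=1000, bin_size=500)
        assert list(out["value"]) == [0.0, 0.0, 1.0, 1.0]

    def test_translation_invariance(self):
        rng = np.random.default_rng(10)
        centers = _pos([("chr1", int(p)) for p in rng.integers(10_000, 50_000, 20)])
        peaks = self._peaks([("chr1", int(s), int(s) + 300, "p", ".")
                             for s in rng.integers(10_000, 50_000, 15)])
        base = metaprofile(centers, peaks, window=2000, bin_size=100)
        shift = 1_000_000
        centers2 = centers.assign(pos=centers["pos"] + shift)
        peaks2 = peaks.assign(start=peaks["start"] + shift, end=peaks["end"] + shift)
        shifted = metaprofile(centers2, peaks2, window=2000, bin_size=100)
        pd.testing.assert_frame_equal(base, shifted)

    def test_window_not_divisible_rejected(self):
        with pytest.raises(ValidationError):
            metaprofile(_pos([("chr1", 10)]), self._peaks([]), window=1000, bin_size=300)

    def test_empty_centers_rejected(self):
        with pytest.raises(ValidationError):
            metaprofile(_pos([]), self._peaks([]), window=1000, bin_size=500)
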