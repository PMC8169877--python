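"""Enrichment statistics: pre-ranked GSEA, distribution comparisons,
chromatin-state distributions and peak metaprofiles.

The GSEA here is the weighted Kolmogorov–Smirnov-style running sum over a
pre-ranked gene list: hits advance by |score|^weight (normalised so the hit
increments sum to 1), misses retreat by 1/(N − N_hit), and the enrichment
score (ES) is the signed extremum of the running sum.  Significance comes
from a gene-label permutation null: ``n_perm`` random same-size gene draws,
a direction-matched permutation p with the +1 floor, and NES = ES divided by
the mean |permutation ES| of matching sign.  Benjamini–Hochberg adjustment
is applied across all tested sets in one batch.
"""

from __future__ import annotations

import logging
from math import comb

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ValidationError

logger = logging.getLogger("methdyn")

GSEA_MIN_SIZE = 5
GSEA_MAX_SIZE = 2000


# ---------------------------------------------------------------------------
# Ranking from differential expression


def rank_from_de(de: pd.DataFrame, fdr: float = 0.05, fc: float = 1.5):
    """Build a Wald-statistic ranking and the DEG up/down sets.

    The ranked list is ordered by Wald statistic descending, ties broken
    lexicographically by gene symbol.  A gene is an up-DEG when its adjusted
    p < ``fdr`` and its fold change 2^log2FC > ``fc``; a down-DEG when the
    fold change is below 1/``fc``.

    Returns (ranked DataFrame [gene, score], up set, down set).
    """
    if "wald" not in de.columns or de["wald"].isna().all():
        raise ValidationError("DE table lacks a Wald statistic column")
    ranked = de[["gene", "wald"]].rename(columns={"wald": "score"})
    ranked = ranked.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    ranked = ranked.reset_index(drop=True)
    sig = de["padj"].notna() & (de["padj"] < fdr)
    foldchange = np.exp2(de["log2fc"].to_numpy(dtype=float))
    up = set(de.loc[sig & (foldchange > fc), "gene"])
    down = set(de.loc[sig & (foldchange < 1.0 / fc), "gene"])
    return ranked, up, down


def rank_from_scores(table: pd.DataFrame, gene_col: str = "gene", score_col: str = "score") -> pd.DataFrame:
    """Rank any per-gene score table (e.g. TSS methylation variability)
    descending, ties broken by gene symbol."""
    ranked = table[[gene_col, score_col]].rename(columns={gene_col: "gene", score_col: "score"})
    return ranked.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Pre-ranked GSEA


def enrichment_score(scores: np.ndarray, hit_idx: np.ndarray, weight: float = 1.0) -> float:
    """Signed extremum of the weighted running sum for hits at ``hit_idx``
    (sorted positions into the descending-ranked ``scores``)."""
    n = len(scores)
    k = len(hit_idx)
    if k == 0:
        raise ValidationError("enrichment_score: empty hit set")
    if k == n:
        return 1.0
    w = np.abs(scores[hit_idx]) ** weight
    total = w.sum()
    cumw = np.cumsum(w) / total if total > 0 else (np.arange(1, k + 1) / k)
    misses_before = hit_idx - np.arange(k)
    miss_unit = 1.0 / (n - k)
    after_hit = cumw - misses_before * miss_unit
    before_hit = np.concatenate(([0.0], cumw[:-1])) - misses_before * miss_unit
    max_dev = after_hit.max()
    min_dev = min(before_hit.min(), 0.0)
    # positive side wins an analytic tie (tolerance absorbs summation noise)
    return float(max_dev) if max_dev >= -min_dev - 1e-12 else float(min_dev)


def _leading_edge(genes_ranked, hit_idx, scores, weight, es):
    """Hit genes at or before (after, for negative ES) the running-sum extremum."""
    n, k = len(scores), len(hit_idx)
    if k == n:
        return [genes_ranked[i] for i in hit_idx]
    w = np.abs(scores[hit_idx]) ** weight
    total = w.sum()
    cumw = np.cumsum(w) / total if total > 0 else (np.arange(1, k + 1) / k)
    misses_before = hit_idx - np.arange(k)
    miss_unit = 1.0 / (n - k)
    after_hit = cumw - misses_before * miss_unit
    before_hit = np.concatenate(([0.0], cumw[:-1])) - misses_before * miss_unit
    if es >= 0:
        j = int(np.argmax(after_hit))
        chosen = hit_idx[: j + 1]
    else:
        j = int(np.argmin(before_hit))
        chosen = hit_idx[j:]
    return [genes_ranked[i] for i in chosen]


def preranked_gsea(ranked: pd.DataFrame, sets: dict[str, list[str]], weight: float = 1.0,
                   n_perm: int = 10000, seed: int = 0,
                   min_size: int = GSEA_MIN_SIZE, max_size: int = GSEA_MAX_SIZE) -> pd.DataFrame:
    """Run pre-ranked GSEA over a gene-set collection.

    Sets are intersected with the ranked genes; sets outside
    [min_size, max_size] after intersection are skipped (logged).  The
    permutation null for a given set size is computed once and shared by all
    sets of that size, so p-values across many same-size sets cost one null.

    Returns a DataFrame sorted by set name: name, size, es, nes, p_value,
    p_adjusted, leading_edge ('|'-joined).
    """
    if ranked.empty:
        raise ValidationError("ranked list is empty")
    genes = ranked["gene"].tolist()
    scores = ranked["score"].to_numpy(dtype=float)
    index_of = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    tested = []
    for name, members in sets.items():
        idx = sorted(index_of[g] for g in set(members) if g in index_of)
        if not (min_size <= len(idx) <= min(max_size, n)):
            logger.info("gsea: set %r skipped (size %d after intersection)", name, len(idx))
            continue
        tested.append((name, np.asarray(idx, dtype=np.int64)))
    if not tested:
        return pd.DataFrame(columns=["name", "size", "es", "nes", "p_value", "p_adjusted", "leading_edge"])

    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}

    def null_for(k: int) -> np.ndarray:
        if k not in null_cache:
            es_perm = np.empty(n_perm)
            for i in range(n_perm):
                draw = np.sort(rng.choice(n, size=k, replace=False))
                es_perm[i] = enrichment_score(scores, draw, weight)
            null_cache[k] = es_perm
        return null_cache[k]

    rows = []
    for name, idx in sorted(tested):
        es = enrichment_score(scores, idx, weight)
        null = null_for(len(idx))
        same_sign = null >= 0 if es >= 0 else null < 0
        matched = null[same_sign]
        hits = int((np.abs(matched) >= abs(es)).sum())
        # +1-floored, conditional on the matching-sign null (keeps null
        # p-values uniform; normalising by all permutations halves them)
        p = (1 + hits) / (1 + matched.size)
        denom = np.abs(matched).mean() if matched.size else np.nan
        nes = es / denom if denom and denom > 0 else np.nan
        le = _leading_edge(genes, idx, scores, weight, es)
        rows.append((name, len(idx), es, nes, p, le))

    out = pd.DataFrame(rows, columns=["name", "size", "es", "nes", "p_value", "leading_edge"])
    out["p_adjusted"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    out["leading_edge"] = out["leading_edge"].map("|".join)
    return out[["name", "size", "es", "nes", "p_value", "p_adjusted", "leading_edge"]]


# ---------------------------------------------------------------------------
# Two-sample distribution comparisons


def ks_two_sample(a, b):
    """Two-sided two-sample Kolmogorov–Smirnov test.

    Returns (D = sup |ECDF_a − ECDF_b|, asymptotic two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("KS test needs >= 2 values per sample")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def _mann_whitney_u(a, b):
    """U statistic of a vs b: #{a_i > b_j} + 0.5 #{a_i == b_j}."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[None, :]
    return float((a > b).sum() + 0.5 * (a == b).sum())


def _exact_rank_sum_p(pooled, n1, u_obs):
    """Exact two-sided permutation p for the Mann–Whitney U with ties.

    Enumerates the rank-sum distribution over all C(n, n1) label assignments
    via a subset-sum count over doubled midranks (exact with ties), and
    returns P(|U − n1 n2 / 2| >= |u_obs − n1 n2 / 2|).
    """
    n = len(pooled)
    n2 = n - n1
    ranks2 = (2 * stats.rankdata(pooled)).astype(np.int64)  # doubled midranks: integers
    max_sum = int(ranks2.sum())
    # counts[j, s] = number of j-subsets of the first i ranks with doubled rank sum s
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for r in ranks2:
        counts[1:, r:] += counts[:-1, : max_sum + 1 - r]
    dist = counts[n1]  # over doubled rank sums of sample 1
    total = comb(n, n1)
    # U = R1 - n1(n1+1)/2 ; doubled: 2U = sum2 - n1(n1+1)
    mu2 = n1 * n2  # doubled null mean of U
    dev_obs = abs(2 * u_obs - mu2)
    sums = np.arange(max_sum + 1)
    u2 = sums - n1 * (n1 + 1)
    extreme = np.abs(u2 - mu2) >= dev_obs - 1e-9
    return float(dist[extreme].sum() / total)


def rank_sum_compare(a, b):
    """Mann–Whitney rank-sum comparison of two samples.

    Exact permutation p (tie-aware enumeration) when both samples have
    <= 20 values; tie-corrected normal approximation otherwise.  Returns
    (U of a vs b, two-sided p).  Fully tied inputs give p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("rank-sum comparison needs non-empty samples")
    u = _mann_whitney_u(a, b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.warning("rank_sum_compare: all values tied across both samples")
        return u, 1.0
    if len(a) <= 20 and len(b) <= 20:
        p = _exact_rank_sum_p(pooled, len(a), u)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return u, min(p, 1.0)


# ---------------------------------------------------------------------------
# Chromatin-state distributions


UNANNOTATED = "unannotated"


def _assign_states(positions: pd.DataFrame, states: pd.DataFrame) -> np.ndarray:
    labels = np.full(len(positions), UNANNOTATED, dtype=object)
    st = states.sort_values(["chrom", "start"], kind="mergesort")
    prev_chrom, prev_end = None, -1
    for r in st.itertuples(index=False):
        if r.chrom == prev_chrom and r.start < prev_end:
            raise ValidationError("state intervals overlap; states must partition the genome")
        prev_chrom, prev_end = r.chrom, r.end
    pos_arr = positions["pos"].to_numpy()
    for chrom, sub in st.groupby("chrom", sort=False):
        mask = (positions["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        names = sub["name"].to_numpy()
        p = pos_arr[mask]
        j = np.searchsorted(starts, p, side="right") - 1
        inside = (j >= 0) & (p < ends[np.clip(j, 0, None)])
        lab = np.full(len(p), UNANNOTATED, dtype=object)
        lab[inside] = names[j[inside]]
        labels[mask] = lab
    return labels


def state_distribution(query: pd.DataFrame, background: pd.DataFrame, states: pd.DataFrame) -> pd.DataFrame:
    """Relative distribution of query vs background sites over chromatin states.

    Sites outside every state get the label 'unannotated'.  Per state the
    table reports counts, within-collection proportions (each column sums to
    1), log2(query proportion / background proportion) where both are
    positive, and a two-sided binomial test of the query count against the
    background proportion.
    """
    q_labels = _assign_states(query, states)
    b_labels = _assign_states(background, states)
    all_states = sorted(set(states["name"]) | set(q_labels) | set(b_labels))
    nq, nb = len(q_labels), len(b_labels)
    rows = []
    for s in all_states:
        kq = int((q_labels == s).sum())
        kb = int((b_labels == s).sum())
        pq = kq / nq if nq else np.nan
        pb = kb / nb if nb else np.nan
        log2_enr = np.log2(pq / pb) if pq > 0 and pb > 0 else np.nan
        pval = stats.binomtest(kq, nq, pb).pvalue if 0 < pb < 1 and nq > 0 else np.nan
        rows.append((s, kb, kq, pb, pq, log2_enr, pval))
    return pd.DataFrame(rows, columns=["state", "background_count", "query_count",
                                       "background_prop", "query_prop",
                                       "log2_enrichment", "p_value"])


# ---------------------------------------------------------------------------
# Peak metaprofiles around site groups


def metaprofile(centers, peaks: pd.DataFrame, window: int = 2000, bin_size: int = 100,
                mode: str = "frequency") -> pd.DataFrame:
    """Average peak signal in bins around centered genomic positions.

    ``centers`` is either a positions DataFrame (chrom, pos) or a dict of
    group name -> positions DataFrame; one profile per group.  Each window
    [center − window, center + window) is split into 2·window/bin bins.  In
    'frequency' mode the per-bin value is the fraction of centers whose bin
    overlaps at least one peak; in 'signal' mode it is the mean over centers
    of the overlap-length-weighted mean of the peaks' score column.

    Returns a tidy DataFrame: group, bin_start, bin_end (bp offsets from the
    center), value.
    """
    if window % bin_size != 0:
        raise ValidationError("window must be divisible by bin size")
    if mode not in ("frequency", "signal"):
        raise ValidationError(f"unknown metaprofile mode: {mode!r}")
    if not isinstance(centers, dict):
        centers = {"sites": centers}
    trees: dict[str, IntervalTree] = {}
    for r in peaks.itertuples(index=False):
        score = float(getattr(r, "score", 1.0) or 1.0) if mode == "signal" else 1.0
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, score)
    n_bins = 2 * window // bin_size
    offsets = -window + bin_size * np.arange(n_bins)
    rows = []
    for group, pos_df in centers.items():
        if pos_df.empty:
            raise ValidationError(f"metaprofile: group {group!r} has no centers")
        acc = np.zeros(n_bins)
        for r in pos_df.itertuples(index=False):
            tree = trees.get(r.chrom)
            if tree is None:
                continue
            for i, off in enumerate(offsets):
                lo, hi = r.pos + int(off), r.pos + int(off) + bin_size
                hits = tree.overlap(lo, hi)
                if not hits:
                    continue
                if mode == "frequency":
                    acc[i] += 1.0
                else:
                    ww = np.array([min(h.end, hi) - max(h.begin, lo) for h in hits], dtype=float)
                    vv = np.array([h.data for h in hits], dtype=float)
                    acc[i] += float((ww * vv).sum() / ww.sum())
        acc /= len(pos_df)
        for i in range(n_bins):
            rows.append((group, int(offsets[i]), int(offsets[i]) + bin_size, acc[i]))
    return pd.DataFrame(rows, columns=["group", "bin_start", "bin_end", "value"])
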