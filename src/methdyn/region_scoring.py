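"""TSS / CpG-island windowing and methylation-dispersion scoring.

The dispersion score of a genomic window is the mean, over CpGs contained in
the window, of each CpG's standard deviation of methylation fractions across
the time points (sample sd, ddof=1 by default).  TSS windows are the
transcription start site ± 5 kb; CpG-island windows are the island
boundaries ± 500 bp.  Only windows holding at least ``min_cpgs`` CpGs
(default 20) are scored.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dmp_calling import MethylationTimeCourse
from .io_formats import INTERVAL_COLUMNS, ConfigError, ValidationError, interval_member_indices

logger = logging.getLogger("methdyn")


def tss_position(strand: str, tx_start: int, tx_end: int) -> int:
    """Transcription start: txStart on '+', txEnd on '-'."""
    return tx_start if strand == "+" else tx_end


def make_tss_regions(models: pd.DataFrame, flank: int = 5000, chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """One window [TSS − flank, TSS + flank) per transcript, clipped to the
    chromosome when sizes are supplied (and at 0 always).  The window name is
    ``gene|transcript`` for gene-level aggregation downstream."""
    tss = np.where(models["strand"].values == "+", models["tx_start"].values, models["tx_end"].values)
    start = np.maximum(tss - flank, 0)
    end = tss + flank
    if chrom_sizes:
        limit = models["chrom"].map(chrom_sizes).to_numpy()
        if np.isnan(limit.astype(float)).any():
            raise ValidationError("chromosome missing from chrom_sizes")
        end = np.minimum(end, limit.astype(np.int64))
    out = pd.DataFrame(
        {
            "chrom": models["chrom"].values,
            "start": start.astype(np.int64),
            "end": end.astype(np.int64),
            "name": models["gene"].str.cat(models["transcript"], sep="|").values,
            "strand": models["strand"].values,
        }
    )
    return out[INTERVAL_COLUMNS]


def make_island_regions(islands: pd.DataFrame, flank: int = 500) -> pd.DataFrame:
    """Expand each island by ``flank`` bp on both sides, clipped at 0."""
    out = islands.copy()
    out["start"] = np.maximum(out["start"].values - flank, 0).astype(np.int64)
    out["end"] = (out["end"].values + flank).astype(np.int64)
    return out


def score_region_dispersion(tc: MethylationTimeCourse, regions: pd.DataFrame, min_cpgs: int = 20) -> pd.DataFrame:
    """Score every region holding >= ``min_cpgs`` CpGs of the time course.

    Per contained CpG the sd of its fractions across time points (ddof=1);
    the region score is the mean of those sds.  Overlapping regions are
    scored independently — a CpG may contribute to many windows.  Regions
    below the CpG floor are omitted (their count is logged).

    Returns interval columns + n_cpgs + mean_dispersion, in input region
    order.
    """
    if regions.empty:
        raise ValidationError("region set is empty")
    fr = tc.fractions()
    per_cpg_sd = fr.std(axis=1, ddof=1)
    rows = []
    n_skipped = 0
    pos = tc.sites[["chrom", "pos"]]
    for ridx, member_idx in interval_member_indices(pos, regions):
        n = len(member_idx)
        if n < min_cpgs:
            n_skipped += 1
            continue
        rows.append((ridx, n, float(per_cpg_sd[member_idx].mean())))
    if n_skipped:
        logger.info("score_region_dispersion: %d region(s) below min_cpgs=%d omitted", n_skipped, min_cpgs)
    if not rows:
        return regions.iloc[0:0].assign(n_cpgs=pd.Series(dtype=np.int64), mean_dispersion=pd.Series(dtype=float))
    idx, ns, scores = zip(*rows)
    out = regions.loc[list(idx)].copy()
    out["n_cpgs"] = np.asarray(ns, dtype=np.int64)
    out["mean_dispersion"] = np.asarray(scores, dtype=float)
    return out.reset_index(drop=True)


def gene_level_scores(scores: pd.DataFrame, models: pd.DataFrame | None = None,
                      expressed=None, agg: str = "mean") -> pd.DataFrame:
    """Aggregate transcript-window scores to one score per gene.

    The gene symbol is taken from the window name (``gene|transcript``).
    ``agg`` is 'mean' (default) or 'max'.  When an ``expressed`` gene set is
    given, genes outside it are dropped (only detectably expressed genes are
    ranked downstream).

    Returns a DataFrame: gene, score, n_regions, sorted by gene.
    """
    if agg not in ("mean", "max"):
        raise ConfigError(f"unknown gene aggregation: {agg!r}")
    if scores.empty:
        return pd.DataFrame({"gene": pd.Series(dtype=str), "score": pd.Series(dtype=float),
                             "n_regions": pd.Series(dtype=np.int64)})
    genes = scores["name"].str.partition("|")[0]
    tab = pd.DataFrame({"gene": genes, "score": scores["mean_dispersion"].values})
    if expressed is not None:
        tab = tab.loc[tab["gene"].isin(set(expressed))]
    grouped = tab.groupby("gene")["score"]
    out = grouped.agg(agg).to_frame("score")
    out["n_regions"] = grouped.size()
    return out.reset_index().sort_values("gene", kind="mergesort").reset_index(drop=True)


def percentile_exceedance(table: pd.DataFrame, gene_set, q: float = 0.90):
    """Count gene-set members whose score strictly exceeds the q-quantile of
    *all* gene scores (linear interpolation between order statistics).

    Returns (k exceeding, number of set members present in the table).
    """
    if table.empty:
        raise ValidationError("gene score table is empty")
    members = table.loc[table["gene"].isin(set(gene_set))]
    if members.empty:
        logger.warning("percentile_exceedance: gene set has no overlap with score table")
        return 0, 0
    threshold = float(np.quantile(table["score"].to_numpy(), q))
    k = int((members["score"].to_numpy() > threshold).sum())
    return k, len(members)
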