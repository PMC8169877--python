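"""CpG-island classification by DMP association and tumor-vs-normal shift.

Flanked CpG islands are partitioned into DMP-associated (>= 1 dynamic
methylation position falls inside the flanked interval) and non-DMP
islands.  For each island group, island-level mean beta values across
normal and tumor samples are pooled and compared (rank-sum and KS), with a
signed median delta (tumor − normal).  The expectation from normal
differentiation biology is that islands hosting dynamic methylation are the
ones that become hypermethylated in tumors, while non-DMP islands barely
move.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .enrichment import ks_two_sample, rank_sum_compare
from .io_formats import BetaMatrix, ValidationError, interval_member_indices

logger = logging.getLogger("methdyn")

DMP_ASSOCIATED = "DMP-associated"
NON_DMP = "non-DMP"


def classify_islands(islands_flanked: pd.DataFrame, dmps: pd.DataFrame) -> pd.DataFrame:
    """Label each flanked island DMP-associated iff >= 1 DMP position lies in
    [start, end) (half-open: a DMP exactly at ``end`` does not count).

    Returns the island table plus columns ``n_dmps`` and ``label``; every
    island is labeled exactly once.
    """
    out = islands_flanked.copy().reset_index(drop=True)
    n_dmps = np.zeros(len(out), dtype=np.int64)
    if not dmps.empty:
        pos = dmps[["chrom", "pos"]].reset_index(drop=True)
        for ridx, members in interval_member_indices(pos, out):
            n_dmps[ridx] = len(members)
    out["n_dmps"] = n_dmps
    out["label"] = np.where(n_dmps >= 1, DMP_ASSOCIATED, NON_DMP)
    return out


def summarize_island_methylation(betas: BetaMatrix, classes: pd.DataFrame) -> pd.DataFrame:
    """Per-island per-sample mean beta over the measured probes the island
    contains (missing entries skipped; islands with zero measured probes are
    excluded and counted).

    Returns a long DataFrame: island index, label, sample, group, mean_beta
    (NaN when every probe is missing for that sample).
    """
    vals = betas.values
    rows = []
    n_empty = 0
    for ridx, members in interval_member_indices(betas.coords, classes):
        if len(members) == 0:
            n_empty += 1
            continue
        sub = vals.iloc[members]
        means = sub.mean(axis=0, skipna=True)  # NaN if all probes missing
        label = classes.loc[ridx, "label"]
        for sample, m in means.items():
            rows.append((ridx, label, sample, betas.groups[sample], m))
    if n_empty:
        logger.info("summarize_island_methylation: %d island(s) without measured probes excluded", n_empty)
    return pd.DataFrame(rows, columns=["island", "label", "sample", "group", "mean_beta"])


def shift_report(summary: pd.DataFrame) -> pd.DataFrame:
    """Tumor-vs-normal methylation shift per island group.

    Pools island-level means across samples within each sample group and
    reports, per island group: median normal, median tumor, delta
    (tumor − normal), rank-sum p and KS D/p.  Island groups with no islands
    are omitted with a warning.
    """
    groups_present = set(summary["group"])
    if not {"normal", "tumor"} <= groups_present:
        raise ValidationError("shift_report needs both 'normal' and 'tumor' samples")
    rows = []
    for label in (DMP_ASSOCIATED, NON_DMP):
        sub = summary.loc[(summary["label"] == label) & summary["mean_beta"].notna()]
        if sub.empty:
            logger.warning("shift_report: no islands in group %r", label)
            continue
        normal = sub.loc[sub["group"] == "normal", "mean_beta"].to_numpy()
        tumor = sub.loc[sub["group"] == "tumor", "mean_beta"].to_numpy()
        med_n, med_t = float(np.median(normal)), float(np.median(tumor))
        _, p_rank = rank_sum_compare(tumor, normal)
        d, p_ks = ks_two_sample(tumor, normal) if len(tumor) > 1 and len(normal) > 1 else (np.nan, np.nan)
        rows.append((label, len(sub["island"].unique()), med_n, med_t, med_t - med_n, p_rank, d, p_ks))
    return pd.DataFrame(rows, columns=["island_group", "n_islands", "median_normal",
                                       "median_tumor", "delta", "rank_sum_p", "ks_d", "ks_p"])
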