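"""Per-CpG time-course assembly and dynamic methylation position (DMP) calling.

A DMP is a CpG whose methylation fraction changes *progressively* across the
exposure time course — strictly monotone in design order (0h < 1h < 24h <
96h for gains, reversed for losses) — with an overall change
|fraction(last) − fraction(first)| strictly greater than ``min_delta``
(default 0.20).  Coverage is gated per time point (default 20×) before any
site enters the time course.

Monotonicity is decided in exact integer arithmetic on count ratios
(cross-multiplication), so strict comparisons are never settled by floating
point round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ConfigError, ValidationError

DEFAULT_TIME_LABELS = ("0h", "1h", "24h", "96h")


@dataclass(frozen=True)
class TimeCourseDesign:
    """Ordered exposure time labels and the per-time-point coverage gate."""

    labels: tuple[str, ...] = DEFAULT_TIME_LABELS
    min_coverage: int = 20

    def __post_init__(self):
        if len(self.labels) < 3:
            raise ConfigError("a time-course design needs at least 3 time points")
        if len(set(self.labels)) != len(self.labels):
            raise ConfigError("time labels must be unique")
        if self.min_coverage < 1:
            raise ConfigError("minimum coverage must be >= 1")


@dataclass
class MethylationTimeCourse:
    """Joined per-CpG counts across all time points, coverage-gated.

    ``sites`` columns: chrom, pos, then per label meth_<l>, total_<l>,
    frac_<l>.  Every retained site has total >= design.min_coverage at every
    time point.
    """

    design: TimeCourseDesign
    sites: pd.DataFrame
    n_input_sites: int = 0

    def __len__(self):
        return len(self.sites)

    @property
    def labels(self):
        return self.design.labels

    def fractions(self) -> np.ndarray:
        """(n_sites, n_timepoints) float array of methylation fractions."""
        return self.sites[[f"frac_{l}" for l in self.labels]].to_numpy(dtype=float)

    def counts(self):
        """(meth, total) int arrays, each (n_sites, n_timepoints)."""
        meth = self.sites[[f"meth_{l}" for l in self.labels]].to_numpy(dtype=np.int64)
        total = self.sites[[f"total_{l}" for l in self.labels]].to_numpy(dtype=np.int64)
        return meth, total


def build_timecourse(tables: dict[str, pd.DataFrame], design: TimeCourseDesign) -> MethylationTimeCourse:
    """Inner-join per-time-point call tables on position and apply the
    per-time-point coverage gate.

    ``tables`` maps each design label to a methylation-call DataFrame
    (io_formats.CALL_COLUMNS).  If several tables (replicates) are supplied
    for one label as a list, counts are pooled by summation first.
    """
    missing = [l for l in design.labels if l not in tables]
    if missing:
        raise ConfigError(f"missing time point table(s): {missing}")
    joined = None
    n_union = 0
    for label in design.labels:
        tab = tables[label]
        if isinstance(tab, (list, tuple)):
            tab = _pool_replicates(tab)
        sub = tab[["chrom", "pos", "meth", "unmeth"]].copy()
        sub[f"total_{label}"] = sub["meth"] + sub["unmeth"]
        sub = sub.rename(columns={"meth": f"meth_{label}"}).drop(columns=["unmeth"])
        n_union = max(n_union, len(sub))
        joined = sub if joined is None else joined.merge(sub, on=["chrom", "pos"], how="inner")
    total_cols = [f"total_{l}" for l in design.labels]
    covered = (joined[total_cols] >= design.min_coverage).all(axis=1)
    joined = joined.loc[covered].sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    for l in design.labels:
        joined[f"frac_{l}"] = joined[f"meth_{l}"] / joined[f"total_{l}"]
    return MethylationTimeCourse(design=design, sites=joined, n_input_sites=n_union)


def _pool_replicates(tabs) -> pd.DataFrame:
    pooled = pd.concat([t[["chrom", "pos", "meth", "unmeth"]] for t in tabs])
    pooled = pooled.groupby(["chrom", "pos"], as_index=False, sort=False)[["meth", "unmeth"]].sum()
    return pooled


# ---------------------------------------------------------------------------
# DMP calling


def call_dmps(tc: MethylationTimeCourse, min_delta: float = 0.20, strict: bool = True) -> pd.DataFrame:
    """Call dynamic methylation positions from a built time course.

    A site is a DMP iff its fractions are monotone across all time points in
    design order (strictly, unless ``strict`` is off) *and*
    |fraction(last) − fraction(first)| > ``min_delta``.  Comparisons between
    adjacent time points use exact cross-multiplied counts.

    Returns a DataFrame: chrom, pos, direction ('hyper'/'hypo'), delta
    (signed, fraction(last) − fraction(first)), and the frac_<label>
    trajectory columns, sorted by (chrom, pos).
    """
    if len(tc.labels) < 3:
        raise ConfigError("DMP calling needs at least 3 time points")
    meth, total = tc.counts()
    # adjacent comparison i vs i+1: sign of meth_i*total_{i+1} - meth_{i+1}*total_i
    lhs = meth[:, :-1] * total[:, 1:]
    rhs = meth[:, 1:] * total[:, :-1]
    if strict:
        increasing = (lhs < rhs).all(axis=1)
        decreasing = (lhs > rhs).all(axis=1)
    else:
        increasing = (lhs <= rhs).all(axis=1)
        decreasing = (lhs >= rhs).all(axis=1)
    # overall gate: |m_L/t_L - m_0/t_0| > min_delta, cross-multiplied
    diff = meth[:, -1] * total[:, 0] - meth[:, 0] * total[:, -1]
    gate = np.abs(diff) > min_delta * (total[:, 0] * total[:, -1])
    sign = np.sign(diff)
    is_dmp = (increasing | decreasing) & gate & (sign != 0)
    out = tc.sites.loc[is_dmp, ["chrom", "pos"] + [f"frac_{l}" for l in tc.labels]].copy()
    fr = tc.fractions()[np.asarray(is_dmp)]
    out["delta"] = fr[:, -1] - fr[:, 0]
    out["direction"] = np.where(out["delta"] > 0, "hyper", "hypo")
    cols = ["chrom", "pos", "direction", "delta"] + [f"frac_{l}" for l in tc.labels]
    return out[cols].sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def split_by_direction(dmps: pd.DataFrame):
    """Partition a DMP table into (hyper, hypo) subsets."""
    hyper = dmps.loc[dmps["direction"] == "hyper"].reset_index(drop=True)
    hypo = dmps.loc[dmps["direction"] == "hypo"].reset_index(drop=True)
    return hyper, hypo


# ---------------------------------------------------------------------------
# Trajectory normalisation (Z-score plots of site groups)


def zscore_trajectories(tc: MethylationTimeCourse, groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean per-time-point Z-score trajectory for each named group of sites.

    Per site, z_t = (fraction_t − mean_t)/sd over the site's own time points
    (sample sd, ddof=1); a site constant over time gets an all-zero z.
    ``groups`` maps name -> integer row indices into ``tc.sites`` (disjoint).

    Returns a DataFrame indexed by group name with one column per time label.
    """
    seen: set[int] = set()
    for name, idx in groups.items():
        if len(idx) == 0:
            raise ValidationError(f"group {name!r} is empty")
        s = set(int(i) for i in np.asarray(idx))
        if seen & s:
            raise ValidationError("site groups must be disjoint")
        seen |= s
    fr = tc.fractions()
    mean = fr.mean(axis=1, keepdims=True)
    sd = fr.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (fr - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    rows = {name: z[np.asarray(idx, dtype=np.int64)].mean(axis=0) for name, idx in groups.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(tc.labels))


def dmp_row_indices(tc: MethylationTimeCourse, dmps: pd.DataFrame) -> np.ndarray:
    """Row indices into ``tc.sites`` of the sites listed in a DMP table."""
    key = tc.sites.reset_index().set_index(["chrom", "pos"])["index"]
    return key.loc[list(zip(dmps["chrom"], dmps["pos"]))].to_numpy()


# ---------------------------------------------------------------------------
# Cross-platform concordance


def platform_concordance(a: pd.DataFrame, b: pd.DataFrame, min_cov_a: int, min_cov_b: int):
    """Intersect two call tables after per-platform coverage thresholds and
    correlate their methylation fractions.

    Returns (n shared sites, Pearson r of paired fractions)."""
    if a.empty or b.empty:
        raise ValidationError("both call collections must be non-empty")

    def _gate(df, min_cov):
        cov = df["meth"] + df["unmeth"]
        return df.loc[cov >= min_cov, ["chrom", "pos", "fraction"]]

    pair = _gate(a, min_cov_a).merge(_gate(b, min_cov_b), on=["chrom", "pos"], suffixes=("_a", "_b"))
    if len(pair) < 2:
        raise ValidationError("fewer than 2 shared sites; correlation undefined")
    fa, fb = pair["fraction_a"].to_numpy(), pair["fraction_b"].to_numpy()
    if np.ptp(fa) == 0 or np.ptp(fb) == 0:
        import logging
        logging.getLogger("methdyn").warning(
            "platform_concordance: constant fractions on one platform; r undefined")
        return len(pair), float("nan")
    r = stats.pearsonr(fa, fb).statistic
    return len(pair), float(r)
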