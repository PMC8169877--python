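"""Readers and writers for the external file dialects used by the pipeline.

Everything in memory uses 0-based half-open coordinates.  The one input
dialect that does not — the bismark coverage table, which is 1-based
inclusive — is converted on read and back-converted on write.  Methylation
fractions are always recomputed from the read counts; the percent column of
a coverage file is never trusted for arithmetic.

Tables are held as plain :class:`pandas.DataFrame` objects with fixed column
sets (documented per reader); the only richer container is
:class:`BetaMatrix`, which pairs probe coordinates with a sample matrix and
sample-group labels.  All writers emit tab-separated UTF-8 with a single
header line prefixed ``#``; all readers skip ``#`` lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("methdyn")

# ---------------------------------------------------------------------------
# Errors


class MethdynError(Exception):
    """Base class for all package errors."""


class ParseError(MethdynError):
    """A file could not be parsed; the message carries the line number."""


class ValidationError(MethdynError):
    """Parsed content violates an invariant (coordinates, counts, ranges)."""


class ConfigError(MethdynError):
    """A configuration value or key is invalid."""


# ---------------------------------------------------------------------------
# Column contracts

CALL_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "fraction"]
INTERVAL_COLUMNS = ["chrom", "start", "end", "name", "strand"]
GENE_MODEL_COLUMNS = ["gene", "transcript", "chrom", "strand", "tx_start", "tx_end"]
DE_COLUMNS = ["gene", "log2fc", "wald", "padj"]


def _data_lines(path):
    """Yield (1-based line number, stripped line) skipping blanks and '#' lines."""
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield i, line


def _finish_calls(df: pd.DataFrame) -> pd.DataFrame:
    df["fraction"] = df["meth"] / (df["meth"] + df["unmeth"])
    return df[CALL_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Bismark coverage dialect (per-CpG methylation calls)


def read_bismark_coverage(path, merge_strands: bool = True) -> pd.DataFrame:
    """Read a bismark-style coverage TSV into a methylation-call table.

    Input columns: chrom, start (1-based), end, percent methylation,
    methylated count, unmethylated count.  Output columns ``CALL_COLUMNS``
    with ``pos`` 0-based and ``fraction`` recomputed from the counts.

    With ``merge_strands`` (the default, reflecting symmetric CpG
    methylation), calls at adjacent positions — the two cytosines of one
    CpG dinucleotide read on opposite strands — are summed into a single
    unstranded call at the lower (plus-strand C) position.
    """
    chroms, poss, meths, unmeths = [], [], [], []
    n_percent_mismatch = 0
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 6:
            raise ParseError(f"{path}: line {lineno}: expected 6 fields, got {len(parts)}")
        try:
            start = int(parts[1])
            percent = float(parts[3])
            meth = int(parts[4])
            unmeth = int(parts[5])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
        if meth < 0 or unmeth < 0:
            raise ValidationError(f"{path}: line {lineno}: negative read count")
        if meth + unmeth < 1:
            raise ValidationError(f"{path}: line {lineno}: zero total coverage")
        if start < 1:
            raise ValidationError(f"{path}: line {lineno}: 1-based start < 1")
        frac = meth / (meth + unmeth)
        if abs(percent / 100.0 - frac) > 5e-3:
            n_percent_mismatch += 1
        chroms.append(parts[0])
        poss.append(start - 1)
        meths.append(meth)
        unmeths.append(unmeth)
    if n_percent_mismatch:
        logger.warning(
            "%s: percent column disagrees with counts at %d rows; counts are authoritative",
            path, n_percent_mismatch,
        )
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "pos": pd.Series(poss, dtype=np.int64),
            "strand": ".",
            "meth": pd.Series(meths, dtype=np.int64),
            "unmeth": pd.Series(unmeths, dtype=np.int64),
        }
    )
    if merge_strands:
        df = merge_strand_calls(df)
    return _finish_calls(df)


def merge_strand_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Sum calls at adjacent positions (one CpG dinucleotide) into one call.

    Pairs (pos, pos+1) on the same chromosome are merged greedily from the
    left onto the lower position; total reads are conserved.
    """
    df = calls.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    same_chrom = df["chrom"].values[1:] == df["chrom"].values[:-1]
    adjacent = df["pos"].values[1:] - df["pos"].values[:-1] == 1
    pairable = np.concatenate([same_chrom & adjacent, [False]])
    # greedy left-to-right: a row already consumed as a partner cannot start a pair
    is_first = np.zeros(len(df), dtype=bool)
    taken = np.zeros(len(df), dtype=bool)
    for i in np.flatnonzero(pairable):
        if not taken[i]:
            is_first[i] = True
            taken[i] = taken[i + 1] = True
    merged = df.copy()
    idx = np.flatnonzero(is_first)
    for col in ("meth", "unmeth"):
        vals = merged[col].values.copy()
        vals[idx] += vals[idx + 1]
        merged[col] = vals
    merged["strand"] = "."
    keep = ~taken | is_first
    merged = merged.loc[keep].reset_index(drop=True)
    return _finish_calls(merged)


def write_bismark_coverage(calls: pd.DataFrame, path) -> None:
    """Write calls back to the 1-based coverage dialect (percent from counts)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#chrom\tstart\tend\tpercent\tmeth\tunmeth\n")
        for row in calls.itertuples(index=False):
            start = row.pos + 1
            pct = 100.0 * row.meth / (row.meth + row.unmeth)
            fh.write(f"{row.chrom}\t{start}\t{start}\t{pct:.10g}\t{row.meth}\t{row.unmeth}\n")


# ---------------------------------------------------------------------------
# BED intervals


def read_intervals_bed(path) -> pd.DataFrame:
    """Read BED3+ (0-based half-open) into an interval table.

    Columns: chrom, start, end, name ('' when absent), strand ('.' when
    absent).  Rows with start >= end are rejected.
    """
    rows = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}: line {lineno}: expected >= 3 fields")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
        if start < 0:
            raise ValidationError(f"{path}: line {lineno}: negative coordinate")
        if start >= end:
            raise ValidationError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
        name = parts[3] if len(parts) > 3 else ""
        strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
        rows.append((parts[0], start, end, name, strand))
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS).astype(
        {"start": np.int64, "end": np.int64}
    ) if rows else empty_intervals()


def empty_intervals() -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64),
         "end": pd.Series(dtype=np.int64), "name": pd.Series(dtype=str),
         "strand": pd.Series(dtype=str)}
    )


def write_intervals_bed(intervals: pd.DataFrame, path, extra_cols=()) -> None:
    """BED6 (score column fixed at 0) plus any extra columns."""
    cols = ["chrom", "start", "end", "name", "score", "strand"] + list(extra_cols)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for row in intervals.itertuples(index=False):
            d = row._asdict()
            d.setdefault("score", 0)
            fh.write("\t".join(str(d[c]) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# Gene models (refFlat / BED12)


def read_gene_models(path, dialect: str = "refFlat") -> pd.DataFrame:
    """Read transcript models; one row per transcript.

    refFlat: geneName, name, chrom, strand, txStart, txEnd, ... (txStart/
    txEnd already 0-based half-open).  BED12: the name field is taken as
    ``gene|transcript`` when it contains ``|``, otherwise it serves as both.
    Duplicate transcript ids are an error.
    """
    if dialect not in ("refFlat", "BED12"):
        raise ConfigError(f"unknown gene-model dialect: {dialect!r}")
    rows = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        try:
            if dialect == "refFlat":
                if len(parts) < 6:
                    raise ParseError(f"{path}: line {lineno}: expected >= 6 fields")
                gene, tx, chrom, strand = parts[0], parts[1], parts[2], parts[3]
                tx_start, tx_end = int(parts[4]), int(parts[5])
            else:
                if len(parts) < 6:
                    raise ParseError(f"{path}: line {lineno}: expected >= 6 fields")
                chrom, strand = parts[0], parts[5]
                tx_start, tx_end = int(parts[1]), int(parts[2])
                name = parts[3]
                gene, _, tx = name.partition("|")
                tx = tx or name
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
        if strand not in ("+", "-"):
            raise ValidationError(f"{path}: line {lineno}: strand must be + or -")
        if not (0 <= tx_start < tx_end):
            raise ValidationError(f"{path}: line {lineno}: bad transcript span")
        rows.append((gene, tx, chrom, strand, tx_start, tx_end))
    df = pd.DataFrame(rows, columns=GENE_MODEL_COLUMNS)
    dup = df["transcript"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate transcript id(s): {sorted(df.loc[dup, 'transcript'].unique())[:5]}"
        )
    return df.astype({"tx_start": np.int64, "tx_end": np.int64})


def write_gene_models_refflat(models: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#geneName\tname\tchrom\tstrand\ttxStart\ttxEnd\n")
        for r in models.itertuples(index=False):
            fh.write(f"{r.gene}\t{r.transcript}\t{r.chrom}\t{r.strand}\t{r.tx_start}\t{r.tx_end}\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT collection into {set name: member list} (members deduplicated,
    first-occurrence order).  Empty sets are skipped with a warning; duplicate
    set names are an error."""
    sets: dict[str, list[str]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}: line {lineno}: expected name, description, members")
        name = parts[0]
        members = list(dict.fromkeys(g for g in parts[2:] if g))
        if name in sets:
            raise ValidationError(f"{path}: line {lineno}: duplicate set name {name!r}")
        if not members:
            logger.warning("%s: line %d: set %r has no members; skipped", path, lineno, name)
            continue
        sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#name\tdescription\tmembers...\n")
        for name, members in sets.items():
            fh.write(name + "\tna\t" + "\t".join(members) + "\n")


# ---------------------------------------------------------------------------
# Differential-expression results


def read_de_table(path) -> pd.DataFrame:
    """Read a DE results TSV with columns gene, log2fc, wald, padj
    (header line prefixed '#'; 'NA' -> missing padj)."""
    df = pd.read_csv(path, sep="\t", comment=None, header=0, na_values=["NA", ""])
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing DE column(s): {missing}")
    df = df[DE_COLUMNS].copy()
    if df["gene"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene rows")
    bad = df["padj"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValidationError(f"{path}: adjusted p outside [0,1]")
    return df


def write_de_table(de: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(DE_COLUMNS) + "\n")
        de.to_csv(fh, sep="\t", header=False, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Beta-value matrices (array/sequencing methylation fractions)


@dataclass
class BetaMatrix:
    """Probe-level methylation fractions across grouped samples.

    ``coords``: DataFrame (chrom, pos) aligned row-wise with ``values``;
    ``values``: DataFrame of betas in [0,1] (NaN = missing), one column per
    sample; ``groups``: sample id -> group label ('normal' / 'tumor').
    """

    coords: pd.DataFrame
    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.coords) != len(self.values):
            raise ValidationError("coords and values row counts differ")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[~np.isnan(arr)]
        if finite.size and ((finite < 0) | (finite > 1)).any():
            raise ValidationError("beta value outside [0,1]")
        for s in self.values.columns:
            if s not in self.groups:
                raise ValidationError(f"sample {s!r} has no group label")
        labels = set(self.groups[s] for s in self.values.columns)
        if self.values.shape[1] and len(labels) < 1:
            raise ValidationError("no sample groups")

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


def read_beta_matrix(path, group_map: dict[str, str]) -> BetaMatrix:
    """Read a TSV of betas: columns chrom, pos, then one per sample."""
    df = pd.read_csv(path, sep="\t", header=0, na_values=["NA", ""])
    df.columns = [c.lstrip("#") for c in df.columns]
    if "chrom" not in df.columns or "pos" not in df.columns:
        raise ValidationError(f"{path}: need 'chrom' and 'pos' columns")
    coords = df[["chrom", "pos"]].astype({"pos": np.int64})
    values = df.drop(columns=["chrom", "pos"]).astype(float)
    return BetaMatrix(coords=coords, values=values, groups=dict(group_map))


def write_beta_matrix(bm: BetaMatrix, path) -> None:
    out = pd.concat([bm.coords.reset_index(drop=True), bm.values.reset_index(drop=True)], axis=1)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(out.columns) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False, na_rep="NA", float_format="%.10g")


def read_group_map(path) -> dict[str, str]:
    """Read a two-column TSV: sample id, group label."""
    groups = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}: line {lineno}: expected sample<TAB>group")
        groups[parts[0]] = parts[1]
    return groups


def write_group_map(groups: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#sample\tgroup\n")
        for s, g in groups.items():
            fh.write(f"{s}\t{g}\n")


# ---------------------------------------------------------------------------
# Position-in-interval utilities (shared by scoring / classification stages)


def positions_by_chrom(positions: pd.DataFrame) -> dict[str, np.ndarray]:
    """Map chrom -> sorted array of row indices into ``positions`` (by pos)."""
    out = {}
    for chrom, sub in positions.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].values, kind="mergesort")
        out[chrom] = sub.index.values[order]
    return out


def interval_member_indices(positions: pd.DataFrame, intervals: pd.DataFrame):
    """Yield (interval row index, ndarray of position row indices contained in
    [start, end)) for every interval.  A position may belong to many
    (overlapping) intervals; containment tests the single base ``pos``."""
    by_chrom = positions_by_chrom(positions)
    pos_sorted = {c: positions["pos"].values[idx] for c, idx in by_chrom.items()}
    for itv in intervals.itertuples():
        idx = by_chrom.get(itv.chrom)
        if idx is None:
            yield itv.Index, np.empty(0, dtype=np.int64)
            continue
        arr = pos_sorted[itv.chrom]
        lo = np.searchsorted(arr, itv.start, side="left")
        hi = np.searchsorted(arr, itv.end, side="left")
        yield itv.Index, idx[lo:hi]
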