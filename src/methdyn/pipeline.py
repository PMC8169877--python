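"""End-to-end orchestration: one validated config in, a report bundle out.

``run_full_analysis`` executes the stages in analysis order — time-course
assembly, DMP calling, Z-score trajectories, TSS dispersion scoring,
gene-level scores, rankings and pre-ranked GSEA, variance ECDF comparisons,
chromatin-state distribution, peak metaprofiles, island classification and
the tumor/normal shift report — writing every table as sorted TSV plus a
JSON manifest (parameter echo, seed, input checksums), so reruns with the
same config are byte-identical.  Stages whose optional inputs are absent
are skipped; a stage failure aborts with the stage name, moving completed
outputs under ``partial/``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import shutil
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cancer_shift import classify_islands, shift_report, summarize_island_methylation
from .dmp_calling import (
    TimeCourseDesign,
    build_timecourse,
    call_dmps,
    dmp_row_indices,
    zscore_trajectories,
)
from .enrichment import ks_two_sample, metaprofile, preranked_gsea, rank_from_de, rank_from_scores
from .io_formats import (
    ConfigError,
    MethdynError,
    read_beta_matrix,
    read_bismark_coverage,
    read_de_table,
    read_gene_models,
    read_gmt,
    read_group_map,
    read_intervals_bed,
)
from .region_scoring import (
    gene_level_scores,
    make_island_regions,
    make_tss_regions,
    score_region_dispersion,
)

logger = logging.getLogger("methdyn")

_INPUT_KEYS = {"methylation", "genes", "gene_dialect", "islands", "states", "peaks",
               "de_results", "gene_sets", "betas", "beta_groups", "expressed_genes"}
_PARAM_RANGES = {
    "min_coverage": (1, 10_000),
    "min_delta": (0.0, 1.0),
    "tss_flank": (0, 10_000_000),
    "island_flank": (0, 10_000_000),
    "min_cpgs": (1, 100_000),
    "gsea_weight": (0.0, 10.0),
    "gsea_n_perm": (1, 10_000_000),
    "gsea_seed": (0, 2**31 - 1),
    "gsea_min_size": (1, 100_000),
    "gsea_max_size": (1, 1_000_000),
    "metaprofile_window": (1, 10_000_000),
    "metaprofile_bin": (1, 10_000_000),
    "max_profile_centers": (1, 10_000_000),
    "fdr": (0.0, 1.0),
    "fc": (1.0, 1000.0),
}


@dataclass
class RunConfig:
    """Validated inputs and parameters of one full analysis run."""

    methylation: dict[str, str]
    genes: str
    islands: str
    outdir: str
    gene_dialect: str = "refFlat"
    states: str | None = None
    peaks: str | None = None
    de_results: str | None = None
    gene_sets: str | None = None
    betas: str | None = None
    beta_groups: str | None = None
    expressed_genes: str | None = None
    time_labels: tuple = ("0h", "1h", "24h", "96h")
    min_coverage: int = 20
    min_delta: float = 0.20
    strict: bool = True
    merge_strands: bool = True
    tss_flank: int = 5000
    island_flank: int = 500
    min_cpgs: int = 20
    gsea_weight: float = 1.0
    gsea_n_perm: int = 10000
    gsea_seed: int = 17
    gsea_min_size: int = 5
    gsea_max_size: int = 2000
    metaprofile_window: int = 2000
    metaprofile_bin: int = 100
    max_profile_centers: int = 2000
    fdr: float = 0.05
    fc: float = 1.5


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config; every violation is reported."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    problems: list[str] = []
    known_top = {"inputs", "params", "outdir"}
    for k in raw:
        if k not in known_top:
            problems.append(f"unknown top-level key: {k!r}")
    inputs = raw.get("inputs") or {}
    params = raw.get("params") or {}
    for k in inputs:
        if k not in _INPUT_KEYS:
            problems.append(f"unknown input key: {k!r}")
    field_names = {f.name for f in dataclasses.fields(RunConfig)}
    for k in params:
        if k not in field_names or k in _INPUT_KEYS or k == "outdir":
            problems.append(f"unknown parameter key: {k!r}")
    kwargs = {}
    meth = inputs.get("methylation")
    if not isinstance(meth, dict) or not meth:
        problems.append("inputs.methylation must map time labels to coverage files")
        meth = {}
    for label, p in meth.items():
        if not os.path.exists(str(p)):
            problems.append(f"methylation file for {label!r} not found: {p}")
    for key in ("genes", "islands"):
        p = inputs.get(key)
        if not p:
            problems.append(f"inputs.{key} is required")
        elif not os.path.exists(str(p)):
            problems.append(f"inputs.{key} not found: {p}")
    for key in ("states", "peaks", "de_results", "gene_sets", "betas", "beta_groups",
                "expressed_genes"):
        p = inputs.get(key)
        if p and not os.path.exists(str(p)):
            problems.append(f"inputs.{key} not found: {p}")
    if not raw.get("outdir"):
        problems.append("outdir is required")
    for k, v in params.items():
        if k in _PARAM_RANGES:
            lo, hi = _PARAM_RANGES[k]
            try:
                ok = lo <= float(v) <= hi
            except (TypeError, ValueError):
                ok = False
            if not ok:
                problems.append(f"params.{k}={v!r} outside [{lo}, {hi}]")
    w, b = params.get("metaprofile_window", 2000), params.get("metaprofile_bin", 100)
    try:
        if int(w) % int(b) != 0:
            problems.append("metaprofile_window must be divisible by metaprofile_bin")
    except (TypeError, ValueError):
        pass
    if problems:
        raise ConfigError("invalid run config:\n  - " + "\n  - ".join(problems))
    kwargs.update({k: v for k, v in inputs.items()})
    kwargs.update({k: v for k, v in params.items()})
    if "time_labels" in kwargs:
        kwargs["time_labels"] = tuple(kwargs["time_labels"])
    else:
        kwargs["time_labels"] = tuple(meth.keys())
    kwargs["outdir"] = raw["outdir"]
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# Output helpers (sorted, deterministic TSV)


def _write_table(df: pd.DataFrame, path, sort_by=None) -> None:
    out = df.sort_values(sort_by, kind="mergesort").reset_index(drop=True) if sort_by else df
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(map(str, out.columns)) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False, na_rep="NA", float_format="%.10g")


def write_dmps_bed(dmps: pd.DataFrame, path, labels) -> None:
    """BED6+2 per DMP: name, score=|delta|x1000, direction, trajectory."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tdirection\ttrajectory\n")
        for r in dmps.itertuples(index=False):
            traj = ",".join(f"{getattr(r, f'frac_{l}'):.6g}" for l in labels)
            score = int(round(abs(r.delta) * 1000))
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\tdmp_{r.chrom}_{r.pos}\t{score}\t.\t{r.direction}\t{traj}\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _subsample(df: pd.DataFrame, k: int) -> pd.DataFrame:
    """Deterministic, evenly spaced subsample of table rows."""
    if len(df) <= k:
        return df
    idx = np.linspace(0, len(df) - 1, k).round().astype(int)
    return df.iloc[np.unique(idx)].reset_index(drop=True)


class StageFailure(MethdynError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# The full analysis


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute every stage in order and write the report bundle.

    Returns {stage name: result object} for programmatic use.  Optional-input
    stages (GSEA on expression, states, metaprofile, cancer shift) are
    skipped when their inputs are absent from the config.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    written: list[str] = []
    results: dict = {}
    current_stage = "setup"

    def emit(name, df, sort_by=None):
        path = os.path.join(cfg.outdir, name)
        _write_table(df, path, sort_by=sort_by)
        written.append(path)

    try:
        current_stage = "build_timecourse"
        design = TimeCourseDesign(labels=tuple(cfg.time_labels), min_coverage=int(cfg.min_coverage))
        tables = {l: read_bismark_coverage(cfg.methylation[l], merge_strands=cfg.merge_strands)
                  for l in design.labels}
        tc = build_timecourse(tables, design)
        logger.info("build_timecourse: %d sites retained at >=%dx", len(tc), cfg.min_coverage)
        results["timecourse"] = tc
        emit("timecourse.tsv", tc.sites)

        current_stage = "call_dmps"
        dmps = call_dmps(tc, min_delta=float(cfg.min_delta), strict=bool(cfg.strict))
        results["dmps"] = dmps
        path = os.path.join(cfg.outdir, "dmps.bed")
        write_dmps_bed(dmps, path, design.labels)
        written.append(path)

        current_stage = "zscore_trajectories"
        dmp_idx = dmp_row_indices(tc, dmps) if len(dmps) else np.empty(0, dtype=np.int64)
        hyper_idx = dmp_idx[dmps["direction"].values == "hyper"] if len(dmps) else dmp_idx
        hypo_idx = dmp_idx[dmps["direction"].values == "hypo"] if len(dmps) else dmp_idx
        bg_idx = np.setdiff1d(np.arange(len(tc)), dmp_idx)
        groups = {"background": bg_idx}
        if len(hyper_idx):
            groups["hyper"] = hyper_idx
        if len(hypo_idx):
            groups["hypo"] = hypo_idx
        ztab = zscore_trajectories(tc, groups).reset_index(names="group")
        results["zscores"] = ztab
        emit("zscore_trajectories.tsv", ztab, sort_by="group")

        current_stage = "score_tss_dispersion"
        models = read_gene_models(cfg.genes, dialect=cfg.gene_dialect)
        tss = make_tss_regions(models, flank=int(cfg.tss_flank))
        tss_scores = score_region_dispersion(tc, tss, min_cpgs=int(cfg.min_cpgs))
        results["tss_scores"] = tss_scores
        emit("tss_scores.tsv", tss_scores, sort_by=["chrom", "start", "name"])

        current_stage = "gene_level_scores"
        expressed = None
        if cfg.expressed_genes:
            with open(cfg.expressed_genes, encoding="utf-8") as fh:
                expressed = {l.strip() for l in fh if l.strip() and not l.startswith("#")}
        gene_scores = gene_level_scores(tss_scores, models, expressed=expressed)
        results["gene_scores"] = gene_scores
        emit("gene_scores.tsv", gene_scores, sort_by="gene")

        sets = read_gmt(cfg.gene_sets) if cfg.gene_sets else None
        degs_up, degs_down = set(), set()
        if cfg.de_results:
            current_stage = "rank_from_de"
            de = read_de_table(cfg.de_results)
            ranked_expr, degs_up, degs_down = rank_from_de(de, fdr=float(cfg.fdr), fc=float(cfg.fc))
            results["ranked_expression"] = ranked_expr
            emit("de_ranked.tsv", ranked_expr)
            deg_tab = pd.DataFrame(
                sorted([(g, "up") for g in degs_up] + [(g, "down") for g in degs_down]),
                columns=["gene", "direction"],
            )
            results["degs"] = deg_tab
            emit("degs.tsv", deg_tab, sort_by="gene")
            if sets:
                current_stage = "gsea_expression"
                ge = preranked_gsea(ranked_expr, sets, weight=float(cfg.gsea_weight),
                                    n_perm=int(cfg.gsea_n_perm), seed=int(cfg.gsea_seed),
                                    min_size=int(cfg.gsea_min_size), max_size=int(cfg.gsea_max_size))
                results["gsea_expression"] = ge
                emit("gsea_expression.tsv", ge, sort_by="name")
        else:
            logger.info("no DE results supplied; expression ranking and GSEA skipped")

        if sets:
            current_stage = "gsea_methylation"
            ranked_meth = rank_from_scores(gene_scores)
            gm = preranked_gsea(ranked_meth, sets, weight=float(cfg.gsea_weight),
                                n_perm=int(cfg.gsea_n_perm), seed=int(cfg.gsea_seed),
                                min_size=int(cfg.gsea_min_size), max_size=int(cfg.gsea_max_size))
            results["gsea_methylation"] = gm
            emit("gsea_methylation.tsv", gm, sort_by="name")

        current_stage = "variance_ks"
        ks_rows = []
        bg_scores = gene_scores["score"].to_numpy()
        compare_sets = {}
        if degs_up or degs_down:
            compare_sets["DEG"] = degs_up | degs_down
        for name, members in (sets or {}).items():
            compare_sets[name] = set(members)
        for name, members in sorted(compare_sets.items()):
            sub = gene_scores.loc[gene_scores["gene"].isin(members), "score"].to_numpy()
            if len(sub) >= 2:
                d, p = ks_two_sample(sub, bg_scores)
                ks_rows.append((name, len(sub), d, p))
        ks_tab = pd.DataFrame(ks_rows, columns=["set", "n_genes", "ks_d", "ks_p"])
        results["variance_ks"] = ks_tab
        emit("variance_ks.tsv", ks_tab, sort_by="set")

        if cfg.states:
            current_stage = "state_distribution"
            from .enrichment import state_distribution
            states = read_intervals_bed(cfg.states)
            query = dmps[["chrom", "pos"]] if len(dmps) else tc.sites.iloc[0:0][["chrom", "pos"]]
            sd = state_distribution(query, tc.sites[["chrom", "pos"]], states)
            results["state_distribution"] = sd
            emit("state_distribution.tsv", sd, sort_by="state")

        if cfg.peaks:
            current_stage = "metaprofile"
            peaks = read_intervals_bed(cfg.peaks)
            centers = {"background": _subsample(tc.sites[["chrom", "pos"]], int(cfg.max_profile_centers))}
            hyper_tab = dmps.loc[dmps["direction"] == "hyper", ["chrom", "pos"]]
            hypo_tab = dmps.loc[dmps["direction"] == "hypo", ["chrom", "pos"]]
            if len(hyper_tab):
                centers["hyper"] = _subsample(hyper_tab, int(cfg.max_profile_centers))
            if len(hypo_tab):
                centers["hypo"] = _subsample(hypo_tab, int(cfg.max_profile_centers))
            mp = metaprofile(centers, peaks, window=int(cfg.metaprofile_window),
                             bin_size=int(cfg.metaprofile_bin))
            results["metaprofile"] = mp
            emit("metaprofile.tsv", mp, sort_by=["group", "bin_start"])

        current_stage = "classify_islands"
        islands = read_intervals_bed(cfg.islands)
        flanked = make_island_regions(islands, flank=int(cfg.island_flank))
        classes = classify_islands(flanked, dmps)
        results["island_classes"] = classes
        emit("island_classes.tsv", classes, sort_by=["chrom", "start"])

        if cfg.betas and cfg.beta_groups:
            current_stage = "cancer_shift"
            betas = read_beta_matrix(cfg.betas, read_group_map(cfg.beta_groups))
            summary = summarize_island_methylation(betas, classes)
            results["island_summary"] = summary
            emit("island_summary.tsv", summary, sort_by=["island", "sample"])
            rep = shift_report(summary)
            results["shift_report"] = rep
            emit("shift_report.tsv", rep, sort_by="island_group")

        current_stage = "manifest"
        manifest = {
            "package": "methdyn",
            "version": __version__,
            "params": {k: v for k, v in dataclasses.asdict(cfg).items()
                       if not isinstance(v, dict) and k != "outdir"},
            "seed": cfg.gsea_seed,
            "n_sites_retained": int(len(tc)),
            "n_dmps": int(len(dmps)),
            "inputs": {},
            "outputs": sorted(os.path.basename(p) for p in written),
        }
        all_inputs = dict(cfg.methylation)
        for key in ("genes", "islands", "states", "peaks", "de_results", "gene_sets",
                    "betas", "beta_groups", "expressed_genes"):
            p = getattr(cfg, key)
            if p:
                all_inputs[key] = p
        manifest["inputs"] = {k: _sha256(v) for k, v in sorted(all_inputs.items())}
        mpath = os.path.join(cfg.outdir, "manifest.json")
        with open(mpath, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        results["manifest"] = manifest
    except Exception as exc:
        partial = os.path.join(cfg.outdir, "partial")
        os.makedirs(partial, exist_ok=True)
        for p in written:
            if os.path.exists(p):
                shutil.move(p, os.path.join(partial, os.path.basename(p)))
        raise StageFailure(current_stage, exc) from exc
    return results
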