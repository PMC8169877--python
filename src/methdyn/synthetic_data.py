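"""Seeded synthetic study generator.

Emulates the statistical structure of an androgen time-course methylome
study on a small synthetic genome: per-CpG binomial bisulfite counts over
planted monotone trajectories at four exposure times, CpG-island and gene
annotations, chromatin-state segmentations and binding peaks with planted
enrichment at dynamic sites, a post-hoc differential-expression table with
a Wald-like statistic, and tumor/normal beta matrices with planted
hypermethylation of DMP-associated islands.  Every stream is derived from
one seed via spawned ``SeedSequence`` children, so each product is
individually reproducible and mutually consistent.

Ground truth (which CpGs are dynamic, which genes are differentially
expressed, which islands are shifted) is returned alongside every product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dmp_calling import DEFAULT_TIME_LABELS
from .io_formats import (
    CALL_COLUMNS,
    ConfigError,
    write_beta_matrix,
    write_bismark_coverage,
    write_de_table,
    write_gene_models_refflat,
    write_gmt,
    write_group_map,
    write_intervals_bed,
)
from .region_scoring import make_island_regions, make_tss_regions

STATE_LABELS = ("Promoter", "Enhancer", "Bivalent", "PolycombRepressed", "Quiescent")
STATE_BASE_PROBS = (0.05, 0.10, 0.05, 0.10, 0.70)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; ``seed`` is mandatory.

    Defaults mirror the study conditions the analysis assumes: four exposure
    times, ~1% of CpGs dynamic, planted overall deltas uniform in
    [0.25, 0.6], ~50x coverage, CpG islands hypomethylated (Beta(0.5, 8))
    and open sea hypermethylated (Beta(8, 0.5)), and a +0.2 tumor shift on
    DMP-associated islands.
    """

    seed: int
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    n_cpgs: int = 50_000
    island_count: int = 300
    island_size: int = 1500
    island_cpg_fraction: float = 0.25
    dynamic_fraction: float = 0.01
    delta_low: float = 0.25
    delta_high: float = 0.60
    trajectory: str = "linear"  # 'linear' or 'logistic' in time index
    coverage_mean: float = 50.0
    island_beta: tuple = (0.5, 8.0)
    open_sea_beta: tuple = (8.0, 0.5)
    time_labels: tuple = DEFAULT_TIME_LABELS
    time_scale: str = "index"  # 'index' or 'hours'
    n_genes: int = 400
    n_dynamic_genes: int = 40
    tss_dynamic_prob: float = 0.5
    tss_flank: int = 5000
    de_fraction: float = 0.10
    de_up_fraction: float = 0.8
    log2fc_scale: float = 1.0
    wald_se: float = 0.2
    luminal_set_size: int = 96
    luminal_overlap_prob: float = 0.8
    n_random_sets: int = 10
    random_set_size: int = 50
    tumor_shift: float = 0.2
    shifted_island_prob: float = 1.0
    beta_sd: float = 0.05
    probes_per_island: int = 8
    n_normal: int = 10
    n_tumor: int = 10
    state_segment: int = 2000
    dynamic_state_prob: float = 0.6
    peak_width: int = 400
    peak_at_hypo_prob: float = 0.3
    n_background_peaks: int = 200

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("SimulationConfig.seed is mandatory")
        for name in ("island_cpg_fraction", "dynamic_fraction", "tss_dynamic_prob",
                     "de_fraction", "de_up_fraction", "luminal_overlap_prob",
                     "shifted_island_prob", "dynamic_state_prob", "peak_at_hypo_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.delta_low <= self.delta_high <= 1.0:
            raise ConfigError("need 0 < delta_low <= delta_high <= 1")
        if self.trajectory not in ("linear", "logistic"):
            raise ConfigError(f"unknown trajectory shape: {self.trajectory!r}")
        if self.coverage_mean <= 0:
            raise ConfigError("coverage_mean must be positive")


def _time_grid(cfg: SimulationConfig) -> np.ndarray:
    """Monotone [0,1] grid over time points; by default the ordinal index,
    so the first exposure step carries as much signal as the later ones."""
    t = len(cfg.time_labels)
    if cfg.time_scale == "hours":
        hours = np.array([float(l.rstrip("h")) for l in cfg.time_labels])
        return (hours - hours[0]) / (hours[-1] - hours[0])
    return np.arange(t) / (t - 1)


def _trajectory_shape(cfg: SimulationConfig) -> np.ndarray:
    x = _time_grid(cfg)
    if cfg.trajectory == "logistic":
        f = 1.0 / (1.0 + np.exp(-6.0 * (x - 0.5)))
        return (f - f[0]) / (f[-1] - f[0])
    return x


class SyntheticStudy:
    """Lazy generator of all synthetic inputs for one configuration."""

    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        ss = np.random.SeedSequence(cfg.seed)
        kids = ss.spawn(5)
        self._rng_genome = np.random.default_rng(kids[0])
        self._rng_wgbs = np.random.default_rng(kids[1])
        self._rng_expr = np.random.default_rng(kids[2])
        self._rng_betas = np.random.default_rng(kids[3])
        self._rng_states = np.random.default_rng(kids[4])
        self._genome = None
        self._wgbs = None
        self._expression = None
        self._states = None
        self._peaks = None

    # -- genome layout -----------------------------------------------------

    @property
    def genome(self):
        """(islands IntervalSet, gene models, CpG position table)."""
        if self._genome is None:
            self._genome = self._build_genome()
        return self._genome

    def _build_genome(self):
        cfg, rng = self.cfg, self._rng_genome
        chroms = list(cfg.chrom_lengths)
        lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=np.int64)
        total = lengths.sum()
        # islands: evenly slotted per chromosome, random offset inside each
        # slot, so islands never overlap even after +/-500 bp flanking
        per_chrom = np.maximum(1, np.round(cfg.island_count * lengths / total).astype(int))
        isl_rows = []
        for ci, chrom in enumerate(chroms):
            k = per_chrom[ci]
            slot = lengths[ci] // k
            margin = slot - cfg.island_size - 2000
            if margin <= 0:
                raise ConfigError("island_count too high for chromosome lengths")
            offs = 1000 + rng.integers(0, margin, size=k)
            for j in range(k):
                start = j * slot + offs[j]
                isl_rows.append((chrom, int(start), int(start + cfg.island_size), f"island_{chrom}_{j}", "."))
        islands = pd.DataFrame(isl_rows, columns=["chrom", "start", "end", "name", "strand"])
        # CpG positions: a fraction inside islands, the rest genome-wide
        n_isl = int(round(cfg.island_cpg_fraction * cfg.n_cpgs))
        pick = rng.integers(0, len(islands), size=n_isl)
        isl_pos = islands["start"].values[pick] + rng.integers(0, cfg.island_size, size=n_isl)
        isl_chrom = islands["chrom"].values[pick]
        n_sea = cfg.n_cpgs - n_isl
        sea_chrom_idx = rng.choice(len(chroms), size=n_sea, p=lengths / total)
        sea_pos = (rng.random(n_sea) * (lengths[sea_chrom_idx] - 2)).astype(np.int64) + 1
        cpgs = pd.DataFrame(
            {
                "chrom": np.concatenate([isl_chrom, np.array(chroms, dtype=object)[sea_chrom_idx]]),
                "pos": np.concatenate([isl_pos, sea_pos]).astype(np.int64),
                "in_island": np.concatenate([np.ones(n_isl, bool), np.zeros(n_sea, bool)]),
            }
        )
        cpgs = cpgs.drop_duplicates(["chrom", "pos"]).sort_values(["chrom", "pos"], kind="mergesort")
        cpgs = cpgs.reset_index(drop=True)
        # gene models: one transcript per gene, TSS away from chromosome ends
        g_chrom_idx = rng.choice(len(chroms), size=cfg.n_genes, p=lengths / total)
        tss = (rng.random(cfg.n_genes) * (lengths[g_chrom_idx] - 4 * cfg.tss_flank)).astype(np.int64) + 2 * cfg.tss_flank
        strand = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
        span = rng.integers(5_000, 50_000, size=cfg.n_genes)
        genes = pd.DataFrame(
            {
                "gene": [f"G{i:04d}" for i in range(cfg.n_genes)],
                "transcript": [f"T{i:04d}" for i in range(cfg.n_genes)],
                "chrom": np.array(chroms, dtype=object)[g_chrom_idx],
                "strand": strand,
                "tx_start": np.maximum(np.where(strand == "+", tss, tss - span), 0).astype(np.int64),
                "tx_end": np.where(strand == "+", tss + span, tss).astype(np.int64),
            }
        )
        return islands, genes, cpgs

    # -- WGBS time course ----------------------------------------------------

    def wgbs(self):
        """(per-time-point call tables {label: DataFrame}, truth per CpG)."""
        if self._wgbs is None:
            self._wgbs = self._simulate_wgbs()
        return self._wgbs

    def _simulate_wgbs(self):
        cfg, rng = self.cfg, self._rng_wgbs
        islands, genes, cpgs = self.genome
        n = len(cpgs)
        # baseline methylation: islands low, open sea high
        a_i, b_i = cfg.island_beta
        a_s, b_s = cfg.open_sea_beta
        p0 = np.where(cpgs["in_island"].values,
                      rng.beta(a_i, b_i, size=n), rng.beta(a_s, b_s, size=n))
        # dynamic sites: clustered at the TSS windows of designated dynamic
        # genes, topped up with random background sites to the target count
        dynamic = np.zeros(n, dtype=bool)
        dyn_gene_idx = rng.choice(cfg.n_genes, size=min(cfg.n_dynamic_genes, cfg.n_genes), replace=False)
        dyn_genes = genes.iloc[np.sort(dyn_gene_idx)]
        tss_windows = make_tss_regions(dyn_genes, flank=cfg.tss_flank)
        from .io_formats import interval_member_indices  # local: avoids cycle at import time
        for _, members in interval_member_indices(cpgs[["chrom", "pos"]], tss_windows):
            hit = members[rng.random(len(members)) < cfg.tss_dynamic_prob]
            dynamic[hit] = True
        target = int(round(cfg.dynamic_fraction * n))
        deficit = target - int(dynamic.sum())
        if deficit > 0:
            pool = np.flatnonzero(~dynamic)
            dynamic[rng.choice(pool, size=min(deficit, len(pool)), replace=False)] = True
        # planted deltas and directions; infeasible baselines resampled
        delta = np.zeros(n)
        idx_dyn = np.flatnonzero(dynamic)
        mag = rng.uniform(cfg.delta_low, cfg.delta_high, size=len(idx_dyn))
        sign = np.where(rng.random(len(idx_dyn)) < 0.5, 1.0, -1.0)
        n_resampled = 0
        for j, i in enumerate(idx_dyn):
            d = sign[j] * mag[j]
            tries = 0
            while not (0.0 <= p0[i] + d <= 1.0) and tries < 100:
                p0[i] = rng.beta(a_i, b_i) if cpgs["in_island"].values[i] else rng.beta(a_s, b_s)
                tries += 1
                n_resampled += 1
            if not (0.0 <= p0[i] + d <= 1.0):
                p0[i] = 0.5 - d / 2  # midpoint fallback: always feasible for |d| <= 1
            delta[i] = d
        if n_resampled:
            import logging
            logging.getLogger("methdyn").warning(
                "simulate_wgbs: %d infeasible baseline(s) resampled", n_resampled)
        shape = _trajectory_shape(cfg)  # (T,), 0 -> 1 strictly monotone
        traj = p0[:, None] + delta[:, None] * shape[None, :]
        traj = np.clip(traj, 0.0, 1.0)  # non-dynamic rows are constant; dynamic rows never clip
        tables = {}
        for t, label in enumerate(cfg.time_labels):
            total = rng.poisson(cfg.coverage_mean, size=n)
            while (total < 1).any():  # truncate at >= 1
                z = total < 1
                total[z] = rng.poisson(cfg.coverage_mean, size=int(z.sum()))
            meth = rng.binomial(total, traj[:, t])
            tables[label] = pd.DataFrame(
                {
                    "chrom": cpgs["chrom"].values,
                    "pos": cpgs["pos"].values,
                    "strand": ".",
                    "meth": meth.astype(np.int64),
                    "unmeth": (total - meth).astype(np.int64),
                    "fraction": meth / total,
                }
            )[CALL_COLUMNS]
        truth = cpgs[["chrom", "pos", "in_island"]].copy()
        truth["dynamic"] = dynamic
        truth["direction"] = np.where(~dynamic, "", np.where(delta > 0, "hyper", "hypo"))
        truth["true_delta"] = delta
        for t, label in enumerate(cfg.time_labels):
            truth[f"true_frac_{label}"] = traj[:, t]
        return tables, truth

    # -- expression / gene sets ---------------------------------------------

    def expression(self):
        """(DE results table, gene-set collection, per-gene truth)."""
        if self._expression is None:
            self._expression = self._simulate_expression()
        return self._expression

    def _dynamic_overlap_genes(self):
        """Genes whose TSS +/- flank contains >= 1 truth-dynamic CpG."""
        _, genes, _ = self.genome
        _, truth = self.wgbs()
        dyn_pos = truth.loc[truth["dynamic"], ["chrom", "pos"]].reset_index(drop=True)
        windows = make_tss_regions(genes, flank=self.cfg.tss_flank)
        from .io_formats import interval_member_indices
        overlapping = []
        for ridx, members in interval_member_indices(dyn_pos, windows):
            if len(members):
                overlapping.append(genes["gene"].iloc[ridx])
        return sorted(set(overlapping))

    def _simulate_expression(self):
        cfg, rng = self.cfg, self._rng_expr
        _, genes, _ = self.genome
        names = genes["gene"].tolist()
        n = len(names)
        overlap_genes = self._dynamic_overlap_genes()
        overlap_set = set(overlap_genes)
        # DE genes: dynamic-overlap genes first (methylation dynamics and
        # expression change co-occur in this design), topped up at random
        n_de = int(round(cfg.de_fraction * n))
        de_flag = np.zeros(n, dtype=bool)
        pri = [i for i, g in enumerate(names) if g in overlap_set]
        rng.shuffle(pri)
        take = pri[: min(n_de // 2, len(pri))]
        de_flag[take] = True
        rest = np.flatnonzero(~de_flag)
        extra = n_de - de_flag.sum()
        if extra > 0:
            de_flag[rng.choice(rest, size=extra, replace=False)] = True
        sign = np.where(rng.random(n) < cfg.de_up_fraction, 1.0, -1.0)
        mag = np.clip(rng.normal(cfg.log2fc_scale, 0.2, size=n), 0.3, None)
        true_l2fc = np.where(de_flag, sign * mag, 0.0)
        noise = rng.normal(0.0, cfg.wald_se, size=n)
        observed = true_l2fc + noise
        wald = observed / cfg.wald_se
        from scipy.stats import norm
        from statsmodels.stats.multitest import multipletests
        p = 2.0 * norm.sf(np.abs(wald))
        padj = multipletests(p, method="fdr_bh")[1]
        de = pd.DataFrame({"gene": names, "log2fc": observed, "wald": wald, "padj": padj})
        # luminal-like set: members drawn from dynamic-overlap genes with
        # probability luminal_overlap_prob, otherwise from the rest
        others = sorted(set(names) - overlap_set)
        members = []
        pool_a = list(overlap_genes)
        rng.shuffle(pool_a)
        pool_b = list(others)
        rng.shuffle(pool_b)
        for _ in range(min(cfg.luminal_set_size, n)):
            use_overlap = (rng.random() < cfg.luminal_overlap_prob and pool_a) or not pool_b
            pool = pool_a if use_overlap else pool_b
            members.append(pool.pop())
        sets = {"LUMINAL_LIKE": sorted(members)}
        for s in range(cfg.n_random_sets):
            draw = rng.choice(n, size=min(cfg.random_set_size, n), replace=False)
            sets[f"RANDOM_{s:02d}"] = sorted(names[i] for i in draw)
        truth = pd.DataFrame({"gene": names, "de": de_flag, "true_log2fc": true_l2fc,
                              "dynamic_overlap": [g in overlap_set for g in names]})
        return de, sets, truth

    # -- chromatin states and binding peaks -----------------------------------

    def chromatin_states(self) -> pd.DataFrame:
        """Non-overlapping state tiling with Polycomb/bivalent states planted
        preferentially over segments holding dynamic CpGs."""
        if self._states is None:
            cfg, rng = self.cfg, self._rng_states
            _, truth = self.wgbs()
            rows = []
            dyn = truth.loc[truth["dynamic"]]
            dyn_by_chrom = {c: np.sort(s["pos"].values) for c, s in dyn.groupby("chrom")}
            for chrom, length in cfg.chrom_lengths.items():
                starts = np.arange(0, length, cfg.state_segment)
                labels = rng.choice(len(STATE_LABELS), size=len(starts), p=STATE_BASE_PROBS)
                dpos = dyn_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
                has_dyn = np.searchsorted(dpos, starts + cfg.state_segment) > np.searchsorted(dpos, starts)
                relabel = has_dyn & (rng.random(len(starts)) < cfg.dynamic_state_prob)
                labels[relabel] = np.where(rng.random(int(relabel.sum())) < 0.5, 2, 3)  # Bivalent / Polycomb
                for j, s in enumerate(starts):
                    rows.append((chrom, int(s), int(min(s + cfg.state_segment, length)),
                                 STATE_LABELS[labels[j]], "."))
            self._states = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
        return self._states

    def binding_peaks(self) -> pd.DataFrame:
        """AR-like peak intervals: planted at a fraction of hypomethylating
        dynamic sites plus uniform background peaks."""
        if self._peaks is None:
            cfg, rng = self.cfg, self._rng_states
            _, truth = self.wgbs()
            hypo = truth.loc[truth["dynamic"] & (truth["direction"] == "hypo")]
            rows = []
            half = cfg.peak_width // 2
            for r in hypo.itertuples(index=False):
                if rng.random() < cfg.peak_at_hypo_prob:
                    rows.append((r.chrom, max(0, r.pos - half), r.pos + half, "AR_peak", "."))
            chroms = list(cfg.chrom_lengths)
            lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
            ci = rng.choice(len(chroms), size=cfg.n_background_peaks, p=lengths / lengths.sum())
            mid = (rng.random(cfg.n_background_peaks) * (lengths[ci] - cfg.peak_width)).astype(np.int64) + half
            for k in range(cfg.n_background_peaks):
                rows.append((chroms[ci[k]], int(mid[k] - half), int(mid[k] + half), "bg_peak", "."))
            peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
            self._peaks = peaks.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        return self._peaks

    # -- tumor/normal betas ----------------------------------------------------

    def tumor_normal_betas(self, classes: pd.DataFrame):
        """(BetaMatrix, per-island truth) with a +tumor_shift planted on a
        ``shifted_island_prob`` subset of the DMP-associated islands."""
        cfg, rng = self.cfg, self._rng_betas
        from .cancer_shift import DMP_ASSOCIATED
        n_islands = len(classes)
        shifted = (classes["label"].values == DMP_ASSOCIATED) & (rng.random(n_islands) < cfg.shifted_island_prob)
        a_i, b_i = cfg.island_beta
        island_base = rng.beta(a_i, b_i, size=n_islands)
        coords_rows, base_rows, shift_rows = [], [], []
        for j, itv in enumerate(classes.itertuples(index=False)):
            offs = np.sort(rng.integers(itv.start, itv.end, size=cfg.probes_per_island))
            for o in offs:
                coords_rows.append((itv.chrom, int(o)))
                base_rows.append(np.clip(island_base[j] + rng.normal(0, 0.02), 0.0, 1.0))
                shift_rows.append(cfg.tumor_shift if shifted[j] else 0.0)
        coords = pd.DataFrame(coords_rows, columns=["chrom", "pos"])
        base = np.asarray(base_rows)
        shift = np.asarray(shift_rows)
        samples, groups, cols = [], {}, {}
        for i in range(cfg.n_normal):
            s = f"normal_{i:02d}"
            cols[s] = np.clip(rng.normal(base, cfg.beta_sd), 0.0, 1.0)
            groups[s] = "normal"
            samples.append(s)
        for i in range(cfg.n_tumor):
            s = f"tumor_{i:02d}"
            cols[s] = np.clip(rng.normal(base + shift, cfg.beta_sd), 0.0, 1.0)
            groups[s] = "tumor"
            samples.append(s)
        from .io_formats import BetaMatrix
        bm = BetaMatrix(coords=coords, values=pd.DataFrame(cols, columns=samples), groups=groups)
        truth = classes[["chrom", "start", "end", "name"]].copy()
        truth["shifted"] = shifted
        truth["true_shift"] = np.where(shifted, cfg.tumor_shift, 0.0)
        return bm, truth

    # -- file bundle -------------------------------------------------------------

    def write_bundle(self, outdir) -> dict[str, str]:
        """Write every product as text files under ``outdir``; returns the
        path map used by the pipeline config."""
        import os

        os.makedirs(outdir, exist_ok=True)
        cfg = self.cfg
        islands, genes, _ = self.genome
        tables, truth_cpgs = self.wgbs()
        de, sets, truth_genes = self.expression()
        states = self.chromatin_states()
        peaks = self.binding_peaks()
        from .cancer_shift import classify_islands
        from .dmp_calling import TimeCourseDesign, build_timecourse, call_dmps
        flanked = make_island_regions(islands, flank=500)
        design = TimeCourseDesign(labels=cfg.time_labels)
        dmps = call_dmps(build_timecourse(tables, design))
        classes = classify_islands(flanked, dmps)
        betas, truth_islands = self.tumor_normal_betas(classes)

        paths = {}

        def p(name):
            paths[name] = os.path.join(outdir, name)
            return paths[name]

        for label, tab in tables.items():
            write_bismark_coverage(tab, p(f"meth_{label}.cov"))
        write_intervals_bed(islands, p("islands.bed"))
        write_intervals_bed(states, p("states.bed"))
        write_intervals_bed(peaks, p("peaks.bed"))
        write_gene_models_refflat(genes, p("genes.refflat"))
        write_de_table(de, p("de_results.tsv"))
        write_gmt(sets, p("gene_sets.gmt"))
        write_beta_matrix(betas, p("betas.tsv"))
        write_group_map(betas.groups, p("beta_groups.tsv"))
        for name, tab in (("truth_cpgs.tsv", truth_cpgs), ("truth_genes.tsv", truth_genes),
                          ("truth_islands.tsv", truth_islands)):
            with open(p(name), "w", encoding="utf-8") as fh:
                fh.write("#" + "\t".join(tab.columns) + "\n")
                tab.to_csv(fh, sep="\t", header=False, index=False, float_format="%.10g")
        return paths


# ---------------------------------------------------------------------------
# Flat operation surface


def simulate_wgbs_timecourse(cfg: SimulationConfig):
    """(per-time-point call tables, per-CpG truth) for one configuration."""
    return SyntheticStudy(cfg).wgbs()


def simulate_expression(cfg: SimulationConfig):
    """(DE table, gene sets, per-gene truth) consistent with the WGBS truth
    the same configuration generates."""
    return SyntheticStudy(cfg).expression()


def simulate_tumor_normal_betas(cfg: SimulationConfig, classes: pd.DataFrame):
    """(BetaMatrix, per-island truth) for a given island classification."""
    return SyntheticStudy(cfg).tumor_normal_betas(classes)
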