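# Methods

## Data model and coordinates

All genomic coordinates in memory are 0-based half-open. The bismark
coverage dialect (1-based inclusive) is converted on read and back on
write; a round-trip re-derives the source coordinate exactly. Methylation
fractions are always recomputed from read counts — the percent column of a
coverage file is checked against the counts and warned about, never used
in arithmetic, so threshold comparisons are free of upstream rounding.

Opposite-strand calls of one CpG dinucleotide (adjacent positions) are
summed into a single unstranded call at the plus-strand C by default,
reflecting symmetric CpG methylation; `merge_strands=False` preserves raw
records. Whether the upstream 20× filter should see merged or unmerged
counts is a genuinely open convention, so both are supported and the merge
happens before time-course assembly.

## DMP calling

A site enters the time course only if its coverage is at least
`min_coverage` (default 20) at *every* time point; assembly is an inner
join on position across the per-time-point tables. If replicate tables are
given for one time point, counts are pooled by summation — the pooled
fraction is the maximum-likelihood estimate of a shared underlying
fraction.

A dynamic methylation position must be *progressive*: strictly monotone in
design order, in either direction, with overall change
|fraction(last) − fraction(first)| strictly greater than `min_delta`
(default 0.20, i.e. "more than 20%"; the boundary value 0.20 itself is
excluded). Two numerical choices matter:

- Adjacent fractions are compared by cross-multiplication of integer
  counts (m_i·t_j vs m_j·t_i), so equality and strict order are exact.
  Bisulfite fractions tie easily at high coverage and IEEE division could
  otherwise turn an exact tie into a spurious strict step.
- Strict monotonicity is the default (matching the inequality chains as
  stated); `strict=False` relaxes intermediate comparisons to ≤/≥ while
  keeping the overall gate, for designs where ties at interior time points
  should not disqualify a site. Strictness makes the caller conservative:
  on planted linear trajectories with Δ = 0.4 at ~50× coverage, per-step
  binomial noise leaves recall around 0.8 while the false-positive rate on
  null sites stays near 10⁻³.

Z-score trajectory summaries normalise each site's fractions to mean 0 /
sd 1 across its own time points (sample sd); sites constant over time are
assigned an all-zero profile rather than NaN so they contribute neutrally
to group means.

Cross-platform concordance intersects two call sets after per-platform
coverage gates (e.g. 20× WGBS vs 10× capture) and reports the Pearson r of
paired fractions; constant input on either side yields r = NaN with a
warning instead of an exception.

## Region dispersion scores

Per CpG, dispersion is the standard deviation of its methylation fractions
across the time points. The sample sd (denominator n−1) is used: it is the
unbiased-variance convention and, with only four time points, the n vs n−1
choice rescales every score by the same factor — rankings and percentile
comparisons are unaffected. The region score is the unweighted mean of
per-CpG sds over CpGs contained in the window ([start, end) containment of
the C position); windows with fewer than `min_cpgs` (default 20) CpGs are
filtered out, never re-scored. Overlapping windows are scored
independently, so a CpG may contribute to several regions.

TSS windows are TSS ± 5 kb per transcript (TSS = txStart on +, txEnd on −),
clipped to the chromosome; island windows are island boundaries ± 500 bp.
Gene-level scores average a gene's transcript-window scores (mean is least
sensitive to transcript count; max is available), optionally restricted to
an expressed-gene list so the downstream ranking covers only detectably
expressed genes. Percentile exceedance uses the linear-interpolation
quantile of all gene scores and strict `>`.

## Enrichment statistics

The pre-ranked GSEA running sum advances at hits by |score|^weight
(normalised so hit increments sum to 1; weight 1 by default, weight 0
recovers the classical KS-style statistic) and retreats at misses by
1/(N − N_hit). ES is the signed extremum; at an exact tie between the
positive and negative excursions the positive one is reported.

The null is a gene-label permutation: `n_perm` uniform same-size draws
from the ranked genes, computed once per set size and shared by all sets of
that size. The permutation p is the +1-floored, direction-matched tail
*conditional on the matching-sign null* — dividing instead by all
permutations halves null p-values and destroys calibration, which the test
suite checks directly (p-values uniform under random membership). NES
divides ES by the mean |permutation ES| of matching sign. BH adjustment is
applied across all tested sets in one batch. Sets with fewer than 5 or
more than 2000 members after intersection with the ranked list are skipped
and logged.

Two-sample comparisons: KS uses the ECDF supremum with the asymptotic
two-sided p (scipy). The rank-sum comparison reports the Mann–Whitney U of
the first sample; for samples of ≤ 20 values each the two-sided p is exact
— the permutation distribution of U is enumerated over all C(n, n₁) label
assignments via a subset-sum count over doubled midranks, which is exact
in the presence of ties — otherwise the tie-corrected normal approximation
is used. Fully tied inputs give p = 1 with a warning.

Chromatin-state distributions require non-overlapping states; sites
outside every state are labelled `unannotated`, so the per-collection
proportions sum to 1. Enrichment is log2(query/background proportion),
reported as missing when either proportion is 0, with a two-sided binomial
test of the query count against the background proportion.

Metaprofiles split the window (default ± 2000 bp, 100 bp bins — the
window/bin sizes are this package's choice, config-exposed) around each
center and report, per bin, the fraction of centers whose bin overlaps at
least one peak. This binary-occupancy signal is the natural quantity when
the input is peak calls; a `signal` mode averages an
overlap-length-weighted peak score instead when a scored track is
supplied.

## Island classification and tumor shift

Flanked islands are labelled DMP-associated iff at least one DMP position
falls in [start, end) — half-open, so a DMP exactly at the end coordinate
does not count. The island-level summary per sample is the unweighted mean
beta of contained probes (missing entries skipped; islands without probes
excluded and counted); the tumor/normal comparison pools island-level
means across samples within each sample group — matching a
distribution-level comparison, not a paired design — and reports the
median delta (tumor − normal) with rank-sum and KS tests per island group.

## Synthetic study generator

One seed drives independent `SeedSequence` child streams for genome
layout, WGBS counts, expression, betas and chromatin annotation, so the
products are individually reproducible and mutually consistent, and the
emitted file bundle is byte-identical across reruns.

What it emulates: a 2 × 5 Mb genome with 300 non-overlapping CpG islands
(~1.5 kb) and 50,000 CpGs (25% inside islands); island CpGs start
hypomethylated (Beta(0.5, 8)) and open-sea CpGs hypermethylated
(Beta(8, 0.5)); ~1% of CpGs are dynamic (the magnitude observed genome-wide
in this kind of time course), clustered in the TSS windows of 40 designated
dynamic genes and topped up at random; planted overall deltas are uniform
in [0.25, 0.6] with random direction, baselines resampled (with a warning
counter) when a delta would leave [0, 1]. Trajectories interpolate over the
*time index* (0,1,2,3), not wall-clock hours — the progressive criterion is
ordinal in time, and index interpolation gives the 1 h step real signal; an
hours-scaled option exists. Per time point, coverage is truncated
Poisson(50) ≥ 1 drawn independently (so the per-time-point coverage gate is
exercised) and methylated counts are Binomial(coverage, true fraction).

Expression is simulated at the post-DE-test level: a true log2FC (0 for
non-DE genes; DE fraction 10%, 80% up, magnitudes ~N(1, 0.2)), Gaussian
noise with SE 0.2, the Wald-like statistic observed/SE, and BH-adjusted
normal-tail p-values. DE genes are drawn preferentially from genes whose
TSS windows contain dynamic CpGs, and a 96-member "luminal-like" set is
drawn with probability 0.8 per member from those same dynamic-overlap
genes — planting the methylation-dynamics/expression association the
analysis is designed to detect. Chromatin states tile the genome in 2 kb
segments with Polycomb/bivalent labels planted preferentially over
segments holding dynamic CpGs; AR-like peaks are planted at a fraction of
hypomethylating sites plus uniform background peaks. Tumor/normal betas
place 8 probes per flanked island, normals ~ clipped N(island baseline,
0.05), tumors additionally shifted by +0.2 in (by default all)
DMP-associated islands.

What it does **not** emulate — and hence what passing tests do not show
about real data: read-level artefacts (incomplete bisulfite conversion,
mapping bias, SNPs at CpGs), spatial correlation of methylation beyond
island/open-sea baselines, replicate structure and batch effects,
count-model DE (the DE table is simulated directly, not via a negative
binomial), tumor purity/copy-number effects on betas, and realistic
genome-scale annotation density.

## Pipeline

`run_full_analysis` executes the stages in analysis order from one
validated YAML config (unknown keys rejected; all violations reported
together; defaults 20×, 0.20, ±5 kb, ±500 bp, ≥20 CpGs). Every table is
written as sorted TSV (by coordinates or set name) so diffs are
meaningful, and `manifest.json` echoes parameters, the GSEA seed and
SHA-256 checksums of every input; reruns with the same config are
byte-identical. Optional inputs (DE table, states, peaks, betas) skip
their stages; a stage failure aborts with the stage name and moves
completed outputs under `partial/`.

## Problem sizes

The test suite and acceptance script run on deliberately compact studies —
oracle equivalence on 10,000 sites, calibration on 500 random sets at
1,000 permutations, a 30,000-CpG end-to-end study — sizes at which every
statistical property being asserted (recall, calibration, exactness to
1e-12) is already stable across seeds.

## Known limitations

- No regional smoothing or DMR calling: the unit of inference is the
  single CpG, and the strict-monotone rule has no significance model
  (no beta-binomial dispersion, no multiple-testing control at the site
  level).
- The permutation GSEA p floor is 1/(1 + matched permutations); very small
  p-values require raising `n_perm` (no adaptive/multilevel refinement).
- The rank-sum exact path enumerates only up to 20 + 20 values; beyond
  that the tie-corrected normal approximation applies regardless of tie
  structure.
- Beta-matrix probes are matched to islands by single-base position; no
  probe-to-genome liftover or cross-assembly handling.
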