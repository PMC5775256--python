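# Methods

This note documents the models and procedures implemented in `methylaxis`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## Coordinate and data conventions

Per-cytosine count tables ("allc-style" TSV) carry
`chrom, pos (1-based), strand, context (trinucleotide), mc_count,
total_count, assay`. Minus-strand contexts are read from the reverse
complement; every cytosine belongs to exactly one class of
{CG, CA, CC, CT}. All interval data (DMRs, peaks, genes) are BED-convention
0-based half-open; a site at 1-based `pos` occupies `[pos−1, pos)`. TSS
coordinates are the 0-based first transcribed base (`start` on plus,
`end − 1` on minus strands). Distance comparisons ("within 500 bp") are
closed at the boundary.

## Forward model (simulator)

Each cytosine carries a latent state `(p_mC_only, p_hmC)` with
`p_total = p_mC_only + p_hmC ≤ 1`. Observed counts are binomial draws with

* BS: `p_read = p_total + (1 − p_total)·NCR` — both mC and hmC resist
  conversion; unmethylated cytosines fail conversion at the NCR;
* TAB: `q = (1 − t)·p_hmC + s·p_total + r·(1 − p_total)` — protected hmC
  survives, mC survives at the non-oxidation rate `s`, unmethylated C at
  the non-conversion rate `r`.

Coverage is Poisson(`coverage_mean`) truncated at 1 — the simplest model
that still exercises low-coverage edge cases; real WGBS coverage is
over-dispersed and GC-biased, which the generator does not emulate (nor does
it model reads, PCR duplicates, or mapping error). Passing tests therefore
demonstrate correctness of the statistical machinery under binomial
sampling, not robustness to alignment artifacts.

CG sites draw a per-site base level from a Beta distribution with mean
`baseline_mcg` (default 0.75, typical for neuronal CpG methylation) and
concentration `beta_concentration` (default 30). The per-site level is
shared by all groups, so group differences exist only where implanted.
hmC is placed only at CG sites (a negative-control CH-hmC mode exists
behind `allow_ch_hmc`), at a Beta level around `hmcg_level` (default 0.15)
capped by the site's total methylation. CH sites draw independent levels
per region around `mch_dorsal` / `mch_ventral` (defaults 0.02 / 0.04 — the
ventral level twice dorsal, matching the regional asymmetry the pipeline
must recover).

DMRs are non-overlapping intervals with Gamma(shape 4)-distributed lengths
around `dmr_length_bp`. The default implanted element is 1 kb —
enhancer-scale; the caller's reported regions are narrower cores anchored on
significant sites, consistent with observed mean DMR lengths of ~200 bp.
Each DMR draws its methylation difference from
Normal(`dmr_mean_diff` = 0.26, `dmr_diff_sd` = 0.045), the reported scale of
regional differences, and lowers the hypomethylated group's total; when
`dmr_mean_diff = 0` all differences are exactly zero. A `clipped` flag
records sites where the base level could not accommodate the full
difference. By default 97% of DMRs are dorsal-hypomethylated, mirroring the
strong observed dorsal bias.

Spike-ins are three contigs: fully unmethylated (NCR and `r`), fully
CG-methylated (`s`), and CG-hydroxymethylated at purity
`hmc_spike_purity` (default 0.9) — deliberately impure, because commercial
5hmC controls are not 100% hydroxymethylated, so the estimation of `t` must
route through a matched BS measurement of the true abundance. Both assays
are generated for all three contigs.

Expression counts are negative-binomial over a 2×2 region × condition
design with `n_replicates` (default 5) per cell. Gene means are lognormal
(median 200, σ = 1); dispersion defaults to 0.01 — low, reflecting
replicates that are pools of many animals. DE genes apply
±`de_log2fc` to one design cell (default `dorsal_EE`), signs alternating. An
optional contaminated sample carries a high `Xist` marker level to exercise
sample QC. All draws flow from one seed sequence spawned per stage in fixed
order, so identical configs give identical outputs.

## Calibration

Rates are pooled per contig as ratios of summed counts — the binomial MLE,
weighting sites by coverage — with Clopper–Pearson 95% intervals. The hmC
abundance `a` of the impure spike-in is the NCR-corrected pooled CG level of
its matched BS table. `t` then solves the linear model
`q_C = (1 − t)·a + s·a + r·(1 − a)`, i.e. the exact inverse of the forward
model above (the non-oxidation term `s·a` matters: omitting it biases `t`
downward by ≈ `s`). Because `t` is a derived quantity, its interval comes
from first-order error propagation over the four binomial inputs rather
than a direct Clopper–Pearson interval; the small uncertainty of the NCR
used inside `a` is neglected. `a ≤ r` makes `t` unidentifiable and is a
hard error.

Corrections clamp into the probability simplex: `p_mC` to [0, 1] and
`p_hmC` to [0, p_mC]. The canonical `g[·]` only floors at zero; the upper
clamps guard against sampling noise pushing estimates over the ceiling, and
clamp events are counted on corrected tables. Site-level `p_hmC` uses the
same biological sample's BS-derived `p_mC`; where BS coverage is below
`min_bs_cov` (default 3) the value is withheld rather than imputed. The
correction can be applied per site or to pooled aggregates (`global_level`
accepts an `ncr` argument); both paths are exposed since pooling before or
after the affine correction is equivalent away from the clamp.

## Methylation levels and profiles

Levels are *weighted* — Σ methylated / Σ total calls over qualifying sites —
everywhere, consistent with coverage-weighted pooling in the calibration;
a per-site-mean alternative sits behind a flag. Binned levels use fixed
0-based half-open bins whose numerators and denominators sum exactly to the
global values. Profiles anchor on the feature *midpoint* (center-anchored
views), orient offsets 5'→3' by negating minus-strand features, use
half-open offset bins, and report a bin only when it has at least
`min_sites` contributing sites (per-site coverage filter defaults: 1 for
levels, 3 for profiles). The stratified treatment-difference summary
(median treatment effect per stratum of regional difference) takes its
stratum edges as an argument — no canonical edges exist, so they are
explicit and logged by the caller.

## DMR calling

The caller is a fully specified substitute for smoothing-based
beta-binomial callers, chosen so that every step has an independent oracle:

1. counts are pooled across replicates per group per site;
2. each site gets a two-sided test of equal methylation — Fisher's exact
   test where pooled coverage is below `deep_total` (200), otherwise the
   two-proportion normal approximation;
3. a dispersion guard drops sites whose within-group range of replicate
   fractions exceeds the between-group difference (protection against
   inconsistent replicates, at the cost of power at low coverage);
4. candidate sites (p < α, |difference| ≥ `min_diff`, consistent sign) merge
   when separated by ≤ `max_gap_bp`;
5. regions survive if they hold ≥ `min_sites` candidates, their pooled
   difference still clears `min_diff`, and the Stouffer combination of the
   directed site p-values is below α.

Defaults `min_diff = 0.15`, `alpha = 0.05` are the conventional reporting
thresholds; `max_gap_bp = 250` and `min_sites = 3` were set so called
regions land at the few-hundred-bp scale typical of reported DMRs. Inside
`call_dmrs` the exact Fisher test is evaluated lazily — only where a site
could become a candidate — which is output-identical to testing everywhere
(candidacy requires the difference threshold first) and dominates runtime
otherwise. Groups are tested unpaired; a paired design is future work.

## Enrichment and colocalization

The enrichment score is the density of DMRs per gene per Mb in
strand-oriented TSS-distance bins (default 100-kb bins over ±1 Mb; the
per-Mb normalization is canonical, the bin width is not and is
configurable). Every gene within the window pairs with every DMR — not
nearest-gene assignment — matching the per-gene density normalization
(duplicating the gene set leaves scores unchanged). Control bands resample
gene sets matched to the target's composition across deciles of mean
expression, without replacement and excluding target genes; deficient
strata borrow from the nearest neighbouring stratum with a warning. The
band is the pointwise 2.5/97.5 percentile envelope. Because controls come
from the complement of the target set, target and control curves are weakly
anti-correlated in small gene universes; the band is honest for target sets
that are a small fraction of the universe.

The gene-level urn test is an upper-tail hypergeometric on genes containing
≥ 1 DMR within the gene body ± 10 kb (configurable span). Peak–DMR
colocalization counts a peak as a hit when its midpoint lies within
`max_dist` (closed) of a DMR interval; the urn population defaults to
fixed-width windows tiling the genome, successes being windows near a DMR by
the same rule. The urn definition is a convention — published analyses
rarely state theirs — so the universe is an explicit argument.

## Differential expression

Counts are normalized by median-of-ratios size factors (scaled so the
average library totals one million), log2-transformed with a pseudocount of
0.5, and tested per contrast with a Welch-style statistic on the linear
combination of cell means, with Satterthwaite degrees of freedom; the
`region` contrast is the difference-of-differences
`(dorsal SH − ventral SH) − (dorsal EE − ventral EE)` with variance summed
over all four cells. This is a deliberate, fully documented substitute for
a negative-binomial GLM; it is validated by simulation recovery, not by
concordance with any GLM implementation. BH runs across retained genes per
contrast; a DE call needs q < 0.05 **and** |fold change| ≥ 1.2 (applied to
the contrast estimate on the log2 scale). The default gene filter keeps
counts > 10 (strict) in ≥ 2 samples; the alternative keeps TPM > 1 in ≥ 3
samples using exonic length as effective length.

Marker-gene QC flags samples whose marker CPM exceeds
median + 5 × MAD. The MAD is floored at the CPM equivalent of five reads in
the median library (at least 1 CPM): with an essentially silent marker the
raw MAD collapses to zero and shot noise would otherwise flag arbitrary
samples. Exclusions are reported, never silent.

## Problem sizes used in validation

The recovery checks run at desk scale: calibration exactness on 5×10³
noiseless sites; rate-coverage over 100 spike-in simulations with ≥ 10⁴
calls per contig; DMR recovery on a 2-Mb genome with 100 implanted DMRs
(26% mean difference, 15×, 5 vs 5) plus a ~10⁵-site null genome at 30×;
mCH asymmetry on ~10⁵ CH sites; enrichment calibration over 20 worlds of
1 000 genes / 500 DMRs on 50 Mb with 1 000 resamples; DE recovery on 2 000
genes with 200 DE at log2FC = 1. These sizes give tolerances (3 s.e. bands,
recall/precision floors) that are meaningful yet quick to compute.

## Known limitations

* The simulator's noise model is binomial given a latent truth shared
  across replicates; it does not generate biological replicate-to-replicate
  methylation variance, so the dispersion guard's false-positive behaviour
  on real over-dispersed data is untested here.
* The Welch test on log-CPM is approximate for very low counts; the gene
  filter is assumed to have removed those.
* The TAB forward model is the algebraic counterpart of the standard
  correction formula; at `p_hmC → 1` with `s > t` it can exceed 1 (the
  formula double-counts protected-and-unoxidized molecules), which the
  simulator treats as a hard error rather than silently clipping.
* CpG dyads are kept per strand; strand merging is available but off by
  default. CH-context DMRs are out of scope (levels and profiles cover CH).
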