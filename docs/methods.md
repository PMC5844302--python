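# Methods

This note records the models, parameter choices, and numerical decisions
behind the package, and what the synthetic test-bed does and does not
establish about real data.

## The synthetic study

The generator emulates the post-alignment products of a paired-end WGBS
comparison of two genotypes ("wt" and "ko", three replicates each) on a
toy genome. It deliberately simulates *pileups*, not reads: alignment,
deduplication, and mate-overlap clipping are upstream concerns, and every
downstream statistic in this package consumes per-position counts.
Read-position information, which only the M-bias analysis needs, is
carried by a separate aggregate call table.

Default study conditions (all configurable via `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| `chrom_lengths` | 2 × 1 Mb | autosome surrogate; ~40,000 CpGs at `cpg_rate` 0.02 |
| `spike_in_length` | 48,502 bp | unmethylated control contig ("lambda"), the phage λ genome size |
| `high/low/mid_frac` | 0.82 / 0.07 / 0.11 | methylome mixture weights |
| `depth_mean` | 30 | Poisson mean coverage per CpG **per strand** |
| `conversion_failure` | 0.0016 | unmethylated C read as methylated (conversion ≥ 99.84%) |
| `snp_rate` | 0.05 | fraction of reference CpGs destroyed in the sample genotype |
| `n_hypo`, `n_hyper` | 20, 10 | planted focal effects, `dmr_delta` 0.4 over `dmr_n_cpgs` 10 |
| `p_genic` | 0.8 | probability a hypo effect lands in an expressed gene body |
| `miscall_rate` | 0.005 | per-base error on guanine pileup positions |
| `mbias_spec` | +0.10 at positions 1–5 (mate 1), −0.08 at the last 5 (mate 2) | planted read-end artifacts |

Choices worth flagging:

* **Mixture components.** Levels are uniform on (0.80, 1.00), (0.00, 0.20)
  and (0.30, 0.70). The margins around the 0.25/0.75 class boundaries keep
  binomial sampling noise at realistic depth from shuffling sites between
  classes, so the distribution summary can be meaningfully compared to the
  mixture weights (tolerance ±0.02 at 100k CpGs).
* **Planted effects.** Wild-type levels inside a planted region are
  resampled into a range that accommodates the full effect size (hypo:
  WT ≥ 0.6; hyper: WT ≤ 0.4), so |KO − WT| equals `dmr_delta` at every
  member CpG; clipping to [0, 1] is retained as a safety net. This mirrors
  the empirical observation that hypomethylation hits previously
  methylated regions. Hyper effects are placed uniformly; only hypo
  effects are gene-targeted.
* **Polymorphisms.** A destroyed CpG carries a non-G base at N+1 on the
  plus strand (homozygous). The minus-strand G at N is untouched, so such
  sites fail validation through the plus-strand criteria. Heterozygous
  sites, indels, and allele-specific methylation are not modelled.
* **M-bias magnitude.** Real M-bias curves are library-specific; the
  planted ±0.1/−0.08 offsets are free parameters chosen to be large
  against the mid-read sampling noise at 5,000 calls/position so boundary
  recovery is a sharp test of the rule, not of the noise level.
* **Conversion failure** applies per call; the spike-in is fully
  unmethylated, so its methylated-call fraction estimates the failure rate
  directly (binomial SE ≈ √(p(1−p)/n) ≈ 1.8 × 10⁻⁴ at 50k calls).

What passing tests on this generator does **not** show: robustness to
mapping artifacts, coverage dips and gaps, non-CpG methylation, partial
deletion efficiency (mixed cell populations), batch effects between
replicates, or genome-scale CpG clustering beyond the simple island model.

## M-bias trim rule

Profiles are per (mate, length-class) library aggregates. The mid-read
window (30–100 for PE150, 20–50 for PE75) yields mean and sample SD
(n − 1 denominator); a constant window falls back to `sd_floor` = 0.002 so
the acceptance band never has zero width. Selection returns the longest
contiguous run in which every position is within ±3 SD, except isolated
(never adjacent) positions within ±4 SD, and whose endpoints meet the
±3 SD bound. Zero-depth positions terminate runs. Ties between
equal-length runs prefer the run containing the window midpoint, then the
earlier run. A per-sequenced-read statistic is not computable from
single-read Bernoulli calls, so the library-level profile is the unit —
the same semantics as standard M-bias extractors.

## Context validation

Thresholds are inclusive ("at least"): 19 G / 20 bases passes at 95%. The
denominator is all mapped bases at the coordinate. Validation runs once on
the pileup combined over all libraries and the resulting pass/fail set is
applied to every sample, enforcing "CpG context in all samples". Sites
absent from the reference CpG list are never assessed.

## Methylation calling

Strand evidence is pooled per CpG before depth filtering (one mCG/CG per
site); group-level calls sum replicate counts rather than averaging
ratios, so the group ratio is the depth-weighted mean. The depth filter
(≥ 10) and the distribution boundaries (strict > 0.75 and < 0.25; the
boundary values count as intermediate) are inclusive/strict exactly as
stated. Zero-depth records carry an undefined (NaN) ratio rather than
being errors.

## Credible methylation difference

The DMR stage needs a per-site significance call that respects depth. We
use Jeffreys-prior Beta posteriors Beta(m + ½, t − m + ½) per group and
the equal-tailed 95% credible interval (L, U) of Δ = p₂ − p₁:
cdif = L if L > 0, U if U < 0, else 0. This is a principled stand-in for
credible-difference DMR callers; no claim is made that it reproduces any
specific tool's output on real data. Replicates are pooled into group
counts before testing, matching the replicate-merging used upstream.

Numerics: P(Δ ≤ d) = E\_u[F₂(Q₁(u) + d)] is evaluated by 32-node
Gauss–Legendre quadrature in quantile space (exact importance sampling of
p₁, stable for the extreme skew of near-boundary posteriors), and the two
quantiles are found by vectorized bisection on d ∈ [−1, 1] to 10⁻⁴. A
conservative screen skips the computation when the 80% normal
approximation interval of Δ already contains zero — the exact 95% interval
is strictly wider, so screened sites are genuinely non-significant. A
Monte-Carlo path (`method="mc"`, fixed seed) exists for cross-checking.
The test-suite oracle is an independent 10⁶-draw Monte-Carlo evaluation;
agreement is required within ±0.01 over a 20-case grid.

Chaining: significant sites of identical sign are chained while the gap
between successive *significant* CpGs is ≤ 300 bp (intervening
non-significant sites do not break a chain; they simply are not members);
chains need ≥ 3 member CpGs; region ratios are count-weighted pools and
regions must reach |pooled Δ| ≥ 0.2. The gap and minimum-CpG defaults
mirror common DMR-caller practice and are exposed in `DmrConfig`.

## Annotation

All coordinates are 0-based half-open; a CpG spans [N, N+2). Promoter
[t − 1000, t + 500) and its minus-strand mirror [t − 499, t + 1001) count
the anchor base as the first downstream base; the 3′-end window is built
the same way with 1000 bp on each side. Shores are island ± 2 kb minus
islands; shelves the next 2 kb minus shores and islands — the three
classes partition disjointly by construction. Category flags are
non-exclusive ≥ 1 bp overlaps (percentages may sum past 100%);
`intergenic` means no gene-model overlap. TSS distance is edge-to-point,
0 for containment, signed by the TSS's strand (downstream positive), with
ties broken toward downstream then the lower coordinate; bin edges default
to 5 kb / 50 kb / 500 kb.

## Shuffled-null enrichment

Null regions preserve each query's length, avoid the mask and (by
default) each other, and are drawn uniformly over the *valid placements* —
computed exactly by inverse-CDF sampling over the free space rather than
by rejection, so constrained placements (e.g. a mask leaving exactly one
fitting window) succeed deterministically. Default seed 1000. The
two-proportion Z-test uses the pooled estimate; z is defined as 0 for
degenerate pooled proportions; z² equals the 2 × 2 Pearson chi-square
without continuity correction. P-values are raw (no multiple-testing
correction across categories); stars at 0.05 and 0.001. The expressed-gene
threshold (mean FPKM ≥ 1 across replicates) is inclusive.

## Problem sizes

The bundled study runs at 2 × 1 Mb (~40k CpGs), chosen so the full
pipeline — simulation through enrichment — completes in well under a
minute while leaving every statistic comfortably powered (each group
pools ~180 reads per CpG). The distribution-recovery check uses a 2.5 Mb
/ 100k-CpG configuration; conversion recovery uses a spike-in sized to
~50k control calls.

## Known limitations

* The credible-difference statistic is this package's own construction;
  concordance with MOABS/metilene/dmrseq on real data is untested.
* Validation assumes homozygous polymorphisms; heterozygous sites would
  show ~50% G and still fail, but are not simulated.
* One TSS/TES per gene model; supply multiple transcripts as separate
  models if needed.
* No FDR control across DMRs or enrichment categories.
* The shuffle draws a single null set per region set; resampling-based
  empirical P-values are not implemented.
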