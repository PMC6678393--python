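# Methods

`cfmir` reimplements, as a tested library, the computational analysis of a
cell-free small-RNA profiling study that sequenced three plasma fractions —
whole plasma (WP), extracellular vesicles (EV), and EV-depleted plasma (EVD) —
from two subject groups (PTSD+ / PTSD−, 12 per group). This note documents the
models, the defaults and where they come from, the synthetic-data design, and
the numerical choices.

## Count model and differential abundance

Counts are modelled as negative binomial with mean `mu` and variance
`mu + phi * mu^2`; `phi = 0` degenerates to Poisson. The analysis chain is:

1. **Reliable-detection filter.** A feature is kept in a fraction when it has
   at least `min_reads = 5` mapped reads in *strictly more than*
   `min_sample_share = 50%` of that fraction's samples. The boundary is
   strict: 12 of 24 samples is removed, 13 of 24 retained. Filtering happens
   per fraction on raw counts, before normalization.
2. **TMM normalization.** One scaling factor per sample from the weighted
   trimmed mean of M-values against a reference sample (the sample whose
   75th-percentile count share is closest to the cohort mean). Per-feature
   M (log2 between-sample ratio) and A (average log2 abundance) values are
   trimmed at 30% per M tail and 5% per A tail; surviving M-values are
   averaged with inverse asymptotic-variance (delta-method binomial) weights,
   and factors are rescaled to geometric mean 1. The implementation is
   cross-checked in the test suite against an independent step-by-step
   reimplementation and against edgeR's `calcNormFactors` (agreement 1e-9).
   Note that because the precision weights depend on absolute counts, TMM is
   only asymptotically invariant to rescaling a single library; the exact
   invariance holds in the two-sample case and is tested there.
3. **Common dispersion.** A single cohort-level `phi` maximizes the
   conditional NB log-likelihood on library-size-equalized pseudo-counts.
   Equalization maps each count quantile-for-quantile (averaging a normal and
   a gamma approximation of the NB CDF) from its fitted per-sample mean to the
   same abundance at the geometric-mean effective library size. Because the
   equalization itself needs `phi`, estimation alternates two passes starting
   from `phi = 0.01`, optimizing over `delta = phi/(1+phi)` in (1e-6, 0.99);
   estimates driven to the lower bound are reported as exactly 0. No tagwise
   or empirical-Bayes moderation is applied: a common `phi` is the minimal,
   fully testable variant of the exact-test framework.
4. **Exact test.** Per feature, group pseudo-totals are rounded and the
   two-sided p-value is computed from the conditional distribution of one
   group's total given the overall total (negative hypergeometric for
   `phi > 0`, binomial at `phi = 0`). Two-sidedness uses the
   minimum-likelihood rule — sum the probabilities of every split no more
   likely than the observed one — capped at 1. For small totals this equals
   brute-force enumeration to 1e-10 (tested); type-I error on null cohorts is
   calibrated to 5% ± 1%.
5. **Calling.** A feature is differentially abundant when `p < 0.05` and
   `max(FC, 1/FC) > 1.5`, with FC the ratio of mean normalized abundances
   (PTSD+ over PTSD−; EV over EVD for the fraction comparison). p-values are
   left unadjusted for calling — matching the study design — with a
   Benjamini–Hochberg FDR column reported alongside. Fold-changes for
   reporting add a proportional prior count of 0.125 per effective library
   only when a group mean is zero; the prior never enters the test.

The EV/EVD partition applies the same machinery with plasma fraction as the
grouping variable, unpaired (the source design does not describe pairing),
restricted to features detected in both fractions. EV-sorting motifs (GGAG,
GGCU) are scanned at the 3' end of mature sequences, either as the terminal
4 nt (`suffix`, default) or anywhere in the last 6 nt (`window`).

## qPCR reference selection and validation

Reference assays are chosen from the sequencing data: candidates must show
`max(FC, 1/FC) < 1.1` and `p > 0.05` in every fraction and a coefficient of
variation `< 0.05` of TMM-normalized counts within each group of each
fraction; survivors are ranked by mean normalized abundance (mean CPM across
all samples of all fractions — the abundance metric is otherwise unspecified
upstream) and the top `k = 4` are used. Cq values are normalized as
`delta-Cq = Cq(target) − mean(Cq(references))`; the arithmetic mean of Cqs is
the geometric mean of the linear-scale quantities. Group differences use
Welch's unequal-variance t-test with Satterthwaite degrees of freedom, applied
on `−delta-Cq` (the log2 measurement scale) rather than on linearized
quantities `2^(−delta-Cq)`: Cq is the native scale of the instrument and the
upstream description does not specify which was used. Fold-change is
`2^(mean difference of −delta-Cq)`. Concordance between platforms is the
share of features whose sequencing and qPCR log fold-changes agree in sign.

## Target enrichment and fold-enrichment score

Term enrichment of a target-gene set is one-sided hypergeometric
overrepresentation on the 2×2 table over the annotation universe, with terms
selected at `p < 0.1` and overlap `>= 3`. The universe is the set of genes
appearing in any term of the annotation table, not the whole genome. An
EASE-style variant (discounting one overlapping gene before taking the tail)
is available behind a flag but off by default, since the plain tail is the
exactly specified rule.

The fold-enrichment score of miRNA *m* for term *t* is
`FES = (a/b) / (c/d)` with `a` = *m*'s targets in *t*, `b` = *m*'s targets in
the universe, `c` = genes in *t*, `d` = genes in the universe. Its
significance is judged empirically: the background percentile is the share of
non-altered miRNAs (all database miRNAs minus the focal one and a
caller-supplied exclusion list of group-altered miRNAs) whose FES for the same
term *strictly* exceeds the focal FES; ties do not count against the focal
miRNA. Percentiles below 5% are flagged.

## Synthetic cohort design

The generator emulates the study conditions so that every stage is testable
without the (undeposited) cohort data:

- **Design:** 12 subjects per group, three fractions per subject drawn from a
  shared baseline (fractions conditionally independent given the subject — no
  cross-fraction covariance is specified upstream).
- **Composition:** miRNA carries 80% of reads in WP and EVD but 33% in EV,
  with the balance across piRNA, lncRNA, snoRNA, rRNA, tRNA and miscellaneous
  classes; per-fraction read shares converge to these targets as library size
  grows (tested at ±0.02).
- **Abundance spectrum:** per-feature baselines are log-normal
  (`sigma = 1.5` on the natural-log scale), giving the dynamic range the
  abundance-ranked reference selection needs.
- **Noise:** NB with a common `phi = 0.1` (BCV ≈ 0.32, typical for
  between-subject small-RNA counts); library sizes log-normal with CV 0.2
  around a 1e6-read mean (smaller sizes are used in tests and in the
  acceptance script to keep runtimes modest; the printed `n` fields record
  the sizes used).
- **Stable reference assays:** a designated subset (6 by default) is
  simulated with a much smaller dispersion (`2e-4`) and a ×200 abundance
  boost. This is deliberate: with a uniform `phi = 0.1`, no feature can meet
  the CV < 0.05 selection rule, because TMM-normalized counts carry a 2–4%
  noise floor from factor estimation itself. Real plasma is dominated by a
  handful of highly abundant, tightly regulated miRNAs (the usual qPCR
  normalizers), and the boosted stable subset models exactly that.
- **Planted effects:** group fold-changes are planted per (feature, fraction)
  and the affected features get a ×4 baseline boost, mirroring the study's
  choice of validation assays among abundant miRNAs; empirical group-mean
  ratios converge to the planted fold-change.
- **Sequences:** 18–25 nt RNA strings with an exact number
  (`round(n × motif_fraction)`) ending in GGAG/GGCU, the remainder guaranteed
  motif-free at the 3' end.
- **Annotations:** random term sets and target sets over a synthetic gene
  universe; genes not drawn into any term are collected into a remainder term
  so the FES denominator `d` equals the configured gene count without
  distorting drawn term sizes. Planted (miRNA, term, FES) pairs are realized
  by direct construction of the overlap `a = round(FES·b·c/d)` (within 10% of
  the target or a configuration error); unplanted target sets are uniform, so
  the background FES distribution centers on 1.
- **qPCR:** `Cq = 30 − log2(relative abundance) + sample offset +
  N(0, 0.2 cycles)`; the per-sample offset (RNA input variability, sd 0.5
  cycles) is shared across assays and cancels exactly in delta-Cq; a planted
  fold-change `f` appears as a `−log2(f)` group shift. The 30-cycle origin is
  an arbitrary affine constant that cancels in delta-Cq.

What the generator does *not* model: read-level artifacts (adapter/ligation
bias, fragment-size selection, per-read length spectra), per-feature
dispersion trends beyond the stable subset, cross-fraction abundance
covariance, and qPCR amplification-efficiency differences. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under the stated model, not robustness to those real-data
artifacts.

## Numerical choices and degenerate inputs

- Exact-test ties use a `1e-10` relative slack when comparing split
  probabilities to the observed one; all-zero features get `p = 1`, `FC = 1`,
  flagged.
- Pseudo-count quantile mapping clips probabilities to `[1e-300, 1]` and
  shifts means below `1e-4` by +0.25 before mapping (zero-mean guard).
- The one-group NB mean fit uses Fisher scoring with step clipping at ±5 on
  the log scale, 50 iterations or score < 1e-10.
- Welch's test with zero variance in both groups returns `p = 1` at equal
  means and `p = 0` otherwise.
- Samples missing any reference Cq are dropped per assay with a warning;
  features without sequences are skipped and counted in the motif report;
  genes outside the annotation universe are dropped with a warning.
- Fewer than `k` reference candidates yields all of them with a warning; the
  pipeline proceeds with however many pass.

## Problem sizes

Default test and acceptance runs use 300–2000 features, libraries of 1e5–5e5
reads and 12 subjects per group per fraction; the end-to-end pipeline run uses
the full three-fraction design with ~490 features and 2e5-read libraries.
These sizes were chosen so that every distributional check has comfortable
resolution (e.g., 20 000 null features for the 5% ± 1% calibration band)
while a complete run of the suite plus the acceptance script stays within a
few minutes on one CPU.
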