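# Methods

## Scope and model

`cnvburden` implements a complete aCGH CNV-burden workflow: per-sample
segmentation of log2 intensity ratios into CNV calls, rarity and
inheritance annotation, and cohort-level burden statistics. Because raw
hybridization data for such studies are rarely redistributable, the package
pairs the analysis chain with a synthetic-data generator whose defaults
encode the study conditions the analysis was designed for; everything
downstream is validated against planted truth.

### Coordinates

All intervals are 0-based half-open; `size = end − start`. Published call
tables printed with 1-based starts and `size = end − start` are ingested
through a declared `one_based` dialect that shifts **both** bounds by one
(1-based start with exclusive end), which preserves every printed size
exactly. Readers reject tables whose `size` column disagrees with
`end − start` after ingestion.

### Segmentation

1. **Normalization.** `z = (x − μ_c)/σ_c` per chromosome, with μ_c, σ_c the
   mean and sample SD (ddof = 1) over all of the chromosome's non-missing
   probes, CNV probes included — the simplest defensible reading of
   chromosome-specific normalization. A robust variant (median, MAD × 1.4826)
   is available behind `AnalysisConfig.robust_zscore`. It matters on the
   scaled-down synthetic genome: hotspots are probe-dense, so a single
   Mbp-scale hotspot deletion can cover a third of a chromosome's probes and
   drag the naive μ_c/σ_c enough to push its own |mean z| under the filter
   threshold. On a full-size genome the naive mode is normally adequate.
2. **Decoding.** A three-state Gaussian HMM on the z scale, decoded with
   Viterbi independently per chromosome on the probe-order sequence;
   inter-probe distance deliberately does not enter the decode (distance
   rules are applied afterwards, below). The HMM parameters are not
   published for the original platform; our defaults are emission means
   (−3, 0, +2.5) with unit SDs — deletions sit deeper than duplications on
   the z scale because losing one of two copies is a larger relative
   intensity change than gaining a third — self-transitions 0.999 with the
   remaining mass split evenly, and initial distribution
   (0.001, 0.998, 0.001). All are configurable; the decoder is verified
   against exhaustive path enumeration.
3. **Assembly.** Consecutive same-state probes merge into a segment iff the
   gap (next start − previous end) is **strictly** less than 50 kbp.
4. **Bridging.** Two same-state, non-normal segments whose intervening run
   has ≤ 5 probes **and** spans ≤ 10 kbp merge, intervening probes
   included, iterating left-to-right to a fixed point. Bridging never joins
   a deletion with a duplication.
5. **Filters.** Keep iff |mean z| > 1.5 and probe count > 10 (both strict)
   and size > 50 kbp, plus size > 300 kbp for calls classified non-hotspot
   (the backbone's ~36 kbp spacing cannot support confident smaller calls).
   Rejected variants are retained with machine-readable reason codes.
   A segment-mean reading of the z filter is used throughout.
6. **Homozygous deletions.** A deletion segment with mean z below a
   configurable floor (default −6) is labelled `homozygous_deletion`; the
   original tables contain the category but no rule, so the threshold is
   explicit and tunable.
7. **Sample QC.** The criteria behind the original ~89% pass rate are
   unpublished; our stand-in fails a sample iff its log2-ratio SD exceeds
   0.35 (strict) or its raw variant count exceeds 3× the cohort median.

### Annotation

* **Hotspot class.** `HS` when hotspot sequence covers ≥ 50% of the call;
  `HS_assoc` when a breakpoint lands in a hotspot or its
  segmental-duplication flank; else `non_HS`. The exact region rule behind
  published "HS assoc" labels is unpublished; this three-way rule is a
  reconstruction.
* **Control matching.** A call matches a control-map event when both
  directions of reciprocal overlap reach 50% ("of their length" read as
  both ways) and the type family agrees (homozygous deletions match
  deletions; a type-blind mode exists behind a flag). Match counts sum over
  qualifying events; no merging of fragmented control calls.
* **Rarity.** Strict = zero matched control carriers. Relaxed = control
  frequency strictly below 0.1%: with 8,635 controls, ≤ 8 carriers pass
  and 9 do not. Strict-rare ⊆ relaxed-rare by construction.
* **Genes.** Gene count = genes overlapped by ≥ 1 bp; a call "breaks" a
  gene when a breakpoint falls strictly inside it (touching a boundary does
  not count, consistent with half-open coordinates).
* **Genomic disorders.** Best region at ≥ 50% reciprocal overlap, ties
  broken by larger overlapped span. The shipped region table is a
  synthetic, editable stand-in, not reference coordinates.
* **Inheritance.** With both parents genotyped: de novo iff neither parent
  has a same-family call at ≥ 50% reciprocal overlap; otherwise the
  matching parent's label, or `both`. With one genotyped parent we emit
  that parent's label on a match and `NA` otherwise — a single
  non-matching parent cannot prove de novo status — and record parent
  availability separately rather than compound labels.

### Burden statistics

All comparisons use Fisher's exact test (two-sided, point-probability
rule, delegated to `scipy.stats.fisher_exact` and test-verified against
exhaustive hypergeometric enumeration) with the unconditional cross-product
odds ratio `ad/bc` — this is the estimator that reproduces the published
values (10.04, 1.64, 6.12, 2.65, 11.2); the conditional MLE does not.
Zero-denominator tables report OR = infinity (both products zero: NA); a
Haldane–Anscombe option exists. No multiple-testing correction is applied
by default (a Bonferroni helper is provided). Note the published ID-vs-autism
de novo comparison prints p = 0.027 where the two-sided Fisher value for
(30, 17; 14, 21) is 0.044; the package reports the exact-test value.

"Large" means strictly greater than 1 Mbp. Survivor curves report, per
cohort, the fraction of individuals whose largest passing CNV is ≥ each
grid size (call-free individuals count with a maximum of 0). The
two-proportion power routine uses the normal approximation with pooled SE
under the null and unpooled SE under the alternative; at delta = 0 it
returns exactly alpha, and it is cross-validated against Monte-Carlo
simulation of the z-test.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the features the analysis is sensitive to:

* **Genome/array geometry.** Default 4 chromosomes × 25 Mbp with 32
  hotspot regions of 200–300 kbp (~8% of the genome, the hotspot-target
  fraction of the emulated array: ~251 Mbp of ~3.1 Gbp), each flanked by
  20 kbp segmental-duplication proxies. Probes tile hotspots at ~2.6 kbp
  and the backbone at ~36 kbp, start-to-start spacing jittered ±25% — the
  jitter cap keeps the largest backbone gap (45 kbp) under the 50 kbp
  merge radius, as on the real design.
* **Signal model.** Probe value = state mean + per-chromosome offset
  δ_c ~ N(0, τ) + N(0, σ). State means: deletion −1 (log2 1/2),
  duplication +0.585 (log2 3/2), homozygous deletion floored at −3.
  Defaults σ = 0.15, τ = 0.05. The platform's true noise magnitude is
  unpublished; σ = 0.15 is our choice of a realistic mid-range aCGH noise
  level, and τ > 0 exists to exercise chromosome-specific normalization.
* **Cohorts.** Sizes are the emulated study's pass-QC counts (306
  controls, 322 dyslexia, 246/90 autism without/with ID, 358 idiopathic
  ID, 73 ID+MCA). Rare-CNV carrier probabilities follow the reported
  carrier fractions (0.020/0.019/0.102/0.111/0.168/0.123); two-hit
  probabilities 0.44 (ID_MCA), 0.067 (ID), 0.10 (autism_ID); de novo
  fractions 0.64 (ID cohorts), 0.40 (autism), 0 (dyslexia, controls).
  Rare sizes are log-uniform with bounds chosen so the median tracks each
  cohort's reported median rare size (e.g. dyslexia 60 kbp–1.5 Mbp,
  median ≈ 300 kbp; ID_MCA 0.4–10 Mbp, median ≈ 2 Mbp). Trios cover 75%
  of case probands (parental DNA resolved ~3/4 of rare CNVs in the
  emulated design) and no controls. De novo events anchor at hotspot loci
  with probability 0.5, echoing hotspot-mediated mutation while keeping
  both placement classes tested. Common polymorphisms arrive per sample at
  Poisson rate 3.3 drawn from control-map loci, so rarity filtering has
  realistic work to do.
* **Control map.** 60 loci by default, 70% hotspot-anchored, 40%
  "rare-but-present" (1–8 of 8,635 carriers, i.e. < 0.1%), the rest
  common with counts log-uniform up to ~10% of controls. An explicit site
  frequency spectrum can override this.

Not emulated: dye-swap and wave artifacts, GC bias, cell-line mosaicism,
sex-chromosome baselines, genome-build issues, and realistic gene/disorder
coordinates (both tables are synthetic stand-ins). Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not performance on any particular real platform's artifact spectrum.

## Problem sizes used in validation

Tests and the acceptance script run on scaled-down instances chosen to
keep the whole suite quick while preserving the regimes that matter: the
recovery experiment uses 2 × 12 Mbp chromosomes (~1,000 probes) with 40
samples carrying one ~30-probe hotspot deletion and one ~25-probe backbone
duplication each; trio classification uses 150 complete trios with Mbp
planted events (robust normalization, see above); carrier-rate recovery
uses 2,000 simulated samples; the full-study drivers under `analysis/` run
all 2,641 samples (probands plus parents) at the default genome scale.

## Numerical and convention notes

* Deterministic seeding throughout: one integer seed, child streams via
  `numpy` seed sequences keyed by stage and sample index; identical inputs
  produce byte-identical outputs.
* Viterbi runs in log space; missing probes (NaN) contribute a flat
  emission (uninformative) rather than being dropped, preserving probe
  indexing.
* Strictness conventions are tested at their boundaries: 49,999 bp merges
  and 50,000 bp does not; 5 intervening probes bridge and 6 do not; a
  10-probe variant and a |z| = 1.5 variant are rejected; exactly 1 Mbp is
  not "large"; 8/8,635 is relaxed-rare and 9/8,635 is not.
* Zero-variance chromosomes raise a named error instead of emitting NaN
  z-scores.
* Breakpoint accuracy is assessed at probe resolution: an aCGH call's
  boundary is defined by its first/last probe, so recovery requires the
  called boundary probes to lie within one probe of the planted interval's
  probe span. With sticky transitions a boundary probe whose noise leans
  toward the event mean is occasionally absorbed; the acceptance test
  counts an event as recovered only if both boundaries are within one
  probe, and requires ≥ 95% of planted ≥ 20-probe events to qualify.

## Known limitations

* The HMM is decoded on probe order only; no wavelet smoothing or EM
  parameter re-estimation, and no mosaic (partial-copy) states.
* Control matching is per-event; a control CNV fragmented into several map
  records can under-count matches.
* The sample-QC rule is a principled stand-in; its pass rate on real data
  has no published criterion to compare against.
* The power routine is a plain normal approximation; it is accurate to
  ~0.02 against simulation at the sample sizes tested but is not an exact
  unconditional power calculation.
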