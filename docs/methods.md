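# Methods

## Scope and model

`karyocin` implements three quantitative analyses that share no data but
form one study design: (1) per-cell integer copy-number calling from
shallow single-cell whole-genome sequencing with dual-algorithm curation,
feeding three karyotype-instability scores; (2) label-free spectral-count
classification of FLAG-IP interactors across an empty-vector control and
two bait conditions; (3) rank-sum comparison of per-tumor autosomal CNA
burden between subtype cohorts. A synthetic-data module generates inputs
for all three with known ground truth; all development and validation is
against that ground truth.

## Synthetic data

**Cell populations.** The genome is a set of named chromosomes cut into
fixed-width bins (default 1 Mb; the last bin of each chromosome is
truncated). The default genome has 22 autosome-like chromosomes with
linearly decaying lengths summing to 2,875 Mb — the approximate span of
the human autosomes — giving ~2,900 bins. A founder karyotype (base
ploidy 2, doubled with probability `wgd_probability`) receives
`founder_event_count` clonal events shared by all founder cells
(70% whole-chromosome, 30% segmental); optional subclones apply explicit
event lists. Each cell then draws private whole-chromosome and segmental
events (Poisson with rates `missegregation_rate`, `segmental_rate`).
Segmental events pick a uniform random pair of bin boundaries within one
chromosome and apply ±1 — deliberately mechanism-free. Losses that would
push any bin below copy 0 are resampled (up to 100 tries, then dropped),
so profiles are always non-negative.

**Read counts.** The count for (cell, bin) has mean
`copy × reads_per_bin_per_copy × gc_factor × width/mean_width` and is
drawn negative-binomially with variance m + d·m² (`dispersion` d = 0
reduces to Poisson). Shallow scWGS libraries are mildly overdispersed;
d = 0.05 is used in the end-to-end validation. The GC bias is a
multiplicative quadratic factor 1 − a·(GC − 0.45)², floored at 0.05, with
per-bin GC drawn uniformly on [0.30, 0.60]; it is exactly the kind of
smooth bias the GC correction is designed to remove. What the generator
does **not** emulate: mappability artifacts, replication-timing waves,
supercontracted coverage at centromeres/telomeres, doublets, or
chromothripsis-like clustered rearrangement. Passing tests therefore
demonstrate correctness of the algorithms under the stated noise model,
not performance on every real library.

**Spectral counts.** Every protein carries Poisson background
(`background_mean`, default 1 count) in every condition; WT-specific and
shared proteins add `effect_mean` (default 10) in WT replicates,
K27M-specific and shared in K27M replicates; the H4 anchor is drawn with
condition-specific means (defaults EV 6, WT 40, K27M 40 — the baits
pull down far more nucleosome than the empty-vector control). Four
technical replicates per condition. Zero draws are omitted from the
table, as in real spectral-count exports. Default class sizes
(40 background / 20 WT-specific / 10 K27M-specific / 33 shared) are a
roughly 10× scale-down of a realistic interactome screen, keeping the
Monte-Carlo validation fast.

**Cohort burden.** Per-tumor totals are negative-binomial with group
means and a common dispersion (default 0.3, a realistic overdispersion
for CNA counts across tumors).

All generators are pure functions of (config, seed).

## Copy-number calling

**GC correction.** Bins are stratified into GC deciles (over retained,
non-blacklisted bins). Per cell, counts in a stratum are rescaled by
(global median / stratum median). Strata with fewer than 10 bins, or
with zero median, are left uncorrected; uniform GC therefore yields the
identity. The correction is deliberately rank-based and model-free — it
removes any smooth monotone-or-quadratic GC trend without assuming its
form.

**Variance stabilization.** Segmentation operates on the Anscombe
square-root transform 2·√(x + 3/8) of the width-normalized corrected
track. Count noise grows with copy number (for negative-binomial counts,
var = m + d·m²), so on the linear scale a one-copy step on a triploid
background has a worse step-to-noise ratio than the same step on a
diploid background; the square root equalizes them and tames high-copy
outliers that would otherwise be selected as spurious focal events.
Integerization (below) uses the linear track.

**Segmentation.** Two independent detectors per chromosome, both with
permutation significance:

- *CBS* — the maximal two-sample |t| of any candidate segment [i, j)
  against its complement within the current window. Testing interior
  segments directly is what gives CBS its sensitivity to focal events: a
  short interior copy change barely moves either half-mean of a plain
  binary split (during development, a 22-bin whole-copy loss inside a
  165-bin chromosome reached only t ≈ 3.0 as a best binary split but
  t ≈ 11 as a segment-vs-complement contrast). A significant segment
  contributes its one or two interior bounds as change points and the
  resulting pieces are re-scanned recursively. Candidate segments and
  their flanks must each span at least `min_seg_len` bins (default 3).
- *e-divisive* — strict hierarchical bisection, placing at each step the
  split maximizing the two-sample energy distance
  n₁n₂/(n₁+n₂) · (2·E|X−Y| − E|X−X′| − E|Y−Y′|) with unbiased
  within-sample means. Distribution-free, but as a bisection method it is
  known to be less sensitive to short interior segments; it serves as the
  independent concordance partner.

Each test permutes the window's values (1,000 permutations) and compares
the observed maximal statistic with the permuted maxima; the candidate is
accepted if the permutation p-value falls below `alpha`. Permutation
stops early as soon as the exceedance count already guarantees
p ≥ `alpha` — the accept/reject decision is identical to the full run;
only the p estimate on accepted-null windows is a conservative partial
one. Both statistics are invariant to adding a constant to the track, so
segmentations are shift-invariant.

**Significance level.** `alpha` defaults to 0.002 per test. Calibration:
each cell incurs ~22 chromosome-level root tests plus a few recursive
ones; at level α the expected number of spurious events per cell is
≈ 25·α. Because a "significant" noise excursion is by selection a large
one (a few bins shifted by nearly a full copy), each spurious event
survives integerization as a real ±1 segment and inflates the structural
score. α = 0.002 keeps the spurious-event rate near 0.05 per cell while
genuine events at the validation depth (30 reads/bin/copy, |t| ≳ 8 for
events of ≥ 10 bins) remain far above threshold. Events shorter than ~5
bins at that depth are below the detection floor of any max-statistic
scan and are the dominant residual error of the structural score.

**Integerization.** Candidate reads-per-copy scales are every
`segment_mean / c` for c = 1..`max_copy` (8). The chosen scale minimizes
the width-weighted mean squared distance of segment means to their
nearest non-negative integers, restricted to scales with genome-mean copy
in [0.5, `max_copy`]. Scales within `scale_tie_tol` (0.02 copy², i.e.
RMS residual differences under ~0.14 copies) of the optimum are treated
as ties: a flat genome is intrinsically scale-ambiguous, and a segment
left unsplit by the segmenter has a fractional mean whose residual
shrinks at every coarser scale, so small objective gaps are not evidence.
Ties resolve toward the scale whose width-weighted median copy is closest
to 2 — the euploid-reference convention — then toward the larger scale
(lower ploidy). Consequence, by design: a perfectly flat tetraploid
genome is reported as diploid; any odd-copy segment covering a
non-trivial genome fraction disambiguates the true scale.

**Curation.** A cell is kept iff (1) the CBS- and e-divisive-derived
integer profiles agree on ≥ `concordance_threshold` of bins (0.90), and
(2) mean reads per bin per copy — raw reads over retained bins divided by
the summed called copies — is ≥ `min_reads_per_bin_per_copy` (5).
Both thresholds are inclusive: a cell at exactly 0.90 or exactly 5.0
passes ("less than" semantics). The reported profile is the CBS-derived
one; the choice is recorded per cell in the QC report
(`reported_algorithm`), and the denominator of the coverage filter uses
the same profile, so the QC is self-consistent.

## Karyotype scores

Definitions as in the README. Numerical conventions: sex chromosomes
(X/Y under chr-prefixed or bare naming) are excluded by default — the
cohort analysis is explicitly autosomal and a male X would otherwise
register as constitutive aneuploidy — and this is configurable
(`include_sex_chromosomes`). The structural denominator is the summed
width of the scored (non-blacklisted, autosomal) bins in Mb, recorded in
the output (`genome_length_mb`) so the convention is auditable.
Transitions are counted between consecutive bins in map order;
overlapping (sliding) bins are permitted by the data model but inflate
transition counts, so the generator emits non-overlapping bins and the
caveat is documented here rather than guarded in code. Heterogeneity
compares unordered cell pairs; with every profile complete (guaranteed
downstream of curation) no pair is ever skipped.

## Interactor classification

Pipeline order is fixed: replicate QC → condition means → background
subtraction → anchor normalization → classification.

- *Replicate QC*: bait replicates need an anchor count strictly above the
  mean EV anchor (configurable to non-strict via `strict_qc`); EV
  replicates are always kept. The anchor must be present in at least one
  EV replicate.
- *Means* zero-fill proteins missing from a replicate, dividing by the
  number of retained replicates.
- *Subtraction* clamps at zero — negative abundances are not
  interpretable; proteins with nothing left in either bait are
  background-only.
- *Normalization* multiplies condition c by anchor(WT)/anchor(c), so the
  WT factor is exactly 1 and a global rescaling of one condition's
  counts (anchor included) cancels.
- *Classification*: a protein present in exactly one bait is unique to
  it; present in both, |WT − K27M| ≤ `enrichment_delta` (2 counts) is
  common-not-enriched, otherwise enriched for the larger side.

"Present" means a post-subtraction normalized mean above
`presence_floor`, default 2.0 counts — the same magnitude as the
enrichment threshold. The floor exists because subtracted means are
noisy around zero: with Poisson background of mean 1 over 4 replicates,
mean(bait) − mean(EV) is positive roughly half the time by symmetry, so
a floor at zero would label about half of all truly-absent proteins as
present. Counts at or below the enrichment threshold are treated as
indistinguishable from residual background. Both the floor and the stage
at which the delta rule applies (`classify_on_normalized`) are exposed
for sensitivity analysis. The anchor protein itself is excluded from
classification — it is the yardstick, not an interactor.

The label set partitions every protein, and
common_total = common_not_enriched + enriched_WT + enriched_K27M holds
structurally (the Venn summary is computed from the same labels).

## Cohort statistics

Autosome parsing accepts `chr1`–`chr22` and bare numerals; `X/Y/chrX/chrY`
rows are dropped; anything else raises with the offending label (silent
misparsing of a burden table is worse than an error). Pre-summed tables
pass through unchanged. The U test uses joint mid-ranks; for
n₁ + n₂ ≤ 12 without ties the two-sided p is exact by full enumeration of
all C(n, n₁) labelings (two-sided = 2 × the smaller tail, capped at 1);
otherwise a normal approximation with tie correction
(Σ(tⱼ³ − tⱼ) term) and a 0.5 continuity correction. Fully tied data
yields p = 1. The enumeration cutoff keeps the exact oracle cheap while
both code paths stay exercised; realistic cohort sizes always take the
approximation.

## Problem sizes used in validation

The end-to-end calling validation uses 50 cells × ~2,900 bins at
30 reads/bin/copy and dispersion 0.05 — deep enough that integer copies
are identifiable, shallow enough to exercise the noise model — and the
Monte-Carlo interactome validation uses 200 seeded runs at effect 10 /
background 1. The rank-sum null calibration uses 1,000 simulated
two-group cohorts of 50 + 50 tumors. These sizes are the package's
standing validation conditions, reproduced by `scripts/acceptance.py`.

## Known limitations

- Events shorter than ~5 bins (≈ 5 Mb at the default binning) at
  30 reads/bin/copy are below the detection floor, and events of ~8-14
  bins sit at the permutation threshold (t ≈ 5), where detection is a
  near toss-up per cell. Because a typical simulated cell carries only
  one-to-a-few true breakpoints, and a clonal event repeats the same
  marginal call across every cell, the structural score has by far the
  largest sampling variability of the three: its relative recovery error
  under the validation conditions ranges from a few percent to several
  tens of percent depending on whether the founder draw contains a
  marginal-length segmental event. The aneuploidy and heterogeneity
  scores, dominated by whole-chromosome events, recover to within ~1%
  and ~4% respectively across seeds.
- The euploid-reference scale search collapses flat whole-genome
  duplications to diploid calls (see Integerization); genomes whose
  aberrant fraction exceeds ~half the genome may resolve to the wrong
  ploidy anchor.
- The spectral-count model treats replicates as independent Poisson
  draws; correlated run-to-run efficiency variation is only captured to
  the extent the anchor normalization removes it.
- The Mann-Whitney normal approximation is used for all realistic cohort
  sizes; its continuity-corrected p can differ from the exact p by up to
  ~0.02 near n = 12, decreasing with n.
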