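# karyocin

Quantifying chromosomal instability and histone-mutant interactomes in
pediatric high-grade glioma — and in any single-cell whole-genome
sequencing (scWGS) or spectral-count IP/MS dataset with the same shape.

H3.3K27M-mutant gliomas are highly aneuploid tumors with ongoing genomic
and chromosomal instability: individual tumor cells carry private
chromosome gains/losses and segmental changes on top of clonal events.
`karyocin` packages the quantitative machinery needed to measure this from
shallow scWGS, to classify the mutant histone's protein interactors from
label-free spectral counts, and to compare copy-number-aberration (CNA)
burden between tumor subtype cohorts — with a synthetic-data module that
generates every input with known ground truth, so the whole pipeline is
testable without any sequencing download.

## What it computes

**Copy-number calling and curation** (`karyocin.calling`). Binned read
counts are GC-corrected (median-of-GC-decile rescaling, blacklisted bins
dropped), segmented per chromosome by two independent change-point
detectors — CBS (max two-sample *t* of any candidate segment against its
complement, 1,000-permutation significance) and e-divisive (hierarchical
bisection on the two-sample energy distance) — and integerized by a
reads-per-copy scale search with a euploid (median-copy-2) reference.
Cells are kept only if the two detectors agree on ≥ 90% of bins and the
library carries ≥ 5 reads per bin per chromosome copy (≈ 30,000 reads for
a diploid genome at 1 Mb bins).

**Karyotype instability scores** (`karyocin.scores`), for a curated cell
population over bins *b* with widths *w_b* and cells *i = 1..n*:

- *aneuploidy* — per cell, Σ_b w_b · |c_b − e| / Σ_b w_b with euploid
  expectation e (default 2); sample score = mean over cells. Static
  deviation from the euploid karyotype.
- *heterogeneity* — per bin, the fraction of the n(n−1)/2 unordered cell
  pairs with unequal copy; sample score = width-weighted mean over bins.
  Cell-to-cell karyotype variation, i.e. ongoing instability.
- *structural* — per cell, copy-number transitions between consecutive
  same-chromosome bins divided by the genome length in Mb (breakpoints
  per Mb); sample score = mean over cells.

**Interactor classification** (`karyocin.interactome`). For a
three-condition FLAG-IP experiment (EV empty-vector control, WT and K27M
baits) quantified by spectral counts: replicates whose histone-H4 anchor
count does not exceed the EV background are discarded; per-protein
condition means are background-subtracted (EV, clamped at 0) and
normalized to the WT H4 anchor; proteins are then partitioned into
WT-unique / K27M-unique / common-not-enriched (|WT − K27M| ≤ 2 spectral
counts) / WT- or K27M-enriched / background-only.

**Cohort CNA burden** (`karyocin.cohort`). Autosomal CNA events are
summed per tumor (sex chromosomes dropped) and compared between subtype
groups with a Mann-Whitney U test implemented from first principles:
mid-rank U, exact enumeration for small untied samples, tie- and
continuity-corrected normal approximation otherwise.

## Worked example

```python
import numpy as np
from karyocin import (
    PopulationSimConfig, ReadSimConfig, CallerParams,
    simulate_population, simulate_read_counts, call_and_curate, score_sample,
)

pop = simulate_population(PopulationSimConfig(
    n_cells=10, founder_event_count=4,
    missegregation_rate=0.5, segmental_rate=0.5, seed=7,
))
counts = simulate_read_counts(pop, ReadSimConfig(
    mean_reads_per_bin_per_copy=30, dispersion=0.05, seed=8))
called, qc = call_and_curate(counts, pop.binmap, CallerParams(seed=9))
print(qc[["cell_id", "concordance", "mean_reads_per_bin_per_copy", "passed"]].head(3))
print("bin accuracy:", np.mean(called.copies == pop.copies).round(4))
s = score_sample(called)
print(f"aneuploidy={s.sample_aneuploidy:.4f} "
      f"heterogeneity={s.sample_heterogeneity:.4f} "
      f"structural={s.sample_structural:.5f}")
```

prints

```
    cell_id  concordance  mean_reads_per_bin_per_copy  passed
0  cell0001     0.996883                    30.026904    True
1  cell0002     0.997229                    29.814531    True
2  cell0003     0.979910                    30.041320    True
bin accuracy: 0.998
aneuploidy=0.1617 heterogeneity=0.0891 structural=0.00160
```

Every simulated cell passed both curation filters with ≥ 98%
inter-detector concordance, and 99.8% of bins received their true copy
number. The scores say: the average cell deviates from the diploid
expectation on ~16% of its genome (width-weighted), 8.9% of
genome-weighted cell pairs disagree in copy number (ongoing
instability), and cells carry ~0.0016 breakpoints per Mb (≈ 4.6
sub-chromosomal transitions per cell on this ~2.9 Gb genome).

The same stages are available from the shell:

```bash
karyocin simulate-population --n-cells 10 --founder-events 4 --seed 7 --out-prefix sim
karyocin simulate-reads --population sim.population.tsv --binmap sim.binmap.bed \
    --mean-reads 30 --dispersion 0.05 --seed 8 --out counts.tsv
karyocin call-cnv --counts counts.tsv --binmap sim.binmap.bed --out-prefix called
karyocin score-karyotype --population called.profiles.tsv --binmap sim.binmap.bed --out scores.json
```

plus `simulate-spectra` / `classify-interactome` and `simulate-burden` /
`cna-burden` for the other two analyses. Every artifact gets a JSON
sidecar with the version, config hash and seed that produced it.

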