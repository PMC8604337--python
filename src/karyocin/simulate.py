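"""Synthetic data generators for every pipeline stage.

Four generators emulate the statistical structure the downstream analyses
assume, so each stage can be verified against known ground truth:

* :func:`simulate_population` — clonal tumor cell populations with
  whole-chromosome missegregations, segmental events and optional
  whole-genome duplication, as integer copy-number profiles over a bin map.
* :func:`simulate_read_counts` — shallow-coverage binned read counts with
  negative-binomial noise and a quadratic multiplicative GC bias.
* :func:`simulate_spectral_counts` — label-free IP/MS spectral-count tables
  with an empty-vector background condition, an H4 anchor protein and
  bait-specific interactor classes.
* :func:`simulate_cna_burden` — per-tumor autosomal CNA totals for cohort
  group comparisons.

All generators are pure functions of (config, seed): identical configs give
bit-identical output. Ground-truth labels/profiles are always returned so
every downstream stage has an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CONDITIONS, CellPopulation, GenomeBinMap, ReadCountMatrix, SpectralCountTable

__all__ = [
    "SimEvent",
    "PopulationSimConfig",
    "ReadSimConfig",
    "SpectraSimConfig",
    "BurdenSimConfig",
    "simulate_population",
    "simulate_read_counts",
    "simulate_spectral_counts",
    "simulate_cna_burden",
    "default_chromosome_lengths",
]

_MAX_EVENT_RETRIES = 100


def default_chromosome_lengths(n_chromosomes: int = 22, total_mb: float = 2875.0) -> dict[str, int]:
    """Autosome lengths decaying roughly like the human karyotype.

    Lengths fall off linearly from chr1 to chr22 and sum to ``total_mb``
    megabases (the human autosomal genome is ~2,875 Mb).
    """
    raw = np.linspace(2.0, 0.5, n_chromosomes)
    mb = raw / raw.sum() * total_mb
    return {f"chr{i + 1}": int(round(m * 1e6)) for i, m in enumerate(mb)}


@dataclass(frozen=True)
class SimEvent:
    """One copy-number event: whole-chromosome or segmental gain/loss."""

    kind: str  # "whole" | "segment"
    chrom: str
    delta: int  # +1 / -1 (or +ploidy for duplications)
    start: int | None = None  # bp, segmental only
    end: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("whole", "segment"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "segment" and (self.start is None or self.end is None):
            raise ValueError("segmental events need start/end")


@dataclass
class PopulationSimConfig:
    """Parameters for a clonal cell-population simulation.

    ``missegregation_rate`` and ``segmental_rate`` are the expected number
    of private whole-chromosome and segmental events per cell (Poisson).
    ``subclone_fractions`` lists (fraction, events) for discrete subclones;
    the remaining fraction is the founder clone.
    """

    n_cells: int = 20
    chromosome_lengths: dict[str, int] = field(default_factory=default_chromosome_lengths)
    bin_width: int = 1_000_000
    base_ploidy: int = 2
    wgd_probability: float = 0.0
    founder_event_count: int = 0
    missegregation_rate: float = 0.0
    segmental_rate: float = 0.0
    subclone_fractions: list[tuple[float, list[SimEvent]]] = field(default_factory=list)
    gc_range: tuple[float, float] = (0.3, 0.6)  # symmetric about 0.45
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not self.chromosome_lengths:
            raise ValueError("empty genome: no chromosomes given")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if min(self.missegregation_rate, self.segmental_rate) < 0:
            raise ValueError("event rates must be >= 0")
        if not 0.0 <= self.wgd_probability <= 1.0:
            raise ValueError("wgd_probability must be in [0, 1]")
        if self.base_ploidy < 0 or self.founder_event_count < 0:
            raise ValueError("base_ploidy and founder_event_count must be >= 0")
        if sum(f for f, _ in self.subclone_fractions) > 1.0 + 1e-12:
            raise ValueError("subclone fractions must sum to <= 1")


@dataclass
class ReadSimConfig:
    """Read-depth model: counts per (cell, bin) have mean

    ``copy * mean_reads_per_bin_per_copy * gc_factor(bin) * width / mean_width``

    drawn negative-binomially with variance ``m + dispersion * m^2``
    (``dispersion = 0`` reduces to Poisson). The default mean of 5 reads per
    bin per copy sits exactly on the library QC floor used downstream.
    """

    mean_reads_per_bin_per_copy: float = 5.0
    dispersion: float = 0.0
    gc_bias_amplitude: float = 0.0  # quadratic multiplicative bias, centred at GC 0.45
    seed: int = 0

    def validate(self) -> None:
        if self.mean_reads_per_bin_per_copy <= 0:
            raise ValueError("mean_reads_per_bin_per_copy must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class SpectraSimConfig:
    """Spectral-count model for a three-condition FLAG-IP experiment.

    Every protein carries Poisson background in every condition
    (``background_mean``); bait-specific classes add ``effect_mean`` in
    their designated bait condition(s). The H4 anchor is drawn with
    condition-specific means reflecting nucleosome pull-down yield. Four
    technical replicates per condition by default.
    """

    n_background_proteins: int = 40
    n_wt_specific: int = 20
    n_k27m_specific: int = 10
    n_shared: int = 33
    n_replicates_per_condition: int = 4
    background_mean: float = 1.0
    effect_mean: float = 10.0
    h4_mean_per_condition: dict[str, float] = field(
        default_factory=lambda: {"EV": 6.0, "WT": 40.0, "K27M": 40.0}
    )
    anchor: str = "H4"
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_background_proteins,
            self.n_wt_specific,
            self.n_k27m_specific,
            self.n_shared,
        )
        if any(c < 0 for c in counts):
            raise ValueError("protein class counts must be >= 0")
        if self.n_replicates_per_condition < 1:
            raise ValueError("need at least one replicate per condition")
        if self.background_mean <= 0 and self.n_background_proteins > 0:
            raise ValueError("background_mean must be > 0")
        if self.effect_mean < 0:
            raise ValueError("effect_mean must be >= 0")
        if set(self.h4_mean_per_condition) != set(CONDITIONS):
            raise ValueError(f"h4_mean_per_condition must cover {CONDITIONS}")


@dataclass
class BurdenSimConfig:
    """Per-tumor autosomal CNA totals, negative-binomial per subtype group."""

    group_sizes: dict[str, int] = field(default_factory=lambda: {"A": 50, "B": 50})
    group_cna_means: dict[str, float] = field(default_factory=lambda: {"A": 10.0, "B": 10.0})
    dispersion: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes:
            raise ValueError("no groups given")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} must have >= 2 tumors")
            if g not in self.group_cna_means:
                raise ValueError(f"no CNA mean for group {g!r}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


# ----------------------------------------------------------------------
# population simulation


def _build_binmap(config: PopulationSimConfig, rng: np.random.Generator) -> GenomeBinMap:
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for name in sorted(config.chromosome_lengths):
        length = config.chromosome_lengths[name]
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length")
        edges = list(range(0, length, config.bin_width)) + [length]
        for s, e in zip(edges[:-1], edges[1:]):
            chroms.append(name)
            starts.append(s)
            ends.append(e)
    lo, hi = config.gc_range
    gc = rng.uniform(lo, hi, size=len(chroms))
    return GenomeBinMap(
        chroms=np.array(chroms, object),
        starts=np.array(starts, np.int64),
        ends=np.array(ends, np.int64),
        gc=gc,
        blacklisted=np.zeros(len(chroms), bool),
    )


def _event_mask(event: SimEvent, binmap: GenomeBinMap) -> np.ndarray:
    mask = binmap.chroms == event.chrom
    if not mask.any():
        raise ValueError(f"event on unknown chromosome {event.chrom!r}")
    if event.kind == "segment":
        mask &= (binmap.starts < event.end) & (binmap.ends > event.start)
    return mask


def _random_event(binmap: GenomeBinMap, rng: np.random.Generator, kind: str) -> SimEvent:
    blocks = binmap.chromosome_slices()
    name, sl = blocks[rng.integers(len(blocks))]
    delta = int(rng.choice((-1, 1)))
    if kind == "whole":
        return SimEvent("whole", name, delta)
    # segmental: a uniform random pair of distinct bin boundaries within the chromosome
    n = sl.stop - sl.start
    if n < 2:
        return SimEvent("whole", name, delta)
    i, j = sorted(rng.choice(n + 1, size=2, replace=False))
    if j == i:  # pragma: no cover - replace=False forbids this
        j = i + 1
    bounds = np.append(binmap.starts[sl], binmap.ends[sl][-1])
    return SimEvent("segment", name, delta, start=int(bounds[i]), end=int(bounds[j]))


def _apply_events_clamped(
    base: np.ndarray,
    binmap: GenomeBinMap,
    n_events: int,
    rng: np.random.Generator,
    seg_prob: float,
) -> np.ndarray:
    """Apply n random events; losses that would go below zero are resampled."""
    copies = base.copy()
    for _ in range(n_events):
        for _try in range(_MAX_EVENT_RETRIES):
            kind = "segment" if rng.random() < seg_prob else "whole"
            ev = _random_event(binmap, rng, kind)
            mask = _event_mask(ev, binmap)
            if np.all(copies[mask] + ev.delta >= 0):
                copies[mask] += ev.delta
                break
        # all retries exhausted: the event is dropped (fully null genome region)
    return copies


def simulate_population(config: PopulationSimConfig) -> CellPopulation:
    """Draw a clonal cell population with ground-truth integer profiles.

    The founder karyotype is ``base_ploidy`` everywhere, doubled with
    probability ``wgd_probability``, plus ``founder_event_count`` random
    clonal events shared by every founder-clone cell. Subclones apply their
    configured event lists on top of the founder. Each cell then receives
    Poisson-distributed private missegregation and segmental events.
    Copy numbers are clamped at zero by resampling impossible losses.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    binmap = _build_binmap(config, rng)
    n_bins = binmap.n_bins

    ploidy = config.base_ploidy
    if rng.random() < config.wgd_probability:
        ploidy *= 2
    founder = np.full(n_bins, ploidy, np.int64)
    founder = _apply_events_clamped(founder, binmap, config.founder_event_count, rng, seg_prob=0.3)

    # assign cells to clones: subclone blocks first, founder takes the rest
    clone_bases: list[tuple[str, np.ndarray]] = []
    assigned = 0
    for k, (frac, events) in enumerate(config.subclone_fractions):
        n_sub = int(round(frac * config.n_cells))
        base = founder.copy()
        for ev in events:
            mask = _event_mask(ev, binmap)
            base[mask] = np.maximum(base[mask] + ev.delta, 0)
        clone_bases.extend((f"subclone{k + 1}", base) for _ in range(min(n_sub, config.n_cells - assigned)))
        assigned = len(clone_bases)
    clone_bases.extend(("founder", founder) for _ in range(config.n_cells - assigned))

    copies = np.empty((n_bins, config.n_cells), np.int64)
    clone_labels: list[str] = []
    cell_ids: list[str] = []
    for j, (label, base) in enumerate(clone_bases):
        cell = base.copy()
        n_mis = rng.poisson(config.missegregation_rate)
        n_seg = rng.poisson(config.segmental_rate)
        cell = _apply_events_clamped(cell, binmap, n_mis, rng, seg_prob=0.0)
        cell = _apply_events_clamped(cell, binmap, n_seg, rng, seg_prob=1.0)
        copies[:, j] = cell
        clone_labels.append(label)
        cell_ids.append(f"cell{j + 1:04d}")

    return CellPopulation(
        binmap=binmap,
        cell_ids=cell_ids,
        copies=copies,
        sample_id=f"sim-seed{config.seed}",
        clone_labels=clone_labels,
    )


# ----------------------------------------------------------------------
# read-count simulation


def gc_bias_factor(gc: np.ndarray, amplitude: float) -> np.ndarray:
    """Quadratic multiplicative coverage bias centred at GC 0.45.

    ``amplitude`` ~10 produces a ±20% depth swing over GC 0.3-0.6;
    the factor is floored at 0.05 to keep means positive.
    """
    return np.maximum(1.0 - amplitude * (np.asarray(gc) - 0.45) ** 2, 0.05)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion  # var = m + d m^2
    p = size / (size + mean)
    out = np.zeros(mean.shape, np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size, p[pos])
    return out


def simulate_read_counts(population: CellPopulation, config: ReadSimConfig) -> ReadCountMatrix:
    """Draw binned read counts for every cell of a simulated population."""
    config.validate()
    if np.any(population.copies < 0):
        raise ValueError("negative copy states in population")
    rng = np.random.default_rng(config.seed)
    binmap = population.binmap
    widths = binmap.widths.astype(float)
    width_factor = widths / widths.mean()
    gc_factor = gc_bias_factor(binmap.gc, config.gc_bias_amplitude)
    per_bin = config.mean_reads_per_bin_per_copy * gc_factor * width_factor
    mean = population.copies * per_bin[:, None]
    values = _nb_draw(rng, mean, config.dispersion)
    return ReadCountMatrix(binmap=binmap, cell_ids=list(population.cell_ids), values=values)


# ----------------------------------------------------------------------
# spectral-count simulation


def simulate_spectral_counts(config: SpectraSimConfig) -> SpectralCountTable:
    """Draw a long-form spectral-count table with known interactor classes.

    Every protein has Poisson background in every condition; WT-specific
    and shared proteins gain ``effect_mean`` in WT replicates, K27M-specific
    and shared in K27M replicates. Zero draws are omitted from the table
    (a protein not identified in a run has no record), matching real
    spectral-count exports. Ground-truth class labels ride along in
    ``truth_labels`` (``anchor`` for H4 itself).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    proteins: list[str] = []
    truth: dict[str, str] = {}

    def add(prefix: str, n: int, label: str) -> None:
        for i in range(n):
            name = f"{prefix}{i + 1:04d}"
            proteins.append(name)
            truth[name] = label

    add("BG", config.n_background_proteins, "background")
    add("WTSP", config.n_wt_specific, "wt_specific")
    add("KMSP", config.n_k27m_specific, "k27m_specific")
    add("SH", config.n_shared, "shared")
    truth[config.anchor] = "anchor"

    records: list[tuple[str, str, int, int]] = []
    for cond in CONDITIONS:
        for rep in range(1, config.n_replicates_per_condition + 1):
            h4 = int(rng.poisson(config.h4_mean_per_condition[cond]))
            if h4 > 0:
                records.append((config.anchor, cond, rep, h4))
            for name in proteins:
                mean = config.background_mean
                label = truth[name]
                if cond == "WT" and label in ("wt_specific", "shared"):
                    mean += config.effect_mean
                elif cond == "K27M" and label in ("k27m_specific", "shared"):
                    mean += config.effect_mean
                c = int(rng.poisson(mean))
                if c > 0:
                    records.append((name, cond, rep, c))

    df = pd.DataFrame(records, columns=["protein", "condition", "replicate", "spec_count"])
    return SpectralCountTable(data=df, anchor=config.anchor, truth_labels=truth)


# ----------------------------------------------------------------------
# cohort burden simulation


def simulate_cna_burden(config: BurdenSimConfig) -> pd.DataFrame:
    """Per-tumor autosomal CNA totals with subtype labels.

    Returns a tidy frame (tumor, subtype, total) drawn negative-binomially
    with the stated group means and shared dispersion.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for group in sorted(config.group_sizes):
        n = config.group_sizes[group]
        mean = np.full(n, config.group_cna_means[group], float)
        totals = _nb_draw(rng, mean, config.dispersion)
        for i, t in enumerate(totals):
            rows.append((f"{group}-T{i + 1:03d}", group, int(t)))
    return pd.DataFrame(rows, columns=["tumor", "subtype", "total"])
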