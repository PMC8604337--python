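import numpy as np
import pytest

from karyocin.containers import CellPopulation, GenomeBinMap


def build_binmap(spec, gc=None, blacklisted=None) -> GenomeBinMap:
    """Build a bin map from [(chrom, [width, width, ...]), ...]."""
    chroms, starts, ends = [], [], []
    for chrom, widths in spec:
        pos = 0
        for w in widths:
            chroms.append(chrom)
            starts.append(pos)
            ends.append(pos + w)
            pos += w
    n = len(chroms)
    return GenomeBinMap(
        chroms=np.array(chroms, object),
        starts=np.array(starts, np.int64),
        ends=np.array(ends, np.int64),
        gc=np.asarray(gc, float) if gc is not None else np.full(n, 0.45),
        blacklisted=np.asarray(blacklisted, bool) if blacklisted is not None else np.zeros(n, bool),
    )


def build_population(spec, copies, sample_id="test") -> CellPopulation:
    """Population from a bin-map spec and a (n_bins, n_cells) copy array."""
    binmap = build_binmap(spec)
    copies = np.asarray(copies, np.int64)
    if copies.ndim == 1:
        copies = copies[:, None]
    return CellPopulation(
        binmap=binmap,
        cell_ids=[f"c{j + 1}" for j in range(copies.shape[1])],
        copies=copies,
        sample_id=sample_id,
    )


def brute_force_scores(copies, widths, chroms, euploid=2):
    """Score oracle: explicit loops over every bin and every cell pair.

    Returns (sample aneuploidy, sample heterogeneity, sample structural);
    deliberately naive and independent of the library implementation.
    """
    copies = np.asarray(copies)
    n_bins, n_cells = copies.shape
    total_w = float(sum(widths))

    per_cell_an = []
    for j in range(n_cells):
        acc = 0.0
        for b in range(n_bins):
            acc += widths[b] * abs(int(copies[b, j]) - euploid)
        per_cell_an.append(acc / total_w)

    het_acc = 0.0
    n_pairs = n_cells * (n_cells - 1) / 2
    for b in range(n_bins):
        discordant = 0
        for i in range(n_cells):
            for j in range(i + 1, n_cells):
                if copies[b, i] != copies[b, j]:
                    discordant += 1
        het_acc += widths[b] * (discordant / n_pairs)
    het = het_acc / total_w

    genome_mb = total_w / 1e6
    per_cell_st = []
    for j in range(n_cells):
        transitions = 0
        for b in range(1, n_bins):
            if chroms[b] == chroms[b - 1] and copies[b, j] != copies[b - 1, j]:
                transitions += 1
        per_cell_st.append(transitions / genome_mb)

    return (
        float(np.mean(per_cell_an)),
        float(het),
        float(np.mean(per_cell_st)),
    )


@pytest.fixture
def binmap_factory():
    return build_binmap


@pytest.fixture
def population_factory():
    return build_population
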