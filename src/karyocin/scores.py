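"""Aneuploidy, heterogeneity and structural instability scores.

Three statistics summarize a curated single-cell copy-number population:

* **Aneuploidy** — per cell, the bin-width-weighted mean of
  ``|copy - euploid|``; the sample score is the unweighted mean over
  cells. Measures the static deviation from the euploid karyotype.
* **Heterogeneity** — per bin, the proportion of the ``n(n-1)/2``
  unordered cell pairs with unequal copy; the sample score is the
  bin-width-weighted mean of those proportions. Measures cell-to-cell
  karyotype variation, i.e. ongoing instability.
* **Structural** — per cell, the number of copy-number transitions
  between consecutive bins of the same chromosome divided by the total
  genome length in Mb (breakpoints per Mb); the sample score is the
  unweighted mean over cells. Measures sub-chromosomal rearrangement.

Sex chromosomes are excluded by default; scoring runs on autosomal,
non-blacklisted bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CellPopulation, CopyNumberProfile, GenomeBinMap

__all__ = [
    "KaryotypeScores",
    "cell_aneuploidy",
    "sample_aneuploidy",
    "sample_heterogeneity",
    "cell_structural",
    "score_sample",
]


@dataclass
class KaryotypeScores:
    """Bundle of the per-cell and per-sample instability scores."""

    sample_id: str
    cell_ids: list[str]
    per_cell_aneuploidy: np.ndarray
    per_cell_structural: np.ndarray
    sample_aneuploidy: float
    sample_heterogeneity: float
    sample_structural: float
    euploid_reference_copy: int = 2
    genome_length_mb: float = 0.0  # structural-score denominator actually used
    include_sex_chromosomes: bool = False

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "sample_scores": {
                "aneuploidy": self.sample_aneuploidy,
                "heterogeneity": self.sample_heterogeneity,
                "structural": self.sample_structural,
            },
            "per_cell": {
                cid: {
                    "aneuploidy": float(a),
                    "structural": float(s),
                }
                for cid, a, s in zip(
                    self.cell_ids, self.per_cell_aneuploidy, self.per_cell_structural
                )
            },
            "parameters": {
                "euploid_reference_copy": self.euploid_reference_copy,
                "genome_length_mb": self.genome_length_mb,
                "include_sex_chromosomes": self.include_sex_chromosomes,
            },
        }


def _scoring_mask(binmap: GenomeBinMap, include_sex: bool) -> np.ndarray:
    mask = ~binmap.blacklisted
    if not include_sex:
        mask &= binmap.autosome_mask()
    if not mask.any():
        raise ValueError("no scorable bins (all blacklisted or sex-chromosomal)")
    return mask


def cell_aneuploidy(
    profile: CopyNumberProfile | np.ndarray,
    binmap: GenomeBinMap,
    euploid_copy: int = 2,
    include_sex_chromosomes: bool = False,
) -> float:
    """Width-weighted mean absolute deviation from the euploid copy number."""
    copies = profile.copies if isinstance(profile, CopyNumberProfile) else np.asarray(profile)
    if copies.size != binmap.n_bins:
        raise ValueError("profile does not cover the bin map")
    mask = _scoring_mask(binmap, include_sex_chromosomes)
    w = binmap.widths[mask].astype(float)
    dev = np.abs(copies[mask] - euploid_copy)
    return float((w * dev).sum() / w.sum())


def sample_aneuploidy(
    population: CellPopulation,
    euploid_copy: int = 2,
    include_sex_chromosomes: bool = False,
) -> float:
    """Unweighted mean of the per-cell aneuploidy scores."""
    return float(
        np.mean(
            [
                cell_aneuploidy(population.copies[:, j], population.binmap, euploid_copy, include_sex_chromosomes)
                for j in range(population.n_cells)
            ]
        )
    )


def sample_heterogeneity(
    population: CellPopulation,
    include_sex_chromosomes: bool = False,
) -> float:
    """Width-weighted mean, over bins, of the fraction of discordant cell pairs.

    For each bin, every unordered pair of cells is compared; the bin score
    is the proportion of pairs with unequal copy number. Requires at least
    two cells.
    """
    n = population.n_cells
    if n < 2:
        raise ValueError(f"heterogeneity needs >= 2 cells, got {n}")
    mask = _scoring_mask(population.binmap, include_sex_chromosomes)
    copies = population.copies[mask]
    w = population.binmap.widths[mask].astype(float)
    total_pairs = n * (n - 1) / 2
    # pairs sharing a copy state: sum over states of C(count, 2), per bin
    discordant = np.empty(copies.shape[0])
    for i, row in enumerate(copies):
        _, counts = np.unique(row, return_counts=True)
        same = (counts * (counts - 1) / 2).sum()
        discordant[i] = (total_pairs - same) / total_pairs
    return float((w * discordant).sum() / w.sum())


def cell_structural(
    profile: CopyNumberProfile | np.ndarray,
    binmap: GenomeBinMap,
    include_sex_chromosomes: bool = False,
) -> float:
    """Copy-number transitions between consecutive same-chromosome bins, per Mb.

    The denominator is the total span (sum of widths) of the scored bins,
    in megabases. Transitions across chromosome boundaries are never
    counted; single-bin chromosomes contribute zero.
    """
    copies = profile.copies if isinstance(profile, CopyNumberProfile) else np.asarray(profile)
    if copies.size != binmap.n_bins:
        raise ValueError("profile does not cover the bin map")
    mask = _scoring_mask(binmap, include_sex_chromosomes)
    sub_map = binmap.subset(mask)
    sub = copies[mask]
    transitions = 0
    for _, sl in sub_map.chromosome_slices():
        seg = sub[sl]
        transitions += int(np.sum(seg[1:] != seg[:-1]))
    genome_mb = sub_map.widths.sum() / 1e6
    return float(transitions / genome_mb)


def score_sample(
    population: CellPopulation,
    euploid_copy: int = 2,
    include_sex_chromosomes: bool = False,
) -> KaryotypeScores:
    """Compute all three instability scores for one sample."""
    if population.n_cells < 2:
        raise ValueError("sample scoring needs >= 2 cells")
    mask = _scoring_mask(population.binmap, include_sex_chromosomes)
    per_an = np.array(
        [
            cell_aneuploidy(population.copies[:, j], population.binmap, euploid_copy, include_sex_chromosomes)
            for j in range(population.n_cells)
        ]
    )
    per_st = np.array(
        [
            cell_structural(population.copies[:, j], population.binmap, include_sex_chromosomes)
            for j in range(population.n_cells)
        ]
    )
    return KaryotypeScores(
        sample_id=population.sample_id,
        cell_ids=list(population.cell_ids),
        per_cell_aneuploidy=per_an,
        per_cell_structural=per_st,
        sample_aneuploidy=float(per_an.mean()),
        sample_heterogeneity=sample_heterogeneity(population, include_sex_chromosomes),
        sample_structural=float(per_st.mean()),
        euploid_reference_copy=euploid_copy,
        genome_length_mb=float(population.binmap.widths[mask].sum() / 1e6),
        include_sex_chromosomes=include_sex_chromosomes,
    )
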