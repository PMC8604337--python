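"""Core in-memory containers shared by every pipeline stage.

The coordinate frame for all single-cell work is a :class:`GenomeBinMap` —
an ordered list of genomic intervals (BED convention, 0-based half-open)
with per-bin GC content and blacklist flags. Copy-number profiles, read
counts and instability scores are all expressed over one bin map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBinMap",
    "ReadCountMatrix",
    "CopyNumberProfile",
    "CellPopulation",
    "SpectralCountTable",
    "CONDITIONS",
]

#: the fixed immunoprecipitation conditions: empty-vector control and the two baits
CONDITIONS = ("EV", "WT", "K27M")

_SEX_CHROM_NAMES = {"x", "y", "chrx", "chry"}


def is_sex_chromosome(name: str) -> bool:
    """True for X/Y under common naming conventions (chrX, X, ...)."""
    return str(name).lower() in _SEX_CHROM_NAMES


@dataclass(frozen=True)
class GenomeBinMap:
    """Ordered genomic bins with widths, GC content and blacklist flags.

    Bins are sorted by (chromosome, start), may overlap within a chromosome
    (sliding windows) but never span two chromosomes. Coordinates are
    0-based half-open.
    """

    chroms: np.ndarray  # object array of chromosome names, len n_bins
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64
    gc: np.ndarray  # float64 in [0, 1]
    blacklisted: np.ndarray  # bool

    def __post_init__(self) -> None:
        n = len(self.chroms)
        for name in ("starts", "ends", "gc", "blacklisted"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"bin map column {name!r} has wrong length")
        if n == 0:
            raise ValueError("empty bin map")
        if np.any(self.ends <= self.starts):
            bad = int(np.argmax(self.ends <= self.starts))
            raise ValueError(f"bin {bad}: end <= start")
        # sorted by (chromosome, start); chromosomes must form contiguous blocks
        order = np.lexsort((self.starts, self.chroms))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("bin map is not sorted by (chromosome, start)")

    # ------------------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return len(self.chroms)

    @property
    def widths(self) -> np.ndarray:
        return (self.ends - self.starts).astype(np.int64)

    def chromosome_slices(self) -> list[tuple[str, slice]]:
        """Contiguous (chromosome, slice) blocks in map order."""
        out: list[tuple[str, slice]] = []
        start = 0
        for i in range(1, self.n_bins + 1):
            if i == self.n_bins or self.chroms[i] != self.chroms[start]:
                out.append((str(self.chroms[start]), slice(start, i)))
                start = i
        return out

    def autosome_mask(self) -> np.ndarray:
        return ~np.array([is_sex_chromosome(c) for c in self.chroms])

    def subset(self, mask: np.ndarray) -> "GenomeBinMap":
        if not mask.any():
            raise ValueError("subset would produce an empty bin map")
        return GenomeBinMap(
            chroms=self.chroms[mask],
            starts=self.starts[mask],
            ends=self.ends[mask],
            gc=self.gc[mask],
            blacklisted=self.blacklisted[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "gc": self.gc,
                "blacklist": self.blacklisted.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeBinMap":
        gc = df["gc"].to_numpy(float) if "gc" in df else np.full(len(df), np.nan)
        bl = (
            df["blacklist"].to_numpy().astype(bool)
            if "blacklist" in df
            else np.zeros(len(df), bool)
        )
        return cls(
            chroms=df["chrom"].to_numpy(object),
            starts=df["start"].to_numpy(np.int64),
            ends=df["end"].to_numpy(np.int64),
            gc=gc,
            blacklisted=bl,
        )

    def bin_keys(self) -> list[str]:
        """chrom:start-end identifiers, one per bin."""
        return [
            f"{c}:{s}-{e}" for c, s, e in zip(self.chroms, self.starts, self.ends)
        ]

    def same_frame(self, other: "GenomeBinMap") -> bool:
        return (
            self.n_bins == other.n_bins
            and np.array_equal(self.chroms, other.chroms)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )


@dataclass(frozen=True)
class ReadCountMatrix:
    """Bin-by-cell matrix of non-negative read counts bound to a bin map."""

    binmap: GenomeBinMap
    cell_ids: list[str]
    values: np.ndarray  # shape (n_bins, n_cells)

    def __post_init__(self) -> None:
        if self.values.shape != (self.binmap.n_bins, len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{self.binmap.n_bins} bins x {len(self.cell_ids)} cells"
            )
        if np.any(self.values < 0):
            raise ValueError("read counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass(frozen=True)
class CopyNumberProfile:
    """Integer copy state per bin for one cell."""

    cell_id: str
    copies: np.ndarray  # int64, aligned to a bin map

    def __post_init__(self) -> None:
        if np.any(self.copies < 0):
            raise ValueError("copy states must be >= 0")


@dataclass
class CellPopulation:
    """A set of per-cell integer copy-number profiles over one bin map."""

    binmap: GenomeBinMap
    cell_ids: list[str]
    copies: np.ndarray  # shape (n_bins, n_cells), int
    sample_id: str = "sample"
    clone_labels: list[str] | None = None  # simulator ground truth, if any

    def __post_init__(self) -> None:
        if self.copies.shape != (self.binmap.n_bins, len(self.cell_ids)):
            raise ValueError("copy matrix shape does not match bin map / cells")
        if len(self.cell_ids) < 1:
            raise ValueError("population needs at least one cell")
        if np.any(self.copies < 0):
            raise ValueError("copy states must be >= 0")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def profile(self, cell_id: str) -> CopyNumberProfile:
        j = self.cell_ids.index(cell_id)
        return CopyNumberProfile(cell_id, self.copies[:, j])

    def profiles(self) -> list[CopyNumberProfile]:
        return [
            CopyNumberProfile(cid, self.copies[:, j])
            for j, cid in enumerate(self.cell_ids)
        ]


@dataclass
class SpectralCountTable:
    """Long-form protein x condition x replicate spectral counts.

    Rows with zero counts are conventionally absent (a protein not
    identified in a run simply has no record); downstream averaging
    zero-fills missing (protein, replicate) pairs.
    """

    data: pd.DataFrame  # columns: protein, condition, replicate, spec_count
    anchor: str = "H4"
    truth_labels: dict[str, str] | None = None  # simulator ground truth

    REQUIRED = ("protein", "condition", "replicate", "spec_count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"spectral count table missing columns {missing}")
        bad = set(self.data["condition"].unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        if (self.data["spec_count"] < 0).any():
            raise ValueError("spectral counts must be non-negative")

    def replicates(self, condition: str) -> list:
        sub = self.data[self.data["condition"] == condition]
        return sorted(sub["replicate"].unique().tolist())
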