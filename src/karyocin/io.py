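"""File formats: BED bin maps, TSV matrices, CSV spectral counts, configs.

Coordinates are 0-based half-open everywhere (BED convention). Matrices
are TSV with a leading ``bin`` column of ``chrom:start-end`` keys and one
column per cell; integer profiles are serialized without decimal points
and round-trip exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CellPopulation, GenomeBinMap, ReadCountMatrix, SpectralCountTable

__all__ = [
    "read_binmap",
    "write_binmap",
    "read_matrix",
    "write_matrix",
    "read_counts",
    "read_population",
    "write_population",
    "read_spectral_counts",
    "write_spectral_counts",
    "read_burden_table",
    "write_segments_bed",
    "load_config",
    "write_run_sidecar",
]

log = logging.getLogger("karyocin")


class BinmapFormatError(ValueError):
    """Malformed BED bin-map input, with the offending line number."""


def read_binmap(path) -> GenomeBinMap:
    """Read a bin map from BED (chrom, start, end[, name, gc, blacklist]).

    Lines are validated individually; malformed lines are reported with
    their 1-based line number. Unsorted input is sorted with a warning.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BinmapFormatError(f"{path}:{lineno}: expected >= 3 columns, got {len(parts)}")
            try:
                chrom = parts[0]
                start = int(parts[1])
                end = int(parts[2])
            except ValueError as exc:
                raise BinmapFormatError(f"{path}:{lineno}: non-integer coordinate: {exc}") from None
            if end <= start:
                raise BinmapFormatError(f"{path}:{lineno}: end ({end}) <= start ({start})")
            gc = float("nan")
            blacklist = False
            if len(parts) >= 5 and parts[4] != ".":
                try:
                    gc = float(parts[4])
                except ValueError:
                    raise BinmapFormatError(f"{path}:{lineno}: bad gc value {parts[4]!r}") from None
            if len(parts) >= 6 and parts[5] != ".":
                blacklist = parts[5] not in ("0", "", "false", "False")
            rows.append((chrom, start, end, gc, blacklist))
    if not rows:
        raise BinmapFormatError(f"{path}: no bins found")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gc", "blacklist"])
    sorted_df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if not sorted_df[["chrom", "start"]].equals(df[["chrom", "start"]].reset_index(drop=True)):
        warnings.warn(f"{path}: bins were not sorted; sorting on load", stacklevel=2)
        df = sorted_df
    return GenomeBinMap.from_frame(df)


def write_binmap(binmap: GenomeBinMap, path) -> None:
    with open(path, "w") as fh:
        for i, (c, s, e, g, b) in enumerate(
            zip(binmap.chroms, binmap.starts, binmap.ends, binmap.gc, binmap.blacklisted)
        ):
            gc = f"{g:.4f}" if np.isfinite(g) else "."
            fh.write(f"{c}\t{s}\t{e}\tbin{i + 1}\t{gc}\t{int(b)}\n")


# ----------------------------------------------------------------------
# matrices


def write_matrix(values: np.ndarray, binmap: GenomeBinMap, cell_ids: list[str], path) -> None:
    df = pd.DataFrame(values, index=binmap.bin_keys(), columns=cell_ids)
    df.index.name = "bin"
    fmt = None if np.issubdtype(np.asarray(values).dtype, np.integer) else "%.6g"
    df.to_csv(path, sep="\t", float_format=fmt)


def read_matrix(path, binmap: GenomeBinMap, integer: bool = False) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    keys = binmap.bin_keys()
    if list(df.index) != keys:
        if set(df.index) != set(keys):
            raise ValueError(f"{path}: bins do not match the bin map")
        df = df.loc[keys]
    values = df.to_numpy()
    if integer:
        values = values.astype(np.int64)
    return values, [str(c) for c in df.columns]


def read_counts(path, binmap: GenomeBinMap) -> ReadCountMatrix:
    values, cells = read_matrix(path, binmap, integer=True)
    return ReadCountMatrix(binmap=binmap, cell_ids=cells, values=values)


def read_population(path, binmap: GenomeBinMap, sample_id: str = "sample") -> CellPopulation:
    values, cells = read_matrix(path, binmap, integer=True)
    return CellPopulation(binmap=binmap, cell_ids=cells, copies=values, sample_id=sample_id)


def write_population(population: CellPopulation, path) -> None:
    write_matrix(population.copies, population.binmap, population.cell_ids, path)


# ----------------------------------------------------------------------
# spectral counts / burden tables


def write_spectral_counts(table: SpectralCountTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_spectral_counts(path, anchor: str = "H4") -> SpectralCountTable:
    df = pd.read_csv(path)
    return SpectralCountTable(data=df, anchor=anchor)


def read_burden_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_segments_bed(population: CellPopulation, path) -> None:
    """Per-cell copy-number segments as BED (chrom, start, end, cell, copy)."""
    binmap = population.binmap
    with open(path, "w") as fh:
        for j, cell in enumerate(population.cell_ids):
            copies = population.copies[:, j]
            for _, sl in binmap.chromosome_slices():
                seg_start = sl.start
                for i in range(sl.start + 1, sl.stop + 1):
                    if i == sl.stop or copies[i] != copies[seg_start]:
                        fh.write(
                            f"{binmap.chroms[seg_start]}\t{binmap.starts[seg_start]}\t"
                            f"{binmap.ends[i - 1]}\t{cell}\t{copies[seg_start]}\n"
                        )
                        seg_start = i


# ----------------------------------------------------------------------
# configs and provenance


def load_config(path) -> dict:
    """YAML or JSON configuration file -> dict (flat key: value)."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_run_sidecar(out_path, config: dict) -> None:
    """JSON sidecar embedding the parameters that produced an artifact."""
    from . import __version__

    sidecar = {
        "version": __version__,
        "config_hash": config_hash(config),
        "config": config,
    }
    Path(str(out_path) + ".run.json").write_text(json.dumps(sidecar, indent=2, default=str))
    log.info("run: version=%s hash=%s seed=%s", __version__, sidecar["config_hash"], config.get("seed"))
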