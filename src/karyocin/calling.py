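"""Binned read counts -> curated integer copy-number profiles.

The calling strategy mirrors low-coverage scWGS practice: GC-correct the
binned counts, segment each cell's depth track with two independent
change-point detectors (a CBS-style recursive binary segmenter and an
e-divisive energy-statistic segmenter), integerize each segmentation by a
reads-per-copy scale search, and keep only cells where the two algorithms
agree on at least ``concordance_threshold`` of bins (default 90%) and the
library carries at least ``min_reads_per_bin_per_copy`` reads (default 5;
~30,000 reads for a diploid genome at 1 Mb bins).

Both detectors test each candidate split with a permutation test on the
maximal split statistic (1,000 permutations by default). Permutation is
stopped early once the exceedance count already guarantees the p-value
cannot fall below the significance level; the accept/reject decision is
identical to the full run.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .containers import CellPopulation, CopyNumberProfile, GenomeBinMap, ReadCountMatrix

__all__ = [
    "CallerParams",
    "gc_correct",
    "segment_binary",
    "segment_edivisive",
    "assign_copy_numbers",
    "concordance",
    "library_qc",
    "call_and_curate",
]

_EPS = 1e-12


@dataclass
class CallerParams:
    """Tunable knobs of the calling/curation pipeline."""

    concordance_threshold: float = 0.90  # min agreement between the two callers
    min_reads_per_bin_per_copy: float = 5.0  # library QC floor; strict less-than fails
    # per-test permutation level; calibrated so that ~22 chromosome-level
    # tests per cell keep the expected spurious-event rate near 0.05/cell
    alpha: float = 0.002
    n_permutations: int = 1000
    min_seg_len: int = 3  # bins
    max_copy: int = 8  # copy-scale search admits genome-mean copies in [0.5, max_copy]
    scale_tie_tol: float = 0.05  # copy^2; near-tied scales resolve toward euploid
    min_stratum_bins: int = 10  # GC strata smaller than this are left uncorrected
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.concordance_threshold <= 1:
            raise ValueError("concordance_threshold must be in (0, 1]")
        if self.min_reads_per_bin_per_copy <= 0:
            raise ValueError("min_reads_per_bin_per_copy must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_seg_len < 1 or self.n_permutations < 1 or self.max_copy < 1:
            raise ValueError("min_seg_len, n_permutations and max_copy must be >= 1")


# ----------------------------------------------------------------------
# GC correction


def gc_correct(
    counts: ReadCountMatrix, binmap: GenomeBinMap, params: CallerParams | None = None
) -> tuple[np.ndarray, GenomeBinMap]:
    """Median-of-stratum GC correction; drops blacklisted bins.

    Bins are stratified into GC deciles (computed over retained bins); per
    cell, counts in a stratum are rescaled by the ratio of the cell's
    global median count to the stratum median. Strata with fewer than
    ``min_stratum_bins`` bins, or with median zero, are left uncorrected.

    Returns the corrected real-valued matrix together with the retained
    (non-blacklisted) bin map.
    """
    params = params or CallerParams()
    keep = ~binmap.blacklisted
    if not keep.any():
        raise ValueError("all bins are blacklisted")
    kept_map = binmap.subset(keep)
    x = counts.values[keep].astype(float)

    gc = kept_map.gc
    edges = np.unique(np.quantile(gc, np.linspace(0, 1, 11)))
    # assign each bin to a stratum; a single unique edge means one stratum
    strata = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, max(len(edges) - 2, 0))

    corrected = x.copy()
    for j in range(x.shape[1]):
        col = x[:, j]
        global_med = np.median(col)
        if global_med <= 0:
            continue
        factors = np.ones(len(edges))
        for s in np.unique(strata):
            mask = strata == s
            if mask.sum() < params.min_stratum_bins:
                continue
            med = np.median(col[mask])
            if med > 0:
                factors[s] = global_med / med
        corrected[:, j] = col * factors[strata]
    return corrected, kept_map


# ----------------------------------------------------------------------
# split statistics (batched over rows)


@lru_cache(maxsize=64)
def _cbs_pairs(n: int, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Candidate (i, j) interior/edge segments of an n-bin window.

    A candidate segment [i, j) must be at least ``min_len`` bins, leave a
    complement of at least ``min_len`` bins, and leave no flank shorter
    than ``min_len`` (a flank of zero — an edge segment — is allowed, in
    which case the test degenerates to a plain binary split).
    """
    i_parts, j_parts = [], []
    for length in range(min_len, n - min_len + 1):
        i = np.arange(0, n - length + 1)
        j = i + length
        ok = ((i == 0) | (i >= min_len)) & ((j == n) | (n - j >= min_len))
        i_parts.append(i[ok])
        j_parts.append(j[ok])
    return np.concatenate(i_parts), np.concatenate(j_parts)


def _best_segment_cbs(xs: np.ndarray, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    """CBS statistic: max |t| of any candidate segment vs its complement.

    Testing interior segments directly (rather than only binary splits)
    is what gives CBS its sensitivity to focal events: a short interior
    copy change barely moves either half-mean of a binary split but
    stands out against its own complement. Returns per row the best
    statistic and the (i, j) bounds of the best segment.
    """
    B, n = xs.shape
    i_idx, j_idx = _cbs_pairs(n, min_len)
    length = (j_idx - i_idx).astype(float)
    comp = n - length
    dof = max(n - 2, 1)
    best = np.empty(B)
    pairs = np.empty((B, 2), np.int64)
    chunk = max(1, int(6_000_000 // max(len(i_idx), 1)))
    for r in range(0, B, chunk):
        v = xs[r : r + chunk]
        cs = np.zeros((v.shape[0], n + 1))
        np.cumsum(v, axis=1, out=cs[:, 1:])
        css = np.zeros((v.shape[0], n + 1))
        np.cumsum(v * v, axis=1, out=css[:, 1:])
        s1 = cs[:, j_idx] - cs[:, i_idx]
        q1 = css[:, j_idx] - css[:, i_idx]
        m1 = s1 / length
        m2 = (cs[:, -1:] - s1) / comp
        ss1 = np.maximum(q1 - length * m1 * m1, 0.0)
        ss2 = np.maximum(css[:, -1:] - q1 - comp * m2 * m2, 0.0)
        pooled = (ss1 + ss2) / dof
        denom = np.sqrt(pooled * (1.0 / length + 1.0 / comp))
        diff = np.abs(m1 - m2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / denom
        t = np.where(denom <= _EPS, np.where(diff > _EPS, np.inf, 0.0), t)
        a = np.argmax(t, axis=1)
        rows = np.arange(t.shape[0])
        best[r : r + chunk] = t[rows, a]
        pairs[r : r + chunk, 0] = i_idx[a]
        pairs[r : r + chunk, 1] = j_idx[a]
    return best, pairs


def _cbs_cuts(info_row: np.ndarray, n: int) -> list[int]:
    i, j = int(info_row[0]), int(info_row[1])
    return [c for c in (i, j) if 0 < c < n]


def _best_split_energy(xs: np.ndarray, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Max divisive energy statistic over splits for each row of ``xs``.

    For a split into X (n1) and Y (n2) the statistic is
    ``n1 n2/(n1+n2) * (2 E|X-Y| - E|X-X'| - E|Y-Y'|)`` with unbiased
    within-sample means. All splits of one row are evaluated at once from
    2-D prefix sums of the pairwise-distance matrix.
    """
    B, n = xs.shape
    ks = np.arange(min_len, n - min_len + 1)
    n1 = ks.astype(float)
    n2 = n - n1
    best = np.empty(B)
    arg = np.empty(B, np.int64)
    chunk = max(1, int(4_000_000 // (n * n)))
    for i in range(0, B, chunk):
        v = xs[i : i + chunk]
        D = np.abs(v[:, :, None] - v[:, None, :])
        P = D.cumsum(axis=1).cumsum(axis=2)
        s_xx = P[:, ks - 1, ks - 1]
        s_x_all = P[:, ks - 1, n - 1]
        total = P[:, n - 1, n - 1][:, None]
        s_xy = s_x_all - s_xx
        s_yy = total - s_xx - 2.0 * s_xy
        within_x = np.where(n1 > 1, s_xx / (n1 * np.maximum(n1 - 1, 1)), 0.0)
        within_y = np.where(n2 > 1, s_yy / (n2 * np.maximum(n2 - 1, 1)), 0.0)
        q = (n1 * n2 / n) * (2.0 * s_xy / (n1 * n2) - within_x - within_y)
        a = np.argmax(q, axis=1)
        rows = np.arange(q.shape[0])
        best[i : i + chunk] = q[rows, a]
        arg[i : i + chunk] = ks[a]
    return best, arg


def _energy_cuts(info_row, n: int) -> list[int]:
    return [int(info_row)]


# ----------------------------------------------------------------------
# permutation decision + recursion


def _significant(
    x: np.ndarray,
    obs: float,
    best_fn,
    params: CallerParams,
    rng: np.random.Generator,
) -> bool:
    """Permutation test on the maximal split statistic.

    Decision-equivalent to running all ``n_permutations``: the loop stops
    as soon as the exceedance count guarantees p >= alpha.
    """
    n_perm = params.n_permutations
    exceed = 0
    done = 0
    thresh = obs - abs(obs) * 1e-10 if np.isfinite(obs) else obs
    for batch in (50, 150, 300, n_perm):
        b = min(batch, n_perm - done)
        if b <= 0:
            break
        idx = np.argsort(rng.random((b, x.size)), axis=1)
        stats, _ = best_fn(x[idx], params.min_seg_len)
        exceed += int(np.sum(stats >= thresh))
        done += b
        if (1 + exceed) / (1 + n_perm) >= params.alpha:
            return False
    return (1 + exceed) / (1 + n_perm) < params.alpha


def _recursive_segment(
    x: np.ndarray, best_fn, cuts_fn, params: CallerParams, rng: np.random.Generator
) -> list[int]:
    out: list[int] = []
    stack: list[tuple[int, int]] = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo
        if n < 2 * params.min_seg_len:
            continue
        seg = x[lo:hi]
        if np.ptp(seg) <= _EPS:
            continue
        stats, info = best_fn(seg[None, :], params.min_seg_len)
        obs = float(stats[0])
        cuts = cuts_fn(info[0], n)
        if not obs > 0 or not cuts:
            continue
        if _significant(seg, obs, best_fn, params, rng):
            out.extend(lo + c for c in cuts)
            bounds = [lo] + [lo + c for c in cuts] + [hi]
            for a, b in zip(bounds[:-1], bounds[1:]):
                stack.append((a, b))
    return sorted(out)


def _segment(
    track: np.ndarray,
    params: CallerParams,
    best_fn,
    cuts_fn,
    binmap: GenomeBinMap | None,
    rng: np.random.Generator | None,
) -> list[int]:
    params.validate()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if binmap is None:
        return _recursive_segment(np.asarray(track, float), best_fn, cuts_fn, params, rng)
    cps: list[int] = []
    x = np.asarray(track, float)
    for _, sl in binmap.chromosome_slices():
        cps.extend(
            sl.start + k
            for k in _recursive_segment(x[sl], best_fn, cuts_fn, params, rng)
        )
    return sorted(cps)


def segment_binary(
    cell_track: np.ndarray,
    params: CallerParams | None = None,
    binmap: GenomeBinMap | None = None,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Recursive CBS segmentation (segment-vs-complement t statistic).

    At each step the candidate segment maximizing |t| against its
    complement is located; if its permutation p-value is below
    ``params.alpha`` its bounds become change points and the resulting
    pieces are segmented recursively. Returns strictly increasing bin
    indices; with a ``binmap``, segmentation runs within each chromosome
    and never returns a chromosome boundary itself.
    """
    return _segment(
        cell_track, params or CallerParams(), _best_segment_cbs, _cbs_cuts, binmap, rng
    )


def segment_edivisive(
    cell_track: np.ndarray,
    params: CallerParams | None = None,
    binmap: GenomeBinMap | None = None,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Hierarchical e-divisive segmentation via the energy-distance statistic.

    Same contract as :func:`segment_binary`, but strictly bisecting: each
    accepted step places the single split maximizing the two-sample energy
    distance. Distribution-free — sensitive to any change in distribution,
    not only in mean — but, being a bisection, less sensitive than CBS to
    short interior segments.
    """
    return _segment(
        cell_track, params or CallerParams(), _best_split_energy, _energy_cuts, binmap, rng
    )


# ----------------------------------------------------------------------
# integerization


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    cw = np.cumsum(weights[order])
    return float(values[order][np.searchsorted(cw, 0.5 * cw[-1])])


def assign_copy_numbers(
    cell_track: np.ndarray,
    change_points: list[int],
    widths: np.ndarray,
    params: CallerParams | None = None,
) -> tuple[np.ndarray, float]:
    """Integerize a segmented depth track by a reads-per-copy scale search.

    Candidate scales are every ``segment_mean / c`` for integer copies
    ``c = 1..max_copy``; the chosen scale minimizes the bin-width-weighted
    squared distance of segment means to their nearest non-negative
    integers, restricted to scales whose genome-wide mean copy lies in
    ``[0.5, max_copy]``. Objective ties are broken toward the scale whose
    genome-wide (width-weighted) median copy is closest to 2, then toward
    the larger scale (lower ploidy).

    ``change_points`` is the full set of segment boundaries (callers
    include chromosome starts). Returns (per-bin integer copies, scale);
    an all-zero track yields all-zero copies and scale NaN.
    """
    params = params or CallerParams()
    x = np.asarray(cell_track, float)
    w = np.asarray(widths, float)
    n = x.size
    if n == 0:
        raise ValueError("empty track")
    bounds = sorted({0, n, *change_points})
    if bounds[0] != 0 or bounds[-1] != n:
        raise ValueError("change points out of range")
    seg_slices = [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]
    seg_means = np.array([np.average(x[s], weights=w[s]) for s in seg_slices])
    seg_w = np.array([w[s].sum() for s in seg_slices])
    seg_len = np.array([s.stop - s.start for s in seg_slices])

    if np.all(seg_means <= _EPS):
        return np.zeros(n, np.int64), float("nan")

    cands = sorted(
        {m / c for m in seg_means if m > _EPS for c in range(1, params.max_copy + 1)},
        reverse=True,
    )
    total_w = seg_w.sum()
    evaluated = []  # (mean squared residual in copy units, |median-2|, -scale)
    for s in cands:
        ratio = seg_means / s
        copies = np.maximum(_round_half_up(ratio), 0.0)
        mean_copy = float((copies * seg_w).sum() / total_w)
        if not 0.5 <= mean_copy <= params.max_copy:
            continue
        obj = float((seg_w * (ratio - copies) ** 2).sum()) / total_w
        med = _weighted_median(np.repeat(copies, seg_len), np.repeat(seg_w / seg_len, seg_len))
        evaluated.append((obj, abs(med - 2.0), -s))
    if not evaluated:  # no candidate in range: fall back to the largest mean
        best_scale = float(seg_means.max())
    else:
        # scales fitting the integer grid near-equally (within scale_tie_tol
        # mean squared copy residual) are ties: a flat genome is scale-
        # ambiguous, and a segment left as a mixture by the segmenter has a
        # fractional mean whose residual shrinks at every coarser scale, so
        # small objective gaps cannot be trusted. The euploid reference
        # breaks ties toward median copy 2, then the larger scale (lower
        # ploidy).
        obj_min = min(e[0] for e in evaluated)
        ties = [e for e in evaluated if e[0] <= obj_min + params.scale_tie_tol]
        best_scale = -min((med, neg_s) for _, med, neg_s in ties)[1]
    copies = np.maximum(_round_half_up(seg_means / best_scale), 0.0).astype(np.int64)
    return np.repeat(copies, seg_len), float(best_scale)


# ----------------------------------------------------------------------
# curation


def concordance(
    profile_a: CopyNumberProfile | np.ndarray,
    profile_b: CopyNumberProfile | np.ndarray,
    binmap: GenomeBinMap | None = None,
) -> float:
    """Fraction of non-blacklisted bins with identical integer copy."""
    a = profile_a.copies if isinstance(profile_a, CopyNumberProfile) else np.asarray(profile_a)
    b = profile_b.copies if isinstance(profile_b, CopyNumberProfile) else np.asarray(profile_b)
    if a.shape != b.shape:
        raise ValueError("profiles are on different bin maps")
    keep = np.ones(a.shape, bool)
    if binmap is not None:
        if binmap.n_bins != a.size:
            raise ValueError("profiles do not match the bin map")
        keep = ~binmap.blacklisted
    if not keep.any():
        raise ValueError("no bins to compare")
    return float(np.mean(a[keep] == b[keep]))


def library_qc(conc: float, mean_reads_per_bin_per_copy: float, params: CallerParams) -> tuple[bool, bool, str]:
    """Apply the two curation filters to one library.

    Boundary semantics follow the curation rule "less than N ... discarded":
    a cell at exactly the concordance or coverage threshold passes.
    Returns (pass_concordance, pass_coverage, reason-string).
    """
    pass_conc = conc >= params.concordance_threshold
    pass_cov = mean_reads_per_bin_per_copy >= params.min_reads_per_bin_per_copy
    reasons = []
    if not pass_conc:
        reasons.append("discordant-callers")
    if not pass_cov:
        reasons.append("low-coverage")
    return pass_conc, pass_cov, ";".join(reasons)


def call_and_curate(
    counts: ReadCountMatrix,
    binmap: GenomeBinMap,
    params: CallerParams | None = None,
) -> tuple[CellPopulation | None, pd.DataFrame]:
    """Full per-cell calling with dual-algorithm concordance curation.

    Per cell: GC-correct, segment with both detectors, integerize each
    segmentation, compute bin-wise concordance, and apply the two library
    filters — concordance >= threshold and mean reads per bin per copy
    >= threshold (raw reads over retained bins divided by the sum of
    called copies). Cells failing either filter are discarded with a
    reason; survivors report the CBS-derived profile (the more sensitive
    detector for short interior segments; recorded in the QC report).

    Returns (population of passing cells or None if none pass, per-cell QC
    report).
    """
    params = params or CallerParams()
    params.validate()
    corrected, kept_map = gc_correct(counts, binmap, params)
    keep = ~binmap.blacklisted
    raw_kept = counts.values[keep].astype(float)
    widths = kept_map.widths.astype(float)
    width_factor = widths / widths.mean()
    chrom_starts = [sl.start for _, sl in kept_map.chromosome_slices()]

    master = np.random.default_rng(params.seed)
    rows = []
    passing_cols = []
    passing_ids = []
    for j, cell_id in enumerate(counts.cell_ids):
        track = corrected[:, j] / width_factor
        # segment a variance-stabilized track: count noise grows with copy
        # number, so the Anscombe square root keeps step-to-noise ratios
        # comparable across copy levels and tames high-copy outliers;
        # integerization below stays on the linear track
        stabilized = 2.0 * np.sqrt(track + 0.375)
        cell_seed = master.integers(2**31)
        cps_bin = segment_binary(stabilized, params, kept_map, np.random.default_rng(cell_seed))
        cps_edi = segment_edivisive(stabilized, params, kept_map, np.random.default_rng(cell_seed))
        prof_bin, scale_bin = assign_copy_numbers(track, sorted(set(cps_bin) | set(chrom_starts)), widths, params)
        prof_edi, scale_edi = assign_copy_numbers(track, sorted(set(cps_edi) | set(chrom_starts)), widths, params)
        conc = concordance(prof_bin, prof_edi)
        copies_total = prof_bin.sum()
        reads_total = raw_kept[:, j].sum()
        mean_rpb = reads_total / copies_total if copies_total > 0 else 0.0
        pass_conc, pass_cov, reason = library_qc(conc, mean_rpb, params)
        rows.append(
            {
                "cell_id": cell_id,
                "mean_reads_per_bin_per_copy": mean_rpb,
                "concordance": conc,
                "scale_binary": scale_bin,
                "scale_edivisive": scale_edi,
                "n_changepoints_binary": len(cps_bin),
                "n_changepoints_edivisive": len(cps_edi),
                "pass_concordance": pass_conc,
                "pass_coverage": pass_cov,
                "passed": pass_conc and pass_cov,
                "reason": reason,
                "reported_algorithm": "cbs",
            }
        )
        if pass_conc and pass_cov:
            passing_cols.append(prof_bin)
            passing_ids.append(cell_id)

    report = pd.DataFrame(rows)
    if not passing_ids:
        import warnings

        warnings.warn("no cells passed curation", stacklevel=2)
        return None, report
    population = CellPopulation(
        binmap=kept_map,
        cell_ids=passing_ids,
        copies=np.column_stack(passing_cols),
        sample_id="called",
    )
    return population, report
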