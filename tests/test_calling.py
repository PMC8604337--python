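"""GC correction, both segmenters, integerization, concordance curation."""

import numpy as np
import pytest
from scipy import stats

from conftest import build_binmap
from karyocin.calling import (
    CallerParams,
    assign_copy_numbers,
    call_and_curate,
    concordance,
    gc_correct,
    library_qc,
    segment_binary,
    segment_edivisive,
)
from karyocin.containers import CopyNumberProfile, ReadCountMatrix
from karyocin.simulate import (
    PopulationSimConfig,
    ReadSimConfig,
    default_chromosome_lengths,
    simulate_population,
    simulate_read_counts,
)


def _counts(binmap, values):
    values = np.asarray(values)
    if values.ndim == 1:
        values = values[:, None]
    return ReadCountMatrix(
        binmap=binmap, cell_ids=[f"c{j + 1}" for j in range(values.shape[1])], values=values
    )


class TestGcCorrect:
    def test_uniform_gc_is_identity(self):
        binmap = build_binmap([("chr1", [1_000_000] * 30)])  # gc all 0.45
        rng = np.random.default_rng(0)
        counts = _counts(binmap, rng.poisson(40, size=(30, 2)))
        corrected, kept = gc_correct(counts, binmap)
        assert np.array_equal(corrected, counts.values.astype(float))
        assert kept.n_bins == 30

    def test_blacklisted_bins_dropped(self):
        black = np.zeros(20, bool)
        black[[3, 7]] = True
        binmap = build_binmap([("chr1", [1_000_000] * 20)], blacklisted=black)
        counts = _counts(binmap, np.full(20, 10))
        corrected, kept = gc_correct(counts, binmap)
        assert corrected.shape[0] == 18
        assert kept.n_bins == 18

    def test_all_blacklisted_fails(self):
        binmap = build_binmap([("chr1", [1_000_000] * 5)], blacklisted=np.ones(5, bool))
        with pytest.raises(ValueError, match="blacklisted"):
            gc_correct(_counts(binmap, np.full(5, 10)), binmap)

    def test_quadratic_gc_bias_removed(self):
        # simulate flat-copy counts with strong quadratic GC bias; after
        # decile-median correction the count-vs-GC slope is insignificant
        pop = simulate_population(
            PopulationSimConfig(
                n_cells=1, chromosome_lengths=default_chromosome_lengths(total_mb=3000), seed=0
            )
        )
        counts = simulate_read_counts(
            pop, ReadSimConfig(mean_reads_per_bin_per_copy=30, gc_bias_amplitude=10.0, seed=1)
        )
        curv = (pop.binmap.gc - 0.45) ** 2  # the simulated bias is quadratic
        biased = stats.linregress(curv, counts.values[:, 0])
        corrected, kept = gc_correct(counts, pop.binmap)
        flat_quad = stats.linregress((kept.gc - 0.45) ** 2, corrected[:, 0])
        flat_lin = stats.linregress(kept.gc, corrected[:, 0])
        assert abs(biased.slope / biased.stderr) > 10  # bias is really there
        assert abs(flat_quad.slope / flat_quad.stderr) < 2
        assert abs(flat_lin.slope / flat_lin.stderr) < 2


NOISELESS_STEP = np.array([5.0] * 10 + [15.0] * 10)


@pytest.mark.parametrize("segment", [segment_binary, segment_edivisive], ids=["binary", "edivisive"])
class TestSegmenters:
    def test_constant_track_has_no_changepoints(self, segment):
        assert segment(np.full(40, 7.0)) == []

    def test_noiseless_step_found_exactly(self, segment):
        assert segment(NOISELESS_STEP) == [10]

    def test_shift_invariance(self, segment):
        rng = np.random.default_rng(5)
        track = np.concatenate([rng.normal(10, 1, 25), rng.normal(20, 1, 25)])
        assert segment(track) == segment(track + 1000.0)

    def test_seeded_reproducibility(self, segment):
        rng = np.random.default_rng(6)
        track = np.concatenate([rng.normal(10, 1, 20), rng.normal(14, 1, 20)])
        params = CallerParams(seed=3)
        assert segment(track, params) == segment(track, params)

    def test_respects_chromosome_boundaries(self, segment):
        # a copy step that coincides with the chromosome boundary is not a
        # within-chromosome change point
        binmap = build_binmap([("chr1", [1_000_000] * 10), ("chr2", [1_000_000] * 10)])
        track = np.array([10.0] * 10 + [20.0] * 10)
        assert segment(track, CallerParams(), binmap) == []

    def test_recovers_multi_step_noiseless_track(self, segment):
        track = np.array([4.0] * 8 + [8.0] * 7 + [2.0] * 9)
        assert segment(track) == [8, 15]


def test_segmenters_agree_on_noiseless_single_step():
    assert segment_binary(NOISELESS_STEP) == segment_edivisive(NOISELESS_STEP)


def test_exhaustive_split_oracle_on_noiseless_step():
    """Both detectors place the split where brute-force maximization does."""

    def sse(track, k):
        return ((track[:k] - track[:k].mean()) ** 2).sum() + (
            (track[k:] - track[k:].mean()) ** 2
        ).sum()

    best_k = min(range(3, 18), key=lambda k: sse(NOISELESS_STEP, k))
    assert best_k == 10
    assert segment_binary(NOISELESS_STEP) == [best_k]
    assert segment_edivisive(NOISELESS_STEP) == [best_k]


class TestAssignCopyNumbers:
    WIDTHS = np.full(3, 1_000_000.0)

    def test_means_10_20_30_give_copies_1_2_3(self):
        copies, scale = assign_copy_numbers(
            np.array([10.0, 20.0, 30.0]), [1, 2], self.WIDTHS
        )
        assert list(copies) == [1, 2, 3]
        assert scale == pytest.approx(10.0)

    def test_all_zero_track_gives_zero_profile(self):
        copies, scale = assign_copy_numbers(np.zeros(3), [1, 2], self.WIDTHS)
        assert list(copies) == [0, 0, 0]
        assert np.isnan(scale)

    def test_flat_track_resolves_to_euploid_two(self):
        widths = np.full(30, 1_000_000.0)
        copies, _ = assign_copy_numbers(np.full(30, 60.0), [], widths)
        assert np.all(copies == 2)

    def test_empty_track_fails(self):
        with pytest.raises(ValueError, match="empty"):
            assign_copy_numbers(np.array([]), [], np.array([]))

    def test_simulation_recovery_95_percent(self):
        pop = simulate_population(
            PopulationSimConfig(
                n_cells=6,
                chromosome_lengths=default_chromosome_lengths(total_mb=1000),
                founder_event_count=3,
                missegregation_rate=0.5,
                segmental_rate=0.5,
                seed=21,
            )
        )
        counts = simulate_read_counts(
            pop, ReadSimConfig(mean_reads_per_bin_per_copy=30, dispersion=0.05, seed=22)
        )
        called, report = call_and_curate(counts, pop.binmap, CallerParams(seed=23))
        assert report["passed"].all()
        acc = np.mean(called.copies == pop.copies)
        assert acc >= 0.95


class TestConcordance:
    def test_identical_profiles_give_one(self):
        p = CopyNumberProfile("a", np.array([2, 2, 3]))
        assert concordance(p, p) == 1.0

    def test_one_in_ten_disagreement(self):
        a = np.full(10, 2)
        b = a.copy()
        b[0] = 3
        assert concordance(a, b) == pytest.approx(0.9)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.integers(0, 4, 50), rng.integers(0, 4, 50)
        assert concordance(a, b) == concordance(b, a)

    def test_mismatched_lengths_fail(self):
        with pytest.raises(ValueError, match="different bin maps"):
            concordance(np.array([2, 2]), np.array([2, 2, 2]))


class TestCuration:
    def test_boundary_exactly_five_reads_passes(self):
        # 10 bins x 10 reads, diploid call: 100 reads / 20 copies = 5.0 exactly
        binmap = build_binmap([("chr1", [1_000_000] * 10)])
        counts = _counts(binmap, np.full(10, 10))
        pop, report = call_and_curate(counts, binmap, CallerParams())
        assert report.loc[0, "mean_reads_per_bin_per_copy"] == pytest.approx(5.0)
        assert bool(report.loc[0, "passed"])
        assert np.all(pop.copies == 2)

    def test_below_five_reads_discarded_low_coverage(self):
        # 98 reads / 20 copies = 4.9 < 5
        binmap = build_binmap([("chr1", [1_000_000] * 10)])
        counts = _counts(binmap, np.array([10] * 8 + [9] * 2))
        with pytest.warns(UserWarning, match="no cells passed"):
            pop, report = call_and_curate(counts, binmap, CallerParams())
        assert report.loc[0, "mean_reads_per_bin_per_copy"] == pytest.approx(4.9)
        assert not bool(report.loc[0, "passed"])
        assert "low-coverage" in report.loc[0, "reason"]
        assert pop is None

    @pytest.mark.parametrize(
        "conc,reads,expect_pass",
        [
            (0.90, 10.0, True),
            (0.899, 10.0, False),
            (1.0, 5.0, True),
            (1.0, 4.9, False),
        ],
    )
    def test_library_qc_boundaries(self, conc, reads, expect_pass):
        pass_c, pass_r, reason = library_qc(conc, reads, CallerParams())
        assert (pass_c and pass_r) is expect_pass

    def test_noiseless_identical_tracks_fully_concordant(self):
        binmap = build_binmap([("chr1", [1_000_000] * 12), ("chr2", [1_000_000] * 8)])
        track = np.array([20] * 12 + [30] * 8)
        counts = _counts(binmap, track)
        pop, report = call_and_curate(counts, binmap, CallerParams())
        assert report.loc[0, "concordance"] == 1.0
        assert bool(report.loc[0, "passed"])
        assert list(np.unique(pop.copies[:12])) == [2]
        assert list(np.unique(pop.copies[12:])) == [3]
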