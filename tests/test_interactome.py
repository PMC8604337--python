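"""Spectral-count pipeline: QC, averaging, subtraction, normalization, labels."""

import numpy as np
import pandas as pd
import pytest

from karyocin.containers import SpectralCountTable
from karyocin.interactome import (
    ClassificationParams,
    classify,
    condition_means,
    normalize_to_anchor,
    replicate_qc,
    run_interactome_pipeline,
    subtract_background,
)
from karyocin.simulate import SpectraSimConfig, simulate_spectral_counts


def table_from_rows(rows, anchor="H4"):
    df = pd.DataFrame(rows, columns=["protein", "condition", "replicate", "spec_count"])
    return SpectralCountTable(data=df, anchor=anchor)


class TestReplicateQc:
    def test_bait_replicate_kept_only_if_anchor_above_ev_mean(self):
        rows = [
            ("H4", "EV", 1, 2), ("H4", "EV", 2, 2),
            ("H4", "WT", 1, 10), ("H4", "WT", 2, 1),
            ("H4", "K27M", 1, 8), ("H4", "K27M", 2, 9),
            ("P1", "WT", 1, 5), ("P1", "WT", 2, 5),
        ]
        kept = replicate_qc(table_from_rows(rows))
        wt_reps = set(kept.data.loc[kept.data["condition"] == "WT", "replicate"])
        assert wt_reps == {1}  # replicate 2 anchor (1) not above EV mean (2)
        ev_reps = set(kept.data.loc[kept.data["condition"] == "EV", "replicate"])
        assert ev_reps == {1, 2}  # EV always retained

    def test_all_anchors_equal_background_raises(self):
        rows = [(p, c, r, 10) for p in ("H4",) for c in ("EV", "WT", "K27M") for r in (1, 2)]
        with pytest.raises(ValueError, match="above the EV background"):
            replicate_qc(table_from_rows(rows))

    def test_missing_ev_anchor_raises(self):
        rows = [("H4", "WT", 1, 5), ("P1", "EV", 1, 3)]
        with pytest.raises(ValueError, match="absent from every EV replicate"):
            replicate_qc(table_from_rows(rows))


class TestConditionMeans:
    def test_plain_average(self):
        rows = [("P1", "WT", r, 4) for r in (1, 2, 3, 4)] + [("H4", "EV", 1, 1)]
        means = condition_means(table_from_rows(rows))
        assert means.loc["P1", "WT"] == pytest.approx(4.0)

    def test_zero_fill_for_missing_replicates(self):
        # protein seen in 2 of 4 replicates at 6 -> mean 3
        rows = [("H4", "WT", r, 10) for r in (1, 2, 3, 4)]
        rows += [("P1", "WT", 1, 6), ("P1", "WT", 2, 6)]
        means = condition_means(table_from_rows(rows))
        assert means.loc["P1", "WT"] == pytest.approx(3.0)

    def test_single_replicate_mean_is_value(self):
        means = condition_means(table_from_rows([("P1", "K27M", 1, 7)]))
        assert means.loc["P1", "K27M"] == pytest.approx(7.0)


class TestSubtractBackground:
    def test_zero_ev_is_identity(self):
        means = pd.DataFrame({"EV": [0.0], "WT": [5.0], "K27M": [3.0]}, index=["P1"])
        out = subtract_background(means)
        assert out.loc["P1", "WT"] == 5.0
        assert out.loc["P1", "K27M"] == 3.0

    def test_clamped_at_zero(self):
        means = pd.DataFrame({"EV": [3.0], "WT": [2.0], "K27M": [0.0]}, index=["P1"])
        out = subtract_background(means)
        assert out.loc["P1", "WT"] == 0.0
        assert bool(out.loc["P1", "background_only"])

    def test_direct_arithmetic(self):
        means = pd.DataFrame({"EV": [1.0], "WT": [5.0], "K27M": [1.0]}, index=["P1"])
        out = subtract_background(means)
        assert out.loc["P1", "WT"] == 4.0
        assert out.loc["P1", "K27M"] == 0.0


class TestNormalizeToAnchor:
    def _table(self, wt_anchor, k27m_anchor):
        rows = [("H4", "EV", 1, 1.0), ("H4", "WT", 1, wt_anchor), ("H4", "K27M", 1, k27m_anchor)]
        rows += [("P1", "K27M", 1, 5.0)]
        return table_from_rows(rows)

    def test_wt_factor_is_one_and_k27m_rescaled(self):
        table = self._table(40.0, 20.0)
        corrected = pd.DataFrame({"WT": [7.0], "K27M": [5.0]}, index=["P1"])
        out = normalize_to_anchor(corrected, table)
        assert out.loc["P1", "WT"] == pytest.approx(7.0)  # factor exactly 1
        assert out.loc["P1", "K27M"] == pytest.approx(10.0)  # x 40/20

    def test_zero_anchor_raises(self):
        table = self._table(40.0, 0.0)
        corrected = pd.DataFrame({"WT": [1.0], "K27M": [1.0]}, index=["P1"])
        with pytest.raises(ValueError, match="anchor mean is zero"):
            normalize_to_anchor(corrected, table)


class TestClassify:
    @pytest.mark.parametrize(
        "wt,k27m,label",
        [
            (5.0, 5.0, "common-not-enriched"),
            (10.0, 3.0, "WT-enriched"),
            (4.0, 6.0, "common-not-enriched"),  # |diff| = 2 is the boundary
            (0.0, 4.0, "K27M-unique"),
            (4.0, 0.0, "WT-unique"),
            (10.0, 3.1, "WT-enriched"),
            (3.0, 10.0, "K27M-enriched"),
        ],
    )
    def test_label_rules(self, wt, k27m, label):
        normalized = pd.DataFrame({"WT": [wt], "K27M": [k27m]}, index=["P1"])
        result = classify(normalized, ClassificationParams(presence_floor=0.0))
        assert result.labels["P1"] == label

    def test_venn_identity(self):
        rng = np.random.default_rng(0)
        normalized = pd.DataFrame(
            {"WT": rng.integers(0, 12, 50).astype(float), "K27M": rng.integers(0, 12, 50).astype(float)},
            index=[f"P{i}" for i in range(50)],
        )
        venn = classify(normalized).venn()
        assert venn["common_total"] == (
            venn["common_not_enriched"] + venn["enriched_WT"] + venn["enriched_K27M"]
        )
        total = sum(
            venn[k]
            for k in ("unique_WT", "unique_K27M", "common_not_enriched", "enriched_WT", "enriched_K27M", "background_only")
        )
        assert total == 50  # labels partition the protein set


class TestPipeline:
    def test_equal_conditions_yield_no_unique_or_enriched(self):
        rng = np.random.default_rng(3)
        rows = [("H4", c, r, 20) for c in ("EV", "WT", "K27M") for r in (1, 2)]
        # identical counts in every condition
        for i in range(10):
            v = int(rng.integers(1, 15))
            rows += [(f"P{i}", c, r, v) for c in ("EV", "WT", "K27M") for r in (1, 2)]
        with pytest.raises(ValueError):
            # all anchors equal: replicate QC rightfully refuses
            run_interactome_pipeline(table_from_rows(rows))
        rows = [r for r in rows if r[0] != "H4"]
        rows += [("H4", "EV", 1, 5), ("H4", "EV", 2, 5), ("H4", "WT", 1, 20), ("H4", "WT", 2, 20),
                 ("H4", "K27M", 1, 20), ("H4", "K27M", 2, 20)]
        result = run_interactome_pipeline(table_from_rows(rows))
        venn = result.venn()
        assert venn["unique_WT"] == venn["unique_K27M"] == 0
        assert venn["enriched_WT"] == venn["enriched_K27M"] == 0

    def test_swapping_bait_labels_swaps_unique_and_enriched(self):
        table = simulate_spectral_counts(SpectraSimConfig(seed=42))
        # anchor-normalize to the WT reference is swap-symmetric only when
        # both bait anchors agree, so pin them to their common expectation
        anchors = (table.data["protein"] == table.anchor) & table.data["condition"].isin(["WT", "K27M"])
        table.data.loc[anchors, "spec_count"] = 40
        swapped_df = table.data.copy()
        swapped_df["condition"] = swapped_df["condition"].map(
            {"EV": "EV", "WT": "K27M", "K27M": "WT"}
        )
        swapped = SpectralCountTable(data=swapped_df, anchor=table.anchor)
        v1 = run_interactome_pipeline(table).venn()
        v2 = run_interactome_pipeline(swapped).venn()
        assert v1["unique_WT"] == v2["unique_K27M"]
        assert v1["unique_K27M"] == v2["unique_WT"]
        assert v1["enriched_WT"] == v2["enriched_K27M"]
        assert v1["common_not_enriched"] == v2["common_not_enriched"]

    def test_global_scaling_of_one_condition_cancels(self):
        # doubling all K27M counts including the anchor leaves normalized
        # K27M means unchanged (anchor normalization cancels global scale)
        table = simulate_spectral_counts(SpectraSimConfig(seed=7))
        doubled_df = table.data.copy()
        k27m = doubled_df["condition"] == "K27M"
        doubled_df.loc[k27m, "spec_count"] *= 2
        doubled = SpectralCountTable(data=doubled_df, anchor=table.anchor)

        def normalized_k27m(t):
            kept = replicate_qc(t)
            corrected = subtract_background(condition_means(kept))
            return normalize_to_anchor(corrected, kept)["K27M"]

        a, b = normalized_k27m(table), normalized_k27m(doubled)
        # subtraction uses unscaled EV, so allow the EV-sized wiggle
        assert float((b - a).abs().max()) <= condition_means(table)["EV"].max() + 1e-9

    def test_designed_classes_recovered(self):
        table = simulate_spectral_counts(SpectraSimConfig(seed=11))
        labels = run_interactome_pipeline(table).labels
        expect = {
            "background": {"background-only"},
            "wt_specific": {"WT-unique"},
            "k27m_specific": {"K27M-unique"},
            "shared": {"common-not-enriched", "WT-enriched", "K27M-enriched"},
        }
        hits = total = 0
        for protein, truth in table.truth_labels.items():
            if truth == "anchor":
                continue
            total += 1
            hits += labels.get(protein, "background-only") in expect[truth]
        assert hits / total >= 0.95
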