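"""Label-free spectral-count interactor classification.

Pipeline for a three-condition FLAG-IP experiment (empty-vector control
EV, wild-type bait WT, mutant bait K27M), quantified by spectral counts:

1. :func:`replicate_qc` — keep bait replicates whose histone-H4 anchor
   count exceeds the EV background (pull-down yield QC).
2. :func:`condition_means` — average counts per protein per condition,
   zero-filling replicates where a protein was not identified.
3. :func:`subtract_background` — subtract the EV mean per protein,
   clamping at zero; proteins with nothing left are background-only.
4. :func:`normalize_to_anchor` — rescale each condition by its H4 anchor
   so nucleosome pull-down yield cancels (WT is the reference, factor 1).
5. :func:`classify` — partition proteins into unique, common-not-enriched
   (|WT - K27M| within ``enrichment_delta``) and enriched interactors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CONDITIONS, SpectralCountTable

__all__ = [
    "ClassificationParams",
    "InteractorClassification",
    "replicate_qc",
    "condition_means",
    "subtract_background",
    "normalize_to_anchor",
    "classify",
    "run_interactome_pipeline",
    "LABELS",
]

LABELS = (
    "WT-unique",
    "K27M-unique",
    "common-not-enriched",
    "WT-enriched",
    "K27M-enriched",
    "background-only",
)


@dataclass
class ClassificationParams:
    """Thresholds of the interactor classifier.

    ``enrichment_delta``: common proteins whose normalized WT/K27M means
    differ by more than this many spectral counts are called enriched.
    ``presence_floor``: a protein is "present" in a condition only if its
    post-subtraction normalized mean exceeds this; counts at or below it
    are indistinguishable from residual background. ``strict_qc`` controls
    whether replicate QC requires the anchor strictly above the EV mean.
    ``classify_on_normalized`` applies the delta rule to anchor-normalized
    means (the default) rather than raw background-subtracted means.
    """

    enrichment_delta: float = 2.0
    presence_floor: float = 2.0
    strict_qc: bool = True
    classify_on_normalized: bool = True

    def validate(self) -> None:
        if self.enrichment_delta < 0 or self.presence_floor < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class InteractorClassification:
    """Per-protein labels plus the Venn summary of the interactome."""

    table: pd.DataFrame  # protein, wt_mean, k27m_mean, label
    params: ClassificationParams

    @property
    def labels(self) -> pd.Series:
        return self.table.set_index("protein")["label"]

    def venn(self) -> dict[str, int]:
        c = self.table["label"].value_counts()
        out = {
            "unique_WT": int(c.get("WT-unique", 0)),
            "unique_K27M": int(c.get("K27M-unique", 0)),
            "common_not_enriched": int(c.get("common-not-enriched", 0)),
            "enriched_WT": int(c.get("WT-enriched", 0)),
            "enriched_K27M": int(c.get("K27M-enriched", 0)),
            "background_only": int(c.get("background-only", 0)),
        }
        out["common_total"] = (
            out["common_not_enriched"] + out["enriched_WT"] + out["enriched_K27M"]
        )
        return out


# ----------------------------------------------------------------------


def _anchor_counts(df: pd.DataFrame, anchor: str, condition: str) -> pd.Series:
    """Anchor count per retained replicate of one condition (0 if absent)."""
    reps = df.loc[df["condition"] == condition, "replicate"].unique()
    sub = df[(df["condition"] == condition) & (df["protein"] == anchor)]
    per_rep = sub.set_index("replicate")["spec_count"]
    return pd.Series([per_rep.get(r, 0.0) for r in reps], index=reps, dtype=float)


def replicate_qc(table: SpectralCountTable, params: ClassificationParams | None = None) -> SpectralCountTable:
    """Keep bait replicates whose anchor count is above the EV background.

    The background is the average EV anchor count; EV replicates are
    always retained. Fails if either bait condition loses all replicates.
    """
    params = params or ClassificationParams()
    df = table.data
    ev_anchor = _anchor_counts(df, table.anchor, "EV")
    if ev_anchor.empty or ev_anchor.max() <= 0:
        raise ValueError(f"anchor {table.anchor!r} absent from every EV replicate")
    background = float(ev_anchor.mean())

    keep = df["condition"] == "EV"
    for cond in ("WT", "K27M"):
        anchors = _anchor_counts(df, table.anchor, cond)
        if params.strict_qc:
            good = anchors.index[anchors > background]
        else:
            good = anchors.index[anchors >= background]
        if len(good) == 0:
            raise ValueError(
                f"no {cond} replicate has anchor {table.anchor!r} above the EV "
                f"background ({background:g})"
            )
        keep |= (df["condition"] == cond) & df["replicate"].isin(good)
    return SpectralCountTable(
        data=df[keep].reset_index(drop=True),
        anchor=table.anchor,
        truth_labels=table.truth_labels,
    )


def condition_means(table: SpectralCountTable) -> pd.DataFrame:
    """Mean spectral count per (protein, condition) over retained replicates.

    A protein absent from a replicate counts as zero in that replicate, so
    the mean divides by the number of retained replicates, not the number
    of observations.
    """
    df = table.data
    n_reps = df.groupby("condition")["replicate"].nunique()
    sums = df.groupby(["protein", "condition"])["spec_count"].sum().unstack(fill_value=0.0)
    for cond in CONDITIONS:
        if cond not in sums.columns:
            sums[cond] = 0.0
    means = sums[list(CONDITIONS)].div(n_reps.reindex(list(CONDITIONS)).fillna(1), axis=1)
    means.columns.name = None
    return means


def subtract_background(means: pd.DataFrame) -> pd.DataFrame:
    """EV-subtracted WT/K27M means, clamped at zero.

    Returns columns WT, K27M plus a boolean ``background_only`` marking
    proteins with nothing above background in either bait.
    """
    if "EV" not in means.columns:
        raise ValueError("EV condition means are required for background subtraction")
    out = pd.DataFrame(index=means.index)
    out["WT"] = np.maximum(means["WT"] - means["EV"], 0.0)
    out["K27M"] = np.maximum(means["K27M"] - means["EV"], 0.0)
    out["background_only"] = (out["WT"] == 0.0) & (out["K27M"] == 0.0)
    return out


def normalize_to_anchor(corrected: pd.DataFrame, table: SpectralCountTable) -> pd.DataFrame:
    """Rescale each bait condition by its anchor mean, WT as reference.

    Condition c is multiplied by ``anchor_mean(WT) / anchor_mean(c)``; the
    WT factor is exactly 1. Raises if an anchor mean is zero.
    """
    means = condition_means(table)
    if table.anchor not in means.index:
        raise ValueError(f"anchor {table.anchor!r} absent from the table")
    anchors = means.loc[table.anchor]
    out = corrected.copy()
    for cond in ("WT", "K27M"):
        if anchors[cond] <= 0:
            raise ValueError(f"anchor mean is zero in condition {cond}")
        out[cond] = corrected[cond] * (anchors["WT"] / anchors[cond])
    return out


def classify(
    normalized: pd.DataFrame, params: ClassificationParams | None = None
) -> InteractorClassification:
    """Partition proteins into unique / common / enriched / background-only.

    A protein present (above ``presence_floor``) in exactly one bait is
    unique to it. Present in both: the difference of means within
    ``enrichment_delta`` is common-not-enriched, otherwise enriched for
    the larger side.
    """
    params = params or ClassificationParams()
    params.validate()
    wt = normalized["WT"].to_numpy(float)
    km = normalized["K27M"].to_numpy(float)
    bg = (
        normalized["background_only"].to_numpy(bool)
        if "background_only" in normalized
        else (wt == 0) & (km == 0)
    )
    wt_present = wt > params.presence_floor
    km_present = km > params.presence_floor

    labels = np.empty(len(normalized), object)
    labels[:] = "background-only"
    only_wt = ~bg & wt_present & ~km_present
    only_km = ~bg & km_present & ~wt_present
    both = ~bg & wt_present & km_present
    neither = ~bg & ~wt_present & ~km_present
    labels[only_wt] = "WT-unique"
    labels[only_km] = "K27M-unique"
    diff = wt - km
    labels[both & (np.abs(diff) <= params.enrichment_delta)] = "common-not-enriched"
    labels[both & (diff > params.enrichment_delta)] = "WT-enriched"
    labels[both & (-diff > params.enrichment_delta)] = "K27M-enriched"
    # detectable signal but below the presence floor in both baits: background
    labels[neither] = "background-only"

    out = pd.DataFrame(
        {
            "protein": normalized.index,
            "wt_mean": wt,
            "k27m_mean": km,
            "label": labels,
        }
    ).reset_index(drop=True)
    return InteractorClassification(table=out, params=params)


def run_interactome_pipeline(
    table: SpectralCountTable, params: ClassificationParams | None = None
) -> InteractorClassification:
    """QC -> average -> subtract background -> normalize -> classify."""
    params = params or ClassificationParams()
    kept = replicate_qc(table, params)
    means = condition_means(kept)
    corrected = subtract_background(means)
    if params.classify_on_normalized:
        scaled = normalize_to_anchor(corrected, kept)
        scaled["background_only"] = corrected["background_only"]
    else:
        scaled = corrected
    # the anchor itself is the yardstick, not an interactor to classify
    scaled = scaled.drop(index=table.anchor, errors="ignore")
    return classify(scaled, params)
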