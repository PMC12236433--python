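"""Depth-resolved community profiles and between-eddy enrichment tests.

Counts become within-sample relative abundances, samples are restricted to
a depth window defined relative to each eddy's DCM (default: at or above
the DCM, inclusive), and a feature's relative abundances are compared
between the two eddy types with a Kruskal-Wallis rank test.  Direction is
the sign of the median difference (group a minus group b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import TestResult, kruskal_wallis
from .tables import AbundanceTable, SampleMetadata, ValidationError

__all__ = [
    "WindowSpec",
    "to_relative_abundance",
    "select_window",
    "enrichment_test",
    "depth_profiles",
    "ProfileEnrichmentModel",
    "ProfileEnrichmentResults",
]


@dataclass(frozen=True)
class WindowSpec:
    """Depth window relative to the DCM (negative offsets are shallower)."""

    mode: str = "at_or_above_dcm"
    min_offset_m: float = float("-inf")
    max_offset_m: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("at_or_above_dcm", "custom"):
            raise ValidationError(f"unknown window mode {self.mode!r}")
        if self.min_offset_m > self.max_offset_m:
            raise ValidationError(
                f"min_offset_m ({self.min_offset_m}) exceeds max_offset_m ({self.max_offset_m})"
            )


def to_relative_abundance(counts: AbundanceTable) -> AbundanceTable:
    """Per-sample relative abundances: each column divided by its total."""
    totals = counts.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(f"sample {zero.index[0]!r} has zero total abundance")
    rel = counts.values / totals
    return AbundanceTable(rel, counts.kind, counts.annotations)


def select_window(meta: SampleMetadata, window: WindowSpec) -> list[str]:
    """Samples whose depth lies inside the DCM-relative window.

    ``at_or_above_dcm`` keeps depth <= DCM; ``custom`` keeps
    DCM + min_offset <= depth <= DCM + max_offset.  Order follows the
    metadata set.
    """
    f = meta.frame
    kept: list[str] = []
    for s in meta.sample_ids:
        depth, dcm = f.at[s, "depth_m"], f.at[s, "dcm_depth_m"]
        if not (np.isfinite(depth) and np.isfinite(dcm)):
            raise ValidationError(f"sample {s!r} lacks depth or DCM depth for windowing")
        if window.mode == "at_or_above_dcm":
            if depth <= dcm:
                kept.append(s)
        else:
            if dcm + window.min_offset_m <= depth <= dcm + window.max_offset_m:
                kept.append(s)
    if not kept:
        raise ValidationError("depth window retained no samples")
    return kept


def enrichment_test(
    rel: AbundanceTable,
    meta: SampleMetadata,
    feature: str,
    window: WindowSpec = WindowSpec(),
    group_a: str = "cyclone",
    group_b: str = "anticyclone",
    exact: bool = False,
) -> tuple[TestResult, int]:
    """Kruskal-Wallis comparison of one feature's relative abundance
    between two eddy groups inside the depth window.

    Returns (TestResult, direction) with direction = sign(median_a -
    median_b).
    """
    row = rel.row(feature)
    in_window = select_window(meta.subset(rel.samples), window)
    a_ids = meta.samples_in_eddy(group_a, in_window)
    b_ids = meta.samples_in_eddy(group_b, in_window)
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValidationError(
            f"need >= 2 windowed samples per group, got {len(a_ids)} {group_a} / "
            f"{len(b_ids)} {group_b}"
        )
    a = row[a_ids].to_numpy(dtype=float)
    b = row[b_ids].to_numpy(dtype=float)
    result = kruskal_wallis([a, b], exact=exact)
    direction = int(np.sign(np.median(a) - np.median(b)))
    return result, direction


def depth_profiles(rel: AbundanceTable, meta: SampleMetadata) -> pd.DataFrame:
    """Long-format depth profiles: (feature_id, eddy, depth_m,
    dcm_offset_m, relative_abundance), ordered by feature then depth."""
    f = meta.frame
    rows = []
    for feat in rel.features:
        series = rel.row(feat)
        for s in rel.samples:
            depth, dcm = f.at[s, "depth_m"], f.at[s, "dcm_depth_m"]
            rows.append(
                dict(
                    feature_id=feat,
                    eddy=f.at[s, "eddy"],
                    depth_m=depth,
                    dcm_offset_m=depth - dcm,
                    relative_abundance=series[s],
                )
            )
    return pd.DataFrame(rows).sort_values(
        ["feature_id", "eddy", "depth_m"], kind="stable"
    ).reset_index(drop=True)


class ProfileEnrichmentModel:
    """Between-eddy enrichment of one feature's depth profile.

    Built from a raw count (or RPB) table and sample metadata; ``fit``
    converts to relative abundance, applies the depth window, and runs the
    rank test for the named feature.
    """

    def __init__(
        self,
        counts: AbundanceTable,
        meta: SampleMetadata,
        feature: str,
        window: WindowSpec = WindowSpec(),
        groups: tuple[str, str] = ("cyclone", "anticyclone"),
    ) -> None:
        if feature not in counts.features:
            raise ValidationError(f"feature {feature!r} not in table")
        self.counts = counts
        self.meta = meta
        self.feature = feature
        self.window = window
        self.groups = groups
        self.relative = to_relative_abundance(counts)

    def fit(self, exact: bool = False) -> "ProfileEnrichmentResults":
        test, direction = enrichment_test(
            self.relative, self.meta, self.feature, self.window, *self.groups, exact=exact
        )
        return ProfileEnrichmentResults(self, test, direction)


class ProfileEnrichmentResults:
    def __init__(self, model: ProfileEnrichmentModel, test: TestResult, direction: int):
        self.model = model
        self.test = test
        self.direction = direction

    @property
    def statistic(self) -> float:
        return self.test.statistic

    @property
    def p_value(self) -> float:
        return self.test.p_value

    def profiles(self) -> pd.DataFrame:
        return depth_profiles(self.model.relative, self.model.meta.subset(self.model.relative.samples))

    def summary(self) -> str:
        a, b = self.model.groups
        arrow = {1: f"enriched in {a}", -1: f"enriched in {b}", 0: "no median difference"}
        return "\n".join(
            [
                "Depth-profile enrichment (Kruskal-Wallis rank test)",
                "===================================================",
                f"feature: {self.model.feature}   window: {self.model.window.mode}",
                f"groups: {a} vs {b}",
                f"H = {self.test.statistic:.4f}   p = {self.test.p_value:.4g}   "
                f"df = {self.test.df_or_n}",
                f"direction: {arrow[self.direction]}",
            ]
        )
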