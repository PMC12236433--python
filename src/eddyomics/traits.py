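"""KO-level functional trait enrichment against ecotype marker abundance.

Metagenomic gene abundances (reads per billion, RPB) aggregated by KEGG
Orthology are screened for association with a target ecotype's marker
abundance across the pooled depth surveys of both eddies, and for
between-eddy enrichment via the difference/total ratio

    D = (C - A) / (C + A)

where C and A sum the KO's RPB over cyclone and anticyclone samples inside
the depth window (default: at or above each eddy's DCM).  A KO passes the
screen when r_target > r_min, its correlation p-value < p_corr_max and
D > diff_total_min (defaults 0.5 / 0.01 / 0.5).  A log2 ratio with a unit
pseudocount accompanies D for reporting; D alone drives the pass flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .profiles import WindowSpec, select_window
from .stats import pearson
from .tables import AbundanceTable, SampleMetadata, ValidationError

__all__ = [
    "EnrichmentRecord",
    "aggregate_by_ko",
    "ecotype_mean_vector",
    "correlate_with_ecotype",
    "difference_total_ratio",
    "TraitEnrichmentModel",
    "TraitEnrichmentResults",
]

LOG_RATIO_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-KO screen outcome (NaN statistics mark constant/degenerate rows)."""

    ko_id: str
    r_target: float
    p_target: float
    r_other: float
    p_other: float
    diff_total: float
    log_ratio: float
    sum_cyclone_rpb: float
    sum_anticyclone_rpb: float
    passes: bool


def aggregate_by_ko(gene_table: AbundanceTable, ko_map: pd.Series | dict) -> tuple[AbundanceTable, int]:
    """Sum member-gene RPB per KO; genes without a KO are dropped.

    Returns the KO table and the number of dropped (unannotated) genes.
    KO order follows first appearance among the table's features.
    """
    ko_map = pd.Series(ko_map).astype(str)
    order: list[str] = []
    groups: dict[str, list[str]] = {}
    dropped = 0
    for g in gene_table.features:
        ko = ko_map.get(g, "")
        if not ko:
            dropped += 1
            continue
        if ko not in groups:
            groups[ko] = []
            order.append(ko)
        groups[ko].append(g)
    if not order:
        raise ValidationError("no gene carries a KO annotation")
    rows = {ko: gene_table.values.loc[groups[ko]].sum(axis=0) for ko in order}
    values = pd.DataFrame(rows).T.loc[order]
    return AbundanceTable(values, "ko_rpb"), dropped


def ecotype_mean_vector(ecotype_table: AbundanceTable, ecotype: str) -> pd.Series:
    """Per-sample mean RPB over an ecotype's reference sequences.

    If the table's features are ecotype names themselves the matching row
    is returned; otherwise rows are selected by their ecotype annotation
    and averaged per sample.
    """
    if ecotype in ecotype_table.features:
        return ecotype_table.row(ecotype).astype(float)
    if ecotype_table.annotations is None:
        raise ValidationError(f"ecotype {ecotype!r} not found and table has no annotations")
    members = ecotype_table.annotations.index[ecotype_table.annotations["ecotype"] == ecotype]
    if len(members) == 0:
        raise ValidationError(f"no reference sequence annotated as ecotype {ecotype!r}")
    return ecotype_table.values.loc[members].mean(axis=0)


def correlate_with_ecotype(ko_table: AbundanceTable, ecotype_vector: pd.Series) -> pd.DataFrame:
    """Pearson r and p of every KO row against the ecotype marker vector.

    Constant KO rows get NaN r/p (flagged degenerate, excluded from any
    pass decision).  Samples are aligned by id; >= 3 shared samples
    required.
    """
    shared = [s for s in ko_table.samples if s in ecotype_vector.index]
    if len(shared) < 3:
        raise ValidationError(f"need >= 3 shared samples, got {len(shared)}")
    y = ecotype_vector[shared].to_numpy(dtype=float)
    out = []
    for ko in ko_table.features:
        x = ko_table.row(ko)[shared].to_numpy(dtype=float)
        if np.all(x == x[0]):
            out.append((np.nan, np.nan))
            continue
        res = pearson(x, y)
        out.append((res.statistic, res.p_value))
    return pd.DataFrame(out, index=ko_table.features, columns=["r", "p"])


def difference_total_ratio(
    row: pd.Series,
    meta: SampleMetadata,
    window: WindowSpec = WindowSpec(),
) -> tuple[float, float]:
    """Difference/total ratio D = (C - A)/(C + A) and log2 ratio.

    C and A sum the row over cyclone / anticyclone samples inside the
    depth window (same window for both eddies).  D is NaN when C + A = 0.
    The log2 ratio carries a pseudocount of 1 in both numerator and
    denominator.
    """
    in_window = select_window(meta.subset(list(row.index)), window)
    cyc = meta.samples_in_eddy("cyclone", in_window)
    ant = meta.samples_in_eddy("anticyclone", in_window)
    if not cyc or not ant:
        raise ValidationError("both eddy groups must be nonempty inside the window")
    c = float(row[cyc].sum())
    a = float(row[ant].sum())
    eps = LOG_RATIO_PSEUDOCOUNT
    log_ratio = float(np.log2((c + eps) / (a + eps)))
    if c + a == 0:
        return float("nan"), log_ratio
    return (c - a) / (c + a), log_ratio


class TraitEnrichmentModel:
    """Screen of KO abundances against a target ecotype's distribution.

    Parameters
    ----------
    ko_table
        KO x sample RPB table over the pooled depth surveys of both eddies.
    ecotype_table
        Marker RPB table from which target/comparison ecotype vectors are
        taken (per-sample means over each ecotype's reference sequences).
    meta
        Sample metadata (depths and DCM depths drive the window).
    target, other
        Ecotype whose niche the screen targets and the comparison ecotype
        reported alongside (defaults HLI vs HLII).
    """

    def __init__(
        self,
        ko_table: AbundanceTable,
        ecotype_table: AbundanceTable,
        meta: SampleMetadata,
        target: str = "HLI",
        other: str = "HLII",
        window: WindowSpec = WindowSpec(),
        config: RunConfig | None = None,
    ) -> None:
        self.ko_table = ko_table
        self.meta = meta
        self.window = window
        self.config = config or RunConfig()
        self.target = target
        self.other = other
        self.target_vector = ecotype_mean_vector(ecotype_table, target)
        self.other_vector = ecotype_mean_vector(ecotype_table, other)

    def fit(self) -> "TraitEnrichmentResults":
        thr = self.config.thresholds
        cor_t = correlate_with_ecotype(self.ko_table, self.target_vector)
        cor_o = correlate_with_ecotype(self.ko_table, self.other_vector)
        records = []
        for ko in self.ko_table.features:
            row = self.ko_table.row(ko)
            d, log_ratio = difference_total_ratio(row, self.meta, self.window)
            in_window = select_window(self.meta.subset(list(row.index)), self.window)
            c = float(row[self.meta.samples_in_eddy("cyclone", in_window)].sum())
            a = float(row[self.meta.samples_in_eddy("anticyclone", in_window)].sum())
            r_t, p_t = cor_t.at[ko, "r"], cor_t.at[ko, "p"]
            passes = bool(
                np.isfinite(r_t)
                and np.isfinite(d)
                and r_t > thr.r_min
                and d > thr.diff_total_min
                and p_t < thr.p_corr_max
            )
            records.append(
                EnrichmentRecord(
                    ko_id=ko,
                    r_target=float(r_t),
                    p_target=float(p_t),
                    r_other=float(cor_o.at[ko, "r"]),
                    p_other=float(cor_o.at[ko, "p"]),
                    diff_total=float(d),
                    log_ratio=float(log_ratio),
                    sum_cyclone_rpb=c,
                    sum_anticyclone_rpb=a,
                    passes=passes,
                )
            )
        # report sorted by total windowed RPB, descending, stable
        records.sort(key=lambda r: -(r.sum_cyclone_rpb + r.sum_anticyclone_rpb))
        return TraitEnrichmentResults(self, records)


class TraitEnrichmentResults:
    def __init__(self, model: TraitEnrichmentModel, records: list[EnrichmentRecord]):
        self.model = model
        self.records = records

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records]).set_index("ko_id")

    @property
    def passing(self) -> list[EnrichmentRecord]:
        return [r for r in self.records if r.passes]

    def top(self, k: int = 20) -> list[EnrichmentRecord]:
        """Top-k passing KOs by total relative abundance (records are
        already sorted by descending summed RPB)."""
        return self.passing[:k]

    def summary(self) -> str:
        thr = self.model.config.thresholds
        n_pass = len(self.passing)
        lines = [
            "KO trait-enrichment screen",
            "==========================",
            f"target ecotype: {self.model.target}   comparison: {self.model.other}",
            f"KOs screened: {len(self.records)}   passing: {n_pass}",
            f"criteria: r > {thr.r_min}, p < {thr.p_corr_max}, "
            f"difference/total > {thr.diff_total_min}",
        ]
        for r in self.top(10):
            lines.append(
                f"  {r.ko_id}: r={r.r_target:.3f} p={r.p_target:.2e} "
                f"D={r.diff_total:.3f} RPB(C/A)={r.sum_cyclone_rpb:.0f}/{r.sum_anticyclone_rpb:.0f}"
            )
        return "\n".join(lines)
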