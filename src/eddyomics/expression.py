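"""Within-taxon differential expression and functional category summaries.

To compare gene regulation rather than cell abundance, each transcript's
per-ml value is first normalized to its taxon's total expression in that
sample (a within-taxon fraction).  Per transcript, a two-group negative-
binomial Wald test contrasts the eddies on pseudo-counts (fraction x 1e6,
rounded; unit size factors, the normalization being already applied), and
Benjamini-Hochberg runs once over all transcripts of all tested taxa.  A
transcript takes a side when q < q_max and |log2FC| > log2fc_flag
(defaults 0.05 and 2; positive log2FC = anticyclone).

Significant transcripts are then summarized by COG functional category or
KEGG pathway with two retention rules: transcripts whose eggNOG annotation
has significant members on *both* sides are dropped as ambiguous, and in
pathway mode only categories keeping more than two transcripts survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .stats import benjamini_hochberg, nb_wald_matrix
from .tables import (
    AbsoluteAbundanceTable,
    AbundanceTable,
    SampleMetadata,
    ValidationError,
)

__all__ = [
    "ExpressionRecord",
    "CategorySummary",
    "within_taxon_normalize",
    "summarize_by_category",
    "ExpressionDifferentialModel",
    "ExpressionDifferentialResults",
]

PSEUDOCOUNT_SCALE = 1e6


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-transcript between-eddy expression outcome."""

    transcript_id: str
    taxon_id: str
    eggnog_id: str
    ko_id: str
    cog_category: str
    log2_fold_change: float  # anticyclone over cyclone
    p_value: float
    q_value: float
    side: str  # anticyclone | cyclone | none


@dataclass
class CategorySummary:
    """Counts and effect sizes of retained transcripts in one category."""

    category_id: str
    n_cyclone: int
    n_anticyclone: int
    member_log2fc: list[float] = field(default_factory=list)


def within_taxon_normalize(
    transcripts: AbundanceTable,
    taxon_map: pd.Series | dict,
    exclude_below_detection: bool = True,
) -> tuple[AbundanceTable, dict[str, list[str]]]:
    """Normalize each transcript to its taxon's total expression per sample.

    value(t, s) = per_ml(t, s) / taxon_total(s): fractions in [0, 1] that
    sum to 1 over each taxon's transcripts.  Below-detection entries are
    zeroed before totals when the flag is set.  Samples where a taxon's
    total is zero are excluded for that taxon (fractions set to 0) and
    reported in the returned mapping taxon -> excluded sample ids.
    """
    taxon_map = pd.Series(taxon_map).astype(str)
    values = transcripts.values.astype(float)
    if exclude_below_detection and isinstance(transcripts, AbsoluteAbundanceTable):
        values = values.where(~transcripts.below_detection, 0.0)
    out = pd.DataFrame(0.0, index=values.index, columns=values.columns)
    excluded: dict[str, list[str]] = {}
    taxa = pd.Series([taxon_map.get(t, "") for t in transcripts.features], index=values.index)
    for taxon in taxa[taxa != ""].unique():
        members = taxa.index[taxa == taxon]
        block = values.loc[members]
        totals = block.sum(axis=0)
        zero = totals[totals <= 0].index.tolist()
        if zero:
            excluded[taxon] = zero
        ok = totals.index[totals > 0]
        out.loc[members, ok] = (block[ok] / totals[ok]).to_numpy()
    return AbundanceTable(out, transcripts.kind, transcripts.annotations), excluded


class ExpressionDifferentialModel:
    """Per-transcript eddy contrast within selected taxa.

    Parameters
    ----------
    per_ml
        Absolute transcript table over the diel DCM samples.
    meta
        Sample metadata with eddy labels.
    annotations
        Per-transcript frame with taxon / eggnog / ko / cog_categories /
        pathways columns (defaults to the table's own annotations).
    taxa
        Taxa to test (e.g. the cyclone-flagged set from the taxon stage);
        ``None`` tests every annotated taxon.
    use_fractions
        Default True: test within-taxon fractions scaled to pseudo-counts.
        False tests the per-ml values directly scaled the same way (the
        cell-abundance-confounded route, kept behind this flag).
    """

    def __init__(
        self,
        per_ml: AbundanceTable,
        meta: SampleMetadata,
        annotations: pd.DataFrame | None = None,
        taxa: list[str] | None = None,
        config: RunConfig | None = None,
        use_fractions: bool = True,
        exclude_below_detection: bool = True,
    ) -> None:
        ann = annotations if annotations is not None else per_ml.annotations
        if ann is None or "taxon" not in ann.columns:
            raise ValidationError("transcript annotations with a 'taxon' column are required")
        self.per_ml = per_ml
        self.meta = meta
        self.annotations = ann
        self.config = config or RunConfig()
        self.use_fractions = use_fractions
        self.exclude_below_detection = exclude_below_detection
        all_taxa = [t for t in ann["taxon"].loc[[f for f in per_ml.features if f in ann.index]].unique() if t]
        self.taxa = list(taxa) if taxa is not None else all_taxa
        self.cyclone_ids = meta.samples_in_eddy("cyclone", per_ml.samples)
        self.anticyclone_ids = meta.samples_in_eddy("anticyclone", per_ml.samples)
        if len(self.cyclone_ids) < 2 or len(self.anticyclone_ids) < 2:
            raise ValidationError("need >= 2 samples per eddy")

    def fit(self) -> "ExpressionDifferentialResults":
        thr = self.config.thresholds
        taxon_map = self.annotations["taxon"]
        if self.use_fractions:
            normalized, excluded = within_taxon_normalize(
                self.per_ml, taxon_map, self.exclude_below_detection
            )
        else:
            normalized, excluded = self.per_ml, {}

        rows, ids = [], []
        for taxon in self.taxa:
            members = [f for f in normalized.features if taxon_map.get(f, "") == taxon]
            if not members:
                raise ValidationError(f"taxon {taxon!r} has no transcripts in the table")
            ids.extend(members)
            rows.append(normalized.values.loc[members])
        block = pd.concat(rows)
        pseudo = np.rint(block.to_numpy(dtype=float) * PSEUDOCOUNT_SCALE)
        cols = list(block.columns)
        idx_c = [cols.index(s) for s in self.cyclone_ids]
        idx_a = [cols.index(s) for s in self.anticyclone_ids]
        log2fc, _, p = nb_wald_matrix(pseudo[:, idx_c], pseudo[:, idx_a])
        q = benjamini_hochberg(p).adjusted

        records = []
        for i, tid in enumerate(ids):
            side = "none"
            if q[i] < thr.q_max and abs(log2fc[i]) > thr.log2fc_flag:
                side = "anticyclone" if log2fc[i] > 0 else "cyclone"
            ann = self.annotations.loc[tid] if tid in self.annotations.index else {}
            records.append(
                ExpressionRecord(
                    transcript_id=str(tid),
                    taxon_id=str(taxon_map.get(tid, "")),
                    eggnog_id=str(ann.get("eggnog", "")),
                    ko_id=str(ann.get("ko", "")),
                    cog_category=str(ann.get("cog_categories", "")),
                    log2_fold_change=float(log2fc[i]),
                    p_value=float(p[i]),
                    q_value=float(q[i]),
                    side=side,
                )
            )
        return ExpressionDifferentialResults(self, records, excluded)


def summarize_by_category(
    records: list[ExpressionRecord],
    mode: str,
    config: RunConfig | None = None,
    pathway_annotations: pd.Series | None = None,
    merge_map: dict[str, str] | None = None,
) -> list[CategorySummary]:
    """Summarize sided transcripts by COG category or KEGG pathway.

    Steps: (1) drop transcripts whose eggNOG annotation has significant
    members on both sides; (2) expand each remaining transcript into its
    categories (COG letters, or the comma-separated pathway list from
    ``pathway_annotations``), applying ``merge_map`` renames first; (3) in
    pathway mode retain only categories with more than two transcripts.
    """
    config = config or RunConfig()
    if mode not in ("cog", "pathway"):
        raise ValidationError(f"unknown summary mode {mode!r}; expected 'cog' or 'pathway'")
    sided = [r for r in records if r.side != "none"]
    # both-sides exclusion on the eggNOG annotation level
    sides_by_eggnog: dict[str, set[str]] = {}
    for r in sided:
        if r.eggnog_id:
            sides_by_eggnog.setdefault(r.eggnog_id, set()).add(r.side)
    retained = [
        r for r in sided if not (r.eggnog_id and len(sides_by_eggnog[r.eggnog_id]) > 1)
    ]

    merge_map = merge_map or {}
    groups: dict[str, CategorySummary] = {}
    order: list[str] = []
    for r in retained:
        if mode == "cog":
            cats = [c for c in r.cog_category if c.strip()]
        else:
            raw = "" if pathway_annotations is None else str(pathway_annotations.get(r.transcript_id, ""))
            cats = [c for c in raw.split(",") if c]
        for cat in cats:
            cat = merge_map.get(cat, cat)
            if cat not in groups:
                groups[cat] = CategorySummary(cat, 0, 0)
                order.append(cat)
            summ = groups[cat]
            if r.side == "cyclone":
                summ.n_cyclone += 1
            else:
                summ.n_anticyclone += 1
            summ.member_log2fc.append(r.log2_fold_change)
    out = [groups[c] for c in order]
    if mode == "pathway":
        out = [s for s in out if s.n_cyclone + s.n_anticyclone >= config.thresholds.pathway_min_transcripts]
    return out


class ExpressionDifferentialResults:
    def __init__(
        self,
        model: ExpressionDifferentialModel,
        records: list[ExpressionRecord],
        excluded_samples: dict[str, list[str]],
    ):
        self.model = model
        self.records = records
        self.excluded_samples = excluded_samples

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records]).set_index("transcript_id")

    def sided(self, side: str | None = None) -> list[ExpressionRecord]:
        if side is None:
            return [r for r in self.records if r.side != "none"]
        return [r for r in self.records if r.side == side]

    def summarize(self, mode: str = "cog", merge_map: dict[str, str] | None = None) -> list[CategorySummary]:
        pathways = None
        ann = self.model.annotations
        if "pathways" in ann.columns:
            pathways = ann["pathways"]
        return summarize_by_category(self.records, mode, self.model.config, pathways, merge_map)

    def category_long_frame(self, mode: str = "cog", merge_map: dict[str, str] | None = None) -> pd.DataFrame:
        """Violin-ready long format: one row per (category, side, log2FC)."""
        rows = []
        for s in self.summarize(mode, merge_map):
            # recover per-member sides from the sign convention
            for l2 in s.member_log2fc:
                rows.append(
                    dict(category=s.category_id, side="anticyclone" if l2 > 0 else "cyclone", log2fc=l2)
                )
        return pd.DataFrame(rows, columns=["category", "side", "log2fc"])

    def summary(self) -> str:
        thr = self.model.config.thresholds
        n_sig = sum(r.q_value < thr.q_max for r in self.records)
        sided = self.sided()
        lines = [
            "Within-taxon differential expression (NB Wald, anticyclone / cyclone)",
            "=====================================================================",
            f"taxa tested: {len(self.model.taxa)}   transcripts tested: {len(self.records)}",
            f"significant at q < {thr.q_max}: {n_sig}",
            f"sided (also |log2FC| > {thr.log2fc_flag}): {len(sided)} "
            f"({len(self.sided('cyclone'))} cyclone, {len(self.sided('anticyclone'))} anticyclone)",
        ]
        return "\n".join(lines)
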