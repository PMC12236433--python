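"""Core in-memory containers: abundance tables and sample metadata.

The whole pipeline speaks two currencies: a feature-by-sample
:class:`AbundanceTable` of non-negative values (counts, reads-per-billion,
or transcripts per ml) and a :class:`SampleMetadata` set describing where
and how each sample was taken (eddy, depth, DCM depth, filtered volume,
diel timepoint).  Both wrap pandas objects and validate on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TableKind",
    "EDDY_LABELS",
    "AbundanceTable",
    "AbsoluteAbundanceTable",
    "SampleMetadata",
    "ValidationError",
]

#: Recognised table kinds, tagging what the matrix values mean.
TableKind = (
    "asv_count",
    "its_rpb",
    "ko_rpb",
    "transcript_count",
    "transcript_per_ml",
    "species_sum",
)

#: Allowed eddy labels.  "front" marks the inter-eddy frontal station.
EDDY_LABELS = ("cyclone", "anticyclone", "front")

#: Annotation columns carried alongside a table (strings; "" when absent).
ANNOTATION_COLUMNS = ("taxon", "ecotype", "ko", "eggnog", "cog_categories", "pathways")


class ValidationError(ValueError):
    """A table or metadata set violated a structural invariant."""


def _check_unique(values: Iterable[str], what: str) -> None:
    s = pd.Index(values)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class AbundanceTable:
    """Feature x sample matrix of non-negative abundances.

    Parameters
    ----------
    values
        DataFrame with feature ids on the index and sample ids on the
        columns.  All entries must be finite and >= 0; absence is encoded
        as 0, never as NaN.
    kind
        One of :data:`TableKind`, tagging the unit of the values.
    annotations
        Optional per-feature annotation frame (taxon, ecotype, ko, eggnog,
        cog_categories, pathways).  Missing fields are empty strings.
    """

    values: pd.DataFrame
    kind: str
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.kind not in TableKind:
            raise ValidationError(f"unknown table kind {self.kind!r}; expected one of {TableKind}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.shape[0] == 0:
            raise ValidationError("no features")
        _check_unique(self.values.index, "feature id")
        _check_unique(self.values.columns, "sample id")
        arr = self.values.to_numpy(dtype=float)
        bad = ~np.isfinite(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value at feature {self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        neg = arr < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative value {arr[i, j]} at feature {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        if self.annotations is not None:
            self.annotations = normalize_annotations(self.annotations, self.values.index)

    # -- convenience accessors ------------------------------------------------

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, feature: str) -> pd.Series:
        if feature not in self.values.index:
            raise KeyError(f"feature {feature!r} not in table")
        return self.values.loc[feature]

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        ids = [s for s in self.samples if s in set(sample_ids)]  # order-stable
        return AbundanceTable(self.values[ids], self.kind, self.annotations)

    def with_kind(self, kind: str) -> "AbundanceTable":
        return AbundanceTable(self.values.copy(), kind, self.annotations)


def normalize_annotations(ann: pd.DataFrame | Mapping, features: pd.Index) -> pd.DataFrame:
    """Coerce an annotation mapping/frame to the canonical string frame."""
    if not isinstance(ann, pd.DataFrame):
        ann = pd.DataFrame.from_dict(dict(ann), orient="index")
    out = pd.DataFrame(index=pd.Index(features), columns=list(ANNOTATION_COLUMNS), dtype=object)
    for col in ANNOTATION_COLUMNS:
        if col in ann.columns:
            out[col] = ann[col].reindex(out.index)
    return out.fillna("").astype(str)


@dataclass
class AbsoluteAbundanceTable(AbundanceTable):
    """Transcripts-per-ml table with a below-detection flag per cell.

    ``below_detection`` distinguishes entries whose back-calculated molecule
    estimate fell under the sample's spike-in detection limit from genuine
    observed zeros; values are retained, the flag marks them.
    """

    below_detection: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.below_detection is None:
            self.below_detection = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if not self.below_detection.index.equals(self.values.index) or not (
            self.below_detection.columns.equals(self.values.columns)
        ):
            raise ValidationError("below_detection mask must align with values")
        self.below_detection = self.below_detection.astype(bool)


_META_NUMERIC = ("depth_m", "dcm_depth_m", "volume_ml", "timepoint_h")


@dataclass
class SampleMetadata:
    """Per-sample eddy label, depth, DCM depth, filtered volume and timepoint.

    Wraps a DataFrame indexed by ``sample_id`` with columns ``eddy`` (one of
    cyclone / anticyclone / front), ``depth_m``, ``dcm_depth_m``,
    ``volume_ml``, ``timepoint_h`` and ``station``.  Numeric fields may be
    NaN (e.g. no depth for purely diel samples); constraints on positivity
    are enforced lazily at the point of use (per-ml normalization demands a
    positive volume, windowing demands depths).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        _check_unique(df.index, "sample id")
        if "eddy" not in df.columns:
            raise ValidationError("metadata missing required column 'eddy'")
        bad = ~df["eddy"].isin(EDDY_LABELS)
        if bad.any():
            raise ValidationError(
                f"unknown eddy label {df['eddy'][bad].iloc[0]!r} for sample "
                f"{df.index[bad][0]!r}; allowed labels: {EDDY_LABELS}"
            )
        for col in _META_NUMERIC:
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="raise")
        if (df["depth_m"].dropna() < 0).any():
            raise ValidationError("depth_m must be >= 0")
        if (df["dcm_depth_m"].dropna() <= 0).any():
            raise ValidationError("dcm_depth_m must be > 0")
        if "station" not in df.columns:
            df["station"] = ""
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def eddy_of(self) -> pd.Series:
        return self.frame["eddy"]

    def samples_in_eddy(self, eddy: str, sample_ids: Iterable[str] | None = None) -> list[str]:
        if eddy not in EDDY_LABELS:
            raise ValidationError(f"unknown eddy label {eddy!r}; allowed: {EDDY_LABELS}")
        pool = self.sample_ids if sample_ids is None else [s for s in self.sample_ids if s in set(sample_ids)]
        return [s for s in pool if self.frame.at[s, "eddy"] == eddy]

    def volume_ml(self, sample_id: str) -> float:
        v = self.frame.at[sample_id, "volume_ml"]
        if not np.isfinite(v) or v <= 0:
            raise ValidationError(
                f"sample {sample_id!r} has no positive filtered volume (volume_ml={v!r}) "
                "but per-ml normalization was requested"
            )
        return float(v)

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return SampleMetadata(self.frame.loc[keep].copy())
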