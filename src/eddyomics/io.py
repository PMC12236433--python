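"""Tabular input/output and structured stage logging.

All tables travel as tab-separated UTF-8 text with "." decimals: a header
row of sample ids, a first column of feature ids.  Floats are written with
12 significant digits so that write -> read round-trips are lossless at
that precision, and feature/sample order is preserved exactly as read.
"""

from __future__ import annotations

import dataclasses
import sys
import time
from contextlib import contextmanager
from pathlib import Path
from typing import Any, Iterator, Sequence, Type, TypeVar

import numpy as np
import pandas as pd

from .tables import AbundanceTable, SampleMetadata, ValidationError

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_sample_meta",
    "write_sample_meta",
    "read_annotations",
    "write_records",
    "read_records",
    "log_stage",
]

FLOAT_FORMAT = "%.12g"


def read_abundance_table(path: str | Path, kind: str) -> AbundanceTable:
    """Read a feature x sample TSV into a validated :class:`AbundanceTable`.

    The first column holds feature ids, the header row sample ids.  Any
    negative, missing, or non-numeric cell raises :class:`ValidationError`
    naming the offending row and column; duplicate feature or sample ids
    are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no features (empty file)") from None
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: no features")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            raise ValidationError(
                f"{path}: unparseable value {df[col][bad].iloc[0]!r} at "
                f"feature {df.index[bad][0]!r}, sample {col!r}"
            )
        numeric[col] = converted
    try:
        return AbundanceTable(numeric, kind)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="feature_id")


def read_sample_meta(path: str | Path) -> SampleMetadata:
    """Read sample metadata TSV (columns: sample_id, eddy, and optional
    depth_m, dcm_depth_m, volume_ml, timepoint_h, station)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "eddy": str, "station": str})
    for required in ("sample_id", "eddy"):
        if required not in df.columns:
            raise ValidationError(f"{path}: missing required column {required!r}")
    try:
        return SampleMetadata(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_sample_meta(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="sample_id")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a feature annotation map TSV (feature_id plus any of: taxon,
    ecotype, ko, eggnog, cog_categories, pathways).  Absent fields become
    empty strings."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "feature_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'feature_id'")
    return df.set_index("feature_id")


R = TypeVar("R")


def _record_type(records: Sequence[Any]) -> Type:
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise ValidationError(f"records of mixed types: {sorted(k.__name__ for k in kinds)}")
    (kind,) = kinds
    if not dataclasses.is_dataclass(kind):
        raise ValidationError(f"records must be dataclasses, got {kind.__name__}")
    return kind


def write_records(records: Sequence[Any], path: str | Path, record_type: Type | None = None) -> None:
    """Write a homogeneous list of result records as TSV.

    Column order is the dataclass field order (deterministic); floats keep
    12 significant digits.  An empty list with an explicit ``record_type``
    yields a header-only file.
    """
    if record_type is None:
        if not records:
            raise ValidationError("empty record list requires an explicit record_type")
        record_type = _record_type(records)
    elif records:
        actual = _record_type(records)
        if actual is not record_type:
            raise ValidationError(f"records are {actual.__name__}, expected {record_type.__name__}")
    cols = [f.name for f in dataclasses.fields(record_type)]
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_records(path: str | Path, record_type: Type[R]) -> list[R]:
    """Read records written by :func:`write_records` back into dataclasses."""
    df = pd.read_csv(path, sep="\t")
    out: list[R] = []
    hints = {f.name: f.type for f in dataclasses.fields(record_type)}
    for _, row in df.iterrows():
        kwargs = {}
        for name in hints:
            v = row[name]
            if isinstance(v, (np.floating, np.integer)):
                v = v.item()
            if isinstance(v, float) and np.isnan(v):
                v = ""
            kwargs[name] = v
        out.append(record_type(**kwargs))
    return out


@contextmanager
def log_stage(stage: str, **counts: int) -> Iterator[None]:
    """Log a pipeline stage to stderr with elapsed wall time and counts."""
    t0 = time.perf_counter()
    yield
    elapsed = time.perf_counter() - t0
    extra = "".join(f" {k}={v}" for k, v in counts.items())
    print(f"[eddyomics] stage={stage} elapsed={elapsed:.3f}s{extra}", file=sys.stderr)
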