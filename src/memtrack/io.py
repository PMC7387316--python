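"""Shared TSV readers/writers with validation.

All tables are plain tab-separated text.  The expression dialect is a
probeset x visit matrix with a header row of visit ids and the probeset id
in the first column; detection calls use the same shape with P/A cells.
Floats are written with 6 significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.6g"

METADATA_COLUMNS = [
    "visit_id", "subject_id", "gender", "diagnosis", "day",
    "retention", "neuropsych_event", "event_day",
]


class ParseError(ValueError):
    """Raised when an input table fails validation."""


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a probeset x visit expression matrix.

    Rejects duplicate probeset or visit ids, ragged rows and non-numeric
    cells, naming the offending line/id.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate probeset id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate visit id {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = df.index.get_loc(bad.idxmax()) + 2  # header + 1-based
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = coerced
    if df.isna().any().any():
        raise ParseError(f"{path}: missing values in expression matrix")
    if not np.isfinite(df.to_numpy()).all():
        raise ParseError(f"{path}: non-finite expression values")
    df.index.name = "probeset_id"
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="probeset_id")


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a probeset x visit Present/Absent call matrix (cells P or A)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = df.to_numpy()
    bad = ~np.isin(values, ("P", "A"))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(f"{path}: invalid call {values[i, j]!r} at row {df.index[i]!r}")
    df.index.name = "probeset_id"
    return df


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index_label="probeset_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read visit-level metadata; validates required columns and uniqueness."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing metadata columns {missing}")
    if df["visit_id"].duplicated().any():
        dup = df.loc[df["visit_id"].duplicated(), "visit_id"].iloc[0]
        raise ParseError(f"{path}: duplicate visit id {dup!r}")
    df["neuropsych_event"] = df["neuropsych_event"].astype(bool)
    return df


def write_metadata(visits: pd.DataFrame, path: str | Path) -> None:
    visits[METADATA_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_evidence(path: str | Path) -> pd.DataFrame:
    """Read an evidence table (gene_symbol, line, direction, source_tag,
    disorder_tag); the line vocabulary is validated downstream."""
    from .cfg import validate_evidence

    df = pd.read_csv(path, sep="\t")
    required = ["gene_symbol", "line"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing evidence columns {missing}")
    return validate_evidence(df)


def read_panel(path: str | Path) -> list[tuple[str, str]]:
    """Read a panel definition TSV (probeset_id, direction)."""
    df = pd.read_csv(path, sep="\t")
    for c in ("probeset_id", "direction"):
        if c not in df.columns:
            raise ParseError(f"{path}: missing panel column {c!r}")
    bad = ~df["direction"].isin(["increased_risk", "decreased_risk"])
    if bad.any():
        raise ParseError(f"{path}: invalid panel direction {df.loc[bad, 'direction'].iloc[0]!r}")
    if df["probeset_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate panel member")
    return list(zip(df["probeset_id"], df["direction"]))


def read_gene_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for c in ("probeset_id", "gene_symbol"):
        if c not in df.columns:
            raise ParseError(f"{path}: missing gene-map column {c!r}")
    if df["probeset_id"].duplicated().any():
        raise ParseError(f"{path}: probeset mapped to multiple symbols")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a generic results table with the package float convention."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
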