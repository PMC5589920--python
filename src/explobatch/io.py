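"""Reading and writing expression matrices, annotations and result tables.

Expression files are TSV or CSV with one header row and one identifier
column; the orientation flag declares whether genes or samples sit in rows
(genes-in-rows is the default, matching the common series-matrix layout).
The delimiter is inferred from the extension (.csv -> comma, otherwise tab)
and can be overridden.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .ppcca import ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_forest",
    "write_provenance",
]


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path, orientation: str = "genes_in_rows",
                    delimiter: str | None = None) -> ExpressionMatrix:
    """Parse a delimited expression table into a samples x genes matrix."""
    path = Path(path)
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"expression file {path} is missing or empty")
    sep = _sep_for(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup_header = sorted({h for h in header if header.count(h) > 1})
    if dup_header:
        kind = "sample" if orientation == "genes_in_rows" else "gene"
        raise ValueError(f"duplicate {kind} ids: {dup_header[:10]}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.empty:
        raise ValueError(f"expression file {path} has no data rows")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric or missing cell at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} (value {df.iat[r, c]!r})"
        )
    if orientation == "genes_in_rows":
        numeric = numeric.T
    dup = numeric.columns[numeric.columns.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene ids: {dup[:10]}")
    return ExpressionMatrix.from_dataframe(numeric)


def write_expression(path, em: ExpressionMatrix,
                     orientation: str = "genes_in_rows",
                     delimiter: str | None = None) -> None:
    """Write a matrix in the same dialect ``read_expression`` accepts, at
    full float precision so a round-trip is lossless to ~1e-16."""
    path = Path(path)
    df = em.to_dataframe()
    if orientation == "genes_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=_sep_for(path, delimiter), float_format="%.17g")


def read_annotation(path, em: ExpressionMatrix,
                    delimiter: str | None = None) -> pd.DataFrame:
    """Sample annotation table (sample_id, batch, optional covariates),
    checked for set-equality with the expression samples and re-ordered to
    match them."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"annotation file {path} is missing or empty")
    ann = pd.read_csv(path, sep=_sep_for(path, delimiter), dtype=str)
    if ann.shape[1] < 2:
        raise ValueError("annotation needs a sample_id column plus at least "
                         "one label column")
    idcol = ann.columns[0]
    ann[idcol] = ann[idcol].astype(str)
    if ann[idcol].duplicated().any():
        dups = ann.loc[ann[idcol].duplicated(), idcol].tolist()
        raise ValueError(f"duplicate sample ids in annotation: {dups[:10]}")
    have, want = set(ann[idcol]), set(em.sample_ids)
    if have != want:
        missing = sorted(want - have)[:5]
        extra = sorted(have - want)[:5]
        raise ValueError(
            "annotation samples do not match expression samples; "
            f"missing {missing}, unexpected {extra}"
        )
    return ann.set_index(idcol).loc[list(em.sample_ids)]


def write_forest(path, table: pd.DataFrame, delimiter: str = "\t") -> None:
    """Tidy forest-plot table (one row per pPC x contrast) as TSV."""
    table.to_csv(path, sep=delimiter, index=False, float_format="%.6g")


def write_provenance(path, payload: Mapping) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")
    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
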