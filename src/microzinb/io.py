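"""Reading and writing the pipeline's tabular formats.

ASV/OTU tables are TSV with the taxon id in the first column and one
column of integer counts per sample; metadata is CSV keyed by
``sample_id``; taxonomy is a two-column TSV mapping taxon id to a
SINTAX-style lineage string.  Column layouts are documented in
FORMATS.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_asv_table",
    "write_asv_table",
    "read_metadata",
    "read_taxonomy",
    "write_posterior_summary",
]

METADATA_COLUMNS = ["sample_id", "age_years", "sex", "ethnic", "geography", "height_m", "weight_kg"]


def read_asv_table(path) -> pd.DataFrame:
    """Read a taxa x samples count table from TSV.

    The header row holds sample ids; the first column holds taxon ids.
    Cells must be non-negative integers; duplicates among taxon ids and
    empty cells are rejected with the offending coordinates named.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon ids: {dups}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    try:
        out = raw.astype(np.int64)
        if (out < 0).any().any():
            raise ValueError
        return out
    except (ValueError, TypeError):
        pass  # locate the offending cell for the error message
    for col in raw.columns:
        for taxon, value in raw[col].items():
            if value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() == "":
                raise ValueError(f"empty cell at taxon {taxon!r}, sample {col!r}")
            try:
                iv = int(str(value).strip())
            except ValueError as exc:
                raise ValueError(
                    f"non-integer count {value!r} at taxon {taxon!r}, sample {col!r}"
                ) from exc
            if iv < 0:
                raise ValueError(f"negative count at taxon {taxon!r}, sample {col!r}")
    raise ValueError("count table could not be parsed as integers")


def write_asv_table(counts: pd.DataFrame, path) -> None:
    """Write a taxa x samples count table as TSV (taxon id first column)."""
    counts.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata CSV; requires the documented columns."""
    meta = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    return meta.set_index("sample_id", drop=False)


def read_taxonomy(path) -> pd.Series:
    """Read a taxon id -> SINTAX lineage TSV into a Series."""
    tax = pd.read_csv(path, sep="\t", index_col=0, header=0)
    return tax.iloc[:, 0].astype(str)


def write_posterior_summary(summary: pd.DataFrame, path, failed: bool = False) -> None:
    """Write a posterior summary CSV with a ``failed`` marker column."""
    out = summary.copy()
    out["failed"] = failed
    out.to_csv(path, index=False)
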