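"""Tabular I/O: tab-separated tables with a metadata header comment.

One dialect everywhere: TSV, UTF-8, '.' decimal, missing values as "NA",
gzip transparent by file extension.  Writers prepend '#'-prefixed header
lines carrying the config hash and seed; readers skip them.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_counts_table",
    "read_annotation",
    "read_psup_table",
    "read_tpm_table",
    "write_table",
    "read_table",
    "config_hash",
]

COUNTS_KEY = ["gene_id", "condition", "replicate", "fraction"]
_COUNTS_REQUIRED = COUNTS_KEY + ["counts"]
_ANNOT_REQUIRED = ["gene_id", "length_total", "utr5_len", "utr3_len"]
_PSUP_REQUIRED = ["gene_id", "psup", "lopsup"]
_TPM_REQUIRED = ["gene_id", "fraction", "tpm", "est_counts", "is_spike"]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a TSV with optional '#'-prefixed metadata header lines."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", encoding="utf-8") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_table(path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`; tolerant of extra columns."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_counts_table(path) -> pd.DataFrame:
    """Read a fraction-counts table; reject duplicate keys, count gaps.

    Required columns: gene_id, condition, replicate, fraction, counts;
    extra columns are preserved.
    """
    df = read_table(path, required=_COUNTS_REQUIRED)
    numeric = pd.to_numeric(df["counts"], errors="coerce")
    bad = numeric.isna() & df["counts"].notna()
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValueError(f"{path}: malformed counts value at line ~{line}")
    df["counts"] = numeric
    dup = df.duplicated(subset=COUNTS_KEY, keep=False)
    if dup.any():
        key = df.loc[df.index[dup][0], COUNTS_KEY].tolist()
        raise ValueError(f"{path}: duplicated key row {key}")
    frac_counts = df.groupby(["gene_id", "condition", "replicate"])["fraction"].nunique()
    n_incomplete = int((frac_counts < 3).sum())
    df.attrs["n_genes_missing_fractions"] = n_incomplete
    return df


def read_annotation(path) -> pd.DataFrame:
    df = read_table(path, required=_ANNOT_REQUIRED)
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene_id in annotation")
    return df


def read_psup_table(path) -> pd.DataFrame:
    return read_table(path, required=_PSUP_REQUIRED)


def read_tpm_table(path) -> pd.DataFrame:
    return read_table(path, required=_TPM_REQUIRED)
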