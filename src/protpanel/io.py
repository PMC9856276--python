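"""Readers and writers for the delimited-text formats the pipeline consumes.

Expression matrices and metadata are tab-separated text; gene sets are
standard GMT (name, description, then members, tab-separated).  Writers
and readers round-trip: write-then-read reproduces the container up to
float formatting.
"""

from __future__ import annotations

import os
from typing import Literal

import numpy as np
import pandas as pd

from .datamodel import GeneSetCollection, ProteinMatrix, SampleMetadata

Orientation = Literal["samples_in_rows", "proteins_in_rows"]


class FormatError(ValueError):
    """Raised for malformed input files."""


def read_expression_matrix(
    path: str | os.PathLike,
    orientation: Orientation = "samples_in_rows",
    transform_state: str = "raw",
) -> ProteinMatrix:
    """Read a TSV expression matrix.

    The file has one header row and one id column; ``orientation`` says
    whether rows are samples (default) or proteins.  The result is always
    samples-in-rows.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen: set[str] = set()
    dup = sorted({h for h in header[1:] if h in seen or seen.add(h)})
    if dup:
        raise FormatError(f"{path}: duplicate header column(s) {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise FormatError(f"{path}: empty expression matrix")
    if orientation == "proteins_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate protein column(s) {dup}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample id(s) {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at sample "
            f"{df.index[r]!r}, protein {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at sample {df.index[r]!r}, "
            f"protein {df.columns[c]!r}"
        )
    return ProteinMatrix(numeric.astype(float), transform_state=transform_state)


def write_expression_matrix(matrix: ProteinMatrix, path: str | os.PathLike) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="sample_id", float_format="%.12g")


def read_sample_metadata(path: str | os.PathLike) -> SampleMetadata:
    """Read a TSV metadata table; '' and 'NA' are treated as missing."""
    df = pd.read_csv(path, sep="\t", na_values=["", "NA"], keep_default_na=True)
    if "sample_id" not in df.columns:
        # first column is the id column by convention
        df = df.rename(columns={df.columns[0]: "sample_id"})
    return SampleMetadata(df)


def write_sample_metadata(metadata: SampleMetadata, path: str | os.PathLike) -> None:
    metadata.table.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT gene-set file; members are de-duplicated per set."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields; "
                    "expected name, description and at least one member"
                )
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            members = sorted(collection[name])
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
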