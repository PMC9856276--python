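"""Shared data model for aptamer proteomics pipelines.

Expression data travel as a :class:`ProteinMatrix` — a samples x assays
table of relative fluorescence units (RFU) plus a flag recording which
transform has been applied (raw RFU, log2, per-protein Z, or covariate
residuals).  Clinical and technical covariates travel as a
:class:`SampleMetadata` table keyed by sample id.  Pathway/gene-set
collections are plain name -> member-set maps (:class:`GeneSetCollection`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TRANSFORM_STATES = ("raw", "log2", "standardized", "residualized")
STATUS_LEVELS = ("case", "control")
MODALITIES = ("serum", "csf", "brain")
SEX_LEVELS = ("male", "female")

#: metadata columns that are numeric when present
_NUMERIC_META = ("age", "moca", "updrs3", "ledd")


class DataModelError(ValueError):
    """Raised when a container violates its invariants."""


class ProteinMatrix:
    """Samples x protein-assays expression matrix with a transform state.

    Parameters
    ----------
    values
        DataFrame with sample ids as the index and assay ids as columns.
        Values are RFU when ``transform_state == "raw"``.
    transform_state
        One of ``raw``, ``log2``, ``standardized``, ``residualized``.

    Invariants (checked at construction): unique sample and protein ids,
    all values finite, raw values strictly positive.
    """

    def __init__(self, values: pd.DataFrame, transform_state: str = "raw"):
        if transform_state not in TRANSFORM_STATES:
            raise DataModelError(
                f"unknown transform_state {transform_state!r}; "
                f"expected one of {TRANSFORM_STATES}"
            )
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate sample ids: {dups}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate protein ids: {dups}")
        arr = values.to_numpy(dtype=float, copy=False)
        if arr.size and not np.isfinite(arr).all():
            n_bad = int((~np.isfinite(arr)).sum())
            raise DataModelError(f"{n_bad} non-finite expression values")
        if transform_state == "raw" and arr.size and (arr <= 0).any():
            n_bad = int((arr <= 0).sum())
            raise DataModelError(
                f"raw RFU values must be strictly positive ({n_bad} violations)"
            )
        self.values = values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        self.transform_state = transform_state

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(self.values.copy(), self.transform_state)

    def with_values(self, values: pd.DataFrame, transform_state: str) -> "ProteinMatrix":
        """Return a new matrix with replaced values and state."""
        return ProteinMatrix(values, transform_state)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ProteinMatrix":
        ids = [str(s) for s in sample_ids]
        return ProteinMatrix(self.values.loc[ids], self.transform_state)

    def subset_proteins(self, protein_ids: Iterable[str]) -> "ProteinMatrix":
        ids = [str(p) for p in protein_ids]
        return ProteinMatrix(self.values.loc[:, ids], self.transform_state)

    def require_state(self, *states: str) -> None:
        if self.transform_state not in states:
            raise DataModelError(
                f"matrix is {self.transform_state}; expected one of {states}"
            )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ProteinMatrix({self.n_samples} samples x {self.n_proteins} "
            f"proteins, {self.transform_state})"
        )


class SampleMetadata:
    """Per-sample clinical and technical covariates.

    Wraps a DataFrame indexed by sample id with (at least) a ``status``
    column taking values ``case``/``control``.  Recognized optional
    columns: ``age`` (years), ``sex`` (male/female), ``cohort``,
    ``modality`` (serum/csf/brain), ``moca`` (0-30), ``updrs3`` (>= 0),
    ``ledd`` (mg/day), ``batch``, ``assay_date``, ``prep_date``.
    Missing values stay missing; nothing is imputed here.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "sample_id" in table.columns:
            table = table.set_index("sample_id")
        table.index = table.index.astype(str)
        table.index.name = "sample_id"
        if table.index.duplicated().any():
            dups = table.index[table.index.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate sample ids in metadata: {dups}")
        if "status" not in table.columns:
            raise DataModelError("metadata requires a 'status' column")
        status = table["status"].astype(str)
        bad = sorted(set(status) - set(STATUS_LEVELS))
        if bad:
            raise DataModelError(
                f"unknown status labels {bad}; expected {STATUS_LEVELS}"
            )
        table["status"] = status
        if "sex" in table.columns:
            sex = table["sex"].dropna().astype(str)
            bad = sorted(set(sex) - set(SEX_LEVELS))
            if bad:
                raise DataModelError(f"unknown sex labels {bad}")
        if "modality" in table.columns:
            mod = table["modality"].dropna().astype(str)
            bad = sorted(set(mod) - set(MODALITIES))
            if bad:
                raise DataModelError(f"unknown modality labels {bad}")
        for col in _NUMERIC_META:
            if col in table.columns:
                table[col] = pd.to_numeric(table[col], errors="raise")
        if "moca" in table.columns:
            moca = table["moca"].dropna()
            if ((moca < 0) | (moca > 30)).any():
                bad_ids = table.index[
                    table["moca"].notna() & ((table["moca"] < 0) | (table["moca"] > 30))
                ].tolist()
                raise DataModelError(f"MoCA outside [0, 30] for samples {bad_ids}")
        if "updrs3" in table.columns:
            up = table["updrs3"].dropna()
            if (up < 0).any():
                raise DataModelError("UPDRS-III scores must be >= 0")
        self.table = table

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def status(self) -> pd.Series:
        return self.table["status"]

    def __len__(self) -> int:
        return len(self.table)

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        ids = [str(s) for s in sample_ids]
        return SampleMetadata(self.table.loc[ids])

    def status_binary(self) -> pd.Series:
        """Disease status as 1 = case, 0 = control."""
        return (self.table["status"] == "case").astype(int)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_case = int((self.table["status"] == "case").sum())
        return f"SampleMetadata({len(self)} samples, {n_case} cases)"


@dataclass
class GeneSetCollection:
    """Named protein sets (e.g. KEGG or GO pathways read from GMT)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataModelError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets that vanish."""
        uni = set(universe)
        kept = {
            name: frozenset(m & uni)
            for name, m in ((n, set(s) & uni) for n, s in self.sets.items())
            if m
        }
        return GeneSetCollection(
            kept, {n: self.descriptions.get(n, "") for n in kept}
        )


def align(matrix: ProteinMatrix, metadata: SampleMetadata) -> tuple[ProteinMatrix, SampleMetadata, int]:
    """Join a matrix and metadata on their common samples.

    Returns the aligned pair (identical sample order) and the number of
    samples dropped from the union of the two id sets.
    """
    common = [s for s in matrix.sample_ids if s in set(metadata.sample_ids)]
    if not common:
        raise DataModelError("matrix and metadata share no samples")
    n_dropped = (
        len(set(matrix.sample_ids) | set(metadata.sample_ids)) - len(common)
    )
    return matrix.subset_samples(common), metadata.subset(common), n_dropped
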