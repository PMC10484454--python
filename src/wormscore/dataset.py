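"""Tidy per-animal assay containers.

Every assay in the pipeline — viability (brood size / embryonic lethality),
swimming (body bends per second), nuclear migration, nuclear morphology
(blebs) and nuclear-envelope fluorescence — is carried as an
:class:`AssayDataset`: a pandas DataFrame of one row per animal (or per
nucleus, for fluorescence) plus the assay tag and free-form metadata. All
statistics and the scoring rubric consume this one container.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: assay tag -> required value columns and their dtypes/constraints
ASSAY_SCHEMAS: dict[str, dict[str, str]] = {
    "viability": {"brood_size": "count", "unhatched": "count"},
    "swimming": {"bbps": "nonneg_float"},
    "migration": {"mislocalized": "count", "nuclei_total": "count"},
    "morphology": {"blebs": "count"},
    "fluorescence": {"intensity": "float"},
}

ID_COLUMNS = ("genotype", "animal_id")


def normalize_genotype(label: str) -> str:
    """Canonicalize a genotype label: strip and collapse whitespace.

    Case is preserved (residue labels like ``Y59C`` are case-sensitive), but
    surrounding and repeated whitespace never distinguishes two strains.
    """
    return re.sub(r"\s+", " ", str(label).strip())


class SchemaError(ValueError):
    """A dataset does not match its assay schema; message names the cell."""


def _check_column(df: pd.DataFrame, col: str, kind: str, assay: str) -> None:
    if col not in df.columns:
        raise SchemaError(f"{assay} dataset is missing required column {col!r}")
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{assay} dataset column {col!r} has a non-numeric value "
            f"{df[col].iloc[row]!r} at row {row}"
        )
    if kind == "count":
        arr = vals.dropna()
        if ((arr < 0) | (arr != np.floor(arr))).any():
            idx = arr.index[(arr < 0) | (arr != np.floor(arr))][0]
            raise SchemaError(
                f"{assay} dataset column {col!r} must hold nonnegative integers; "
                f"found {df[col].loc[idx]!r} at row {int(idx)}"
            )
    elif kind == "nonneg_float":
        arr = vals.dropna()
        if (arr < 0).any():
            idx = arr.index[arr < 0][0]
            raise SchemaError(
                f"{assay} dataset column {col!r} must be nonnegative; "
                f"found {df[col].loc[idx]!r} at row {int(idx)}"
            )
    else:  # plain float: finite where present
        arr = vals.dropna()
        if not np.isfinite(arr.to_numpy(dtype=float)).all():
            raise SchemaError(f"{assay} dataset column {col!r} has non-finite values")


@dataclass
class AssayDataset:
    """One assay's per-animal records across genotypes.

    Parameters
    ----------
    assay
        One of ``viability``, ``swimming``, ``migration``, ``morphology``,
        ``fluorescence``.
    records
        Tidy table with at least ``genotype``, ``animal_id`` and the assay's
        value columns (see :data:`ASSAY_SCHEMAS`).
    metadata
        Units, provenance notes, extra columns preserved on read.
    """

    assay: str
    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assay not in ASSAY_SCHEMAS:
            raise ValueError(
                f"unknown assay {self.assay!r}; expected one of {sorted(ASSAY_SCHEMAS)}"
            )
        df = self.records.copy()
        for col in ID_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"{self.assay} dataset is missing column {col!r}")
        df["genotype"] = df["genotype"].map(normalize_genotype)
        for col, kind in ASSAY_SCHEMAS[self.assay].items():
            _check_column(df, col, kind, self.assay)
            df[col] = pd.to_numeric(df[col])
        if self.assay == "viability":
            over = df["unhatched"] > df["brood_size"]
            if over.any():
                row = int(np.flatnonzero(over.to_numpy())[0])
                raise SchemaError(
                    f"viability dataset row {row}: unhatched exceeds brood_size"
                )
        if self.assay == "migration":
            over = df["mislocalized"] > df["nuclei_total"]
            if over.any():
                row = int(np.flatnonzero(over.to_numpy())[0])
                raise SchemaError(
                    f"migration dataset row {row}: mislocalized exceeds nuclei_total"
                )
        self.records = df.reset_index(drop=True)

    @property
    def genotypes(self) -> list[str]:
        """Genotype labels in first-appearance order."""
        return list(dict.fromkeys(self.records["genotype"]))

    def group(self, genotype: str) -> pd.DataFrame:
        """Rows for one genotype (normalized label)."""
        g = normalize_genotype(genotype)
        return self.records[self.records["genotype"] == g]

    def values(self, genotype: str, column: str) -> np.ndarray:
        """Value column for one genotype as a float array (NaNs dropped)."""
        v = pd.to_numeric(self.group(genotype)[column], errors="coerce").dropna()
        return v.to_numpy(dtype=float)
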