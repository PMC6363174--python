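"""Shared data model for the plasma small-RNA pipeline.

Coordinates are 1-based inclusive throughout (the native convention of both
GFF3 and SAM), so no conversion happens inside the pipeline — only at format
boundaries, where there is none to do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

STRANDS = ("+", "-")

#: canonical column sets for the tabular inputs
META_COLUMNS = ["sample_id", "group", "compartment", "sex", "patient_id"]
SURVIVAL_COLUMNS = ["sample_id", "time", "event"]
CT_COLUMNS = ["sample_id", "assay", "replicate", "ct"]

GROUPS = ("healthy", "hcc")
COMPARTMENTS = ("plasma", "tumor", "normal", "cell", "medium")


@dataclass(frozen=True)
class MirnaSite:
    """One annotated mature-miRNA genomic interval.

    The same miRNA name may appear at multiple loci; duplicates are preserved
    at I/O time and pooled per name during counting.
    """

    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("miRNA site name must be non-empty")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(
                f"site {self.name}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"site {self.name}: 1-based start must be >= 1")


@dataclass(frozen=True)
class AlignmentRecord:
    """A mapped (or unmapped) small-RNA read, reduced to the fields the
    counting rule needs: reference interval and strand."""

    read_id: str
    chrom: Optional[str]
    start: Optional[int]  # 1-based inclusive leftmost mapped base
    end: Optional[int]  # 1-based inclusive rightmost mapped base
    strand: Optional[str]
    mapped: bool

    def __post_init__(self) -> None:
        if self.mapped:
            if self.chrom is None or self.start is None or self.end is None:
                raise ValueError(f"mapped read {self.read_id} lacks coordinates")
            if self.strand not in STRANDS:
                raise ValueError(
                    f"read {self.read_id}: strand must be '+' or '-'"
                )
            if self.start > self.end:
                raise ValueError(
                    f"read {self.read_id}: start {self.start} > end {self.end}"
                )
        else:
            if any(v is not None for v in (self.chrom, self.start, self.end)):
                raise ValueError(
                    f"unmapped read {self.read_id} must carry no coordinates"
                )


class CountMatrix:
    """miRNA x sample raw read counts plus an optional RPM view.

    ``counts`` is an integer DataFrame indexed by miRNA name with sample-id
    columns.  ``rpm`` (same shape) is populated by
    :func:`plasmir.quantify.normalize_rpm`; each sample column of ``rpm``
    sums to 1e6 whenever the sample has any miRNA-assigned reads.
    """

    def __init__(self, counts: pd.DataFrame, rpm: Optional[pd.DataFrame] = None):
        counts = counts.copy()
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate miRNA names: {dupes}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if counts.size:
            vals = counts.to_numpy()
            if not np.issubdtype(vals.dtype, np.number):
                raise ValueError("counts must be numeric")
            if (vals < 0).any():
                raise ValueError("counts must be non-negative")
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
        self.counts = counts.astype(np.int64) if counts.size else counts.astype(np.int64)
        if rpm is not None:
            if not rpm.index.equals(self.counts.index) or not rpm.columns.equals(
                self.counts.columns
            ):
                raise ValueError("rpm labels must match counts labels")
            if rpm.size and (rpm.to_numpy() < 0).any():
                raise ValueError("rpm must be non-negative")
            rpm = rpm.astype(float)
        self.rpm = rpm

    @property
    def mirna_names(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_mirnas(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def require_rpm(self) -> pd.DataFrame:
        if self.rpm is None:
            raise ValueError(
                "RPM view not populated; run quantify.normalize_rpm first"
            )
        return self.rpm

    def equals(self, other: "CountMatrix", rpm_rtol: float = 1e-9) -> bool:
        if not self.counts.equals(other.counts):
            return False
        if (self.rpm is None) != (other.rpm is None):
            return False
        if self.rpm is not None:
            return bool(
                np.allclose(
                    self.rpm.to_numpy(), other.rpm.to_numpy(), rtol=rpm_rtol, atol=0
                )
            )
        return True

    def __repr__(self) -> str:  # pragma: no cover
        state = "rpm" if self.rpm is not None else "raw"
        return f"CountMatrix({self.n_mirnas} miRNAs x {self.n_samples} samples, {state})"


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table (see ``META_COLUMNS``)."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    bad = set(meta["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    bad = set(meta["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise ValueError(f"unknown compartment labels: {sorted(bad)}")
    return meta


def validate_survival(surv: pd.DataFrame) -> pd.DataFrame:
    """Validate a survival table: sample_id, time (days, >=0), event in {0,1}."""
    missing = [c for c in SURVIVAL_COLUMNS if c not in surv.columns]
    if missing:
        raise ValueError(f"survival table missing columns: {missing}")
    if surv["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in survival table")
    if (surv["time"] < 0).any():
        raise ValueError("survival times must be non-negative")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (death)")
    return surv


def validate_ct(ct: pd.DataFrame) -> pd.DataFrame:
    """Validate a qPCR Ct table: sample_id, assay, replicate, ct (cycles)."""
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if not np.isfinite(ct["ct"].to_numpy(dtype=float)).all():
        raise ValueError("Ct values must be finite")
    return ct
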