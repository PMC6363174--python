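"""Readers and writers for the formats the pipeline touches.

GFF3 (miRBase dialect) and SAM are parsed with a deliberately small surface:
the counting rule needs only name, reference interval and strand, so only
those fields are interpreted.  The SAM reader accepts headerless files and
skips individually malformed records (with a counted warning) instead of
aborting the stream; tests cross-check its coordinate arithmetic against
pysam.  Tabular matrices and tables are plain TSV via pandas.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Union

import pandas as pd

from .model import (
    CT_COLUMNS,
    META_COLUMNS,
    SURVIVAL_COLUMNS,
    AlignmentRecord,
    CountMatrix,
    MirnaSite,
    validate_ct,
    validate_meta,
    validate_survival,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised for malformed GFF3/SAM input, naming the offending line."""


# ---------------------------------------------------------------------------
# GFF3 (miRBase dialect)
# ---------------------------------------------------------------------------

_ATTR_NAME = re.compile(r"(?:^|;)\s*Name=([^;]+)")
_ATTR_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gff3(path: PathLike, feature_type: str = "miRNA") -> List[MirnaSite]:
    """Read mature-miRNA sites from a GFF3 annotation.

    One :class:`MirnaSite` is returned per row whose third column equals
    ``feature_type``.  The name is taken from the ``Name=`` attribute,
    falling back to ``ID=``.  Duplicate names (multi-locus miRNAs) are
    preserved.
    """
    sites: List[MirnaSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if fields[2] != feature_type:
                continue
            chrom, start_s, end_s, strand, attrs = (
                fields[0],
                fields[3],
                fields[4],
                fields[6],
                fields[8],
            )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: malformed coordinates {start_s!r}/{end_s!r}"
                ) from None
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            m = _ATTR_NAME.search(attrs) or _ATTR_ID.search(attrs)
            if not m:
                raise ParseError(f"{path}:{lineno}: no Name= or ID= attribute")
            try:
                sites.append(MirnaSite(m.group(1).strip(), chrom, start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return sites


# ---------------------------------------------------------------------------
# SAM (coordinate fields only)
# ---------------------------------------------------------------------------

_CIGAR_OP = re.compile(r"(\d+)([MIDNSHP=X])")
#: CIGAR operations that consume reference bases
_REF_CONSUMING = set("MDN=X")


def cigar_reference_span(cigar: str) -> int:
    """Number of reference bases covered by a CIGAR string (M/D/N/=/X)."""
    if cigar == "*" or not cigar:
        raise ParseError(f"CIGAR {cigar!r} has no reference span")
    pos = 0
    span = 0
    for m in _CIGAR_OP.finditer(cigar):
        if m.start() != pos:
            raise ParseError(f"unparsable CIGAR {cigar!r}")
        pos = m.end()
        if m.group(2) in _REF_CONSUMING:
            span += int(m.group(1))
    if pos != len(cigar):
        raise ParseError(f"unparsable CIGAR {cigar!r}")
    if span == 0:
        raise ParseError(f"CIGAR {cigar!r} consumes no reference bases")
    return span


@dataclass
class SamReadStats:
    """Per-file record bookkeeping from :func:`read_sam`."""

    n_records: int = 0
    n_skipped: int = 0
    skipped_lines: List[int] = field(default_factory=list)


def read_sam(path: PathLike, stats: SamReadStats | None = None) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM file (header optional).

    Unmapped reads (flag 0x4) are yielded with ``mapped=False``.  The end
    coordinate is 1-based inclusive, computed from the reference span of the
    CIGAR.  Records with an unparsable CIGAR or truncated fields are skipped
    with a logged warning and counted in ``stats``.
    """
    own_stats = stats if stats is not None else SamReadStats()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                if len(fields) < 11:
                    raise ParseError("fewer than 11 mandatory SAM fields")
                qname, flag_s, rname, pos_s, _mapq, cigar = fields[:6]
                flag = int(flag_s)
                if flag & 0x4:
                    yield AlignmentRecord(qname, None, None, None, None, mapped=False)
                    own_stats.n_records += 1
                    continue
                pos = int(pos_s)
                if rname == "*" or pos <= 0:
                    raise ParseError("mapped record without valid RNAME/POS")
                end = pos + cigar_reference_span(cigar) - 1
                strand = "-" if flag & 0x10 else "+"
                yield AlignmentRecord(qname, rname, pos, end, strand, mapped=True)
                own_stats.n_records += 1
            except (ParseError, ValueError) as exc:
                own_stats.n_skipped += 1
                own_stats.skipped_lines.append(lineno)
                logger.warning("%s:%d: skipping record (%s)", path, lineno, exc)
    if own_stats.n_skipped:
        logger.warning(
            "%s: skipped %d malformed record(s)", path, own_stats.n_skipped
        )


# ---------------------------------------------------------------------------
# TSV matrices and tables
# ---------------------------------------------------------------------------

MIRNA_COLUMN = "mirna"


def _check_header_unique(path: PathLike) -> None:
    # pandas silently renames duplicate headers; check the raw line
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate column labels {sorted(dupes)}")


def read_counts(path: PathLike) -> CountMatrix:
    """Read a raw-count TSV (first column miRNA name, then sample columns)."""
    _check_header_unique(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = MIRNA_COLUMN
    return CountMatrix(df)


def write_counts(matrix: CountMatrix, path: PathLike) -> None:
    out = matrix.counts.copy()
    out.index.name = MIRNA_COLUMN
    out.to_csv(path, sep="\t")


def read_rpm(path: PathLike) -> pd.DataFrame:
    """Read an RPM TSV into a miRNA x sample DataFrame of floats."""
    _check_header_unique(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0]).astype(float)
    df.index.name = MIRNA_COLUMN
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate row or column labels")
    if df.size and (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative RPM values")
    return df


def write_rpm(rpm: pd.DataFrame, path: PathLike) -> None:
    out = rpm.copy()
    out.index.name = MIRNA_COLUMN
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_meta(path: PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    return validate_meta(meta)


def write_meta(meta: pd.DataFrame, path: PathLike) -> None:
    validate_meta(meta)[META_COLUMNS].to_csv(path, sep="\t", index=False)


def read_survival(path: PathLike) -> pd.DataFrame:
    surv = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "time": float, "event": int}
    )
    return validate_survival(surv)


def write_survival(surv: pd.DataFrame, path: PathLike) -> None:
    validate_survival(surv)[SURVIVAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ct(path: PathLike) -> pd.DataFrame:
    ct = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "assay": str, "replicate": int, "ct": float},
    )
    return validate_ct(ct)


def write_ct(ct: pd.DataFrame, path: PathLike) -> None:
    validate_ct(ct)[CT_COLUMNS].to_csv(path, sep="\t", index=False)
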