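"""Read counting against annotated miRNA sites, RPM normalization, and
expression filters.

The counting rule anchors the read's biological 5' end exactly on the site's
5' end and tolerates 3'-end trimming/extension between -1 and +3 nt.  On the
minus strand the biological 5' end is the genomic *end* coordinate, so the
tolerance window applies to the genomic start (transcript orientation; see
docs/methods.md).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .model import AlignmentRecord, CountMatrix, MirnaSite

logger = logging.getLogger(__name__)

AMBIGUOUS_POLICIES = ("count_all", "drop")


@dataclass(frozen=True)
class CountingPolicy:
    """Site-matching tolerances for small-RNA read assignment.

    The 5' end must match exactly; the 3' end may deviate from the annotated
    site end by ``three_prime_lower``..``three_prime_upper`` nt (defaults
    -1..+3).  Offsets are in transcript orientation.  ``ambiguous_read_policy``
    governs reads matching two or more distinct miRNA names.
    """

    five_prime_tolerance: int = 0
    three_prime_lower: int = -1
    three_prime_upper: int = 3
    require_strand_match: bool = True
    ambiguous_read_policy: str = "count_all"

    def __post_init__(self) -> None:
        if self.five_prime_tolerance != 0:
            raise ValueError("5' end matching is exact (tolerance fixed at 0)")
        if self.three_prime_lower > self.three_prime_upper:
            raise ValueError("three_prime_lower must be <= three_prime_upper")
        if self.ambiguous_read_policy not in AMBIGUOUS_POLICIES:
            raise ValueError(
                f"ambiguous_read_policy must be one of {AMBIGUOUS_POLICIES}"
            )


def match_read(
    read: AlignmentRecord, site: MirnaSite, policy: CountingPolicy = CountingPolicy()
) -> bool:
    """Does ``read`` count towards ``site`` under ``policy``?

    Plus-strand site: read.start == site.start and
    site.end + lower <= read.end <= site.end + upper.
    Minus-strand site: the window is mirrored onto the genomic start, anchored
    at the genomic end (the biological 5' end).
    """
    if not read.mapped:
        raise ValueError(f"read {read.read_id} is unmapped; filter before matching")
    if read.chrom != site.chrom:
        return False
    if policy.require_strand_match and read.strand != site.strand:
        return False
    lo, hi = policy.three_prime_lower, policy.three_prime_upper
    if site.strand == "+":
        return read.start == site.start and (
            site.end + lo <= read.end <= site.end + hi
        )
    return read.end == site.end and (
        site.start - hi <= read.start <= site.start - lo
    )


def _site_index(sites: Sequence[MirnaSite]):
    """Index sites by their 5'-anchor coordinate for O(1) candidate lookup."""
    plus: Dict[tuple, List[MirnaSite]] = {}
    minus: Dict[tuple, List[MirnaSite]] = {}
    for site in sites:
        if site.strand == "+":
            plus.setdefault((site.chrom, site.start), []).append(site)
        else:
            minus.setdefault((site.chrom, site.end), []).append(site)
    return plus, minus


def count_matrix(
    reads_by_sample: Mapping[str, Iterable[AlignmentRecord]],
    sites: Sequence[MirnaSite],
    policy: CountingPolicy = CountingPolicy(),
) -> CountMatrix:
    """Count reads per miRNA name and sample.

    Reads mapping to multiple loci of the *same* name are pooled: one read
    contributes at most 1 to each distinct name it matches.  Under
    ``ambiguous_read_policy="drop"``, a read matching >= 2 distinct names
    contributes nothing.
    """
    if not sites:
        raise ValueError("empty site list")
    # first-appearance order of names, deterministic
    names: List[str] = []
    seen: Set[str] = set()
    for site in sites:
        if site.name not in seen:
            seen.add(site.name)
            names.append(site.name)
    plus_idx, minus_idx = _site_index(sites)
    sample_ids = list(reads_by_sample)
    mat = np.zeros((len(names), len(sample_ids)), dtype=np.int64)
    row = {name: i for i, name in enumerate(names)}
    n_ambiguous = 0
    for j, sample in enumerate(sample_ids):
        for read in reads_by_sample[sample]:
            if not read.mapped:
                continue
            candidates = plus_idx.get((read.chrom, read.start), []) + minus_idx.get(
                (read.chrom, read.end), []
            )
            matched = {s.name for s in candidates if match_read(read, s, policy)}
            if len(matched) > 1:
                n_ambiguous += 1
                if policy.ambiguous_read_policy == "drop":
                    continue
            for name in matched:
                mat[row[name], j] += 1
    if n_ambiguous:
        logger.info(
            "%d read(s) matched >=2 distinct miRNA names (policy=%s)",
            n_ambiguous,
            policy.ambiguous_read_policy,
        )
    return CountMatrix(pd.DataFrame(mat, index=names, columns=sample_ids))


def normalize_rpm(matrix: CountMatrix) -> CountMatrix:
    """Reads-per-million normalization.

    Each count is divided by the sample's total miRNA-assigned reads and
    scaled by 1e6, so every non-empty sample column sums to 1e6.  The
    denominator is the total of reads assigned to miRNAs, not the library
    size.  Samples with zero total get all-zero RPM and a warning.
    """
    counts = matrix.counts
    totals = counts.sum(axis=0).astype(float)
    zero = totals == 0
    if zero.any():
        logger.warning(
            "samples with zero miRNA reads get all-zero RPM: %s",
            list(counts.columns[zero]),
        )
    safe = totals.replace(0, np.nan)
    rpm = (counts / safe * 1e6).fillna(0.0)
    return CountMatrix(counts, rpm)


def filter_expressed(
    matrix: CountMatrix,
    samples: Optional[Sequence[str]] = None,
    min_rpm: float = 10.0,
) -> Set[str]:
    """miRNAs expressed (RPM strictly > ``min_rpm``) in any of ``samples``."""
    rpm = matrix.require_rpm()
    if samples is not None:
        rpm = rpm[list(samples)]
    mask = (rpm > min_rpm).any(axis=1)
    return set(rpm.index[mask])


def filter_prevalent(
    matrix: CountMatrix,
    min_rpm: float = 10.0,
    min_fraction: float = 0.10,
    samples: Optional[Sequence[str]] = None,
) -> Set[str]:
    """miRNAs with RPM > ``min_rpm`` in at least ``min_fraction`` of samples.

    The sample threshold is ``ceil(min_fraction * n_samples)``, so with ten
    samples and the default 10% one qualifying sample suffices.
    """
    rpm = matrix.require_rpm()
    if samples is not None:
        rpm = rpm[list(samples)]
    needed = math.ceil(min_fraction * rpm.shape[1])
    n_passing = (rpm > min_rpm).sum(axis=1)
    return set(rpm.index[n_passing >= needed])
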