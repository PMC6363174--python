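"""Inter-individual heterogeneity of plasma miRNA profiles.

Healthy plasma profiles are nearly interchangeable between subjects (pairwise
Pearson R close to 1, dominated by a single highly abundant miRNA), while
patient profiles diverge.  This module quantifies that contrast three ways:
the distribution of pairwise correlations per group (compared by a one-way
ANOVA F-test), per-subject top-k abundance lists with a shared-fraction
statistic (|intersection| / |union| of the lists), and exhaustive enumeration
of equal-size patient subsets so group sizes do not confound the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .model import CountMatrix
from .quantify import filter_expressed

logger = logging.getLogger(__name__)


@dataclass
class CorrelationSet:
    """All pairwise Pearson coefficients within one sample group."""

    group: str
    pairs: List[Tuple[str, str, float]]  # (sample_a, sample_b, r); r NaN if undefined

    @property
    def values(self) -> np.ndarray:
        """Defined r values (NaN pairs dropped)."""
        r = np.array([p[2] for p in self.pairs], dtype=float)
        return r[~np.isnan(r)]


@dataclass
class SharedFractionResult:
    """Shared-top-k statistic for one subject subset."""

    subset: Tuple[str, ...]
    k: int
    union_size: int
    intersection_size: int

    @property
    def percent_shared(self) -> float:
        if self.union_size == 0:
            return float("nan")
        return 100.0 * self.intersection_size / self.union_size


def pairwise_r(
    matrix: CountMatrix,
    samples: Sequence[str],
    group: str = "",
    log_scale: bool = False,
) -> CorrelationSet:
    """Pearson correlation for every unordered sample pair.

    For each pair the miRNA universe is the union of miRNAs with nonzero RPM
    in either sample.  ``log_scale`` computes r on log2(RPM+1) instead of raw
    RPM.  A constant vector makes r undefined; the pair is recorded with NaN
    and a warning.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples for pairwise correlation")
    rpm = matrix.require_rpm()[list(samples)]
    vals = np.log2(rpm + 1.0) if log_scale else rpm
    pairs: List[Tuple[str, str, float]] = []
    for a, b in combinations(samples, 2):
        x, y = vals[a].to_numpy(float), vals[b].to_numpy(float)
        mask = (rpm[a].to_numpy(float) > 0) | (rpm[b].to_numpy(float) > 0)
        x, y = x[mask], y[mask]
        if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("pair (%s, %s): correlation undefined", a, b)
            pairs.append((a, b, float("nan")))
            continue
        r = float(stats.pearsonr(x, y).statistic)
        pairs.append((a, b, r))
    return CorrelationSet(group=group, pairs=pairs)


def compare_groups_anova(
    set_a: CorrelationSet, set_b: CorrelationSet
) -> Tuple[float, float]:
    """One-way ANOVA F-test between two groups of correlation coefficients.

    With two groups F equals the squared pooled-variance t statistic.  If the
    within-group variance is zero the statistic degenerates: F=0, p=1 when
    the group means coincide, else F=+inf, p=0.
    """
    a, b = set_a.values, set_b.values
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 defined correlation values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    res = stats.f_oneway(a, b)
    return float(res.statistic), float(res.pvalue)


def top_k(matrix: CountMatrix, sample: str, k: int = 20) -> List[str]:
    """The k most abundant miRNAs of one sample, by RPM.

    Ties are broken by lexicographic name so the list is deterministic; a tie
    straddling the k-boundary is logged.
    """
    rpm = matrix.require_rpm()[sample]
    order = sorted(rpm.index, key=lambda name: (-rpm[name], name))
    if k < len(order) and rpm[order[k - 1]] == rpm[order[k]]:
        logger.info(
            "sample %s: tie at rank %d broken lexicographically", sample, k
        )
    return order[:k]


def shared_fraction(
    matrix: CountMatrix, subset: Sequence[str], k: int = 20
) -> SharedFractionResult:
    """Union/intersection of the subset's top-k lists and the shared percent."""
    if not subset:
        raise ValueError("empty subject subset")
    lists = [set(top_k(matrix, s, k)) for s in subset]
    union: Set[str] = set().union(*lists)
    inter: Set[str] = set.intersection(*lists)
    return SharedFractionResult(
        subset=tuple(subset),
        k=k,
        union_size=len(union),
        intersection_size=len(inter),
    )


def enumerate_subsets(
    matrix: CountMatrix,
    group_samples: Sequence[str],
    subset_size: int = 4,
    k: int = 20,
) -> List[SharedFractionResult]:
    """Shared-fraction statistic for every subset of ``subset_size`` subjects.

    Complete enumeration — exactly C(n, subset_size) results in lexicographic
    order of sample ids, no randomness.
    """
    if subset_size < 1:
        raise ValueError("subset_size must be >= 1")
    if subset_size > len(group_samples):
        raise ValueError("subset_size exceeds group size")
    ordered = sorted(group_samples)
    results = [
        shared_fraction(matrix, subset, k)
        for subset in combinations(ordered, subset_size)
    ]
    assert len(results) == comb(len(ordered), subset_size)
    return results


def venn_counts(
    matrix: CountMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    min_rpm: float = 10.0,
) -> Tuple[int, int, int]:
    """Partition expressed miRNAs of two sample groups into (only_a, only_b, both)."""
    set_a = filter_expressed(matrix, samples_a, min_rpm)
    set_b = filter_expressed(matrix, samples_b, min_rpm)
    both = set_a & set_b
    return len(set_a - both), len(set_b - both), len(both)
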