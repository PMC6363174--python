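"""Negative-binomial differential expression and the biomarker cascade.

Counts are normalized by median-of-ratios size factors.  Per-miRNA
dispersion is estimated by the method of moments on the pooled within-group
variance of normalized counts, alpha = max(0, (v - mu*xi) / mu^2) with
xi = mean(1/s_j) accounting for the Poisson component, then floored by a
mean-dispersion trend a0 + a1/mu fit across miRNAs.  The two-sided test is a
Wald test on the log2 fold change of group means with NB variance
mu/s + alpha*mu^2, which reduces to a Poisson Wald test as alpha -> 0.

The biomarker cascade reproduces a three-stage selection: (1) significance
and effect size (|log2FC| > 1, adjusted p < 0.05), (2) abundance in the
patient group (baseMean above a detection floor so qPCR validation is
feasible), (3) the strongest effects, a fixed number up- and down-regulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: columns of the DE result frame
DE_COLUMNS = [
    "baseMean",
    "baseMean_group1",
    "baseMean_group2",
    "log2fc",
    "dispersion",
    "pvalue",
    "padj",
    "direction",
]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For every sample, the factor is the median across miRNAs (restricted to
    miRNAs with a nonzero geometric mean, i.e. no zero count) of the ratio
    count / geometric-mean-count.  Falls back to all-ones with a warning if
    no miRNA is everywhere nonzero.
    """
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(arr)
    logc[arr == 0] = np.nan
    loggeo = logc.mean(axis=1)
    ok = np.isfinite(loggeo)
    if not ok.any():
        logger.warning("no miRNA with all-nonzero counts; size factors set to 1")
        return pd.Series(1.0, index=counts.columns)
    ratios = np.exp(logc[ok] - loggeo[ok, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment with NA propagation.

    NaN entries (untested miRNAs) are excluded from the denominator and
    returned as NaN, mirroring independent-filtering practice.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _dispersion_trend(mu: np.ndarray, raw_alpha: np.ndarray) -> np.ndarray:
    """Fit the mean-dispersion trend alpha ~ a0 + a1/mu.

    Fit by least squares on the positive gene-wise moment estimates, with
    iterative trimming of genes whose estimate deviates from the fitted
    curve by more than 15x (or less than 1e-4x) so that the handful of
    near-zero-mean genes with astronomical moment estimates cannot inflate
    the curve.  Returns the fitted value per gene, clipped at zero.
    """
    mask = (mu > 0) & (raw_alpha > 0)
    if mask.sum() < 10:
        return np.zeros_like(mu)
    x = 1.0 / mu[mask]
    y = raw_alpha[mask]
    keep = np.ones(len(y), dtype=bool)
    coef = np.zeros(2)
    weights = np.ones(len(y))
    # IRLS with 1/fitted^2 weights: minimizes *relative* squared error, so
    # genes with small dispersion count as much as genes with huge one
    # (moment-estimate noise scales with the dispersion itself)
    for _ in range(10):
        X = np.column_stack([np.ones(int(keep.sum())), x[keep]])
        w = np.sqrt(weights[keep])
        coef, *_ = np.linalg.lstsq(X * w[:, None], y[keep] * w, rcond=None)
        coef = np.clip(coef, 0.0, None)
        fitted = np.clip(coef[0] + coef[1] * x, 1e-12, None)
        weights = 1.0 / fitted**2
        ratio = y / fitted
        new_keep = (ratio > 1e-4) & (ratio < 15.0)
        if new_keep.sum() < 10:
            break
        keep = new_keep
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.where(mu > 0, mu, np.inf)
    return np.clip(trend, 0.0, None)


def nb_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    group_order: Optional[Tuple[str, str]] = None,
    padj_cut: float = 0.05,
    lfc_cut: float = 1.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Two-group NB Wald differential-expression test.

    Parameters
    ----------
    counts
        Raw counts, miRNA x sample.
    groups
        sample id -> group label (exactly two labels).
    group_order
        (group1, group2); log2fc is log2(group2 / group1).  Defaults to the
        sorted label order.
    padj_cut, lfc_cut
        Thresholds used only for the ``direction`` column (up/down/ns).

    Returns a DataFrame indexed by miRNA with ``DE_COLUMNS``.  miRNAs with
    zero counts in both groups get pvalue and padj of NaN and are excluded
    from the BH denominator.
    """
    labels = sorted(set(groups[s] for s in counts.columns))
    if group_order is None:
        if len(labels) != 2:
            raise ValueError(f"expected exactly 2 group labels, got {labels}")
        group_order = (labels[0], labels[1])
    g1 = [s for s in counts.columns if groups[s] == group_order[0]]
    g2 = [s for s in counts.columns if groups[s] == group_order[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(
            "each group needs >= 2 replicate samples for dispersion estimation"
        )
    sf = size_factors(counts)
    norm = counts / sf
    n1, n2 = len(g1), len(g2)
    m1 = norm[g1].mean(axis=1).to_numpy()
    m2 = norm[g2].mean(axis=1).to_numpy()
    mu = norm.mean(axis=1).to_numpy()
    v1 = norm[g1].var(axis=1, ddof=1).to_numpy()
    v2 = norm[g2].var(axis=1, ddof=1).to_numpy()
    v = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    xi = float(np.mean(1.0 / sf.to_numpy()))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_alpha = np.where(mu > 0, (v - mu * xi) / np.where(mu > 0, mu, 1) ** 2, 0.0)
    alpha_gene = np.clip(raw_alpha, 0.0, None)
    alpha = np.maximum(alpha_gene, _dispersion_trend(mu, raw_alpha))

    lfc = np.log2((m2 + pseudocount) / (m1 + pseudocount))
    inv1 = float(np.sum(1.0 / sf[g1].to_numpy()))
    inv2 = float(np.sum(1.0 / sf[g2].to_numpy()))
    mu1 = np.maximum(m1, pseudocount)
    mu2 = np.maximum(m2, pseudocount)
    var_m1 = (mu1 * inv1 + alpha * mu1**2 * n1) / n1**2
    var_m2 = (mu2 * inv2 + alpha * mu2**2 * n2) / n2**2
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_m1 / (ln2 * (m1 + pseudocount)) ** 2
        + var_m2 / (ln2 * (m2 + pseudocount)) ** 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))
    untested = (m1 == 0) & (m2 == 0)
    pvalue = np.where(untested, np.nan, pvalue)
    padj = bh_adjust(pvalue)

    direction = np.full(len(mu), "ns", dtype=object)
    sig = (padj < padj_cut) & ~np.isnan(padj)
    direction[sig & (lfc > lfc_cut)] = "up"
    direction[sig & (lfc < -lfc_cut)] = "down"

    res = pd.DataFrame(
        {
            "baseMean": mu,
            "baseMean_group1": m1,
            "baseMean_group2": m2,
            "log2fc": lfc,
            "dispersion": alpha,
            "pvalue": pvalue,
            "padj": padj,
            "direction": direction,
        },
        index=counts.index,
    )
    res.attrs["group1"], res.attrs["group2"] = group_order
    return res


@dataclass
class BiomarkerPanel:
    """Result of the three-stage biomarker selection cascade."""

    candidates_stage1: List[str] = field(default_factory=list)
    candidates_stage2: List[str] = field(default_factory=list)
    panel_up: List[str] = field(default_factory=list)
    panel_down: List[str] = field(default_factory=list)

    @property
    def panel(self) -> List[str]:
        return self.panel_up + self.panel_down

    def check_nested(self) -> None:
        assert set(self.panel) <= set(self.candidates_stage2)
        assert set(self.candidates_stage2) <= set(self.candidates_stage1)


def select_biomarkers(
    results: pd.DataFrame,
    min_base: float = 10.0,
    n_up: int = 5,
    n_down: int = 2,
    padj_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> BiomarkerPanel:
    """Three-stage biomarker cascade on a DE result frame.

    Stage 1: |log2fc| > ``lfc_cut`` and padj < ``padj_cut``.
    Stage 2: stage 1 restricted to baseMean_group2 > ``min_base`` (abundant
    enough in the patient group for qPCR validation).
    Panel: the ``n_up`` largest and ``n_down`` most negative log2fc among
    stage-2 candidates ("most variant" = largest |log2fc|); ties broken by
    name.  Stages are verified nested on every call.
    """
    ok = results["padj"].notna()
    s1_mask = ok & (results["padj"] < padj_cut) & (results["log2fc"].abs() > lfc_cut)
    stage1 = results.index[s1_mask]
    s2_mask = s1_mask & (results["baseMean_group2"] > min_base)
    stage2 = results.index[s2_mask]
    if len(stage2) == 0:
        logger.warning("no miRNA passed the biomarker cascade; empty panel")
    sub = results.loc[stage2]
    up = sub[sub["log2fc"] > 0]
    down = sub[sub["log2fc"] < 0]
    up_rank = sorted(up.index, key=lambda m: (-up.at[m, "log2fc"], m))
    down_rank = sorted(down.index, key=lambda m: (down.at[m, "log2fc"], m))
    panel = BiomarkerPanel(
        candidates_stage1=sorted(stage1),
        candidates_stage2=sorted(stage2),
        panel_up=up_rank[:n_up],
        panel_down=down_rank[:n_down],
    )
    panel.check_nested()
    return panel


def cluster_samples(
    rpm: pd.DataFrame, mirna_subset: Optional[Sequence[str]] = None
) -> Tuple[List[str], Dict[str, int]]:
    """Hierarchical clustering of samples with correlation distance.

    Distance = 1 - Pearson r between sample expression vectors; average
    linkage.  Returns the dendrogram leaf order and the 2-group cut as a
    sample -> {1, 2} mapping.
    """
    if mirna_subset is not None:
        rpm = rpm.loc[list(mirna_subset)]
    samples = list(rpm.columns)
    if len(samples) == 1:
        return samples, {samples[0]: 1}
    corr = np.corrcoef(rpm.to_numpy(dtype=float).T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [samples[i] for i in hierarchy.leaves_list(link)]
    cut = hierarchy.fcluster(link, t=2, criterion="maxclust")
    return order, {s: int(c) for s, c in zip(samples, cut)}
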