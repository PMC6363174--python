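"""Plasma-vs-tissue fold-change concordance and qPCR relative quantification.

If tumor cells dumped their miRNA content into circulation unselectively, the
direction of change of a marker in patient plasma (vs healthy plasma) would
track its direction in tumor tissue (vs adjacent normal).  This module
computes both families of per-sample fold changes — with a +0.01 guard
against zero denominators — summarizes them as boxplot statistics, and calls
a *direction reversal* when the median log2 fold changes disagree in sign.
It also implements 2^-ddCt relative quantification for qRT-PCR validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GUARD = 0.01
GUARD_MODES = ("both", "denominator-only")

FC_COLUMNS = ["mirna", "context", "unit_id", "fc", "log2fc"]


def _guarded_ratio(num: np.ndarray, den: np.ndarray, mode: str) -> np.ndarray:
    """fc = num/den with +0.01 added to zero denominators (and, in the
    default symmetric mode, to zero numerators so log2fc stays finite)."""
    if mode not in GUARD_MODES:
        raise ValueError(f"guard mode must be one of {GUARD_MODES}")
    num = np.asarray(num, dtype=float).copy()
    den = np.asarray(den, dtype=float).copy()
    n_guard = int((den == 0).sum())
    den[den == 0] += GUARD
    if mode == "both":
        n_guard += int((num == 0).sum())
        num[num == 0] += GUARD
    if n_guard:
        logger.info("fold-change guard applied to %d zero value(s)", n_guard)
    return num / den


def plasma_fc(
    rpm: pd.DataFrame,
    hcc_samples: Sequence[str],
    healthy_samples: Sequence[str],
    mirnas: Optional[Sequence[str]] = None,
    guard_mode: str = "both",
) -> pd.DataFrame:
    """Per-(miRNA, patient sample) fold change vs the healthy-plasma mean."""
    rows = rpm.index if mirnas is None else list(mirnas)
    sub = rpm.loc[rows]
    healthy_mean = sub[list(healthy_samples)].mean(axis=1).to_numpy()
    out = []
    for s in hcc_samples:
        fc = _guarded_ratio(sub[s].to_numpy(), healthy_mean, guard_mode)
        out.append(
            pd.DataFrame(
                {
                    "mirna": sub.index,
                    "context": "plasma_vs_healthy_mean",
                    "unit_id": s,
                    "fc": fc,
                }
            )
        )
    res = pd.concat(out, ignore_index=True) if out else pd.DataFrame(columns=FC_COLUMNS)
    if len(res):
        res["log2fc"] = np.log2(res["fc"])
    return res


def tissue_fc(
    rpm: pd.DataFrame,
    pairs: Sequence[Tuple[str, str, str]],
    mirnas: Optional[Sequence[str]] = None,
    guard_mode: str = "both",
) -> pd.DataFrame:
    """Per-(miRNA, patient) tumor/normal fold change.

    ``pairs`` is a sequence of (tumor_sample, normal_sample, patient_id).
    """
    rows = rpm.index if mirnas is None else list(mirnas)
    sub = rpm.loc[rows]
    out = []
    for tumor, normal, patient in pairs:
        fc = _guarded_ratio(sub[tumor].to_numpy(), sub[normal].to_numpy(), guard_mode)
        out.append(
            pd.DataFrame(
                {
                    "mirna": sub.index,
                    "context": "tumor_vs_normal_paired",
                    "unit_id": patient,
                    "fc": fc,
                }
            )
        )
    res = pd.concat(out, ignore_index=True) if out else pd.DataFrame(columns=FC_COLUMNS)
    if len(res):
        res["log2fc"] = np.log2(res["fc"])
    return res


def fc_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Boxplot summary per miRNA, ordered by median fold change (descending).

    Quartiles use linear interpolation; whiskers are the Tukey rule (the most
    extreme points within 1.5 IQR of the box edges).
    """
    out = []
    for mirna, grp in records.groupby("mirna", sort=False):
        fc = grp["fc"].to_numpy(dtype=float)
        q25, med, q75 = np.percentile(fc, [25, 50, 75])
        iqr = q75 - q25
        in_lo = fc[fc >= q25 - 1.5 * iqr]
        in_hi = fc[fc <= q75 + 1.5 * iqr]
        out.append(
            {
                "mirna": mirna,
                "n": len(fc),
                "median": med,
                "q25": q25,
                "q75": q75,
                "whisker_lo": in_lo.min() if len(in_lo) else np.nan,
                "whisker_hi": in_hi.max() if len(in_hi) else np.nan,
                "median_log2fc": np.median(grp["log2fc"].to_numpy(dtype=float)),
            }
        )
    summary = pd.DataFrame(out)
    if len(summary):
        summary = summary.sort_values("median", ascending=False).reset_index(drop=True)
    return summary


@dataclass
class ReversalCall:
    mirna: str
    median_log2fc_plasma: float
    median_log2fc_tissue: float

    @property
    def reversed(self) -> bool:
        """Opposite signs of the two median log2 fold changes; an exact zero
        median is treated as non-reversed."""
        return self.median_log2fc_plasma * self.median_log2fc_tissue < 0


def call_reversals(
    plasma_summary: pd.DataFrame,
    tissue_summary: pd.DataFrame,
    mirnas: Optional[Sequence[str]] = None,
) -> List[ReversalCall]:
    """Direction-reversal calls for miRNAs present in both summaries."""
    p = plasma_summary.set_index("mirna")["median_log2fc"]
    t = tissue_summary.set_index("mirna")["median_log2fc"]
    shared = [m for m in p.index if m in t.index]
    if mirnas is not None:
        shared = [m for m in shared if m in set(mirnas)]
    return [ReversalCall(m, float(p[m]), float(t[m])) for m in shared]


def ddct(
    ct: pd.DataFrame,
    target: str,
    control_assay: str,
    case_id: str,
    ref_id: str,
) -> Dict[str, float]:
    """Relative quantification by the 2^-ddCt method.

    Replicates are averaged per (sample, assay) first.  dCt = Ct(target) -
    Ct(control); ddCt = dCt(case) - dCt(ref); fold = 2^-ddCt.  A fold > 1
    means the target is more abundant in the case sample.
    """

    def mean_ct(sample: str, assay: str, required: bool) -> float:
        sel = ct[(ct["sample_id"] == sample) & (ct["assay"] == assay)]["ct"]
        if sel.empty:
            if required:
                raise ValueError(f"no {assay!r} Ct values for sample {sample!r}")
            logger.warning("no %r replicates for %r", assay, sample)
            return float("nan")
        return float(sel.mean())

    dct_case = mean_ct(case_id, target, True) - mean_ct(case_id, control_assay, True)
    dct_ref = mean_ct(ref_id, target, True) - mean_ct(ref_id, control_assay, True)
    ddct_val = dct_case - dct_ref
    return {
        "dct_case": dct_case,
        "dct_ref": dct_ref,
        "ddct": ddct_val,
        "fold": 2.0 ** (-ddct_val),
    }
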