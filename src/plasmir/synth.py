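"""Synthetic cohort generator.

Emulates the statistical structure of a plasma small-RNA biomarker study of
hepatocellular carcinoma (HCC) so every pipeline stage can be exercised and
validated against planted ground truth:

* a small healthy group whose plasma profiles are nearly identical and
  dominated by one miRNA (miR-486-5p at ~60% of miRNA-assigned reads);
* a larger, heterogeneous patient group with planted up/down-regulated
  plasma markers (the dominant miRNA itself is planted down, as observed in
  patient plasma);
* a paired tumor/normal tissue cohort in which a chosen subset of the
  plasma markers reverses direction (the selective-secretion signature);
* survival times whose hazard is tied to the tumor expression of chosen
  markers.

The generative family is Dirichlet-multinomial with a reproducibility floor:
per-sample compositions are built from independent Gamma variates with shape
max(concentration * proportion, min_component_shape) and normalized.  For
abundant miRNAs this is exactly a Dirichlet whose concentration controls
inter-individual heterogeneity (high = homogeneous, healthy-like; low =
heterogeneous, patient-like); the shape floor keeps rare miRNAs from
degenerating into all-or-nothing dropout across subjects, which real plasma
profiles do not show.  Counts are multinomial given a lognormal library
size.  All randomness flows through one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import AlignmentRecord, CountMatrix, MirnaSite
from .quantify import CountingPolicy, normalize_rpm

DEFAULT_PLANTED_UP = {
    "hsa-miR-21-5p": 3.5,
    "hsa-miR-221-3p": 3.0,
    "hsa-miR-222-3p": 3.0,
    "hsa-miR-1271-5p": 2.5,
    "hsa-miR-1180-3p": 2.5,
}
DEFAULT_PLANTED_DOWN = {
    "hsa-miR-486-5p": -2.5,
    "hsa-miR-486-3p": -3.0,
}
DEFAULT_REVERSALS = ("hsa-miR-21-5p", "hsa-miR-1271-5p", "hsa-miR-486-3p")
DEFAULT_SURVIVAL_EFFECTS = {
    "hsa-miR-21-5p": 6.0,
    "hsa-miR-221-3p": 6.0,
    "hsa-miR-486-5p": 1.0 / 6.0,
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic study.

    Concentrations are Dirichlet precision parameters: the healthy default
    (10000) makes plasma profiles nearly interchangeable between subjects,
    the patient default (100) produces the broad pairwise-correlation spread
    seen in heterogeneous cohorts.  Planted effects are log2 fold changes of
    patient vs healthy plasma composition; tissue effects have the same
    magnitude, with the sign flipped for ``planted_reversals``.  Survival
    hazard is scaled by ``survival_marker_effects`` (hazard ratios between
    high and low tumor expression of the marker).
    """

    n_healthy: int = 4
    n_hcc: int = 10
    n_mirnas: int = 300
    library_size_mean: float = 1_000_000.0
    library_size_cv: float = 0.1
    dominant_mirna: str = "hsa-miR-486-5p"
    dominant_proportion: float = 0.60
    healthy_concentration: float = 10000.0
    hcc_concentration: float = 100.0
    tissue_concentration: float = 200.0
    min_component_shape: float = 4.0
    planted_up: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_UP)
    )
    planted_down: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_DOWN)
    )
    planted_reversals: Tuple[str, ...] = DEFAULT_REVERSALS
    survival_marker_effects: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SURVIVAL_EFFECTS)
    )
    n_tissue_pairs: int = 80
    base_hazard: float = 1.0 / 1500.0  # events per day at the reference level
    censor_low: float = 500.0  # administrative censoring window (days)
    censor_high: float = 3000.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.dominant_proportion < 1:
            raise ValueError("dominant_proportion must lie in (0, 1)")
        if self.n_healthy < 2 or self.n_hcc < 2:
            raise ValueError("need >= 2 samples per plasma group")
        planted = set(self.planted_up) | set(self.planted_down)
        if set(self.planted_up) & set(self.planted_down):
            raise ValueError("a marker cannot be planted both up and down")
        if not set(self.planted_reversals) <= planted:
            raise ValueError("planted_reversals must be planted markers")
        if not set(self.survival_marker_effects) <= planted:
            raise ValueError("survival markers must be planted markers")
        for name, eff in {**self.planted_up, **self.planted_down}.items():
            if not np.isfinite(eff):
                raise ValueError(f"non-finite effect for {name}")
        if len(planted) + 1 > self.n_mirnas:
            raise ValueError("n_mirnas too small for the planted markers")


@dataclass
class CohortData:
    """One simulated study, plus the planted-truth ledger for recovery tests."""

    plasma: CountMatrix
    tissue: CountMatrix
    meta: pd.DataFrame
    survival: pd.DataFrame
    tissue_pairs: List[Tuple[str, str, str]]
    truth: Dict

    @property
    def healthy_samples(self) -> List[str]:
        m = self.meta
        return list(m.loc[(m["group"] == "healthy") & (m["compartment"] == "plasma"),
                          "sample_id"])

    @property
    def hcc_samples(self) -> List[str]:
        m = self.meta
        return list(m.loc[(m["group"] == "hcc") & (m["compartment"] == "plasma"),
                          "sample_id"])


def _mirna_names(spec: CohortSpec) -> List[str]:
    planted = list(spec.planted_up) + [
        m for m in spec.planted_down if m != spec.dominant_mirna
    ]
    names = [spec.dominant_mirna] + planted
    i = 1
    while len(names) < spec.n_mirnas:
        cand = f"hsa-miR-sim-{i:04d}"
        if cand not in names:
            names.append(cand)
        i += 1
    return names


def _baseline(
    rng: np.random.Generator, names: Sequence[str], dominant: str, dom_prop: float,
    planted: Sequence[str], planted_floor: Tuple[float, float] = (0.002, 0.01),
) -> np.ndarray:
    """Skewed baseline composition: fixed dominant share, planted markers at
    qPCR-detectable abundance, the rest lognormal-weighted."""
    weights = rng.lognormal(mean=0.0, sigma=1.5, size=len(names))
    base = pd.Series(weights, index=list(names))
    base[dominant] = 0.0
    planted_props = {
        m: rng.uniform(*planted_floor) for m in planted if m != dominant
    }
    for m in planted_props:
        base[m] = 0.0
    rest_total = 1.0 - dom_prop - sum(planted_props.values())
    base = base / base.sum() * rest_total
    for m, p in planted_props.items():
        base[m] = p
    base[dominant] = dom_prop
    return base.to_numpy()


def _apply_effects(
    baseline: np.ndarray, names: Sequence[str], effects: Mapping[str, float]
) -> np.ndarray:
    """Scale planted components by 2^effect and renormalize (composition
    closure: the renormalization itself shifts all components, as in real
    compositional data)."""
    out = baseline.copy()
    idx = {n: i for i, n in enumerate(names)}
    for name, eff in effects.items():
        out[idx[name]] *= 2.0**eff
    return out / out.sum()


def _sample_counts(
    rng: np.random.Generator, baseline: np.ndarray, concentration: float,
    n_samples: int, lib_mean: float, lib_cv: float, min_shape: float = 2.0,
) -> np.ndarray:
    """Floored-Dirichlet multinomial sampling (see module docstring)."""
    sigma = np.sqrt(np.log(1.0 + lib_cv**2))
    mu = np.log(lib_mean) - sigma**2 / 2.0
    shapes = np.maximum(concentration * baseline, min_shape)
    scales = baseline / shapes
    counts = np.empty((len(baseline), n_samples), dtype=np.int64)
    for j in range(n_samples):
        g = rng.gamma(shapes) * scales
        props = g / g.sum()
        lib = max(1, int(round(rng.lognormal(mu, sigma))))
        counts[:, j] = rng.multinomial(lib, props)
    return counts


def simulate_cohort(spec: CohortSpec = CohortSpec()) -> CohortData:
    """Simulate plasma and tissue cohorts with planted ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = _mirna_names(spec)
    planted_effects = {**spec.planted_up, **spec.planted_down}
    planted = list(planted_effects)

    healthy_base = _baseline(
        rng, names, spec.dominant_mirna, spec.dominant_proportion, planted
    )
    hcc_base = _apply_effects(healthy_base, names, planted_effects)

    healthy_ids = [f"H{i + 1:02d}" for i in range(spec.n_healthy)]
    hcc_ids = [f"P{i + 1:02d}" for i in range(spec.n_hcc)]
    plasma_counts = np.hstack(
        [
            _sample_counts(rng, healthy_base, spec.healthy_concentration,
                           spec.n_healthy, spec.library_size_mean, spec.library_size_cv,
                           spec.min_component_shape),
            _sample_counts(rng, hcc_base, spec.hcc_concentration,
                           spec.n_hcc, spec.library_size_mean, spec.library_size_cv,
                           spec.min_component_shape),
        ]
    )
    plasma = normalize_rpm(
        CountMatrix(pd.DataFrame(plasma_counts, index=names,
                                 columns=healthy_ids + hcc_ids))
    )

    # tissue: its own baseline (plasma dominance does not carry over), tumor
    # effects concordant with plasma except for the planted reversals
    tissue_base = _baseline(rng, names, spec.dominant_mirna, 0.05, planted)
    tissue_effects = {
        name: (-eff if name in spec.planted_reversals else eff)
        for name, eff in planted_effects.items()
    }
    tumor_base = _apply_effects(tissue_base, names, tissue_effects)
    patients = [f"PT{i + 1:02d}" for i in range(spec.n_tissue_pairs)]
    tumor_ids = [f"{p}_T" for p in patients]
    normal_ids = [f"{p}_N" for p in patients]
    tumor_counts = _sample_counts(rng, tumor_base, spec.tissue_concentration,
                                  spec.n_tissue_pairs, spec.library_size_mean,
                                  spec.library_size_cv, spec.min_component_shape)
    normal_counts = _sample_counts(rng, tissue_base, spec.tissue_concentration,
                                   spec.n_tissue_pairs, spec.library_size_mean,
                                   spec.library_size_cv, spec.min_component_shape)
    tissue = normalize_rpm(
        CountMatrix(pd.DataFrame(np.hstack([tumor_counts, normal_counts]),
                                 index=names, columns=tumor_ids + normal_ids))
    )
    tissue_pairs = list(zip(tumor_ids, normal_ids, patients))

    # survival: hazard scales with tumor expression (above/below the cohort
    # median) of each survival marker; administrative censoring
    tumor_rpm = tissue.rpm[tumor_ids]
    log_hr = np.zeros(spec.n_tissue_pairs)
    for marker, hr in spec.survival_marker_effects.items():
        expr = tumor_rpm.loc[marker].to_numpy()
        high = expr > np.median(expr)
        log_hr += np.where(high, 0.5, -0.5) * np.log(hr)
    hazard = spec.base_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(spec.censor_low, spec.censor_high,
                           size=spec.n_tissue_pairs)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    survival = pd.DataFrame(
        {"sample_id": tumor_ids, "time": np.round(time, 1), "event": event}
    )

    sexes = ["F", "M"] * (spec.n_healthy // 2 + 1)
    meta_rows = [
        {"sample_id": s, "group": "healthy", "compartment": "plasma",
         "sex": sexes[i], "patient_id": s}
        for i, s in enumerate(healthy_ids)
    ]
    meta_rows += [
        {"sample_id": s, "group": "hcc", "compartment": "plasma",
         "sex": "M", "patient_id": s}
        for s in hcc_ids
    ]
    for tid, nid, pid in tissue_pairs:
        meta_rows.append({"sample_id": tid, "group": "hcc", "compartment": "tumor",
                          "sex": "unknown", "patient_id": pid})
        meta_rows.append({"sample_id": nid, "group": "hcc", "compartment": "normal",
                          "sex": "unknown", "patient_id": pid})
    meta = pd.DataFrame(meta_rows)

    n_up, n_down = 5, 2
    expected_panel = sorted(
        spec.planted_up, key=lambda m: -spec.planted_up[m]
    )[:n_up] + sorted(spec.planted_down, key=lambda m: spec.planted_down[m])[:n_down]
    truth = {
        "seed": spec.seed,
        "planted_up": dict(spec.planted_up),
        "planted_down": dict(spec.planted_down),
        "planted_reversals": list(spec.planted_reversals),
        "survival_markers": dict(spec.survival_marker_effects),
        "dominant_mirna": spec.dominant_mirna,
        "expected_panel": expected_panel,
    }
    return CohortData(plasma=plasma, tissue=tissue, meta=meta, survival=survival,
                      tissue_pairs=tissue_pairs, truth=truth)


# ---------------------------------------------------------------------------
# alignment fixtures for the counting rule
# ---------------------------------------------------------------------------

DEFAULT_OFFSET_DIST = {-2: 0.05, -1: 0.15, 0: 0.40, 1: 0.15, 2: 0.10, 3: 0.10, 4: 0.05}


def simulate_alignments(
    sites: Sequence[MirnaSite],
    counts_per_site: Mapping[str, Mapping[str, int]],
    end_offset_distribution: Optional[Mapping[int, float]] = None,
    seed: int = 0,
    policy: CountingPolicy = CountingPolicy(),
) -> Tuple[Dict[str, str], CountMatrix]:
    """Emit SAM text whose reads anchor exactly on site 5' ends, with 3'
    offsets drawn from ``end_offset_distribution``.

    ``counts_per_site`` maps sample id -> miRNA name -> number of reads.
    Offsets are in transcript orientation; reads drawn outside the policy's
    3' window must not be counted, and the returned expected
    :class:`CountMatrix` is computed analytically from the drawn offsets.
    """
    dist = dict(end_offset_distribution or DEFAULT_OFFSET_DIST)
    offsets = np.array(sorted(dist))
    probs = np.array([dist[o] for o in offsets], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("offset distribution has no mass")
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    by_name: Dict[str, List[MirnaSite]] = {}
    for s in sites:
        by_name.setdefault(s.name, []).append(s)

    names = list(dict.fromkeys(s.name for s in sites))
    sample_ids = list(counts_per_site)
    expected = np.zeros((len(names), len(sample_ids)), dtype=np.int64)
    row = {n: i for i, n in enumerate(names)}
    sam_texts: Dict[str, str] = {}
    lo, hi = policy.three_prime_lower, policy.three_prime_upper
    for j, sample in enumerate(sample_ids):
        lines = ["@HD\tVN:1.6\tSO:unsorted"]
        read_no = 0
        for name, n_reads in counts_per_site[sample].items():
            loci = by_name.get(name)
            if not loci:
                raise ValueError(f"unknown miRNA name {name!r}")
            for _ in range(n_reads):
                site = loci[rng.integers(len(loci))]
                off = int(offsets[rng.choice(len(offsets), p=probs)])
                if site.strand == "+":
                    start, end = site.start, site.end + off
                    flag = 0
                else:
                    start, end = site.start - off, site.end
                    flag = 16
                read_no += 1
                lines.append(
                    "\t".join(
                        [
                            f"{sample}.r{read_no}",
                            str(flag),
                            site.chrom,
                            str(start),
                            "255",
                            f"{end - start + 1}M",
                            "*", "0", "0", "*", "*",
                        ]
                    )
                )
                if lo <= off <= hi:
                    expected[row[name], j] += 1
        sam_texts[sample] = "\n".join(lines) + "\n"
    expected_matrix = CountMatrix(
        pd.DataFrame(expected, index=names, columns=sample_ids)
    )
    return sam_texts, expected_matrix


# ---------------------------------------------------------------------------
# qPCR fixtures
# ---------------------------------------------------------------------------


def simulate_ct(
    true_fold_changes: Mapping[str, float],
    control_ct: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    case_id: str = "case",
    ref_id: str = "ref",
    control_assay: str = "U6",
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Ct table consistent with 2^-ddCt recovery of the requested fold
    changes (case vs ref), plus Gaussian replicate noise."""
    rng = np.random.default_rng(seed)
    rows = []

    def add(sample: str, assay: str, base_ct: float) -> None:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": sample,
                    "assay": assay,
                    "replicate": rep,
                    "ct": base_ct + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
                }
            )

    add(case_id, control_assay, control_ct)
    add(ref_id, control_assay, control_ct)
    for assay, fold in true_fold_changes.items():
        if fold <= 0:
            raise ValueError(f"fold change for {assay} must be positive")
        ref_target = control_ct + float(rng.uniform(2.0, 8.0))
        add(ref_id, assay, ref_target)
        add(case_id, assay, ref_target - np.log2(fold))
    return pd.DataFrame(rows)
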