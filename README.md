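# plasmir

Circulating (plasma) miRNAs are promising diagnostic biomarkers for
hepatocellular carcinoma (HCC): healthy individuals carry remarkably
uniform plasma miRNA profiles — dominated by miR-486-5p at roughly 60% of
miRNA-mapped reads — while patient profiles are heterogeneous, and a small
set of miRNAs changes direction between patient plasma and the tumor
itself, suggesting selective secretion.  `plasmir` is a Python library and
CLI for the full analysis chain behind such a study, aimed at
bioinformaticians working with small-RNA sequencing of liquid biopsies:

* **quantify** — assign reads (SAM) to mature-miRNA sites (miRBase-style
  GFF3): exact 5′ match, 3′ end within −1..+3 nt, multi-locus names
  pooled; normalize to reads per million,
  RPM(i,s) = count(i,s) / Σᵢ count(i,s) × 10⁶;
* **heterogeneity** — pairwise Pearson R distributions per group compared
  by an ANOVA F-test; per-subject top-20 abundance lists; the shared
  fraction |∩ lists|/|∪ lists| with exhaustive enumeration of all C(n,k)
  equal-size subject subsets;
* **diffexpr** — negative-binomial Wald test (median-of-ratios size
  factors; moments dispersion α̂ = max(0, (v − μξ)/μ²) floored by a fitted
  mean–dispersion trend; BH adjustment), then a biomarker cascade:
  |log2FC| > 1 & p_adj < 0.05 → baseMean in patients > 10 → top 5 up +
  2 down by |log2FC|;
* **concordance** — per-sample fold changes in plasma (vs healthy mean)
  and tissue (tumor vs paired normal) with a +0.01 zero guard; a
  *direction reversal* is called when the median log2FCs disagree in
  sign; 2^−ΔΔCt quantification for qRT-PCR validation;
* **survival** — upper-vs-lower quartile expression strata (≥5 patients
  each), Kaplan–Meier curves and the two-group log-rank test;
* **synth** — a seeded cohort generator (floored-Dirichlet multinomial)
  with planted markers, reversals and survival effects, so the whole
  pipeline is testable without access to controlled raw data.

## Worked example

Run the whole pipeline on a synthetic cohort (4 healthy + 10 HCC plasma
samples, 80 tumor/normal pairs, 300 miRNAs):

```bash
plasmir run-all --seed 1 --outdir out/
```

prints

```json
{
  "median_r_healthy": 0.9998937674537431,
  "median_r_hcc": 0.8673844340478488,
  "anova_F": 29.080325714013934,
  "anova_p": 1.987346433511573e-06,
  "healthy_shared_percent": 85.71428571428571,
  "n_enumerated_subsets": 210,
  "max_subset_shared_percent": 75.0,
  "n_differential": 7,
  "panel": ["hsa-miR-21-5p", "hsa-miR-222-3p", "hsa-miR-221-3p",
            "hsa-miR-1180-3p", "hsa-miR-1271-5p",
            "hsa-miR-486-3p", "hsa-miR-486-5p"],
  "n_reversed": 3,
  "reversed": ["hsa-miR-21-5p", "hsa-miR-1271-5p", "hsa-miR-486-3p"],
  "survival_associated": ["hsa-miR-21-5p", "hsa-miR-221-3p",
                          "hsa-miR-486-5p"]
}
```

Reading the numbers: healthy plasma profiles are nearly interchangeable
(median pairwise R ≈ 1.000) while patients diverge (median R 0.867;
ANOVA p ≈ 2×10⁻⁶).  The four healthy subjects share 85.7% of their
pooled top-20 miRNAs, more than the best of the 210 exhaustively
enumerated 4-patient subsets (75.0%).  The differential-expression
cascade selects a 7-marker panel (5 up-regulated in patient plasma, 2
down — including the dominant miR-486-5p); three of the seven markers
reverse direction between plasma and tumor tissue, and three are
associated with survival in the quartile-stratified log-rank scan.  All
selections match the cohort's planted ground truth (`out/…/truth.json`
when generated via `plasmir synth`).

Individual stages are available as subcommands operating on TSV files
(`plasmir synth | quantify | normalize | heterogeneity | de | panel |
concordance | ddct | survival`); `--help` on each lists the thresholds,
which default to the values above.

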