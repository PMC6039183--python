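# hlabquant

Quantitative analysis of allele- and cell-type-dependent HLA-B cell
surface expression from flow-cytometry, bead-array and immunopeptidome
data — built for immunogenetics groups comparing HLA class I allotypes
across donor cohorts and leukocyte subsets.

HLA-B heavy chains carry mutually exclusive Bw4/Bw6 serologic epitopes
(determined by residues 77 and 80–83), which makes epitope-specific
antibodies the broadest available reagents for comparing HLA-B surface
levels across allotypes in primary cells. The pipeline covers every
quantitative step of such a study:

* **ABC calibration** — geometric MFI of gated subsets is converted to
  antibody binding capacity (ABC, molecules/cell) via a standard curve
  fitted to beads bearing known numbers of capture sites (log-log or
  linear-linear OLS), after isotype-control background subtraction.
  Donors homozygous for the epitope (at HLA-B, with both HLA-C alleles
  also epitope-bearing) report 0.5× the derived epitope ABC; pan-class-I
  (W6/32) values are never halved. Replicate blood draws aggregate to
  per-donor mean ± SEM, epitope/W6/32 ratios, and reference-subset
  normalizations.
* **Surface half-life** — after Brefeldin A blocks forward trafficking,
  the surface signal decays as *y(t) = y₀·e^(−kt)* (plateau constrained
  to zero); nonlinear least squares gives *t*₁/₂ = ln 2 ∕ *k* per day,
  averaged per donor, with the QC rule SEM/mean < 0.33 on *n* ≥ 2
  independent measurements.
* **Antibody specificity** — single-antigen (Luminex) bead signals are
  normalized to the W6/32 signal on the same bead (cancelling coupling
  differences); heavy-chain sequences are scanned for Bw4/Bw6-like motifs
  in the 77–83 window; cell-derived ABC is regressed on the bead binding
  ratio, flagging allotypes whose donors mostly fall below the line
  (expression lower than the antibody-affinity expectation).
* **Peptidome entropy** — per-position Shannon entropy
  *E(i) = −Σₐ q(a,i)·log₂ q(a,i)* of allele-assigned 9-mers, in bits
  (0 = fully restricted anchor, log₂ 20 ≈ 4.32 = unrestricted), with
  length filtering and exclusive-assignment filtering of peptides shared
  between motif-incompatible alleles.
* **Group statistics** — receptivity and staining ratios (HC10
  specific/control peptide, surface fraction, tapasin/W6/32, 2^−ΔCt) and
  the comparison statistics used on donor-level means: one-way ANOVA with
  Tukey HSD follow-up, Welch's *t*, Pearson correlation, and the
  conventional star tiers (\*&nbsp;p<0.05 … \*\*\*\*&nbsp;p<0.0001).
* **Synthetic cohorts** — every input (bead tables, stain tables, decay
  series, bead panels, peptidomes) can be generated with controllable
  ground truth and multiplicative lognormal noise, so the full pipeline
  is testable end to end without any measured data.

## Worked example

```python
import numpy as np
from hlabquant import calibration, cohort, decay, entropy, stats

# bead standards -> calibration curve
beads = cohort.simulate_bead_standards(curve_slope=0.95, curve_intercept=0.8,
                                       abc_levels=[1e3, 1e4, 1e5, 1e6],
                                       noise_cv=0.03, seed=1)
curve = calibration.fit_standard_curve(beads, mode="log-log")
print(curve.summary())
```

```
Standard curve (log-log)
  slope          1.06049
  intercept    -0.926852
  r^2           0.999957
  MFI range [1591.26, 1.07217e+06]
```

The fitted slope/intercept map measured MFI back to molecules/cell;
r² ≈ 1 confirms the log-linear bead response. Next, a synthetic cohort in
which CD4⁺ T cells express B\*08:01 1.5× above the other allotypes:

```python
design = cohort.default_expression_design(seed=1)
stains, genotypes, truth = cohort.simulate_cohort(design)
cal_beads = cohort.simulate_bead_standards(1.0, 0.0, [1e2, 1e3, 1e4, 1e5, 1e6])
cal_curve = calibration.fit_standard_curve(cal_beads)
abc = calibration.aggregate_abc(
    calibration.calibrate_stains(stains, cal_curve, genotypes))
abc = abc[abc["antibody"] == "anti-Bw6"].copy()
abc["allele"] = abc["donor"].str.split("|").str[0]
cd4 = abc[abc["subset"] == "CD4T"]
groups = {a: g["mean_abc"].to_numpy() for a, g in cd4.groupby("allele")}
print(stats.one_way_anova(groups, posthoc="none").summary())
```

```
one-way ANOVA: statistic = 6.3968, p = 0.0001681 ***
       B*07:02  mean = 2.485e+04
       B*08:01  mean = 3.486e+04
       B*15:01  mean = 2.177e+04
       B*18:01  mean = 2.231e+04
       B*35:01  mean = 2.413e+04
       B*40:01  mean = 2.492e+04
```

The designed hierarchy (B\*08:01 ≈ 35 000 molecules/cell vs ≈ 25 000
baseline) is recovered and significant at the \*\*\* tier. Half-life
fitting on a decay time course designed at *t*₁/₂ = 10 h:

```python
d, _ = cohort.simulate_decay(cohort.DecayDesign(
    half_lives={("B*08:01", "CD4T"): 10.0}, noise_cv=0.05,
    n_replicates=3, seed=1))
print(decay.aggregate_halflife_table(decay.fit_decay_table(d)))
```

```
  donor subset antibody   t_half      sem  n  qc_pass
B*08:01   CD4T anti-Bw6 9.733417 0.183689  3     True
```

Three replicate fits average to 9.73 ± 0.18 h (SEM/mean ≈ 0.02 < 0.33,
so the donor passes QC). Finally, a peptidome with a designed per-position
entropy profile is recovered from 20 000 sampled 9-mers:

```python
pfm = cohort.pfm_from_entropy_profile([3.5, 1.0, 2.5, 4.0, 1.5, 4.0, 3.0, 3.8, 0.5])
peps = cohort.simulate_peptidome(cohort.PeptidomeDesign(
    pfms={"B*08:01": pfm}, n_peptides=20_000, seed=1))
print(np.round(entropy.entropy_profile(peps, "B*08:01").entropy_bits, 2))
```

```
[3.49 1.   2.54 4.   1.48 4.   2.98 3.8  0.49]
```

Positions designed as anchors (P2 at 1.0 bit, P9 at 0.5 bits) come back
restricted; free positions come back near the 4.32-bit maximum.

A `hlabquant` console script exposes the same stages from the shell
(`simulate`, `abc`, `halflife`, `entropy`, `luminex`, `compare`); run
`hlabquant --help` for the options.

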