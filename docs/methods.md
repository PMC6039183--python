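# Methods

This note documents the models implemented in hlabquant, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about measured data.

## ABC calibration

Antibody binding capacity (ABC) quantitation assumes the instrument's
fluorescence response is shared between calibration beads and cells
stained in the same experiment with the same antibody concentration. The
standard curve is an ordinary least-squares regression of known bead ABC
on measured geometric MFI; in the default `log-log` mode both axes are
log-transformed, which linearises the power-law response observed when
bead standards span several decades. `linear-linear` is retained for
experiments confined to a narrow range. At least three bead populations
with distinct ABC are required; the fit refuses a non-positive slope
(signal must increase with ABC).

Background is removed by subtracting the paired isotype-control MFI from
the specific MFI before interpolation; negative differences are floored
at zero and flagged, since a binding capacity cannot be negative. MFIs
outside the bead range are clamped to the range with a warning by
default — extrapolating a log-log fit far below the dimmest standard can
produce wild values on dim subsets. `extrapolate` and `error` policies
are available.

The homozygote correction implements a genotype-driven rule: when a donor
is HLA-B epitope-homozygous *and* both HLA-C alleles carry the epitope
motif, every HLA class I allele the epitope antibody can see contributes,
so the derived epitope ABC is halved to report a per-allele value. The
factor is exactly 0.5 and is applied to epitope antibodies only, never to
pan-class-I (W6/32) signals. The rule lives behind a single predicate so
cohorts with different cross-reactivity structure can adapt it.

Replicates aggregate as mean, SEM = s/√N and N over independent blood
draws; N = 1 yields SEM = 0 with a `single_draw` flag rather than a NaN.
The epitope/pan ratio is computed as a ratio of per-donor means (each
donor's averaged epitope ABC over the same donor's averaged W6/32 ABC),
which corrects allele comparisons for donor-to-donor differences in total
class I expression; ratio-per-draw-then-average is the obvious
alternative and differs only at second order in the replicate noise.

## Surface half-life

Surface decay after Brefeldin A is modelled as a one-phase exponential
with the plateau fixed at exactly zero: y(t) = y₀·e^(−kt), t½ = ln2/k. A
free-plateau variant is deliberately not offered; the zero constraint
encodes the assumption that all surface epitope eventually internalises.
The fit is nonlinear least squares with bounds y₀, k > 0, initialised
from the log-linear regression of ln y on t over the positive points.
Points with MFI ≤ 0 after isotype subtraction stay in the NLS objective
(least squares tolerates them) but are excluded from the initialiser.

The default loss is unweighted on the linear MFI scale, matching the
common graphing-software default this workflow is normally run through; a
log-scale loss is exposed as an option. The choice matters: with
multiplicative noise the linear loss effectively down-weights the late,
low-MFI points that carry most of the information about k, so its
sampling error is noticeably larger (median relative error ≈ 0.10 at
10% CV on a 0–24 h five-point grid, versus ≈ 0.04 for the log loss).
Fits are performed per day and then averaged per donor — not pooled —
so day-to-day variation enters the SEM. The QC inclusion rule is
SEM/mean < 0.33 with n ≥ 2 independent measurements; failing donors are
flagged, not silently dropped. Non-convergent series are excluded from a
batch with a log entry rather than aborting it.

## Antibody specificity

Single-antigen bead signals are normalized per bead as test-antibody MFI
over W6/32 MFI, cancelling differences in HLA protein coupling to beads;
the ratio is averaged across replicates at a single analysed dilution
(default "1:50") because ratios drift with dilution. Beads with a
non-positive reference are excluded with a warning.

Bw4/Bw6 motif definitions are data, not code: an editable TSV maps each
motif to allowed residue sets over mature heavy-chain positions 77–83
(1-based, signal peptide removed; a configurable offset handles precursor
numbering). The shipped defaults are the published serologic motifs
(Bw6: S77 L78 R79 N80 L81 R82 G83; Bw4: N/D/S 77, L78, R79, T/I 80,
A/L 81, L82, R83). The scanner returns the first motif, in table order,
whose constraints all hold — deterministic because the table is ordered.
Cross-reactivity screening flags alleles of non-target loci whose
normalized ratio reaches a threshold (inclusive); alleles absent from the
panel are reported `unknown`, never assumed negative.

The bead-vs-cell regression is OLS of donor-level ABC on the bead binding
ratio with Pearson r and its two-sided p. An allotype is flagged "below
the regression line" when more than 50% of its donor points have negative
residuals (beyond a numerical tolerance so a perfect fit flags nothing).
At small donor counts this majority rule has appreciable by-chance flag
probability for on-line allotypes (binomial: ~34% at 6 donors), so the
flag list should be read as a screen; the designed-deviant detection rate
is the quantity the acceptance checks track.

## Peptidome entropy

Per-position frequencies are raw counts over the peptide set — no
pseudocounts, sequence weighting or clustering, unlike logo tools —
because the entropy statistic is defined on the observed frequencies.
Entropy is the standard Shannon form E(i) = −Σ q log₂ q in non-negative
bits with 0·log₂0 ≡ 0, bounded by [0, log₂20]; higher values mean higher
sequence diversity at that position. Peptides are filtered to one exact
length (default 9) and to the 20 standard residues; non-standard residues
drop the peptide (counted, not recoded). The exclusive-assignment filter
removes peptides shared between alleles not declared motif-compatible
from both alleles, retaining sharing between compatible alleles. When
multiple datasets contribute, peptides are pooled before computing E
(per-dataset averaging can be done by calling the profile per dataset);
pooling weights each peptide equally, which is the natural choice when
datasets differ greatly in depth.

## Group statistics

All comparisons operate on donor-level means — one point per donor — so
technical replicates never inflate degrees of freedom. One-way ANOVA uses
the classical F test; all-constant input is rejected as degenerate rather
than returning an undefined F. The pairwise follow-up after ANOVA is
Tukey HSD by default with Bonferroni-adjusted Welch tests and `none` as
alternatives, since the star annotations in this kind of figure rarely
state the multiplicity procedure. Welch's t uses Satterthwaite degrees of
freedom; two identical groups return t = 0, p = 1 by convention. Ratio
operations (HC10 receptivity, surface fraction, tapasin ratio, 2^−ΔCt)
exclude records with non-positive denominators rather than imputing them.
Significance tiers are strict thresholds: p < 0.05 (*), < 0.01 (**),
< 0.001 (***), < 0.0001 (****).

## Synthetic cohorts: what they emulate, and what they don't

All measurement noise is multiplicative lognormal, parameterised by a CV,
because flow intensities are strictly positive and approximately
log-normal — consistent with geometric-mean summarisation upstream. Mean
one is enforced (σ² = ln(1+CV²), μ = −σ²/2) so designed means are
unbiased, and CV = 0 yields exactly noise-free values, which is what
makes the zero-noise calibration round trip exact to machine precision.
Donor effects and draw effects are independent lognormal factors shared
across a donor's subsets within a draw.

Defaults define the study conditions: donor CV 0.2 and replicate CV 0.1
(plausible biological and technical scales for primary-cell flow
measurements; no published per-subset CVs exist for this assay, so these
are explicit, configurable choices), 8 donors per allele group, 4 draws
per donor, baseline 25 000 molecules/cell, effect size 1.5× for the
designed hierarchy (B*08:01 high in lymphocytes; B*07:02/B*35:01 — the
B7-supertype members — high in monocytes). The pan-class-I signal
defaults to 2× the epitope signal (epitope/pan ratio 0.5, roughly one of
two HLA-B alleles contributing to total class I). The isotype control is
2% of the pan signal. Epitope-homozygous donors contribute twice the
per-allele ABC before the forward MFI curve. Decay series use the grid
0, 2, 4, 8, 24 h. Peptidome columns with a designed entropy are built by
mixing a point mass with the uniform distribution and solving the mixture
weight by bisection — a one-parameter family that spans [0, log₂20]
exactly.

Not emulated: raw list-mode events, spillover/compensation, gating,
autofluorescence structure, antibody titration effects, day effects
shared across donors, or correlations between subsets beyond the shared
donor factor. Passing the recovery tests therefore shows the estimators
are correct and well-calibrated under lognormal noise of realistic
magnitude — not that real cytometry satisfies those assumptions.

## Problem sizes and numerics

The test suite and the acceptance script use: 5-level bead sets spanning
10³–10⁶ molecules/cell; 200 noisy decay series for recovery (with a
400-point geometric grid search over t½ as the independent oracle, y₀
profiled in closed form); 10⁵ peptides for entropy-profile recovery
(tolerance 0.05 bits); 10⁴ random windows for the motif-scan comparison
against a brute-force matcher; 2000 null simulations for the type-I error
of ANOVA and Welch (band 0.05 ± 0.015); and 100 seeded cohort runs for
the hierarchy-detection rate. These sizes give Monte-Carlo error well
below the tolerances being checked while keeping a full run in the
tens-of-seconds range.

Numerical details worth knowing: curve interpolation at MFI = 0 in
log-log mode returns 0 rather than −∞; the decay fitter bounds parameters
at 1e-12 to keep the optimiser in-domain; an increasing series is fitted
at the boundary and flagged `non_decaying`; Tukey HSD comes from scipy's
studentized-range implementation; frequency columns are validated to sum
to 1 within 1e-9 before entropy is computed.

## Known limitations

Single-exponential decay only — no internalization/recycling compartment
models. No FCS parsing, gating or compensation; inputs are gated
geometric-MFI summaries. No binding-affinity prediction or logo
rendering; frequency matrices are exported for external tools. The
motif table ships serologic defaults and should be reviewed against the
specific cross-reactive allele set of any new antibody lot before being
used for donor exclusion.
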