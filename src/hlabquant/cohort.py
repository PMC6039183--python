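"""Synthetic donor-cohort generators.

Every input the pipeline consumes can be generated here with controllable
ground truth: bead standard curves with multiplicative lognormal noise,
donor cohorts with allele-group and cell-subset effect sizes and replicate
blood draws, Brefeldin-A decay time courses, Luminex single-antigen bead
panels, and peptidomes sampled from position frequency matrices with
designed entropy profiles.

Conventions
-----------
* Flow intensities are strictly positive and approximately log-normal, so
  all measurement noise is multiplicative lognormal, parameterised by a
  coefficient of variation (CV).  A CV of 0 produces exactly noise-free
  values, which gives bit-exact round trips through the calibration chain.
* Ground truth is always returned as a sidecar table so tests never have
  to re-derive it from the design parameters.
* All randomness flows through a single integer seed per design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import DesignError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: default cell subsets measured in the quantitative flow panel
DEFAULT_SUBSETS = ("CD4T", "CD8T", "B", "NK", "monocyte")

__all__ = [
    "AMINO_ACIDS",
    "DEFAULT_SUBSETS",
    "CohortDesign",
    "DecayDesign",
    "PeptidomeDesign",
    "simulate_bead_standards",
    "simulate_cohort",
    "simulate_decay",
    "simulate_peptidome",
    "simulate_luminex_panel",
    "uniform_column",
    "degenerate_column",
    "column_with_entropy",
    "pfm_from_entropy_profile",
    "write_cohort_tables",
    "default_expression_design",
    "simulate_bw4_regression_cohort",
    "DEFAULT_BW6_ALLELES",
    "B7_SUPERTYPE",
    "DEFAULT_BW4_BINDING_RATIOS",
    "DEFAULT_BELOW_LINE_ALLELE",
    "DEFAULT_BELOW_LINE_SCALE",
]


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation *cv*.

    Returns exact ones when cv == 0 so that noise-free designs round-trip
    to machine precision.
    """
    if cv < 0:
        raise DesignError(f"coefficient of variation must be >= 0, got {cv}")
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _forward_mfi(abc, slope: float, intercept: float) -> np.ndarray:
    """Log-linear bead response: MFI = exp(intercept + slope * ln(ABC))."""
    return np.exp(intercept + slope * np.log(abc))


# ---------------------------------------------------------------------------
# bead standards
# ---------------------------------------------------------------------------

def simulate_bead_standards(
    curve_slope: float,
    curve_intercept: float,
    abc_levels,
    noise_cv: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Simulate calibration beads bearing known numbers of antibody capture sites.

    Each bead population has a known ABC (molecules/cell) and a measured
    geometric MFI drawn from the log-linear response perturbed by
    multiplicative lognormal noise.

    Returns a DataFrame with columns ``population``, ``abc``, ``mfi``
    (and ``replicate`` when ``n_replicates > 1``).
    """
    levels = np.asarray(abc_levels, dtype=float)
    if levels.ndim != 1 or len(levels) == 0:
        raise DesignError("abc_levels must be a non-empty 1-D sequence")
    if np.any(levels <= 0):
        raise DesignError("all ABC levels must be > 0")
    if np.any(np.diff(levels) <= 0):
        raise DesignError("abc_levels must be strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        noise = _lognormal_factors(rng, noise_cv, len(levels))
        mfi = _forward_mfi(levels, curve_slope, curve_intercept) * noise
        for i, (abc, m) in enumerate(zip(levels, mfi)):
            rows.append({"population": f"P{i + 1}", "abc": abc, "mfi": m,
                         "replicate": rep + 1})
    df = pd.DataFrame(rows)
    if n_replicates == 1:
        df = df.drop(columns="replicate")
    return df


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Ground-truth description of a synthetic donor cohort.

    Parameters
    ----------
    alleles
        Mapping from allele label (e.g. ``"B*08:01"``) to serologic epitope
        class: ``"Bw4"``, ``"Bw6"`` or ``"none"``.
    cell_subsets
        Gated subsets measured per donor.
    mean_abc
        ``(allele, subset) -> true mean epitope-antibody ABC`` in
        molecules/cell.  Every allele x subset pair must be present.
    pan_mean_abc
        Optional ``(allele, subset) -> true mean pan-class-I (W6/32) ABC``;
        defaults to twice the epitope mean (epitope/pan ratio 0.5).
    donor_cv, replicate_cv
        Biological CV across donors and technical CV across repeat blood
        draws (fractions).
    n_donors_per_allele, n_draws
        Cohort size per allele group and independent draws per donor.
    n_homozygous_per_allele
        Number of donors per allele group flagged epitope-homozygous (their
        measured signal doubles; the calibration module halves it back).
    curve_slope, curve_intercept
        The log-linear MFI response the generator inverts; should match the
        bead standards so calibration round-trips.
    isotype_fraction
        Isotype-control MFI as a fraction of the pan-class-I MFI.
    """

    alleles: dict
    cell_subsets: tuple = DEFAULT_SUBSETS
    mean_abc: dict = field(default_factory=dict)
    pan_mean_abc: dict | None = None
    donor_cv: float = 0.2
    replicate_cv: float = 0.1
    n_donors_per_allele: int = 8
    n_draws: int = 4
    n_homozygous_per_allele: int = 0
    curve_slope: float = 1.0
    curve_intercept: float = 0.0
    isotype_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not self.alleles:
            raise DesignError("at least one allele required")
        bad = {c for c in self.alleles.values()} - {"Bw4", "Bw6", "none"}
        if bad:
            raise DesignError(f"unknown epitope class(es): {bad}")
        if self.donor_cv < 0 or self.replicate_cv < 0:
            raise DesignError("CVs must be >= 0")
        if self.n_donors_per_allele < 1 or self.n_draws < 1:
            raise DesignError("n_donors_per_allele and n_draws must be >= 1")
        if self.n_homozygous_per_allele > self.n_donors_per_allele:
            raise DesignError("more homozygous donors than donors per allele")
        for allele in self.alleles:
            for subset in self.cell_subsets:
                key = (allele, subset)
                if key not in self.mean_abc:
                    raise DesignError(f"mean_abc missing entry for {key}")
                if self.mean_abc[key] <= 0:
                    raise DesignError(f"mean_abc must be > 0 at {key}")
        if self.pan_mean_abc is not None:
            for allele in self.alleles:
                for subset in self.cell_subsets:
                    key = (allele, subset)
                    if key not in self.pan_mean_abc:
                        raise DesignError(f"pan_mean_abc missing entry for {key}")
                    if self.pan_mean_abc[key] <= 0:
                        raise DesignError(f"pan_mean_abc must be > 0 at {key}")

    def pan_abc(self, allele: str, subset: str) -> float:
        if self.pan_mean_abc is not None:
            return self.pan_mean_abc[(allele, subset)]
        return 2.0 * self.mean_abc[(allele, subset)]


def simulate_cohort(design: CohortDesign):
    """Generate stain records, donor genotypes and a ground-truth sidecar.

    Returns ``(stains, genotypes, truth)`` DataFrames.

    ``stains`` columns: donor, draw, subset, antibody, mfi, isotype_mfi.
    The epitope antibody is ``anti-Bw6`` or ``anti-Bw4`` per the allele's
    class; every donor also gets pan-class-I ``W6/32`` records.  Specific
    MFIs are emitted as signal-plus-isotype so that isotype subtraction
    followed by curve inversion recovers the true ABC exactly at zero noise.

    Epitope-homozygous donors (both HLA-B alleles and both HLA-C alleles
    carrying the epitope) contribute twice the epitope-bearing molecules,
    so their generated epitope signal corresponds to 2x the per-allele ABC;
    the pan-class-I signal is not doubled.
    """
    rng = np.random.default_rng(design.seed)
    stain_rows, geno_rows, truth_rows = [], [], []
    for allele, epi_class in design.alleles.items():
        ab = f"anti-{epi_class}" if epi_class != "none" else None
        iso = {"Bw6": "isotype-IgG3", "Bw4": "isotype-IgG2a"}.get(epi_class, "isotype-IgG2a")
        for d in range(design.n_donors_per_allele):
            donor = f"{allele}|D{d + 1:02d}"
            homozygous = d < design.n_homozygous_per_allele
            geno_rows.append({
                "donor": donor,
                "hla_b_1": allele,
                "hla_b_2": allele if homozygous else "B*Bw4-other",
                "hla_c_1": "C*07:02" if homozygous else "C*07:02",
                "hla_c_2": "C*07:02" if homozygous else "C*04:01",
                "epitope_class": epi_class,
                "epitope_homozygous": homozygous,
                "both_c_epitope_bearing": homozygous,
                "cross_reactive_hla_a": False,
            })
            donor_f = _lognormal_factors(rng, design.donor_cv, len(design.cell_subsets))
            for draw in range(design.n_draws):
                rep_f = _lognormal_factors(rng, design.replicate_cv,
                                           len(design.cell_subsets))
                for j, subset in enumerate(design.cell_subsets):
                    true_epi = design.mean_abc[(allele, subset)] * donor_f[j] * rep_f[j]
                    true_pan = design.pan_abc(allele, subset) * donor_f[j] * rep_f[j]
                    pan_mfi = _forward_mfi(true_pan, design.curve_slope,
                                           design.curve_intercept)
                    iso_mfi = design.isotype_fraction * pan_mfi
                    draw_id = f"d{draw + 1}"
                    stain_rows.append({
                        "donor": donor, "draw": draw_id, "subset": subset,
                        "antibody": "W6/32",
                        "mfi": pan_mfi + iso_mfi, "isotype_mfi": iso_mfi,
                    })
                    truth_rows.append({
                        "donor": donor, "draw": draw_id, "subset": subset,
                        "antibody": "W6/32", "true_abc": true_pan,
                        "design_mean_abc": design.pan_abc(allele, subset),
                    })
                    if ab is not None:
                        measured = 2.0 * true_epi if homozygous else true_epi
                        epi_mfi = _forward_mfi(measured, design.curve_slope,
                                               design.curve_intercept)
                        stain_rows.append({
                            "donor": donor, "draw": draw_id, "subset": subset,
                            "antibody": ab,
                            "mfi": epi_mfi + iso_mfi, "isotype_mfi": iso_mfi,
                        })
                        truth_rows.append({
                            "donor": donor, "draw": draw_id, "subset": subset,
                            "antibody": ab, "true_abc": true_epi,
                            "design_mean_abc": design.mean_abc[(allele, subset)],
                        })
    return (pd.DataFrame(stain_rows), pd.DataFrame(geno_rows),
            pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# decay
# ---------------------------------------------------------------------------

@dataclass
class DecayDesign:
    """Ground truth for Brefeldin-A surface-decay time courses.

    ``half_lives`` maps ``(allele, subset)`` to the true surface half-life
    in hours; each series decays as ``y0 * exp(-ln2 * t / t_half)`` with
    multiplicative lognormal noise of CV ``noise_cv``.
    """

    half_lives: dict
    y0: float = 100.0
    time_points: tuple = (0.0, 2.0, 4.0, 8.0, 24.0)
    noise_cv: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if not self.half_lives:
            raise DesignError("at least one (allele, subset) half-life required")
        for key, hl in self.half_lives.items():
            if not (0 < hl < math.inf):
                raise DesignError(f"half-life must be finite and > 0 at {key}")
        t = np.asarray(self.time_points, dtype=float)
        if len(t) < 3:
            raise DesignError("at least 3 time points required")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise DesignError("time points must be non-negative and strictly increasing")
        if t[0] != 0:
            raise DesignError("time points must include 0")
        if self.y0 <= 0:
            raise DesignError("y0 must be > 0")
        if self.noise_cv < 0 or self.n_replicates < 1:
            raise DesignError("noise_cv >= 0 and n_replicates >= 1 required")


def simulate_decay(design: DecayDesign):
    """Generate decay time courses.  Returns ``(decay, truth)`` DataFrames.

    ``decay`` columns: donor, draw, subset, antibody, time_h, mfi,
    isotype_mfi (already-subtracted signal, so isotype_mfi is 0).
    ``truth`` carries the true half-life per series.
    """
    rng = np.random.default_rng(design.seed)
    t = np.asarray(design.time_points, dtype=float)
    rows, truth = [], []
    for (allele, subset), hl in design.half_lives.items():
        k = math.log(2.0) / hl
        for rep in range(design.n_replicates):
            y = design.y0 * np.exp(-k * t)
            y = y * _lognormal_factors(rng, design.noise_cv, len(t))
            draw = f"d{rep + 1}"
            for ti, yi in zip(t, y):
                rows.append({
                    "donor": allele, "draw": draw, "subset": subset,
                    "antibody": "anti-Bw6", "time_h": ti, "mfi": yi,
                    "isotype_mfi": 0.0,
                })
            truth.append({"donor": allele, "draw": draw, "subset": subset,
                          "true_half_life": hl, "true_y0": design.y0})
    return pd.DataFrame(rows), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# peptidome
# ---------------------------------------------------------------------------

@dataclass
class PeptidomeDesign:
    """Per-allele position frequency matrices over the 20 standard residues.

    ``pfms`` maps allele -> array of shape (20, length) whose columns sum
    to 1; peptides are drawn i.i.d. per position.
    """

    pfms: dict
    n_peptides: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not self.pfms:
            raise DesignError("at least one allele PFM required")
        for allele, q in self.pfms.items():
            q = np.asarray(q, dtype=float)
            if q.shape[0] != len(AMINO_ACIDS):
                raise DesignError(
                    f"PFM for {allele} must have {len(AMINO_ACIDS)} rows")
            if np.any(q < 0):
                raise DesignError(f"PFM for {allele} has negative entries")
            if np.any(np.abs(q.sum(axis=0) - 1.0) > 1e-9):
                raise DesignError(f"PFM columns for {allele} must sum to 1")
        if self.n_peptides < 1:
            raise DesignError("n_peptides must be >= 1")


def simulate_peptidome(design: PeptidomeDesign) -> pd.DataFrame:
    """Draw peptides from each allele's PFM.

    Returns a two-column DataFrame ``(allele, peptide)``.
    """
    rng = np.random.default_rng(design.seed)
    aa = np.array(list(AMINO_ACIDS))
    rows = []
    for allele, q in design.pfms.items():
        q = np.asarray(q, dtype=float)
        length = q.shape[1]
        # sample residue indices column by column, then join
        idx = np.empty((design.n_peptides, length), dtype=int)
        for i in range(length):
            col = q[:, i] / q[:, i].sum()  # renormalise within 1e-9 slack
            idx[:, i] = rng.choice(len(AMINO_ACIDS), size=design.n_peptides, p=col)
        for pep in ["".join(r) for r in aa[idx]]:
            rows.append({"allele": allele, "peptide": pep})
    return pd.DataFrame(rows)


def uniform_column() -> np.ndarray:
    """Maximum-diversity column: all 20 residues equally likely (log2(20) bits)."""
    n = len(AMINO_ACIDS)
    return np.full(n, 1.0 / n)


def degenerate_column(residue: str) -> np.ndarray:
    """Fully restricted column: a single residue (0 bits)."""
    q = np.zeros(len(AMINO_ACIDS))
    q[AMINO_ACIDS.index(residue)] = 1.0
    return q


def column_with_entropy(bits: float, anchor: str = "L") -> np.ndarray:
    """Column with a designed Shannon entropy, in bits.

    Mixes a point mass on *anchor* with the uniform distribution:
    ``q = w * delta_anchor + (1 - w) * uniform``; entropy decreases
    monotonically from log2(20) at w=0 to 0 at w=1, so the weight is found
    by bisection.
    """
    max_bits = math.log2(len(AMINO_ACIDS))
    if not 0 <= bits <= max_bits:
        raise DesignError(f"entropy must lie in [0, {max_bits:.4f}] bits")
    if bits == 0:
        return degenerate_column(anchor)
    if abs(bits - max_bits) < 1e-12:
        return uniform_column()

    delta = degenerate_column(anchor)
    unif = uniform_column()

    def entropy_of(w):
        q = w * delta + (1 - w) * unif
        nz = q[q > 0]
        return -np.sum(nz * np.log2(nz))

    w = brentq(lambda w: entropy_of(w) - bits, 0.0, 1.0 - 1e-12, xtol=1e-14)
    return w * delta + (1 - w) * unif


def pfm_from_entropy_profile(bits_per_position, anchors=None) -> np.ndarray:
    """Build a PFM whose per-position entropies equal *bits_per_position*.

    ``anchors`` optionally sets the favoured residue per position (defaults
    to a fixed rotation so adjacent positions restrict different residues).
    """
    bits = list(bits_per_position)
    if anchors is None:
        anchors = [AMINO_ACIDS[(3 * i) % len(AMINO_ACIDS)] for i in range(len(bits))]
    cols = [column_with_entropy(b, a) for b, a in zip(bits, anchors)]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Luminex single-antigen beads
# ---------------------------------------------------------------------------

def simulate_luminex_panel(
    binding_ratios: dict,
    ref_mfi: float = 10_000.0,
    noise_cv: float = 0.0,
    n_replicates: int = 2,
    dilution: str = "1:50",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a single-antigen bead panel.

    *binding_ratios* maps allele -> true test-antibody/pan-class-I ratio
    (0 for non-recognised allotypes).  Each bead carries one allele; the
    pan-class-I reference MFI absorbs coupling variation via the same
    lognormal noise, and the test MFI is ratio x reference (with its own
    noise), mirroring how W6/32 normalization cancels coupling differences.

    Returns columns: bead, allele, test_mfi, ref_mfi, dilution, replicate.
    """
    if ref_mfi <= 0:
        raise DesignError("ref_mfi must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for b, (allele, ratio) in enumerate(binding_ratios.items()):
        if ratio < 0:
            raise DesignError(f"binding ratio must be >= 0 for {allele}")
        for rep in range(n_replicates):
            coupling = _lognormal_factors(rng, noise_cv, 1)[0]
            ref = ref_mfi * coupling
            test = ratio * ref * _lognormal_factors(rng, noise_cv, 1)[0]
            rows.append({"bead": f"bead{b + 1:03d}", "allele": allele,
                         "test_mfi": test, "ref_mfi": ref,
                         "dilution": dilution, "replicate": rep + 1})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

#: Bw6-bearing allotypes with enough donors for expression comparisons
DEFAULT_BW6_ALLELES = ("B*07:02", "B*08:01", "B*15:01", "B*18:01",
                       "B*35:01", "B*40:01")
#: B7-supertype members (proline-at-P2 binders disfavored by TAP)
B7_SUPERTYPE = ("B*07:02", "B*35:01", "B*51:01")
LYMPHOCYTE_SUBSETS = ("CD4T", "CD8T", "B", "NK")


def default_expression_design(seed: int = 0, baseline_abc: float = 25_000.0,
                              effect_size: float = 1.5,
                              donor_cv: float = 0.2,
                              replicate_cv: float = 0.1,
                              n_donors_per_allele: int = 8,
                              n_draws: int = 4) -> CohortDesign:
    """Default synthetic expression study.

    In lymphocytes the high-expressing allotype is B*08:01 (effect_size x
    baseline); in monocytes the hierarchy reverses for the B7-supertype
    members (B*07:02, B*35:01 at effect_size x baseline while B*08:01 sits
    at baseline), emulating the cell-type-dependent pattern the pipeline
    is designed to detect.
    """
    alleles = {a: "Bw6" for a in DEFAULT_BW6_ALLELES}
    subsets = LYMPHOCYTE_SUBSETS + ("monocyte",)
    mean_abc = {}
    for a in alleles:
        for s in subsets:
            if s == "monocyte":
                high = a in B7_SUPERTYPE
            else:
                high = a == "B*08:01"
            mean_abc[(a, s)] = baseline_abc * (effect_size if high else 1.0)
    return CohortDesign(alleles=alleles, cell_subsets=subsets,
                        mean_abc=mean_abc, donor_cv=donor_cv,
                        replicate_cv=replicate_cv,
                        n_donors_per_allele=n_donors_per_allele,
                        n_draws=n_draws, seed=seed)


#: antibody binding-preference hierarchy across the default Bw4 panel
DEFAULT_BW4_BINDING_RATIOS = {
    "B*57:01": 1.5, "B*27:05": 1.2, "B*51:01": 0.9,
    "B*37:01": 0.6, "B*13:02": 0.6, "B*44:02": 0.4,
}
#: allotype whose cell surface expression sits below the binding-affinity
#: expectation, and the designed shortfall (40% below the line)
DEFAULT_BELOW_LINE_ALLELE = "B*51:01"
DEFAULT_BELOW_LINE_SCALE = 0.6


def simulate_bw4_regression_cohort(seed: int = 0, n_donors: int = 6,
                                   donor_cv: float = 0.2,
                                   abc_per_unit_ratio: float = 30_000.0,
                                   subset: str = "CD4T") -> pd.DataFrame:
    """Donor-level Bw4 ABC values proportional to antibody binding ratio,
    except the below-line allotype whose expression is scaled down by
    ``DEFAULT_BELOW_LINE_SCALE``.

    Returns columns donor, allele, subset, mean_abc, ready for
    bead-vs-cell regression against ``DEFAULT_BW4_BINDING_RATIOS``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for allele, ratio in DEFAULT_BW4_BINDING_RATIOS.items():
        scale = (DEFAULT_BELOW_LINE_SCALE
                 if allele == DEFAULT_BELOW_LINE_ALLELE else 1.0)
        noise = _lognormal_factors(rng, donor_cv, n_donors)
        for d in range(n_donors):
            rows.append({"donor": f"{allele}|D{d + 1:02d}", "allele": allele,
                         "subset": subset,
                         "mean_abc": abc_per_unit_ratio * ratio * scale
                         * noise[d]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# output plumbing
# ---------------------------------------------------------------------------

def write_cohort_tables(outdir, stains=None, genotypes=None, truth=None,
                        beads=None, decay=None, peptides=None) -> None:
    """Write whichever generated tables are provided as TSV files."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    named = {"stains.tsv": stains, "genotypes.tsv": genotypes,
             "truth.tsv": truth, "beads.tsv": beads, "decay.tsv": decay,
             "peptides.tsv": peptides}
    for name, df in named.items():
        if df is not None:
            df.to_csv(outdir / name, sep="\t", index=False)
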