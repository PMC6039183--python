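"""Epitope-antibody specificity from single-antigen bead panels.

HLA-B allotypes carry mutually exclusive Bw4 or Bw6 serologic epitopes
determined by heavy-chain residues 77 and 80-83; the commercial anti-Bw4
and anti-Bw6 antibodies also recognise some HLA-A or HLA-C allotypes
bearing similar motifs.  This module

* normalises single-antigen (Luminex) bead signals against the pan-class-I
  W6/32 signal on the same bead, cancelling bead-coupling differences;
* scans mature heavy-chain sequences for Bw4/Bw6-like motifs in the 77-83
  window (motif residue sets are editable data, not code);
* flags cross-reactive alleles of non-target loci above a ratio threshold,
  used to exclude donors from epitope-antibody quantitation;
* regresses cell-derived ABC values on the bead-normalised binding ratio
  and flags allotypes whose donors mostly fall below the regression line —
  i.e. cell surface expression lower than the antibody-affinity
  expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DomainError, InsufficientDataError, ScanError
from .cohort import AMINO_ACIDS

__all__ = [
    "EpitopeMotifTable", "load_motif_table", "normalize_panel",
    "scan_epitope_motif", "classify_cross_reactivity",
    "BeadCellRegression", "BeadCellRegressionResults",
    "bead_vs_cell_regression", "MOTIF_WINDOW",
]

#: 1-based mature heavy-chain positions defining the serologic epitopes
MOTIF_WINDOW = (77, 83)
_STANDARD = frozenset(AMINO_ACIDS)


@dataclass
class EpitopeMotifTable:
    """Ordered motif definitions: name -> {position: allowed residue set}.

    Positions are 1-based on the mature heavy chain (signal peptide
    removed) and must lie in the 77-83 window.
    """

    motifs: dict = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = MOTIF_WINDOW
        for name, constraints in self.motifs.items():
            if not constraints:
                raise DomainError(f"motif {name!r} has no constraints")
            for pos, residues in constraints.items():
                if not lo <= pos <= hi:
                    raise DomainError(
                        f"motif {name!r} position {pos} outside {lo}..{hi}")
                if not residues or not set(residues) <= _STANDARD:
                    raise DomainError(
                        f"motif {name!r} at {pos}: residue set must be "
                        "non-empty standard amino acids")

    @classmethod
    def from_tsv(cls, path) -> "EpitopeMotifTable":
        df = pd.read_csv(path, sep="\t")
        motifs: dict = {}
        for rec in df.itertuples(index=False):
            motifs.setdefault(rec.motif, {})[int(rec.position)] = frozenset(
                rec.residues)
        return cls(motifs)


def load_motif_table() -> EpitopeMotifTable:
    """Load the default (editable) Bw4/Bw6 serologic motif definitions."""
    with resources.as_file(
            resources.files("hlabquant") / "data" / "motifs.tsv") as p:
        return EpitopeMotifTable.from_tsv(p)


def scan_epitope_motif(sequence: str, motifs: EpitopeMotifTable | None = None,
                       offset: int = 0) -> str:
    """Call the serologic epitope of a mature heavy-chain sequence.

    Checks the residue constraints of each motif, in table order, against
    the 77-83 window; returns the first motif whose constraints all match,
    or ``"none"``.  ``offset`` shifts the numbering for precursor
    sequences (e.g. 24 for a FASTA retaining the signal peptide).
    """
    if motifs is None:
        motifs = load_motif_table()
    lo, hi = MOTIF_WINDOW
    if len(sequence) < hi + offset:
        raise ScanError(
            f"sequence length {len(sequence)} < {hi + offset}; cannot scan")
    window = sequence[lo - 1 + offset: hi + offset].upper()
    if not set(window) <= _STANDARD:
        raise ScanError(f"non-standard residue in 77-83 window: {window!r}")
    for name, constraints in motifs.motifs.items():
        if all(window[pos - lo] in residues
               for pos, residues in constraints.items()):
            return name
    return "none"


def normalize_panel(panel: pd.DataFrame, dilution: str | None = "1:50"
                    ) -> pd.DataFrame:
    """Per-allele test-antibody / pan-class-I binding ratios.

    Each bead's test MFI is divided by its W6/32 reference MFI, cancelling
    differences in HLA coupling to beads; ratios are then averaged across
    replicates at the analysed dilution (default the single 1:50 dilution;
    pass ``None`` to pool all dilutions).  Beads with a zero reference are
    excluded with a warning.

    Returns columns: allele, ratio, ratio_sd, n.
    """
    df = panel
    if dilution is not None and "dilution" in df.columns:
        df = df[df["dilution"] == dilution]
    bad = df["ref_mfi"] <= 0
    if bad.any():
        warnings.warn(f"excluded {int(bad.sum())} bead record(s) with "
                      "non-positive reference MFI", stacklevel=2)
        df = df[~bad]
    if (df["test_mfi"] < 0).any():
        raise DomainError("test MFIs must be >= 0")
    ratios = df["test_mfi"] / df["ref_mfi"]
    out = (df.assign(_r=ratios)
             .groupby("allele", sort=False)["_r"]
             .agg(ratio="mean", ratio_sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
                  n="size")
             .reset_index())
    out["n"] = out["n"].astype(int)
    return out


def classify_cross_reactivity(alleles, binding: pd.DataFrame,
                              threshold: float) -> pd.DataFrame:
    """Flag alleles whose normalized binding ratio reaches *threshold*.

    Intended for alleles of non-target loci (e.g. HLA-A screened against
    anti-Bw4): a ratio >= threshold (inclusive) marks the allele
    cross-reactive, so donors carrying it are excluded from epitope
    quantitation.  Alleles absent from the panel are flagged ``unknown``,
    never assumed negative.

    Returns columns: allele, ratio, status in {cross_reactive, negative,
    unknown}.
    """
    if threshold <= 0:
        raise DomainError("threshold must be > 0")
    lut = binding.set_index("allele")["ratio"]
    rows = []
    for allele in alleles:
        if allele not in lut.index:
            rows.append({"allele": allele, "ratio": np.nan,
                         "status": "unknown"})
            continue
        r = float(lut[allele])
        rows.append({"allele": allele, "ratio": r,
                     "status": "cross_reactive" if r >= threshold
                     else "negative"})
    return pd.DataFrame(rows)


class BeadCellRegression:
    """Model relating bead-normalised antibody binding to cell-derived ABC.

    One point per donor: x = the Luminex test/W6/32 ratio of the donor's
    epitope allele, y = the donor's cell-derived ABC (or ABC ratio) in one
    subset.  A significant positive slope indicates that antibody-affinity
    differences drive part of the apparent expression differences; alleles
    whose donors mostly fall below the fitted line express less than the
    affinity expectation.
    """

    def __init__(self, binding: pd.DataFrame, abc: pd.DataFrame,
                 subset: str, value_col: str = "mean_abc"):
        df = abc[abc["subset"] == subset] if "subset" in abc.columns else abc
        if "allele" not in df.columns:
            raise DomainError("abc table must carry an 'allele' column")
        merged = df.merge(binding[["allele", "ratio"]], on="allele",
                          how="inner")
        if merged["allele"].nunique() < 3:
            raise InsufficientDataError(
                "need >= 3 alleles with both bead and cell values")
        self.data = merged
        self.value_col = value_col

    def fit(self) -> "BeadCellRegressionResults":
        x = self.data["ratio"].to_numpy(dtype=float)
        y = self.data[self.value_col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise DomainError("bead ratios have zero variance")
        lr = sps.linregress(x, y)
        resid = y - (lr.intercept + lr.slope * x)
        points = self.data[["donor", "allele"]].copy()
        points["residual"] = resid
        # numerically-zero residuals (perfect fit) do not count as negative
        tol = 1e-9 * max(np.abs(y).max(), 1.0)
        below = (points.assign(neg=points["residual"] < -tol)
                       .groupby("allele")["neg"].mean())
        flagged = sorted(below[below > 0.5].index)
        return BeadCellRegressionResults(
            slope=float(lr.slope), intercept=float(lr.intercept),
            r=float(lr.rvalue), p_value=float(lr.pvalue),
            residuals=points, below_line_alleles=flagged)


@dataclass(frozen=True)
class BeadCellRegressionResults:
    """OLS fit of cell ABC on bead binding ratio, with residual flags.

    ``below_line_alleles`` lists alleles for which more than half of the
    donor points have negative residuals.
    """

    slope: float
    intercept: float
    r: float
    p_value: float
    residuals: pd.DataFrame
    below_line_alleles: list

    def summary(self) -> str:
        flagged = ", ".join(self.below_line_alleles) or "none"
        return ("Bead-vs-cell regression\n"
                f"  slope      {self.slope:12.6g}\n"
                f"  intercept  {self.intercept:12.6g}\n"
                f"  Pearson r  {self.r:12.4f}  (p = {self.p_value:.3g})\n"
                f"  below-line alleles: {flagged}")


def bead_vs_cell_regression(binding: pd.DataFrame, abc: pd.DataFrame,
                            subset: str, value_col: str = "mean_abc"
                            ) -> BeadCellRegressionResults:
    """Functional wrapper around :class:`BeadCellRegression`."""
    return BeadCellRegression(binding, abc, subset, value_col).fit()
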