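"""Positional Shannon-entropy profiles of allele-assigned peptidomes.

For a set of 9-mer peptides assigned to an HLA allotype, the per-position
amino-acid frequencies q(a, i) are tabulated (raw counts, no pseudocounts
or sequence weighting) and the positional diversity is summarised as

    E(i) = - sum_a q(a, i) * log2 q(a, i)        (0 * log2 0 == 0),

in bits: 0 at a fully restricted (anchor) position, log2(20) ~ 4.32 when
all twenty residues are used uniformly.  Low entropy at P2 and Pc marks
the canonical anchors; unusually restricted auxiliary positions (e.g. P3,
P5, Pc-1) distinguish allotypes with deeply buried peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, InsufficientDataError
from .cohort import AMINO_ACIDS

__all__ = [
    "filter_peptides", "exclusive_assignment_filter", "frequency_matrix",
    "shannon_entropy", "entropy_profile", "EntropyProfile", "MAX_ENTROPY_BITS",
]

logger = logging.getLogger(__name__)

MAX_ENTROPY_BITS = float(np.log2(len(AMINO_ACIDS)))
_STANDARD = frozenset(AMINO_ACIDS)
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def filter_peptides(table: pd.DataFrame, length: int = 9):
    """Keep peptides of exact *length* made only of the 20 standard residues.

    Parameters
    ----------
    table
        Two-column DataFrame ``(allele, peptide)``.
    length
        Exact peptide length to retain (9 for the canonical class I core).

    Returns
    -------
    (kept, counts)
        ``kept`` mirrors the input restricted to surviving peptides
        (uppercased); ``counts`` reports kept/dropped per allele.  Alleles
        left with no peptides are omitted with a warning.
    """
    if length < 1:
        raise DomainError("length must be >= 1")
    kept_rows, count_rows = [], []
    for allele, g in table.groupby("allele", sort=False):
        peps = g["peptide"].astype(str).str.upper()
        ok = peps.str.len().eq(length) & peps.map(
            lambda p: set(p) <= _STANDARD)
        n_kept, n_dropped = int(ok.sum()), int((~ok).sum())
        count_rows.append({"allele": allele, "kept": n_kept,
                           "dropped": n_dropped})
        if n_kept == 0:
            logger.warning("allele %s has no %d-mers after filtering; omitted",
                           allele, length)
            continue
        for p in peps[ok]:
            kept_rows.append({"allele": allele, "peptide": p})
    return pd.DataFrame(kept_rows), pd.DataFrame(count_rows)


def exclusive_assignment_filter(table: pd.DataFrame,
                                compatible: set | None = None) -> pd.DataFrame:
    """Remove peptides shared by alleles that do not share binding motifs.

    A peptide assigned to two alleles not declared motif-compatible is
    removed from both; sharing between compatible alleles is retained.
    ``compatible`` is a set of frozensets of allele pairs (order-free).
    """
    compatible = compatible or set()
    by_pep = table.groupby("peptide")["allele"].agg(lambda s: set(s))
    drop = set()
    for pep, alleles in by_pep.items():
        alleles = sorted(alleles)
        for i, a in enumerate(alleles):
            for b in alleles[i + 1:]:
                if frozenset((a, b)) not in compatible:
                    drop.add(pep)
    return table[~table["peptide"].isin(drop)].reset_index(drop=True)


def frequency_matrix(peptides) -> np.ndarray:
    """Per-position residue frequencies q(a, i) of an aligned peptide set.

    Returns an array of shape (20, L) whose columns sum to 1 (raw counts
    over n peptides, no pseudocounts).
    """
    peptides = list(peptides)
    if not peptides:
        raise InsufficientDataError("empty peptide set")
    length = len(peptides[0])
    if any(len(p) != length for p in peptides):
        raise DomainError("all peptides must have equal length")
    counts = np.zeros((len(AMINO_ACIDS), length))
    for p in peptides:
        for i, a in enumerate(p):
            try:
                counts[_AA_INDEX[a], i] += 1
            except KeyError:
                raise DomainError(f"non-standard residue {a!r} in {p!r}") from None
    return counts / len(peptides)


def shannon_entropy(q) -> float:
    """Shannon entropy of one frequency column, in bits.

    ``q`` must be non-negative and sum to 1 within 1e-9; the 0*log2(0)
    terms contribute zero.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise DomainError("frequencies must be >= 0")
    if abs(q.sum() - 1.0) > 1e-9:
        raise DomainError(f"frequency column sums to {q.sum()!r}, not 1")
    nz = q[q > 0]
    return float(-np.sum(nz * np.log2(nz)))


@dataclass(frozen=True)
class EntropyProfile:
    """Per-position entropy summary of one allotype's peptidome."""

    allele: str
    entropy_bits: np.ndarray   # shape (L,)
    q: np.ndarray              # shape (20, L)
    n_peptides: int
    n_datasets: int = 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "allele": self.allele,
            "position": np.arange(1, len(self.entropy_bits) + 1),
            "entropy_bits": self.entropy_bits,
            "n_peptides": self.n_peptides,
            "n_datasets": self.n_datasets,
        })

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pos = np.arange(1, len(self.entropy_bits) + 1)
        ax.bar(pos, self.entropy_bits)
        ax.set_ylim(0, MAX_ENTROPY_BITS)
        ax.set_xlabel("peptide position")
        ax.set_ylabel("Shannon entropy (bits)")
        ax.set_title(f"{self.allele}  (x = {self.n_peptides})")
        return ax


def entropy_profile(table: pd.DataFrame, allele: str,
                    n_datasets: int = 1) -> EntropyProfile:
    """Frequency matrix and per-position entropy for one allele's peptides.

    Expects a filtered (fixed-length, standard-residue) peptide table.
    """
    peps = table.loc[table["allele"] == allele, "peptide"].tolist()
    if not peps:
        raise InsufficientDataError(f"no peptides for allele {allele}")
    q = frequency_matrix(peps)
    ent = np.array([shannon_entropy(q[:, i]) for i in range(q.shape[1])])
    return EntropyProfile(allele=allele, entropy_bits=ent, q=q,
                          n_peptides=len(peps), n_datasets=n_datasets)
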