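"""Ratio summaries and group-comparison statistics.

Ratio readouts
--------------
* HC10 receptivity: specific/control-peptide HC10 staining; HC10 binds
  open (peptide-deficient) class I, so a ratio above 1 reports surface
  molecules receptive to exogenous peptide.
* surface fraction: fixed / (fixed + permeabilized) staining; values
  below 1 indicate an intracellular pool.
* tapasin ratio: tapasin MFI relative to W6/32 per subset, normalized to
  the donor's monocyte value.
* 2^-dCt: relative transcript abundance from RT-PCR cycle thresholds.

Comparisons operate on donor-level means (one point per donor): classical
one-way ANOVA with a configurable pairwise follow-up (Tukey HSD default),
Welch's t-test with Satterthwaite degrees of freedom, and Pearson
correlation/OLS.  Significance tiers follow the conventional star map
(* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateDataError, DomainError, InsufficientDataError

__all__ = [
    "hc10_ratio", "surface_fraction", "tapasin_ratio", "expr_2dct",
    "significance_tier", "one_way_anova", "welch_t", "pearson_regression",
    "GroupComparison", "PairwiseResult", "RegressionSummary",
]


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------

def _positive_denominator(value: float, what: str) -> None:
    if value <= 0:
        raise DomainError(f"{what} must be > 0, got {value}")


def hc10_ratio(specific_mfi: float, control_mfi: float) -> float:
    """Exogenous-peptide receptivity: HC10 signal with the specific peptide
    over the matched mutated/truncated control peptide.  1.0 = no signal."""
    _positive_denominator(control_mfi, "control-peptide MFI")
    return specific_mfi / control_mfi


def surface_fraction(fixed_mfi: float, fixed_perm_mfi: float) -> float:
    """Surface/total class I: fixed over fixed-and-permeabilized staining."""
    _positive_denominator(fixed_perm_mfi, "fixed+permeabilized MFI")
    return fixed_mfi / fixed_perm_mfi


def tapasin_ratio(tapasin_mfi, pan_mfi, reference_ratio: float) -> float:
    """(tapasin / W6/32) for one subset, normalized to the donor's
    reference-subset (monocyte) tapasin/W6/32 ratio."""
    _positive_denominator(pan_mfi, "pan-class-I MFI")
    _positive_denominator(reference_ratio, "reference-subset ratio")
    return (tapasin_mfi / pan_mfi) / reference_ratio


def expr_2dct(ct_target: float, ct_reference: float) -> float:
    """Relative transcript abundance 2^-(Ct_target - Ct_reference)."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise DomainError("Ct values must be finite")
    return float(2.0 ** (-(ct_target - ct_reference)))


# ---------------------------------------------------------------------------
# significance tiers
# ---------------------------------------------------------------------------

_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_tier(p: float) -> str:
    """Map a p value to the conventional star annotation ('' if n.s.)."""
    if not 0 <= p <= 1:
        raise DomainError(f"p value must lie in [0, 1], got {p}")
    for cut, stars in _TIERS:
        if p < cut:
            return stars
    return ""


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_adjusted: float
    tier: str


@dataclass(frozen=True)
class GroupComparison:
    """Results of a one-way ANOVA or Welch comparison across groups."""

    method: str
    group_means: dict
    statistic: float        # F for ANOVA, t for Welch
    p_value: float
    tier: str
    df: tuple               # (between, within) or Satterthwaite df
    pairwise: list = field(default_factory=list)
    posthoc: str = "none"

    def summary(self) -> str:
        lines = [f"{self.method}: statistic = {self.statistic:.4f}, "
                 f"p = {self.p_value:.4g} {self.tier}"]
        for name, m in self.group_means.items():
            lines.append(f"  {name:>12}  mean = {m:.4g}")
        if self.pairwise:
            lines.append(f"  post-hoc ({self.posthoc}):")
            for pr in self.pairwise:
                lines.append(f"    {pr.group_a} vs {pr.group_b}: "
                             f"p_adj = {pr.p_adjusted:.4g} {pr.tier}")
        return "\n".join(lines)


def _check_groups(groups: dict, min_per_group: int = 2) -> dict:
    clean = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < min_per_group:
            raise InsufficientDataError(
                f"group {name!r} has {arr.size} observation(s); "
                f"need >= {min_per_group}")
        clean[str(name)] = arr
    if len(clean) < 2:
        raise InsufficientDataError("need at least 2 groups")
    return clean


def one_way_anova(groups: dict, posthoc: str = "tukey",
                  alpha: float = 0.05) -> GroupComparison:
    """Classical one-way ANOVA across allele (or subset) groups.

    *groups* maps group label -> donor-level observations.  The pairwise
    follow-up is Tukey HSD by default (``posthoc`` in {"tukey",
    "bonferroni", "none"}); Bonferroni uses pairwise Welch tests with
    multiplied p values.
    """
    clean = _check_groups(groups)
    allv = np.concatenate(list(clean.values()))
    if np.ptp(allv) == 0:
        raise DegenerateDataError("all observations identical; F undefined")
    within = sum(np.sum((v - v.mean()) ** 2) for v in clean.values())
    if within == 0:
        raise DegenerateDataError("zero within-group variance in every group")
    f_stat, p = sps.f_oneway(*clean.values())
    k = len(clean)
    n = sum(v.size for v in clean.values())
    pairwise: list[PairwiseResult] = []
    if posthoc == "tukey":
        names = list(clean)
        res = sps.tukey_hsd(*clean.values())
        for i, a in enumerate(names):
            for j in range(i + 1, k):
                padj = float(res.pvalue[i, j])
                pairwise.append(PairwiseResult(
                    a, names[j], float(res.statistic[i, j]), padj,
                    significance_tier(padj)))
    elif posthoc == "bonferroni":
        names = list(clean)
        m = k * (k - 1) // 2
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                t, pr = sps.ttest_ind(clean[a], clean[b], equal_var=False)
                padj = min(1.0, float(pr) * m)
                pairwise.append(PairwiseResult(a, b, float(t), padj,
                                               significance_tier(padj)))
    elif posthoc != "none":
        raise ValueError(f"unknown posthoc {posthoc!r}")
    return GroupComparison(
        method="one-way ANOVA",
        group_means={name: float(v.mean()) for name, v in clean.items()},
        statistic=float(f_stat), p_value=float(p),
        tier=significance_tier(float(p)),
        df=(k - 1, n - k), pairwise=pairwise, posthoc=posthoc)


def welch_t(values_a, values_b, name_a: str = "a",
            name_b: str = "b") -> GroupComparison:
    """Welch's two-sample t-test (unequal variances, Satterthwaite df)."""
    clean = _check_groups({name_a: values_a, name_b: values_b})
    a, b = clean[name_a], clean[name_b]
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            # identical groups: no evidence of difference by convention
            return GroupComparison(
                method="Welch's t-test",
                group_means={name_a: float(a.mean()), name_b: float(b.mean())},
                statistic=0.0, p_value=1.0, tier="",
                df=(float(a.size + b.size - 2),))
        raise DegenerateDataError("both groups constant; t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    return GroupComparison(
        method="Welch's t-test",
        group_means={name_a: float(a.mean()), name_b: float(b.mean())},
        statistic=float(t), p_value=float(p),
        tier=significance_tier(float(p)), df=(float(df),))


@dataclass(frozen=True)
class RegressionSummary:
    slope: float
    intercept: float
    r: float
    p_value: float
    tier: str


def pearson_regression(x, y) -> RegressionSummary:
    """OLS slope/intercept with Pearson r and its two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero variance in x")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-y yields r = 0 warning
        lr = sps.linregress(x, y)
    return RegressionSummary(slope=float(lr.slope),
                             intercept=float(lr.intercept),
                             r=float(lr.rvalue), p_value=float(lr.pvalue),
                             tier=significance_tier(float(lr.pvalue)))
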