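"""Bead-calibrated antibody binding capacity (ABC) quantitation.

Converts background-subtracted geometric MFI into ABC (antibody molecules
bound per cell) via a standard curve fitted to calibration beads bearing
known numbers of capture sites, applies the epitope-homozygote genotype
correction, and aggregates replicate blood draws into per-donor summaries
and epitope/pan-class-I ratios.

The fitted mapping is a statsmodels-style Model/Results pair:

>>> curve = StandardCurve(abc=[10, 100, 1000], mfi=[10, 100, 1000]).fit()
>>> curve.interpolate(250.0)
250.0...
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import (CalibrationError, DomainError, InsufficientDataError,
                         PairingError, RangeError)

__all__ = [
    "StandardCurve", "CalibrationCurve", "fit_standard_curve",
    "subtract_isotype", "BackgroundSubtracted", "interpolate_abc",
    "compute_abc", "calibrate_stains", "aggregate_donor", "aggregate_abc",
    "AbcSummary", "epitope_ratio", "epitope_ratio_table",
    "normalize_to_reference_subset",
]

EPITOPE_ANTIBODIES = ("anti-Bw6", "anti-Bw4")
PAN_ANTIBODY = "W6/32"


class StandardCurve:
    """Model for the bead standard curve: ABC regressed on measured MFI.

    Parameters
    ----------
    abc, mfi
        Known ABC per bead population (molecules/cell) and the measured
        geometric MFI.  At least three populations with distinct ABC are
        required.
    """

    def __init__(self, abc, mfi):
        abc = np.asarray(abc, dtype=float)
        mfi = np.asarray(mfi, dtype=float)
        if abc.shape != mfi.shape or abc.ndim != 1:
            raise CalibrationError("abc and mfi must be 1-D arrays of equal length")
        if len(np.unique(abc)) < 3:
            raise CalibrationError(
                "at least 3 bead populations with distinct known ABC required")
        if np.any(abc <= 0):
            raise CalibrationError("known ABC values must be > 0")
        if not np.all(np.isfinite(mfi)):
            raise CalibrationError("bead MFIs must be finite")
        self.abc = abc
        self.mfi = mfi

    @classmethod
    def from_dataframe(cls, beads: pd.DataFrame, abc_col="abc", mfi_col="mfi"):
        return cls(beads[abc_col].to_numpy(), beads[mfi_col].to_numpy())

    def fit(self, mode: str = "log-log") -> "CalibrationCurve":
        """Ordinary least squares of ABC on MFI.

        In ``log-log`` mode (default; bead standards span decades) both
        axes are log-transformed before the fit; ``linear-linear`` fits the
        raw values.
        """
        if mode == "log-log":
            if np.any(self.mfi <= 0):
                raise CalibrationError("log-log mode requires all MFIs > 0")
            x, y = np.log(self.mfi), np.log(self.abc)
        elif mode == "linear-linear":
            x, y = self.mfi, self.abc
        else:
            raise ValueError(f"unknown fit mode {mode!r}")
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid ** 2) / ss_tot
        if slope <= 0:
            raise CalibrationError(
                "fitted slope is not positive: signal must increase with ABC")
        return CalibrationCurve(mode=mode, slope=float(slope),
                                intercept=float(intercept),
                                r_squared=float(min(r2, 1.0)),
                                mfi_range=(float(self.mfi.min()),
                                           float(self.mfi.max())))


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted MFI -> ABC mapping (results object of :class:`StandardCurve`)."""

    mode: str
    slope: float
    intercept: float
    r_squared: float
    mfi_range: tuple

    def interpolate(self, mfi, out_of_range: str = "clamp"):
        """Map measured MFI to ABC (monotone non-decreasing in MFI).

        ``out_of_range`` controls behaviour outside the bead MFI range:
        ``clamp`` (default) pins to the range with a warning,
        ``extrapolate`` extends the fitted line, ``error`` raises.
        """
        scalar = np.isscalar(mfi)
        mfi = np.atleast_1d(np.asarray(mfi, dtype=float))
        if np.any(mfi < 0):
            raise DomainError("MFI must be >= 0")
        lo, hi = self.mfi_range
        outside = (mfi < lo) | (mfi > hi)
        if np.any(outside):
            if out_of_range == "error":
                raise RangeError(
                    f"MFI outside calibrated range [{lo:g}, {hi:g}]")
            if out_of_range == "clamp":
                warnings.warn("MFI outside calibrated range; clamped",
                              stacklevel=2)
                mfi = np.clip(mfi, lo, hi)
            elif out_of_range != "extrapolate":
                raise ValueError(f"unknown out_of_range policy {out_of_range!r}")
        if self.mode == "log-log":
            with np.errstate(divide="ignore"):
                abc = np.exp(self.intercept + self.slope * np.log(mfi))
            abc = np.where(mfi == 0, 0.0, abc)
        else:
            abc = self.intercept + self.slope * mfi
        return float(abc[0]) if scalar else abc

    def summary(self) -> str:
        lo, hi = self.mfi_range
        return (f"Standard curve ({self.mode})\n"
                f"  slope     {self.slope:12.6g}\n"
                f"  intercept {self.intercept:12.6g}\n"
                f"  r^2       {self.r_squared:12.6f}\n"
                f"  MFI range [{lo:g}, {hi:g}]")


def fit_standard_curve(beads, mode: str = "log-log") -> CalibrationCurve:
    """Functional wrapper: fit a curve from a beads DataFrame or (abc, mfi)."""
    if isinstance(beads, pd.DataFrame):
        return StandardCurve.from_dataframe(beads).fit(mode)
    abc, mfi = beads
    return StandardCurve(abc, mfi).fit(mode)


class BackgroundSubtracted(NamedTuple):
    value: float
    floored: bool


def subtract_isotype(specific_mfi: float, isotype_mfi: float,
                     floor: float = 0.0) -> BackgroundSubtracted:
    """Subtract the isotype-control background from a specific stain.

    Returns ``max(specific - isotype, floor)`` with a flag recording
    whether the floor was applied (signal at or below background).
    """
    for name, v in (("specific_mfi", specific_mfi),
                    ("isotype_mfi", isotype_mfi)):
        if not np.isfinite(v) or v < 0:
            raise DomainError(f"{name} must be finite and >= 0, got {v}")
    raw = specific_mfi - isotype_mfi
    if raw < floor:
        return BackgroundSubtracted(floor, True)
    return BackgroundSubtracted(raw, False)


def interpolate_abc(curve: CalibrationCurve, mfi,
                    out_of_range: str = "clamp"):
    """Functional wrapper around :meth:`CalibrationCurve.interpolate`."""
    return curve.interpolate(mfi, out_of_range=out_of_range)


def _correction_applies(geno_row) -> bool:
    """Homozygote rule: HLA-B epitope homozygous AND both HLA-C alleles
    carry the epitope motif -> the epitope antibody sees two doses."""
    return bool(geno_row["epitope_homozygous"]) and bool(
        geno_row["both_c_epitope_bearing"])


def calibrate_stains(stains: pd.DataFrame, curve: CalibrationCurve,
                     genotypes: pd.DataFrame,
                     out_of_range: str = "clamp") -> pd.DataFrame:
    """Chain isotype subtraction -> curve interpolation -> genotype correction
    over a full stain table.

    Epitope-antibody ABC values of donors satisfying the homozygote rule are
    halved (reported as the per-allele contribution); pan-class-I (W6/32)
    values are never halved.

    Returns columns: donor, draw, subset, antibody, abc, corrected, floored.
    """
    if stains["isotype_mfi"].isna().any():
        missing = stains[stains["isotype_mfi"].isna()].iloc[0]
        raise PairingError(
            f"missing isotype pair for donor={missing['donor']} "
            f"draw={missing['draw']} subset={missing['subset']}")
    geno = genotypes.set_index("donor")
    rows = []
    for rec in stains.itertuples(index=False):
        sub = subtract_isotype(rec.mfi, rec.isotype_mfi)
        abc = curve.interpolate(sub.value, out_of_range=out_of_range)
        corrected = False
        if rec.antibody in EPITOPE_ANTIBODIES:
            if rec.donor not in geno.index:
                raise PairingError(f"no genotype for donor {rec.donor}")
            if _correction_applies(geno.loc[rec.donor]):
                abc *= 0.5
                corrected = True
        rows.append({"donor": rec.donor, "draw": rec.draw,
                     "subset": rec.subset, "antibody": rec.antibody,
                     "abc": abc, "corrected": corrected,
                     "floored": sub.floored})
    return pd.DataFrame(rows)


# spec operation name; works on one donor/draw or the full table alike
compute_abc = calibrate_stains


@dataclass(frozen=True)
class AbcSummary:
    """Per-donor ABC summary over independent blood draws."""

    mean: float
    sem: float
    n: int
    single_draw: bool  # SEM undefined from one draw; reported as 0, flagged


def aggregate_donor(values) -> AbcSummary:
    """Mean, SEM = sd/sqrt(N) and N over a donor's independent draws."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InsufficientDataError("no draws to aggregate")
    n = int(values.size)
    if n == 1:
        return AbcSummary(float(values[0]), 0.0, 1, True)
    sem = float(np.std(values, ddof=1) / np.sqrt(n))
    return AbcSummary(float(values.mean()), sem, n, False)


def aggregate_abc(abc: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a calibrated stain table to donor level.

    Returns one row per (donor, subset, antibody) with mean, sem, n and the
    correction flag.
    """
    def _agg(g):
        s = aggregate_donor(g["abc"].to_numpy())
        return pd.Series({"mean_abc": s.mean, "sem": s.sem, "n": s.n,
                          "single_draw": s.single_draw,
                          "corrected": bool(g["corrected"].any())})

    out = (abc.groupby(["donor", "subset", "antibody"], sort=False)
              .apply(_agg, include_groups=False).reset_index())
    out["n"] = out["n"].astype(int)
    return out


def epitope_ratio(abc_epitope: float, abc_pan: float) -> float:
    """Epitope ABC / pan-class-I ABC for one donor and subset."""
    if abc_pan <= 0:
        raise DomainError("pan-class-I ABC must be > 0")
    return abc_epitope / abc_pan


def epitope_ratio_table(agg: pd.DataFrame,
                        pan_antibody: str = PAN_ANTIBODY) -> pd.DataFrame:
    """Per-donor epitope/pan ABC ratios from an aggregated ABC table.

    The ratio of per-donor means is used (each donor's averaged epitope ABC
    divided by the same donor/subset averaged pan ABC).
    """
    pan = (agg[agg["antibody"] == pan_antibody]
           .set_index(["donor", "subset"])["mean_abc"])
    epi = agg[agg["antibody"].isin(EPITOPE_ANTIBODIES)]
    rows = []
    for rec in epi.itertuples(index=False):
        key = (rec.donor, rec.subset)
        if key not in pan.index:
            continue
        rows.append({"donor": rec.donor, "subset": rec.subset,
                     "antibody": rec.antibody,
                     "ratio_to_pan": epitope_ratio(rec.mean_abc, pan[key])})
    return pd.DataFrame(rows)


def normalize_to_reference_subset(agg: pd.DataFrame,
                                  reference_subset: str = "monocyte"
                                  ) -> pd.DataFrame:
    """Divide each donor's per-subset ABC by that donor's reference-subset
    value (per antibody); the reference row normalizes to 1.0.

    Donors lacking the reference subset get NaN with ``missing_reference``
    set, rather than being dropped silently.
    """
    ref = (agg[agg["subset"] == reference_subset]
           .set_index(["donor", "antibody"])["mean_abc"])
    out = agg.copy()
    norm, missing = [], []
    for rec in agg.itertuples(index=False):
        key = (rec.donor, rec.antibody)
        if key in ref.index and ref[key] > 0:
            norm.append(rec.mean_abc / ref[key])
            missing.append(False)
        else:
            norm.append(np.nan)
            missing.append(True)
    out["normalized"] = norm
    out["missing_reference"] = missing
    return out
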