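"""Cell-surface half-life estimation from Brefeldin-A decay time courses.

After Brefeldin A blocks forward trafficking of newly synthesised class I
to the cell surface, the surface epitope signal decays with the molecule's
surface half-life.  Each time course is fitted with a one-phase exponential
decay with the plateau constrained to zero,

    y(t) = y0 * exp(-k * t),        t_half = ln(2) / k,

by nonlinear least squares initialised from the log-linear regression of
ln(y) on t.  Replicate fits from independent blood draws are averaged per
donor, and a QC inclusion rule keeps donors with SEM/mean < 0.33 based on
n >= 2 independent measurements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import DomainError, FitError, InsufficientDataError

__all__ = [
    "OnePhaseDecay", "DecayFit", "fit_one_phase_decay",
    "halflife_from_rate", "HalfLifeEstimate", "aggregate_halflives",
    "fit_decay_table", "aggregate_halflife_table", "QC_SEM_FRACTION",
]

logger = logging.getLogger(__name__)

#: donors pass QC when SEM of replicate half-lives is below this fraction
#: of the mean, with at least two independent measurements
QC_SEM_FRACTION = 0.33


def halflife_from_rate(k: float) -> float:
    """t_half = ln(2)/k for a one-phase decay with zero plateau."""
    if k <= 0:
        raise DomainError(f"decay rate must be > 0, got {k}")
    return math.log(2.0) / k


class OnePhaseDecay:
    """Model for one surface-decay time course.

    Parameters
    ----------
    time
        Hours after Brefeldin-A addition; non-negative, strictly
        increasing, at least three points.
    mfi
        Isotype-subtracted geometric MFI at each time point.  Non-positive
        values are kept in the least-squares objective but excluded from
        the log-linear initialiser.
    """

    def __init__(self, time, mfi):
        t = np.asarray(time, dtype=float)
        y = np.asarray(mfi, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise InsufficientDataError("time and mfi must be 1-D and equal length")
        if len(t) < 3:
            raise InsufficientDataError("at least 3 time points required")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise DomainError("times must be non-negative and strictly increasing")
        self.time = t
        self.mfi = y

    def fit(self, loss: str = "linear") -> "DecayFit":
        """Nonlinear least squares of ``y0 * exp(-k t)`` with y0, k > 0.

        ``loss='linear'`` (default) minimises squared error on the MFI
        scale; ``loss='log'`` fits on the log scale using positive points
        only.  Raises :class:`FitError` on non-convergence.
        """
        t, y = self.time, self.mfi
        pos = y > 0
        if pos.sum() < 2:
            raise FitError("fewer than 2 positive MFIs; cannot initialise")
        b, a = np.polyfit(t[pos], np.log(y[pos]), 1)
        non_decaying = b >= 0
        y0_init = float(np.exp(a))
        k_init = max(-float(b), 1e-6)
        try:
            if loss == "log":
                popt, _ = curve_fit(
                    lambda tt, ly0, k: ly0 - k * tt, t[pos], np.log(y[pos]),
                    p0=(math.log(y0_init), k_init),
                    bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
                    maxfev=10_000)
                y0_hat, k_hat = math.exp(popt[0]), float(popt[1])
            elif loss == "linear":
                popt, _ = curve_fit(
                    lambda tt, y0, k: y0 * np.exp(-k * tt), t, y,
                    p0=(y0_init, k_init),
                    bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                    maxfev=10_000)
                y0_hat, k_hat = float(popt[0]), float(popt[1])
            else:
                raise ValueError(f"unknown loss {loss!r}")
        except RuntimeError as exc:  # scipy signals non-convergence this way
            raise FitError(f"decay fit did not converge: {exc}") from exc
        resid = y - y0_hat * np.exp(-k_hat * t)
        return DecayFit(y0=y0_hat, k=k_hat,
                        t_half=halflife_from_rate(k_hat),
                        ssr=float(np.sum(resid ** 2)),
                        n_points=len(t), non_decaying=bool(non_decaying),
                        loss=loss)


@dataclass(frozen=True)
class DecayFit:
    """Results of a one-phase decay fit (plateau fixed at zero)."""

    y0: float
    k: float          # per hour
    t_half: float     # hours
    ssr: float
    n_points: int
    non_decaying: bool
    loss: str

    def predict(self, time):
        return self.y0 * np.exp(-self.k * np.asarray(time, dtype=float))

    def summary(self) -> str:
        flag = "  [non-decaying initial slope]" if self.non_decaying else ""
        return (f"One-phase decay (plateau = 0, {self.loss} loss){flag}\n"
                f"  y0      {self.y0:12.4f} MFI\n"
                f"  k       {self.k:12.6f} /h\n"
                f"  t_half  {self.t_half:12.4f} h\n"
                f"  SSR     {self.ssr:12.4g}  (n = {self.n_points})")

    def plot(self, ax=None):
        """Overlay the fitted curve on nothing (callers add their data)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tt = np.linspace(0, 1.1 * 3 * self.t_half, 200)
        ax.plot(tt, self.predict(tt), label=f"t1/2 = {self.t_half:.2f} h")
        ax.set_xlabel("hours after BFA")
        ax.set_ylabel("MFI")
        ax.legend()
        return ax


def fit_one_phase_decay(time, mfi, loss: str = "linear") -> DecayFit:
    """Functional wrapper: fit one series and return a :class:`DecayFit`."""
    return OnePhaseDecay(time, mfi).fit(loss=loss)


@dataclass(frozen=True)
class HalfLifeEstimate:
    """Donor-level half-life summary with the QC inclusion flag.

    ``qc_pass`` is true iff n >= 2 independent measurements and
    SEM/mean < 0.33.
    """

    mean: float   # hours
    sem: float
    n: int
    qc_pass: bool


def aggregate_halflives(t_halves) -> HalfLifeEstimate:
    """Average a donor's replicate half-life fits and evaluate QC."""
    vals = np.asarray(list(t_halves), dtype=float)
    if vals.size == 0:
        raise InsufficientDataError("no successful fits to aggregate")
    n = int(vals.size)
    mean = float(vals.mean())
    sem = 0.0 if n == 1 else float(np.std(vals, ddof=1) / np.sqrt(n))
    qc = n >= 2 and sem / mean < QC_SEM_FRACTION
    return HalfLifeEstimate(mean=mean, sem=sem, n=n, qc_pass=bool(qc))


def fit_decay_table(decay: pd.DataFrame, loss: str = "linear") -> pd.DataFrame:
    """Fit every (donor, draw, subset, antibody) series in a decay table.

    Series that fail to converge are excluded and logged rather than
    aborting the batch.  Expects columns donor, draw, subset, antibody,
    time_h, mfi and optionally isotype_mfi (subtracted when present).
    """
    rows = []
    keys = ["donor", "draw", "subset", "antibody"]
    for key, g in decay.groupby(keys, sort=False):
        g = g.sort_values("time_h")
        y = g["mfi"].to_numpy(dtype=float)
        if "isotype_mfi" in g:
            y = y - g["isotype_mfi"].to_numpy(dtype=float)
        try:
            fit = fit_one_phase_decay(g["time_h"].to_numpy(), y, loss=loss)
        except (FitError, InsufficientDataError) as exc:
            logger.warning("decay fit failed for %s: %s", key, exc)
            continue
        rows.append(dict(zip(keys, key)) | {
            "t_half": fit.t_half, "k": fit.k, "y0": fit.y0,
            "ssr": fit.ssr, "non_decaying": fit.non_decaying})
    return pd.DataFrame(rows)


def aggregate_halflife_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-day fits to donor level with the QC flag.

    Returns one row per (donor, subset, antibody): t_half, sem, n, qc_pass.
    """
    rows = []
    for (donor, subset, ab), g in fits.groupby(["donor", "subset", "antibody"],
                                               sort=False):
        est = aggregate_halflives(g["t_half"])
        rows.append({"donor": donor, "subset": subset, "antibody": ab,
                     "t_half": est.mean, "sem": est.sem, "n": est.n,
                     "qc_pass": est.qc_pass})
    return pd.DataFrame(rows)
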