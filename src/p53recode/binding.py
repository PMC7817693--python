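"""Fluorescence-polarization binding isotherm: model, normalization, fitting.

The titration signal follows the single-site hyperbola

    mP(C) = mP_max * C / (Kd + C) + mP_baseline

with C the protein concentration (molar).  Percent bound is the linear
rescaling of mP between baseline and saturation.  No ligand-depletion
(quadratic) correction is applied: the probe (2.5 nM) is far below the Kd
range of interest, so the free and total protein concentrations coincide;
this is a documented limitation below Kd ~ 10 nM.

Kd is fitted on a log scale to enforce positivity; confidence intervals come
from the parameter covariance at the optimum (delta method on log10 Kd).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class TitrationCurve:
    """One titration: protein concentrations (M) vs millipolarization."""

    concentrations: np.ndarray
    mP: np.ndarray
    salt_mM: float = 275.0
    probe_nM: float = 2.5
    name: str = ""

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        mp = np.asarray(self.mP, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "mP", mp)
        if conc.shape != mp.shape:
            raise ValueError("concentrations and mP must align")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(np.unique(conc)) < 4:
            raise ValueError("need at least 4 distinct concentrations")


@dataclass(frozen=True)
class FitResult:
    Kd: float  # molar
    mP_max: float
    mP_baseline: float
    residual_norm: float
    converged: bool
    Kd_ci: tuple[float, float]
    saturation_reached: bool = True
    message: str = ""


class NormalizationError(ValueError):
    """Zero mP span: percent bound is undefined."""


def model_mP(C, Kd: float, mP_max: float, mP_baseline: float):
    """The printed hyperbola; C may be scalar or array, molar units."""
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    C = np.asarray(C, dtype=float)
    return mP_max * C / (Kd + C) + mP_baseline


def percent_bound(mP, mP_baseline: float, mP_max: float):
    """Normalize mP to percent: ((mP - baseline) / (max - baseline)) * 100.

    Here ``mP_max`` is the saturated reading (baseline + span), matching the
    printed normalization.  Noisy values may fall outside [0, 100]; they are
    returned as-is (callers may flag them).
    """
    span = mP_max - mP_baseline
    if span == 0:
        raise NormalizationError("zero span between baseline and maximum mP")
    return (np.asarray(mP, dtype=float) - mP_baseline) / span * 100.0


def fit_kd(curve: TitrationCurve) -> FitResult:
    """Least-squares (Kd, mP_max, mP_baseline) from one titration.

    Non-convergence is flagged on the result, never raised.  If the largest
    concentration is well below the fitted Kd the curve never approached
    saturation and ``saturation_reached`` is False.
    """
    C = curve.concentrations
    y = curve.mP
    span0 = float(y.max() - y.min())
    if span0 == 0:
        return FitResult(
            Kd=np.nan, mP_max=0.0, mP_baseline=float(y[0]), residual_norm=0.0,
            converged=False, Kd_ci=(np.nan, np.nan), saturation_reached=False,
            message="flat curve: zero mP span",
        )
    # init: baseline = min reading, span = observed span, Kd = concentration
    # nearest the half-signal reading -- robust for monotone data
    half = y.min() + span0 / 2.0
    kd0 = float(C[np.argmin(np.abs(y - half))])

    def f(conc, log10_kd, mp_max, mp_base):
        return model_mP(conc, 10.0 ** log10_kd, mp_max, mp_base)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                f, C, y,
                p0=[np.log10(kd0), span0, float(y.min())],
                maxfev=10000,
            )
        converged = np.all(np.isfinite(popt)) and np.all(np.isfinite(pcov))
        message = ""
    except RuntimeError as exc:
        return FitResult(
            Kd=np.nan, mP_max=np.nan, mP_baseline=np.nan, residual_norm=np.nan,
            converged=False, Kd_ci=(np.nan, np.nan), saturation_reached=False,
            message=str(exc),
        )
    log_kd, mp_max, mp_base = popt
    kd = float(10.0 ** log_kd)
    resid = y - f(C, *popt)
    se_log = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    ci = (10.0 ** (log_kd - 1.959964 * se_log), 10.0 ** (log_kd + 1.959964 * se_log))
    saturated = C.max() >= kd  # max tested concentration at least reaches Kd
    if not saturated:
        message = "saturation not reached: max concentration below fitted Kd"
    return FitResult(
        Kd=kd,
        mP_max=float(mp_max),
        mP_baseline=float(mp_base),
        residual_norm=float(np.linalg.norm(resid)),
        converged=bool(converged),
        Kd_ci=(float(ci[0]), float(ci[1])),
        saturation_reached=bool(saturated),
        message=message,
    )


def average_kd(fits: list[FitResult]) -> float:
    """Replicate-averaged Kd (mean over converged fits), as reported."""
    kds = [f.Kd for f in fits if f.converged and np.isfinite(f.Kd)]
    if not kds:
        return float("nan")
    return float(np.mean(kds))


def salt_sensitivity_index(
    kd_low_salt: float | None, kd_high_salt: float | None
) -> float:
    """kd_high_salt / kd_low_salt; > 1 means affinity lost at high salt.

    Large ratios indicate the electrostatic binding mode, near-1 ratios the
    hydrophobic mode (no fixed cutoff is asserted).  An undetectable Kd on
    either side yields NaN, mirroring a non-detectable binding read-out.
    """
    if kd_low_salt is None or kd_high_salt is None:
        return float("nan")
    if not (kd_low_salt > 0 and kd_high_salt > 0):
        raise ValueError("Kd values must be positive")
    return kd_high_salt / kd_low_salt
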