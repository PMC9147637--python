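"""Assay-quality metrics: the Z-factor and the positive-control IC50.

Z = 1 - 3 (s_sample + s_PC) / (NC_mean - blank_mean)

where ``s_sample`` is the mean signal SD of the test chemicals after a
two-stage trim (chemicals below 5 % depletion are dropped, then chemicals
whose SD exceeds three times the mean SD of the remainder are dropped and
the mean recomputed) and ``s_PC`` is the SD of a maximal-depletion
(about 99 %) compound.  A Z-factor near 1 indicates an assay with a wide
window relative to its noise; near 0, a bare yes/no discriminator.

The positive-control dose-response (7-point 1:2 dilution series, triplicate)
is summarized by the concentration producing 50 % depletion, from a
four-parameter log-logistic fit with a log-linear interpolation fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import NotEvaluableError


@dataclass
class DoseResponseFit:
    bottom: float  # percent depletion at zero dose
    top: float  # percent depletion at saturating dose
    ic50: Optional[float]  # concentration giving 50 % depletion, mmol/L
    hill: float
    residual_rms: float  # percent
    method: str  # "fit" or "interpolation"


def _four_pl(logc: np.ndarray, bottom: float, top: float, log_ic50: float, hill: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ic50 - logc)))


def fit_pc_dose_response(
    concentrations_mmol: Sequence[float], pct_depletions: Sequence[Sequence[float]]
) -> DoseResponseFit:
    """Fit the positive-control curve and locate the 50 % crossing.

    ``pct_depletions[i]`` holds the replicate percent depletions at
    ``concentrations_mmol[i]``.  The reported ic50 is the concentration at
    which the *fitted* curve crosses 50 % depletion (not the curve midpoint),
    or a log-linear interpolation between the bracketing levels if the
    least-squares fit does not converge.  ``ic50`` is None when the response
    never crosses 50 %.
    """
    conc = np.asarray(concentrations_mmol, dtype=float)
    means = np.array([np.mean(p) for p in pct_depletions])
    if conc.size < 5:
        raise NotEvaluableError("dose-response fit needs at least 5 levels with data")
    order = np.argsort(conc)
    conc, means = conc[order], means[order]
    logc = np.log10(conc)

    def crossing_from(bottom, top, log_ic50, hill) -> Optional[float]:
        # invert the 4PL at 50 %: x with f(x) = 50
        if not (min(bottom, top) < 50.0 < max(bottom, top)):
            return None
        ratio = (top - bottom) / (50.0 - bottom) - 1.0
        if ratio <= 0:
            return None
        return float(10.0 ** (log_ic50 - np.log10(ratio) / hill))

    try:
        p0 = (float(means.min()), float(means.max()), float(np.median(logc)), 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_four_pl, logc, means, p0=p0, maxfev=20_000)
        fitted = _four_pl(logc, *popt)
        rms = float(np.sqrt(np.mean((fitted - means) ** 2)))
        ic50 = crossing_from(*popt)
        if ic50 is not None or not _brackets_50(means):
            return DoseResponseFit(
                bottom=float(min(popt[0], popt[1])),
                top=float(max(popt[0], popt[1])),
                ic50=ic50,
                hill=float(popt[3]),
                residual_rms=rms,
                method="fit",
            )
    except RuntimeError:
        pass  # fall through to interpolation

    # log-linear interpolation between the levels bracketing 50 %
    ic50 = _interpolate_50(conc, means)
    return DoseResponseFit(
        bottom=float(means.min()),
        top=float(means.max()),
        ic50=ic50,
        hill=float("nan"),
        residual_rms=0.0,
        method="interpolation",
    )


def _brackets_50(means: np.ndarray) -> bool:
    return bool(means.min() < 50.0 < means.max())


def _interpolate_50(conc: np.ndarray, means: np.ndarray) -> Optional[float]:
    for i in range(len(conc) - 1):
        lo, hi = means[i], means[i + 1]
        if (lo - 50.0) * (hi - 50.0) <= 0 and lo != hi:
            f = (50.0 - lo) / (hi - lo)
            return float(10.0 ** (np.log10(conc[i]) + f * (np.log10(conc[i + 1] / conc[i]))))
    return None


# ---------------------------------------------------------------------------


@dataclass
class ZFactorResult:
    z: float
    s_sample: float
    s_pc: float
    window: float
    removed_low_depletion: list = field(default_factory=list)
    removed_high_sd: list = field(default_factory=list)


def z_factor(
    sample_stats: dict,
    pc_sd: float,
    window: float,
    min_pct: float = 5.0,
    sd_trim_factor: float = 3.0,
) -> ZFactorResult:
    """Z-factor with the two-stage sample-SD trim.

    ``sample_stats`` maps chemical name -> (pct_depletion, signal_sd).
    Stage 1 drops chemicals below ``min_pct`` percent depletion; stage 2
    drops (once, without iteration) chemicals whose SD exceeds
    ``sd_trim_factor`` times the mean SD of the stage-1 survivors.
    """
    if window <= 0:
        raise NotEvaluableError("signal window must be positive")
    stage1 = {k: v for k, v in sample_stats.items() if v[0] >= min_pct}
    removed_low = sorted(set(sample_stats) - set(stage1))
    if not stage1:
        raise NotEvaluableError("no chemicals above the depletion floor; Z not computable")
    mean_sd = float(np.mean([sd for _, sd in stage1.values()]))
    stage2 = {k: v for k, v in stage1.items() if v[1] <= sd_trim_factor * mean_sd}
    removed_high = sorted(set(stage1) - set(stage2))
    if not stage2:
        raise NotEvaluableError("SD trim removed every chemical; Z not computable")
    s_sample = float(np.mean([sd for _, sd in stage2.values()]))
    z = 1.0 - 3.0 * (s_sample + pc_sd) / window
    return ZFactorResult(
        z=z,
        s_sample=s_sample,
        s_pc=pc_sd,
        window=window,
        removed_low_depletion=removed_low,
        removed_high_sd=removed_high,
    )
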