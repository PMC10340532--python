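"""Dose-response analysis: MTT preprocessing, three-parameter
log-logistic IC50 fitting, and IC50 fold-change.

The model is the classic "log(inhibitor) vs. response, three
parameters" fit:

    response = Bottom + (Top - Bottom) / (1 + 10**(x - logIC50))

with x = log10(dose) and the Hill slope fixed at unity -- fixing the
slope is exactly what distinguishes the three-parameter option from the
four-parameter fit, and is appropriate when few dose levels are
available.  Fitting operates on normalized viability (DMSO control = 1);
the zero-dose control is used only for normalization, never in the
log-dose fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synth import log_logistic3

__all__ = ["DoseResponseFit", "mtt_preprocess", "fit_log_logistic3", "ic50_fold_change"]


@dataclass(frozen=True)
class DoseResponseFit:
    top: float
    bottom: float
    log_ic50: float   # log10 of the dose giving half-maximal response
    rss: float
    n_points: int
    converged: bool = True

    @property
    def ic50(self) -> float:
        return 10.0 ** self.log_ic50


def mtt_preprocess(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw MTT absorbances into viability.

    ``table`` is tidy with columns dose, a570, a650; rows with dose 0 are
    the DMSO controls.  The 650 nm reading is subtracted from the 570 nm
    reading, duplicate wells of a dose are averaged, and the averages are
    divided by the mean control delta.  Returns columns dose, viability
    (controls excluded).
    """
    required = {"dose", "a570", "a650"}
    if not required.issubset(table.columns):
        raise ValueError(f"MTT table must have columns {sorted(required)}")
    df = table.copy()
    df["delta"] = df["a570"] - df["a650"]
    controls = df[df["dose"] == 0]
    if len(controls) == 0:
        raise ValueError("MTT table has no DMSO (dose 0) control wells")
    dmso = controls["delta"].mean()
    if dmso <= 0:
        raise ValueError(f"non-positive DMSO control delta: {dmso}")
    means = (
        df[df["dose"] > 0].groupby("dose", as_index=False)["delta"].mean()
    )
    means["viability"] = means["delta"] / dmso
    return means[["dose", "viability"]]


def fit_log_logistic3(
    doses, viability, bottom_floor: float = 0.0, weighting: str = "relative"
) -> DoseResponseFit:
    """Least-squares fit of the three-parameter log-logistic model.

    Initialization: Top = max response, Bottom = min response, and
    logIC50 at the log-dose nearest the half-range response (by linear
    interpolation when it is bracketed).  Flat data or a failed
    optimization return a flagged (non-converged) fit.

    ``weighting="relative"`` (default) minimizes log-scale residuals,
    which is the efficient scheme when responses carry a constant
    coefficient of variation, as normalized viability readings do;
    ``weighting="none"`` minimizes plain residuals.  Both recover
    noiseless model data exactly.
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(viability, dtype=float)
    if doses.shape != y.shape:
        raise ValueError("doses and viability must have equal length")
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0 (exclude the zero-dose control)")
    if np.unique(doses).size < 4:
        raise ValueError("need at least 4 distinct dose levels")
    x = np.log10(doses)
    top0, bot0 = float(y.max()), float(max(y.min(), bottom_floor))
    if np.ptp(y) < 1e-12:  # flat data: no transition to locate
        return DoseResponseFit(top0, bot0, math.nan, 0.0, y.size, converged=False)
    half = (top0 + bot0) / 2.0
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    log_ic50_0 = float(xs[np.argmin(np.abs(ys - half))])
    for i in range(len(xs) - 1):
        y1, y2 = ys[i], ys[i + 1]
        if (y1 - half) * (y2 - half) <= 0 and y1 != y2:
            log_ic50_0 = float(xs[i] + (half - y1) * (xs[i + 1] - xs[i]) / (y2 - y1))
            break

    def model(xx, top, bottom, log_ic50):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (xx - log_ic50))

    if weighting == "relative":
        floor = 1e-9

        def objective(xx, top, bottom, log_ic50):
            return np.log(np.maximum(model(xx, top, bottom, log_ic50), floor))

        target = np.log(np.maximum(y, floor))
    elif weighting == "none":
        objective = model
        target = y
    else:
        raise ValueError(f"weighting must be 'relative' or 'none', got {weighting!r}")

    try:
        popt, _ = curve_fit(
            objective,
            x,
            target,
            p0=[top0, max(bot0, bottom_floor), log_ic50_0],
            bounds=([bottom_floor, bottom_floor, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
    except RuntimeError:
        return DoseResponseFit(top0, bot0, log_ic50_0, math.inf, y.size, converged=False)
    top, bottom, log_ic50 = (float(v) for v in popt)
    if bottom > top:  # enforce top >= bottom by swapping a pathological fit
        top, bottom = bottom, top
    rss = float(np.sum((model(x, top, bottom, log_ic50) - y) ** 2))
    return DoseResponseFit(top, bottom, log_ic50, rss, y.size, converged=True)


def _round_half_away(x: float, ndigits: int) -> float:
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def ic50_fold_change(
    fit_reference: DoseResponseFit, fit_treated: DoseResponseFit
) -> float:
    """IC50(reference) / IC50(treated), reported to one decimal.

    A value above 1 means the treatment sensitized the cells (lower
    IC50).  Flagged (non-converged) inputs propagate as NaN.
    """
    if not (fit_reference.converged and fit_treated.converged):
        return math.nan
    return _round_half_away(
        10.0 ** (fit_reference.log_ic50 - fit_treated.log_ic50), 1
    )
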