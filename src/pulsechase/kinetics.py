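"""Back-diffusion kinetics and tracer partitioning summaries.

A dark pulse labelling (canopy darkened so no photosynthetic uptake) puts
tracer into the soil air space only; the subsequent 13CO2 efflux decays as
physical back-diffusion.  Fitting r(t) = r0 * exp(-k t) gives the mean
residence time MRT = 1/k of label in soil air, which separates the fast
physical signal (tens of minutes) from the multi-day biological tracer
dynamics.

Cumulative tracer effluxes are converted to the fraction of assimilated
label respired belowground, rel13C = cumulative abs13C / U, with U the
monolith's total 13C uptake (shoots + roots, an input).  Group summaries
report replicate mean ± SD and the percent change of drought relative to
control (positive = reduction under drought).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io_schema import MonolithMeta
from .series import CumulativeFlux

logger = logging.getLogger(__name__)


class DecayFitError(RuntimeError):
    """Non-convergent exponential fit; carries the log-linear fallback."""

    def __init__(self, message: str, fallback: "DecayFit | None" = None):
        super().__init__(message)
        self.fallback = fallback


@dataclass(frozen=True)
class DecayFit:
    r0: float   # initial tracer efflux, mg 13C m^-2 hr^-1
    k: float    # rate constant, min^-1
    mrt: float  # mean residence time 1/k, min
    rss: float
    n: int


def _loglinear_init(t_min: np.ndarray, rate: np.ndarray) -> tuple[float, float]:
    pos = rate > 0
    if pos.sum() < 2:
        raise DecayFitError("too few positive values for log-linear initialisation")
    slope, intercept = np.polyfit(t_min[pos], np.log(rate[pos]), 1)
    return float(np.exp(intercept)), float(-slope)


def fit_exponential_decay(
    t_min: np.ndarray, rate: np.ndarray, k_floor: float = 1e-8
) -> DecayFit:
    """Nonlinear least-squares fit of r(t) = r0 * exp(-k t), t in minutes.

    Initialised from a log-linear regression on the positive values.
    Raises :class:`DecayFitError` (with the fallback estimate attached)
    when the optimiser fails or the fitted decay is non-positive.
    """
    t = np.asarray(t_min, dtype=float)
    r = np.asarray(rate, dtype=float)
    if len(t) < 5:
        raise DecayFitError("need at least 5 points")
    if (r > 0).sum() < len(r) / 2:
        raise DecayFitError("positive values must dominate")
    r0_init, k_init = _loglinear_init(t, r)
    fallback = None
    if k_init > k_floor:
        resid = r - r0_init * np.exp(-k_init * t)
        fallback = DecayFit(r0_init, k_init, 1.0 / k_init, float(np.sum(resid**2)), len(t))
    try:
        popt, _ = curve_fit(
            lambda x, r0, k: r0 * np.exp(-k * x),
            t, r, p0=[r0_init, max(k_init, 1e-4)], maxfev=10000,
        )
    except RuntimeError as exc:
        raise DecayFitError(f"exponential fit did not converge: {exc}", fallback)
    r0, k = float(popt[0]), float(popt[1])
    if not (k > k_floor) or not math.isfinite(k):
        raise DecayFitError(
            f"fitted rate constant k={k:g} min^-1 is not positive (flat series?)",
            fallback,
        )
    resid = r - r0 * np.exp(-k * t)
    return DecayFit(r0=r0, k=k, mrt=1.0 / k, rss=float(np.sum(resid**2)), n=len(t))


def relative_tracer(cumulative: CumulativeFlux, uptake_13c: float) -> float:
    """Fraction of assimilated tracer respired: rel13C = total / U.

    Both quantities are per m^2 (mg 13C); returned as a fraction.
    """
    if cumulative.variable != "abs13c":
        raise ValueError("relative_tracer expects a cumulative abs13c integral")
    if not uptake_13c > 0:
        raise ValueError("total 13C uptake U must be > 0")
    return cumulative.total / uptake_13c


def summarize_groups(
    cumulatives: list[CumulativeFlux],
    metas: dict[str, MonolithMeta],
    window_label: str = "",
) -> pd.DataFrame:
    """Replicate mean ± SD per (land_use, treatment, campaign, variable)
    group, with drought-vs-control percent change within land use.

    Percent change = 100 * (1 - drought_mean / control_mean); positive
    values mean a reduction under drought.
    """
    rows = []
    for c in cumulatives:
        meta = metas.get(c.monolith_id)
        if meta is None:
            logger.warning("no metadata for monolith %s; skipped", c.monolith_id)
            continue
        rows.append({
            "monolith_id": c.monolith_id, "variable": c.variable,
            "land_use": meta.land_use, "treatment": meta.treatment,
            "campaign": meta.campaign, "total": c.total,
        })
    if not rows:
        return pd.DataFrame(columns=[
            "variable", "campaign", "land_use", "treatment", "window",
            "mean", "sd", "n", "percent_change"])
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(["variable", "campaign", "land_use", "treatment"])["total"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="size")
        .reset_index()
    )
    grouped["window"] = window_label
    grouped["percent_change"] = np.nan
    for key, sub in grouped.groupby(["variable", "campaign", "land_use"]):
        ctrl = sub[sub["treatment"] == "control"]
        drt = sub[sub["treatment"] == "drought"]
        if len(ctrl) == 1 and len(drt) == 1 and ctrl["mean"].iloc[0] != 0:
            pc = 100.0 * (1.0 - drt["mean"].iloc[0] / ctrl["mean"].iloc[0])
            grouped.loc[drt.index, "percent_change"] = pc
    return grouped[["variable", "campaign", "land_use", "treatment", "window",
                    "mean", "sd", "n", "percent_change"]]
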