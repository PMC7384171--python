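"""Soil-respiration flux and isotope-mixing computations with uncertainty.

For a steady-state flow-through chamber the soil respiration rate is

    SR = f_molar * (CO2_out - CO2_in) / A        [µmol CO2 m^-2 s^-1]

with f_molar the molar flow through the chamber and A the chamber
footprint.  The isotopic composition of the respired CO2 follows from
two-member mixing of inlet air and the soil source,

    chi_SR = (chi_out * CO2_out - chi_in * CO2_in) / (CO2_out - CO2_in),

where chi = 13CO2 / (13CO2 + 12CO2) is the 13C atom fraction.  The tracer
signal is the excess over the pre-label natural abundance,
chi_E = chi_SR - chi_NA, and the absolute tracer efflux is
abs13C = chi_E * SR converted to mg 13C m^-2 hr^-1.

Standard deviations of the measured inputs are propagated through each
expression by first-order Taylor expansion with independent inputs.
Observations with SR < 0 or chi_E < 0, or with a coefficient of variation
above 1 on either quantity, are excluded by the QC filter (the boundary
CV = 1 is retained).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_schema import ChamberMeasurement, MonolithMeta

logger = logging.getLogger(__name__)

M_13C = 13.00335        # g/mol
MOLAR_VOLUME_STP = 22.414  # L/mol at 273.15 K, 101.325 kPa
UMOL_S_TO_MG_HR = M_13C * 3600.0 / 1000.0  # µmol 13C m^-2 s^-1 -> mg 13C m^-2 hr^-1

QC_OK = "ok"
QC_NEGATIVE = "excluded_negative"
QC_CV = "excluded_cv"
QC_INVALID = "invalid_input"

FLUX_COLUMNS = [
    "monolith_id", "t_mid", "sr", "sr_sd", "chi_sr", "chi_sr_sd",
    "chi_excess", "chi_excess_sd", "abs13c", "abs13c_sd", "qc",
]


@dataclass
class FluxObservation:
    monolith_id: str
    t_mid: pd.Timestamp
    sr: float = math.nan
    sr_sd: float = math.nan
    chi_sr: float = math.nan
    chi_sr_sd: float = math.nan
    chi_excess: float = math.nan
    chi_excess_sd: float = math.nan
    abs13c: float = math.nan
    abs13c_sd: float = math.nan
    qc: str = QC_OK        # overall verdict (worst of the per-variable ones)
    qc_sr: str = QC_OK     # negativity / CV rules applied to SR
    qc_tracer: str = QC_OK  # negativity / CV rules applied to chi_E
    chi_sr_valid: bool = False  # mixing equation evaluable and sane

    @property
    def cv_sr(self) -> float:
        return self.sr_sd / self.sr if self.sr > 0 else math.nan

    @property
    def cv_excess(self) -> float:
        return self.chi_excess_sd / self.chi_excess if self.chi_excess > 0 else math.nan


def molar_flow(
    flow_ml_min: float,
    ref_temperature_k: float = 273.15,
    ref_pressure_kpa: float = 101.325,
) -> float:
    """Volumetric flow (ml/min) to molar flow (mol/s) at reference T, P.

    Mass-flow meters report volumetric flow at their calibration reference;
    the default is STP (22.414 L/mol).
    """
    molar_volume = MOLAR_VOLUME_STP * (ref_temperature_k / 273.15) * (101.325 / ref_pressure_kpa)
    return flow_ml_min / 1000.0 / molar_volume / 60.0


def taylor_sd(partials: Sequence[float], sds: Sequence[float]) -> float:
    """First-order Taylor (delta-method) sd: sqrt(sum (dg/dx_i)^2 sd_i^2).

    Inputs are treated as independent.  Any non-finite partial marks the
    propagation undefined (returns NaN).
    """
    partials = np.asarray(partials, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if np.any(sds < 0):
        raise ValueError("input sds must be >= 0")
    if not np.all(np.isfinite(partials)):
        return math.nan
    return float(np.sqrt(np.sum((partials * sds) ** 2)))


def atom_fraction(c13: float, c12: float) -> float:
    """13C atom fraction chi = c13 / (c13 + c12); NaN when the total is 0."""
    total = c13 + c12
    if total <= 0:
        return math.nan
    return c13 / total


def atom_fraction_sd(c13: float, c12: float, sd13: float, sd12: float) -> float:
    total = c13 + c12
    if total <= 0:
        return math.nan
    return taylor_sd([c12 / total**2, -c13 / total**2], [sd13, sd12])


def compute_sr(
    meas: ChamberMeasurement,
    area: float,
    ref_temperature_k: float = 273.15,
    ref_pressure_kpa: float = 101.325,
) -> tuple[float, float]:
    """Soil respiration (µmol m^-2 s^-1) ± Taylor sd from one measurement."""
    if area <= 0:
        raise ValueError("chamber area must be > 0")
    f_mean, f_sd = meas.flow
    if f_mean <= 0:
        return math.nan, math.nan
    fm = molar_flow(f_mean, ref_temperature_k, ref_pressure_kpa)
    fm_sd = molar_flow(f_sd, ref_temperature_k, ref_pressure_kpa)
    delta = meas.co2_out - meas.co2_in
    sr = fm * delta / area
    # uncertainty of each window MEAN (standard error), not the raw scatter
    sd_out = math.hypot(meas.outlet12.se, meas.outlet13.se)
    sd_in = math.hypot(meas.inlet12.se, meas.inlet13.se)
    sd = taylor_sd(
        [delta / area, fm / area, -fm / area],
        [fm_sd, sd_out, sd_in],
    )
    return sr, sd


def source_atom_fraction(
    meas: ChamberMeasurement,
    min_gradient: float = 5.0,
    sanity_interval: tuple[float, float] = (-0.1, 1.1),
) -> tuple[float, float, str]:
    """Two-member mixing source composition chi_SR ± Taylor sd.

    Requires the chamber gradient |CO2_out - CO2_in| to exceed
    ``min_gradient`` (µmol/mol): below it the mixing ratio blows up and the
    observation is marked invalid.  chi_SR may legitimately fall outside
    [chi_in, chi_out] but is flagged outside ``sanity_interval``.
    """
    co2_in, co2_out = meas.co2_in, meas.co2_out
    delta = co2_out - co2_in
    if abs(delta) < min_gradient:
        return math.nan, math.nan, QC_INVALID
    chi_out = atom_fraction(meas.outlet13.mean, meas.outlet12.mean)
    chi_in = atom_fraction(meas.inlet13.mean, meas.inlet12.mean)
    if math.isnan(chi_out) or math.isnan(chi_in):
        return math.nan, math.nan, QC_INVALID
    chi_sr = (chi_out * co2_out - chi_in * co2_in) / delta

    sd_chi_out = atom_fraction_sd(
        meas.outlet13.mean, meas.outlet12.mean, meas.outlet13.se, meas.outlet12.se)
    sd_chi_in = atom_fraction_sd(
        meas.inlet13.mean, meas.inlet12.mean, meas.inlet13.se, meas.inlet12.se)
    sd_co2_out = math.hypot(meas.outlet12.se, meas.outlet13.se)
    sd_co2_in = math.hypot(meas.inlet12.se, meas.inlet13.se)
    sd = taylor_sd(
        [
            co2_out / delta,                 # d/d chi_out
            -co2_in / delta,                 # d/d chi_in
            (chi_out - chi_sr) / delta,      # d/d CO2_out
            (chi_sr - chi_in) / delta,       # d/d CO2_in
        ],
        [sd_chi_out, sd_chi_in, sd_co2_out, sd_co2_in],
    )
    lo, hi = sanity_interval
    qc = QC_OK if lo <= chi_sr <= hi else QC_INVALID
    return chi_sr, sd, qc


def excess_atom_fraction(
    chi_sr: float, chi_sr_sd: float, chi_na: float, chi_na_sd: float = 0.0
) -> tuple[float, float]:
    """Tracer excess chi_E = chi_SR - chi_NA; may be negative (noise)."""
    if chi_na is None or math.isnan(chi_na):
        raise ValueError("natural abundance chi_NA is required and not defaultable")
    return chi_sr - chi_na, taylor_sd([1.0, -1.0], [chi_sr_sd, chi_na_sd])


def estimate_natural_abundance(
    observations: Iterable[FluxObservation],
    label_start: pd.Timestamp,
    window_h: float = 48.0,
) -> tuple[float, float]:
    """Mean ± sd of valid pre-label chi_SR within ``window_h`` before labelling."""
    t0 = label_start - pd.Timedelta(hours=window_h)
    vals = [
        o.chi_sr for o in observations
        if o.chi_sr_valid and t0 <= o.t_mid < label_start
    ]
    if not vals:
        raise ValueError("no valid pre-label observation: cannot estimate natural abundance")
    arr = np.asarray(vals)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return float(np.mean(arr)), sd


def tracer_flux(
    chi_excess: float, chi_excess_sd: float, sr: float, sr_sd: float
) -> tuple[float, float]:
    """Absolute tracer efflux abs13C = chi_E * SR in mg 13C m^-2 hr^-1.

    Covariance between SR and chi_E is set to zero: each measured variable
    is propagated independently.
    """
    abs13c = chi_excess * sr * UMOL_S_TO_MG_HR
    sd = taylor_sd(
        [sr * UMOL_S_TO_MG_HR, chi_excess * UMOL_S_TO_MG_HR],
        [chi_excess_sd, sr_sd],
    )
    return abs13c, sd


def _verdict(value: float, sd: float) -> str:
    """Negativity and strict CV>1 rules for one quantity."""
    if math.isnan(value):
        return QC_INVALID
    if value < 0:
        return QC_NEGATIVE
    if value > 0 and sd / value > 1.0:
        return QC_CV
    return QC_OK


def qc_filter(obs: FluxObservation) -> FluxObservation:
    """Set the QC verdicts: negativity and CV>1 exclusions (strict).

    The rules are applied per variable: ``qc_sr`` judges SR (gates the CO2
    series), ``qc_tracer`` judges chi_E (gates the tracer series; it is
    invalid when the tracer excess is undefined, e.g. below the mixing
    gradient floor or before a natural abundance exists).  ``qc`` is the
    overall verdict: the most severe of the two.
    """
    if obs.qc == QC_INVALID and math.isnan(obs.sr):
        return replace(obs, qc_sr=QC_INVALID, qc_tracer=QC_INVALID)
    qc_sr = _verdict(obs.sr, obs.sr_sd)
    if math.isnan(obs.chi_excess) or qc_sr == QC_INVALID:
        qc_tracer = QC_INVALID
    else:
        qc_tracer = _verdict(obs.chi_excess, obs.chi_excess_sd)
    order = {QC_INVALID: 3, QC_NEGATIVE: 2, QC_CV: 1, QC_OK: 0}
    overall = max(qc_sr, qc_tracer, key=order.get)
    return replace(obs, qc=overall, qc_sr=qc_sr, qc_tracer=qc_tracer)


def compute_flux_observation(
    meas: ChamberMeasurement,
    meta: MonolithMeta,
    min_gradient: float = 5.0,
    ref_temperature_k: float = 273.15,
    ref_pressure_kpa: float = 101.325,
) -> FluxObservation:
    """Full per-measurement chain: SR, chi_SR, chi_E, abs13C with sds.

    The excess and tracer efflux are computed only when ``meta.chi_na`` has
    been estimated; before that the observation carries SR and chi_SR only
    (as needed to estimate the natural abundance itself).
    """
    obs = FluxObservation(monolith_id=meas.monolith_id, t_mid=meas.t_mid)
    if not meas.valid:
        obs.qc = QC_INVALID
        return qc_filter(obs)
    obs.sr, obs.sr_sd = compute_sr(meas, meta.area, ref_temperature_k, ref_pressure_kpa)
    if math.isnan(obs.sr):
        obs.qc = QC_INVALID
        return qc_filter(obs)
    obs.chi_sr, obs.chi_sr_sd, qc_mix = source_atom_fraction(meas, min_gradient)
    obs.chi_sr_valid = qc_mix == QC_OK
    if obs.chi_sr_valid and meta.chi_na is not None and not math.isnan(meta.chi_na):
        obs.chi_excess, obs.chi_excess_sd = excess_atom_fraction(
            obs.chi_sr, obs.chi_sr_sd, meta.chi_na)
        obs.abs13c, obs.abs13c_sd = tracer_flux(
            obs.chi_excess, obs.chi_excess_sd, obs.sr, obs.sr_sd)
    return qc_filter(obs)


def flux_table(observations: Iterable[FluxObservation]) -> pd.DataFrame:
    rows = [{
        "monolith_id": o.monolith_id, "t_mid": o.t_mid,
        "sr": o.sr, "sr_sd": o.sr_sd,
        "chi_sr": o.chi_sr, "chi_sr_sd": o.chi_sr_sd,
        "chi_excess": o.chi_excess, "chi_excess_sd": o.chi_excess_sd,
        "abs13c": o.abs13c, "abs13c_sd": o.abs13c_sd, "qc": o.qc,
        "qc_sr": o.qc_sr, "qc_tracer": o.qc_tracer,
    } for o in observations]
    return pd.DataFrame(rows, columns=FLUX_COLUMNS + ["qc_sr", "qc_tracer"])
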