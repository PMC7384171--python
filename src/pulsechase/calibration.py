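"""Span-offset calibration of the isotopologue concentrations.

The analyzer is recalibrated roughly every two hours against three
calibration gases (400, 1,500 and 5,000 ppm total CO2 in synthetic air)
of known isotopic composition, giving per-isotopologue true 12CO2 and
13CO2 levels.  Each calibration cycle is fitted as an ordinary
least-squares line

    true = span * measured + offset

per isotopologue, and records between two cycles are corrected with the
span and offset linearly interpolated in time between the bracketing fits
(nearest fit outside the bracket).  The fitted direction makes application
a single affine map.  Valid ranges follow the instrument calibration:
400-5,000 ppm for 12CO2 and 4-50 ppm for 13CO2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_schema import CalibrationSegment, SchemaError

logger = logging.getLogger(__name__)

VALID_RANGE = {"c12": (400.0, 5000.0), "c13": (4.0, 50.0)}


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationGas:
    """A calibration gas of known total CO2 and isotopic composition."""

    gas_id: str
    true_c12: float  # µmol/mol
    true_c13: float  # µmol/mol

    @classmethod
    def from_total(cls, gas_id: str, total_co2_ppm: float, atom_fraction_13c: float):
        return cls(
            gas_id=gas_id,
            true_c12=total_co2_ppm * (1.0 - atom_fraction_13c),
            true_c13=total_co2_ppm * atom_fraction_13c,
        )


@dataclass(frozen=True)
class CalibrationCurve:
    isotopologue: str  # "c12" | "c13"
    span: float
    offset: float  # µmol/mol
    fit_time: pd.Timestamp
    valid_range: tuple[float, float]
    residual_sd: float

    def apply(self, measured):
        return self.span * np.asarray(measured, dtype=float) + self.offset


def read_calibration_gases(path) -> dict[str, CalibrationGas]:
    df = pd.read_csv(path)
    need = {"gas_id", "total_co2_ppm", "atom_fraction_13C"}
    if not need.issubset(df.columns):
        raise SchemaError(f"calibration gas table lacks {need - set(df.columns)}")
    return {
        str(r["gas_id"]): CalibrationGas.from_total(
            str(r["gas_id"]), float(r["total_co2_ppm"]), float(r["atom_fraction_13C"])
        )
        for _, r in df.iterrows()
    }


def fit_span_offset(
    measured_means: np.ndarray,
    true_values: np.ndarray,
    isotopologue: str,
    fit_time: pd.Timestamp,
) -> CalibrationCurve:
    """OLS line ``true = span * measured + offset`` over >= 2 gas levels."""
    measured = np.asarray(measured_means, dtype=float)
    true = np.asarray(true_values, dtype=float)
    if len(measured) < 2 or len(measured) != len(true):
        raise CalibrationError("need >= 2 paired gas levels")
    if np.ptp(measured) == 0:
        raise CalibrationError("identical measured values: singular span-offset fit")
    span, offset = np.polyfit(measured, true, 1)
    if span <= 0:
        raise CalibrationError("non-positive span")
    resid = true - (span * measured + offset)
    dof = len(measured) - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    return CalibrationCurve(
        isotopologue=isotopologue,
        span=float(span),
        offset=float(offset),
        fit_time=fit_time,
        valid_range=VALID_RANGE[isotopologue],
        residual_sd=residual_sd,
    )


def fit_calibration_cycles(
    cal_segments: list[CalibrationSegment],
    gases: dict[str, CalibrationGas],
    max_cycle_span_s: float = 1800.0,
) -> dict[str, list[CalibrationCurve]]:
    """Group calibration segments into cycles and fit one curve pair each.

    Segments closer than ``max_cycle_span_s`` belong to one cycle; a cycle
    is fitted only if it saw >= 2 distinct gases.
    """
    curves: dict[str, list[CalibrationCurve]] = {"c12": [], "c13": []}
    if not cal_segments:
        return curves
    segs = sorted(cal_segments, key=lambda s: s.t_mid)
    cycles: list[list[CalibrationSegment]] = [[segs[0]]]
    for s in segs[1:]:
        if (s.t_mid - cycles[-1][-1].t_mid).total_seconds() <= max_cycle_span_s:
            cycles[-1].append(s)
        else:
            cycles.append([s])
    for cyc in cycles:
        known = [s for s in cyc if s.gas_id in gases]
        if len({s.gas_id for s in known}) < 2:
            logger.warning("calibration cycle with <2 known gases skipped")
            continue
        t_mid = known[0].t_mid + (known[-1].t_mid - known[0].t_mid) / 2
        for iso in ("c12", "c13"):
            measured = np.array([getattr(s, iso).mean for s in known])
            true = np.array([
                gases[s.gas_id].true_c12 if iso == "c12" else gases[s.gas_id].true_c13
                for s in known
            ])
            curves[iso].append(fit_span_offset(measured, true, iso, t_mid))
    return curves


def _interp_params(
    curves: list[CalibrationCurve], times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Span and offset linearly interpolated in time; nearest at margins."""
    fit_times = np.array([c.fit_time.value for c in curves], dtype=float)
    order = np.argsort(fit_times)
    fit_times = fit_times[order]
    spans = np.array([curves[i].span for i in order])
    offsets = np.array([curves[i].offset for i in order])
    span = np.interp(times, fit_times, spans)
    offset = np.interp(times, fit_times, offsets)
    return span, offset


def apply_calibration(
    records: pd.DataFrame,
    curves: dict[str, list[CalibrationCurve]],
    staleness_horizon_s: float = 6 * 3600.0,
) -> pd.DataFrame:
    """Correct raw concentrations with time-interpolated span-offset curves.

    Records farther than ``staleness_horizon_s`` from every calibration fit
    are flagged ``uncalibrated`` and left unchanged.  Corrected values
    outside the instrument's valid range are flagged ``out_of_range``.
    Double application is guarded by the ``calibrated`` column.
    """
    if "calibrated" in records.columns and bool(records["calibrated"].any()):
        raise CalibrationError("records already calibrated; refusing double application")
    if not curves.get("c12") or not curves.get("c13"):
        raise CalibrationError("need at least one fitted curve per isotopologue")
    out = records.copy()
    t = out["time"].astype("int64").to_numpy(dtype=float)
    stale = np.ones(len(out), dtype=bool)
    for iso, col in (("c12", "c12_ppm"), ("c13", "c13_ppm")):
        cs = curves[iso]
        span, offset = _interp_params(cs, t)
        corrected = span * out[col].to_numpy() + offset
        fit_times = np.array([c.fit_time.value for c in cs], dtype=float)
        dist = np.min(np.abs(t[:, None] - fit_times[None, :]), axis=1)
        iso_stale = dist > staleness_horizon_s * 1e9
        stale &= iso_stale
        corrected = np.where(iso_stale, out[col].to_numpy(), corrected)
        lo, hi = VALID_RANGE[iso]
        out[f"{iso}_out_of_range"] = (~iso_stale) & ((corrected < lo) | (corrected > hi))
        out[col] = corrected
    out["uncalibrated"] = stale
    out["calibrated"] = ~stale
    out["negative_flag"] = (out["c12_ppm"] < 0) | (out["c13_ppm"] < 0)
    return out
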