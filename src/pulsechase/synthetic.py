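"""Synthetic pulse-chase scenario generator with analytic ground truth.

Emulates a drought/rewetting grassland labelling experiment end to end so
every pipeline stage can be exercised without field data:

* diel soil respiration per monolith, suppressed ~50% under drought, with
  a rewetting (Birch) pulse up to 3x control decaying over ~2 days;
* a 75-min canopy 13CO2 pulse whose respired tracer appears in soil efflux
  after a ~1.5-h delay and declines over days following two-pool
  first-order kinetics with diel modulation (damped under drought);
* steady-state flow-through chamber concentrations reconstructed by
  inverting the flux and mixing equations, analyzer noise of 200/10 ppb
  (12CO2/13CO2), span-offset instrument distortion that the pipeline must
  undo, and the 100/250/100-s multiplexed measurement protocol with
  periodic three-gas calibration cycles.

The generator emits the raw streams in the package's CSV schemas together
with a :class:`SyntheticTruth` record (closed-form rates, quadrature
integrals, true fractions) that the pipeline never consumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .calibration import CalibrationGas
from .fluxes import UMOL_S_TO_MG_HR, molar_flow
from .io_schema import MonolithMeta

DEFAULT_AREA = math.pi * 0.0225**2  # 4.5-cm diameter chamber footprint, m^2


class ScenarioError(ValueError):
    pass


@dataclass
class SyntheticScenario:
    """Study conditions for one simulated campaign.

    Defaults encode the experiment the generator emulates: ~50% drought
    suppression of soil respiration, a rewetting pulse up to 3x control
    decaying within ~2 days, tracer efflux starting 1.5 h after the 75-min
    labelling, analyzer noise of 0.200/0.010 µmol/mol, 170 ml/min chamber
    flow, and ~2-h measurement/calibration cadence.
    """

    # experimental design
    n_replicates: int = 3
    land_uses: tuple = ("managed", "abandoned")
    treatments: tuple = ("control", "drought")
    campaign: str = "peak_drought"
    seed: int = 0

    # baseline respiration (µmol CO2 m^-2 s^-1) per land use
    baseline_sr: dict = field(default_factory=lambda: {"managed": 2.5, "abandoned": 2.0})
    diel_amplitude: float = 0.4
    diel_peak_hour: float = 13.0  # local hour of the diel maximum
    drought_multiplier: float = 0.5
    drought_diel_damping: float = 0.05  # diel amplitude factor under drought
    birch_peak_factor: float = 3.0
    birch_tau_h: float = 12.0

    # tracer kinetics
    tracer_delay_h: float = 1.5
    w_fast: float = 0.7  # two-pool weights, w_fast + w_slow = 1
    k_fast: float = 1.0 / 12.0   # h^-1
    k_slow: float = 1.0 / 96.0   # h^-1
    respired_fraction: float = 0.12  # asymptotic fraction of U respired belowground
    tracer_diel_amplitude: float = 0.3
    remobilized_fraction: float = 0.015  # extra U fraction released at rewetting (drought)
    remob_tau_h: float = 12.0

    # per-monolith inputs
    uptake_control: float = 400.0  # mg 13C / m^2
    uptake_drought_factor: dict = field(
        default_factory=lambda: {"managed": 0.7, "abandoned": 0.85})
    uptake_jitter_cv: float = 0.05
    biological_cv: float = 0.08  # lognormal sd of per-monolith baseline SR
    chi_na: float = 0.0108
    area_m2: float = DEFAULT_AREA

    # chamber system
    inlet_co2: float = 420.0  # µmol/mol at the buffer volume
    flow_ml_min: float = 170.0
    flow_jitter_ml_min: float = 1.0
    noise_c12: float = 0.200  # µmol/mol per sample
    noise_c13: float = 0.010
    span_c12: float = 0.98
    offset_c12: float = 5.0
    span_c13: float = 1.01
    offset_c13: float = -0.05

    # calibration gases: id -> (total ppm, atom fraction 13C)
    cal_gases: dict = field(default_factory=lambda: {
        "G400": (400.0, 0.0105), "G1500": (1500.0, 0.0105), "G5000": (5000.0, 0.0105)})

    # schedule (hours from stream start unless noted)
    epoch: str = "2014-06-10T00:00:00Z"
    pre_label_h: float = 24.0
    label_duration_min: float = 75.0
    chase_h: float = 120.0
    rewet_after_label_h: float = 126.0
    post_rewet_h: float = 78.0
    cadence_h: float = 2.0
    sample_period_s: float = 2.0
    inlet_window_s: float = 100.0
    outlet_window_s: float = 250.0
    cal_window_s: float = 100.0

    def validate(self) -> None:
        if not 0 < self.drought_multiplier <= 1:
            raise ScenarioError("drought multiplier must be in (0, 1]")
        if self.birch_peak_factor < 1:
            raise ScenarioError("Birch peak factor must be >= 1")
        if not self.k_fast > self.k_slow > 0:
            raise ScenarioError("need k_fast > k_slow > 0")
        if abs(self.w_fast + (1 - self.w_fast) - 1) > 1e-12 or not 0 <= self.w_fast <= 1:
            raise ScenarioError("pool weights must be in [0,1] and sum to 1")
        if not 0 < self.respired_fraction + self.remobilized_fraction <= 1:
            raise ScenarioError("respired + remobilised fraction must lie in (0, 1]")
        n_mono = self.n_replicates * len(self.land_uses) * len(self.treatments)
        block_s = n_mono * (2 * self.inlet_window_s + self.outlet_window_s) \
            + len(self.cal_gases) * self.cal_window_s
        if block_s > self.cadence_h * 3600:
            raise ScenarioError(
                f"measurement block ({block_s:.0f} s) exceeds cadence "
                f"({self.cadence_h} h); reduce monoliths or lengthen cadence")

    # derived schedule, hours from epoch
    @property
    def label_start_h(self) -> float:
        return self.pre_label_h

    @property
    def label_end_h(self) -> float:
        return self.pre_label_h + self.label_duration_min / 60.0

    @property
    def rewetting_h(self) -> float:
        return self.label_start_h + self.rewet_after_label_h

    @property
    def total_h(self) -> float:
        return self.rewetting_h + self.post_rewet_h

    @property
    def w_slow(self) -> float:
        return 1.0 - self.w_fast


@dataclass
class MonolithTruth:
    """Closed-form rates and exact parameters for one simulated monolith."""

    monolith_id: str
    land_use: str
    treatment: str
    baseline: float  # jittered B, µmol m^-2 s^-1
    uptake: float    # U, mg 13C m^-2
    scenario: SyntheticScenario

    def _diel(self, t_h: np.ndarray, amplitude: float) -> np.ndarray:
        sc = self.scenario
        damped = np.where(
            (np.asarray(t_h) < sc.rewetting_h) & (self.treatment == "drought"),
            amplitude * sc.drought_diel_damping, amplitude)
        tod = np.mod(t_h, 24.0)
        return 1.0 + damped * np.cos(2 * np.pi * (tod - sc.diel_peak_hour) / 24.0)

    def sr_true(self, t_h) -> np.ndarray:
        """Soil respiration, µmol CO2 m^-2 s^-1."""
        sc = self.scenario
        t = np.asarray(t_h, dtype=float)
        out = self.baseline * self._diel(t, sc.diel_amplitude)
        if self.treatment == "drought":
            mult = np.where(t < sc.rewetting_h, sc.drought_multiplier, 1.0)
            birch = np.where(
                t >= sc.rewetting_h,
                1.0 + (sc.birch_peak_factor - 1.0)
                * np.exp(-(t - sc.rewetting_h) / sc.birch_tau_h),
                1.0)
            out = out * mult * birch
        return out

    def r13_true(self, t_h) -> np.ndarray:
        """Tracer efflux, mg 13C m^-2 hr^-1.

        Two-pool first-order release scaled by the asymptotic respired
        fraction, with a smooth diffusion ramp that reaches ~95% of the
        pool rate ``tracer_delay_h`` after the start of the labelling.
        """
        sc = self.scenario
        t = np.asarray(t_h, dtype=float)
        s = t - sc.label_start_h
        pools = sc.w_fast * sc.k_fast * np.exp(-sc.k_fast * np.maximum(s, 0)) \
            + sc.w_slow * sc.k_slow * np.exp(-sc.k_slow * np.maximum(s, 0))
        ramp = 1.0 - np.exp(-3.0 * np.maximum(s, 0) / sc.tracer_delay_h)
        rate = np.where(s >= 0, self.uptake * sc.respired_fraction * pools * ramp, 0.0)
        rate = rate * self._diel(t, sc.tracer_diel_amplitude)
        if self.treatment == "drought":
            srw = t - sc.rewetting_h
            remob = np.where(
                srw >= 0,
                self.uptake * sc.remobilized_fraction / sc.remob_tau_h
                * np.exp(-np.maximum(srw, 0) / sc.remob_tau_h),
                0.0)
            rate = rate + remob
        return rate

    def _integrate(self, f, window: tuple[float, float]) -> float:
        sc = self.scenario
        breaks = sorted({window[0], window[1], sc.label_start_h,
                         sc.label_start_h + sc.tracer_delay_h, sc.rewetting_h})
        pts = [b for b in breaks if window[0] < b < window[1]]
        val, _ = quad(lambda x: float(f(x)), window[0], window[1],
                      points=pts or None, limit=400)
        return val

    def integral_sr_mol(self, window: tuple[float, float]) -> float:
        """Cumulative respired CO2 over a window, mol m^-2."""
        return self._integrate(self.sr_true, window) * 3600.0 / 1e6

    def integral_abs13c(self, window: tuple[float, float]) -> float:
        """Cumulative tracer efflux over a window, mg 13C m^-2."""
        return self._integrate(self.r13_true, window)

    def rel13c(self, window: tuple[float, float]) -> float:
        return self.integral_abs13c(window) / self.uptake


@dataclass
class SyntheticTruth:
    scenario: SyntheticScenario
    monoliths: dict  # monolith_id -> MonolithTruth
    chi_na: float
    epoch_ref: pd.Timestamp

    def chase_window(self) -> tuple[float, float]:
        sc = self.scenario
        return (sc.label_start_h, sc.label_start_h + sc.chase_h)

    def rewetting_window(self) -> tuple[float, float]:
        sc = self.scenario
        return (sc.rewetting_h, sc.rewetting_h + 72.0)

    def to_json(self, path=None) -> dict:
        chase = self.chase_window()
        rewet = self.rewetting_window()
        payload = {
            "chi_na": self.chi_na,
            "windows": {"chase": chase, "rewetting": rewet},
            "monoliths": {
                mid: {
                    "land_use": m.land_use, "treatment": m.treatment,
                    "baseline_sr": m.baseline, "uptake_mg13C_m2": m.uptake,
                    "co2_chase_mol_m2": m.integral_sr_mol(chase),
                    "abs13c_chase_mg_m2": m.integral_abs13c(chase),
                    "rel13c_chase": m.rel13c(chase),
                    "co2_rewet_mol_m2": m.integral_sr_mol(rewet),
                    "abs13c_rewet_mg_m2": m.integral_abs13c(rewet),
                    "rel13c_rewet": m.rel13c(rewet),
                }
                for mid, m in self.monoliths.items()
            },
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1)
        return payload


@dataclass
class ScenarioData:
    records: pd.DataFrame    # raw analyzer stream (distorted, noisy)
    flow_log: pd.DataFrame
    metas: dict              # monolith_id -> MonolithMeta
    gases: dict              # gas_id -> CalibrationGas
    truth: SyntheticTruth
    epoch_ref: pd.Timestamp


def _chamber_concentrations(
    truth: MonolithTruth, t_h: np.ndarray, scenario: SyntheticScenario
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the flux and mixing equations: outlet (c12, c13) at times t_h."""
    sc = scenario
    sr = truth.sr_true(t_h)
    r13 = truth.r13_true(t_h)
    fm = molar_flow(sc.flow_ml_min)
    delta = sr * sc.area_m2 / fm  # µmol/mol
    co2_in = sc.inlet_co2
    co2_out = co2_in + delta
    chi_excess = np.where(sr > 0, r13 / (sr * UMOL_S_TO_MG_HR), 0.0)
    chi_sr = sc.chi_na + chi_excess
    chi_out = (chi_sr * delta + sc.chi_na * co2_in) / co2_out
    if np.any((chi_out < 0) | (chi_out > 1)):
        raise ScenarioError(
            "scenario implies outlet atom fraction outside [0, 1] "
            f"(min {chi_out.min():.4f}, max {chi_out.max():.4f}); "
            "reduce tracer rates or raise respiration")
    return (1.0 - chi_out) * co2_out, chi_out * co2_out


def _distort(c12, c13, sc: SyntheticScenario):
    """Apply the inverse instrument calibration so the pipeline must undo it."""
    return (c12 - sc.offset_c12) / sc.span_c12, (c13 - sc.offset_c13) / sc.span_c13


def generate_scenario(scenario: SyntheticScenario | None = None) -> ScenarioData:
    """Simulate the full measurement campaign for one scenario.

    All randomness flows from ``scenario.seed``; identical seeds give
    identical outputs.
    """
    sc = scenario or SyntheticScenario()
    sc.validate()
    rng = np.random.default_rng(sc.seed)
    epoch = pd.Timestamp(sc.epoch)

    # per-monolith truths and metadata
    monoliths: dict[str, MonolithTruth] = {}
    metas: dict[str, MonolithMeta] = {}
    i = 0
    for land_use in sc.land_uses:
        for treatment in sc.treatments:
            for rep in range(sc.n_replicates):
                i += 1
                mid = f"M{i:02d}"
                b = sc.baseline_sr[land_use] * rng.lognormal(0.0, sc.biological_cv)
                u = sc.uptake_control * rng.lognormal(0.0, sc.uptake_jitter_cv)
                if treatment == "drought" and sc.campaign == "peak_drought":
                    u *= sc.uptake_drought_factor[land_use]
                monoliths[mid] = MonolithTruth(mid, land_use, treatment, b, u, sc)
                metas[mid] = MonolithMeta(
                    monolith_id=mid, land_use=land_use, treatment=treatment,
                    campaign=sc.campaign, block_id=f"B{rep + 1}",
                    area=sc.area_m2, uptake_13c=u,
                    label_start=epoch + pd.Timedelta(hours=sc.label_start_h),
                    label_end=epoch + pd.Timedelta(hours=sc.label_end_h),
                    rewetting_time=epoch + pd.Timedelta(hours=sc.rewetting_h),
                )

    gases = {
        gid: CalibrationGas.from_total(gid, total, chi)
        for gid, (total, chi) in sc.cal_gases.items()
    }

    dt = sc.sample_period_s
    n_in = int(round(sc.inlet_window_s / dt))
    n_out = int(round(sc.outlet_window_s / dt))
    n_cal = int(round(sc.cal_window_s / dt))
    meas_s = (2 * n_in + n_out) * dt

    sweep_starts = np.arange(0.0, sc.total_h, sc.cadence_h)
    mono_ids = list(monoliths)

    times_parts, lines_parts, c12_parts, c13_parts = [], [], [], []
    chi_na = sc.chi_na
    for sweep_h in sweep_starts:
        offset_s = 0.0
        for mid in mono_ids:
            truth = monoliths[mid]
            t0 = sweep_h * 3600.0 + offset_s
            rel = t0 + dt * np.arange(2 * n_in + n_out)
            t_h = rel / 3600.0
            seg = np.array(
                ["buffer"] * n_in + ["chamber"] * n_out + ["buffer"] * n_in)
            c12 = np.empty(len(rel))
            c13 = np.empty(len(rel))
            is_in = seg == "buffer"
            c12[is_in] = sc.inlet_co2 * (1 - chi_na)
            c13[is_in] = sc.inlet_co2 * chi_na
            c12_out, c13_out = _chamber_concentrations(truth, t_h[~is_in], sc)
            c12[~is_in], c13[~is_in] = c12_out, c13_out
            lines = np.where(is_in, f"buffer-{mid}", f"chamber-{mid}")
            times_parts.append(rel)
            lines_parts.append(lines)
            c12_parts.append(c12)
            c13_parts.append(c13)
            offset_s += meas_s
        for gid, gas in gases.items():
            t0 = sweep_h * 3600.0 + offset_s
            rel = t0 + dt * np.arange(n_cal)
            times_parts.append(rel)
            lines_parts.append(np.full(n_cal, f"cal-{gid}"))
            c12_parts.append(np.full(n_cal, gas.true_c12))
            c13_parts.append(np.full(n_cal, gas.true_c13))
            offset_s += n_cal * dt

    t_s = np.concatenate(times_parts)
    c12 = np.concatenate(c12_parts)
    c13 = np.concatenate(c13_parts)
    lines = np.concatenate(lines_parts)

    # instrument distortion, then analyzer noise on the measured signal
    c12, c13 = _distort(c12, c13, sc)
    if sc.noise_c12 > 0:
        c12 = c12 + rng.normal(0.0, sc.noise_c12, len(c12))
    if sc.noise_c13 > 0:
        c13 = c13 + rng.normal(0.0, sc.noise_c13, len(c13))

    records = pd.DataFrame({
        "time": epoch + pd.to_timedelta(np.round(t_s, 3), unit="s"),
        "line_id": lines,
        "c12_ppm": c12,
        "c13_ppm": c13,
    })
    records["negative_flag"] = (records["c12_ppm"] < 0) | (records["c13_ppm"] < 0)
    records["calibrated"] = False

    flow_t = np.arange(0.0, sc.total_h * 3600.0, 10.0)
    flow_vals = np.full(len(flow_t), sc.flow_ml_min)
    if sc.flow_jitter_ml_min > 0:
        flow_vals = flow_vals + rng.normal(0.0, sc.flow_jitter_ml_min, len(flow_t))
    flow_log = pd.DataFrame({
        "time": epoch + pd.to_timedelta(flow_t, unit="s"),
        "flow_ml_min": flow_vals,
    })

    truth = SyntheticTruth(scenario=sc, monoliths=monoliths, chi_na=chi_na,
                           epoch_ref=epoch)
    return ScenarioData(records=records, flow_log=flow_log, metas=metas,
                        gases=gases, truth=truth, epoch_ref=epoch)


def generate_dark_pulse(
    mrt_true_min: float = 23.0,
    noise_sd: float = 0.0,
    duration_min: float = 120.0,
    n_points: int = 60,
    r0: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Single-exponential back-diffusion efflux after a dark labelling.

    Returns (series, truth) where the series has columns t_min and
    rate (mg 13C m^-2 hr^-1) and truth records the generating parameters.
    """
    if not mrt_true_min > 0:
        raise ScenarioError("true MRT must be positive")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration_min, n_points)
    rate = r0 * np.exp(-t / mrt_true_min)
    if noise_sd > 0:
        rate = rate + rng.normal(0.0, noise_sd, n_points)
    series = pd.DataFrame({"t_min": t, "rate": rate})
    truth = {"mrt_min": mrt_true_min, "k_per_min": 1.0 / mrt_true_min,
             "r0": r0, "noise_sd": noise_sd}
    return series, truth
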