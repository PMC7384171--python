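"""Raw-to-report orchestration: calibrate, segment, flux, QC, grid,
cumulate, partition, test.

The stages run in a fixed order; every threshold is carried in
:class:`RunConfig` (defaults are the study-anchored values: 2-h grid, 6-h
maximum spline gap, 120-h chase and 72-h rewetting windows, 1,000
Monte-Carlo draws, CV > 1 and negativity QC exclusions, 6-h calibration
staleness horizon).  The configuration is serialised into the run report
so a run is reproducible from its snapshot.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import fluxes, io_schema, kinetics, series
from .anova import permutation_anova
from .io_schema import MonolithMeta, SegmentationProtocol
from .synthetic import ScenarioData

logger = logging.getLogger(__name__)

UMOL_S_TO_MOL_H = 3600.0 / 1e6  # µmol m^-2 s^-1 -> mol m^-2 h^-1


@dataclass
class RunConfig:
    grid_step_h: float = 2.0
    max_gap_h: float = 6.0
    chase_window_h: float = 120.0
    rewet_window_h: float = 72.0
    mc_n: int = 1000
    seed: int = 0
    smoothing: float = series.DEFAULT_SMOOTHING
    min_gradient: float = 5.0
    calibration_staleness_h: float = 6.0
    dead_band_s: float = 30.0
    na_window_h: float = 48.0
    ref_temperature_k: float = 273.15
    ref_pressure_kpa: float = 101.325
    n_perm: int = 5000
    default_flow: tuple = (170.0, 0.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        params = {k: v for k, v in raw.items() if k in known}
        cfg = cls(**params)
        if isinstance(cfg.default_flow, list):
            cfg.default_flow = tuple(cfg.default_flow)
        return cfg


@dataclass
class PipelineResult:
    config: RunConfig
    flux: pd.DataFrame
    series_list: list
    cumulatives: list
    summary: pd.DataFrame
    stats: dict
    exclusions: dict
    chi_na: dict
    epoch_ref: pd.Timestamp
    metas: dict

    def cumulative_frame(self) -> pd.DataFrame:
        return series.cumulative_table(self.cumulatives, self.epoch_ref)


def _hours(ts: pd.Series | pd.Timestamp, epoch: pd.Timestamp):
    if isinstance(ts, pd.Timestamp):
        return (ts - epoch).total_seconds() / 3600.0
    return (ts - epoch).dt.total_seconds() / 3600.0


def _estimate_all_chi_na(observations, metas, window_h):
    chi_na = {}
    by_mono: dict[str, list] = {}
    for o in observations:
        by_mono.setdefault(o.monolith_id, []).append(o)
    for mid, obs in by_mono.items():
        meta = metas.get(mid)
        if meta is None:
            continue
        chi, sd = fluxes.estimate_natural_abundance(
            obs, meta.label_start, window_h=window_h)
        chi_na[mid] = (chi, sd)
    return chi_na


def _build_series(
    flux_df: pd.DataFrame, variable: str, epoch: pd.Timestamp, cfg: RunConfig
) -> list[series.FluxSeries]:
    col, sd_col, qc_col = (
        ("sr", "sr_sd", "qc_sr") if variable == "sr"
        else ("abs13c", "abs13c_sd", "qc_tracer"))
    out = []
    for mid, sub in flux_df[flux_df[qc_col] == fluxes.QC_OK].groupby("monolith_id"):
        sub = sub.dropna(subset=[col])
        if len(sub) < 2:
            logger.warning("monolith %s: too few %s observations for a series", mid, variable)
            continue
        t = _hours(sub["t_mid"], epoch).to_numpy()
        fitted = series.fit_smoothing_spline(
            t, sub[col].to_numpy(), sub[sd_col].to_numpy(), smoothing=cfg.smoothing)
        out.append(series.resample_to_grid(
            fitted, mid, variable, epoch,
            step_h=cfg.grid_step_h, max_gap_h=cfg.max_gap_h))
    return out


def run_pipeline(
    data: ScenarioData,
    config: RunConfig | None = None,
    out_dir=None,
) -> PipelineResult:
    """Execute the full chain on in-memory scenario data (or loaded inputs).

    Stage order: calibrate -> segment -> flux -> QC -> natural abundance ->
    grid -> cumulate (with Monte-Carlo uncertainty) -> partition -> stats.
    """
    cfg = config or RunConfig()
    epoch = data.epoch_ref
    protocol = SegmentationProtocol(dead_band=cfg.dead_band_s)

    # calibration curves from the raw (uncalibrated) stream
    _, cal_segments = io_schema.segment_stream(
        data.records, protocol, data.flow_log, cfg.default_flow)
    curves = cal.fit_calibration_cycles(cal_segments, data.gases)
    records = cal.apply_calibration(
        data.records, curves, staleness_horizon_s=cfg.calibration_staleness_h * 3600)

    measurements, _ = io_schema.segment_stream(
        records, protocol, data.flow_log, cfg.default_flow)

    # first pass without natural abundance: SR and chi_SR only
    first_pass = [
        fluxes.compute_flux_observation(
            m, data.metas[m.monolith_id], cfg.min_gradient,
            cfg.ref_temperature_k, cfg.ref_pressure_kpa)
        for m in measurements if m.monolith_id in data.metas
    ]
    chi_na = _estimate_all_chi_na(first_pass, data.metas, cfg.na_window_h)

    metas = {
        mid: (meta.with_chi_na(chi_na[mid][0]) if mid in chi_na else meta)
        for mid, meta in data.metas.items()
    }
    observations = [
        fluxes.compute_flux_observation(
            m, metas[m.monolith_id], cfg.min_gradient,
            cfg.ref_temperature_k, cfg.ref_pressure_kpa)
        for m in measurements if m.monolith_id in metas
    ]
    flux_df = fluxes.flux_table(observations)
    exclusions = {
        "overall": flux_df["qc"].value_counts().to_dict(),
        "sr": flux_df["qc_sr"].value_counts().to_dict(),
        "tracer": flux_df["qc_tracer"].value_counts().to_dict(),
    }
    logger.info("QC exclusions: %s", exclusions)

    sr_series = _build_series(flux_df, "sr", epoch, cfg)
    tracer_series = _build_series(flux_df, "abs13c", epoch, cfg)

    any_meta = next(iter(metas.values()))
    label_h = _hours(any_meta.label_start, epoch)
    rewet_h = _hours(any_meta.rewetting_time, epoch)
    windows = {
        "chase": (label_h, label_h + cfg.chase_window_h),
        "rewetting": (rewet_h, rewet_h + cfg.rewet_window_h),
    }

    rng = np.random.default_rng(cfg.seed)
    by_window: dict[str, list[series.CumulativeFlux]] = {w: [] for w in windows}
    for win_name, window in windows.items():
        for s_list, variable in ((sr_series, "co2"), (tracer_series, "abs13c")):
            for s in s_list:
                try:
                    c = series.cumulate_trapezoid(s, window)
                except ValueError as exc:
                    logger.warning("%s %s %s: %s", s.monolith_id, variable, win_name, exc)
                    continue
                mc_sd, mc_int = series.mc_cumulative_uncertainty(
                    s, window, n=cfg.mc_n, seed=rng)
                scale = UMOL_S_TO_MOL_H if variable == "co2" else 1.0
                c = series.CumulativeFlux(
                    monolith_id=c.monolith_id, variable=variable,
                    window=c.window, total=c.total * scale,
                    mc_sd=mc_sd * scale,
                    mc_interval=(mc_int[0] * scale, mc_int[1] * scale),
                    fill_fraction=c.fill_fraction)
                by_window[win_name].append(c)
                if variable == "abs13c":
                    u = metas[c.monolith_id].uptake_13c
                    by_window[win_name].append(series.CumulativeFlux(
                        monolith_id=c.monolith_id, variable="rel13c",
                        window=c.window, total=c.total / u,
                        mc_sd=c.mc_sd / u,
                        mc_interval=(c.mc_interval[0] / u, c.mc_interval[1] / u),
                        fill_fraction=c.fill_fraction))
    cumulatives = [c for cs in by_window.values() for c in cs]

    # group summaries and treatment statistics per window
    summaries = []
    stats: dict = {}
    for win_name, in_win in by_window.items():
        summary = kinetics.summarize_groups(in_win, metas, window_label=win_name)
        summaries.append(summary)
        stats[win_name] = {}
        for variable in ("co2", "abs13c", "rel13c"):
            cs = [c for c in in_win if c.variable == variable]
            if len(cs) < 8:
                continue
            vals = np.array([c.total for c in cs])
            treat = [metas[c.monolith_id].treatment for c in cs]
            land = [metas[c.monolith_id].land_use for c in cs]
            try:
                res = permutation_anova(
                    vals, treat, land, n_perm=cfg.n_perm, seed=cfg.seed)
            except ValueError as exc:
                logger.warning("ANOVA skipped for %s/%s: %s", win_name, variable, exc)
                continue
            stats[win_name][variable] = {
                {"factor_a": "drought", "factor_b": "land_use",
                 "interaction": "interaction"}[t]: {
                    "F": r.F, "p_classical": r.p_classical, "p_exact": r.p_exact,
                    "n_perm": r.n_perm, "seed": r.seed, "enumerated": r.enumerated,
                }
                for t, r in res.items()
            }
    summary = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()

    result = PipelineResult(
        config=cfg, flux=flux_df, series_list=sr_series + tracer_series,
        cumulatives=cumulatives, summary=summary, stats=stats,
        exclusions=exclusions,
        chi_na={k: v[0] for k, v in chi_na.items()},
        epoch_ref=epoch, metas=metas,
    )
    if out_dir is not None:
        write_run_directory(result, out_dir)
    return result


def load_inputs(
    analyzer_path, flow_path, monolith_path, gas_path, epoch_ref=None
) -> ScenarioData:
    """Load the four delimited-text inputs into a processable bundle."""
    records, report = io_schema.read_analyzer_stream(analyzer_path)
    logger.info("read %d analyzer rows (%d rejected)", report.n_read, report.n_rejected)
    flow_log = pd.read_csv(flow_path, parse_dates=["time"])
    metas = io_schema.read_monolith_meta(monolith_path)
    gases = cal.read_calibration_gases(gas_path)
    epoch = epoch_ref or records["time"].iloc[0].floor("D")
    return ScenarioData(records=records, flow_log=flow_log, metas=metas,
                        gases=gases, truth=None, epoch_ref=epoch)


def write_run_directory(result: PipelineResult, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.flux.to_csv(out / "flux.csv", index=False)
    series.series_table(result.series_list).to_csv(out / "series.csv", index=False)
    result.cumulative_frame().to_csv(out / "cumulative.csv", index=False)
    result.summary.to_csv(out / "summary.csv", index=False)
    with open(out / "stats.json", "w") as fh:
        json.dump(result.stats, fh, indent=1)
    with open(out / "config.yml", "w") as fh:
        yaml.safe_dump(result.config.to_dict(), fh)
    with open(out / "log.txt", "w") as fh:
        fh.write(f"epoch_ref: {result.epoch_ref}\n")
        fh.write(f"qc_counts: {json.dumps(result.exclusions)}\n")
        fh.write(f"chi_na: {json.dumps(result.chi_na)}\n")
    return out


def make_report(result: PipelineResult) -> str:
    """Human-readable run summary: group means ± SD, percent changes, tests."""
    lines = ["Cumulative flux summary", "=" * 60]
    if len(result.summary):
        for (win, var), sub in result.summary.groupby(["window", "variable"]):
            unit = {"co2": "mol CO2 m-2", "abs13c": "mg 13C m-2",
                    "rel13c": "fraction"}.get(var, "")
            lines.append(f"\n[{win}] {var} ({unit})")
            for _, r in sub.iterrows():
                pc = ("" if math.isnan(r["percent_change"])
                      else f"  change vs control: {r['percent_change']:+.1f}%")
                lines.append(
                    f"  {r['campaign']:>12} {r['land_use']:>9} {r['treatment']:>8}: "
                    f"{r['mean']:.4g} ± {r['sd']:.4g} (n={int(r['n'])}){pc}")
    lines.append("\nTreatment statistics (permutation ANOVA)")
    lines.append("=" * 60)
    for win, by_var in result.stats.items():
        for var, terms in by_var.items():
            for term, r in terms.items():
                lines.append(
                    f"  [{win}] {var:>7} {term:>11}: F={r['F']:.3f} "
                    f"p_F={r['p_classical']:.3f} p_exact={r['p_exact']:.3f}"
                    f" ({'enumerated' if r['enumerated'] else str(r['n_perm']) + ' perms'})")
    lines.append("\nQC exclusion counts: " + json.dumps(result.exclusions))
    return "\n".join(lines)
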