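"""Domain types, delimited-text schemas, and stream segmentation.

The raw input is a long-format analyzer stream: one row per analyzer
reading, carrying the gas line currently routed to the analyzer
(``chamber-<id>`` outlet, ``buffer-<id>`` inlet, or ``cal-<gas>``) and the
two isotopologue concentrations in µmol/mol.  A soil-respiration
measurement is a contiguous triplet of line runs

    buffer-k (inlet, 100 s)  ->  chamber-k (outlet, 250 s)  ->  buffer-k (inlet, 100 s)

and is summarised here into per-window means and standard deviations after
discarding a configurable dead band at the start of each window (line-switch
flushing transient).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANALYZER_COLUMNS = ["time", "line_id", "c12_ppm", "c13_ppm"]
MONOLITH_COLUMNS = [
    "monolith_id", "land_use", "treatment", "campaign", "block", "area_m2",
    "uptake_mg13C_m2", "label_start", "label_end", "rewetting_time",
]

LAND_USES = ("managed", "abandoned")
TREATMENTS = ("control", "drought")
CAMPAIGNS = ("peak_drought", "recovery")

_CHAMBER_RE = re.compile(r"^chamber-(?P<id>.+)$")
_BUFFER_RE = re.compile(r"^buffer-(?P<id>.+)$")
_CAL_RE = re.compile(r"^cal-(?P<gas>.+)$")


class SchemaError(ValueError):
    """Raised when an input table does not match the declared schema."""


@dataclass(frozen=True)
class SegmentSummary:
    """Mean ± sd of one concentration over one line window."""

    mean: float
    sd: float
    n: int
    window: tuple[pd.Timestamp, pd.Timestamp]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("SegmentSummary needs n >= 1")
        if self.sd < 0:
            raise ValueError("SegmentSummary sd must be >= 0")

    @property
    def se(self) -> float:
        """Standard error of the window mean (what propagation consumes)."""
        return self.sd / math.sqrt(self.n)


@dataclass(frozen=True)
class ChamberMeasurement:
    """One inlet/outlet measurement cycle, summarised.

    Inlet summaries pool the 100-s windows before and after the outlet
    window with equal weight.  ``flow`` is the volumetric flow (ml/min)
    through the chamber over the outlet window, mean ± sd.
    """

    monolith_id: str
    t_mid: pd.Timestamp
    inlet12: SegmentSummary
    inlet13: SegmentSummary
    outlet12: SegmentSummary
    outlet13: SegmentSummary
    flow: tuple[float, float]
    valid: bool = True
    note: str = ""

    @property
    def co2_in(self) -> float:
        return self.inlet12.mean + self.inlet13.mean

    @property
    def co2_out(self) -> float:
        return self.outlet12.mean + self.outlet13.mean


@dataclass(frozen=True)
class MonolithMeta:
    monolith_id: str
    land_use: str
    treatment: str
    campaign: str
    block_id: str
    area: float  # chamber footprint, m^2
    uptake_13c: float  # total assimilated tracer U, mg 13C / m^2
    label_start: pd.Timestamp
    label_end: pd.Timestamp
    rewetting_time: pd.Timestamp
    chi_na: float | None = None  # natural-abundance atom fraction of SR

    def __post_init__(self) -> None:
        if self.land_use not in LAND_USES:
            raise SchemaError(f"unknown land_use {self.land_use!r}")
        if self.treatment not in TREATMENTS:
            raise SchemaError(f"unknown treatment {self.treatment!r}")
        if self.campaign not in CAMPAIGNS:
            raise SchemaError(f"unknown campaign {self.campaign!r}")
        if not self.area > 0:
            raise SchemaError("chamber area must be > 0")

    def with_chi_na(self, chi_na: float) -> "MonolithMeta":
        return replace(self, chi_na=chi_na)


@dataclass
class SegmentationProtocol:
    """Durations of the measurement windows, in seconds."""

    inlet_pre: float = 100.0
    outlet: float = 250.0
    inlet_post: float = 100.0
    dead_band: float = 30.0  # flushing transient discarded per window

    def __post_init__(self) -> None:
        shortest = min(self.inlet_pre, self.outlet, self.inlet_post)
        if not self.dead_band < shortest:
            raise ValueError("dead_band must be shorter than every window")


@dataclass
class ReadReport:
    n_read: int
    n_rejected: int
    n_flagged_negative: int
    reordered: bool


def read_analyzer_stream(
    path, schema: dict[str, str] | None = None
) -> tuple[pd.DataFrame, ReadReport]:
    """Read a raw analyzer stream CSV into a validated record table.

    Returns the table sorted by time together with a :class:`ReadReport`
    (rows read / rejected).  Duplicate (time, line_id) pairs are rejected;
    negative concentrations are flagged in a boolean ``negative_flag``
    column but retained.  An unparseable timestamp is a hard error naming
    the offending row.
    """
    colmap = {c: c for c in ANALYZER_COLUMNS}
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"analyzer stream {path} lacks columns {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})[ANALYZER_COLUMNS]

    times = pd.to_datetime(df["time"], utc=True, errors="coerce")
    bad = times.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"unparseable timestamp {df['time'].iloc[row]!r} at data row {row}"
        )
    df["time"] = times

    n_read = len(df)
    dup = df.duplicated(subset=["time", "line_id"], keep="first")
    if dup.any():
        logger.warning("rejecting %d duplicate (time, line) rows", int(dup.sum()))
    df = df[~dup]

    reordered = not df["time"].is_monotonic_increasing
    if reordered:
        logger.info("input rows out of time order; sorting ascending")
        df = df.sort_values("time", kind="mergesort")
    df = df.reset_index(drop=True)

    neg = (df["c12_ppm"] < 0) | (df["c13_ppm"] < 0)
    df["negative_flag"] = neg
    df["calibrated"] = False
    report = ReadReport(
        n_read=n_read,
        n_rejected=int(dup.sum()),
        n_flagged_negative=int(neg.sum()),
        reordered=reordered,
    )
    return df, report


def write_analyzer_stream(df: pd.DataFrame, path) -> None:
    out = df[ANALYZER_COLUMNS].copy()
    out["time"] = out["time"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)


def read_monolith_meta(path) -> dict[str, MonolithMeta]:
    df = pd.read_csv(path)
    missing = [c for c in MONOLITH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"monolith metadata {path} lacks columns {missing}")
    metas: dict[str, MonolithMeta] = {}
    for _, row in df.iterrows():
        m = MonolithMeta(
            monolith_id=str(row["monolith_id"]),
            land_use=row["land_use"],
            treatment=row["treatment"],
            campaign=row["campaign"],
            block_id=str(row["block"]),
            area=float(row["area_m2"]),
            uptake_13c=float(row["uptake_mg13C_m2"]),
            label_start=pd.Timestamp(row["label_start"], tz="UTC"),
            label_end=pd.Timestamp(row["label_end"], tz="UTC"),
            rewetting_time=pd.Timestamp(row["rewetting_time"], tz="UTC"),
        )
        metas[m.monolith_id] = m
    return metas


def write_monolith_meta(metas: Sequence[MonolithMeta], path) -> None:
    rows = []
    for m in metas:
        rows.append({
            "monolith_id": m.monolith_id, "land_use": m.land_use,
            "treatment": m.treatment, "campaign": m.campaign,
            "block": m.block_id, "area_m2": m.area,
            "uptake_mg13C_m2": m.uptake_13c,
            "label_start": m.label_start.isoformat(),
            "label_end": m.label_end.isoformat(),
            "rewetting_time": m.rewetting_time.isoformat(),
        })
    pd.DataFrame(rows, columns=MONOLITH_COLUMNS).to_csv(path, index=False)


def _summary(values: np.ndarray, t0: pd.Timestamp, t1: pd.Timestamp) -> SegmentSummary:
    return SegmentSummary(
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        n=int(len(values)),
        window=(t0, t1),
    )


def _trim_dead_band(run: pd.DataFrame, dead_band: float) -> pd.DataFrame:
    cut = run["time"].iloc[0] + pd.Timedelta(seconds=dead_band)
    return run[run["time"] >= cut]


def segment_measurement(
    pre: pd.DataFrame,
    outlet: pd.DataFrame,
    post: pd.DataFrame,
    monolith_id: str,
    flow: tuple[float, float],
    protocol: SegmentationProtocol | None = None,
) -> ChamberMeasurement:
    """Summarise one inlet/outlet/inlet cycle into a ChamberMeasurement.

    Per-window mean/sd are computed after discarding the first
    ``protocol.dead_band`` seconds of each window; the inlet summary pools
    the pre and post windows (equal weight on samples).  A window left
    empty after dead-band removal marks the measurement invalid rather
    than fabricating values.
    """
    protocol = protocol or SegmentationProtocol()
    windows = [_trim_dead_band(w, protocol.dead_band) for w in (pre, outlet, post)]
    t_mid = outlet["time"].iloc[0] + (outlet["time"].iloc[-1] - outlet["time"].iloc[0]) / 2

    if any(len(w) == 0 for w in windows):
        zero = SegmentSummary(0.0, 0.0, 1, (t_mid, t_mid))
        return ChamberMeasurement(
            monolith_id, t_mid, zero, zero, zero, zero, flow,
            valid=False, note="empty window after dead-band removal",
        )
    pre_t, out_t, post_t = windows
    inlet = pd.concat([pre_t, post_t])
    inlet_win = (pre_t["time"].iloc[0], post_t["time"].iloc[-1])
    out_win = (out_t["time"].iloc[0], out_t["time"].iloc[-1])
    return ChamberMeasurement(
        monolith_id=monolith_id,
        t_mid=t_mid,
        inlet12=_summary(inlet["c12_ppm"].to_numpy(), *inlet_win),
        inlet13=_summary(inlet["c13_ppm"].to_numpy(), *inlet_win),
        outlet12=_summary(out_t["c12_ppm"].to_numpy(), *out_win),
        outlet13=_summary(out_t["c13_ppm"].to_numpy(), *out_win),
        flow=flow,
        valid=bool(flow[0] > 0),
        note="" if flow[0] > 0 else "non-positive flow",
    )


def iter_line_runs(df: pd.DataFrame) -> Iterator[pd.DataFrame]:
    """Yield maximal contiguous runs of a single line_id, in time order."""
    if len(df) == 0:
        return
    change = (df["line_id"] != df["line_id"].shift()).cumsum()
    for _, run in df.groupby(change, sort=False):
        yield run


@dataclass
class CalibrationSegment:
    """Summaries of one calibration-gas window within a calibration cycle."""

    gas_id: str
    t_mid: pd.Timestamp
    c12: SegmentSummary
    c13: SegmentSummary


def _flow_stats(
    flow_log: pd.DataFrame | None,
    window: tuple[pd.Timestamp, pd.Timestamp],
    default_flow: tuple[float, float],
) -> tuple[float, float]:
    """Mean flow over the outlet window and the standard error of that mean."""
    if flow_log is None:
        return default_flow
    sel = flow_log[(flow_log["time"] >= window[0]) & (flow_log["time"] <= window[1])]
    if len(sel) == 0:
        return default_flow
    vals = sel["flow_ml_min"].to_numpy()
    se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), se


def segment_stream(
    records: pd.DataFrame,
    protocol: SegmentationProtocol | None = None,
    flow_log: pd.DataFrame | None = None,
    default_flow: tuple[float, float] = (170.0, 0.0),
) -> tuple[list[ChamberMeasurement], list[CalibrationSegment]]:
    """Split a multiplexed analyzer stream into chamber measurements and
    calibration segments.

    Chamber measurements are recognised as buffer-k / chamber-k / buffer-k
    run triplets; any ``cal-*`` run becomes one calibration segment.  Runs
    that do not complete a triplet are dropped with a log message.
    """
    protocol = protocol or SegmentationProtocol()
    runs = list(iter_line_runs(records))
    measurements: list[ChamberMeasurement] = []
    cal_segments: list[CalibrationSegment] = []
    i = 0
    while i < len(runs):
        run = runs[i]
        line = run["line_id"].iloc[0]
        m_cal = _CAL_RE.match(line)
        if m_cal:
            trimmed = _trim_dead_band(run, protocol.dead_band)
            if len(trimmed) > 0:
                win = (trimmed["time"].iloc[0], trimmed["time"].iloc[-1])
                t_mid = win[0] + (win[1] - win[0]) / 2
                cal_segments.append(CalibrationSegment(
                    gas_id=m_cal.group("gas"),
                    t_mid=t_mid,
                    c12=_summary(trimmed["c12_ppm"].to_numpy(), *win),
                    c13=_summary(trimmed["c13_ppm"].to_numpy(), *win),
                ))
            i += 1
            continue
        m_buf = _BUFFER_RE.match(line)
        if m_buf and i + 2 < len(runs):
            k = m_buf.group("id")
            mid, nxt = runs[i + 1], runs[i + 2]
            mid_m = _CHAMBER_RE.match(mid["line_id"].iloc[0])
            nxt_m = _BUFFER_RE.match(nxt["line_id"].iloc[0])
            if mid_m and nxt_m and mid_m.group("id") == k and nxt_m.group("id") == k:
                out_win = (mid["time"].iloc[0], mid["time"].iloc[-1])
                flow = _flow_stats(flow_log, out_win, default_flow)
                measurements.append(segment_measurement(
                    run, mid, nxt, monolith_id=k, flow=flow, protocol=protocol,
                ))
                i += 3
                continue
        logger.debug("dropping incomplete run on line %s", line)
        i += 1
    return measurements, cal_segments
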