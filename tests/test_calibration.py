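"""Span-offset fitting, time interpolation and the double-application guard."""

import numpy as np
import pandas as pd
import pytest

from pulsechase import apply_calibration, fit_span_offset
from pulsechase.calibration import CalibrationError, CalibrationGas, fit_calibration_cycles
from pulsechase.io_schema import CalibrationSegment, SegmentSummary

from conftest import T0

TRUE_C12 = np.array([400.0, 1500.0, 5000.0]) * (1 - 0.0105)


def _curve(span, offset, t, iso="c12"):
    measured = (TRUE_C12 - offset) / span
    return fit_span_offset(measured, TRUE_C12, iso, t)


class TestFitSpanOffset:
    def test_identity(self):
        c = fit_span_offset(TRUE_C12, TRUE_C12, "c12", T0)
        assert c.span == pytest.approx(1.0, abs=1e-12)
        assert c.offset == pytest.approx(0.0, abs=1e-9)

    def test_recovers_generating_line(self):
        # measured generated as (true - 5) / 0.98
        c = _curve(0.98, 5.0, T0)
        assert c.span == pytest.approx(0.98, rel=1e-12)
        assert c.offset == pytest.approx(5.0, rel=1e-9)
        assert c.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_two_points_exact(self):
        c = fit_span_offset(TRUE_C12[:2], TRUE_C12[:2] * 1.02, "c12", T0)
        assert c.residual_sd == 0.0

    def test_singular_fit(self):
        with pytest.raises(CalibrationError, match="singular"):
            fit_span_offset(np.array([400.0, 400.0]), np.array([400.0, 1500.0]),
                            "c12", T0)


def _records(times_h, c12, c13=5.0):
    n = len(times_h)
    return pd.DataFrame({
        "time": T0 + pd.to_timedelta(times_h, unit="h"),
        "line_id": "chamber-M01",
        "c12_ppm": np.broadcast_to(c12, n).astype(float),
        "c13_ppm": np.broadcast_to(c13, n).astype(float),
        "calibrated": False,
    })


class TestApplyCalibration:
    def test_identity_curves_leave_records_unchanged(self):
        curves = {"c12": [_curve(1.0, 0.0, T0)],
                  "c13": [fit_span_offset(np.array([4.2, 15.75]),
                                          np.array([4.2, 15.75]), "c13", T0)]}
        rec = _records([0.5], 1000.0)
        out = apply_calibration(rec, curves)
        assert out["c12_ppm"].iloc[0] == pytest.approx(1000.0, rel=1e-12)

    def test_constant_span_offset_applied(self):
        curves = {"c12": [_curve(0.98, 5.0, T0)],
                  "c13": [fit_span_offset(np.array([4.0, 15.0]),
                                          np.array([4.2, 15.75]), "c13", T0)]}
        out = apply_calibration(_records([0.5], 1000.0), curves)
        assert out["c12_ppm"].iloc[0] == pytest.approx(0.98 * 1000 + 5, rel=1e-10)

    def test_time_interpolated_span(self):
        # spans 1.00 at t=0 and 1.02 at t=2 h -> 1.01 at t=1 h: 1000 -> 1010
        c13 = fit_span_offset(np.array([4.2, 15.75]), np.array([4.2, 15.75]), "c13", T0)
        curves = {
            "c12": [_curve(1.00, 0.0, T0),
                    _curve(1.02, 0.0, T0 + pd.Timedelta(hours=2))],
            "c13": [c13],
        }
        out = apply_calibration(_records([1.0], 1000.0), curves)
        assert out["c12_ppm"].iloc[0] == pytest.approx(1010.0, rel=1e-10)

    def test_nearest_curve_outside_bracket(self):
        c13 = fit_span_offset(np.array([4.2, 15.75]), np.array([4.2, 15.75]), "c13", T0)
        curves = {
            "c12": [_curve(1.00, 0.0, T0),
                    _curve(1.02, 0.0, T0 + pd.Timedelta(hours=2))],
            "c13": [c13],
        }
        out = apply_calibration(_records([3.0], 1000.0), curves)
        assert out["c12_ppm"].iloc[0] == pytest.approx(1020.0, rel=1e-10)

    def test_stale_records_flagged_uncalibrated(self):
        c13 = fit_span_offset(np.array([4.2, 15.75]), np.array([4.2, 15.75]), "c13", T0)
        curves = {"c12": [_curve(0.98, 5.0, T0)], "c13": [c13]}
        out = apply_calibration(_records([7.0], 1000.0), curves)  # > 6 h horizon
        assert bool(out["uncalibrated"].iloc[0])
        assert out["c12_ppm"].iloc[0] == 1000.0  # left unchanged

    def test_double_application_guarded(self):
        c13 = fit_span_offset(np.array([4.2, 15.75]), np.array([4.2, 15.75]), "c13", T0)
        curves = {"c12": [_curve(1.0, 0.0, T0)], "c13": [c13]}
        once = apply_calibration(_records([0.5], 1000.0), curves)
        with pytest.raises(CalibrationError, match="already calibrated"):
            apply_calibration(once, curves)


class TestRoundTrip:
    def test_fit_from_segments_recovers_distortion(self):
        """Distort truth by a known (span, offset), fit from calibration
        segments, apply: concentrations recovered."""
        span12, off12, span13, off13 = 0.97, 8.0, 1.03, -0.1
        gases = {
            g: CalibrationGas.from_total(g, total, 0.0105)
            for g, total in (("G400", 400.0), ("G1500", 1500.0), ("G5000", 5000.0))
        }
        segs = []
        for gid, gas in gases.items():
            segs.append(CalibrationSegment(
                gas_id=gid, t_mid=T0,
                c12=SegmentSummary((gas.true_c12 - off12) / span12, 0.0, 50, (T0, T0)),
                c13=SegmentSummary((gas.true_c13 - off13) / span13, 0.0, 50, (T0, T0)),
            ))
        curves = fit_calibration_cycles(segs, gases)
        true12, true13 = 1200.0, 13.0
        rec = _records([0.1], (true12 - off12) / span12, (true13 - off13) / span13)
        out = apply_calibration(rec, curves)
        assert out["c12_ppm"].iloc[0] == pytest.approx(true12, rel=1e-10)
        assert out["c13_ppm"].iloc[0] == pytest.approx(true13, rel=1e-10)
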