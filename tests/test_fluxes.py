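"""Flux, mixing and error-propagation arithmetic against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from pulsechase import (
    FluxObservation,
    atom_fraction,
    compute_sr,
    estimate_natural_abundance,
    excess_atom_fraction,
    qc_filter,
    source_atom_fraction,
    taylor_sd,
    tracer_flux,
)
from pulsechase.fluxes import QC_CV, QC_INVALID, QC_NEGATIVE, QC_OK, UMOL_S_TO_MG_HR

from conftest import T0, make_measurement

AREA = math.pi * 0.0225**2


class TestComputeSR:
    def test_no_gradient_is_zero_flux(self):
        m = make_measurement(co2_in=400.0, co2_out=400.0, chi_in=0.011, chi_out=0.011)
        sr, _ = compute_sr(m, AREA)
        assert sr == pytest.approx(0.0, abs=1e-12)

    def test_dimensional_hand_calculation(self):
        # 170 ml/min at STP = 0.170/22.414/60 mol/s; delta = 100 µmol/mol
        m = make_measurement(co2_in=400.0, co2_out=500.0, chi_in=0.0, chi_out=0.0)
        sr, _ = compute_sr(m, AREA)
        expected = (0.170 / 22.414 / 60.0) * 100.0 / AREA
        assert sr == pytest.approx(expected, rel=1e-12)
        assert sr == pytest.approx(7.947, rel=1e-3)

    def test_linear_in_flow(self):
        m1 = make_measurement(flow=(170.0, 0.0))
        m2 = make_measurement(flow=(340.0, 0.0))
        assert compute_sr(m2, AREA)[0] == pytest.approx(2 * compute_sr(m1, AREA)[0])

    def test_nonpositive_flow_invalid(self):
        m = make_measurement(flow=(0.0, 0.0))
        sr, sd = compute_sr(m, AREA)
        assert math.isnan(sr)


class TestAtomFraction:
    @pytest.mark.parametrize("c13,c12,expected", [
        (4.4, 395.6, 0.011),
        (0.0, 400.0, 0.0),
        (50.0, 50.0, 0.5),
    ])
    def test_values(self, c13, c12, expected):
        assert atom_fraction(c13, c12) == pytest.approx(expected, rel=1e-12)

    def test_zero_total_undefined(self):
        assert math.isnan(atom_fraction(0.0, 0.0))


class TestSourceAtomFraction:
    def test_hand_arithmetic(self):
        # chi_out=0.02, CO2_out=500; chi_in=0.011, CO2_in=400
        m = make_measurement(co2_in=400.0, co2_out=500.0, chi_in=0.011, chi_out=0.02)
        chi, _, qc = source_atom_fraction(m)
        assert chi == pytest.approx((0.02 * 500 - 0.011 * 400) / 100, rel=1e-12)
        assert chi == pytest.approx(0.056)
        assert qc == QC_OK

    def test_mixing_identity(self):
        m = make_measurement(co2_in=400.0, co2_out=500.0, chi_in=0.013, chi_out=0.013)
        chi, _, _ = source_atom_fraction(m)
        assert chi == pytest.approx(0.013, rel=1e-12)

    def test_zero_gradient_invalid(self):
        m = make_measurement(co2_in=450.0, co2_out=450.0)
        _, _, qc = source_atom_fraction(m)
        assert qc == QC_INVALID

    @given(
        co2_in=st.floats(380.0, 450.0),
        delta=st.floats(6.0, 200.0),
        chi_in=st.floats(0.009, 0.013),
        chi_src=st.floats(0.005, 0.2),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce_mixing_solver(self, co2_in, delta, chi_in, chi_src):
        """Eq for the source equals a numeric two-endmember mass-balance
        solution on random instances above the minimum gradient."""
        co2_out = co2_in + delta
        chi_out = (chi_src * delta + chi_in * co2_in) / co2_out
        m = make_measurement(co2_in=co2_in, co2_out=co2_out,
                             chi_in=chi_in, chi_out=chi_out)
        chi, _, qc = source_atom_fraction(m)
        # brute force: find chi_s such that mixing inlet+source gives outlet
        def mismatch(chi_s):
            return (chi_s * delta + chi_in * co2_in) / co2_out - chi_out
        solved = brentq(mismatch, -1.0, 2.0, xtol=1e-14)
        assert chi == pytest.approx(solved, abs=1e-9)
        assert chi == pytest.approx(chi_src, rel=1e-6)


class TestExcessAndNaturalAbundance:
    @pytest.mark.parametrize("chi_sr,chi_na,expected", [
        (0.0108, 0.0108, 0.0),
        (0.0300, 0.0108, 0.0192),
        (0.0100, 0.0108, -0.0008),
    ])
    def test_subtraction(self, chi_sr, chi_na, expected):
        chi_e, _ = excess_atom_fraction(chi_sr, 0.0, chi_na)
        assert chi_e == pytest.approx(expected, abs=1e-15)

    def test_missing_natural_abundance_errors(self):
        with pytest.raises(ValueError, match="natural abundance"):
            excess_atom_fraction(0.02, 0.0, math.nan)

    def test_estimate_from_prelabel_window(self):
        import pandas as pd
        label = T0 + pd.Timedelta(hours=24)
        obs = [FluxObservation("M01", T0 + pd.Timedelta(hours=h), sr=1.0,
                               chi_sr=v, chi_sr_sd=0.0, chi_sr_valid=True)
               for h, v in [(20, 0.0106), (21, 0.0108), (22, 0.0110)]]
        chi, sd = estimate_natural_abundance(obs, label)
        assert chi == pytest.approx(0.0108)
        single, _ = estimate_natural_abundance(obs[:1], label)
        assert single == pytest.approx(0.0106)
        with pytest.raises(ValueError):
            estimate_natural_abundance([], label)


class TestTracerFlux:
    def test_zero_excess(self):
        assert tracer_flux(0.0, 0.0, 5.0, 0.0)[0] == 0.0

    def test_unit_conversion_oracle(self):
        # 5 µmol m-2 s-1 * 0.01 = 0.05 µmol 13C m-2 s-1
        # = 0.05 * 13.00335 * 3600 / 1000 mg m-2 hr-1
        v, _ = tracer_flux(0.01, 0.0, 5.0, 0.0)
        assert v == pytest.approx(0.05 * 13.00335 * 3600 / 1000, rel=1e-12)
        assert v == pytest.approx(2.341, abs=5e-4)

    def test_linear_in_sr(self):
        assert tracer_flux(0.01, 0.0, 10.0, 0.0)[0] == pytest.approx(
            2 * tracer_flux(0.01, 0.0, 5.0, 0.0)[0])


class TestTaylorSD:
    def test_zero_inputs_zero_sd(self):
        assert taylor_sd([1.0, 2.0], [0.0, 0.0]) == 0.0

    def test_single_term_closed_form(self):
        # SR = f*delta/A with sigma_f only: sd = |delta/A| * sigma_f
        delta, area, sigma_f = 100.0, AREA, 0.5
        assert taylor_sd([delta / area], [sigma_f]) == pytest.approx(
            abs(delta / area) * sigma_f)

    def test_eq3_sd_against_monte_carlo(self):
        """Propagated mixing sd vs a 1e6-draw MC oracle, CVs <= 0.1."""
        rng = np.random.default_rng(42)
        n_draw = 10**6
        co2_in, co2_out = 400.0, 500.0
        chi_in, chi_out = 0.011, 0.02
        # per-mean uncertainties (CV <= 0.1 on the gradient-relevant scale)
        s_ci, s_co, s_xi, s_xo = 2.0, 2.5, 0.0004, 0.0008
        m = make_measurement(
            co2_in=co2_in, co2_out=co2_out, chi_in=chi_in, chi_out=chi_out,
            sd_in12=s_ci * 10, sd_out12=s_co * 10,
            sd_in13=s_xi * co2_in * 10, sd_out13=s_xo * co2_out * 10, n=100)
        # analytic propagation as implemented
        _, sd_taylor, _ = source_atom_fraction(m)
        # MC oracle with the same four input uncertainties
        ci = rng.normal(co2_in, math.hypot(m.inlet12.se, m.inlet13.se), n_draw)
        co = rng.normal(co2_out, math.hypot(m.outlet12.se, m.outlet13.se), n_draw)
        xi = rng.normal(chi_in, s_xi, n_draw)
        xo = rng.normal(chi_out, s_xo, n_draw)
        chi_sr = (xo * co - xi * ci) / (co - ci)
        # the implementation derives chi sds from the isotopologue sds
        from pulsechase.fluxes import atom_fraction_sd
        sd_xi = atom_fraction_sd(m.inlet13.mean, m.inlet12.mean,
                                 m.inlet13.se, m.inlet12.se)
        sd_xo = atom_fraction_sd(m.outlet13.mean, m.outlet12.mean,
                                 m.outlet13.se, m.outlet12.se)
        xi = rng.normal(chi_in, sd_xi, n_draw)
        xo = rng.normal(chi_out, sd_xo, n_draw)
        chi_sr = (xo * co - xi * ci) / (co - ci)
        assert sd_taylor == pytest.approx(np.std(chi_sr), rel=0.02)


class TestQCFilter:
    def _obs(self, sr=5.0, sr_sd=0.1, chi_e=0.01, chi_e_sd=0.001):
        return FluxObservation("M01", T0, sr=sr, sr_sd=sr_sd, chi_sr=0.02,
                               chi_sr_sd=0.001, chi_excess=chi_e,
                               chi_excess_sd=chi_e_sd)

    def test_negative_sr_excluded(self):
        assert qc_filter(self._obs(sr=-0.1)).qc == QC_NEGATIVE

    def test_high_cv_excluded(self):
        obs = qc_filter(self._obs(chi_e=0.01, chi_e_sd=0.012))  # CV = 1.2
        assert obs.qc == QC_CV
        assert obs.qc_tracer == QC_CV and obs.qc_sr == QC_OK

    def test_boundary_cv_retained(self):
        obs = qc_filter(self._obs(chi_e=0.01, chi_e_sd=0.01))  # CV = 1 exactly
        assert obs.qc == QC_OK

    def test_negative_excess_excluded_for_tracer_only(self):
        obs = qc_filter(self._obs(chi_e=-0.0008))
        assert obs.qc_tracer == QC_NEGATIVE and obs.qc_sr == QC_OK
        assert obs.qc == QC_NEGATIVE


class TestInvariants:
    @given(
        co2_in=st.floats(380.0, 450.0),
        sr=st.floats(0.1, 10.0),
        flow=st.floats(100.0, 400.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_flux_equation_round_trip(self, co2_in, sr, flow):
        """Reconstruct CO2_out from (CO2_in, SR, f, A), re-run the flux
        equation: SR comes back exactly."""
        from pulsechase.fluxes import molar_flow
        fm = molar_flow(flow)
        co2_out = co2_in + sr * AREA / fm
        m = make_measurement(co2_in=co2_in, co2_out=co2_out,
                             chi_in=0.011, chi_out=0.011, flow=(flow, 0.0))
        sr_back, _ = compute_sr(m, AREA)
        assert sr_back == pytest.approx(sr, rel=1e-9)

    @given(split=st.floats(0.001, 0.3))
    @settings(max_examples=25, deadline=None)
    def test_abs13c_invariant_to_isotopologue_split(self, split):
        """abs13C depends only on totals and atom fractions, not on the
        particular (c12, c13) split realising them."""
        m1 = make_measurement(co2_in=400.0, co2_out=500.0,
                              chi_in=0.011, chi_out=split)
        chi1, _, _ = source_atom_fraction(m1)
        sr1, _ = compute_sr(m1, AREA)
        # same totals/chis but built from a different decomposition route
        m2 = make_measurement(co2_in=400.0, co2_out=500.0,
                              chi_in=0.011, chi_out=split, n=7)
        chi2, _, _ = source_atom_fraction(m2)
        sr2, _ = compute_sr(m2, AREA)
        e1, _ = excess_atom_fraction(chi1, 0.0, 0.0108)
        e2, _ = excess_atom_fraction(chi2, 0.0, 0.0108)
        assert tracer_flux(e1, 0.0, sr1, 0.0)[0] == pytest.approx(
            tracer_flux(e2, 0.0, sr2, 0.0)[0], rel=1e-12)
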