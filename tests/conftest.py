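import logging

import numpy as np
import pandas as pd
import pytest

from pulsechase import (
    ChamberMeasurement,
    RunConfig,
    SegmentSummary,
    SyntheticScenario,
    generate_scenario,
    run_pipeline,
)

logging.getLogger("pulsechase").setLevel(logging.ERROR)

T0 = pd.Timestamp("2014-06-10T00:00:00Z")


def make_summary(mean, sd=0.0, n=100):
    return SegmentSummary(mean=mean, sd=sd, n=n,
                          window=(T0, T0 + pd.Timedelta(seconds=250)))


def make_measurement(
    co2_in=400.0, co2_out=500.0, chi_in=0.011, chi_out=0.02,
    flow=(170.0, 0.0), sd_in12=0.0, sd_in13=0.0, sd_out12=0.0, sd_out13=0.0,
    n=100, monolith_id="M01",
):
    """ChamberMeasurement from total CO2 and atom fractions."""
    return ChamberMeasurement(
        monolith_id=monolith_id,
        t_mid=T0,
        inlet12=make_summary(co2_in * (1 - chi_in), sd_in12, n),
        inlet13=make_summary(co2_in * chi_in, sd_in13, n),
        outlet12=make_summary(co2_out * (1 - chi_out), sd_out12, n),
        outlet13=make_summary(co2_out * chi_out, sd_out13, n),
        flow=flow,
    )


def closure_scenario(**overrides):
    """Noise-free, identity-calibration scenario with dense cadence."""
    params = dict(
        seed=3, n_replicates=1, treatments=("control",), land_uses=("managed",),
        diel_amplitude=0.0, tracer_diel_amplitude=0.0, biological_cv=0.0,
        uptake_jitter_cv=0.0, noise_c12=0.0, noise_c13=0.0,
        flow_jitter_ml_min=0.0,
        span_c12=1.0, offset_c12=0.0, span_c13=1.0, offset_c13=0.0,
        pre_label_h=12.0, chase_h=120.0, rewet_after_label_h=126.0,
        post_rewet_h=6.0, cadence_h=0.25, sample_period_s=5.0,
    )
    params.update(overrides)
    return SyntheticScenario(**params)


@pytest.fixture(scope="session")
def closure_run():
    data = generate_scenario(closure_scenario())
    cfg = RunConfig(grid_step_h=0.25, mc_n=50, n_perm=100, smoothing=1e-7)
    return data, run_pipeline(data, cfg)


@pytest.fixture(scope="session")
def default_run():
    """Full default campaign at default noise, n=3 replicates per cell."""
    data = generate_scenario(SyntheticScenario(seed=11))
    return data, run_pipeline(data, RunConfig(seed=11))


def get_cumulative(result, variable, window_start, monolith_id=None):
    out = [c for c in result.cumulatives
           if c.variable == variable and abs(c.window[0] - window_start) < 0.5
           and (monolith_id is None or c.monolith_id == monolith_id)]
    return out
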