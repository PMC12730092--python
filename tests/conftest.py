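from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from enteric import SimulationConfig, TrueEmissionProfile


@pytest.fixture
def quiet_config():
    """Noise/drift-free chamber configuration at the study setpoints."""
    return SimulationConfig(
        seed=0,
        temp_c=16.0,
        rh_pct=70.0,
        analyzer_noise_sd_ppm=0.0,
        analyzer_drift_per_day=0.0,
    )


@pytest.fixture
def constant_profile():
    """Constant 454 g/d emission, no diurnal pattern or noise."""
    return TrueEmissionProfile(
        baseline_g_per_day=454.0, diurnal_amplitude=0.0, meal_peaks=(),
        noise_sd=0.0,
    )


def make_stream(
    n_min=18,
    start=datetime(2025, 6, 1, 0, 0, 0),
    step_s=20,
    ch4_by_source=None,
    temp_c=16.0,
    rh_pct=70.0,
    pressure_hpa=1013.25,
    wet_vr_lpm=140_000.0 / 60.0,
):
    """Deterministic multiplexed stream for demultiplexer tests."""
    ch4_by_source = ch4_by_source or {"RC1": 200.0, "RC2": 150.0, "FRESH": 2.0}
    order = ("RC1", "RC2", "FRESH")
    rows = []
    n = int(n_min * 60 / step_s)
    for i in range(n):
        t = start + timedelta(seconds=i * step_s)
        slot = (i * step_s) // 120 % 3
        src = order[slot]
        rows.append(
            {
                "timestamp": t,
                "source": src,
                "ch4_ppm": ch4_by_source[src],
                "co2_ppm": 420.0,
                "o2_pct": 20.6,
                "temp_c": temp_c,
                "rh_pct": rh_pct,
                "pressure_hpa": pressure_hpa,
                "wet_vr_lpm": wet_vr_lpm,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def multiplexed_stream():
    return make_stream()
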