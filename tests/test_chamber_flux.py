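"""Flux equation chain, demultiplexing, gap filling, daily totals."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enteric import chamber_flux as cf
from conftest import make_stream


class TestEquationChain:
    @pytest.mark.parametrize(
        "temp_c,rh,expected",
        [
            (15.0, 100.0, 17.052),
            (15.0, 0.0, 0.0),
            (15.0, 70.0, 11.937),
        ],
    )
    def test_partial_water_pressure(self, temp_c, rh, expected):
        assert cf.partial_water_pressure(temp_c, rh) == pytest.approx(
            expected, abs=5e-4
        )

    def test_pwp_rejects_out_of_range_temperature(self):
        with pytest.raises(ValueError, match="-5"):
            cf.partial_water_pressure(60.0, 50.0)
        with pytest.raises(ValueError):
            cf.partial_water_pressure(20.0, 150.0)

    @pytest.mark.parametrize(
        "pwp,p,expected",
        [(11.937, 1013.25, 1.178), (0.0, 1013.25, 0.0), (17.052, 1013.25, 1.683)],
    )
    def test_volume_mixing_ratio(self, pwp, p, expected):
        assert cf.volume_mixing_ratio(pwp, p) == pytest.approx(expected, abs=5e-4)

    def test_vmr_rejects_nonphysical_pressure(self):
        with pytest.raises(ValueError):
            cf.volume_mixing_ratio(1013.0, 1013.0)

    @pytest.mark.parametrize(
        "wet,vmr,expected",
        [(2333.33, 1.178, 2305.8), (2333.33, 0.0, 2333.33), (0.0, 50.0, 0.0)],
    )
    def test_dry_ventilation_rate(self, wet, vmr, expected):
        assert cf.dry_ventilation_rate(wet, vmr) == pytest.approx(expected, abs=0.1)

    @pytest.mark.parametrize(
        "p,dvr,t,expected",
        [
            (1013.25, 2305.8, 15.0, 2185.8),
            (1013.25, 1234.5, 0.0, 1234.5),
            (900.0, 2305.8, 15.0, 1941.5),
        ],
    )
    def test_stp_ventilation_rate(self, p, dvr, t, expected):
        assert cf.stp_ventilation_rate(p, dvr, t) == pytest.approx(expected, abs=0.1)

    @pytest.mark.parametrize(
        "dstpvr,diff,rec,expected",
        [
            (2185.8, 200.0, 0.993, 0.44024),
            (2185.8, 0.0, 0.7, 0.0),
            (2185.8, 200.0, 1.0, 0.43716),
        ],
    )
    def test_emission_rate(self, dstpvr, diff, rec, expected):
        assert cf.emission_rate(dstpvr, diff, rec) == pytest.approx(
            expected, abs=5e-5
        )

    def test_emission_rate_rejects_nonpositive_recovery(self):
        with pytest.raises(ValueError):
            cf.emission_rate(2000.0, 100.0, 0.0)

    @given(
        t=st.floats(0.0, 44.0),
        p=st.floats(900.0, 1050.0),
        dvr=st.floats(1.0, 5000.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_dstpvr_monotone_in_temperature_and_pressure(self, t, p, dvr):
        base = cf.stp_ventilation_rate(p, dvr, t)
        assert cf.stp_ventilation_rate(p, dvr, t + 1.0) < base
        assert cf.stp_ventilation_rate(p + 10.0, dvr, t) > base

    def test_humidity_correction_band_at_chamber_setpoints(self):
        # direct evaluation over the chamber T/RH setpoint box
        ratios = [
            1.0 - cf.volume_mixing_ratio(
                cf.partial_water_pressure(t, rh), 1013.25
            ) / 100.0
            for t in np.linspace(15, 18, 13)
            for rh in np.linspace(60, 80, 13)
        ]
        assert min(ratios) > 0.9835
        assert max(ratios) < 0.991


class TestDemultiplex:
    def test_three_retained_windows_per_source(self, multiplexed_stream):
        out = cf.demultiplex(multiplexed_stream)
        assert set(out) == {"RC1", "RC2", "FRESH"}
        for src, df in out.items():
            assert len(df) == 3
        # retained slot values are slot means of the second minute
        assert out["RC1"]["ch4_ppm"].tolist() == [200.0, 200.0, 200.0]

    def test_purge_zero_keeps_all_in_slot_records(self, multiplexed_stream):
        cycle = cf.SamplingCycle(purge_fraction=0.0)
        out = cf.demultiplex(multiplexed_stream, cycle)
        # same slot means, just from 6 instead of 3 readings each
        assert out["RC2"]["ch4_ppm"].tolist() == [150.0, 150.0, 150.0]

    def test_constant_fresh_air_interpolates_to_constant(self, multiplexed_stream):
        pts = cf.chamber_emission_points(multiplexed_stream, "RC1")
        assert np.allclose(pts["diff_ppm"], 198.0)

    def test_unknown_source_rejected(self, multiplexed_stream):
        bad = multiplexed_stream.copy()
        bad.loc[0, "source"] = "RC9"
        with pytest.raises(ValueError, match="RC9"):
            cf.demultiplex(bad)

    def test_out_of_order_timestamps_rejected(self, multiplexed_stream):
        bad = multiplexed_stream.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="increasing"):
            cf.demultiplex(bad)

    def test_timestamps_label_slot_starts(self, multiplexed_stream):
        out = cf.demultiplex(multiplexed_stream)
        t0 = multiplexed_stream["timestamp"].iloc[0]
        assert out["RC1"]["timestamp"].iloc[0] == t0
        assert out["RC2"]["timestamp"].iloc[0] == t0 + timedelta(minutes=2)


def _series(values, start=datetime(2025, 6, 1), step_min=6):
    return pd.DataFrame(
        {
            "timestamp": [start + timedelta(minutes=step_min * i) for i in range(len(values))],
            "emission_lpm": values,
            "filled": False,
        }
    )


class TestFillGaps:
    def test_pooled_neighbor_mean_worked_example(self):
        vals = [8, 9, 10, 9, 99, 99, 11, 10, 9, 10]
        s = _series(vals)
        ev = cf.EventInterval(s.timestamp[4], s.timestamp[6])
        out = cf.fill_gaps(s, [ev], k=4)
        assert out["emission_lpm"].tolist()[4:6] == [9.5, 9.5]
        assert out["filled"].tolist() == [False] * 4 + [True] * 2 + [False] * 4

    def test_constant_neighbors_fill_with_constant(self):
        s = _series([7.0] * 12)
        ev = cf.EventInterval(s.timestamp[5], s.timestamp[8])
        out = cf.fill_gaps(s, [ev], k=4)
        assert np.allclose(out["emission_lpm"], 7.0)

    def test_edge_gap_uses_one_sided_mean(self):
        s = _series([99, 10, 10, 12, 12])
        ev = cf.EventInterval(s.timestamp[0], s.timestamp[1])
        with pytest.warns(UserWarning, match="edge"):
            out = cf.fill_gaps(s, [ev], k=4)
        assert out["emission_lpm"].iloc[0] == pytest.approx(11.0)

    def test_gap_with_no_neighbors_errors(self):
        s = _series([1.0, 2.0])
        ev = cf.EventInterval(
            s.timestamp[0] - timedelta(minutes=1),
            s.timestamp[1] + timedelta(minutes=1),
        )
        with pytest.raises(ValueError, match="neighbor"):
            cf.fill_gaps(s, [ev])

    def test_points_outside_events_never_change(self):
        rng = np.random.default_rng(7)
        s = _series(rng.uniform(0.3, 0.6, size=50))
        ev = cf.EventInterval(s.timestamp[20], s.timestamp[25])
        out = cf.fill_gaps(s, [ev], k=4)
        outside = ~((s.index >= 20) & (s.index < 25))
        assert (out.loc[outside, "emission_lpm"] == s.loc[outside, "emission_lpm"]).all()

    def test_no_events_is_identity(self):
        s = _series([1, 2, 3.0])
        out = cf.fill_gaps(s, [])
        pd.testing.assert_frame_equal(out, s)


class TestDailyTotal:
    def test_constant_rate_integrates_to_expected_mass(self):
        s = _series([0.44024] * 240, step_min=6)
        daily = cf.daily_total(s)
        assert daily["total_l_d"].iloc[0] == pytest.approx(633.9, abs=0.1)
        assert daily["total_g_d"].iloc[0] == pytest.approx(454.0, abs=0.1)

    def test_zero_series_gives_zero(self):
        s = _series([0.0] * 240)
        daily = cf.daily_total(s)
        assert daily["total_l_d"].iloc[0] == 0.0
        assert daily["total_g_d"].iloc[0] == 0.0

    def test_half_days_sum_to_full_day(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.3, 0.5, size=240)
        s = _series(list(vals))
        full = cf.daily_total(s)["total_l_d"].iloc[0]
        h1 = cf.daily_total(s.iloc[:120])["total_l_d"].iloc[0]
        h2 = cf.daily_total(s.iloc[120:])["total_l_d"].iloc[0]
        assert h1 + h2 == pytest.approx(full, rel=1e-12)

    def test_mass_conversion_constant(self):
        s = _series([0.5] * 240)
        daily = cf.daily_total(s)
        assert daily["total_g_d"].iloc[0] == pytest.approx(
            daily["total_l_d"].iloc[0] / cf.L_PER_G_CH4
        )

    def test_low_coverage_day_flagged_invalid(self):
        s = _series([0.4] * 100)  # 600 of 1440 min measured
        daily = cf.daily_total(s)
        assert not daily["valid"].iloc[0]
        assert daily["coverage"].iloc[0] == pytest.approx(100 * 6 / 1440)

    def test_filled_points_do_not_count_as_coverage(self):
        s = _series([0.4] * 240)
        s.loc[:59, "filled"] = True
        daily = cf.daily_total(s)
        assert daily["n_filled"].iloc[0] == 60
        assert daily["coverage"].iloc[0] == pytest.approx(180 * 6 / 1440)
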