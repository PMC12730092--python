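"""Open-circuit respiration-chamber methane flux computation.

Turns a multiplexed analyzer stream (chamber outlets + fresh inlet air,
sampled sequentially through a switching device) into per-chamber,
background-corrected, recovery-corrected methane emission series and
daily totals.

The emission at each retained time point is

    CH4 (L/min) = DSTPVR * (dCH4_ppm / 1e6) / recovery_rate

where ``dCH4_ppm`` is the chamber-minus-fresh-air methane mixing ratio and
DSTPVR is the ventilation rate expressed as dry gas at standard temperature
and pressure (0 degC, 1013.25 hPa).  The wet->dry->STP correction chain is

    PWP     (hPa)   = sat_vapor_pressure(T) * RH/100
    VMR     (%)     = 100 * PWP / P
    DVR     (L/min) = WetVR * (100 - VMR)/100
    DSTPVR  (L/min) = DVR * (P/1013.25) * (273.15/(T + 273.15))

Daily totals are the sum of per-slot emissions, each representing one full
sampling cycle, converted to mass with 1 g CH4 = 1.3962 L CH4 (STP).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: litres of CH4 (STP) per gram
L_PER_G_CH4 = 1.3962

#: standard pressure, hPa
STANDARD_PRESSURE_HPA = 1013.25

#: 0 degC in kelvin
KELVIN_0C = 273.15

# Saturation vapor pressure polynomial in chamber temperature (degC),
# ascending powers, result in hPa.  Valid roughly -5..45 degC.
_SVP_COEFFS = (
    6.1117675,
    0.4439,
    0.014305,
    0.000265,
    0.00000302,
    0.0000000204,
    0.00000000006388,
)

TEMP_VALID_RANGE_C = (-5.0, 45.0)

#: required sensor-stream columns
SENSOR_COLUMNS = [
    "timestamp",
    "source",
    "ch4_ppm",
    "co2_ppm",
    "o2_pct",
    "temp_c",
    "rh_pct",
    "pressure_hpa",
    "wet_vr_lpm",
]

VALID_SOURCES = ("RC1", "RC2", "FRESH")


# ---------------------------------------------------------------------------
# the equation chain
# ---------------------------------------------------------------------------

def partial_water_pressure(temp_c, rh_pct):
    """Partial water (vapor) pressure of chamber air, hPa.

    Sixth-order polynomial fit to the saturation vapor pressure over
    water, scaled by relative humidity.  Vectorized over numpy arrays.

    Parameters
    ----------
    temp_c : float or array
        Chamber temperature, degC; must lie within -5..45 degC.
    rh_pct : float or array
        Relative humidity, % (0..100).
    """
    temp_c = np.asarray(temp_c, dtype=float)
    rh_pct = np.asarray(rh_pct, dtype=float)
    lo, hi = TEMP_VALID_RANGE_C
    if np.any(temp_c < lo) or np.any(temp_c > hi):
        raise ValueError(
            f"temperature outside the polynomial validity range [{lo}, {hi}] degC"
        )
    if np.any(rh_pct < 0) or np.any(rh_pct > 100):
        raise ValueError("relative humidity must be within [0, 100] %")
    svp = np.polynomial.polynomial.polyval(temp_c, _SVP_COEFFS)
    out = svp * rh_pct / 100.0
    return out if out.ndim else float(out)


def volume_mixing_ratio(pwp_hpa, pressure_hpa):
    """Volume mixing ratio of water vapor, % of total air."""
    pwp_hpa = np.asarray(pwp_hpa, dtype=float)
    pressure_hpa = np.asarray(pressure_hpa, dtype=float)
    if np.any(pwp_hpa < 0):
        raise ValueError("partial water pressure must be non-negative")
    if np.any(pressure_hpa <= pwp_hpa):
        raise ValueError("air pressure must exceed partial water pressure")
    out = 100.0 * pwp_hpa / pressure_hpa
    return out if out.ndim else float(out)


def dry_ventilation_rate(wet_vr_lpm, vmr_pct):
    """Dry ventilation rate, L/min: wet flow stripped of its water vapor."""
    wet_vr_lpm = np.asarray(wet_vr_lpm, dtype=float)
    if np.any(wet_vr_lpm < 0):
        raise ValueError("wet ventilation rate must be non-negative")
    out = wet_vr_lpm * (100.0 - np.asarray(vmr_pct, dtype=float)) / 100.0
    return out if out.ndim else float(out)


def stp_ventilation_rate(pressure_hpa, dvr_lpm, temp_c):
    """Dry ventilation rate corrected to STP (0 degC, 1013.25 hPa), L/min."""
    temp_c = np.asarray(temp_c, dtype=float)
    if np.any(temp_c <= -KELVIN_0C):
        raise ValueError("temperature below absolute zero")
    out = (
        (np.asarray(pressure_hpa, dtype=float) * np.asarray(dvr_lpm, dtype=float))
        / (temp_c + KELVIN_0C)
        * (KELVIN_0C / STANDARD_PRESSURE_HPA)
    )
    return out if out.ndim else float(out)


def emission_rate(dstpvr_lpm, ch4_diff_ppm, recovery_rate=1.0):
    """Gas emission, L/min (STP), from a chamber-minus-fresh mixing ratio.

    ``recovery_rate`` is the fraction of a known injected flow the system
    reports (from CO2 recovery tests); measured emission is divided by it.
    """
    recovery_rate = np.asarray(recovery_rate, dtype=float)
    if np.any(recovery_rate <= 0):
        raise ValueError("recovery rate must be positive")
    out = (
        np.asarray(dstpvr_lpm, dtype=float)
        * (np.asarray(ch4_diff_ppm, dtype=float) / 1e6)
        / recovery_rate
    )
    return out if out.ndim else float(out)


def stp_ventilation_from_wet(wet_vr_lpm, temp_c, rh_pct, pressure_hpa):
    """Full wet -> dry -> STP chain in one call, L/min."""
    pwp = partial_water_pressure(temp_c, rh_pct)
    vmr = volume_mixing_ratio(pwp, pressure_hpa)
    dvr = dry_ventilation_rate(wet_vr_lpm, vmr)
    return stp_ventilation_rate(pressure_hpa, dvr, temp_c)


# ---------------------------------------------------------------------------
# sampling cycle & demultiplexing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingCycle:
    """Gas-switching sequence of the analyzer.

    One full cycle visits every source once; the leading ``purge_fraction``
    of each slot is discarded while the sample line flushes the previous
    source's remains.
    """

    cycle_length_min: float = 6.0
    slot_length_min: float = 2.0
    source_order: tuple[str, ...] = ("RC1", "RC2", "FRESH")
    purge_fraction: float = 0.5

    def __post_init__(self):
        if not np.isclose(
            self.slot_length_min * len(self.source_order), self.cycle_length_min
        ):
            raise ValueError("slot_length * n_sources must equal cycle_length")
        if not 0 <= self.purge_fraction < 1:
            raise ValueError("purge_fraction must be in [0, 1)")


@dataclass(frozen=True)
class EventInterval:
    """Interval whose readings are unusable (door opening, failure, manual)."""

    start: datetime
    end: datetime
    kind: str = "door"

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("event start must precede end")


def _check_stream(stream: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SENSOR_COLUMNS if c not in stream.columns]
    if missing:
        raise ValueError(f"sensor stream missing columns: {missing}")
    bad = set(stream["source"].unique()) - set(VALID_SOURCES)
    if bad:
        raise ValueError(f"unknown source labels: {sorted(bad)}")
    ts = pd.to_datetime(stream["timestamp"])
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("timestamps must be strictly increasing")
    return stream.assign(timestamp=ts)


def demultiplex(
    stream: pd.DataFrame,
    cycle: SamplingCycle | None = None,
    origin: datetime | None = None,
) -> dict[str, pd.DataFrame]:
    """Split a multiplexed stream into one averaged series per source.

    Records are assigned to 2-min slots counted from ``origin`` (default:
    first timestamp).  Within each slot the leading ``purge_fraction`` is
    discarded and the remaining readings averaged into a single value,
    timestamped at the slot start (timestamps label interval starts).

    Returns a dict mapping source name to a time-indexed DataFrame of the
    numeric sensor columns.
    """
    cycle = cycle or SamplingCycle()
    stream = _check_stream(stream)
    if origin is None:
        origin = stream["timestamp"].iloc[0]
    elapsed_s = (stream["timestamp"] - origin).dt.total_seconds().to_numpy()
    slot_s = cycle.slot_length_min * 60.0
    slot_idx = np.floor(elapsed_s / slot_s).astype(np.int64)
    pos_in_slot = elapsed_s - slot_idx * slot_s
    keep = pos_in_slot >= cycle.purge_fraction * slot_s

    kept = stream.loc[keep].copy()
    kept["_slot"] = slot_idx[keep]
    num_cols = [c for c in SENSOR_COLUMNS if c not in ("timestamp", "source")]
    out: dict[str, pd.DataFrame] = {}
    for src, grp in kept.groupby("source", sort=False):
        agg = grp.groupby("_slot")[num_cols].mean()
        agg.insert(
            0,
            "timestamp",
            [origin + timedelta(seconds=i * slot_s) for i in agg.index],
        )
        out[str(src)] = agg.reset_index(drop=True)
    return out


def chamber_emission_points(
    stream: pd.DataFrame,
    chamber: str = "RC1",
    cycle: SamplingCycle | None = None,
    recovery_rate: float = 1.0,
    gas: str = "ch4",
    origin: datetime | None = None,
) -> pd.DataFrame:
    """Per-slot emission series for one chamber, with the full correction chain.

    The fresh-air reference (sampled once per cycle) is linearly interpolated
    onto the chamber's retained slot timestamps before subtraction.

    Returns a DataFrame with the intermediate quantities of the chain
    (pwp_hpa, vmr_pct, dvr_lpm, dstpvr_lpm, diff_ppm) and ``emission_lpm``.
    """
    cycle = cycle or SamplingCycle()
    if chamber not in cycle.source_order or chamber == "FRESH":
        raise ValueError(f"{chamber!r} is not a chamber in the cycle")
    gas_col = {"ch4": "ch4_ppm", "co2": "co2_ppm"}[gas]

    per_source = demultiplex(stream, cycle, origin=origin)
    if chamber not in per_source or "FRESH" not in per_source:
        raise ValueError("stream lacks chamber or fresh-air slots")
    cham = per_source[chamber]
    fresh = per_source["FRESH"]

    t_cham = cham["timestamp"].astype("int64").to_numpy()
    t_fresh = fresh["timestamp"].astype("int64").to_numpy()
    fresh_interp = np.interp(t_cham, t_fresh, fresh[gas_col].to_numpy())

    pwp = partial_water_pressure(cham["temp_c"], cham["rh_pct"])
    vmr = volume_mixing_ratio(pwp, cham["pressure_hpa"])
    dvr = dry_ventilation_rate(cham["wet_vr_lpm"], vmr)
    dstpvr = stp_ventilation_rate(cham["pressure_hpa"], dvr, cham["temp_c"])
    diff = cham[gas_col].to_numpy() - fresh_interp

    return pd.DataFrame(
        {
            "timestamp": cham["timestamp"],
            "pwp_hpa": pwp,
            "vmr_pct": vmr,
            "dvr_lpm": dvr,
            "dstpvr_lpm": dstpvr,
            "diff_ppm": diff,
            "emission_lpm": emission_rate(dstpvr, diff, recovery_rate),
            "filled": False,
        }
    )


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------

def fill_gaps(
    series: pd.DataFrame,
    events: Sequence[EventInterval],
    k: int = 4,
    value_col: str = "emission_lpm",
) -> pd.DataFrame:
    """Overwrite readings inside event intervals with neighbor means.

    Every point inside an event interval is replaced by the mean of the
    ``k`` nearest valid points before the interval and the ``k`` nearest
    after (2k values pooled).  At a series edge, the available side is used
    alone (with a warning); a gap with no valid neighbor on either side is
    an error.  Points outside events are never changed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = series.copy()
    if "filled" not in out.columns:
        out["filled"] = False
    if not events:
        return out
    t = pd.to_datetime(out["timestamp"]).to_numpy()
    in_event = np.zeros(len(out), dtype=bool)
    for ev in events:
        in_event |= (t >= np.datetime64(ev.start)) & (t < np.datetime64(ev.end))
    valid_idx = np.flatnonzero(~in_event)

    # contiguous runs of in-event points are filled as one gap
    gap_idx = np.flatnonzero(in_event)
    if gap_idx.size == 0:
        return out
    runs = np.split(gap_idx, np.flatnonzero(np.diff(gap_idx) > 1) + 1)
    values = out[value_col].to_numpy(dtype=float).copy()
    for run in runs:
        before = valid_idx[valid_idx < run[0]][-k:]
        after = valid_idx[valid_idx > run[-1]][:k]
        pool = np.concatenate([before, after])
        if pool.size == 0:
            raise ValueError(
                "gap has no valid neighboring points on either side"
            )
        if before.size < k or after.size < k:
            warnings.warn(
                f"gap at index {run[0]}..{run[-1]} filled from "
                f"{before.size}+{after.size} neighbors (series edge)",
                stacklevel=2,
            )
        values[run] = values[pool].mean()
    out[value_col] = values
    out.loc[in_event, "filled"] = True
    return out


def door_schedule(
    dates: Sequence,
    open_times: Sequence[str] = ("08:00", "16:00"),
    duration_min: float = 30.0,
    kind: str = "door",
) -> list[EventInterval]:
    """Twice-daily door-opening intervals for chamber cleaning/feeding/milking."""
    events = []
    for d in pd.to_datetime(pd.Index(dates)):
        for hm in open_times:
            h, m = (int(x) for x in hm.split(":"))
            start = d.replace(hour=h, minute=m)
            events.append(
                EventInterval(start, start + timedelta(minutes=duration_min), kind)
            )
    return events


# ---------------------------------------------------------------------------
# daily totals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DailyEmission:
    """One chamber-day methane total."""

    date: datetime
    total_l_per_day: float
    total_g_per_day: float
    n_points: int
    n_filled: int
    coverage_fraction: float
    valid: bool


def daily_total(
    series: pd.DataFrame,
    day_origin: datetime | None = None,
    cycle_length_min: float = 6.0,
    coverage_threshold: float = 0.9,
) -> pd.DataFrame:
    """Sum per-slot emissions into 24-h totals.

    Each retained slot value represents one full sampling cycle
    (``cycle_length_min`` minutes) in the sum.  Days are 24-h windows
    counted from ``day_origin`` (default: first timestamp — i.e. aligned
    to chamber entry rather than midnight).  ``coverage_fraction`` is the
    measured (unfilled) minutes over 1440; days below
    ``coverage_threshold`` are flagged invalid.
    """
    if series.empty:
        raise ValueError("empty emission series")
    ts = pd.to_datetime(series["timestamp"])
    if day_origin is None:
        day_origin = ts.iloc[0]
    day_idx = np.floor(
        (ts - day_origin).dt.total_seconds().to_numpy() / 86400.0
    ).astype(int)
    filled = series["filled"].to_numpy() if "filled" in series else np.zeros(len(series), bool)
    em = series["emission_lpm"].to_numpy(dtype=float)

    rows = []
    for d in np.unique(day_idx):
        m = day_idx == d
        total_l = float(em[m].sum() * cycle_length_min)
        n_points = int(m.sum())
        n_filled = int(filled[m].sum())
        coverage = (n_points - n_filled) * cycle_length_min / 1440.0
        rows.append(
            {
                "date": day_origin + timedelta(days=int(d)),
                "total_l_d": total_l,
                "total_g_d": total_l / L_PER_G_CH4,
                "n_points": n_points,
                "n_filled": n_filled,
                "coverage": coverage,
                "valid": coverage >= coverage_threshold,
            }
        )
    return pd.DataFrame(rows)


def compute_emissions(
    stream: pd.DataFrame,
    chamber: str = "RC1",
    cycle: SamplingCycle | None = None,
    recovery_rate: float = 1.0,
    events: Sequence[EventInterval] = (),
    fill_k: int = 4,
    day_origin: datetime | None = None,
    coverage_threshold: float = 0.9,
    event_pad_min: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full chain: demultiplex -> correct -> gap-fill -> daily totals.

    ``event_pad_min`` extends each event's end before gap filling, to also
    discard the chamber's re-equilibration tail after a door closes (the
    concentration needs ~3 time constants to recover; 0 fills only the
    registered interval).  Returns ``(points, daily)`` DataFrames.
    """
    cycle = cycle or SamplingCycle()
    points = chamber_emission_points(
        stream, chamber=chamber, cycle=cycle, recovery_rate=recovery_rate
    )
    if event_pad_min:
        pad = timedelta(minutes=event_pad_min)
        events = [EventInterval(ev.start, ev.end + pad, ev.kind) for ev in events]
    points = fill_gaps(points, list(events), k=fill_k)
    daily = daily_total(
        points,
        day_origin=day_origin,
        cycle_length_min=cycle.cycle_length_min,
        coverage_threshold=coverage_threshold,
    )
    return points, daily


def plot_emission_series(points: pd.DataFrame, ax=None):
    """Plot an emission series, marking gap-filled points.  Needs matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    meas = points[~points["filled"]]
    fill = points[points["filled"]]
    ax.plot(meas["timestamp"], meas["emission_lpm"], ".", ms=3, label="measured")
    if len(fill):
        ax.plot(fill["timestamp"], fill["emission_lpm"], "x", ms=4,
                color="tab:red", label="gap-filled")
    ax.set_ylabel("CH$_4$ (L/min)")
    ax.legend(frameon=False)
    return ax
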