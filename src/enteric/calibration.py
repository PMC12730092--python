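"""Gas-analyzer calibration and chamber recovery-rate estimation.

The analyzer is calibrated manually at the start and end of each
measurement period: ultrapure N2 sets the zero, and a certified span gas
(CH4 0-800 ppm, CO2 0-5000 ppm, O2 0-21 %) sets the gain.  Drift detected
at the period end is back-corrected by interpolating the two affine
corrections linearly in time over the stream.

Chamber recovery is measured by injecting pure CO2 at a known rate
(rotameter, e.g. 2 L/min) until the computed emission plateaus; the
recovery rate is the plateau-mean measured emission as a percentage of
the injected rate, and divides all subsequent emission estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

from . import chamber_flux

GAS_COLUMN = {"CH4": "ch4_ppm", "CO2": "co2_ppm", "O2": "o2_pct"}

#: certified span ranges per gas (upper bound of the calibration range)
SPAN_RANGES = {"CH4": 800.0, "CO2": 5000.0, "O2": 21.0}


@dataclass(frozen=True)
class CalibrationRecord:
    """One manual two-point calibration of a single gas sensor."""

    time: datetime
    gas: str
    zero_reading: float
    span_certified: float
    span_reading: float

    def __post_init__(self):
        if self.gas not in GAS_COLUMN:
            raise ValueError(f"unknown gas {self.gas!r}")
        if self.span_certified <= 0:
            raise ValueError("certified span concentration must be positive")
        if self.span_certified > SPAN_RANGES[self.gas]:
            raise ValueError(
                f"span {self.span_certified} outside the {self.gas} "
                f"calibration range 0-{SPAN_RANGES[self.gas]}"
            )


@dataclass(frozen=True)
class AffineCorrection:
    """reading -> gain * reading + offset"""

    gain: float
    offset: float

    def apply(self, reading):
        return self.gain * np.asarray(reading, dtype=float) + self.offset


def fit_two_point(cal: CalibrationRecord) -> AffineCorrection:
    """Affine correction mapping (zero_reading, span_reading) -> (0, certified)."""
    denom = cal.span_reading - cal.zero_reading
    if denom == 0:
        raise ValueError("degenerate calibration: span and zero readings equal")
    gain = cal.span_certified / denom
    return AffineCorrection(gain=gain, offset=-gain * cal.zero_reading)


def drift_correct(
    stream: pd.DataFrame,
    cal_start: CalibrationRecord,
    cal_end: CalibrationRecord | None = None,
) -> pd.DataFrame:
    """Back-correct analyzer drift over a period.

    The affine correction is interpolated linearly in time between the
    period-start and period-end calibrations and applied to the gas's
    concentration column.  With a missing end calibration the start
    correction is applied uniformly (flagged with a warning), as it is when
    both calibrations coincide.
    """
    if cal_end is not None and cal_end.gas != cal_start.gas:
        raise ValueError("start and end calibrations are for different gases")
    col = GAS_COLUMN[cal_start.gas]
    if col not in stream.columns:
        raise ValueError(f"stream lacks column {col!r}")
    out = stream.copy()
    t = pd.to_datetime(out["timestamp"])
    c0 = fit_two_point(cal_start)

    if cal_end is None:
        warnings.warn(
            "missing end calibration: start correction applied uniformly",
            stacklevel=2,
        )
        out[col] = c0.apply(out[col])
        return out

    if (cal_start.time > t.iloc[0]) or (cal_end.time < t.iloc[-1]):
        raise ValueError("stream extends outside the calibration interval")
    c1 = fit_two_point(cal_end)
    span_s = (cal_end.time - cal_start.time).total_seconds()
    if span_s == 0:
        out[col] = c0.apply(out[col])
        return out
    w = (t - cal_start.time).dt.total_seconds().to_numpy() / span_s
    gain = (1 - w) * c0.gain + w * c1.gain
    offset = (1 - w) * c0.offset + w * c1.offset
    out[col] = gain * out[col].to_numpy(dtype=float) + offset
    return out


@dataclass(frozen=True)
class RecoveryTest:
    """Result of one CO2 injection recovery test."""

    injected_lpm: float
    plateau_mean_lpm: float
    recovery_pct: float
    plateau_start: datetime
    n_plateau_points: int


def recovery_rate(
    times,
    measured_lpm,
    injected_lpm: float,
    window_min: float = 15.0,
    tolerance: float = 0.01,
) -> RecoveryTest:
    """Estimate chamber recovery from a measured CO2 emission series.

    The plateau is the longest suffix of the series over which the rolling
    mean (window ``window_min``) stays within ``tolerance`` (relative) of
    its final value; the recovery is 100 * mean(measured)/injected on that
    suffix only.
    """
    if injected_lpm <= 0:
        raise ValueError("injected rate must be positive")
    times = pd.to_datetime(pd.Index(times))
    y = np.asarray(measured_lpm, dtype=float)
    if len(y) < 3:
        raise ValueError("series too short for plateau detection")
    step_s = np.median(np.diff(times.view("int64"))) / 1e9
    win = max(2, int(round(window_min * 60.0 / step_s)))
    if win >= len(y):
        raise ValueError(
            "no plateau found: series shorter than the rolling window; "
            "run the test longer"
        )
    roll = pd.Series(y).rolling(win, min_periods=win).mean().to_numpy()
    final = roll[-1]
    if not np.isfinite(final) or final == 0:
        raise ValueError("no plateau found: run the test longer")
    ok = np.abs(roll - final) / abs(final) < tolerance
    # longest suffix of valid rolling means
    bad = np.flatnonzero(~ok[win - 1:])
    first = (win - 1) + (bad[-1] + 1 if bad.size else 0)
    if first >= len(y):
        raise ValueError("no plateau found: run the test longer")
    # the rolling mean at index i covers readings i-win+1..i
    plateau_lo = max(0, first - win + 1)
    if len(y) - plateau_lo < win + 1:
        raise ValueError(
            "no plateau found: stability never held for a full window; "
            "run the test longer"
        )
    mean_lpm = float(y[plateau_lo:].mean())
    return RecoveryTest(
        injected_lpm=injected_lpm,
        plateau_mean_lpm=mean_lpm,
        recovery_pct=100.0 * mean_lpm / injected_lpm,
        plateau_start=times[plateau_lo].to_pydatetime(),
        n_plateau_points=len(y) - plateau_lo,
    )


def recovery_from_stream(
    stream: pd.DataFrame,
    injected_lpm: float,
    chamber: str = "RC1",
    cycle: chamber_flux.SamplingCycle | None = None,
    window_min: float = 15.0,
    tolerance: float = 0.01,
) -> RecoveryTest:
    """Recovery test straight from a raw sensor stream.

    Computes the CO2 emission series through the same wet/STP correction
    chain used for methane (recovery 1), then detects the plateau.
    """
    points = chamber_flux.chamber_emission_points(
        stream, chamber=chamber, cycle=cycle, recovery_rate=1.0, gas="co2"
    )
    return recovery_rate(
        points["timestamp"], points["emission_lpm"], injected_lpm,
        window_min=window_min, tolerance=tolerance,
    )


def mean_recovery(tests) -> float:
    """Scalar recovery fraction from a list of RecoveryTest (per-chamber mean)."""
    tests = list(tests)
    if not tests:
        raise ValueError("no recovery tests supplied")
    return float(np.mean([t.recovery_pct for t in tests])) / 100.0
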