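"""Synthetic chamber sensor streams and animal nutrition records.

The generator emulates the measurement setup behind the analysis modules:
two 23 m3 open-circuit respiration chambers ventilated at 140 m3/h, a gas
switching device cycling RC1 -> RC2 -> fresh air on a 6-min cycle (2 min
per source), twice-daily 30-min door openings, period start/end analyzer
calibrations with linear gain drift, and CO2 injection recovery tests.

The chamber is modeled as a single well-mixed compartment (the air-change
rate is ~6 volumes/h and an internal fan stirs the air).  In dry-STP
mixing-ratio space the mass balance is

    V_stp * dX/dt = E_stp(t) + Q_stp(t) * (X_bg - X)

with X the CH4 mixing ratio, E_stp the animal's emission as dry-STP L/min
and Q_stp the dry-STP ventilation rate — the same quantity (DSTPVR) the
flux pipeline reconstructs from the wet flow-meter reading.  Integration
uses the exact exponential update on a 1 s grid (the chamber time constant
is ~10 min, so the piecewise-constant-forcing error is negligible).

Ground truth (exact daily emission integrals, noise-free concentrations,
true balance partitions) is returned separately and never consumed by the
analysis path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from . import chamber_flux, nutrient_balance
from .chamber_flux import EventInterval, L_PER_G_CH4, SamplingCycle

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueEmissionProfile:
    """Ground-truth instantaneous methane emission of one animal.

    The deterministic part is a diurnal sinusoid around ``baseline_g_per_day``
    plus boxcar post-meal peaks; ``noise_sd`` adds multiplicative Gaussian
    fluctuation (fraction of the instantaneous rate), truncated at zero.
    """

    baseline_g_per_day: float = 454.0
    diurnal_amplitude: float = 0.1
    meal_peaks: tuple[tuple[float, float, float], ...] = (
        (8.5, 0.25, 120.0),
        (16.5, 0.25, 120.0),
    )  # (hour of day, extra fraction of baseline, duration min)
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.baseline_g_per_day < 0:
            raise ValueError("baseline emission must be non-negative")
        if not 0 <= self.diurnal_amplitude <= 1:
            raise ValueError("diurnal amplitude must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def rate_g_per_day(self, hours_of_day: np.ndarray) -> np.ndarray:
        """Deterministic emission rate (g/d units) at given times of day."""
        h = np.asarray(hours_of_day, dtype=float) % 24.0
        rate = self.baseline_g_per_day * (
            1.0 + self.diurnal_amplitude * np.sin(2 * np.pi * (h - 6.0) / 24.0)
        )
        for start_h, extra, dur_min in self.meal_peaks:
            in_peak = ((h - start_h) % 24.0) < dur_min / 60.0
            rate = rate + in_peak * extra * self.baseline_g_per_day
        return np.maximum(rate, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Physical and instrumental configuration of a chamber run."""

    seed: int = 0
    chamber_volume_m3: float = 23.0
    wet_vr_lpm: float = 140_000.0 / 60.0  # 140 m3/h
    temp_c: float = 16.5
    rh_pct: float = 70.0
    pressure_hpa: float = 1013.25
    recovery_rate_true: float = 1.0
    analyzer_noise_sd_ppm: float = 0.5
    analyzer_drift_per_day: float = 0.005  # fractional gain change per day
    sampling_cycle: SamplingCycle = field(default_factory=SamplingCycle)
    record_interval_s: float = 20.0
    door_events: tuple[EventInterval, ...] = ()
    door_vent_multiplier: float = 20.0
    background_ch4_ppm: float = 2.0
    background_co2_ppm: float = 420.0
    o2_pct: float = 20.6
    co2_production_l_min: float = 4.2  # occupied-chamber CO2 source
    duration_h: float = 24.0
    start_time: datetime = datetime(2025, 6, 1, 9, 0, 0)
    initial_state: str = "steady"  # or "background"

    def __post_init__(self):
        if self.chamber_volume_m3 <= 0:
            raise ValueError("chamber volume must be positive")
        if self.wet_vr_lpm <= 0:
            raise ValueError("ventilation rate must be positive")
        if not 0.5 < self.recovery_rate_true < 1.5:
            raise ValueError("recovery_rate_true must be in (0.5, 1.5)")
        if not -5.0 <= self.temp_c <= 45.0:
            raise ValueError("temperature outside physical range [-5, 45] degC")
        if not 0.0 <= self.rh_pct <= 100.0:
            raise ValueError("humidity must be in [0, 100] %")
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        if self.initial_state not in ("steady", "background"):
            raise ValueError("initial_state must be 'steady' or 'background'")


@dataclass
class GroundTruth:
    """What the generator actually did, for verification only."""

    daily_emissions: pd.DataFrame | None = None  # chamber, date, true_g_per_day
    sensor_truth: pd.DataFrame | None = None  # noise/drift-free concentrations
    balance: pd.DataFrame | None = None  # per cow-day true partitions
    records: pd.DataFrame | None = None  # noise-free animal records


# ---------------------------------------------------------------------------
# chamber dynamics
# ---------------------------------------------------------------------------

def _chamber_trace(
    emission_lpm_stp: np.ndarray,
    q_stp_lpm: np.ndarray,
    v_stp_l: float,
    background_ppm: float,
    initial_state: str,
) -> np.ndarray:
    """Integrate the well-mixed mass balance on a 1 s grid.

    Exact exponential update x[i] = ss[i] + (x[i-1] - ss[i]) * exp(-Q dt/V)
    for piecewise-constant forcing, run as a first-order recursive filter
    over each segment of constant ventilation.
    """
    from scipy import signal

    n = emission_lpm_stp.shape[0]
    x_ss = background_ppm + emission_lpm_stp * 1e6 / q_stp_lpm
    a = np.exp(-q_stp_lpm / 60.0 / v_stp_l)  # decay over 1 s
    x = np.empty(n)
    prev = x_ss[0] if initial_state == "steady" else background_ppm
    bounds = np.concatenate([[0], np.flatnonzero(np.diff(a) != 0) + 1, [n]])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        ac = a[lo]
        zi = signal.lfiltic([1 - ac], [1.0, -ac], y=[prev])
        seg, _ = signal.lfilter([1 - ac], [1.0, -ac], x_ss[lo:hi], zi=zi)
        x[lo:hi] = seg
        prev = seg[-1]
    return x


def _door_mask(config: SimulationConfig, n: int) -> np.ndarray:
    t0 = np.datetime64(config.start_time)
    sec = np.arange(n)
    mask = np.zeros(n, dtype=bool)
    for ev in config.door_events:
        lo = (np.datetime64(ev.start) - t0) / np.timedelta64(1, "s")
        hi = (np.datetime64(ev.end) - t0) / np.timedelta64(1, "s")
        mask |= (sec >= lo) & (sec < hi)
    return mask


def _stp_quantities(config: SimulationConfig):
    """Dry-STP ventilation (L/min) and dry-STP chamber volume (L)."""
    q_stp = chamber_flux.stp_ventilation_from_wet(
        config.wet_vr_lpm, config.temp_c, config.rh_pct, config.pressure_hpa
    )
    pwp = chamber_flux.partial_water_pressure(config.temp_c, config.rh_pct)
    v_stp = (
        config.chamber_volume_m3
        * 1000.0
        * ((config.pressure_hpa - pwp) / chamber_flux.STANDARD_PRESSURE_HPA)
        * (chamber_flux.KELVIN_0C / (config.temp_c + chamber_flux.KELVIN_0C))
    )
    return float(q_stp), float(v_stp)


def simulate_chamber_run(
    profile: TrueEmissionProfile | dict[str, TrueEmissionProfile],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a multi-source analyzer stream for one chamber run.

    ``profile`` may be a single emission profile (animal in RC1, RC2 empty)
    or a dict keyed by chamber name.  Returns ``(stream, event_log,
    ground_truth)``; the stream is the delimited-text sensor schema, the
    event log has columns start/end/kind.
    """
    if config.duration_h < 24.0:
        raise ValueError("simulation horizon must be at least 1 day")
    profiles = profile if isinstance(profile, dict) else {"RC1": profile}
    for name in profiles:
        if name not in ("RC1", "RC2"):
            raise ValueError(f"unknown chamber {name!r}")
    rng = np.random.default_rng(config.seed)

    n = int(round(config.duration_h * 3600))
    sec = np.arange(n)
    hours = (
        config.start_time.hour
        + config.start_time.minute / 60.0
        + config.start_time.second / 3600.0
        + sec / 3600.0
    )
    q_stp, v_stp = _stp_quantities(config)
    doors = _door_mask(config, n)
    q = np.where(doors, q_stp * config.door_vent_multiplier, q_stp)

    chambers = ("RC1", "RC2")
    ch4_true: dict[str, np.ndarray] = {}
    co2_true: dict[str, np.ndarray] = {}
    daily_rows = []
    for cham in chambers:
        prof = profiles.get(cham)
        if prof is None:
            e_g_d = np.zeros(n)
        else:
            e_g_d = prof.rate_g_per_day(hours)
            if prof.noise_sd > 0:
                e_g_d = np.maximum(
                    e_g_d * (1.0 + prof.noise_sd * rng.standard_normal(n)), 0.0
                )
        e_lpm = e_g_d * L_PER_G_CH4 / 1440.0
        ch4_true[cham] = _chamber_trace(
            e_lpm, q, v_stp, config.background_ch4_ppm, config.initial_state
        )
        co2_src = config.co2_production_l_min if prof is not None else 0.0
        co2_true[cham] = _chamber_trace(
            np.full(n, co2_src), q, v_stp, config.background_co2_ppm,
            config.initial_state,
        )
        # exact daily integral of the realized E(t) (piecewise constant, 1 s)
        for d in range(int(config.duration_h // 24)):
            day = e_g_d[d * 86400 : (d + 1) * 86400]
            daily_rows.append(
                {
                    "chamber": cham,
                    "date": config.start_time + timedelta(days=d),
                    "true_g_per_day": float(day.mean()),
                }
            )

    # analyzer view: recovery scales the above-background signal,
    # gain drifts linearly in time, noise is additive on ppm
    rec_idx = (np.arange(int(n / config.record_interval_s)) *
               config.record_interval_s).astype(int)
    t_rec = np.array(
        [config.start_time + timedelta(seconds=int(s)) for s in rec_idx]
    )
    gain = 1.0 + config.analyzer_drift_per_day * (rec_idx / 86400.0)

    cyc = config.sampling_cycle
    slot_s = cyc.slot_length_min * 60.0
    slot_of_rec = (rec_idx // slot_s).astype(int) % len(cyc.source_order)
    source = np.array([cyc.source_order[i] for i in slot_of_rec])

    def observed(truth_ppm, background):
        return background + config.recovery_rate_true * (truth_ppm - background)

    ch4 = np.full(rec_idx.shape, float(config.background_ch4_ppm))
    co2 = np.full(rec_idx.shape, float(config.background_co2_ppm))
    for cham in chambers:
        m = source == cham
        ch4[m] = observed(ch4_true[cham][rec_idx[m]], config.background_ch4_ppm)
        co2[m] = observed(co2_true[cham][rec_idx[m]], config.background_co2_ppm)
    ch4 = gain * ch4
    co2 = gain * co2
    if config.analyzer_noise_sd_ppm > 0:
        ch4 = ch4 + config.analyzer_noise_sd_ppm * rng.standard_normal(len(ch4))
        co2 = co2 + config.analyzer_noise_sd_ppm * rng.standard_normal(len(co2))

    stream = pd.DataFrame(
        {
            "timestamp": t_rec,
            "source": source,
            "ch4_ppm": ch4,
            "co2_ppm": co2,
            "o2_pct": config.o2_pct,
            "temp_c": config.temp_c,
            "rh_pct": config.rh_pct,
            "pressure_hpa": config.pressure_hpa,
            "wet_vr_lpm": config.wet_vr_lpm,
        }
    )
    event_log = pd.DataFrame(
        [
            {"start": ev.start, "end": ev.end, "kind": ev.kind}
            for ev in config.door_events
        ],
        columns=["start", "end", "kind"],
    )
    truth = GroundTruth(
        daily_emissions=pd.DataFrame(daily_rows),
        sensor_truth=pd.DataFrame(
            {
                "timestamp": t_rec,
                "rc1_ch4_ppm": ch4_true["RC1"][rec_idx],
                "rc2_ch4_ppm": ch4_true["RC2"][rec_idx],
            }
        ),
    )
    return stream, event_log, truth


def simulate_recovery_test(
    config: SimulationConfig,
    injected_lpm: float = 2.0,
    duration_min: float = 240.0,
    chamber: str = "RC1",
) -> pd.DataFrame:
    """CO2 injection recovery test: rise from background to plateau.

    Pure CO2 is injected at ``injected_lpm`` (dry-STP L/min) into an empty
    chamber starting at background.  The analyzer reports the injection
    scaled by ``recovery_rate_true``.  A test shorter than three chamber
    time constants cannot plateau; the returned stream is then flagged via
    ``stream.attrs['too_short']`` and a warning.
    """
    if injected_lpm <= 0:
        raise ValueError("injected rate must be positive")
    rng = np.random.default_rng(config.seed)
    n = int(round(duration_min * 60))
    q_stp, v_stp = _stp_quantities(config)
    tau_min = v_stp / q_stp
    too_short = duration_min < 3 * tau_min
    if too_short:
        warnings.warn(
            f"test of {duration_min:.0f} min is under 3 chamber time "
            f"constants ({3 * tau_min:.0f} min); no plateau expected",
            stacklevel=2,
        )

    q = np.full(n, q_stp)
    co2_true = _chamber_trace(
        np.full(n, injected_lpm), q, v_stp, config.background_co2_ppm,
        "background",
    )
    rec_idx = (np.arange(int(n / config.record_interval_s)) *
               config.record_interval_s).astype(int)
    t_rec = np.array(
        [config.start_time + timedelta(seconds=int(s)) for s in rec_idx]
    )
    cyc = config.sampling_cycle
    slot_s = cyc.slot_length_min * 60.0
    slot_of_rec = (rec_idx // slot_s).astype(int) % len(cyc.source_order)
    source = np.array([cyc.source_order[i] for i in slot_of_rec])

    co2 = np.full(rec_idx.shape, float(config.background_co2_ppm))
    m = source == chamber
    co2[m] = config.background_co2_ppm + config.recovery_rate_true * (
        co2_true[rec_idx[m]] - config.background_co2_ppm
    )
    if config.analyzer_noise_sd_ppm > 0:
        co2 = co2 + config.analyzer_noise_sd_ppm * rng.standard_normal(len(co2))

    stream = pd.DataFrame(
        {
            "timestamp": t_rec,
            "source": source,
            "ch4_ppm": config.background_ch4_ppm,
            "co2_ppm": co2,
            "o2_pct": config.o2_pct,
            "temp_c": config.temp_c,
            "rh_pct": config.rh_pct,
            "pressure_hpa": config.pressure_hpa,
            "wet_vr_lpm": config.wet_vr_lpm,
        }
    )
    stream.attrs["too_short"] = bool(too_short)
    return stream


# ---------------------------------------------------------------------------
# animal nutrition records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnimalSimParams:
    """Uniform sampling ranges for per-cow true quantities.

    Defaults follow a high-producing lactating Holstein on a corn-silage
    TMR: ~26-28 kg DM/d intake at 20.4 % CP, ~40 kg/d milk, 555-600 kg BW.
    """

    dmi_kg_d: tuple[float, float] = (26.0, 28.0)
    cp_frac: tuple[float, float] = (0.200, 0.208)
    om_frac: tuple[float, float] = (0.935, 0.945)
    ndf_frac: tuple[float, float] = (0.30, 0.31)
    adf_frac: tuple[float, float] = (0.21, 0.23)
    adl_frac: tuple[float, float] = (0.012, 0.014)
    starch_frac: tuple[float, float] = (0.22, 0.23)
    ee_frac: tuple[float, float] = (0.024, 0.027)
    ndfi_frac: tuple[float, float] = (0.085, 0.094)
    ge_mj_kg: tuple[float, float] = (16.2, 16.6)
    dm_digestibility: tuple[float, float] = (0.63, 0.68)
    ndf_digestibility: tuple[float, float] = (0.30, 0.38)
    ge_digestibility: tuple[float, float] = (0.58, 0.64)
    milk_kg_d: tuple[float, float] = (36.0, 43.0)
    fat_pct: tuple[float, float] = (3.2, 3.6)
    protein_pct: tuple[float, float] = (3.2, 3.5)
    lactose_pct: tuple[float, float] = (5.0, 5.2)
    bw_kg: tuple[float, float] = (540.0, 610.0)
    fecal_n_pct: tuple[float, float] = (2.5, 3.1)
    urine_creatinine_mg_l: tuple[float, float] = (550.0, 850.0)
    urine_n_g_l: tuple[float, float] = (13.0, 18.0)
    ch4_g_per_kg_dmi: tuple[float, float] = (15.5, 18.5)
    noise: float = 0.02  # multiplicative measurement noise (SD fraction)


#: observed record fields that carry measurement noise
_NOISY_FIELDS = (
    "dmi_kg_d", "milk_kg_d", "fat_kg_d", "protein_kg_d", "lactose_kg_d",
    "milk_n_g_d", "fecal_marker_ndfi_g_kg", "fecal_marker_ndf_g_kg",
    "fecal_marker_ge_mj_kg", "fecal_n_pct", "urine_creatinine_mg_l",
    "urine_n_g_l", "bw_kg", "ch4_g_d",
)


def simulate_animal_days(
    n_cows: int,
    n_days: int,
    seed: int = 0,
    params: AnimalSimParams | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate per-cow per-day nutrition records with known ground truth.

    True quantities are drawn per cow (day-to-day wobble is small), made
    internally consistent (fecal output from true digestibility; marker
    concentrations back-derived so an inert-marker calculation recovers
    fecal output), and the true balance partitions are obtained by running
    the balance calculations on the noise-free records.  Observed records
    equal truth plus multiplicative measurement noise; draws yielding a
    negative mass are resampled (logged).
    """
    if n_cows < 1 or n_days < 1:
        raise ValueError("n_cows and n_days must be >= 1")
    p = params or AnimalSimParams()
    rng = np.random.default_rng(seed)

    def draw(rg, size):
        return rng.uniform(rg[0], rg[1], size=size)

    rows = []
    for cow in range(n_cows):
        base = {name: float(draw(getattr(p, name), 1)[0])
                for name in (
                    "dmi_kg_d", "cp_frac", "om_frac", "ndf_frac", "adf_frac",
                    "adl_frac", "starch_frac", "ee_frac", "ndfi_frac",
                    "ge_mj_kg", "dm_digestibility", "ndf_digestibility",
                    "ge_digestibility", "milk_kg_d", "fat_pct", "protein_pct",
                    "lactose_pct", "bw_kg", "fecal_n_pct",
                    "urine_creatinine_mg_l", "urine_n_g_l",
                    "ch4_g_per_kg_dmi",
                )}
        bcs = float(rng.choice(np.arange(2.75, 3.76, 0.25)))
        for day in range(n_days):
            wobble = 1.0 + 0.01 * rng.standard_normal()
            dmi = base["dmi_kg_d"] * wobble
            gei = dmi * base["ge_mj_kg"]
            fecal_dm = dmi * (1.0 - base["dm_digestibility"])
            milk = base["milk_kg_d"] * (1.0 + 0.01 * rng.standard_normal())
            fat = milk * base["fat_pct"] / 100.0
            protein = milk * base["protein_pct"] / 100.0
            lactose = milk * base["lactose_pct"] / 100.0
            rows.append(
                {
                    "cow_id": f"cow{cow + 1:02d}",
                    "day": day + 1,
                    "treatment": "CG" if cow % 2 == 0 else "SH",
                    "dmi_kg_d": dmi,
                    "om_frac": base["om_frac"],
                    "cp_frac": base["cp_frac"],
                    "ndf_frac": base["ndf_frac"],
                    "adf_frac": base["adf_frac"],
                    "adl_frac": base["adl_frac"],
                    "starch_frac": base["starch_frac"],
                    "ee_frac": base["ee_frac"],
                    "ndfi_frac": base["ndfi_frac"],
                    "ge_mj_kg": base["ge_mj_kg"],
                    "milk_kg_d": milk,
                    "fat_kg_d": fat,
                    "protein_kg_d": protein,
                    "lactose_kg_d": lactose,
                    "milk_n_g_d": protein * 1000.0 / 6.38,
                    # marker concentrations consistent with true digestibility
                    "fecal_marker_ndfi_g_kg": dmi * base["ndfi_frac"] * 1000.0
                    / fecal_dm,
                    "fecal_marker_ndf_g_kg": dmi * base["ndf_frac"]
                    * (1.0 - base["ndf_digestibility"]) * 1000.0 / fecal_dm,
                    "fecal_marker_ge_mj_kg": gei
                    * (1.0 - base["ge_digestibility"]) / fecal_dm,
                    "fecal_n_pct": base["fecal_n_pct"],
                    "urine_creatinine_mg_l": base["urine_creatinine_mg_l"],
                    "urine_n_g_l": base["urine_n_g_l"],
                    "bw_kg": base["bw_kg"],
                    "bcs": bcs,
                    "ch4_g_d": dmi * base["ch4_g_per_kg_dmi"],
                }
            )
    truth_records = pd.DataFrame(rows)
    truth_balance = nutrient_balance.balance_table(truth_records, marker="ndfi")

    observed = truth_records.copy()
    if p.noise > 0:
        n_resampled = 0
        for col in _NOISY_FIELDS:
            vals = observed[col].to_numpy(dtype=float)
            noisy = vals * (1.0 + p.noise * rng.standard_normal(len(vals)))
            neg = noisy <= 0
            while neg.any():
                n_resampled += int(neg.sum())
                noisy[neg] = vals[neg] * (
                    1.0 + p.noise * rng.standard_normal(int(neg.sum()))
                )
                neg = noisy <= 0
            observed[col] = noisy
        if n_resampled:
            logger.info("resampled %d negative noisy values", n_resampled)

    truth = GroundTruth(balance=truth_balance, records=truth_records)
    return observed, truth
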