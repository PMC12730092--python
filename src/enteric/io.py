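"""Delimited-text I/O, run configuration, and the end-to-end pipeline.

All files are UTF-8 comma-separated text with ISO-8601 timestamps.  Output
tables carry the run's config hash and seed as leading ``#`` comment lines
so any result can be traced to the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration, chamber_flux, nutrient_balance
from .chamber_flux import EventInterval, SamplingCycle

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sensor stream
# ---------------------------------------------------------------------------

def read_sensor_stream(path) -> pd.DataFrame:
    """Read and validate a sensor stream file.

    Rows violating physical invariants (RH outside [0,100], non-positive
    pressure, negative flow, unknown source) are rejected and logged with
    their line numbers.  Raises on missing columns or non-increasing
    timestamps among the retained rows.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in chamber_flux.SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])

    bad = (
        ~df["rh_pct"].between(0, 100)
        | (df["pressure_hpa"] <= 0)
        | (df["wet_vr_lpm"] < 0)
        | ~df["source"].isin(chamber_flux.VALID_SOURCES)
        | df[["ch4_ppm", "co2_ppm", "o2_pct", "temp_c"]].isna().any(axis=1)
    )
    if bad.any():
        for i in df.index[bad]:
            logger.warning("%s: rejected malformed row at line %d", path, i + 2)
        df = df.loc[~bad].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"{path}: no valid rows")
    if not df["timestamp"].is_monotonic_increasing or df["timestamp"].duplicated().any():
        raise ValueError(f"{path}: timestamps not strictly increasing")
    return df


def _write_table(df: pd.DataFrame, path, meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, date_format="%Y-%m-%dT%H:%M:%S")
    return path


def write_sensor_stream(df: pd.DataFrame, path, meta: dict | None = None) -> Path:
    return _write_table(df, path, meta)


def read_events(path) -> list[EventInterval]:
    df = pd.read_csv(path, comment="#")
    if df.empty:
        return []
    return [
        EventInterval(
            pd.Timestamp(r["start"]).to_pydatetime(),
            pd.Timestamp(r["end"]).to_pydatetime(),
            str(r.get("kind", "door")),
        )
        for _, r in df.iterrows()
    ]


def write_events(events, path, meta: dict | None = None) -> Path:
    df = pd.DataFrame(
        [{"start": e.start, "end": e.end, "kind": e.kind} for e in events],
        columns=["start", "end", "kind"],
    )
    return _write_table(df, path, meta)


def read_calibrations(path) -> dict[str, dict[str, calibration.CalibrationRecord]]:
    """Calibration file -> {gas: {"start": record, "end": record}}."""
    df = pd.read_csv(path, comment="#")
    out: dict[str, dict[str, calibration.CalibrationRecord]] = {}
    for _, r in df.iterrows():
        rec = calibration.CalibrationRecord(
            time=pd.Timestamp(r["time"]).to_pydatetime(),
            gas=str(r["gas"]),
            zero_reading=float(r["zero_reading"]),
            span_certified=float(r["span_certified"]),
            span_reading=float(r["span_reading"]),
        )
        out.setdefault(rec.gas, {})[str(r["position"])] = rec
    return out


def read_animal_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"cow_id", "dmi_kg_d", "cp_frac", "ge_mj_kg", "milk_kg_d",
                "fat_kg_d", "protein_kg_d", "lactose_kg_d", "milk_n_g_d",
                "fecal_n_pct", "urine_creatinine_mg_l", "urine_n_g_l",
                "bw_kg", "ch4_g_d"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything the flux+balance pipeline needs for one run."""

    output_dir: str = "out"
    stream_path: str | None = None
    events_path: str | None = None
    calibration_path: str | None = None
    animal_path: str | None = None
    seed: int = 0
    chambers: tuple[str, ...] = ("RC1", "RC2")
    recovery_rates: dict = field(default_factory=lambda: {"RC1": 1.0, "RC2": 1.0})
    cycle_length_min: float = 6.0
    slot_length_min: float = 2.0
    purge_fraction: float = 0.5
    fill_k: int = 4
    coverage_threshold: float = 0.9
    event_pad_min: float = 0.0
    marker: str = "ndfi"
    me_mode: str = "standard"

    def __post_init__(self):
        if self.fill_k < 1 or self.coverage_threshold <= 0:
            raise ValueError("thresholds must be positive")
        for v in self.recovery_rates.values():
            if v <= 0:
                raise ValueError("recovery rates must be positive")

    @property
    def cycle(self) -> SamplingCycle:
        return SamplingCycle(
            cycle_length_min=self.cycle_length_min,
            slot_length_min=self.slot_length_min,
            purge_fraction=self.purge_fraction,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "chambers" in raw:
            raw["chambers"] = tuple(raw["chambers"])
        return cls(**raw)

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("output_dir")  # where results land does not change them
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """simulate-independent analysis chain: calibrate -> flux -> balance -> report.

    Reads the configured input files, applies analyzer drift correction when
    calibrations are supplied, computes per-chamber emission series and
    daily totals, runs the nutrient/energy balance on animal records, and
    writes all outputs plus a run log enumerating every correction applied.
    Returns a bundle dict with the in-memory tables and output paths.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_sha256": config.hash(), "seed": config.seed}
    run_log: dict = {"config_sha256": config.hash(), "seed": config.seed,
                     "stages": [], "corrections": []}
    bundle: dict = {"paths": {}, "run_log": run_log}

    def stage(name):
        run_log["stages"].append(name)

    try:
        events: list[EventInterval] = []
        if config.events_path:
            stage("read_events")
            events = read_events(config.events_path)

        if config.stream_path:
            stage("read_stream")
            stream = read_sensor_stream(config.stream_path)

            if config.calibration_path:
                stage("calibrate")
                cals = read_calibrations(config.calibration_path)
                for gas, recs in cals.items():
                    start, end = recs.get("start"), recs.get("end")
                    if start is None:
                        raise ValueError(f"no start calibration for {gas}")
                    stream = calibration.drift_correct(stream, start, end)
                    run_log["corrections"].append(
                        {"type": "drift_correction", "gas": gas,
                         "end_calibration": end is not None}
                    )

            stage("flux")
            daily_all = []
            for cham in config.chambers:
                if cham not in set(stream["source"]):
                    continue
                rec = float(config.recovery_rates.get(cham, 1.0))
                points, daily = chamber_flux.compute_emissions(
                    stream,
                    chamber=cham,
                    cycle=config.cycle,
                    recovery_rate=rec,
                    events=events,
                    fill_k=config.fill_k,
                    coverage_threshold=config.coverage_threshold,
                    event_pad_min=config.event_pad_min,
                )
                run_log["corrections"].append(
                    {"type": "recovery", "chamber": cham, "rate": rec}
                )
                for ev in events:
                    n_in = int(((points["timestamp"] >= ev.start)
                                & (points["timestamp"] < ev.end)).sum())
                    if n_in:
                        run_log["corrections"].append(
                            {"type": "gap_fill", "chamber": cham,
                             "event_kind": ev.kind,
                             "start": str(ev.start), "end": str(ev.end),
                             "n_points": n_in}
                        )
                daily = daily.assign(chamber=cham)
                daily_all.append(daily)
                p = _write_table(points, outdir / f"emission_points_{cham}.csv", meta)
                bundle["paths"][f"points_{cham}"] = p
            if daily_all:
                daily_df = pd.concat(daily_all, ignore_index=True)[
                    ["date", "chamber", "total_l_d", "total_g_d",
                     "n_points", "n_filled", "coverage", "valid"]
                ]
                bundle["daily"] = daily_df
                bundle["paths"]["daily"] = _write_table(
                    daily_df, outdir / "daily_emissions.csv", meta
                )

        if config.animal_path:
            stage("balance")
            records = read_animal_records(config.animal_path)
            results = nutrient_balance.balance_table(
                records, marker=config.marker, me_mode=config.me_mode
            )
            bundle["balance"] = results
            bundle["paths"]["balance"] = _write_table(
                results, outdir / "balance_results.csv", meta
            )
            stage("report")
            if "treatment" in results.columns and results["treatment"].ne("").any():
                summary = nutrient_balance.treatment_summary(results)
                bundle["summary"] = summary
                bundle["paths"]["summary"] = _write_table(
                    summary, outdir / "treatment_summary.csv", meta
                )
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {run_log['stages'][-1] if run_log['stages'] else 'init'}: {exc}"
        ) from exc

    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(run_log, indent=2, default=str))
    bundle["paths"]["run_log"] = log_path
    return bundle
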