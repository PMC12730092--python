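"""Per-cow nutrient and energy balance for lactating dairy cattle.

Computes, from one cow-period's intake/milk/fecal/urine records:

* fat-corrected and energy-corrected milk (FCM, ECM),
* internal-marker fecal output and apparent digestibility,
* the nitrogen partition (fecal, urinary, milk, retained, productive N
  and nitrogen-use efficiency NUE = milk N / intake N),
* the energy partition GE -> DE -> ME with fecal, urinary, methane and
  milk losses, energy balance EB and energy-use efficiency EUE,
* methane yield and intensity metrics (g/kg DMI, % of GE/DE intake,
  g/kg milk, FCM, ECM, fat, protein).

Descriptive per-animal arithmetic only; treatment-effect inference is out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

#: energy content of methane, MJ per g
MJ_PER_G_CH4 = 0.0556

#: urinary energy as a fraction of gross energy intake
URINE_ENERGY_FRACTION = 0.04

#: milk component energy, MJ per kg of fat, protein, lactose
E_MILK_COEFFS = (39.32, 23.84, 16.73)

#: daily creatinine excretion, mg per kg body weight
CREATININE_MG_PER_KG_BW = 29.0

#: g of milk true protein per g of milk N
MILK_PROTEIN_PER_N = 6.38

#: g of crude protein per g of feed N
CP_PER_N = 6.25


# ---------------------------------------------------------------------------
# milk standardizations
# ---------------------------------------------------------------------------

def fcm(milk_kg_d: float, fat_kg_d: float) -> float:
    """4 % fat-corrected milk: 0.4 * milk + 15 * fat (kg/d)."""
    if milk_kg_d < 0 or fat_kg_d < 0:
        raise ValueError("milk and fat yields must be non-negative")
    return 0.4 * milk_kg_d + 15.0 * fat_kg_d


def ecm(milk_kg_d: float, fat_kg_d: float, protein_kg_d: float) -> float:
    """Energy-corrected milk: 12.95*fat + 7.2*protein + 0.327*milk (kg/d)."""
    if min(milk_kg_d, fat_kg_d, protein_kg_d) < 0:
        raise ValueError("yields must be non-negative")
    return 12.95 * fat_kg_d + 7.2 * protein_kg_d + 0.327 * milk_kg_d


# ---------------------------------------------------------------------------
# digestibility
# ---------------------------------------------------------------------------

def marker_fecal_output(marker_intake, fecal_marker_conc) -> float:
    """Total fecal DM output, kg/d, from an internal marker.

    ``marker_intake`` per day (g/d or MJ/d) over the marker's fecal
    concentration (per kg fecal DM, same units).  Assumes the marker is
    fully recovered in feces (valid for indigestible NDF).
    """
    fecal_marker_conc = np.asarray(fecal_marker_conc, dtype=float)
    if np.any(fecal_marker_conc <= 0):
        raise ValueError("fecal marker concentration must be positive")
    out = np.asarray(marker_intake, dtype=float) / fecal_marker_conc
    return out if out.ndim else float(out)


def apparent_digestibility(intake, fecal_output) -> float:
    """Apparent total-tract digestibility, %: (intake - fecal)/intake * 100.

    Applied identically for DM, NDF and GE with their respective intakes
    and fecal quantities.
    """
    intake = np.asarray(intake, dtype=float)
    if np.any(intake <= 0):
        raise ValueError("intake must be positive")
    out = (intake - np.asarray(fecal_output, dtype=float)) / intake * 100.0
    return out if out.ndim else float(out)


def urine_volume(bw_kg, urine_creatinine_mg_l) -> float:
    """Daily urine volume, L/d, from spot creatinine.

    Assumes a constant creatinine excretion of 29 mg per kg body weight per
    day: volume = 29 * BW / concentration.
    """
    urine_creatinine_mg_l = np.asarray(urine_creatinine_mg_l, dtype=float)
    if np.any(urine_creatinine_mg_l <= 0):
        raise ValueError("creatinine concentration must be positive")
    out = CREATININE_MG_PER_KG_BW * np.asarray(bw_kg, dtype=float) / urine_creatinine_mg_l
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# nitrogen partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NitrogenBalanceResult:
    """Nitrogen partition for one cow-period, g/d and % of intake N."""

    intake_n: float
    fecal_n: float
    urinary_n: float
    total_excretion_n: float
    milk_n: float
    retained_n: float
    productive_n: float
    nue: float  # milk N / intake N, fraction
    fecal_n_pct_intake: float
    urinary_n_pct_intake: float
    total_excretion_pct_intake: float
    milk_n_pct_intake: float
    retained_n_pct_intake: float
    productive_n_pct_intake: float


def nitrogen_balance(
    n_intake: float, fecal_n: float, urinary_n: float, milk_n: float
) -> NitrogenBalanceResult:
    """Nitrogen partition identities.

    total excretion = fecal + urinary; retained = intake - total excretion;
    productive = retained + milk; NUE = milk N / intake N.
    """
    if min(n_intake, fecal_n, urinary_n, milk_n) < 0:
        raise ValueError("nitrogen quantities must be non-negative")
    if n_intake == 0:
        if fecal_n or urinary_n or milk_n:
            raise ValueError("zero N intake with nonzero N outputs")
        raise ValueError("N intake must be positive")
    total = fecal_n + urinary_n
    retained = n_intake - total
    productive = retained + milk_n
    pct = lambda x: 100.0 * x / n_intake
    return NitrogenBalanceResult(
        intake_n=n_intake,
        fecal_n=fecal_n,
        urinary_n=urinary_n,
        total_excretion_n=total,
        milk_n=milk_n,
        retained_n=retained,
        productive_n=productive,
        nue=milk_n / n_intake,
        fecal_n_pct_intake=pct(fecal_n),
        urinary_n_pct_intake=pct(urinary_n),
        total_excretion_pct_intake=pct(total),
        milk_n_pct_intake=pct(milk_n),
        retained_n_pct_intake=pct(retained),
        productive_n_pct_intake=pct(productive),
    )


# ---------------------------------------------------------------------------
# energy partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MilkRecord:
    """Milk yield and component yields for one cow-period, kg/d."""

    milk_kg_d: float
    fat_kg_d: float
    protein_kg_d: float
    lactose_kg_d: float
    milk_n_g_d: float = 0.0

    def __post_init__(self):
        if min(self.milk_kg_d, self.fat_kg_d, self.protein_kg_d,
               self.lactose_kg_d, self.milk_n_g_d) < 0:
            raise ValueError("milk quantities must be non-negative")
        if self.fat_kg_d + self.protein_kg_d + self.lactose_kg_d > self.milk_kg_d:
            raise ValueError("component yields exceed milk yield")


@dataclass(frozen=True)
class EnergyPartitionResult:
    """Energy partition for one cow-period, MJ/d and % of GE intake."""

    gei_mj_d: float
    e_feces: float
    de: float
    e_urine: float
    e_methane: float
    e_milk: float
    me: float
    eb: float
    eue: float  # E_milk / GEI, fraction
    e_feces_pct_gei: float
    e_urine_pct_gei: float
    e_methane_pct_gei: float
    e_milk_pct_gei: float


def milk_energy(milk: MilkRecord, coeffs=E_MILK_COEFFS) -> float:
    """Milk energy output, MJ/d, from component yields."""
    cf, cp_, cl = coeffs
    return cf * milk.fat_kg_d + cp_ * milk.protein_kg_d + cl * milk.lactose_kg_d


def energy_partition(
    gei: float,
    e_feces: float,
    ch4_g_d: float,
    milk: MilkRecord,
    bw_kg: float,
    e_milk_coeffs=E_MILK_COEFFS,
    me_mode: str = "standard",
) -> EnergyPartitionResult:
    """Partition gross energy intake into losses, milk and balance.

    DE = GEI - E_feces; E_methane = 0.0556 MJ/g * CH4; E_urine = 4 % of
    GEI; E_milk from component yields.  ME is DE - E_methane - E_urine by
    default (``me_mode="standard"``); ``me_mode="absorbed_fermented"``
    instead takes ME = E_milk + E_methane - E_urine (milk as the absorbed
    energy, methane as the fermented energy; body energy retention is not
    measured here).  EB = ME - 0.08 * BW^0.75 - E_milk; EUE = E_milk/GEI.
    """
    if gei <= 0:
        raise ValueError("gross energy intake must be positive")
    if e_feces < 0:
        raise ValueError("negative fecal energy")
    if e_feces > gei:
        raise ValueError("fecal energy exceeds gross energy intake")
    if ch4_g_d < 0:
        raise ValueError("negative methane production")
    if bw_kg <= 0:
        raise ValueError("body weight must be positive")
    de = gei - e_feces
    e_methane = MJ_PER_G_CH4 * ch4_g_d
    e_urine = URINE_ENERGY_FRACTION * gei
    e_milk = milk_energy(milk, e_milk_coeffs)
    if me_mode == "standard":
        me = de - e_methane - e_urine
    elif me_mode == "absorbed_fermented":
        me = e_milk + e_methane - e_urine
    else:
        raise ValueError(f"unknown me_mode {me_mode!r}")
    eb = me - 0.08 * bw_kg**0.75 - e_milk
    pct = lambda x: 100.0 * x / gei
    return EnergyPartitionResult(
        gei_mj_d=gei,
        e_feces=e_feces,
        de=de,
        e_urine=e_urine,
        e_methane=e_methane,
        e_milk=e_milk,
        me=me,
        eb=eb,
        eue=e_milk / gei,
        e_feces_pct_gei=pct(e_feces),
        e_urine_pct_gei=pct(e_urine),
        e_methane_pct_gei=pct(e_methane),
        e_milk_pct_gei=pct(e_milk),
    )


# ---------------------------------------------------------------------------
# methane metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethaneMetrics:
    """Methane yield and intensity for one cow-period.

    Metrics with a zero denominator are NaN and listed in ``undefined``.
    """

    g_per_day: float
    g_per_kg_dmi: float
    pct_gei: float
    pct_dei: float
    g_per_kg_milk: float
    g_per_kg_fcm: float
    g_per_kg_ecm: float
    g_per_kg_fat: float
    g_per_kg_protein: float
    undefined: tuple[str, ...] = ()


def methane_metrics(
    ch4_g_d: float,
    dmi_kg_d: float,
    gei_mj_d: float,
    dei_mj_d: float,
    milk: MilkRecord,
    fcm_kg_d: float,
    ecm_kg_d: float,
) -> MethaneMetrics:
    """Methane production scaled by intake, energy and milk denominators."""
    if ch4_g_d < 0:
        raise ValueError("negative methane production")
    e_ch4 = MJ_PER_G_CH4 * ch4_g_d
    undefined = []

    def ratio(name, num, den):
        if den <= 0:
            undefined.append(name)
            return float("nan")
        return num / den

    out = MethaneMetrics(
        g_per_day=ch4_g_d,
        g_per_kg_dmi=ratio("g_per_kg_dmi", ch4_g_d, dmi_kg_d),
        pct_gei=ratio("pct_gei", 100.0 * e_ch4, gei_mj_d),
        pct_dei=ratio("pct_dei", 100.0 * e_ch4, dei_mj_d),
        g_per_kg_milk=ratio("g_per_kg_milk", ch4_g_d, milk.milk_kg_d),
        g_per_kg_fcm=ratio("g_per_kg_fcm", ch4_g_d, fcm_kg_d),
        g_per_kg_ecm=ratio("g_per_kg_ecm", ch4_g_d, ecm_kg_d),
        g_per_kg_fat=ratio("g_per_kg_fat", ch4_g_d, milk.fat_kg_d),
        g_per_kg_protein=ratio("g_per_kg_protein", ch4_g_d, milk.protein_kg_d),
        undefined=tuple(undefined),
    )
    return out


# ---------------------------------------------------------------------------
# tidy-table driver
# ---------------------------------------------------------------------------

MARKERS = ("ndfi", "ndf", "ge")


def balance_table(records: pd.DataFrame, marker: str = "ndfi",
                  e_milk_coeffs=E_MILK_COEFFS,
                  me_mode: str = "standard") -> pd.DataFrame:
    """Full balance analysis over a tidy cow-day record table.

    ``records`` uses the documented column dictionary (one row per cow-day
    or cow-period); ``marker`` selects the internal marker for fecal output
    (indigestible NDF, NDF or GE).  Returns one tidy row per input row with
    digestibility, nitrogen partition, energy partition and methane
    metrics.
    """
    if marker not in MARKERS:
        raise ValueError(f"marker must be one of {MARKERS}")
    rows = []
    for _, r in records.iterrows():
        dmi = float(r["dmi_kg_d"])
        gei = dmi * float(r["ge_mj_kg"])
        n_intake = dmi * float(r["cp_frac"]) / CP_PER_N * 1000.0

        if marker == "ndfi":
            marker_intake = dmi * float(r["ndfi_frac"]) * 1000.0  # g/d
            conc = float(r["fecal_marker_ndfi_g_kg"])
        elif marker == "ndf":
            marker_intake = dmi * float(r["ndf_frac"]) * 1000.0
            conc = float(r["fecal_marker_ndf_g_kg"])
        else:
            marker_intake = gei  # MJ/d
            conc = float(r["fecal_marker_ge_mj_kg"])
        fecal_dm = marker_fecal_output(marker_intake, conc)

        dmd = apparent_digestibility(dmi, fecal_dm)
        fecal_ndf = fecal_dm * float(r["fecal_marker_ndf_g_kg"]) / 1000.0
        ndfd = apparent_digestibility(dmi * float(r["ndf_frac"]), fecal_ndf)
        e_feces = fecal_dm * float(r["fecal_marker_ge_mj_kg"])
        ged = apparent_digestibility(gei, e_feces)

        fecal_n = fecal_dm * float(r["fecal_n_pct"]) / 100.0 * 1000.0
        uvol = urine_volume(float(r["bw_kg"]), float(r["urine_creatinine_mg_l"]))
        urinary_n = uvol * float(r["urine_n_g_l"])
        nbal = nitrogen_balance(n_intake, fecal_n, urinary_n,
                                float(r["milk_n_g_d"]))

        milk = MilkRecord(
            milk_kg_d=float(r["milk_kg_d"]),
            fat_kg_d=float(r["fat_kg_d"]),
            protein_kg_d=float(r["protein_kg_d"]),
            lactose_kg_d=float(r["lactose_kg_d"]),
            milk_n_g_d=float(r["milk_n_g_d"]),
        )
        ch4 = float(r["ch4_g_d"])
        epart = energy_partition(gei, e_feces, ch4, milk, float(r["bw_kg"]),
                                 e_milk_coeffs=e_milk_coeffs, me_mode=me_mode)
        fcm_v = fcm(milk.milk_kg_d, milk.fat_kg_d)
        ecm_v = ecm(milk.milk_kg_d, milk.fat_kg_d, milk.protein_kg_d)
        mm = methane_metrics(ch4, dmi, gei, epart.de, milk, fcm_v, ecm_v)

        row = {
            "cow_id": r["cow_id"],
            "day": r.get("day", 1),
            "treatment": r.get("treatment", ""),
            "dmi_kg_d": dmi,
            "fcm_kg_d": fcm_v,
            "ecm_kg_d": ecm_v,
            "milk_per_dmi": milk.milk_kg_d / dmi if dmi > 0 else float("nan"),
            "fecal_dm_kg_d": fecal_dm,
            "dm_digestibility_pct": dmd,
            "ndf_digestibility_pct": ndfd,
            "ge_digestibility_pct": ged,
            "urine_volume_l_d": uvol,
        }
        nb = asdict(nbal)
        row.update(nb)
        ep = asdict(epart)
        row.update(ep)
        mmd = asdict(mm)
        mmd.pop("undefined")
        row.update({f"ch4_{k}": v for k, v in mmd.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def treatment_summary(results: pd.DataFrame,
                      group_col: str = "treatment") -> pd.DataFrame:
    """Descriptive mean +/- SEM per treatment (means of per-cow values)."""
    num = results.select_dtypes("number").columns.difference(["day"])
    per_cow = results.groupby([group_col, "cow_id"])[list(num)].mean()
    g = per_cow.groupby(level=group_col)
    mean = g.mean()
    sem = g.sem(ddof=1)
    out = pd.concat({"mean": mean, "sem": sem}, axis=1)
    out.columns = [f"{c}_{s}" for s, c in out.columns]
    return out.reset_index()
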