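"""Heat-stress phenotyping: THI, derived respirometry traits and the AHTI.

The animal heat-tolerance index (AHTI) counts, per animal, how many of
five physiological parameters (rectal temperature RT, ear temperature
ET, respiration rate RR, tidal volume TV, metabolic rate MR) change by
at least two rest standard deviations between the resting (07:00) and
heat-stressed (14:00) measurement.  0 is the most heat-tolerant animal,
5 the least tolerant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: the five parameters entering the AHTI, in reporting order
AHTI_PARAMS = ("RT", "ET", "RR", "TV", "MR")

#: kcal produced per litre of O2 consumed / CO2 produced (abbreviated
#: Weir coefficients); config point for other calorimetric conventions
WEIR_O2 = 3.941
WEIR_CO2 = 1.106

MINUTES_PER_DAY = 1440.0


class ValidationError(ValueError):
    pass


def thi(dbt: float, rh: float) -> float:
    """Temperature-humidity index from dry-bulb temperature and humidity.

    ``THI = F - 0.55 * (RH/100) * (F - 58)`` with ``F = 1.8*DBT + 32``
    (DBT in deg C, RH in percent).  Values above ~72 indicate heat
    stress in sheep.  Vectorises over array inputs.
    """
    dbt = np.asarray(dbt, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if ((rh < 0) | (rh > 100)).any():
        raise ValidationError("RH must be within [0, 100] percent")
    f = 1.8 * dbt + 32.0
    out = f - 0.55 * (rh / 100.0) * (f - 58.0)
    return float(out) if out.ndim == 0 else out


def tidal_volume(gv: float, rr: float) -> float:
    """Tidal volume TV = GV / RR (litres per breath)."""
    gv = np.asarray(gv, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if (rr <= 0).any():
        raise ValidationError("respiration rate must be positive")
    out = gv / rr
    return float(out) if out.ndim == 0 else out


def metabolic_rate(vo2: float, vco2: float, bw: float) -> float:
    """Metabolic rate in kcal per kg^0.75 per day.

    Energy expenditure per minute is taken from the abbreviated Weir
    equation (3.941*VO2 + 1.106*VCO2 kcal/min, gas volumes in L/min),
    scaled to a day and normalised by metabolic body size BW^0.75.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    bw = np.asarray(bw, dtype=float)
    if (bw <= 0).any():
        raise ValidationError("body weight must be positive")
    if (vo2 < 0).any() or (vco2 < 0).any():
        raise ValidationError("gas exchange volumes must be non-negative")
    kcal_min = WEIR_O2 * vo2 + WEIR_CO2 * vco2
    out = MINUTES_PER_DAY * kcal_min / bw ** 0.75
    return float(out) if out.ndim == 0 else out


RAW_COLUMNS = ["animal_id", "timepoint", "RT", "ET", "RR", "GV", "VO2", "VCO2", "BW"]


def derive_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Add the derived TV and MR columns to a raw physiology table.

    Expects one rest and one stress row per animal with columns
    ``RAW_COLUMNS``; timepoint labels are ``"rest"`` / ``"stress"``.
    """
    missing = [c for c in RAW_COLUMNS if c not in panel.columns]
    if missing:
        raise ValidationError(f"physiology table lacks columns {missing}")
    bad = set(panel["timepoint"]) - {"rest", "stress"}
    if bad:
        raise ValidationError(f"unknown timepoint labels {sorted(bad)}")
    out = panel.copy()
    out["TV"] = tidal_volume(out["GV"].to_numpy(), out["RR"].to_numpy())
    out["MR"] = metabolic_rate(out["VO2"].to_numpy(), out["VCO2"].to_numpy(),
                               out["BW"].to_numpy())
    return out


@dataclass(frozen=True)
class AhtiResult:
    animal_id: str
    flags: dict[str, bool]
    ahti: int


def _paired(panel: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    rest = panel[panel["timepoint"] == "rest"].set_index("animal_id")
    stress = panel[panel["timepoint"] == "stress"].set_index("animal_id")
    if rest.index.duplicated().any() or stress.index.duplicated().any():
        raise ValidationError("animal with more than one row per timepoint")
    if set(rest.index) != set(stress.index):
        raise ValidationError("unpaired animals in physiology table")
    stress = stress.loc[rest.index]
    return rest, stress


def ahti_score(panel: pd.DataFrame, sd_baseline: str | dict = "compute",
               *, signed: bool = False) -> list[AhtiResult]:
    """Score each animal's heat tolerance on the 0-5 AHTI scale.

    For each of RT, ET, RR, TV, MR the animal scores one point when the
    rest-to-stress change is at least twice the rest standard deviation
    of that parameter.  The rest SD is computed across all animals'
    rest values (``sd_baseline="compute"``) or supplied as a
    ``{param: sd}`` mapping.  By default the absolute change is used so
    parameters that fall under stress (e.g. TV) can still flag; pass
    ``signed=True`` to require an increase.
    """
    if "TV" not in panel.columns or "MR" not in panel.columns:
        panel = derive_panel(panel)
    rest, stress = _paired(panel)
    if sd_baseline == "compute":
        if len(rest) < 2:
            raise ValidationError("need >= 2 animals to compute rest SDs")
        sds = {p: float(rest[p].std(ddof=1)) for p in AHTI_PARAMS}
    else:
        sds = {p: float(sd_baseline[p]) for p in AHTI_PARAMS}

    results = []
    for aid in rest.index:
        flags = {}
        for p in AHTI_PARAMS:
            delta = float(stress.at[aid, p] - rest.at[aid, p])
            change = delta if signed else abs(delta)
            if sds[p] == 0.0:
                log.warning("zero rest SD for %s; flagging any nonzero change", p)
                flags[p] = change > 0.0
            else:
                flags[p] = change >= 2.0 * sds[p]
        results.append(AhtiResult(str(aid), flags, int(sum(flags.values()))))
    return results


def ahti_frame(results: list[AhtiResult]) -> pd.DataFrame:
    rows = [{"animal_id": r.animal_id,
             **{f"flag_{p}": int(r.flags[p]) for p in AHTI_PARAMS},
             "ahti": r.ahti} for r in results]
    return pd.DataFrame(rows)


def thi_table(meteo: pd.DataFrame) -> pd.DataFrame:
    """Append a THI column to a meteorological table with DBT and RH columns."""
    out = meteo.copy()
    out["THI"] = np.round(thi(out["DBT"].to_numpy(), out["RH"].to_numpy()), 1)
    return out
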