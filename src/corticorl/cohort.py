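"""Sepsis-3 cohort identification from raw ICU event tables.

Implements the operational definition used throughout the package: an
admission enters the sepsis cohort iff infection is suspected (a culture
paired with antibiotic administration inside a configurable window) AND new
organ dysfunction is present (SOFA >= 2 on the admission day, or a rise of
>= 2 points above the running minimum during the stay), the patient is an
adult, and the ICU stay lasted at least 24 h. Episodes span sepsis onset
through ICU discharge or death.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOFA_ORGANS = ("respiration", "coagulation", "liver", "cardiovascular",
               "cns", "renal")

VASOPRESSOR_NAMES = frozenset({
    "norepinephrine", "epinephrine", "dopamine", "dobutamine",
    "vasopressin", "phenylephrine",
})

# Standard Sepsis-3 SOFA grid, encoded once. Measurement units:
# PaO2/FiO2 mmHg, platelets 10^9/L, bilirubin mg/dL, MAP mmHg,
# norepinephrine ug/kg/min, creatinine mg/dL, urine output mL/day.
PLATELET_GRID = ((20, 4), (50, 3), (100, 2), (150, 1))          # score if value <
BILIRUBIN_GRID = ((12.0, 4), (6.0, 3), (2.0, 2), (1.2, 1))      # score if value >=
CREATININE_GRID = ((5.0, 4), (3.5, 3), (2.0, 2), (1.2, 1))      # score if value >=
GCS_GRID = ((6, 4), (10, 3), (13, 2), (15, 1))                  # score if value <


def _respiration_score(pf_min, ventilated) -> int:
    if pf_min is None:
        return 0
    if pf_min < 100 and ventilated:
        return 4
    if pf_min < 200 and ventilated:
        return 3
    if pf_min < 300:
        return 2
    if pf_min < 400:
        return 1
    return 0


def _grid_score_lt(value, grid) -> int:
    if value is None:
        return 0
    for threshold, score in grid:
        if value < threshold:
            return score
    return 0


def _grid_score_ge(value, grid) -> int:
    if value is None:
        return 0
    for threshold, score in grid:
        if value >= threshold:
            return score
    return 0


def _cardiovascular_score(map_min, dopamine_max, norepi_max, epi_max,
                          dobutamine_any) -> int:
    dopamine_max = dopamine_max or 0.0
    norepi_max = norepi_max or 0.0
    epi_max = epi_max or 0.0
    if dopamine_max > 15 or norepi_max > 0.1 or epi_max > 0.1:
        return 4
    if dopamine_max > 5 or (0 < norepi_max <= 0.1) or (0 < epi_max <= 0.1):
        return 3
    if dopamine_max > 0 or dobutamine_any:
        return 2
    if map_min is not None and map_min < 70:
        return 1
    return 0


def _renal_score(creatinine_max, urine_total) -> int:
    score = _grid_score_ge(creatinine_max, CREATININE_GRID)
    if urine_total is not None:
        if urine_total < 200:
            score = max(score, 4)
        elif urine_total < 500:
            score = max(score, 3)
    return score


@dataclass
class SofaDaily:
    admission_id: str
    day_index: int
    subscores: dict       # organ -> 0..4
    total: int

    def __post_init__(self):
        assert self.total == sum(self.subscores.values())


@dataclass
class SepsisEpisode:
    admission_id: str
    onset_day: int
    included: bool
    exclusion_reason: str       # age_lt_18 | los_lt_24h | no_sepsis | none
    septic_shock: bool = False
    last_day: int = 0


def _day_windows(events: pd.DataFrame, admissions: pd.DataFrame) -> pd.DataFrame:
    """Attach an admission-anchored 24 h day index to every event."""
    adm = admissions.set_index("admission_id")
    ev = events.copy()
    admitted = adm.loc[ev["admission_id"], "admitted_at"].to_numpy()
    hours = (ev["timestamp"].to_numpy() - admitted) / np.timedelta64(1, "h")
    ev["day_index"] = np.floor(hours / 24.0).astype(int)
    return ev


def _n_days(record) -> int:
    los_h = (record["discharged_at"] - record["admitted_at"]) / pd.Timedelta(hours=1)
    return max(1, int(np.ceil(los_h / 24.0 - 1e-9)))


def compute_sofa_daily(events: pd.DataFrame, admissions: pd.DataFrame) -> list:
    """One SofaDaily per admission-day; the worst (most abnormal) value in
    each 24 h window determines each subscore; missing inputs score 0."""
    ev = _day_windows(events, admissions) if len(events) else events
    grouped = {k: v for k, v in ev.groupby("admission_id")} if len(events) else {}
    out = []
    for _, rec in admissions.iterrows():
        adm_id = rec["admission_id"]
        day_groups = {}
        if adm_id in grouped:
            day_groups = {d: g for d, g in grouped[adm_id].groupby("day_index")}
        else:
            logger.warning("admission %s has no events; SOFA scored 0", adm_id)
        for day in range(_n_days(rec)):
            g = day_groups.get(day)
            out.append(_score_day(adm_id, day, g))
    return out


def _extreme(g, name, how):
    vals = g.loc[g["variable_name"] == name, "numeric_value"]
    if vals.empty:
        return None
    return float(vals.min() if how == "min" else
                 vals.max() if how == "max" else vals.sum())


def _score_day(adm_id, day, g) -> SofaDaily:
    if g is None or g.empty:
        sub = {o: 0 for o in SOFA_ORGANS}
        return SofaDaily(str(adm_id), int(day), sub, 0)
    ventilated = bool((g["variable_name"] == "ventilated").any())
    sub = {
        "respiration": _respiration_score(_extreme(g, "pao2_fio2_ratio", "min"),
                                          ventilated),
        "coagulation": _grid_score_lt(_extreme(g, "platelets", "min"),
                                      PLATELET_GRID),
        "liver": _grid_score_ge(_extreme(g, "bilirubin", "max"), BILIRUBIN_GRID),
        "cardiovascular": _cardiovascular_score(
            _extreme(g, "mean_arterial_pressure", "min"),
            _extreme(g, "dopamine", "max"),
            _extreme(g, "norepinephrine", "max"),
            _extreme(g, "epinephrine", "max"),
            _extreme(g, "dobutamine", "max") is not None),
        "cns": _grid_score_lt(_extreme(g, "gcs", "min"), GCS_GRID),
        "renal": _renal_score(_extreme(g, "creatinine", "max"),
                              _extreme(g, "urine_output", "sum")),
    }
    return SofaDaily(str(adm_id), int(day), sub, sum(sub.values()))


def detect_suspected_infection(events: pd.DataFrame,
                               antibiotic_names=("antibiotic",),
                               hours_before: float = 24.0,
                               hours_after: float = 72.0) -> dict:
    """Suspected-infection timestamps per admission.

    A suspicion arises from each culture-sampling event that has at least
    one antibiotic administration within [-hours_before, +hours_after] of
    it; the suspicion time is the earlier member of the pair.
    """
    out: dict = {}
    if not len(events):
        return out
    cultures = events[events["variable_class"] == "culture"]
    abx = events[events["variable_name"].isin(antibiotic_names)]
    for adm_id, cgrp in cultures.groupby("admission_id"):
        a_times = abx.loc[abx["admission_id"] == adm_id, "timestamp"]
        if a_times.empty:
            continue
        times = []
        for c in cgrp["timestamp"]:
            in_window = a_times[(a_times >= c - pd.Timedelta(hours=hours_before))
                                & (a_times <= c + pd.Timedelta(hours=hours_after))]
            if not in_window.empty:
                times.append(min(c, in_window.min()))
        if times:
            out[str(adm_id)] = sorted(times)
    return out


def identify_sepsis(sofa: list, suspicions: dict,
                    admissions: pd.DataFrame) -> list:
    """Apply the operationalized Sepsis-3 definition and exclusions.

    Included iff suspected infection is present AND (SOFA >= 2 on day 0 OR
    total SOFA rises >= 2 above its running minimum on some day) AND
    age >= 18 AND ICU stay >= 24 h. onset_day is the first day the
    qualifying SOFA condition holds; the episode then spans through the
    last ICU day.
    """
    sofa_by_adm: dict = {}
    for s in sofa:
        sofa_by_adm.setdefault(s.admission_id, []).append(s)
    unknown = set(sofa_by_adm) - set(admissions["admission_id"].astype(str))
    if unknown:
        raise ValueError(f"SOFA rows for unknown admissions: {sorted(unknown)[:5]}")
    episodes = []
    for _, rec in admissions.iterrows():
        adm_id = str(rec["admission_id"])
        days = sorted(sofa_by_adm.get(adm_id, []), key=lambda s: s.day_index)
        totals = [s.total for s in days]
        last_day = days[-1].day_index if days else 0
        onset = _sepsis_onset(totals)
        los_h = (rec["discharged_at"] - rec["admitted_at"]) / pd.Timedelta(hours=1)
        if rec["age_years"] < 18:
            reason = "age_lt_18"
        elif los_h < 24.0:
            reason = "los_lt_24h"
        elif onset is None or adm_id not in suspicions:
            reason = "no_sepsis"
        else:
            reason = "none"
        episodes.append(SepsisEpisode(
            admission_id=adm_id,
            onset_day=onset if (reason == "none" and onset is not None) else 0,
            included=reason == "none",
            exclusion_reason=reason,
            last_day=last_day))
    return episodes


def _sepsis_onset(totals) -> int | None:
    """First day the SOFA criterion holds: day 0 if SOFA >= 2 at admission,
    else the first day total rises >= 2 above the running minimum."""
    if not totals:
        return None
    if totals[0] >= 2:
        return 0
    running_min = totals[0]
    for day, t in enumerate(totals[1:], start=1):
        if t - running_min >= 2:
            return day
        running_min = min(running_min, t)
    return None


def flag_septic_shock(episode: SepsisEpisode, events: pd.DataFrame) -> bool:
    """True iff any vasopressor administration AND any lactate > 2 mmol/L
    occurred during the stay."""
    ev = events[events["admission_id"] == episode.admission_id]
    vaso = bool(ev["variable_name"].isin(VASOPRESSOR_NAMES).any())
    lact = ev.loc[ev["variable_name"] == "lactate", "numeric_value"]
    return vaso and bool((lact > 2.0).any())


def flag_all_septic_shock(episodes: list, events: pd.DataFrame) -> list:
    for ep in episodes:
        if ep.included:
            ep.septic_shock = flag_septic_shock(ep, events)
    return episodes


def episodes_frame(episodes: list) -> pd.DataFrame:
    return pd.DataFrame(
        [{"admission_id": e.admission_id, "onset_day": e.onset_day,
          "included": e.included, "exclusion_reason": e.exclusion_reason,
          "septic_shock": e.septic_shock, "last_day": e.last_day}
         for e in episodes])


def sofa_frame(sofa: list) -> pd.DataFrame:
    rows = []
    for s in sofa:
        row = {"admission_id": s.admission_id, "day_index": s.day_index,
               "total": s.total}
        row.update(s.subscores)
        rows.append(row)
    return pd.DataFrame(rows)
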