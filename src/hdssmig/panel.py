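"""Quarterly panel construction from episodic register data.

The episodic register is reduced to one observation per person per quarter,
snapshotted on the 15th of the middle month of each quarter (Feb/May/Aug/Nov
15).  A person appears at a snapshot iff a residence episode covers it;
covariates (household location, roster, parental vital status, survey-derived
education, area variables) are evaluated at the snapshot date.

Age/stage conventions (half-open intervals, boundary ages go up):
  females: child [0, 12), adolescent [12, 25), excluded >= 25
  males:   child [0, 16), adolescent [16, 29), excluded >= 29
with four within-stage age subgroups per sex (youngest/young/older/oldest).
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

from .register import DataIntegrityError, Register

QUARTER_MONTHS = (2, 5, 8, 11)

# (sex, stage) -> ordered [lo, hi) bands for youngest/young/older/oldest
SUBGROUP_BANDS = {
    ("female", "child"): [(0, 2), (2, 6), (6, 9), (9, 12)],
    ("male", "child"): [(0, 3), (3, 8), (8, 12), (12, 16)],
    ("female", "adolescent"): [(12, 15), (15, 18), (18, 21), (21, 25)],
    ("male", "adolescent"): [(16, 19), (19, 22), (22, 25), (25, 29)],
}
SUBGROUP_NAMES = ("youngest", "young", "older", "oldest")

STAGE_CUTS = {"female": (12.0, 25.0), "male": (16.0, 29.0)}


def quarter_dates(start: date, end: date) -> list[pd.Timestamp]:
    """Ordered quarterly snapshot dates (15th of each middle month) in [start, end]."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start > end:
        raise ValueError("empty interval: start after end")
    out = []
    for year in range(start.year, end.year + 1):
        for month in QUARTER_MONTHS:
            d = pd.Timestamp(year, month, 15)
            if start <= d <= end:
                out.append(d)
    return out


def assign_life_stage(sex: str, age_years: float) -> tuple[str, str | None]:
    """(life_stage, age_subgroup) for one person-age; subgroup None if excluded."""
    if age_years < 0:
        raise ValueError("negative age")
    child_hi, adol_hi = STAGE_CUTS[sex]
    if age_years < child_hi:
        stage = "child"
    elif age_years < adol_hi:
        stage = "adolescent"
    else:
        return "excluded", None
    for name, (lo, hi) in zip(SUBGROUP_NAMES, SUBGROUP_BANDS[(sex, stage)]):
        if lo <= age_years < hi:
            return stage, name
    return stage, None  # unreachable for valid bands


def year_band(when, period_start: date, period_end: date) -> str:
    """Two-year band label, e.g. 2004-05, 2006-07, ... 2016-17."""
    when = pd.Timestamp(when)
    if not (pd.Timestamp(period_start) <= when <= pd.Timestamp(period_end)):
        raise ValueError(f"date {when.date()} outside study period")
    y0 = pd.Timestamp(period_start).year
    lo = y0 + 2 * ((when.year - y0) // 2)
    return f"{lo}-{str(lo + 1)[2:]}"


def _spell_map(geo_spells: pd.DataFrame, when) -> dict:
    m = geo_spells[(geo_spells["valid_from"] <= when)
                   & (geo_spells["valid_to"].isna() | (geo_spells["valid_to"] > when))]
    return {r.unique_household_id: (r.geo_household_id, r.lon, r.lat)
            for r in m.itertuples()}


def build_panel(register: Register, period: tuple | None = None,
                survey_back_days: int = 183, survey_fwd_days: int = 366) -> pd.DataFrame:
    """One row per person per covered quarter, with time-varying covariates.

    Survey-derived fields use the closest survey whose validity window covers
    the snapshot (valid ``survey_fwd_days`` after and ``survey_back_days``
    before the survey date); absent a valid survey they stay missing.
    Polygynous duplicate episodes contribute to household rosters but never
    to a person's own row (the primary episode wins).
    """
    start, end = period if period else (register.period_start, register.period_end)
    snaps = quarter_dates(start, end)
    eps = register.episodes
    known_hh = set(register.households["unique_household_id"])
    if not set(eps["unique_household_id"]).issubset(known_hh):
        raise DataIntegrityError("episode references unknown household")

    persons = register.persons.set_index("person_id")
    rows = []
    for q in snaps:
        cov = eps[(eps["start_date"] <= q)
                  & (eps["end_date"].isna() | (eps["end_date"] > q))]
        own = cov[~cov["polygynous"]]
        geo = _spell_map(register.geo_spells, q)
        roster_map: dict[str, list] = {}
        for r in cov.itertuples():
            roster_map.setdefault(r.unique_household_id, []).append(r.person_id)
        for r in own.itertuples():
            hid = r.unique_household_id
            if hid not in geo:
                raise DataIntegrityError(f"no geo spell for {hid} at {q.date()}")
            rows.append((r.person_id, q, hid, *geo[hid],
                         ";".join(sorted(set(roster_map[hid]) - {r.person_id}))))
    panel = pd.DataFrame(rows, columns=["person_id", "quarter_date",
                                        "unique_household_id", "geo_household_id",
                                        "lon", "lat", "roster"])
    if panel.empty:
        return panel

    panel = panel.merge(register.persons[["person_id", "sex", "birth_date",
                                          "mother_id", "father_id"]], on="person_id")
    panel["age_years"] = (panel["quarter_date"] - panel["birth_date"]).dt.days / 365.25
    stages = [assign_life_stage(s, a) for s, a in zip(panel["sex"], panel["age_years"])]
    panel["life_stage"] = [s for s, _ in stages]
    panel["age_subgroup"] = [g for _, g in stages]
    panel["year_band"] = [year_band(q, start, end) for q in panel["quarter_date"]]
    panel["has_parent_ids"] = panel["mother_id"].notna() | panel["father_id"].notna()

    death = persons["death_date"]
    for side in ("mother", "father"):
        pid = panel[f"{side}_id"]
        known = pid.notna() & pid.isin(persons.index)
        dd = pid.map(death)
        flag = pd.array([pd.NA] * len(panel), dtype="boolean")
        flag[known.to_numpy()] = (dd[known] <= panel.loc[known, "quarter_date"]).to_numpy()
        panel[f"{side}_dead"] = flag

    parent_of = {}
    for r in register.persons.itertuples():
        for par in (r.mother_id, r.father_id):
            if pd.notna(par):
                parent_of.setdefault(par, set()).add(r.person_id)
    panel["own_child_present"] = [
        bool(parent_of.get(pid, set()) & set(ro.split(";"))) if ro else False
        for pid, ro in zip(panel["person_id"], panel["roster"])]

    panel = panel.merge(register.households, on="unique_household_id", how="left")
    panel = _merge_surveys(panel, register.surveys, survey_back_days, survey_fwd_days)
    panel = panel.sort_values(["person_id", "quarter_date"]).reset_index(drop=True)
    counts, cats, bounds = population_density(panel)
    panel["pop_density"] = counts
    panel["pop_density_cat"] = cats
    panel.attrs["density_tertiles"] = bounds
    return panel.drop(columns=["birth_date"])


def _merge_surveys(panel, surveys, back_days, fwd_days):
    cols = ["mother_secondary_edu", "father_secondary_edu", "marital_status"]
    if surveys.empty:
        for c in cols:
            panel[c] = pd.NA
        return panel
    sv = surveys[["person_id", "survey_date"] + cols].sort_values("survey_date")
    pnl = panel.sort_values("quarter_date").reset_index()
    back = pd.merge_asof(pnl, sv, left_on="quarter_date", right_on="survey_date",
                         by="person_id", direction="backward",
                         tolerance=pd.Timedelta(days=fwd_days))
    fwd = pd.merge_asof(pnl, sv, left_on="quarter_date", right_on="survey_date",
                        by="person_id", direction="forward",
                        tolerance=pd.Timedelta(days=back_days))
    for c in cols:
        back[c] = back[c].where(back[c].notna(), fwd[c])
    back = back.set_index("index").sort_index()
    panel = panel.copy()
    for c in cols:
        panel[c] = back[c].values
    return panel.drop(columns=[c for c in ("survey_date",) if c in panel])


def population_density(panel: pd.DataFrame, radius_m: float = 250.0):
    """Co-temporal residents within ``radius_m`` of each record, excluding the
    index person (housemates count).  Returns (counts, tertile category,
    tertile boundaries); categories are within-dataset tertiles.
    """
    from .geo import pairwise_km

    counts = np.zeros(len(panel), dtype=int)
    for _, idx in panel.groupby("quarter_date").groups.items():
        sub = panel.loc[idx]
        locs = sub.groupby("geo_household_id").agg(
            lon=("lon", "first"), lat=("lat", "first"), n=("person_id", "size"))
        dmat = pairwise_km(locs["lon"].to_numpy(), locs["lat"].to_numpy())
        within = dmat <= radius_m / 1000.0
        tot = within @ locs["n"].to_numpy()
        per_geo = dict(zip(locs.index, tot))
        counts[panel.index.get_indexer(idx)] = [per_geo[g] - 1
                                                for g in sub["geo_household_id"]]
    if len(counts) == 0:
        return counts, np.array([], dtype=object), (np.nan, np.nan)
    t1, t2 = np.quantile(counts, [1 / 3, 2 / 3])
    cats = np.where(counts <= t1, "low", np.where(counts <= t2, "medium", "high"))
    return counts, cats, (float(t1), float(t2))


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    out = panel.copy()
    out["quarter_date"] = out["quarter_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
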