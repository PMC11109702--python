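"""The in-memory HDSS register: relational tables plus integrity checks.

A register bundles six tables (pandas DataFrames):

persons     person_id, sex, birth_date, mother_id, father_id, death_date,
            secondary_edu
households  unique_household_id, head_id, head_employment_rank, dist_tarmac_km
geo_spells  unique_household_id, geo_household_id, lon, lat, valid_from,
            valid_to (NaT while current)
episodes    person_id, unique_household_id, start_date, end_date,
            start_reason, end_reason, external_place, polygynous
surveys     person_id, survey_date, school_id, grade, in_primary,
            marital_status, spouse_ids, mother_secondary_edu,
            father_secondary_edu
marriages   marriage_id, husband_id, wife_id, start_date, end_date

Households carry a stable unique ID; the location-tied geographic ID lives
in ``geo_spells`` and changes whenever the household relocates.  A man with
several wives may hold concurrent episodes in each wife's household; those
extra episodes are flagged ``polygynous`` and are the only permitted
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import pandas as pd

START_REASONS = {"birth", "in_migration", "internal_move", "enumeration"}
END_REASONS = {"death", "out_migration", "internal_move", "censor"}

TABLES = ("persons", "households", "geo_spells", "episodes", "surveys", "marriages",
          "gazetteer")

_DATE_COLS = {
    "persons": ["birth_date", "death_date"],
    "geo_spells": ["valid_from", "valid_to"],
    "episodes": ["start_date", "end_date"],
    "surveys": ["survey_date"],
    "marriages": ["start_date", "end_date"],
}


class DataIntegrityError(ValueError):
    """A register table violates a structural invariant."""


@dataclass
class Register:
    persons: pd.DataFrame
    households: pd.DataFrame
    geo_spells: pd.DataFrame
    episodes: pd.DataFrame
    surveys: pd.DataFrame
    marriages: pd.DataFrame
    gazetteer: pd.DataFrame
    period_start: date = date(2004, 1, 1)
    period_end: date = date(2017, 12, 31)
    meta: dict = field(default_factory=dict)

    # -- integrity ---------------------------------------------------------

    def validate(self) -> "Register":
        p = self.persons
        if p["person_id"].duplicated().any():
            raise DataIntegrityError("persons: duplicate person_id")
        both = p.dropna(subset=["death_date"])
        if (both["death_date"] < both["birth_date"]).any():
            raise DataIntegrityError("persons: death before birth")
        sex_of = p.set_index("person_id")["sex"]
        for col, want in (("mother_id", "female"), ("father_id", "male")):
            linked = p[col].dropna()
            known = linked[linked.isin(sex_of.index)]
            if (sex_of.loc[known].values != want).any():
                raise DataIntegrityError(f"persons: {col} links to wrong-sex parent")
        hh_ids = set(self.households["unique_household_id"])
        if not set(self.episodes["unique_household_id"]).issubset(hh_ids):
            raise DataIntegrityError("episodes: unknown unique_household_id")
        bad = self.episodes.dropna(subset=["end_date"])
        if (bad["end_date"] < bad["start_date"]).any():
            raise DataIntegrityError("episodes: end before start")
        self._check_episode_overlap()
        self._check_geo_spells()
        ext = self.episodes
        need = ext[(ext["start_reason"] == "in_migration") |
                   (ext["end_reason"] == "out_migration")]
        if need["external_place"].isna().any():
            raise DataIntegrityError("episodes: external move without external_place")
        pid_set = set(p["person_id"])
        for col in ("husband_id", "wife_id"):
            if not set(self.marriages[col]).issubset(pid_set):
                raise DataIntegrityError(f"marriages: unknown {col}")
        if self.gazetteer["label"].duplicated().any():
            raise DataIntegrityError("gazetteer: duplicate label")
        return self

    def _check_episode_overlap(self) -> None:
        eps = self.episodes[~self.episodes["polygynous"].astype(bool)]
        eps = eps.sort_values(["person_id", "start_date"])
        far = pd.Timestamp.max.normalize()
        prev_end = eps.groupby("person_id")["end_date"].shift().fillna(far)
        first = ~eps["person_id"].duplicated()
        if ((eps["start_date"] < prev_end) & ~first).any():
            raise DataIntegrityError("episodes: overlapping non-polygynous episodes")

    def _check_geo_spells(self) -> None:
        gs = self.geo_spells.sort_values(["unique_household_id", "valid_from"])
        for _, grp in gs.groupby("unique_household_id", sort=False):
            ends = grp["valid_to"].iloc[:-1]
            starts = grp["valid_from"].iloc[1:]
            if ends.isna().any():
                raise DataIntegrityError("geo_spells: open spell not last")
            if (ends.values != starts.values).any():
                raise DataIntegrityError("geo_spells: non-contiguous spells")
            g = grp["geo_household_id"]
            if (g.shift() == g).any():
                raise DataIntegrityError("geo_spells: consecutive spells share geo id")

    # -- lookups -----------------------------------------------------------

    def geo_at(self, unique_household_id: str, when) -> tuple:
        """(geo_household_id, lon, lat) of a household on a given date."""
        gs = self.geo_spells
        m = gs[(gs["unique_household_id"] == unique_household_id)
               & (gs["valid_from"] <= when)
               & (gs["valid_to"].isna() | (gs["valid_to"] > when))]
        if m.empty:
            raise DataIntegrityError(
                f"no geo spell for {unique_household_id} at {when}")
        r = m.iloc[0]
        return r["geo_household_id"], float(r["lon"]), float(r["lat"])

    # -- I/O ---------------------------------------------------------------

    def write_csv_dir(self, path) -> dict:
        """Write all tables as RFC-4180 CSVs with ISO-8601 dates.

        Returns {table: filename}.  Output is byte-stable for a fixed
        register (column order fixed, floats at full repr precision).
        """
        import os

        os.makedirs(path, exist_ok=True)
        written = {}
        for name in TABLES:
            df = getattr(self, name).copy()
            for col in _DATE_COLS.get(name, []):
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
            fn = os.path.join(path, f"{name}.csv")
            df.to_csv(fn, index=False)
            written[name] = fn
        meta = pd.DataFrame([{"period_start": self.period_start.isoformat(),
                              "period_end": self.period_end.isoformat()}])
        meta.to_csv(os.path.join(path, "register_meta.csv"), index=False)
        written["register_meta"] = os.path.join(path, "register_meta.csv")
        return written

    @classmethod
    def read_csv_dir(cls, path) -> "Register":
        import os

        frames = {}
        for name in TABLES:
            df = pd.read_csv(os.path.join(path, f"{name}.csv"),
                             dtype={"spouse_ids": "string"} if name == "surveys" else None)
            for col in _DATE_COLS.get(name, []):
                df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
            frames[name] = df
        meta = pd.read_csv(os.path.join(path, "register_meta.csv"))
        reg = cls(period_start=date.fromisoformat(meta["period_start"].iloc[0]),
                  period_end=date.fromisoformat(meta["period_end"].iloc[0]),
                  **frames)
        if "polygynous" in reg.episodes:
            reg.episodes["polygynous"] = reg.episodes["polygynous"].astype(bool)
        return reg


def empty_tables() -> dict:
    """Column-complete empty frames, used by scripted test registers."""
    def mk(cols, dates=()):
        df = pd.DataFrame({c: pd.Series(dtype="object") for c in cols})
        for c in dates:
            df[c] = pd.to_datetime(df[c])
        return df

    return {
        "persons": mk(["person_id", "sex", "birth_date", "mother_id", "father_id",
                       "death_date", "secondary_edu"], ["birth_date", "death_date"]),
        "households": mk(["unique_household_id", "head_id", "head_employment_rank",
                          "dist_tarmac_km"]),
        "geo_spells": mk(["unique_household_id", "geo_household_id", "lon", "lat",
                          "valid_from", "valid_to"], ["valid_from", "valid_to"]),
        "episodes": mk(["person_id", "unique_household_id", "start_date", "end_date",
                        "start_reason", "end_reason", "external_place", "polygynous"],
                       ["start_date", "end_date"]),
        "surveys": mk(["person_id", "survey_date", "school_id", "grade", "in_primary",
                       "marital_status", "spouse_ids", "mother_secondary_edu",
                       "father_secondary_edu"], ["survey_date"]),
        "marriages": mk(["marriage_id", "husband_id", "wife_id", "start_date",
                         "end_date"], ["start_date", "end_date"]),
        "gazetteer": mk(["label", "kind", "lon", "lat"]),
    }
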