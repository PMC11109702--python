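"""Synthetic HDSS register generator.

Simulates a small surveillance population with the event structure the
downstream analysis consumes: founder compounds of related households,
births, deaths, marriages (patrilocal with configurable probability,
polygyny permitted), divorce return-moves, child fostering toward kin
households, whole-household relocations, out-/in-migration across the
surveillance boundary, annual survey rounds, and a gazetteer of external
destinations.

The event engine draws competing exponential hazards held constant within
each calendar month (exact for piecewise-constant hazards) and resolves
event dates to the day.  Identical config + seed gives a bit-identical
register.
"""

from __future__ import annotations

import importlib.resources
import math
from datetime import date

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig, rate_at
from .geo import great_circle_km
from .register import Register, empty_tables

_DAY = pd.Timedelta(days=1)


def load_default_gazetteer() -> pd.DataFrame:
    """Bundled gazetteer of Malawian towns and nearest-border anchor points."""
    with importlib.resources.files("hdssmig.data").joinpath("gazetteer.csv").open() as fh:
        return pd.read_csv(fh)


def gazetteer_geojson(gaz: pd.DataFrame) -> dict:
    """GeoJSON FeatureCollection of gazetteer anchor points."""
    feats = [{"type": "Feature",
              "geometry": {"type": "Point", "coordinates": [float(r.lon), float(r.lat)]},
              "properties": {"label": r.label, "kind": r.kind}}
             for r in gaz.itertuples()]
    return {"type": "FeatureCollection", "features": feats}


def _p_month(annual_rate: float) -> float:
    return 1.0 - math.exp(-annual_rate / 12.0)


def _offset(rng, lon, lat, dist_km):
    """Point at a given great-circle distance, uniform random bearing."""
    theta = rng.uniform(0, 2 * math.pi)
    dlat = (dist_km / 111.32) * math.cos(theta)
    dlon = (dist_km / (111.32 * math.cos(math.radians(lat)))) * math.sin(theta)
    return lon + dlon, lat + dlat


class _Sim:
    """Mutable simulation state; not part of the public surface."""

    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.t0 = pd.Timestamp(config.period_start)
        self.t1 = pd.Timestamp(config.period_end)
        self.persons: dict[str, dict] = {}
        self.households: dict[str, dict] = {}
        self.spells: list[dict] = []
        self.open_spell: dict[str, int] = {}
        self.episodes: list[dict] = []
        self.open_ep: dict[str, int] = {}         # primary open episode index
        self.poly_ep: dict[tuple, int] = {}       # (pid, hid) -> open poly episode
        self.residence: dict[str, str] = {}       # pid -> primary hid
        self.away: dict[str, str] = {}            # pid -> external place label
        self.marriages: list[dict] = []
        self.natal: dict[str, str] = {}
        self.surveys: list[dict] = []
        self.last_end: dict[str, pd.Timestamp] = {}
        self.ever_married: set[str] = set()
        self.widowed: set[str] = set()
        self._np = self._nh = self._ng = self._nm = 0
        self.gazetteer = load_default_gazetteer()
        lon0, lat0, lon1, lat1 = config.area_bounds
        self.schools = [(f"S{i+1}",
                         self.rng.uniform(lon0, lon1), self.rng.uniform(lat0, lat1))
                        for i in range(8)]

    # ------------------------------------------------------------- identity
    def new_pid(self):
        self._np += 1
        return f"P{self._np:05d}"

    def new_hid(self):
        self._nh += 1
        return f"H{self._nh:04d}"

    def new_gid(self):
        self._ng += 1
        return f"G{self._ng:06d}"

    # ------------------------------------------------------------ mutation
    def add_person(self, sex, birth, mother=None, father=None, death=None):
        pid = self.new_pid()
        self.persons[pid] = {"person_id": pid, "sex": sex, "birth_date": birth,
                             "mother_id": mother, "father_id": father,
                             "death_date": death,
                             "secondary_edu": bool(self.rng.random() < 0.25)}
        return pid

    def add_household(self, head, lon, lat, when):
        hid = self.new_hid()
        ranks = ["low", "medium", "high"]
        rank = ranks[int(self.rng.choice(3, p=[0.3, 0.5, 0.2]))]
        # distance to the north-south tarmac road running at lon 33.87
        tarmac = abs(lon - 33.87) * 111.32 * math.cos(math.radians(lat))
        self.households[hid] = {"unique_household_id": hid, "head_id": head,
                                "head_employment_rank": rank,
                                "dist_tarmac_km": round(tarmac, 3)}
        self.spells.append({"unique_household_id": hid,
                            "geo_household_id": self.new_gid(),
                            "lon": round(lon, 6), "lat": round(lat, 6),
                            "valid_from": when, "valid_to": pd.NaT})
        self.open_spell[hid] = len(self.spells) - 1
        return hid

    def relocate_household(self, hid, lon, lat, when):
        old = self.spells[self.open_spell[hid]]
        when = max(when, old["valid_from"])
        old["valid_to"] = when
        self.spells.append({"unique_household_id": hid,
                            "geo_household_id": self.new_gid(),
                            "lon": round(lon, 6), "lat": round(lat, 6),
                            "valid_from": when, "valid_to": pd.NaT})
        self.open_spell[hid] = len(self.spells) - 1

    def hh_loc(self, hid):
        s = self.spells[self.open_spell[hid]]
        return s["lon"], s["lat"]

    def clamp_day(self, pid, when):
        """Events are drawn day-uniform within the month; keep each person's
        episode sequence chronologically consistent."""
        idx = self.open_ep.get(pid)
        if idx is not None and self.episodes[idx]["start_date"] > when:
            return self.episodes[idx]["start_date"]
        last = self.last_end.get(pid)
        if last is not None and last > when:
            return last
        return when

    def open_episode(self, pid, hid, when, reason, place=None, poly=False):
        self.episodes.append({"person_id": pid, "unique_household_id": hid,
                              "start_date": when, "end_date": pd.NaT,
                              "start_reason": reason, "end_reason": None,
                              "external_place": place, "polygynous": poly})
        idx = len(self.episodes) - 1
        if poly:
            self.poly_ep[(pid, hid)] = idx
        else:
            self.open_ep[pid] = idx
            self.residence[pid] = hid

    def close_episode(self, pid, when, reason, place=None):
        idx = self.open_ep.pop(pid, None)
        if idx is not None:
            ep = self.episodes[idx]
            ep["end_date"] = max(when, ep["start_date"])
            ep["end_reason"] = reason
            if place is not None:
                ep["external_place"] = place
            self.last_end[pid] = ep["end_date"]
        self.residence.pop(pid, None)

    def close_poly(self, pid, hid, when, reason, place=None):
        idx = self.poly_ep.pop((pid, hid), None)
        if idx is not None:
            ep = self.episodes[idx]
            ep["end_date"] = max(when, ep["start_date"])
            ep["end_reason"] = reason
            if place is not None:
                ep["external_place"] = place

    def move_person(self, pid, dest_hid, when):
        when = self.clamp_day(pid, when)
        dest_spell = self.spells[self.open_spell[dest_hid]]
        when = max(when, dest_spell["valid_from"])
        self.close_episode(pid, when, "internal_move")
        self.open_episode(pid, dest_hid, when, "internal_move")

    def out_migrate(self, pid, when, place):
        when = self.clamp_day(pid, when)
        self.close_episode(pid, when, "out_migration", place)
        for (p, hid) in [k for k in self.poly_ep if k[0] == pid]:
            self.close_poly(p, hid, when, "censor")
        self.away[pid] = place

    # ------------------------------------------------------------- queries
    def age(self, pid, when) -> float:
        return (when - self.persons[pid]["birth_date"]).days / 365.25

    def alive(self, pid) -> bool:
        return self.persons[pid]["death_date"] is None

    def members(self, hid):
        out = [p for p, h in self.residence.items() if h == hid]
        out += [p for (p, h) in self.poly_ep if h == hid and p not in out]
        return sorted(out)

    def active_marriages(self, pid):
        return [m for m in self.marriages
                if m["end_date"] is pd.NaT and pid in (m["husband_id"], m["wife_id"])]

    def draw_place(self) -> str:
        gaz = self.gazetteer
        w = np.where(gaz["kind"] == "malawi_town", 2.0, 1.0)
        # nearer towns attract more movers
        w = w / (1.0 + np.arange(len(gaz)) * 0.1)
        w = w / w.sum()
        return str(gaz["label"].iloc[int(self.rng.choice(len(gaz), p=w))])

    def nearest_school(self, hid):
        lon, lat = self.hh_loc(hid)
        best = min(self.schools,
                   key=lambda s: great_circle_km(lon, lat, s[1], s[2]))
        return best[0]

    def rand_day(self, month_start: pd.Timestamp) -> pd.Timestamp:
        ndays = month_start.days_in_month
        return month_start + pd.Timedelta(days=int(self.rng.integers(0, ndays)))

    # -------------------------------------------------------------- set-up
    def found_population(self):
        cfg, rng, t0 = self.cfg, self.rng, self.t0
        lon0, lat0, lon1, lat1 = cfg.area_bounds
        lineage = None       # (father_pid, mother_pid, anchor_lon, anchor_lat)
        heads_pool: list[str] = []
        for _ in range(cfg.n_founder_households):
            if lineage is not None and rng.random() < 0.35:
                gf, gm, alon, alat = lineage
                lon, lat = _offset(rng, alon, alat, rng.uniform(0.01, 0.5))
            else:
                head_age = rng.uniform(22, 55)
                gf_birth = t0 - pd.Timedelta(days=int((head_age + rng.uniform(22, 32)) * 365.25))
                gm_birth = gf_birth + pd.Timedelta(days=int(rng.uniform(2, 8) * 365.25))
                gf_death = (t0 - pd.Timedelta(days=int(rng.uniform(0.2, 15) * 365.25))
                            if rng.random() < 0.55 else None)
                gm_death = (t0 - pd.Timedelta(days=int(rng.uniform(0.2, 15) * 365.25))
                            if rng.random() < 0.45 else None)
                gf = self.add_person("male", gf_birth, death=gf_death)
                gm = self.add_person("female", gm_birth, death=gm_death)
                lon = rng.uniform(lon0, lon1)
                lat = rng.uniform(lat0, lat1)
                lineage = (gf, gm, lon, lat)
            gf, gm = lineage[0], lineage[1]
            head_age = rng.uniform(22, 55)
            head = self.add_person("male", t0 - pd.Timedelta(days=int(head_age * 365.25)),
                                   mother=gm, father=gf)
            hid = self.add_household(head, lon, lat, t0)
            self.open_episode(head, hid, t0, "enumeration")
            self.natal[head] = hid
            female_headed = rng.random() < 0.10
            wife = None
            if not female_headed:
                wife_age = max(16.0, head_age - rng.uniform(2, 10))
                wmother = wfather = None
                if heads_pool and rng.random() < 0.4:
                    # wife is a sister of an earlier head: shares his parents
                    bro = str(rng.choice(heads_pool))
                    wmother = self.persons[bro]["mother_id"]
                    wfather = self.persons[bro]["father_id"]
                wife = self.add_person("female",
                                       t0 - pd.Timedelta(days=int(wife_age * 365.25)),
                                       mother=wmother, father=wfather)
                self.open_episode(wife, hid, t0, "enumeration")
                self.natal[wife] = hid
                self.record_marriage(head, wife,
                                     t0 - pd.Timedelta(days=int(rng.uniform(0.5, 15) * 365.25)))
            mother_for_kids = wife if wife else self.add_person(
                "female", t0 - pd.Timedelta(days=int((head_age - 2) * 365.25)))
            if female_headed:
                # widow heads her own household
                self.households[hid]["head_id"] = mother_for_kids
                self.open_episode(mother_for_kids, hid, t0, "enumeration")
                self.natal[mother_for_kids] = hid
                self.widowed.add(mother_for_kids)
            max_kid = max(0.5, min(self.age(mother_for_kids, t0) - 16.0, 17.0))
            for _ in range(rng.poisson(2.2)):
                kage = rng.uniform(0, max_kid)
                kid = self.add_person("female" if rng.random() < 0.5 else "male",
                                      t0 - pd.Timedelta(days=int(kage * 365.25)),
                                      mother=mother_for_kids,
                                      father=None if female_headed else head)
                self.open_episode(kid, hid, t0, "enumeration")
                self.natal[kid] = hid
            if self.alive(gm) and self.residence.get(gm) is None and rng.random() < 0.5:
                self.open_episode(gm, hid, t0, "enumeration")
                self.natal[gm] = hid
            if self.alive(gf) and self.residence.get(gf) is None and rng.random() < 0.5:
                self.open_episode(gf, hid, t0, "enumeration")
                self.natal[gf] = hid
            heads_pool.append(head)

    def record_marriage(self, husband, wife, when):
        self._nm += 1
        self.marriages.append({"marriage_id": f"M{self._nm:05d}",
                               "husband_id": husband, "wife_id": wife,
                               "start_date": when, "end_date": pd.NaT})
        self.ever_married.update((husband, wife))

    # --------------------------------------------------------- month steps
    def step_deaths(self, month):
        cfg = self.cfg
        for pid in sorted(self.residence):
            if not self.alive(pid):
                continue
            if self.rng.random() < _p_month(rate_at(cfg.mortality_rate, self.age(pid, month))):
                day = self.rand_day(month)
                self.persons[pid]["death_date"] = day
                for (p, hid) in [k for k in self.poly_ep if k[0] == pid]:
                    self.close_poly(p, hid, day, "death")
                self.close_episode(pid, day, "death")
                for m in self.active_marriages(pid):
                    m["end_date"] = day
                    other = m["wife_id"] if m["husband_id"] == pid else m["husband_id"]
                    self.widowed.add(other)

    def step_births(self, month):
        cfg = self.cfg
        for pid in sorted(self.residence):
            pers = self.persons[pid]
            if pers["sex"] != "female":
                continue
            if self.rng.random() < _p_month(rate_at(cfg.fertility_rate, self.age(pid, month))):
                day = self.rand_day(month)
                hus = self.active_marriages(pid)
                father = hus[0]["husband_id"] if hus else None
                kid = self.add_person("female" if self.rng.random() < 0.5 else "male",
                                      day, mother=pid, father=father)
                self.open_episode(kid, self.residence[pid], day, "birth")
                self.natal[kid] = self.residence[pid]

    def _groom_candidates(self, bride, when):
        cfg = self.cfg
        bage = self.age(bride, when)
        bmother = self.persons[bride]["mother_id"]
        bfather = self.persons[bride]["father_id"]
        cands, weights = [], []
        for pid in sorted(self.residence):
            p = self.persons[pid]
            if p["sex"] != "male":
                continue
            age = self.age(pid, when)
            if age < 18 or age < bage or age > bage + 12:
                continue
            if pid in (bfather,) or (bmother is not None and p["mother_id"] == bmother):
                continue
            nmarr = len(self.active_marriages(pid))
            if nmarr >= 2:
                continue
            w = rate_at(cfg.marriage_hazard.get("male", []), age) + 0.01
            if nmarr == 1:
                w *= cfg.polygyny_prob
            cands.append(pid)
            weights.append(w)
        return cands, weights

    def step_marriages(self, month):
        cfg = self.cfg
        for bride in sorted(self.residence):
            p = self.persons[bride]
            if p["sex"] != "female" or self.active_marriages(bride):
                continue
            lam = rate_at(cfg.marriage_hazard.get("female", []), self.age(bride, month))
            if self.rng.random() >= _p_month(lam):
                continue
            cands, weights = self._groom_candidates(bride, month)
            if not cands:
                continue
            w = np.asarray(weights, dtype=float)
            groom = cands[int(self.rng.choice(len(cands), p=w / w.sum()))]
            day = self.rand_day(month)
            polygynous = bool(self.active_marriages(groom))
            patrilocal = polygynous or (self.rng.random() < cfg.patrilocality_prob)
            self.record_marriage(groom, bride, day)
            if polygynous:
                # new wife's household founded near the husband's; he holds a
                # concurrent flagged episode there
                lon, lat = self.hh_loc(self.residence[groom])
                nlon, nlat = _offset(self.rng, lon, lat,
                                     self.rng.uniform(0.01, 0.5))
                hid = self.add_household(groom, nlon, nlat, day)
                self.open_episode(groom, hid, day, "internal_move", poly=True)
                self.move_person(bride, hid, day)
            elif patrilocal:
                ghid = self.residence[groom]
                if self.households[ghid]["head_id"] != groom:
                    # household fission: the marrying man founds his own
                    # household near his father's compound
                    fhid = self.residence.get(self.persons[groom]["father_id"] or "", ghid)
                    lon, lat = self.hh_loc(fhid)
                    nlon, nlat = _offset(self.rng, lon, lat,
                                         self.rng.uniform(0.01, 0.5))
                    hid = self.add_household(groom, nlon, nlat, day)
                    self.move_person(groom, hid, day)
                    ghid = hid
                self.move_person(bride, ghid, day)
            else:
                self.move_person(groom, self.residence[bride], day)

    def step_divorces(self, month):
        cfg = self.cfg
        for m in list(self.marriages):
            if m["end_date"] is not pd.NaT:
                continue
            if self.rng.random() >= _p_month(cfg.divorce_hazard):
                continue
            day = self.rand_day(month)
            m["end_date"] = day
            wife, hus = m["wife_id"], m["husband_id"]
            whid = self.residence.get(wife)
            if whid is None or not self.alive(wife):
                continue
            self.close_poly(hus, whid, day, "censor")
            if self.residence.get(hus) != whid and (hus, whid) not in self.poly_ep:
                pass
            kids = [k for k in self.members(whid)
                    if self.persons[k]["mother_id"] == wife and self.age(k, day) < 12]
            if self.rng.random() < cfg.external_move_prob:
                place = self.draw_place()
                self.out_migrate(wife, day, place)
                for k in kids:
                    self.out_migrate(k, day, place)
                continue
            dest = self._return_home(wife, day)
            if dest == whid:
                continue
            self.move_person(wife, dest, day)
            for k in kids:
                self.move_person(k, dest, day)

    def _return_home(self, pid, when) -> str:
        mother = self.persons[pid]["mother_id"]
        if mother and self.residence.get(mother):
            return self.residence[mother]
        natal = self.natal.get(pid)
        if natal and self.members(natal):
            return natal
        lon0, lat0, lon1, lat1 = self.cfg.area_bounds
        return self.add_household(pid, self.rng.uniform(lon0, lon1),
                                  self.rng.uniform(lat0, lat1), when)

    def _kin_households(self, pid):
        """Candidate fostering homes: households of maternal/paternal kin."""
        out = {"maternal": set(), "paternal": set()}
        pers = self.persons[pid]
        for side, parent in (("maternal", pers["mother_id"]),
                             ("paternal", pers["father_id"])):
            if not parent or parent not in self.persons:
                continue
            par = self.persons[parent]
            for gp in (par["mother_id"], par["father_id"]):
                if gp and self.residence.get(gp):
                    out[side].add(self.residence[gp])
            gm, gf = par["mother_id"], par["father_id"]
            if gm or gf:
                for q, qp in self.persons.items():
                    if q == parent or q not in self.residence:
                        continue
                    if (gm and qp["mother_id"] == gm) or (gf and qp["father_id"] == gf):
                        out[side].add(self.residence[q])
        cur = self.residence.get(pid)
        for side in out:
            out[side].discard(cur)
        return out

    def step_fostering(self, month):
        cfg = self.cfg
        for pid in sorted(self.residence):
            p = self.persons[pid]
            lam = rate_at(cfg.fostering_hazard.get(p["sex"], []), self.age(pid, month))
            if lam <= 0 or self.rng.random() >= _p_month(lam):
                continue
            hid = self.residence[pid]
            with_parent = any(q in self.members(hid)
                              for q in (p["mother_id"], p["father_id"]) if q)
            if not with_parent:
                continue
            day = self.rand_day(month)
            if self.rng.random() < cfg.external_move_prob:
                self.out_migrate(pid, day, self.draw_place())
                continue
            kin = self._kin_households(pid)
            mat, pat = sorted(kin["maternal"]), sorted(kin["paternal"])
            cands = mat + pat
            if not cands:
                others = sorted(set(self.residence.values()) - {hid})
                if not others:
                    continue
                dest = others[int(self.rng.integers(len(others)))]
            else:
                w = np.array([cfg.maternal_foster_weight / max(len(mat), 1)] * len(mat)
                             + [(1 - cfg.maternal_foster_weight) / max(len(pat), 1)] * len(pat))
                if w.sum() == 0:
                    w = np.ones(len(cands))
                dest = cands[int(self.rng.choice(len(cands), p=w / w.sum()))]
            self.move_person(pid, dest, day)

    def step_relocations(self, month):
        cfg = self.cfg
        lon0, lat0, lon1, lat1 = cfg.area_bounds
        for hid in sorted(self.households):
            mem = self.members(hid)
            if not mem:
                continue
            if self.rng.random() >= _p_month(cfg.relocation_hazard):
                continue
            day = self.rand_day(month)
            if self.rng.random() < cfg.external_move_prob:
                place = self.draw_place()
                for pid in mem:
                    if self.residence.get(pid) == hid:
                        self.out_migrate(pid, day, place)
                    else:
                        self.close_poly(pid, hid, day, "censor")
                continue
            lon, lat = self.hh_loc(hid)
            if self.rng.random() < cfg.local_relocation_prob:
                nlon, nlat = _offset(self.rng, lon, lat, self.rng.uniform(0.02, 3.9))
            else:
                nlon = self.rng.uniform(lon0, lon1)
                nlat = self.rng.uniform(lat0, lat1)
                if great_circle_km(lon, lat, nlon, nlat) < 0.02:
                    nlon, nlat = _offset(self.rng, lon, lat, 0.05)
            self.relocate_household(hid, nlon, nlat, day)
            for pid in mem:
                if self.residence.get(pid) == hid:
                    d = self.clamp_day(pid, day)
                    self.close_episode(pid, d, "internal_move")
                    self.open_episode(pid, hid, d, "internal_move")
                else:
                    idx = self.poly_ep.pop((pid, hid))
                    ep = self.episodes[idx]
                    d = max(day, ep["start_date"])
                    ep["end_date"] = d
                    ep["end_reason"] = "internal_move"
                    self.open_episode(pid, hid, d, "internal_move", poly=True)

    def step_returns(self, month):
        cfg = self.cfg
        for pid in sorted(self.away):
            if self.rng.random() >= _p_month(cfg.return_hazard):
                continue
            day = self.clamp_day(pid, self.rand_day(month))
            place = self.away.pop(pid)
            dest = self._return_home(pid, day)
            day = max(day, self.spells[self.open_spell[dest]]["valid_from"])
            self.open_episode(pid, dest, day, "in_migration", place=place)

    def step_survey(self, year):
        day = pd.Timestamp(date(year, self.cfg.survey_month, 15))
        if not (self.t0 <= day <= self.t1):
            return
        for pid in sorted(self.residence):
            p = self.persons[pid]
            age = self.age(pid, day)
            grade = int(age) - 5
            in_primary = 1 <= grade <= 8
            active = self.active_marriages(pid)
            if active:
                status = "married"
            elif pid in self.widowed:
                status = "widowed"
            elif pid in self.ever_married:
                status = "separated"
            else:
                status = "never"
            spouses = ";".join(sorted(m["wife_id"] if m["husband_id"] == pid
                                      else m["husband_id"] for m in active))
            mother = p["mother_id"]
            father = p["father_id"]
            self.surveys.append({
                "person_id": pid, "survey_date": day,
                "school_id": self.nearest_school(self.residence[pid]) if in_primary else None,
                "grade": grade if in_primary else None,
                "in_primary": in_primary,
                "marital_status": status,
                "spouse_ids": spouses,
                "mother_secondary_edu": (self.persons[mother]["secondary_edu"]
                                         if mother in self.persons else None),
                "father_secondary_edu": (self.persons[father]["secondary_edu"]
                                         if father in self.persons else None),
            })

    # ------------------------------------------------------------- driver
    def run(self) -> Register:
        self.found_population()
        months = pd.date_range(self.t0.normalize(), self.t1, freq="MS")
        if months.empty or months[0] > self.t0:
            months = months.insert(0, self.t0.normalize().replace(day=1))
        surveyed = set()
        for month in months:
            self.step_deaths(month)
            self.step_births(month)
            self.step_marriages(month)
            self.step_divorces(month)
            self.step_fostering(month)
            self.step_relocations(month)
            self.step_returns(month)
            if month.month == self.cfg.survey_month and month.year not in surveyed:
                self.step_survey(month.year)
                surveyed.add(month.year)
        for idx, ep in enumerate(self.episodes):
            if ep["end_reason"] is None:
                ep["end_reason"] = "censor"
        return self._to_register()

    def _to_register(self) -> Register:
        base = empty_tables()
        persons = pd.DataFrame(sorted(self.persons.values(),
                                      key=lambda r: r["person_id"]))
        persons["birth_date"] = pd.to_datetime(persons["birth_date"])
        persons["death_date"] = pd.to_datetime(persons["death_date"])
        households = pd.DataFrame(sorted(self.households.values(),
                                         key=lambda r: r["unique_household_id"]))
        spells = pd.DataFrame(self.spells).sort_values(
            ["unique_household_id", "valid_from"], kind="stable").reset_index(drop=True)
        episodes = pd.DataFrame(self.episodes).sort_values(
            ["person_id", "start_date", "unique_household_id"],
            kind="stable").reset_index(drop=True)
        episodes["polygynous"] = episodes["polygynous"].astype(bool)
        surveys = (pd.DataFrame(self.surveys, columns=base["surveys"].columns)
                   if self.surveys else base["surveys"])
        marriages = (pd.DataFrame(self.marriages)
                     if self.marriages else base["marriages"])
        reg = Register(persons=persons, households=households, geo_spells=spells,
                       episodes=episodes, surveys=surveys, marriages=marriages,
                       gazetteer=self.gazetteer,
                       period_start=self.cfg.period_start,
                       period_end=self.cfg.period_end,
                       meta={"config": self.cfg.to_dict()})
        return reg.validate()


def simulate_register(config: SimConfig) -> Register:
    """Generate a closed, internally consistent synthetic HDSS register.

    Raises ConfigError naming the offending field if the config is invalid.
    """
    if not isinstance(config, SimConfig):
        raise ConfigError("config: expected a SimConfig")
    config.validate()
    return _Sim(config).run()


def ground_truth_moves(register: Register) -> pd.DataFrame:
    """Exact relocation-event list recounted from episode boundaries.

    One row per person-event: internal moves (episode closed and reopened
    the same day in a different household or at a new geo location),
    out-migrations, and in-migrations.  Independent of the quarterly
    discretisation; used as the oracle for move detection.
    """
    spells_by_hid: dict[str, list] = {}
    for r in register.geo_spells.itertuples():
        spells_by_hid.setdefault(r.unique_household_id, []).append(r)

    def geo_before(hid, when):
        rows = spells_by_hid.get(hid, [])
        prev = None
        for s in rows:
            if s.valid_from <= when - _DAY and (pd.isna(s.valid_to) or s.valid_to > when - _DAY):
                return s.geo_household_id, s.lon, s.lat
            prev = s
        s = rows[0] if prev is None else prev
        return s.geo_household_id, s.lon, s.lat

    def geo_from(hid, when):
        for s in spells_by_hid.get(hid, []):
            if s.valid_from <= when and (pd.isna(s.valid_to) or s.valid_to > when):
                return s.geo_household_id, s.lon, s.lat
        s = spells_by_hid[hid][-1]
        return s.geo_household_id, s.lon, s.lat

    eps = register.episodes[~register.episodes["polygynous"]].sort_values(
        ["person_id", "start_date"])
    events = []
    for pid, grp in eps.groupby("person_id", sort=True):
        rows = list(grp.itertuples())
        for i, ep in enumerate(rows):
            if ep.start_reason == "in_migration":
                g, lon, lat = geo_from(ep.unique_household_id, ep.start_date)
                events.append({"person_id": pid, "date": ep.start_date,
                               "kind": "in_migration",
                               "origin": ep.external_place, "destination": g,
                               "dest_lon": lon, "dest_lat": lat,
                               "origin_lon": np.nan, "origin_lat": np.nan})
            if ep.end_reason == "internal_move":
                og, olon, olat = geo_before(ep.unique_household_id, ep.end_date)
                nxt = rows[i + 1] if i + 1 < len(rows) else None
                if nxt is None:
                    continue
                dg, dlon, dlat = geo_from(nxt.unique_household_id, nxt.start_date)
                events.append({"person_id": pid, "date": ep.end_date,
                               "kind": "internal",
                               "origin": og, "destination": dg,
                               "origin_lon": olon, "origin_lat": olat,
                               "dest_lon": dlon, "dest_lat": dlat})
            elif ep.end_reason == "out_migration":
                og, olon, olat = geo_before(ep.unique_household_id, ep.end_date)
                events.append({"person_id": pid, "date": ep.end_date,
                               "kind": "out_migration",
                               "origin": og, "destination": ep.external_place,
                               "origin_lon": olon, "origin_lat": olat,
                               "dest_lon": np.nan, "dest_lat": np.nan})
    if not events:
        return pd.DataFrame(columns=["person_id", "date", "kind", "origin",
                                     "destination", "origin_lon", "origin_lat",
                                     "dest_lon", "dest_lat", "co_movers"])
    ev = pd.DataFrame(events).sort_values(["person_id", "date"]).reset_index(drop=True)
    key = ev["date"].astype(str) + "|" + ev["origin"].astype(str) + "|" + ev["destination"].astype(str)
    groups = ev.groupby(key)["person_id"].apply(list).to_dict()
    ev["co_movers"] = [sorted(set(groups[k]) - {p}) for k, p in zip(key, ev["person_id"])]
    return ev
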