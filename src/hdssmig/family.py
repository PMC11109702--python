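"""Kinship graph and family-structure variables.

From parent and spousal links we build a typed kinship graph and derive,
for every person-quarter:

* the household-composition category (rule cascade over eleven categories,
  ``parents_siblings`` ... ``no_ids``),
* five kin-proximity flags (a relative of the given type within 250 m but
  not in the index household), and
* seven household age-band counts excluding the index person.

Kin-set definitions (evaluated at the query date):

maternal    blood kin reached through the mother (grandparents, mother's
            siblings, their children, ...), up to ``depth`` blood edges past
            the mother; excludes the mother, the index, the index's own
            siblings and those siblings' children
paternal    symmetric through the father
sisters_fam sisters aged >= 18 plus their current spouses and children
brothers_fam symmetric for brothers
nuclear     parents plus siblings aged < 18
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .geo import great_circle_km
from .register import DataIntegrityError

AGE_BANDS = [0, 1, 5, 12, 19, 30, 60, np.inf]
AGE_BAND_LABELS = ("n_lt1", "n_1_4", "n_5_11", "n_12_18", "n_19_29",
                   "n_30_59", "n_60p")

COMPOSITION_CATEGORIES = (
    "parents_siblings", "sisters_family", "brothers_family", "mother_siblings",
    "father_stepmother", "maternal", "paternal", "spouse", "other", "external",
    "no_ids")


@dataclass
class KinGraph:
    """Typed kinship graph plus the lookup tables the classifiers need."""

    graph: nx.DiGraph
    persons: pd.DataFrame
    marriages: pd.DataFrame
    mother_of: dict = field(default_factory=dict)
    father_of: dict = field(default_factory=dict)
    children_of: dict = field(default_factory=dict)
    birth: dict = field(default_factory=dict)
    sex: dict = field(default_factory=dict)
    _kin_cache: dict = field(default_factory=dict)
    _marr_index: dict | None = None

    def age(self, pid, when) -> float:
        b = self.birth.get(pid)
        return np.nan if b is None or pd.isna(b) else (when - b).days / 365.25

    def has_parent_ids(self, pid) -> bool:
        return pid in self.mother_of or pid in self.father_of

    def siblings(self, pid) -> set:
        out = set()
        for par in (self.mother_of.get(pid), self.father_of.get(pid)):
            if par is not None:
                out |= self.children_of.get(par, set())
        out.discard(pid)
        return out

    def spouses_at(self, pid, when) -> set:
        if self._marr_index is None:
            idx: dict = {}
            for r in self.marriages.itertuples():
                idx.setdefault(r.husband_id, []).append(
                    (r.start_date, r.end_date, r.wife_id))
                idx.setdefault(r.wife_id, []).append(
                    (r.start_date, r.end_date, r.husband_id))
            object.__setattr__(self, "_marr_index", idx)
        return {partner for start, end, partner in self._marr_index.get(pid, ())
                if start <= when and (pd.isna(end) or end > when)}


def build_kin_graph(persons: pd.DataFrame, marriages: pd.DataFrame) -> KinGraph:
    """Typed parent->child graph plus spousal links with validity intervals.

    Raises DataIntegrityError on cyclic parentage or a mother edge that
    originates from a non-female person.
    """
    g = nx.DiGraph()
    g.add_nodes_from(persons["person_id"])
    sex = dict(zip(persons["person_id"], persons["sex"]))
    birth = dict(zip(persons["person_id"], persons["birth_date"]))
    mother_of, father_of, children_of = {}, {}, {}
    for r in persons.itertuples():
        for par, kind in ((r.mother_id, "mother"), (r.father_id, "father")):
            if pd.isna(par):
                continue
            if kind == "mother" and sex.get(par) == "male":
                raise DataIntegrityError(f"mother edge from male person {par}")
            if kind == "father" and sex.get(par) == "female":
                raise DataIntegrityError(f"father edge from female person {par}")
            g.add_edge(par, r.person_id, kind=kind)
            (mother_of if kind == "mother" else father_of)[r.person_id] = par
            children_of.setdefault(par, set()).add(r.person_id)
    if not nx.is_directed_acyclic_graph(g):
        raise DataIntegrityError("cyclic parentage")
    return KinGraph(graph=g, persons=persons, marriages=marriages,
                    mother_of=mother_of, father_of=father_of,
                    children_of=children_of, birth=birth, sex=sex)


def _side_kin(kg: KinGraph, index, parent, depth) -> frozenset:
    """Blood kin within ``depth`` edges of ``parent``, minus the parent, the
    index, the index's siblings and those siblings' children.

    Blood paths climb to ancestors and then descend (up* down*); once a path
    has stepped down to a child it may not step back up, which keeps
    co-parents and other in-laws out of the set.
    """
    if parent is None:
        return frozenset()
    seen = {(parent, False)}
    frontier = {(parent, False)}
    found = {parent}
    for _ in range(depth):
        nxt = set()
        for p, descended in frontier:
            steps = {(c, True) for c in kg.children_of.get(p, set())}
            if not descended:
                steps |= {(q, False) for q in (kg.mother_of.get(p),
                                               kg.father_of.get(p)) if q}
            nxt |= steps - seen
        seen |= nxt
        frontier = nxt
        found |= {p for p, _ in nxt}
    sibs = kg.siblings(index)
    sib_kids = set().union(*(kg.children_of.get(s, set()) for s in sibs)) if sibs else set()
    return frozenset(found - {parent, index} - sibs - sib_kids)


def kin_sets(pid, kg: KinGraph, at_date, depth: int = 3) -> dict:
    """The five kin sets of one person at a date; see module docstring."""
    key = (pid, depth)
    if key in kg._kin_cache:
        maternal, paternal = kg._kin_cache[key]
    else:
        maternal = _side_kin(kg, pid, kg.mother_of.get(pid), depth)
        paternal = _side_kin(kg, pid, kg.father_of.get(pid), depth)
        kg._kin_cache[key] = (maternal, paternal)
    sibs = kg.siblings(pid)
    sisters18 = {s for s in sibs if kg.sex.get(s) == "female"
                 and (a := kg.age(s, at_date)) == a and a >= 18}
    brothers18 = {s for s in sibs if kg.sex.get(s) == "male"
                  and (a := kg.age(s, at_date)) == a and a >= 18}

    def fam(core):
        out = set(core)
        for s in core:
            out |= kg.spouses_at(s, at_date)
            out |= kg.children_of.get(s, set())
        return out

    nuclear = {p for p in (kg.mother_of.get(pid), kg.father_of.get(pid)) if p}
    nuclear |= {s for s in sibs if (a := kg.age(s, at_date)) == a and a < 18}
    return {"maternal": set(maternal), "paternal": set(paternal),
            "sisters_fam": fam(sisters18), "brothers_fam": fam(brothers18),
            "nuclear": nuclear}


def _fathers_other_wives(pid, kg: KinGraph, at_date) -> set:
    father = kg.father_of.get(pid)
    if father is None:
        return set()
    wives = kg.spouses_at(father, at_date)
    wives.discard(kg.mother_of.get(pid))
    return wives


def classify_household_composition(pid, roster, kg: KinGraph, at_date,
                                   external: bool = False,
                                   sets: dict | None = None) -> str:
    """Assign the household-composition category by the documented cascade.

    The category bullets are not mutually exclusive; precedence is: no_ids,
    external, spouse, sister's/brother's family (strict majority tie-break),
    mother & siblings, father & stepmother, maternal/paternal (strict
    majorities), parents & siblings, other.  The cascade is total: every
    (index, roster) pair receives exactly one category.
    """
    if not kg.has_parent_ids(pid):
        return "no_ids"
    if external:
        return "external"
    roster = set(roster) - {pid}
    if kg.spouses_at(pid, at_date) & roster:
        return "spouse"
    if sets is None:
        sets = kin_sets(pid, kg, at_date)
    mother = kg.mother_of.get(pid)
    father = kg.father_of.get(pid)
    mother_here = mother in roster
    father_here = father in roster
    other_wives_here = bool(_fathers_other_wives(pid, kg, at_date) & roster)
    n_mat = len(sets["maternal"] & roster)
    n_pat = len(sets["paternal"] & roster)
    n_sis = len(sets["sisters_fam"] & roster)
    n_bro = len(sets["brothers_fam"] & roster)
    parent_or_no_side_kin = (mother_here or father_here
                             or (n_mat == 0 and n_pat == 0))
    if n_sis >= 1 and (n_bro == 0 or n_sis > n_bro) and parent_or_no_side_kin:
        return "sisters_family"
    if n_bro >= 1 and (n_sis == 0 or n_bro > n_sis) and parent_or_no_side_kin:
        return "brothers_family"
    if mother_here and not father_here and not other_wives_here and n_mat == 0:
        return "mother_siblings"
    if not mother_here and (father_here or other_wives_here):
        return "father_stepmother"
    if not father_here and not other_wives_here and n_mat >= 1 and n_mat > n_pat:
        return "maternal"
    if not mother_here and not other_wives_here and n_pat >= 1 and n_pat > n_mat:
        return "paternal"
    if mother_here and father_here:
        return "parents_siblings"
    return "other"


def nearby_family_flags(pid, kg: KinGraph, at_date, locations: dict,
                        radius_m: float = 250.0,
                        sets: dict | None = None) -> dict:
    """Five flags: >= 1 member of the kin set within ``radius_m`` (inclusive)
    in a different household at the quarter.  ``locations`` maps person_id ->
    (unique_household_id, lon, lat) for co-temporal residents."""
    if sets is None:
        sets = kin_sets(pid, kg, at_date)
    here = locations.get(pid)
    out = {}
    for name, key in (("nearby_maternal", "maternal"), ("nearby_paternal", "paternal"),
                      ("nearby_sisters", "sisters_fam"), ("nearby_brothers", "brothers_fam"),
                      ("nearby_nuclear", "nuclear")):
        flag = False
        if here is not None:
            for m in sets[key]:
                loc = locations.get(m)
                if loc is None or loc[0] == here[0]:
                    continue
                if great_circle_km(here[1], here[2], loc[1], loc[2]) * 1000.0 <= radius_m:
                    flag = True
                    break
        out[name] = flag
    return out


def household_age_counts(ages) -> tuple:
    """Counts per age band (<1, 1-4, 5-11, 12-18, 19-29, 30-59, 60+),
    half-open boundaries; the caller passes roster ages (index excluded)."""
    ages = [a for a in ages if a == a]  # drop unknown birth dates
    hist, _ = np.histogram(ages, bins=AGE_BANDS)
    return tuple(int(x) for x in hist)


def build_family_context(panel: pd.DataFrame, kg: KinGraph,
                         radius_m: float = 250.0) -> pd.DataFrame:
    """FamilyContext rows for every panel record: composition category, five
    nearby-kin flags and seven household age-band counts."""
    records = []
    for q, sub in panel.groupby("quarter_date", sort=True):
        locations = {r.person_id: (r.unique_household_id, r.lon, r.lat)
                     for r in sub.itertuples()}
        for r in sub.itertuples():
            roster = set(r.roster.split(";")) if r.roster else set()
            sets = kin_sets(r.person_id, kg, q)
            comp = classify_household_composition(r.person_id, roster, kg, q,
                                                  sets=sets)
            flags = nearby_family_flags(r.person_id, kg, q, locations,
                                        radius_m=radius_m, sets=sets)
            ages = [kg.age(m, q) for m in roster]
            counts = household_age_counts(ages)
            records.append({"person_id": r.person_id, "quarter_date": q,
                            "composition": comp, **flags,
                            **dict(zip(AGE_BAND_LABELS, counts))})
    cols = (["person_id", "quarter_date", "composition", "nearby_maternal",
             "nearby_paternal", "nearby_sisters", "nearby_brothers",
             "nearby_nuclear"] + list(AGE_BAND_LABELS))
    return pd.DataFrame(records, columns=cols)
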