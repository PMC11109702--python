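"""Kinship graph, kin sets, composition cascade and proximity flags.

The cascade is checked against `oracle_classify`, an independent declarative
re-implementation of the category rules built on brute-force pedigree
traversal (BFS over an adjacency list rebuilt from the persons table).
"""

from collections import deque

import numpy as np
import pandas as pd
import pytest

from hdssmig.family import (build_kin_graph, classify_household_composition,
                            household_age_counts, kin_sets,
                            nearby_family_flags)
from hdssmig.register import DataIntegrityError

from conftest import make_register, person

Q = pd.Timestamp("2010-02-15")


# --------------------------------------------------------------------------
# independent oracle
# --------------------------------------------------------------------------

def _pedigree_maps(persons: pd.DataFrame):
    mother = {r.person_id: r.mother_id for r in persons.itertuples()
              if pd.notna(r.mother_id)}
    father = {r.person_id: r.father_id for r in persons.itertuples()
              if pd.notna(r.father_id)}
    kids = {}
    for child, par in list(mother.items()) + list(father.items()):
        kids.setdefault(par, set()).add(child)
    return mother, father, kids


def _bfs_blood(start, depth, mother, father, kids):
    """Blood kin of ``start`` within ``depth`` edges, by common-ancestor
    enumeration: climb to every ancestor, then walk down its descendants."""
    ancestors = {start: 0}
    dq = deque([start])
    while dq:
        p = dq.popleft()
        if ancestors[p] == depth:
            continue
        for d in (mother, father):
            if p in d and d[p] not in ancestors:
                ancestors[d[p]] = ancestors[p] + 1
                dq.append(d[p])
    out = {}
    for anc, up in ancestors.items():
        desc = {anc: up}
        dq = deque([anc])
        while dq:
            p = dq.popleft()
            if desc[p] == depth:
                continue
            for c in kids.get(p, set()):
                if c not in desc:
                    desc[c] = desc[p] + 1
                    dq.append(c)
        for q, d in desc.items():
            out[q] = min(out.get(q, depth + 1), d)
    out.pop(start, None)
    return set(out)


def oracle_kin_sets(pid, persons, marriages, at_date, depth=3):
    mother, father, kids = _pedigree_maps(persons)
    sex = dict(zip(persons["person_id"], persons["sex"]))
    birth = dict(zip(persons["person_id"], persons["birth_date"]))

    def age(p):
        b = birth.get(p)
        return np.nan if pd.isna(b) else (at_date - b).days / 365.25

    def spouses(p):
        out = set()
        for r in marriages.itertuples():
            if r.start_date <= at_date and (pd.isna(r.end_date) or r.end_date > at_date):
                if r.husband_id == p:
                    out.add(r.wife_id)
                if r.wife_id == p:
                    out.add(r.husband_id)
        return out

    sibs = set()
    for d in (mother, father):
        if pid in d:
            sibs |= kids.get(d[pid], set())
    sibs.discard(pid)
    sib_kids = set()
    for s in sibs:
        sib_kids |= kids.get(s, set())

    def side(par_map):
        if pid not in par_map:
            return set()
        p = par_map[pid]
        return _bfs_blood(p, depth, mother, father, kids) - {p, pid} - sibs - sib_kids

    def sib_family(want_sex):
        core = {s for s in sibs if sex.get(s) == want_sex
                and age(s) == age(s) and age(s) >= 18}
        out = set(core)
        for s in core:
            out |= spouses(s)
            out |= kids.get(s, set())
        return out

    nuclear = {par_map[pid] for par_map in (mother, father) if pid in par_map}
    nuclear |= {s for s in sibs if age(s) == age(s) and age(s) < 18}
    return {"maternal": side(mother), "paternal": side(father),
            "sisters_fam": sib_family("female"),
            "brothers_fam": sib_family("male"), "nuclear": nuclear,
            "_spouses": spouses(pid), "_mother": mother.get(pid),
            "_father": father.get(pid),
            "_other_wives": (spouses(father[pid]) - {mother.get(pid)}
                             if pid in father else set())}


def oracle_classify(pid, roster, persons, marriages, at_date):
    s = oracle_kin_sets(pid, persons, marriages, at_date)
    if s["_mother"] is None and s["_father"] is None:
        return "no_ids"
    roster = set(roster) - {pid}
    if s["_spouses"] & roster:
        return "spouse"
    mom = s["_mother"] in roster
    dad = s["_father"] in roster
    stepmom = bool(s["_other_wives"] & roster)
    n_mat, n_pat = len(s["maternal"] & roster), len(s["paternal"] & roster)
    n_sis, n_bro = len(s["sisters_fam"] & roster), len(s["brothers_fam"] & roster)
    anchored = mom or dad or (n_mat == 0 and n_pat == 0)
    if n_sis >= 1 and (n_bro == 0 or n_sis > n_bro) and anchored:
        return "sisters_family"
    if n_bro >= 1 and (n_sis == 0 or n_bro > n_sis) and anchored:
        return "brothers_family"
    if mom and not dad and not stepmom and n_mat == 0:
        return "mother_siblings"
    if not mom and (dad or stepmom):
        return "father_stepmother"
    if not dad and not stepmom and n_mat >= 1 and n_mat > n_pat:
        return "maternal"
    if not mom and not stepmom and n_pat >= 1 and n_pat > n_mat:
        return "paternal"
    if mom and dad:
        return "parents_siblings"
    return "other"


# --------------------------------------------------------------------------
# explicit pedigree fixture
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def pedigree():
    rows = [
        person("MGM", "female", "1950-01-01"),
        person("MGF", "male", "1948-01-01"),
        person("M", "female", "1975-01-01", mother="MGM", father="MGF"),
        person("A", "female", "1978-01-01", mother="MGM", father="MGF"),
        person("C2", "male", "2000-01-01", mother="A"),
        person("F", "male", "1972-01-01"),
        person("X", "female", "2000-06-01", mother="M", father="F"),
        person("S1", "female", "1990-06-01", mother="M", father="F"),
        person("S2", "female", "1992-06-01", mother="M", father="F"),
        person("B", "male", "1989-06-01", mother="M", father="F"),
        person("SH", "male", "1988-01-01"),
        person("SC", "female", "2008-01-01", mother="S1", father="SH"),
        person("W2", "female", "1980-01-01"),
    ]
    marriages = [
        {"marriage_id": "M1", "husband_id": "SH", "wife_id": "S1",
         "start_date": "2007-01-01", "end_date": None},
        {"marriage_id": "M2", "husband_id": "F", "wife_id": "W2",
         "start_date": "2005-01-01", "end_date": None},
    ]
    reg = make_register(persons=rows, marriages=marriages, validate=False)
    return build_kin_graph(reg.persons, reg.marriages), reg


def test_siblings_and_parent_flags(pedigree):
    kg, _ = pedigree
    assert kg.siblings("X") == {"S1", "S2", "B"}
    assert kg.has_parent_ids("X")
    assert not kg.has_parent_ids("MGM")


def test_kin_sets_match_definitions(pedigree):
    kg, _ = pedigree
    s = kin_sets("X", kg, Q)  # X is 9.7; S1 19.7; S2 17.7; B 20.7
    assert s["maternal"] == {"MGM", "MGF", "A", "C2"}  # mother excluded
    assert s["paternal"] == set()
    assert s["sisters_fam"] == {"S1", "SH", "SC"}
    assert s["brothers_fam"] == {"B"}
    # S2 is under 18: nuclear, not sister's family
    assert s["nuclear"] == {"M", "F", "S2"}


def test_kin_sets_match_bruteforce_oracle(pedigree, small_register):
    kg, reg = pedigree
    for pid in ("X", "S1", "C2", "SC"):
        mine = kin_sets(pid, kg, Q)
        theirs = oracle_kin_sets(pid, reg.persons, reg.marriages, Q)
        for key in ("maternal", "paternal", "sisters_fam", "brothers_fam",
                    "nuclear"):
            assert mine[key] == theirs[key], (pid, key)
    # and on a simulated pedigree
    kg2 = build_kin_graph(small_register.persons, small_register.marriages)
    rng = np.random.default_rng(1)
    pids = rng.choice(small_register.persons["person_id"], size=40, replace=False)
    for pid in pids:
        mine = kin_sets(pid, kg2, Q)
        theirs = oracle_kin_sets(pid, small_register.persons,
                                 small_register.marriages, Q)
        for key in ("maternal", "paternal", "sisters_fam", "brothers_fam",
                    "nuclear"):
            assert mine[key] == theirs[key], (pid, key)


class TestCompositionRules:
    def test_both_parents_plus_minor_sibling(self, pedigree):
        kg, _ = pedigree
        assert classify_household_composition(
            "X", {"M", "F", "S2"}, kg, Q) == "parents_siblings"

    def test_mother_and_siblings(self, pedigree):
        kg, _ = pedigree
        assert classify_household_composition(
            "X", {"M", "S2"}, kg, Q) == "mother_siblings"

    def test_equal_kin_majorities_fall_through_to_other(self):
        rows = [person("X", "female", "2000-01-01", mother="M", father="F"),
                person("M", "female", "1975-01-01", mother="MGM"),
                person("F", "male", "1972-01-01", mother="PGM"),
                person("MGM", "female", "1950-01-01"),
                person("PGM", "female", "1949-01-01"),
                person("MA", "male", "1977-01-01", mother="MGM"),
                person("PA", "male", "1974-01-01", mother="PGM")]
        reg = make_register(persons=rows, validate=False)
        kg = build_kin_graph(reg.persons, reg.marriages)
        # two maternal (MGM, MA) vs two paternal (PGM, PA), no parents
        assert classify_household_composition(
            "X", {"MGM", "MA", "PGM", "PA"}, kg, Q) == "other"

    def test_spouse_dominates(self, pedigree):
        kg, _ = pedigree
        assert classify_household_composition(
            "S1", {"SH", "SC", "M", "F"}, kg, Q) == "spouse"

    def test_fathers_other_wife_is_stepmother(self, pedigree):
        kg, _ = pedigree
        assert classify_household_composition(
            "X", {"W2", "S2"}, kg, Q) == "father_stepmother"

    def test_no_parent_ids(self, pedigree):
        kg, _ = pedigree
        assert classify_household_composition("MGM", {"M"}, kg, Q) == "no_ids"

    def test_external_household(self, pedigree):
        kg, _ = pedigree
        assert classify_household_composition(
            "X", {"M"}, kg, Q, external=True) == "external"


def test_cascade_totality_and_oracle_equivalence(small_register):
    """Fuzz: random rosters never raise and always match the oracle."""
    persons = small_register.persons
    kg = build_kin_graph(persons, small_register.marriages)
    rng = np.random.default_rng(7)
    ids = persons["person_id"].to_numpy()
    for _ in range(2000):
        pid = str(rng.choice(ids))
        roster = set(rng.choice(ids, size=int(rng.integers(0, 8)), replace=False))
        got = classify_household_composition(pid, roster, kg, Q)
        want = oracle_classify(pid, roster, persons, small_register.marriages, Q)
        assert got == want, (pid, sorted(roster))


class TestNearbyFlags:
    def _locs(self, **kw):
        return dict(kw)

    def test_same_household_member_does_not_count(self, pedigree):
        kg, _ = pedigree
        locs = {"X": ("H1", 33.9, -9.9), "A": ("H1", 33.9, -9.9)}
        flags = nearby_family_flags("X", kg, Q, locs)
        assert not flags["nearby_maternal"]

    def test_brother_100m_away_counts(self, pedigree):
        kg, _ = pedigree
        locs = {"X": ("H1", 33.9, -9.9), "B": ("H2", 33.9, -9.9009)}
        flags = nearby_family_flags("X", kg, Q, locs)
        assert flags["nearby_brothers"]
        assert not flags["nearby_maternal"]

    def test_grid_fixture_matches_bruteforce(self, small_register):
        from hdssmig.geo import great_circle_km

        persons = small_register.persons
        kg = build_kin_graph(persons, small_register.marriages)
        rng = np.random.default_rng(5)
        ids = list(persons["person_id"])
        locs = {}
        for i, pid in enumerate(ids):
            locs[pid] = (f"H{i % 40}", 33.9 + (i % 12) * 0.001,
                         -9.9 + (i // 12) * 0.001)
        for pid in rng.choice(ids, size=30, replace=False):
            flags = nearby_family_flags(pid, kg, Q, locs)
            sets = oracle_kin_sets(pid, persons, small_register.marriages, Q)
            here = locs[pid]
            for name, key in (("nearby_maternal", "maternal"),
                              ("nearby_paternal", "paternal"),
                              ("nearby_sisters", "sisters_fam"),
                              ("nearby_brothers", "brothers_fam"),
                              ("nearby_nuclear", "nuclear")):
                brute = any(
                    locs[m][0] != here[0]
                    and great_circle_km(here[1], here[2],
                                        locs[m][1], locs[m][2]) <= 0.250
                    for m in sets[key] if m in locs)
                assert flags[name] == brute, (pid, name)

    def test_radius_monotonicity(self, pedigree):
        kg, _ = pedigree
        locs = {"X": ("H1", 33.9, -9.9), "B": ("H2", 33.9, -9.9020),
                "A": ("H3", 33.91, -9.9)}
        small = nearby_family_flags("X", kg, Q, locs, radius_m=100)
        large = nearby_family_flags("X", kg, Q, locs, radius_m=2000)
        for k, v in small.items():
            assert large[k] or not v


class TestAgeCounts:
    def test_example_roster(self):
        assert household_age_counts([0.5, 3, 25, 61]) == (1, 1, 0, 0, 1, 0, 1)

    def test_empty_roster(self):
        assert household_age_counts([]) == (0, 0, 0, 0, 0, 0, 0)

    def test_age_19_in_19_29_band(self):
        assert household_age_counts([19.0]) == (0, 0, 0, 0, 1, 0, 0)

    def test_counts_sum_to_roster_size(self, small_family_context, small_panel):
        from hdssmig.family import AGE_BAND_LABELS

        merged = small_panel.merge(small_family_context,
                                   on=["person_id", "quarter_date"])
        roster_sizes = merged["roster"].map(
            lambda r: len(r.split(";")) if r else 0)
        sums = merged[list(AGE_BAND_LABELS)].sum(axis=1)
        assert (sums == roster_sizes).all()


def test_cyclic_parentage_raises():
    rows = [person("A", "female", "1980-01-01", mother="B"),
            person("B", "female", "1981-01-01", mother="A")]
    reg = make_register(persons=rows, validate=False)
    with pytest.raises(DataIntegrityError, match="cyclic"):
        build_kin_graph(reg.persons, reg.marriages)


def test_wrong_sex_parent_edge_raises():
    rows = [person("A", "male", "1980-01-01"),
            person("B", "female", "2000-01-01", mother="A")]
    reg = make_register(persons=rows, validate=False)
    with pytest.raises(DataIntegrityError, match="mother"):
        build_kin_graph(reg.persons, reg.marriages)
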