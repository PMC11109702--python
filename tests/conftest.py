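"""Shared fixtures: seeded synthetic registers and a scripted-register builder."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hdssmig import Register, SimConfig, simulate_register
from hdssmig.register import empty_tables
from hdssmig.synthetic import load_default_gazetteer

NAT = pd.NaT


def make_register(persons=(), households=(), spells=(), episodes=(),
                  surveys=(), marriages=(), period=("2004-01-01", "2017-12-31"),
                  validate=True) -> Register:
    """Build a register from literal row dicts; dates may be ISO strings."""
    tabs = empty_tables()

    def frame(rows, name):
        if not rows:
            return tabs[name]
        df = pd.DataFrame(list(rows))
        for col in tabs[name].columns:
            if col not in df:
                df[col] = None
        df = df[list(tabs[name].columns)]
        for col in df.columns:
            if col.endswith("_date") or col.startswith("valid_"):
                df[col] = pd.to_datetime(df[col])
        return df

    eps = frame(episodes, "episodes")
    if len(eps):
        eps["polygynous"] = eps["polygynous"].fillna(False).astype(bool)
    sv = frame(surveys, "surveys")
    if len(sv):
        sv["in_primary"] = sv["in_primary"].fillna(False).astype(bool)
    reg = Register(
        persons=frame(persons, "persons"),
        households=frame(households, "households"),
        geo_spells=frame(spells, "geo_spells"),
        episodes=eps,
        surveys=sv,
        marriages=frame(marriages, "marriages"),
        gazetteer=load_default_gazetteer(),
        period_start=pd.Timestamp(period[0]).date(),
        period_end=pd.Timestamp(period[1]).date(),
    )
    return reg.validate() if validate else reg


def person(pid, sex="female", birth="1990-01-01", mother=None, father=None,
           death=None, edu=False):
    return {"person_id": pid, "sex": sex, "birth_date": birth,
            "mother_id": mother, "father_id": father, "death_date": death,
            "secondary_edu": edu}


def household(hid, head, rank="medium", tarmac=1.0):
    return {"unique_household_id": hid, "head_id": head,
            "head_employment_rank": rank, "dist_tarmac_km": tarmac}


def spell(hid, gid, lon, lat, start="2004-01-01", end=None):
    return {"unique_household_id": hid, "geo_household_id": gid, "lon": lon,
            "lat": lat, "valid_from": start, "valid_to": end}


def episode(pid, hid, start="2004-01-01", end=None, sr="enumeration",
            er="censor", place=None, poly=False):
    return {"person_id": pid, "unique_household_id": hid, "start_date": start,
            "end_date": end, "start_reason": sr, "end_reason": er,
            "external_place": place, "polygynous": poly}


@pytest.fixture(scope="session")
def small_register() -> Register:
    return simulate_register(SimConfig(seed=11, n_founder_households=30))


@pytest.fixture(scope="session")
def small_panel(small_register):
    from hdssmig.panel import build_panel

    return build_panel(small_register)


@pytest.fixture(scope="session")
def small_moves(small_register, small_panel):
    from hdssmig.moves import apply_typology, detect_moves

    return apply_typology(detect_moves(small_panel, small_register, seed=5))


@pytest.fixture(scope="session")
def small_kin_graph(small_register):
    from hdssmig.family import build_kin_graph

    return build_kin_graph(small_register.persons, small_register.marriages)


@pytest.fixture(scope="session")
def small_family_context(small_panel, small_kin_graph):
    from hdssmig.family import build_family_context

    return build_family_context(small_panel, small_kin_graph)


@pytest.fixture(scope="session")
def zero_hazard_register() -> Register:
    cfg = SimConfig(
        seed=4, n_founder_households=12,
        fertility_rate=[], mortality_rate=[],
        marriage_hazard={"female": [], "male": []},
        divorce_hazard=0.0, fostering_hazard={"female": [], "male": []},
        relocation_hazard=0.0, external_move_prob=0.0, return_hazard=0.0)
    return simulate_register(cfg)
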