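"""Descriptive machinery: age-sex risk curves, clustered sex comparisons,
sending/receiving composition flow tables (Sankey export) and
parent-accompaniment tables.

All interval estimates and p-values allow for clustering by unique
household ID and unique individual ID (two-way, see ``cluster``).
Printed percents are count/column-total ratios; `round_half_up` reproduces
one-decimal table rounding.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .cluster import clustered_proportion_ci, twoway_wald_sex_test
from .family import COMPOSITION_CATEGORIES
from .panel import assign_life_stage

PARENT_CATEGORIES = ("neither", "mother_only", "father_only", "both")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding as printed tables use (2.25 -> 2.3 at 1 dp)."""
    if x != x:
        return x
    factor = 10 ** ndigits
    return math.floor(x * factor + 0.5) / factor


def marginal_percents(counts) -> np.ndarray:
    """Percent share of each count in its column total (unrounded)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return np.full_like(counts, np.nan)
    return 100.0 * counts / total


def attach_outcomes(panel: pd.DataFrame, moves: pd.DataFrame) -> pd.DataFrame:
    """Panel with a five-level ``outcome`` column (none + four move types)."""
    out = panel.copy()
    if moves.empty or "move_type" not in moves:
        out["outcome"] = "none"
        return out
    typed = moves.dropna(subset=["move_type"])[
        ["person_id", "quarter_date", "move_type"]]
    out = out.merge(typed, on=["person_id", "quarter_date"], how="left")
    out["outcome"] = out["move_type"].fillna("none")
    return out.drop(columns=["move_type"])


def move_risk_by_age(panel: pd.DataFrame, moves: pd.DataFrame,
                     max_age: int = 34) -> pd.DataFrame:
    """Percent experiencing each move type per age year and sex, with
    two-way cluster-robust 95% CIs.  Empty denominators are omitted."""
    from .moves import MOVE_TYPES

    df = attach_outcomes(panel, moves)
    df = df[df["age_years"] < max_age + 1].copy()
    df["age"] = df["age_years"].astype(int)
    rows = []
    for (sex, age), sub in df.groupby(["sex", "age"], sort=True):
        for mt in MOVE_TYPES:
            y = (sub["outcome"] == mt).to_numpy()
            p, lo, hi = clustered_proportion_ci(
                y, sub["unique_household_id"], sub["person_id"])
            rows.append({"sex": sex, "move_type": mt, "age": age,
                         "n_movers": int(y.sum()), "n_at_risk": len(y),
                         "percent": 100 * p, "ci_lo": 100 * lo, "ci_hi": 100 * hi})
    return pd.DataFrame(rows)


def compare_proportions_by_sex(y, sex, hh, ind) -> dict:
    """Two-sided clustered Wald test that a proportion is equal by sex."""
    is_male = np.asarray(sex) == "male"
    return twoway_wald_sex_test(y, is_male, hh, ind)


def _move_strata(moves: pd.DataFrame, persons: pd.DataFrame) -> pd.DataFrame:
    m = moves.merge(persons[["person_id", "sex", "birth_date"]], on="person_id")
    m["age_years"] = (m["quarter_date"] - m["birth_date"]).dt.days / 365.25
    stages = [assign_life_stage(s, a) for s, a in zip(m["sex"], m["age_years"])]
    m["life_stage"] = [s for s, _ in stages]
    m["independence"] = np.where(m["accompanied"], "accompanied", "independent")
    return m.drop(columns=["birth_date"])


def build_flow_tables(moves: pd.DataFrame, family_context: pd.DataFrame,
                      persons: pd.DataFrame,
                      quarter_successor: dict | None = None) -> dict:
    """Sending -> receiving composition flows for short moves.

    Sending composition is the mover's category at the pre-move snapshot
    (``external`` for in-migrations); receiving is the category at the
    post-move snapshot (``external`` when there is no post-move record).
    Returns ``{"counts": ..., "percents": ..., "sankey": {stratum: json}}``;
    count matrices are stratified by life stage, sex and independence, and
    percent tables carry clustered CIs plus a by-sex Wald p-value.
    """
    short = moves[moves["move_type"].notna()
                  & moves["move_type"].astype(str).str.startswith("short")].copy()
    if short.empty:
        empty = pd.DataFrame(columns=["life_stage", "independence", "sex",
                                      "sending", "receiving", "n"])
        return {"counts": empty, "percents": pd.DataFrame(), "sankey": {},
                "moves": empty, "degenerate": True}
    short = _move_strata(short, persons)
    short = short[short["life_stage"].isin(["child", "adolescent"])]

    fc = family_context.set_index(["person_id", "quarter_date"])["composition"]
    if quarter_successor is None:
        qs = sorted(family_context["quarter_date"].unique())
        quarter_successor = {a: b for a, b in zip(qs[:-1], qs[1:])}

    def comp_at(pid, q):
        try:
            return fc.loc[(pid, q)]
        except KeyError:
            return "external"

    short["sending"] = [
        "external" if d == "in_migration" else comp_at(p, q)
        for p, q, d in zip(short["person_id"], short["quarter_date"], short["direction"])]
    short["receiving"] = [
        "external" if d == "out_migration" or q not in quarter_successor
        else comp_at(p, quarter_successor[q])
        for p, q, d in zip(short["person_id"], short["quarter_date"], short["direction"])]

    counts = (short.groupby(["life_stage", "independence", "sex",
                             "sending", "receiving"])
              .size().rename("n").reset_index())
    pct_rows = []
    for (stage, indep), sub in short.groupby(["life_stage", "independence"]):
        for side in ("sending", "receiving"):
            for cat in COMPOSITION_CATEGORIES:
                row = {"life_stage": stage, "independence": indep,
                       "side": side, "category": cat}
                for sex in ("female", "male"):
                    s = sub[sub["sex"] == sex]
                    y = (s[side] == cat).to_numpy()
                    hh = s["origin_uhid"].fillna(s["dest_uhid"]).fillna(s["person_id"])
                    p, lo, hi = clustered_proportion_ci(y, hh, s["person_id"])
                    row[f"n_{sex}"] = int(y.sum())
                    row[f"pct_{sex}"] = 100 * p
                    row[f"lo_{sex}"] = 100 * lo
                    row[f"hi_{sex}"] = 100 * hi
                y = (sub[side] == cat).to_numpy()
                hh = sub["origin_uhid"].fillna(sub["dest_uhid"]).fillna(sub["person_id"])
                test = compare_proportions_by_sex(y, sub["sex"], hh, sub["person_id"])
                row["p_sex"] = test["p"]
                pct_rows.append(row)
    percents = pd.DataFrame(pct_rows)

    sankey = {}
    for (stage, indep, sex), sub in counts.groupby(
            ["life_stage", "independence", "sex"]):
        sankey[f"{stage}_{sex}_{indep}"] = sankey_json(sub)
    return {"counts": counts, "percents": percents, "sankey": sankey,
            "moves": short}


def sankey_json(counts: pd.DataFrame) -> dict:
    """Nodes/links JSON for a sending -> receiving Sankey diagram."""
    send_cats = [c for c in COMPOSITION_CATEGORIES
                 if c in set(counts["sending"])]
    recv_cats = [c for c in COMPOSITION_CATEGORIES
                 if c in set(counts["receiving"])]
    nodes = [{"name": f"sending:{c}"} for c in send_cats]
    nodes += [{"name": f"receiving:{c}"} for c in recv_cats]
    s_idx = {c: i for i, c in enumerate(send_cats)}
    r_idx = {c: len(send_cats) + i for i, c in enumerate(recv_cats)}
    links = [{"source": s_idx[r.sending], "target": r_idx[r.receiving],
              "value": int(r.n)}
             for r in counts.itertuples()]
    return {"nodes": nodes, "links": links}


def classify_parent_accompaniment(co_movers, mother_id, father_id) -> str:
    ids = {m for m, _, _ in co_movers}
    with_mother = pd.notna(mother_id) and mother_id in ids
    with_father = pd.notna(father_id) and father_id in ids
    if with_mother and with_father:
        return "both"
    if with_mother:
        return "mother_only"
    if with_father:
        return "father_only"
    return "neither"


def parent_accompaniment(moves: pd.DataFrame, persons: pd.DataFrame) -> pd.DataFrame:
    """Accompanied moves classified by which parents are among co-movers,
    tabulated by stage, move length and sex with clustered CIs and sex
    p-values."""
    acc = moves[moves["accompanied"].astype(bool)
                & moves["move_type"].notna()].copy() if len(moves) else moves
    if acc.empty:
        return pd.DataFrame(columns=["life_stage", "length", "category",
                                     "n_female", "pct_female", "n_male",
                                     "pct_male", "p_sex"])
    acc = _move_strata(acc, persons)
    acc = acc[acc["life_stage"].isin(["child", "adolescent"])]
    par = persons.set_index("person_id")[["mother_id", "father_id"]]
    acc["parent_cat"] = [
        classify_parent_accompaniment(cm, par.loc[p, "mother_id"],
                                      par.loc[p, "father_id"])
        for p, cm in zip(acc["person_id"], acc["co_movers"])]
    acc["length"] = acc["distance_class"]
    rows = []
    for (stage, length), sub in acc.groupby(["life_stage", "length"]):
        for cat in PARENT_CATEGORIES:
            row = {"life_stage": stage, "length": length, "category": cat}
            for sex in ("female", "male"):
                s = sub[sub["sex"] == sex]
                y = (s["parent_cat"] == cat).to_numpy()
                hh = s["origin_uhid"].fillna(s["dest_uhid"]).fillna(s["person_id"])
                p, lo, hi = clustered_proportion_ci(y, hh, s["person_id"])
                row[f"n_{sex}"] = int(y.sum())
                row[f"pct_{sex}"] = 100 * p
                row[f"lo_{sex}"] = 100 * lo
                row[f"hi_{sex}"] = 100 * hi
            y = (sub["parent_cat"] == cat).to_numpy()
            hh = sub["origin_uhid"].fillna(sub["dest_uhid"]).fillna(sub["person_id"])
            test = compare_proportions_by_sex(y, sub["sex"], hh, sub["person_id"])
            row["p_sex"] = test["p"]
            rows.append(row)
    return pd.DataFrame(rows)
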