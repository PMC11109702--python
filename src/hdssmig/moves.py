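"""Move detection, distance classification and independence typing.

A move is detected between consecutive quarterly snapshots when (a) the
geographic household ID differs at the next snapshot, (b) an episode ends in
out-migration inside the quarter, or (c) an episode starts with in-migration
inside the quarter.  Candidate moves displacing under 5 m are dropped as
geo-ID reassignment artefacts; if several candidates attach to one
person-quarter exactly one is retained uniformly at random under the run
seed.  Moves are attributed to the earlier of the two bracketing snapshots
(exposure-quarter convention), so panel covariates are pre-move.

External displacements are anchored on gazetteer coordinates: the central
point of a Malawian town, or the point of a foreign country nearest to
Malawi.  Retained moves are classed short (< cutoff, default 4 km) or long,
and independent (no parent of any age, no adult >= 18 among co-movers) or
accompanied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import great_circle_km
from .register import DataIntegrityError, Register

_DAY = pd.Timedelta(days=1)

MOVE_TYPES = ("short_independent", "long_independent",
              "short_accompanied", "long_accompanied")


class UnresolvedPlaceError(KeyError):
    """External place label absent from the gazetteer."""


def normalise_place(label: str) -> str:
    return str(label).strip().casefold()


def resolve_external(label: str, gazetteer: pd.DataFrame) -> tuple[float, float]:
    """(lon, lat) anchor for an external place label (case-folded, trimmed)."""
    norm = normalise_place(label)
    m = gazetteer[gazetteer["label"].map(normalise_place) == norm]
    if m.empty:
        raise UnresolvedPlaceError(label)
    r = m.iloc[0]
    return float(r["lon"]), float(r["lat"])


def classify_move_type(distance_km: float, cutoff_km: float,
                       accompanied: bool) -> str | None:
    """Four-way type; None when the distance is unresolved (excluded rows)."""
    if distance_km != distance_km:  # NaN
        return None
    cls = "short" if distance_km < cutoff_km else "long"
    return f"{cls}_{'accompanied' if accompanied else 'independent'}"


def classify_independence(co_movers: list[tuple]) -> bool:
    """Accompanied iff any co-mover is a parent of the index (any age) or an
    adult aged >= 18.  ``co_movers`` holds (person_id, age_years, is_parent)
    tuples; an empty list means independent."""
    return any(is_parent or (age == age and age >= 18.0)
               for _, age, is_parent in co_movers)


def detect_moves(panel: pd.DataFrame, register: Register, seed: int = 0,
                 min_move_m: float = 5.0) -> pd.DataFrame:
    """Detect candidate moves and retain at most one per person-quarter.

    Returns an untyped move table (no distance class yet) with origin and
    destination geography, resolved displacement where possible, co-mover
    list, and the accompanied flag.  ``attrs['n_unresolved']`` counts moves
    whose external anchor could not be resolved; ``attrs['n_dropped_5m']``
    counts sub-threshold artefacts.
    """
    from .panel import quarter_dates

    snaps = quarter_dates(pd.Timestamp(register.period_start),
                          pd.Timestamp(register.period_end))
    if not snaps:
        return _empty_moves()
    snap_next = {q: snaps[i + 1] for i, q in enumerate(snaps[:-1])}
    pos = {q: i for i, q in enumerate(snaps)}
    gaz = register.gazetteer
    persons = register.persons.set_index("person_id")
    if not set(panel["person_id"]).issubset(persons.index):
        raise DataIntegrityError("panel person absent from register")

    prow = {(r.person_id, r.quarter_date): r for r in panel.itertuples()}
    eps = register.episodes[~register.episodes["polygynous"]]

    def quarter_of(d):
        """Largest snapshot strictly before d (the exposure quarter)."""
        i = int(np.searchsorted(np.asarray(snaps), np.datetime64(d), side="left")) - 1
        if i < 0 or i >= len(snaps) - 1:
            return None
        return snaps[i]

    # external episode events grouped for co-mover matching
    outs = eps[eps["end_reason"] == "out_migration"].copy()
    outs["q"] = outs["end_date"].map(quarter_of)
    outs["place_norm"] = outs["external_place"].map(normalise_place)
    ins = eps[eps["start_reason"] == "in_migration"].copy()
    ins["q"] = ins["start_date"].map(quarter_of)
    ins["place_norm"] = ins["external_place"].map(normalise_place)

    out_groups = outs.dropna(subset=["q"]).groupby(["q", "place_norm"])["person_id"] \
                     .apply(set).to_dict()
    in_groups = ins.dropna(subset=["q"]).groupby(
        ["q", "place_norm", "unique_household_id"])["person_id"].apply(set).to_dict()

    n_unresolved = 0
    candidates = []

    def parents(pid):
        r = persons.loc[pid]
        return {p for p in (r["mother_id"], r["father_id"]) if pd.notna(p)}

    def age_at(pid, when):
        b = persons.loc[pid, "birth_date"]
        return np.nan if pd.isna(b) else (when - b).days / 365.25

    def comover_tuples(index_pid, ids, when):
        par = parents(index_pid)
        return sorted((m, age_at(m, when), m in par) for m in ids)

    # (a) internal: geo ID change between consecutive snapshots
    panel_sorted = panel.sort_values(["person_id", "quarter_date"])
    for (pid), grp in panel_sorted.groupby("person_id", sort=True):
        rows = list(grp.itertuples())
        for a, b in zip(rows[:-1], rows[1:]):
            if snap_next.get(a.quarter_date) != b.quarter_date:
                continue
            if a.geo_household_id == b.geo_household_id:
                continue
            dist = great_circle_km(a.lon, a.lat, b.lon, b.lat)
            roster = set(a.roster.split(";")) if a.roster else set()
            movers = {m for m in roster
                      if (m, b.quarter_date) in prow
                      and prow[(m, b.quarter_date)].unique_household_id
                      == b.unique_household_id
                      and prow[(m, b.quarter_date)].geo_household_id
                      == b.geo_household_id}
            cm = comover_tuples(pid, movers, a.quarter_date)
            candidates.append({
                "person_id": pid, "quarter_date": a.quarter_date,
                "direction": "internal", "move_date": pd.NaT,
                "origin_geo": a.geo_household_id, "destination_geo": b.geo_household_id,
                "origin_uhid": a.unique_household_id,
                "dest_uhid": b.unique_household_id,
                "origin_lon": a.lon, "origin_lat": a.lat,
                "dest_lon": b.lon, "dest_lat": b.lat,
                "distance_km": dist, "co_movers": cm})

    # (b)/(c) boundary crossings from episodes
    for kind, df in (("out_migration", outs), ("in_migration", ins)):
        for r in df.itertuples():
            q = r.q
            if q is None:
                continue
            pid = r.person_id
            try:
                ext_lon, ext_lat = resolve_external(r.external_place, gaz)
            except UnresolvedPlaceError:
                ext_lon = ext_lat = np.nan
                n_unresolved += 1
            if kind == "out_migration":
                when = r.end_date
                g, lon, lat = _geo_near(register, r.unique_household_id, when)
                roster_ids = {m for m, h in _household_members(eps, r.unique_household_id,
                                                               when - _DAY)} - {pid}
                mates = out_groups.get((q, r.place_norm), set()) & roster_ids
                cm = comover_tuples(pid, mates, q)
                candidates.append({
                    "person_id": pid, "quarter_date": q,
                    "direction": "out_migration", "move_date": when,
                    "origin_geo": g, "destination_geo": r.external_place,
                    "origin_uhid": r.unique_household_id, "dest_uhid": None,
                    "origin_lon": lon, "origin_lat": lat,
                    "dest_lon": ext_lon, "dest_lat": ext_lat,
                    "distance_km": great_circle_km(lon, lat, ext_lon, ext_lat)
                    if ext_lon == ext_lon else np.nan,
                    "co_movers": cm})
            else:
                when = r.start_date
                g, lon, lat = _geo_near(register, r.unique_household_id, when,
                                        before=False)
                mates = in_groups.get((q, r.place_norm, r.unique_household_id),
                                      set()) - {pid}
                cm = comover_tuples(pid, mates, q)
                candidates.append({
                    "person_id": pid, "quarter_date": q,
                    "direction": "in_migration", "move_date": when,
                    "origin_geo": r.external_place, "destination_geo": g,
                    "origin_uhid": None, "dest_uhid": r.unique_household_id,
                    "origin_lon": ext_lon, "origin_lat": ext_lat,
                    "dest_lon": lon, "dest_lat": lat,
                    "distance_km": great_circle_km(ext_lon, ext_lat, lon, lat)
                    if ext_lon == ext_lon else np.nan,
                    "co_movers": cm})

    if not candidates:
        return _empty_moves()
    cand = pd.DataFrame(candidates)

    # sub-5 m artefacts are removed before the random draw, and only when the
    # displacement actually resolved
    drop = cand["distance_km"].notna() & (cand["distance_km"] < min_move_m / 1000.0)
    n_dropped = int(drop.sum())
    cand = cand[~drop]

    # one retained move per person-quarter, uniformly at random; draws are
    # consumed in (person_id, quarter) order for reproducibility
    rng = np.random.default_rng(seed)
    order = {"internal": 0, "in_migration": 1, "out_migration": 2}
    cand = cand.sort_values(
        ["person_id", "quarter_date", "direction"],
        key=lambda s: s.map(order) if s.name == "direction" else s,
        kind="stable").reset_index(drop=True)
    keep_idx = []
    for _, idx in cand.groupby(["person_id", "quarter_date"], sort=True).groups.items():
        idx = list(idx)
        keep_idx.append(idx[int(rng.integers(len(idx)))] if len(idx) > 1 else idx[0])
    moves = cand.loc[sorted(keep_idx)].reset_index(drop=True)

    moves["accompanied"] = [classify_independence(cm) for cm in moves["co_movers"]]
    moves["n_co_movers"] = [len(cm) for cm in moves["co_movers"]]
    moves["unresolved"] = moves["distance_km"].isna()
    moves.attrs["n_unresolved"] = n_unresolved
    moves.attrs["n_dropped_5m"] = n_dropped
    return moves


def _empty_moves() -> pd.DataFrame:
    cols = ["person_id", "quarter_date", "direction", "move_date", "origin_geo",
            "destination_geo", "origin_uhid", "dest_uhid", "origin_lon",
            "origin_lat", "dest_lon", "dest_lat", "distance_km", "co_movers",
            "accompanied", "n_co_movers", "unresolved"]
    df = pd.DataFrame(columns=cols)
    df.attrs["n_unresolved"] = 0
    df.attrs["n_dropped_5m"] = 0
    return df


def _geo_near(register: Register, hid, when, before: bool = True):
    when = when - _DAY if before else when
    try:
        return register.geo_at(hid, when)
    except DataIntegrityError:
        return register.geo_at(hid, when + _DAY)


def _household_members(eps: pd.DataFrame, hid, when):
    m = eps[(eps["unique_household_id"] == hid) & (eps["start_date"] <= when)
            & (eps["end_date"].isna() | (eps["end_date"] > when))]
    return [(r.person_id, hid) for r in m.itertuples()]


def apply_typology(moves: pd.DataFrame, cutoff_km: float = 4.0) -> pd.DataFrame:
    """Attach distance_class and the four-way move_type.

    Unresolved-distance moves get NA in both and are excluded from
    distance-classified outputs; their count lands in
    ``attrs['n_unclassified']``.
    """
    out = moves.copy()
    if out.empty:
        out["distance_class"] = pd.Series(dtype="object")
        out["move_type"] = pd.Series(dtype="object")
        out.attrs["n_unclassified"] = 0
        return out
    types = [classify_move_type(d, cutoff_km, a)
             for d, a in zip(out["distance_km"], out["accompanied"])]
    out["move_type"] = types
    out["distance_class"] = [None if t is None else t.split("_")[0] for t in types]
    out.attrs.update(moves.attrs)
    out.attrs["n_unclassified"] = int(sum(t is None for t in types))
    return out


@dataclass
class CutoffDiagnostics:
    """School-change analysis behind the short/long distance cutoff."""

    n_pairs: int
    n_individuals: int
    n_same_school: int
    n_changed_school: int
    mean_km_same: float
    mean_km_changed: float
    ci_same: tuple
    ci_changed: tuple
    chosen_cutoff_km: float

    def to_dict(self) -> dict:
        return {"n_pairs": self.n_pairs, "n_individuals": self.n_individuals,
                "n_same_school": self.n_same_school,
                "n_changed_school": self.n_changed_school,
                "mean_km_same": self.mean_km_same,
                "mean_km_changed": self.mean_km_changed,
                "ci_same": list(self.ci_same), "ci_changed": list(self.ci_changed),
                "chosen_cutoff_km": self.chosen_cutoff_km}


def _cluster_mean_ci(x: np.ndarray, clusters: np.ndarray) -> tuple:
    """Mean with 95% CI, variance cluster-robust by individual."""
    n = len(x)
    if n == 0:
        return (np.nan, np.nan)
    mean = float(np.mean(x))
    resid = x - mean
    sums = pd.Series(resid).groupby(pd.Series(clusters)).sum().to_numpy()
    se = float(np.sqrt(np.sum(sums ** 2)) / n)
    return (mean - 1.959963984540054 * se, mean + 1.959963984540054 * se)


def derive_distance_cutoff(surveys: pd.DataFrame, register: Register,
                           cutoff_km: float = 4.0) -> CutoffDiagnostics:
    """Compare distances moved by primary-school attenders who did or did not
    change school between consecutive annual interviews.

    Pairs are consecutive-year surveys of one person, both still in primary
    school, whose household geographic ID differs between the two interview
    dates.  The chosen cutoff is a configured constant (default 4 km),
    reported alongside the diagnostics rather than estimated from them.
    """
    eps = register.episodes[~register.episodes["polygynous"]]

    def household_at(pid, when):
        m = eps[(eps["person_id"] == pid) & (eps["start_date"] <= when)
                & (eps["end_date"].isna() | (eps["end_date"] > when))]
        if m.empty:
            return None
        return m.iloc[0]["unique_household_id"]

    sv = surveys[surveys["in_primary"].astype(bool)].sort_values(
        ["person_id", "survey_date"])
    dists, changed, people = [], [], []
    for pid, grp in sv.groupby("person_id", sort=True):
        rows = list(grp.itertuples())
        for a, b in zip(rows[:-1], rows[1:]):
            if b.survey_date.year - a.survey_date.year != 1:
                continue
            ha = household_at(pid, a.survey_date)
            hb = household_at(pid, b.survey_date)
            if ha is None or hb is None:
                continue
            ga, lon_a, lat_a = register.geo_at(ha, a.survey_date)
            gb, lon_b, lat_b = register.geo_at(hb, b.survey_date)
            if ga == gb:
                continue
            dists.append(great_circle_km(lon_a, lat_a, lon_b, lat_b))
            changed.append(a.school_id != b.school_id)
            people.append(pid)
    dists = np.asarray(dists, dtype=float)
    changed = np.asarray(changed, dtype=bool)
    people = np.asarray(people, dtype=object)
    n_same = int((~changed).sum())
    n_changed = int(changed.sum())
    return CutoffDiagnostics(
        n_pairs=len(dists), n_individuals=len(set(people)),
        n_same_school=n_same, n_changed_school=n_changed,
        mean_km_same=float(dists[~changed].mean()) if n_same else np.nan,
        mean_km_changed=float(dists[changed].mean()) if n_changed else np.nan,
        ci_same=_cluster_mean_ci(dists[~changed], people[~changed]),
        ci_changed=_cluster_mean_ci(dists[changed], people[changed]),
        chosen_cutoff_km=cutoff_km)
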