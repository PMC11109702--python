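"""Move detection, distance computation, independence and typology."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from hdssmig import ground_truth_moves
from hdssmig.geo import great_circle_km
from hdssmig.moves import (CutoffDiagnostics, UnresolvedPlaceError,
                           apply_typology, classify_independence,
                           classify_move_type, derive_distance_cutoff,
                           detect_moves, resolve_external)
from hdssmig.panel import build_panel
from hdssmig.synthetic import load_default_gazetteer

from conftest import episode, household, make_register, person, spell


class TestGreatCircle:
    def test_identical_points_zero(self):
        assert great_circle_km(34.0, -10.0, 34.0, -10.0) == 0.0

    def test_meridian_arc_against_ellipsoidal_oracle(self):
        """WGS84 meridional-arc oracle: M(phi) * dphi; spherical haversine
        agrees within 0.6% at HDSS scale."""
        a, e2 = 6378.137, 0.00669437999014
        phi = math.radians(-10.0009)
        M = a * (1 - e2) / (1 - e2 * math.sin(phi) ** 2) ** 1.5
        oracle = M * math.radians(0.0018)
        d = great_circle_km(34.0, -10.0, 34.0, -10.0018)
        assert d == pytest.approx(0.2, abs=0.005)
        assert abs(d - oracle) / oracle < 0.006

    def test_symmetry_property(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            lon1, lon2 = rng.uniform(-180, 180, 2)
            lat1, lat2 = rng.uniform(-90, 90, 2)
            assert great_circle_km(lon1, lat1, lon2, lat2) == \
                pytest.approx(great_circle_km(lon2, lat2, lon1, lat1))

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            great_circle_km(200.0, 0.0, 0.0, 0.0)


class TestResolveExternal:
    def test_town_centre(self):
        gaz = load_default_gazetteer()
        lon, lat = resolve_external("Mzuzu", gaz)
        assert (lon, lat) == (34.02, -11.46)

    def test_foreign_border_point_and_normalisation(self):
        gaz = load_default_gazetteer()
        assert resolve_external("  tanzania ", gaz) == (33.95, -9.57)

    def test_unknown_label_raises(self):
        with pytest.raises(UnresolvedPlaceError):
            resolve_external("Atlantis", load_default_gazetteer())


class TestTypology:
    @pytest.mark.parametrize("dist,cutoff,acc,expected", [
        (3.999, 4.0, False, "short_independent"),
        (4.0, 4.0, True, "long_accompanied"),
        (0.006, 4.0, True, "short_accompanied"),
    ])
    def test_boundaries(self, dist, cutoff, acc, expected):
        assert classify_move_type(dist, cutoff, acc) == expected

    def test_unresolved_distance_unclassified(self):
        assert classify_move_type(float("nan"), 4.0, True) is None

    def test_monotone_in_distance(self):
        labels = [classify_move_type(d, 4.0, False)
                  for d in np.linspace(0.01, 10, 50)]
        flips = sum(a != b for a, b in zip(labels, labels[1:]))
        assert flips == 1


class TestIndependence:
    def test_parent_of_any_age_accompanies(self):
        assert classify_independence([("M", 34.0, True)]) is True
        assert classify_independence([("M", 17.0, True)]) is True  # young mother

    def test_minor_sibling_does_not(self):
        # the index's own age is irrelevant
        assert classify_independence([("S", 16.0, False)]) is False

    def test_unrelated_adult_accompanies(self):
        assert classify_independence([("A", 18.0, False)]) is True

    def test_empty_roster_is_independent(self):
        assert classify_independence([]) is False


def _two_household_register(dest_lon=33.95, dest_lat=-9.95, move="2010-06-01"):
    """P1 moves H1 -> H2 on ``move``; P2 stays in H1, P3 lives in H2."""
    return make_register(
        persons=[person("P1", "male", "1995-01-01"),
                 person("P2", "male", "1990-01-01"),
                 person("P3", "male", "1985-01-01")],
        households=[household("H1", "P2"), household("H2", "P3")],
        spells=[spell("H1", "G1", 33.90, -9.90),
                spell("H2", "G2", dest_lon, dest_lat)],
        episodes=[episode("P1", "H1", end=move, er="internal_move"),
                  episode("P1", "H2", start=move, sr="internal_move"),
                  episode("P2", "H1"), episode("P3", "H2")])


def test_no_move_without_geo_change():
    reg = make_register(
        persons=[person("P1", "male", "1995-01-01")],
        households=[household("H1", "P1")],
        spells=[spell("H1", "G1", 33.9, -9.9)],
        episodes=[episode("P1", "H1")])
    panel = build_panel(reg)
    assert detect_moves(panel, reg).empty


def test_internal_move_detected_at_exposure_quarter():
    reg = _two_household_register()
    panel = build_panel(reg)
    mv = detect_moves(panel, reg)
    assert len(mv) == 1
    r = mv.iloc[0]
    assert r["direction"] == "internal"
    assert r["quarter_date"] == pd.Timestamp("2010-05-15")  # pre-move snapshot
    assert r["origin_geo"] == "G1" and r["destination_geo"] == "G2"
    assert r["distance_km"] == pytest.approx(
        great_circle_km(33.90, -9.90, 33.95, -9.95))
    assert not r["accompanied"]  # P2 stayed; P3 was already at destination


def test_geo_id_reassignment_under_5m_is_dropped():
    """New geo ID at identical coordinates is a head-declaration artefact."""
    reg = make_register(
        persons=[person("P1", "male", "1995-01-01")],
        households=[household("H1", "P1")],
        spells=[spell("H1", "G1", 33.9, -9.9, end="2010-06-01"),
                spell("H1", "G2", 33.9, -9.9, start="2010-06-01")],
        episodes=[episode("P1", "H1", end="2010-06-01", er="internal_move"),
                  episode("P1", "H1", start="2010-06-01", sr="internal_move")])
    panel = build_panel(reg)
    mv = detect_moves(panel, reg)
    assert mv.empty
    assert mv.attrs["n_dropped_5m"] == 1


def test_household_relocation_is_accompanied():
    reg = make_register(
        persons=[person("P1", "female", "2000-01-01", mother="P2"),
                 person("P2", "female", "1980-01-01")],
        households=[household("H1", "P2")],
        spells=[spell("H1", "G1", 33.90, -9.90, end="2010-06-01"),
                spell("H1", "G2", 33.95, -9.95, start="2010-06-01")],
        episodes=[e for p in ("P1", "P2") for e in (
            episode(p, "H1", end="2010-06-01", er="internal_move"),
            episode(p, "H1", start="2010-06-01", sr="internal_move"))])
    panel = build_panel(reg)
    mv = detect_moves(panel, reg)
    assert len(mv) == 2
    child = mv[mv["person_id"] == "P1"].iloc[0]
    assert child["accompanied"]  # moves with an adult who is also her mother
    assert child["co_movers"][0][2] is True  # mother flagged as parent
    mother = mv[mv["person_id"] == "P2"].iloc[0]
    # the mother's only co-mover is her minor child: independent by definition
    assert not mother["accompanied"]


def _in_out_register():
    """P1 enters from Mzuzu and leaves for Karonga Town inside one quarter."""
    return make_register(
        persons=[person("P1", "male", "1995-01-01")],
        households=[household("H1", "P1")],
        spells=[spell("H1", "G1", 33.9, -9.9)],
        episodes=[episode("P1", "H1", start="2010-06-01", sr="in_migration",
                          end="2010-07-20", er="out_migration",
                          place="Karonga Town")])


def test_in_and_out_within_quarter_kept_randomly():
    """Both candidates attach to the same person-quarter; the retained one is
    the in-migration in about half of seeds (Monte-Carlo binomial check)."""
    reg = _in_out_register()
    # episode external_place holds the out-migration destination; the entry
    # source is carried by the same field at start in scripted form, so give
    # the in-migration its own episode label via a two-episode variant
    panel = build_panel(reg)
    kept = []
    for seed in range(400):
        mv = detect_moves(panel, reg, seed=seed)
        assert len(mv) == 1
        kept.append(mv.iloc[0]["direction"])
    n_in = kept.count("in_migration")
    assert binomtest(n_in, len(kept), 0.5).pvalue > 0.01


def test_random_keep_is_seed_deterministic():
    reg = _in_out_register()
    panel = build_panel(reg)
    a = detect_moves(panel, reg, seed=42)
    b = detect_moves(panel, reg, seed=42)
    pd.testing.assert_frame_equal(a, b)


def test_unknown_external_place_flagged_unresolved():
    reg = make_register(
        persons=[person("P1", "male", "1995-01-01")],
        households=[household("H1", "P1")],
        spells=[spell("H1", "G1", 33.9, -9.9)],
        episodes=[episode("P1", "H1", end="2010-07-20", er="out_migration",
                          place="Atlantis")])
    panel = build_panel(reg)
    mv = detect_moves(panel, reg)
    assert mv.attrs["n_unresolved"] == 1
    assert mv.iloc[0]["unresolved"]
    typed = apply_typology(mv)
    assert typed.iloc[0]["move_type"] is None
    assert typed.attrs["n_unclassified"] == 1


def test_detected_internal_moves_match_ground_truth(small_register, small_panel):
    """Snapshot-straddling ground-truth relocations are recovered; misses are
    only within-quarter round trips or merged multi-moves."""
    from hdssmig.panel import quarter_dates

    mv = detect_moves(small_panel, small_register, seed=1)
    gt = ground_truth_moves(small_register)
    snaps = quarter_dates(pd.Timestamp(small_register.period_start),
                          pd.Timestamp(small_register.period_end))
    detected = set(zip(mv["person_id"], mv["quarter_date"]))
    missed = 0
    straddling = 0
    grid = pd.Series(snaps)
    for ev in gt[gt["kind"] == "internal"].itertuples():
        before = grid[grid < ev.date]
        after = grid[grid >= ev.date]
        if before.empty or after.empty:
            continue
        q = before.iloc[-1]
        straddling += 1
        if (ev.person_id, q) not in detected:
            missed += 1
    assert straddling > 20
    # a miss needs an offsetting move inside the same quarter (round trip or
    # a retained competing candidate); such events are rare by construction
    assert missed / straddling < 0.25
    # and every detected internal move corresponds to a true event
    gt_keys = set()
    for ev in gt.itertuples():
        before = grid[grid < ev.date]
        if not before.empty:
            gt_keys.add((ev.person_id, before.iloc[-1]))
    assert all(k in gt_keys for k in detected)


def test_typology_partition(small_moves):
    resolved = small_moves[~small_moves["unresolved"]]
    assert resolved["move_type"].notna().all()
    assert set(resolved["move_type"]).issubset(
        {"short_independent", "long_independent",
         "short_accompanied", "long_accompanied"})
    agree = (resolved["move_type"]
             == resolved["distance_class"] + "_"
             + np.where(resolved["accompanied"], "accompanied", "independent"))
    assert agree.all()


class TestCutoffDerivation:
    def _survey(self, pid, date, school):
        return {"person_id": pid, "survey_date": date, "school_id": school,
                "grade": 3, "in_primary": True, "marital_status": "never",
                "spouse_ids": "", "mother_secondary_edu": False,
                "father_secondary_edu": False}

    def _register_with_pairs(self, n_same=3, n_changed=2):
        """Movers at ~1 km keeping their school; ~5 km movers changing it."""
        persons, households, spells, episodes, surveys = [], [], [], [], []
        deg_per_km = 1 / 110.574
        for i in range(n_same + n_changed):
            pid, h1, h2 = f"P{i}", f"HA{i}", f"HB{i}"
            far = i >= n_same
            dlat = (5.0 if far else 1.0) * deg_per_km
            persons.append(person(pid, "male", "1998-01-01"))
            households += [household(h1, pid), household(h2, pid)]
            spells += [spell(h1, f"GA{i}", 33.9, -9.9),
                       spell(h2, f"GB{i}", 33.9, -9.9 + dlat)]
            episodes += [episode(pid, h1, end="2008-01-01", er="internal_move"),
                         episode(pid, h2, start="2008-01-01", sr="internal_move")]
            surveys += [self._survey(pid, "2007-07-15", "S1"),
                        self._survey(pid, "2008-07-15", "S2" if far else "S1")]
        return make_register(persons=persons, households=households,
                             spells=spells, episodes=episodes, surveys=surveys)

    def test_forced_group_means(self):
        reg = self._register_with_pairs()
        diag = derive_distance_cutoff(reg.surveys, reg)
        assert (diag.n_pairs, diag.n_same_school, diag.n_changed_school) == (5, 3, 2)
        assert diag.mean_km_same == pytest.approx(1.0, abs=0.01)
        assert diag.mean_km_changed == pytest.approx(5.0, abs=0.05)
        assert diag.ci_same[0] <= diag.mean_km_same <= diag.ci_same[1]
        assert diag.chosen_cutoff_km == 4.0

    def test_all_same_school_leaves_changed_group_undefined(self):
        reg = self._register_with_pairs(n_same=4, n_changed=0)
        diag = derive_distance_cutoff(reg.surveys, reg)
        assert diag.n_changed_school == 0
        assert math.isnan(diag.mean_km_changed)
        assert diag.chosen_cutoff_km == 4.0  # no override

    def test_synthetic_mixture_recovers_generator_means(self, small_register):
        diag = derive_distance_cutoff(small_register.surveys, small_register)
        assert diag.n_pairs > 0
        # school is assigned by proximity, so school changers moved farther
        if diag.n_same_school and diag.n_changed_school:
            assert diag.mean_km_changed > diag.mean_km_same
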