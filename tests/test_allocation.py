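import datetime as dt

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from raptorcount import (
    allocate_day,
    daily_raw_totals,
    estimate_daily_species_totals,
)

DAY = dt.date(2015, 9, 1)


def test_daily_raw_totals_sums_and_splits(hierarchy, make_record):
    records = [
        make_record(species="HB", number=10),
        make_record(species="HB", number=5),
        make_record(species="MonPalHen", number=11),
        make_record(species="HB_JUV", number=7),  # age sample, not abundance
        make_record(species="HB", number=99, filter=0),  # outside filter set
    ]
    species_tbl, group_tbl = daily_raw_totals(records, hierarchy)
    assert species_tbl.loc[DAY, "HB"] == 15
    assert group_tbl.loc[DAY, "MonPalHen"] == 11
    assert "HB_JUV" not in species_tbl.columns


def test_allocate_day_single_group_split(hierarchy):
    """A 60/40 identified split propagates a group count 6/4."""
    species = pd.Series({"HB": 60.0, "StepBuz": 40.0})
    groups = pd.Series({"Buzzard_SPEC": 10.0})
    out, rest = allocate_day(DAY, species, groups, hierarchy)
    assert out["HB"] == pytest.approx(66.0)
    assert out["StepBuz"] == pytest.approx(44.0)
    assert rest == {}


def test_allocate_day_iterates_up_the_hierarchy(hierarchy):
    """The wider group is split using the already-augmented totals."""
    species = pd.Series({"HB": 60.0, "StepBuz": 40.0, "BlackKite": 10.0})
    groups = pd.Series({"Buzzard_SPEC": 10.0, "MediumRaptor": 12.0})
    out, rest = allocate_day(DAY, species, groups, hierarchy)
    assert out["HB"] == pytest.approx(72.6)
    assert out["StepBuz"] == pytest.approx(48.4)
    assert out["BlackKite"] == pytest.approx(11.0)
    assert rest == {}


def test_allocate_day_degenerate_pool_goes_to_sole_species(hierarchy):
    species = pd.Series({"Pal": 4.0})
    groups = pd.Series({"MonPalHen": 10.0})
    out, rest = allocate_day(DAY, species, groups, hierarchy)
    assert out["Pal"] == pytest.approx(14.0)
    assert out.get("Mon", 0.0) == 0.0
    assert out.get("Hen", 0.0) == 0.0


def test_empty_pool_season_fallback(hierarchy, make_record):
    """A day with only a group count borrows season-wide pool proportions."""
    d2 = DAY + dt.timedelta(days=1)
    season = pd.DataFrame(
        {"Mon": [30.0, 0.0], "Pal": [10.0, 0.0]}, index=[DAY, d2]
    )
    out, rest = allocate_day(
        d2, season.loc[d2], pd.Series({"MonPalHen": 8.0}), hierarchy,
        fallback="season_proportions", season_species_tbl=season,
    )
    assert out["Mon"] == pytest.approx(6.0)
    assert out["Pal"] == pytest.approx(2.0)
    assert rest == {}


def test_empty_pool_skip_reports_unallocated(hierarchy):
    out, rest = allocate_day(
        DAY, pd.Series(dtype=float), pd.Series({"MonPalHen": 8.0}),
        hierarchy, fallback="skip",
    )
    assert rest == {"MonPalHen": 8.0}


def test_empty_pool_equal_split(hierarchy):
    out, rest = allocate_day(
        DAY, pd.Series(dtype=float), pd.Series({"MonPalHen": 9.0}),
        hierarchy, fallback="equal_split",
    )
    assert out["Mon"] == pytest.approx(3.0)
    assert rest == {}


def test_estimate_totals_without_groups_is_identity(
    hierarchy, config, make_record
):
    records = [
        make_record(species="HB", number=10),
        make_record(species="Pal", number=2, age="juv"),
    ]
    table = estimate_daily_species_totals(records, config, hierarchy)
    pd.testing.assert_frame_equal(
        table.allocated[table.raw_identified.columns],
        table.raw_identified,
        check_names=False,
        check_dtype=False,
    )


def test_estimate_totals_matches_allocate_day(hierarchy, config, make_record):
    records = [
        make_record(species="HB", number=60),
        make_record(species="StepBuz", number=40),
        make_record(species="BlackKite", number=10),
        make_record(species="Buzzard_SPEC", number=10),
        make_record(species="MediumRaptor", number=12),
    ]
    table = estimate_daily_species_totals(records, config, hierarchy)
    assert table.allocated.loc[DAY, "HB"] == pytest.approx(72.6)
    assert table.raw_identified.loc[DAY, "HB"] == 60


# -- independent oracle: one sweep per hierarchy level --------------------

def _level_sweep_oracle(species, groups, hierarchy):
    """Allocate strictly level by level (deepest groups first), recomputing
    proportions after each whole level — an independent route to the same
    totals when no two groups share a level on intersecting pools."""
    running = dict(species)
    by_depth = {}
    for g, n in groups.items():
        if n > 0:
            by_depth.setdefault(hierarchy.group_depth(g), []).append((g, n))
    for depth in sorted(by_depth, reverse=True):
        adds = {}
        for g, n in by_depth[depth]:
            pool = hierarchy.pool(g)
            total = sum(running.get(s, 0.0) for s in pool)
            if total <= 0:
                continue
            for s in pool:
                adds[s] = adds.get(s, 0.0) + n * running.get(s, 0.0) / total
        for s, v in adds.items():
            running[s] = running.get(s, 0.0) + v
    return running


@given(data=st.data())
def test_allocation_conservation_and_oracle(hierarchy, data):
    """Conservation (species sum gains exactly the group total) and
    agreement with an independent level-by-level sweep."""
    hb = data.draw(st.integers(0, 100))
    sb = data.draw(st.integers(0, 100))
    bk = data.draw(st.integers(0, 100))
    mph = data.draw(st.integers(0, 50))
    pal = data.draw(st.integers(1, 50))
    groups = {
        "Buzzard_SPEC": data.draw(st.integers(0, 30)),
        "MediumRaptor": data.draw(st.integers(0, 30)),
        "MonPalHen": mph,
    }
    species = pd.Series(
        {"HB": float(hb), "StepBuz": float(sb), "BlackKite": float(bk),
         "Pal": float(pal)}
    )
    out, rest = allocate_day(
        DAY, species, pd.Series(groups, dtype=float), hierarchy,
        fallback="skip",
    )
    assert out.sum() == pytest.approx(species.sum() + sum(groups.values()) - sum(rest.values()))
    oracle = _level_sweep_oracle(species.to_dict(), groups, hierarchy)
    for code, value in oracle.items():
        assert out[code] == pytest.approx(value)


@given(extra=st.integers(0, 40))
def test_allocation_monotone_in_group_count(hierarchy, extra):
    """Raising a group count never lowers any species' allocation."""
    species = pd.Series({"HB": 30.0, "StepBuz": 10.0, "BlackKite": 5.0})
    base_groups = pd.Series({"Buzzard_SPEC": 10.0, "MediumRaptor": 7.0})
    more_groups = base_groups.copy()
    more_groups["MediumRaptor"] += extra
    base, _ = allocate_day(DAY, species, base_groups, hierarchy)
    more, _ = allocate_day(DAY, species, more_groups, hierarchy)
    assert (more >= base - 1e-9).all()
    assert (base >= species.reindex(base.index).fillna(0.0) - 1e-9).all()


def test_chain_widens_bottom_up(hierarchy):
    """A bird pool widens at each level of the chain: the nested group is
    shared with fewer species than the wider one."""
    species = pd.Series({"HB": 50.0, "StepBuz": 50.0, "BlackKite": 100.0})
    nested, _ = allocate_day(
        DAY, species, pd.Series({"Buzzard_SPEC": 10.0}), hierarchy
    )
    wide, _ = allocate_day(
        DAY, species, pd.Series({"MediumRaptor": 10.0}), hierarchy
    )
    # the nested group excludes kites entirely; the wide one includes them
    assert nested["BlackKite"] == pytest.approx(100.0)
    assert wide["BlackKite"] > 100.0
    assert nested["HB"] > wide["HB"]
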