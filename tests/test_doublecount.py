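import datetime as dt

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raptorcount import (
    apply_matches,
    detail_rank,
    is_candidate_pair,
    match_records,
    remove_double_counts,
)

DAY = dt.date(2015, 9, 1)


def pal_s1(make_record, **kw):
    base = dict(species="Pal", number=3, station=1, location="E2",
                time=dt.time(10, 0), age="juv", date=DAY)
    base.update(kw)
    return make_record(**base)


def mph_s2(make_record, **kw):
    base = dict(species="MonPalHen", number=11, station=2, location="W3",
                time=dt.time(10, 4), age=None, date=DAY)
    base.update(kw)
    return make_record(**base)


@pytest.mark.parametrize(
    "kwargs,rank",
    [
        (dict(species="Pal", age="juv"), 5),
        (dict(species="MonPalHen"), 0),
        (dict(species="HB"), 4),
        (dict(species="Buzzard_SPEC", age="juv"), 1),
        (dict(species="Mar", sex="f", age="ad"), 6),
        (dict(species="Mar", sex="m"), 5),
    ],
)
def test_detail_rank(hierarchy, make_record, kwargs, rank):
    assert detail_rank(make_record(**kwargs), hierarchy) == rank


def test_candidate_pair_worked_example(hierarchy, config, make_record):
    assert is_candidate_pair(
        pal_s1(make_record), mph_s2(make_record), config, hierarchy
    )


def test_candidate_pair_outside_window(hierarchy, config, make_record):
    late = mph_s2(make_record, time=dt.time(10, 25))
    assert not is_candidate_pair(pal_s1(make_record), late, config, hierarchy)


def test_candidate_pair_outside_overlap(hierarchy, config, make_record):
    west = pal_s1(make_record, location="W3")
    assert not is_candidate_pair(west, mph_s2(make_record), config, hierarchy)


def test_candidate_pair_same_station(hierarchy, config, make_record):
    a = pal_s1(make_record)
    b = pal_s1(make_record, time=dt.time(10, 2))
    assert not is_candidate_pair(a, b, config, hierarchy)


def test_single_count_flag_blocks_pair(hierarchy, config, make_record):
    flagged = pal_s1(make_record, remark="radio confirmed, single count")
    assert not is_candidate_pair(flagged, mph_s2(make_record), config, hierarchy)


def test_incompatible_taxa_not_paired(hierarchy, config, make_record):
    hb = pal_s1(make_record, species="HB", age=None)
    assert not is_candidate_pair(hb, mph_s2(make_record), config, hierarchy)


def test_large_species_wider_window(hierarchy, config, make_record):
    a = pal_s1(make_record, species="LesserSE", age="ad", location="E1")
    b = mph_s2(make_record, species="LargeEAGLE", time=dt.time(10, 13),
               location="W2")
    assert is_candidate_pair(a, b, config, hierarchy)  # 13 min < 15
    b_small_window = mph_s2(make_record, time=dt.time(10, 13))
    assert not is_candidate_pair(
        pal_s1(make_record), b_small_window, config, hierarchy
    )  # 13 min > 10 for a small species


def test_greedy_prefers_smaller_gap(hierarchy, config, make_record):
    a = pal_s1(make_record)
    near = mph_s2(make_record, time=dt.time(10, 3))
    far = mph_s2(make_record, time=dt.time(10, 7))
    (cand,) = match_records([a, near, far], config, hierarchy)
    assert cand.id_station2 == near.id
    assert cand.quantity == 3


def test_flagged_pair_reported_even_at_zero_quantity(
    hierarchy, config, make_record
):
    a = pal_s1(make_record)
    b = mph_s2(make_record, number=3)
    c = mph_s2(
        make_record, number=2, time=dt.time(10, 8),
        remark="double count with S1",
    )
    candidates = match_records([a, b, c], config, hierarchy)
    flagged = [cand for cand in candidates if cand.observer_flagged]
    assert flagged and flagged[0].quantity >= 0


def test_apply_worked_example(hierarchy, config, make_record):
    """Three aged Pallid Harriers kept; the group record loses three birds."""
    a, b = pal_s1(make_record), mph_s2(make_record)
    out, report = remove_double_counts([a, b], config, hierarchy)
    by_id = {r.id: r for r in out}
    assert by_id[a.id].number == 3
    assert by_id[b.id].number == 8
    assert by_id[a.id].dcremark == f"{b.id}:+3"
    assert by_id[b.id].dcremark == f"{a.id}:-3"
    assert report.n_individuals_removed == 3


def test_equal_pair_drops_the_lower_ranked(hierarchy, config, make_record):
    a = pal_s1(make_record, number=5)
    b = mph_s2(make_record, number=5)
    out, _ = remove_double_counts([a, b], config, hierarchy)
    assert [r.id for r in out] == [a.id]
    assert out[0].number == 5


def test_no_candidates_is_identity(hierarchy, config, make_record):
    records = [pal_s1(make_record), pal_s1(make_record, station=2,
                                           location="W3", date=DAY + dt.timedelta(1))]
    out, report = remove_double_counts(records, config, hierarchy)
    assert [(r.id, r.number) for r in out] == [(r.id, r.number) for r in records]
    assert report.n_individuals_removed == 0


def test_records_without_time_or_zone_are_skipped(hierarchy, config, make_record):
    a = pal_s1(make_record, time=None)
    b = mph_s2(make_record)
    report_out, report = remove_double_counts([a, b], config, hierarchy)
    assert report.skipped_no_time == [a.id]
    assert report.n_individuals_removed == 0


# -- randomized properties -------------------------------------------------

def _random_stream(draw, make_record):
    species = ["Pal", "Mon", "MonPalHen", "Harrier_SPEC", "Mar"]
    n = draw(st.integers(0, 8))
    recs = []
    for _ in range(n):
        recs.append(
            make_record(
                species=draw(st.sampled_from(species)),
                number=draw(st.integers(1, 6)),
                station=draw(st.sampled_from([1, 2])),
                location=draw(st.sampled_from(["E2", "E3", "W2", "W3", "O"])),
                time=dt.time(10, draw(st.integers(0, 59))),
                age=draw(st.sampled_from([None, "juv", "ad"])),
                date=DAY,
            )
        )
    return recs


@given(data=st.data())
def test_dedup_properties(hierarchy, config, make_record, data):
    """Totals never increase, removal is mirrored in dcremark pairs, and a
    second pass removes nothing."""
    records = _random_stream(data.draw, make_record)
    total_before = sum(r.number for r in records)
    out, report = remove_double_counts(records, config, hierarchy)
    total_after = sum(r.number for r in out)
    assert total_after <= total_before
    assert total_before - total_after == report.n_individuals_removed
    # every adjustment mirrored by a +q/-q dcremark pair
    by_id = {r.id: r for r in out}
    for kept, reduced, q in report.adjustments:
        assert f"{reduced}:+{q}" in by_id[kept].dcremark
        if reduced in by_id:
            assert f"{kept}:-{q}" in by_id[reduced].dcremark
    # idempotence
    out2, report2 = remove_double_counts(out, config, hierarchy)
    assert report2.n_individuals_removed == 0
    assert sum(r.number for r in out2) == total_after


def _max_removable(records, config, hierarchy):
    """Independent oracle: maximum jointly removable individuals as a max
    flow from station-1 records to station-2 records over candidate edges."""
    graph = nx.DiGraph()
    graph.add_node("s")
    graph.add_node("t")
    s1 = [r for r in records if r.station == 1]
    s2 = [r for r in records if r.station == 2]
    for r in s1:
        graph.add_edge("s", f"a{r.id}", capacity=r.number)
    for r in s2:
        graph.add_edge(f"b{r.id}", "t", capacity=r.number)
    for a in s1:
        for b in s2:
            if is_candidate_pair(a, b, config, hierarchy):
                graph.add_edge(f"a{a.id}", f"b{b.id}")
    return nx.maximum_flow_value(graph, "s", "t")


def test_greedy_matches_optimal_in_95_percent_of_cases(
    hierarchy, config, make_record
):
    """On small instances (<= 8 records) the greedy pass removes the same
    total quantity as an optimal matching oracle (max flow) in >= 95% of
    randomized cases, and never more."""
    import random

    rng = random.Random(20150901)
    species = ["Pal", "Mon", "MonPalHen", "Harrier_SPEC", "Mar"]
    agreements = []
    for _ in range(200):
        records = [
            make_record(
                species=rng.choice(species),
                number=rng.randint(1, 6),
                station=rng.choice([1, 2]),
                location=rng.choice(["E2", "E3", "W2", "W3", "O"]),
                time=dt.time(10, rng.randrange(60)),
                age=rng.choice([None, "juv", "ad"]),
                date=DAY,
            )
            for _ in range(rng.randint(2, 8))
        ]
        optimal = _max_removable(records, config, hierarchy)
        _, report = remove_double_counts(records, config, hierarchy)
        assert report.n_individuals_removed <= optimal
        agreements.append(report.n_individuals_removed == optimal)
    assert sum(agreements) / len(agreements) >= 0.95
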