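"""Clusters, the permutation null, quartile profiles, cross-recurrence."""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from playnet import (
    DyadSeries,
    SelectionEvent,
    cluster_stats,
    cross_recurrence,
    find_clusters,
    occupancy,
    partition_topics,
    permutation_baseline,
    permute_series,
    quartile_profile,
    simulate_dyad,
    simulate_null,
)
from playnet.simulate import GeneratorParams
from playnet.temporal import _quartile_bounds, series_arrays, total_pair_count


# -- occupancy and clusters -------------------------------------------------


def test_occupancy_worked_example(table_series):
    bits = occupancy(table_series, "hippo")
    assert list(np.flatnonzero(bits) + 1) == [10, 11, 12]
    assert find_clusters(bits) == [3]


def test_occupancy_of_unselected_toy_is_all_false(table_series):
    toy = next(t for t in table_series.toy_universe if t not in table_series.toys_selected)
    assert not occupancy(table_series, toy).any()
    with pytest.raises(ValueError):
        occupancy(table_series, "not-a-toy")


def test_two_acts_in_one_segment_collapse_to_one_bit(table_series):
    bits = occupancy(table_series, "hippo")
    assert bits[10 - 1] == True  # parent handle + parent talk in segment 10
    assert bits.sum() == 3


@pytest.mark.parametrize(
    "bits, runs",
    [
        ([1, 1, 0, 1, 1, 1], [2, 3]),
        ([1, 0, 1, 0, 1], []),
        ([0, 0, 0], []),
        ([1, 1, 1, 1], [4]),
        ([], []),
    ],
)
def test_find_clusters_run_length_encoding(bits, runs):
    assert find_clusters(np.array(bits, dtype=bool)) == runs


def test_cluster_stats_constructed_case():
    """Every topic toy has exactly one length-3 run -> mean 1 cluster, length 3."""
    events = []
    seg = 1
    for i, toy in enumerate("ABCDE"):
        for s in range(seg, seg + 3):
            events.append(SelectionEvent(toy, "toddler", "handle", s))
        seg += 4  # leave a gap so runs do not merge
    events.append(SelectionEvent("F", "parent", "handle", 40))
    series = DyadSeries("d", tuple(events), n_segments=121)
    part = partition_topics(series)
    out = cluster_stats(series, part)
    assert out["topic"].clusters_per_toy == pytest.approx(1.0)
    assert out["topic"].mean_run_length == pytest.approx(3.0)
    assert out["comment"].n_clusters == 0
    assert np.isnan(out["comment"].mean_run_length)


# -- the permutation null ---------------------------------------------------


def test_permute_conserves_everything(table_series):
    rng = np.random.default_rng(0)
    for seed in range(5):
        sim = simulate_dyad(GeneratorParams(n_segments=40), seed=seed)
        perm = permute_series(sim, rng)
        assert perm.total_events == sim.total_events
        assert Counter(e.toy for e in perm.events) == Counter(e.toy for e in sim.events)
        assert [(e.agent, e.act, e.segment) for e in perm.events] == [
            (e.agent, e.act, e.segment) for e in sim.events
        ]


def test_single_toy_series_is_a_fixed_point():
    events = tuple(
        SelectionEvent("only", "toddler", "handle", s) for s in (1, 2, 5, 9)
    )
    series = DyadSeries("d", events, n_segments=10)
    assert permute_series(series, 0).events == series.events


def test_sampled_permutations_match_exhaustive_enumeration():
    """6-event series: sampled cluster counts match the exact distribution.

    The oracle enumerates every distinct assignment of the toy-label
    multiset to the event slots, drops assignments that collide (two
    events in one slot getting the same toy), and tallies the exact
    distribution of the total cluster count.
    """
    events = (
        SelectionEvent("A", "toddler", "handle", 1),
        SelectionEvent("B", "toddler", "handle", 1),  # shares slot with the first
        SelectionEvent("A", "toddler", "handle", 2),
        SelectionEvent("A", "parent", "handle", 3),
        SelectionEvent("B", "parent", "handle", 4),
        SelectionEvent("C", "toddler", "handle", 5),
    )
    series = DyadSeries("d", events, n_segments=6, universe_size=3)
    labels = [e.toy for e in series.events]
    slots = [(e.agent, e.act, e.segment) for e in series.events]

    def n_clusters(assignment):
        total = 0
        for toy in set(assignment):
            bits = np.zeros(6, dtype=bool)
            for lab, (_, _, seg) in zip(assignment, slots):
                if lab == toy:
                    bits[seg - 1] = True
            total += len(find_clusters(bits))
        return total

    exact = Counter()
    for perm in set(itertools.permutations(labels)):
        valid = len(set(zip(perm, slots))) == len(slots)
        if valid:
            exact[n_clusters(perm)] += 1
    total_valid = sum(exact.values())

    ens = permutation_baseline(series, "total_cluster_count", n_perms=10_000, seed=11)
    sampled = Counter(int(v) for v in ens.values[:, 0])
    support = sorted(exact)
    assert set(sampled) <= set(support)
    f_obs = np.array([sampled.get(k, 0) for k in support])
    f_exp = np.array([exact[k] / total_valid for k in support]) * f_obs.sum()
    p = stats.chisquare(f_obs, f_exp).pvalue
    assert p > 0.01


def test_permutation_baseline_is_deterministic_and_invariants_have_zero_sd(table_series):
    e1 = permutation_baseline(table_series, "total_events", n_perms=50, seed=3)
    e2 = permutation_baseline(table_series, "total_events", n_perms=50, seed=3)
    assert np.array_equal(e1.values, e2.values)
    assert e1.sd[0] == 0.0  # total event count is permutation-invariant


def test_unknown_statistic_is_rejected(table_series):
    with pytest.raises(ValueError, match="unknown statistic"):
        permutation_baseline(table_series, "nope", n_perms=2, seed=0)


def test_null_series_sits_inside_its_own_permutation_baseline():
    """Memoryless null: observed cluster count ~ permutation distribution."""
    z = []
    for seed in range(15):
        null = simulate_null(np.full(8, 1 / 8), n_segments=60, rate=2.0, seed=seed)
        arrays = series_arrays(null)
        from playnet.temporal import _runs_matrix

        rows, lengths = _runs_matrix(arrays.count_matrix() > 0)
        obs = float((lengths >= 2).sum())
        ens = permutation_baseline(null, "total_cluster_count", n_perms=400, seed=seed + 99)
        sd = ens.sd[0]
        if sd > 0:
            z.append((obs - ens.mean[0]) / sd)
    z = np.array(z)
    assert abs(z.mean()) < 3 / np.sqrt(len(z)) + 0.5  # centred within MC error
    assert np.all(np.abs(z) < 4)


def test_mean_run_length_increases_with_persistence():
    """Burstiness knob: run lengths rise monotonically with persistence."""
    means = []
    for rho in (0.1, 0.5, 0.9):
        runs = []
        for seed in range(50):
            sim = simulate_dyad(
                GeneratorParams(n_segments=60, persistence_rho=rho), seed=seed
            )
            arrays = series_arrays(sim)
            from playnet.temporal import _runs_matrix

            _, lengths = _runs_matrix(arrays.count_matrix() > 0)
            runs.extend(int(L) for L in lengths if L >= 2)
        means.append(np.mean(runs))
    assert means[0] <= means[1] <= means[2]
    assert means[2] > means[0]


# -- quartiles ---------------------------------------------------------------


def test_quartile_bounds_split_121_as_30_30_30_31():
    assert _quartile_bounds(121) == [(0, 30), (30, 60), (60, 90), (90, 121)]


def test_quartile_profile_hand_computed_case():
    """12-segment series checked against pencil-and-paper arithmetic."""
    events = []
    # topics: t1..t5 (t1 heavily in q1); comments: c1, c2
    for seg in (1, 2, 3):
        events.append(SelectionEvent("t1", "toddler", "handle", seg))
    for i, toy in enumerate(["t2", "t3", "t4", "t5"]):
        events.append(SelectionEvent(toy, "toddler", "handle", 4 + i))  # q2/q3
    events.append(SelectionEvent("c1", "parent", "handle", 8))
    events.append(SelectionEvent("c2", "parent", "handle", 12))
    events.append(SelectionEvent("t1", "parent", "handle", 12))
    series = DyadSeries("d", tuple(events), n_segments=12)
    part = partition_topics(series)
    assert part.topic_order[0] == "t1"
    prof = quartile_profile(series, part)
    # q1 = segments 1-3: all 3 events topic -> (3/3)/5
    assert prof.topic[0] == pytest.approx(1 / 5)
    assert prof.comment[0] == 0.0
    # q3 = segments 7-9: one topic (t5@7) and one comment (c1@8) event
    assert prof.topic[2] == pytest.approx((1 / 2) / 5)
    assert prof.comment[2] == pytest.approx((1 / 2) / 2)
    # q4 = segments 10-12: one comment, one topic of two events
    assert prof.topic[3] == pytest.approx((1 / 2) / 5)
    assert prof.comment[3] == pytest.approx((1 / 2) / 2)
    # rank profile: q1 topic selections all go to rank-1 toy
    assert prof.topic_by_rank[0, 0] == pytest.approx(1.0)


def test_all_topic_events_in_first_quartile():
    events = [
        SelectionEvent(t, "toddler", "handle", s)
        for s, t in enumerate(["A"] * 4 + ["B"] * 3, start=1)
    ]
    series = DyadSeries("d", tuple(events), n_segments=40)
    part = partition_topics(series)
    prof = quartile_profile(series, part)
    assert prof.topic[0] > 0
    assert np.all(prof.topic[1:] == 0)


# -- cross-recurrence --------------------------------------------------------


def test_cross_recurrence_worked_example(table_series):
    part = partition_topics(table_series)
    lp = cross_recurrence(table_series, part)
    assert sorted(lp.lags.tolist()) == [-10.0, -10.0, -5.0, -5.0]
    assert lp.proportion_positive == 0.0
    assert lp.n_pairs == 4  # 2 toddler x 2 parent hippo events


def test_same_segment_pair_has_lag_zero():
    events = (
        SelectionEvent("x", "toddler", "handle", 7),
        SelectionEvent("x", "parent", "talk", 7),
    )
    series = DyadSeries("d", events, n_segments=10)
    lp = cross_recurrence(series, partition_topics(series))
    assert lp.lags.tolist() == [0.0]


def test_role_swap_negates_every_lag(table_series):
    part = partition_topics(table_series)
    lp = cross_recurrence(table_series, part)
    swapped_events = tuple(
        SelectionEvent(
            e.toy,
            "parent" if e.agent == "toddler" else "toddler",
            "handle",  # talk cannot transfer to the toddler
            e.segment,
        )
        for e in table_series.events
        if not (e.agent == "parent" and e.act == "talk")
    )
    swapped = DyadSeries("d", swapped_events, n_segments=table_series.n_segments)
    lp_swapped = cross_recurrence(swapped, partition_topics(swapped))
    # handle-only pairs: original handle-derived lags negated
    orig_handle = (
        cross_recurrence(
            DyadSeries(
                "d",
                tuple(e for e in table_series.events if e.act == "handle"),
                n_segments=table_series.n_segments,
            ),
            part,
        ).lags
    )
    assert sorted(lp_swapped.lags.tolist()) == sorted((-orig_handle).tolist())


def test_lag_multiset_size_identity():
    sim = simulate_dyad(GeneratorParams(n_segments=40), seed=2)
    part = partition_topics(sim)
    lp = cross_recurrence(sim, part)
    expected = 0
    for toy in sim.toys_selected:
        n_t = sum(1 for e in sim.events if e.toy == toy and e.agent == "toddler")
        n_p = sum(1 for e in sim.events if e.toy == toy and e.agent == "parent")
        expected += n_t * n_p
    assert lp.n_pairs == expected


def test_no_shared_toys_is_flagged_empty():
    events = (
        SelectionEvent("a", "toddler", "handle", 1),
        SelectionEvent("b", "parent", "handle", 2),
    )
    series = DyadSeries("d", events, n_segments=5)
    lp = cross_recurrence(series, partition_topics(series))
    assert lp.empty and np.isnan(lp.proportion_positive)


def test_total_pair_count_closed_form_matches_arrays(table_series):
    arrays = series_arrays(table_series)
    assert total_pair_count(arrays.count_matrix()) == 12
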