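"""Temporal coherence statistics and the frequency-preserving permutation null.

The question throughout is whether the *timing* of toy selections carries
structure beyond what the skewed selection frequencies alone would
produce.  The null model therefore shuffles toy labels across the
observed events while holding the (agent, act, segment) scaffold fixed:
every permuted series has exactly the observed per-toy frequencies and
per-segment event counts, but no temporal dependence.

Statistics compared against that null:

* clusters — maximal runs of >= 2 consecutive segments each containing a
  selection of the same toy (number of clusters, run lengths);
* quartile recurrence profiles — normalized Topic/Comment selection
  frequency in each quarter of the session;
* cross-recurrence lag profiles — signed toddler-parent lags over all
  same-toy event pairs (positive lag = toddler preceded parent);
* the mean transition matrix feeding the Random networks downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .events import BEHAVIOURS, SEGMENT_SECONDS, DyadSeries, SelectionEvent
from .frequency import TopicPartition

DEFAULT_N_PERMS = 10_000
MIN_RUN = 2

CATEGORIES = ("topic", "comment")


# ---------------------------------------------------------------------------
# Array representation (shared with the network module)


@dataclass(frozen=True)
class SeriesArrays:
    """Flat array view of a dyad series for the permutation engine.

    ``slot`` encodes the fixed (segment, behaviour) scaffold of each
    event; permutations shuffle ``toy_idx`` over events while slots stay
    put.  ``toys`` orders the universe so matrices are comparable across
    permutations.
    """

    toys: tuple[str, ...]
    toy_idx: np.ndarray
    beh_idx: np.ndarray
    seg0: np.ndarray  # 0-based segments
    n_segments: int

    @property
    def n_events(self) -> int:
        return len(self.toy_idx)

    @property
    def slot(self) -> np.ndarray:
        return self.seg0 * len(BEHAVIOURS) + self.beh_idx

    def count_matrix(self, toy_idx: np.ndarray | None = None) -> np.ndarray:
        """(n_toys, n_segments) matrix of event counts."""
        t = self.toy_idx if toy_idx is None else toy_idx
        C = np.zeros((len(self.toys), self.n_segments), dtype=np.int32)
        np.add.at(C, (t, self.seg0), 1)
        return C


def series_arrays(series: DyadSeries) -> SeriesArrays:
    toys = series.toy_universe
    index = {t: i for i, t in enumerate(toys)}
    beh_index = {b: i for i, b in enumerate(BEHAVIOURS)}
    toy_idx = np.array([index[e.toy] for e in series.events], dtype=np.int64)
    beh_idx = np.array([beh_index[e.behaviour] for e in series.events], dtype=np.int64)
    seg0 = np.array([e.segment - 1 for e in series.events], dtype=np.int64)
    return SeriesArrays(
        toys=toys, toy_idx=toy_idx, beh_idx=beh_idx, seg0=seg0,
        n_segments=series.n_segments,
    )


def _runs_matrix(B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row index and length of every maximal run of True in each row of B."""
    P = np.zeros((B.shape[0], B.shape[1] + 2), dtype=np.int8)
    P[:, 1:-1] = B
    d = np.diff(P, axis=1)
    rows, starts = np.nonzero(d == 1)
    _, ends = np.nonzero(d == -1)
    return rows, ends - starts


# ---------------------------------------------------------------------------
# Occupancy and clusters


def occupancy(series: DyadSeries, toy: str) -> np.ndarray:
    """Boolean per-segment vector: toy selected at least once (any agent/act)."""
    if toy not in series.toy_universe:
        raise ValueError(f"toy {toy!r} not in the toy universe of {series.dyad_id!r}")
    bits = np.zeros(series.n_segments, dtype=bool)
    for e in series.events:
        if e.toy == toy:
            bits[e.segment - 1] = True
    return bits


def find_clusters(occ: Sequence[bool] | np.ndarray, min_run: int = MIN_RUN) -> list[int]:
    """Run lengths (in segments) of maximal runs of >= min_run occupied segments."""
    B = np.asarray(occ, dtype=bool).reshape(1, -1)
    _, lengths = _runs_matrix(B)
    return [int(L) for L in lengths if L >= min_run]


@dataclass(frozen=True)
class ClusterStats:
    """Cluster counts and run lengths for one toy category of one dyad.

    ``n_toys`` is the number of selected toys in the category (5 Topics
    for a typical dyad); run lengths are pooled over all of the
    category's clusters and are in segments (multiply by 5 for seconds).
    """

    category: str
    run_lengths: tuple[int, ...]
    n_toys: int

    @property
    def n_clusters(self) -> int:
        return len(self.run_lengths)

    @property
    def clusters_per_toy(self) -> float:
        if self.n_toys == 0:
            return float("nan")
        return self.n_clusters / self.n_toys

    @property
    def mean_run_length(self) -> float:
        if not self.run_lengths:
            return float("nan")
        return float(np.mean(self.run_lengths))


def cluster_stats(
    series: DyadSeries,
    partition: TopicPartition,
    *,
    min_run: int = MIN_RUN,
) -> dict[str, ClusterStats]:
    """Per-category cluster statistics (keys ``"topic"`` and ``"comment"``).

    The default reading reports the mean number of clusters per toy in
    the category and the mean run length over clusters; per-dyad totals
    are available from the returned objects (``n_clusters``).
    """
    arrays = series_arrays(series)
    B = arrays.count_matrix() > 0
    rows, lengths = _runs_matrix(B)
    keep = lengths >= min_run
    rows, lengths = rows[keep], lengths[keep]
    cat_sets = {"topic": partition.topics, "comment": partition.comments}
    out = {}
    for cat in CATEGORIES:
        members = {i for i, t in enumerate(arrays.toys) if t in cat_sets[cat]}
        runs = tuple(int(L) for r, L in zip(rows, lengths) if r in members)
        out[cat] = ClusterStats(category=cat, run_lengths=runs, n_toys=len(cat_sets[cat]))
    return out


# ---------------------------------------------------------------------------
# The permutation null


def _permuted_toy_idx(
    arrays: SeriesArrays, rng: np.random.Generator, max_tries: int = 3
) -> tuple[np.ndarray, int]:
    """Shuffle toy labels over events without creating duplicate events.

    Two events sharing a (segment, behaviour) slot must not receive the
    same toy, or the permuted series would lose an event to
    deduplication and no longer conserve the frequency distribution.
    Plain rejection sampling is exact and is tried first; when the label
    distribution is skewed enough that collision-free shuffles are
    vanishingly rare, remaining collisions are resolved by uniform label
    swaps accepted only when they remove a collision without creating
    one, which conserves the label multiset exactly.
    """
    slot = arrays.slot
    n_slots = arrays.n_segments * len(BEHAVIOURS)
    toy_idx = arrays.toy_idx.copy()
    n = toy_idx.size
    for tries in range(1, max_tries + 1):
        rng.shuffle(toy_idx)
        key = toy_idx * n_slots + slot
        if np.unique(key).size == key.size:
            return toy_idx, tries
    toy = toy_idx.tolist()
    slots = slot.tolist()
    key = [t * n_slots + s for t, s in zip(toy, slots)]
    cnt: dict[int, int] = {}
    for k in key:
        cnt[k] = cnt.get(k, 0) + 1
    pending = [i for i, k in enumerate(key) if cnt[k] > 1]
    budget = 500 * n
    while pending and budget > 0:
        budget -= 1
        i = pending[-1]
        if cnt[key[i]] == 1:
            pending.pop()
            continue
        j = int(rng.integers(n))
        if j == i or toy[j] == toy[i]:
            continue
        ki_new = toy[j] * n_slots + slots[i]
        kj_new = toy[i] * n_slots + slots[j]
        # occupancy of the proposed keys, net of i's and j's own moves
        ci = cnt.get(ki_new, 0) - (1 if key[j] == ki_new else 0)
        cj = cnt.get(kj_new, 0) - (1 if key[i] == kj_new else 0)
        if ci or cj:
            continue
        cnt[key[i]] -= 1
        cnt[key[j]] -= 1
        toy[i], toy[j] = toy[j], toy[i]
        key[i], key[j] = ki_new, kj_new
        cnt[ki_new] = cnt.get(ki_new, 0) + 1
        cnt[kj_new] = cnt.get(kj_new, 0) + 1
        pending.pop()
    if pending:
        raise RuntimeError(
            "could not resolve duplicate-event collisions while permuting; "
            "the series is too constrained to permute"
        )
    return np.asarray(toy, dtype=np.int64), max_tries + 1


def permute_series(
    series: DyadSeries, rng: np.random.Generator | int | None = None
) -> DyadSeries:
    """One frequency-preserving permutation of a dyad series.

    Toy labels are shuffled across all events; the (agent, act, segment)
    scaffold, the per-toy aggregate counts, and the per-segment event
    counts are conserved exactly.
    """
    if not series.events:
        raise ValueError("cannot permute an empty series")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    arrays = series_arrays(series)
    toy_idx, _ = _permuted_toy_idx(arrays, rng)
    events = tuple(
        SelectionEvent(
            toy=arrays.toys[toy_idx[i]],
            agent=e.agent,
            act=e.act,
            segment=e.segment,
        )
        for i, e in enumerate(series.events)
    )
    return DyadSeries(
        dyad_id=series.dyad_id,
        events=events,
        n_segments=series.n_segments,
        toy_universe=series.toy_universe,
    )


@dataclass
class PermutationEnsemble:
    """Distribution of one statistic over frequency-preserving permutations.

    ``values`` has one row per permutation (columns are the statistic's
    components, e.g. topic/comment).  When transitions were requested,
    ``mean_s_weight``/``mean_d_weight`` hold the expected same-toy and
    different-toy pair counts per toy (pair) — the Random network input.
    """

    statistic: str
    n_perms: int
    seed: int | None
    toys: tuple[str, ...]
    components: tuple[str, ...]
    values: np.ndarray
    mean_s_weight: np.ndarray | None = None
    mean_d_weight: np.ndarray | None = None
    mean_tries: float = 1.0

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)

    @property
    def sd(self) -> np.ndarray:
        return np.nanstd(self.values, axis=0, ddof=1)


def transition_matrices(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-toy (per-node) and different-toy (per-pair) transition counts.

    From a (n_toys, n_segments) count matrix: all unordered pairs of
    distinct events within a segment plus the full cross product of
    events in adjacent segments.  Returns ``(s, D)`` with ``s[a]`` the
    self-loop count of toy ``a`` and symmetric ``D[a, b]`` the pair count
    of the unordered different-toy pair, zero diagonal.
    """
    C = C.astype(np.int64)
    within = C @ C.T
    adj = C[:, :-1] @ C[:, 1:].T
    row_tot = C.sum(axis=1)
    s = (np.diag(within) - row_tot) // 2 + np.diag(adj)
    D = within + adj + adj.T
    np.fill_diagonal(D, 0)
    return s.astype(float), D.astype(float)


def total_pair_count(C: np.ndarray) -> int:
    """Closed form: sum_t C(k_t, 2) + sum_t k_t * k_{t+1}."""
    k = C.sum(axis=0).astype(np.int64)
    return int((k * (k - 1) // 2).sum() + (k[:-1] * k[1:]).sum())


def _quartile_bounds(n_segments: int) -> list[tuple[int, int]]:
    q = n_segments // 4
    cuts = [0, q, 2 * q, 3 * q, n_segments]
    return [(cuts[i], cuts[i + 1]) for i in range(4)]


def _statistic_fns(
    arrays: SeriesArrays,
    partition: TopicPartition | None,
    min_run: int,
) -> dict[str, tuple[tuple[str, ...], Callable[[np.ndarray], np.ndarray]]]:
    n_toys = len(arrays.toys)
    if partition is not None:
        topic_mask = np.array([t in partition.topics for t in arrays.toys])
        comment_mask = np.array([t in partition.comments for t in arrays.toys])
        n_topic = int(topic_mask.sum())
        n_comment = int(comment_mask.sum())

    def per_cat_cluster(C: np.ndarray) -> np.ndarray:
        rows, lengths = _runs_matrix(C > 0)
        keep = lengths >= min_run
        rows, lengths = rows[keep], lengths[keep]
        per_toy = np.bincount(rows, minlength=n_toys)
        return np.array(
            [
                per_toy[topic_mask].sum() / n_topic if n_topic else np.nan,
                per_toy[comment_mask].sum() / n_comment if n_comment else np.nan,
            ]
        )

    def per_cat_run_length(C: np.ndarray) -> np.ndarray:
        rows, lengths = _runs_matrix(C > 0)
        keep = lengths >= min_run
        rows, lengths = rows[keep], lengths[keep]
        out = []
        for mask in (topic_mask, comment_mask):
            L = lengths[mask[rows]]
            out.append(L.mean() if L.size else np.nan)
        return np.array(out)

    def total_cluster_count(C: np.ndarray) -> np.ndarray:
        _, lengths = _runs_matrix(C > 0)
        return np.array([float((lengths >= min_run).sum())])

    def total_events(C: np.ndarray) -> np.ndarray:
        return np.array([float(C.sum())])

    def quartile(C: np.ndarray) -> np.ndarray:
        vals = []
        for lo, hi in _quartile_bounds(arrays.n_segments):
            block = C[:, lo:hi]
            tot = block.sum()
            if tot == 0:
                vals.extend([0.0, 0.0])
                continue
            p_topic = block[topic_mask].sum() / tot
            p_comment = block[comment_mask].sum() / tot
            vals.append(p_topic / 5.0)
            vals.append(p_comment / n_comment if n_comment else 0.0)
        return np.array(vals)

    def cluster_and_run(C: np.ndarray) -> np.ndarray:
        return np.concatenate([per_cat_cluster(C), per_cat_run_length(C)])

    fns: dict[str, tuple[tuple[str, ...], Callable]] = {
        "total_cluster_count": (("all",), total_cluster_count),
        "total_events": (("all",), total_events),
    }
    if partition is not None:
        fns["cluster_count"] = (CATEGORIES, per_cat_cluster)
        fns["run_length"] = (CATEGORIES, per_cat_run_length)
        fns["cluster_and_run"] = (
            ("clusters_topic", "clusters_comment", "run_topic", "run_comment"),
            cluster_and_run,
        )
        q_names = tuple(
            f"q{q}_{cat}" for q in range(1, 5) for cat in CATEGORIES
        )
        fns["quartile_profile"] = (q_names, quartile)
    return fns


def permutation_baseline(
    series: DyadSeries,
    statistic: str,
    *,
    n_perms: int = DEFAULT_N_PERMS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    partition: TopicPartition | None = None,
    min_run: int = MIN_RUN,
    include_transitions: bool = False,
) -> PermutationEnsemble:
    """Distribution of a named statistic under the frequency-preserving null.

    Registered statistics: ``total_cluster_count`` and ``total_events``
    always; ``cluster_count``, ``run_length`` and ``quartile_profile``
    (per Topic/Comment category) when a partition is supplied;
    ``transition_matrix`` to accumulate only the mean transition matrix.
    Reproducible given ``seed``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    arrays = series_arrays(series)
    fns = _statistic_fns(arrays, partition, min_run)
    if statistic == "transition_matrix":
        include_transitions = True
        components, fn = ("all",), lambda C: np.array([float(total_pair_count(C))])
    elif statistic in fns:
        components, fn = fns[statistic]
    else:
        known = sorted(fns) + ["transition_matrix"]
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {known}")

    values = np.empty((n_perms, len(components)))
    sum_s = np.zeros(len(arrays.toys)) if include_transitions else None
    sum_d = (
        np.zeros((len(arrays.toys), len(arrays.toys))) if include_transitions else None
    )
    tries_total = 0
    for i in range(n_perms):
        toy_idx, tries = _permuted_toy_idx(arrays, rng)
        tries_total += tries
        C = arrays.count_matrix(toy_idx)
        values[i] = fn(C)
        if include_transitions:
            s, D = transition_matrices(C)
            sum_s += s
            sum_d += D
    return PermutationEnsemble(
        statistic=statistic,
        n_perms=n_perms,
        seed=seed,
        toys=arrays.toys,
        components=components,
        values=values,
        mean_s_weight=None if sum_s is None else sum_s / n_perms,
        mean_d_weight=None if sum_d is None else sum_d / n_perms,
        mean_tries=tries_total / max(n_perms, 1),
    )


# ---------------------------------------------------------------------------
# Quartile recurrence profile


@dataclass(frozen=True)
class QuartileProfile:
    """Normalized Topic/Comment selection frequency per session quarter.

    Within each quartile the dyad's score is the proportion of that
    quartile's selections going to the category, divided by 5 for Topics
    and by the number of Comment toys the dyad referenced for Comments
    (a per-toy normalization).  ``topic_by_rank[q, r]`` is the share of
    the quartile's Topic selections going to the rank-(r+1) Topic toy.
    """

    dyad_id: str
    bounds: tuple[tuple[int, int], ...]
    topic: np.ndarray  # (4,)
    comment: np.ndarray  # (4,)
    topic_by_rank: np.ndarray  # (4, k)

    def as_cells(self) -> np.ndarray:
        """(2, 4) array: rows topic/comment, columns quartiles."""
        return np.vstack([self.topic, self.comment])


def quartile_profile(series: DyadSeries, partition: TopicPartition) -> QuartileProfile:
    """Quartile recurrence profile of one dyad (30/30/30/31 split of 121)."""
    if series.n_segments < 4:
        raise ValueError("need at least 4 segments to form quartiles")
    arrays = series_arrays(series)
    C = arrays.count_matrix()
    topic_mask = np.array([t in partition.topics for t in arrays.toys])
    comment_mask = np.array([t in partition.comments for t in arrays.toys])
    n_comment = int(comment_mask.sum())
    rank_rows = [arrays.toys.index(t) for t in partition.topic_order]
    bounds = tuple(_quartile_bounds(series.n_segments))
    topic = np.zeros(4)
    comment = np.zeros(4)
    by_rank = np.zeros((4, len(rank_rows)))
    for q, (lo, hi) in enumerate(bounds):
        block = C[:, lo:hi]
        tot = block.sum()
        if tot == 0:
            continue
        topic_tot = block[topic_mask].sum()
        topic[q] = (topic_tot / tot) / 5.0
        if n_comment:
            comment[q] = (block[comment_mask].sum() / tot) / n_comment
        if topic_tot:
            by_rank[q] = [block[r].sum() / topic_tot for r in rank_rows]
    return QuartileProfile(
        dyad_id=series.dyad_id, bounds=bounds, topic=topic, comment=comment,
        topic_by_rank=by_rank,
    )


# ---------------------------------------------------------------------------
# Cross-recurrence lags


@dataclass(frozen=True)
class LagProfile:
    """Signed toddler-parent lags over all same-toy event pairs.

    One lag per (toddler handling event, parent handling-or-talk event)
    pair on the same toy: ``(parent segment - toddler segment) * 5`` s,
    so positive lags mean the toddler selected the toy first.  ``empty``
    flags a series with no shared toys rather than raising.
    """

    dyad_id: str
    lags: np.ndarray  # seconds, multiples of 5
    categories: np.ndarray  # "topic" / "comment" per lag
    empty: bool = False

    @property
    def n_pairs(self) -> int:
        return len(self.lags)

    @property
    def proportion_positive(self) -> float:
        if self.n_pairs == 0:
            return float("nan")
        return float((self.lags > 0).sum() / self.n_pairs)

    def mean_lag(self, category: str | None = None) -> float:
        lags = self.lags if category is None else self.lags[self.categories == category]
        if lags.size == 0:
            return float("nan")
        return float(lags.mean())

    def proportions(self) -> dict[int, float]:
        """Lag histogram normalized to proportions."""
        if self.n_pairs == 0:
            return {}
        vals, counts = np.unique(self.lags, return_counts=True)
        return {int(v): float(c / self.n_pairs) for v, c in zip(vals, counts)}


def cross_recurrence(series: DyadSeries, partition: TopicPartition) -> LagProfile:
    """All toddler-parent same-toy lags, with Topic/Comment category per lag.

    The toddler stream is handling only; the parent stream is handling
    plus talk (each act is its own event, so a parent handle and talk of
    the same toy in one segment contribute two pairs).  All pairs are
    counted over the whole session.
    """
    toddler: dict[str, list[int]] = {}
    parent: dict[str, list[int]] = {}
    for e in series.events:
        if e.agent == "toddler":
            toddler.setdefault(e.toy, []).append(e.segment)
        else:
            parent.setdefault(e.toy, []).append(e.segment)
    lags: list[float] = []
    cats: list[str] = []
    for toy in sorted(set(toddler) & set(parent)):
        t = np.array(toddler[toy])
        p = np.array(parent[toy])
        toy_lags = ((p[None, :] - t[:, None]) * SEGMENT_SECONDS).ravel()
        lags.extend(toy_lags.tolist())
        cats.extend([partition.category_of(toy)] * toy_lags.size)
    return LagProfile(
        dyad_id=series.dyad_id,
        lags=np.array(lags),
        categories=np.array(cats, dtype=object),
        empty=not lags,
    )
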