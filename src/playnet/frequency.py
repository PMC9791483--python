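"""Rank-frequency statistics and the Topic/Comment partition.

Toy selection during free play is highly skewed: a handful of toys draw
most referential acts while many others are touched only occasionally.
This module builds per-behaviour rank-frequency tables, compares the
frequency distributions of the three coded behaviours within a dyad
(Wilcoxon signed-rank on rank-aligned frequency vectors, Spearman rank
correlation on per-toy counts over the full toy universe), and splits a
dyad's toys into the five high-frequency *Topic* toys versus the
remaining *Comment* toys — the information-theoretic given/new partition
used by all downstream temporal and network statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .events import BehaviourStream, DyadSeries, behaviour_stream

DEFAULT_K_TOPICS = 5


@dataclass(frozen=True)
class RankFrequencyTable:
    """Toys ordered by selection count (rank 1 = most frequent)."""

    behaviour: str
    rows: tuple[tuple[str, int, float, int], ...]  # (toy, count, proportion, rank)
    empty: bool = False

    @property
    def toys(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.rows)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(r[1] for r in self.rows)

    def top_share(self, k: int = DEFAULT_K_TOPICS) -> float:
        """Fraction of the stream total going to the k top-ranked toys."""
        total = sum(self.counts)
        if total == 0:
            return float("nan")
        return sum(self.counts[:k]) / total


@dataclass(frozen=True)
class TopicPartition:
    """Per-dyad split into (at most) k Topic toys and the Comment remainder.

    Topics are the most frequently selected toys by the aggregate count
    over all three behaviours; ``topic_order`` lists them by rank.
    """

    dyad_id: str
    topic_order: tuple[str, ...]
    comments: frozenset[str]
    topic_share: float

    @property
    def topics(self) -> frozenset[str]:
        return frozenset(self.topic_order)

    def category_of(self, toy: str) -> str:
        if toy in self.topics:
            return "topic"
        if toy in self.comments:
            return "comment"
        raise KeyError(f"toy {toy!r} was never selected by dyad {self.dyad_id!r}")


@dataclass(frozen=True)
class StreamComparison:
    """Within-dyad comparison of two behaviour streams.

    ``wilcoxon_V`` is the signed-rank sum of positive differences between
    the two rank-aligned frequency vectors (a distribution-shape test that
    ignores toy identity); ``spearman_rho`` correlates per-toy counts over
    the full toy universe, zeros included (df = universe size - 1).
    """

    wilcoxon_V: float
    wilcoxon_p: float
    spearman_rho: float
    spearman_p: float
    n_toys: int

    @property
    def df(self) -> int:
        return self.n_toys - 1


def _order_key(count: int, toy: str, first_selection: Mapping[str, int] | None):
    first = first_selection.get(toy, math.inf) if first_selection else math.inf
    return (-count, first, toy)


def rank_frequency(
    stream: BehaviourStream,
    *,
    first_selection: Mapping[str, int] | None = None,
    include_zero: bool = False,
) -> RankFrequencyTable:
    """Rank toys of one behaviour stream by selection count.

    Ties are broken by earlier first selection (when the caller supplies
    the dyad's first-selection segments) and then lexicographically, so
    tables are reproducible across input orderings.  An empty stream
    yields an empty table flagged via ``empty`` rather than an error.
    """
    total = stream.total
    if total == 0:
        return RankFrequencyTable(behaviour=stream.behaviour, rows=(), empty=True)
    items = [
        (toy, count)
        for toy, count in stream.counts.items()
        if include_zero or count > 0
    ]
    items.sort(key=lambda tc: _order_key(tc[1], tc[0], first_selection))
    rows = tuple(
        (toy, int(count), count / total, rank)
        for rank, (toy, count) in enumerate(items, start=1)
    )
    return RankFrequencyTable(behaviour=stream.behaviour, rows=rows)


def rank_frequency_table(series: DyadSeries, behaviour: str = "all") -> RankFrequencyTable:
    """Convenience wrapper: rank-frequency table straight from a series."""
    return rank_frequency(
        behaviour_stream(series, behaviour), first_selection=series.first_selection()
    )


def _signed_rank_V(diff: np.ndarray) -> float:
    nz = diff[diff != 0]
    if nz.size == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(nz))
    return float(ranks[nz > 0].sum())


def compare_streams(a: BehaviourStream, b: BehaviourStream) -> StreamComparison:
    """Compare two behaviour streams from the same dyad.

    The Wilcoxon signed-rank test pairs frequencies *by rank* (most
    frequent toy of ``a`` against most frequent toy of ``b``, and so on,
    zero-padded to the universe size), asking whether the two
    distributions have the same shape irrespective of which toys carry
    the counts.  ``V`` follows the R convention (rank sum of positive
    differences after dropping zeros).  Spearman's rho is computed on
    per-toy counts aligned on the full universe with average ranks.
    """
    if a.toy_universe != b.toy_universe:
        raise ValueError("streams must share the same toy universe")
    n = len(a.toy_universe)
    x = np.sort(a.count_vector())[::-1]
    y = np.sort(b.count_vector())[::-1]
    diff = x - y
    V = _signed_rank_V(diff)
    if np.all(diff == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(x, y, zero_method="wilcox").pvalue)
    rho, rho_p = stats.spearmanr(a.count_vector(), b.count_vector())
    return StreamComparison(
        wilcoxon_V=V,
        wilcoxon_p=p,
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        n_toys=n,
    )


def partition_topics(series: DyadSeries, k: int = DEFAULT_K_TOPICS) -> TopicPartition:
    """Split a dyad's selected toys into the top-k Topics and Comment rest.

    Counts are the aggregate over all three behaviours (who and how are
    ignored).  Ties at the Topic boundary are broken by earlier first
    selection, then lexicographic toy id, making the partition invariant
    to input row order.  If fewer than k toys were selected, all of them
    are Topics and the Comment set is empty.
    """
    if series.total_events == 0:
        raise ValueError(f"dyad {series.dyad_id!r} has no selection events")
    counts = series.counts("all")
    first = series.first_selection()
    selected = [(toy, c) for toy, c in counts.items() if c > 0]
    selected.sort(key=lambda tc: _order_key(tc[1], tc[0], first))
    k_eff = min(k, len(selected))
    topic_order = tuple(toy for toy, _ in selected[:k_eff])
    comments = frozenset(toy for toy, _ in selected[k_eff:])
    topic_events = sum(c for toy, c in selected[:k_eff])
    return TopicPartition(
        dyad_id=series.dyad_id,
        topic_order=topic_order,
        comments=comments,
        topic_share=topic_events / series.total_events,
    )
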