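"""Transition-pair networks of toy selections.

Every unordered pair of distinct selection events falling in the same or
adjacent 5-s segments is a *transition*: an S pair when both events
select the same toy (a self-loop) and a D pair when they select
different toys (an edge).  Accumulating pair counts over a session gives
a weighted undirected toy graph per dyad; node measures (S/D strength,
degree, betweenness, clustering coefficient) quantify how selectively
the dyad's toys connect.  A Random network built from the mean
transition counts over frequency-preserving permutations gives the
frequency-only baseline for each measure.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .events import DyadSeries, SelectionEvent
from .frequency import TopicPartition
from .temporal import PermutationEnsemble, series_arrays, transition_matrices

MEASURES = ("s_strength", "d_strength", "degree", "betweenness", "clustering")


class TransitionPair(NamedTuple):
    """One same-segment or adjacent-segment pair of distinct selection acts.

    Member events are kept in chronological (then canonical) order;
    ``kind`` is ``"S"`` for same-toy pairs and ``"D"`` otherwise.  The
    unordered edge identity is ``frozenset({toy_a, toy_b})``.
    """

    toy_a: str
    toy_b: str
    kind: str
    segment_a: int
    segment_b: int
    behaviour_a: str
    behaviour_b: str

    @property
    def edge(self) -> tuple[str, str]:
        return tuple(sorted((self.toy_a, self.toy_b)))


def _make_pair(e1: SelectionEvent, e2: SelectionEvent) -> TransitionPair:
    return TransitionPair(
        toy_a=e1.toy,
        toy_b=e2.toy,
        kind="S" if e1.toy == e2.toy else "D",
        segment_a=e1.segment,
        segment_b=e2.segment,
        behaviour_a=e1.behaviour,
        behaviour_b=e2.behaviour,
    )


def enumerate_pairs(series: DyadSeries) -> list[TransitionPair]:
    """All transition pairs of a series.

    Within each segment, every unordered pair of the segment's distinct
    events; across each adjacent segment pair (t, t+1), the full cross
    product of events.  Orientation is never distinguished: giraffe-hippo
    and hippo-giraffe are two instances of the same edge.
    """
    by_segment: dict[int, list[SelectionEvent]] = defaultdict(list)
    for e in series.events:
        by_segment[e.segment].append(e)
    pairs: list[TransitionPair] = []
    for t in range(1, series.n_segments + 1):
        here = by_segment.get(t, ())
        pairs.extend(_make_pair(e1, e2) for e1, e2 in combinations(here, 2))
        nxt = by_segment.get(t + 1, ())
        pairs.extend(_make_pair(e1, e2) for e1, e2 in product(here, nxt))
    return pairs


@dataclass
class DyadNetwork:
    """Weighted undirected toy graph of one dyad.

    ``s_weight`` maps each node to its self-loop (S pair) count;
    ``d_weight`` maps each unordered toy pair (a, b), a < b, to its D
    pair count.  Weights are fractional for Random (permutation-mean)
    networks.  ``measures`` is filled by :func:`node_measures`.
    """

    dyad_id: str
    nodes: tuple[str, ...]
    s_weight: dict[str, float]
    d_weight: dict[tuple[str, str], float]
    kind: str = "observed"
    category: dict[str, str] = field(default_factory=dict)
    measures: pd.DataFrame | None = None
    transitivity: float | None = None

    @property
    def total_pairs(self) -> float:
        return sum(self.s_weight.values()) + sum(self.d_weight.values())

    def d_graph(self, threshold: float = 0.0) -> nx.Graph:
        """The D-edge graph (no self-loops), keeping edges with weight > threshold."""
        G = nx.Graph()
        G.add_nodes_from(self.nodes)
        for (a, b), w in self.d_weight.items():
            if w > threshold:
                G.add_edge(a, b, weight=w)
        return G

    def to_graph(self) -> nx.Graph:
        """Full graph including S self-loops, for export."""
        G = self.d_graph()
        for toy, w in self.s_weight.items():
            if w > 0:
                G.add_edge(toy, toy, weight=w)
        for toy in G.nodes:
            if self.category:
                G.nodes[toy]["category"] = self.category.get(toy, "")
        return G

    def write_edgelist(self, path: str | Path) -> None:
        rows = [
            {"toy_a": t, "toy_b": t, "kind": "S", "weight": w}
            for t, w in sorted(self.s_weight.items())
        ] + [
            {"toy_a": a, "toy_b": b, "kind": "D", "weight": w}
            for (a, b), w in sorted(self.d_weight.items())
        ]
        pd.DataFrame(rows, columns=["toy_a", "toy_b", "kind", "weight"]).to_csv(
            path, index=False, lineterminator="\n"
        )

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), str(path))


def build_network(
    pairs: Iterable[TransitionPair],
    *,
    dyad_id: str = "",
    nodes: Iterable[str] | None = None,
    partition: TopicPartition | None = None,
    kind: str = "observed",
) -> DyadNetwork:
    """Accumulate transition pairs into a weighted toy graph."""
    s_weight: Counter = Counter()
    d_weight: Counter = Counter()
    seen: set[str] = set(nodes) if nodes else set()
    for p in pairs:
        seen.update((p.toy_a, p.toy_b))
        if p.kind == "S":
            s_weight[p.toy_a] += 1
        else:
            d_weight[p.edge] += 1
    category = {}
    if partition is not None:
        category = {
            t: partition.category_of(t)
            for t in seen
            if t in partition.topics or t in partition.comments
        }
    return DyadNetwork(
        dyad_id=dyad_id,
        nodes=tuple(sorted(seen)),
        s_weight=dict(s_weight),
        d_weight=dict(d_weight),
        kind=kind,
        category=category,
    )


def network_from_series(
    series: DyadSeries, partition: TopicPartition | None = None
) -> DyadNetwork:
    """Observed network of a dyad series (nodes = selected toys)."""
    return build_network(
        enumerate_pairs(series),
        dyad_id=series.dyad_id,
        nodes=series.toys_selected,
        partition=partition,
    )


def node_measures(
    net: DyadNetwork,
    *,
    threshold: float = 0.0,
    clustering_mode: str = "weighted",
    betweenness_weighted: bool = False,
) -> DyadNetwork:
    """Fill per-node measures on the D-edge graph; returns the same network.

    * ``s_strength`` — self-loop weight (repeats of the same toy);
    * ``d_strength`` — summed weight of incident D edges;
    * ``degree`` — number of distinct neighbours with edge weight above
      ``threshold`` (self-loops never count);
    * ``betweenness`` — raw (unnormalized) shortest-path counts on the
      binarized graph, endpoints excluded, multiple shortest paths
      contributing fractionally; hop-count paths unless
      ``betweenness_weighted``;
    * ``clustering`` — local clustering coefficient; the default
      ``"weighted"`` mode uses geometric-mean triangle intensities
      (Onnela) on the weighted graph, which keeps the many vanishing
      fractional edges of a permutation-mean network from counting as
      full triangles; ``"binary"`` uses the binarized graph.

    Graph transitivity of the binarized graph is stored on the network.
    """
    if not net.nodes:
        raise ValueError("cannot compute measures of an empty network")
    Gw = net.d_graph(threshold)
    Gb = net.d_graph(threshold)  # same topology; weights ignored where binary
    bet = nx.betweenness_centrality(
        Gb, normalized=False, weight="weight" if betweenness_weighted else None
    )
    if clustering_mode == "weighted":
        clust = nx.clustering(Gw, weight="weight")
    elif clustering_mode == "binary":
        clust = nx.clustering(Gb)
    else:
        raise ValueError(f"unknown clustering_mode {clustering_mode!r}")
    d_strength = {t: 0.0 for t in net.nodes}
    for (a, b), w in net.d_weight.items():
        d_strength[a] += w
        d_strength[b] += w
    net.measures = pd.DataFrame(
        {
            "toy": net.nodes,
            "category": [net.category.get(t, "") for t in net.nodes],
            "s_strength": [float(net.s_weight.get(t, 0.0)) for t in net.nodes],
            "d_strength": [d_strength[t] for t in net.nodes],
            "degree": [float(Gb.degree(t)) for t in net.nodes],
            "betweenness": [float(bet[t]) for t in net.nodes],
            "clustering": [float(clust[t]) for t in net.nodes],
        }
    ).set_index("toy")
    net.transitivity = float(nx.transitivity(Gb))
    return net


def random_network(
    series: DyadSeries,
    ensemble: PermutationEnsemble,
    *,
    partition: TopicPartition | None = None,
) -> DyadNetwork:
    """Random (permutation-mean) network of a dyad.

    Weights are the mean S/D pair counts over the ensemble's
    permutations, so they are fractional; totals are conserved because
    every permutation conserves the pair count.
    """
    if ensemble.mean_s_weight is None or ensemble.mean_d_weight is None:
        raise ValueError(
            "ensemble carries no mean transition matrix; run permutation_baseline "
            "with statistic='transition_matrix' or include_transitions=True"
        )
    toys = ensemble.toys
    selected = set(series.toys_selected)
    s_weight = {
        toys[i]: float(w)
        for i, w in enumerate(ensemble.mean_s_weight)
        if toys[i] in selected
    }
    d_weight = {}
    D = ensemble.mean_d_weight
    for i, j in zip(*np.nonzero(np.triu(D, k=1))):
        a, b = toys[i], toys[j]
        if a in selected and b in selected:
            d_weight[(a, b)] = float(D[i, j])
    category = {}
    if partition is not None:
        category = {t: partition.category_of(t) for t in selected}
    return DyadNetwork(
        dyad_id=series.dyad_id,
        nodes=tuple(sorted(selected)),
        s_weight=s_weight,
        d_weight=d_weight,
        kind="random",
        category=category,
    )


def transition_matrix_from_series(series: DyadSeries) -> tuple[np.ndarray, np.ndarray]:
    """Observed (s, D) transition matrices via the array route.

    Equivalent to accumulating :func:`enumerate_pairs`; useful as a fast
    cross-check and for permutation ensembles.
    """
    return transition_matrices(series_arrays(series).count_matrix())
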