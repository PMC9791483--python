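"""Synthetic dyad generator and its memoryless null counterpart.

Real parent-toddler sessions show four joint signatures: a skewed toy
frequency distribution (the top five toys draw about half of all
selections), bursty same-toy runs, returns to favourite toys after long
delays, and close-in-time parent-toddler coupling on the same toy.  The
generator here is a deliberately minimal mechanism producing all four: a
reinforced urn ("more-gets-more") chooses a focal toy whose selection
weight grows with its past count, a persistence probability carries the
focal toy across segments (bursts), a novelty weight occasionally
introduces never-played toys, and parent acts copy the toddler's focal
toy with a coupling probability.  It is a test harness with the study's
session geometry, not a cognitive model, and none of its parametric
choices are estimated from data.

``simulate_null`` draws selections i.i.d. across segments from a fixed
toy distribution — the frequency-only null the permutation engine is
calibrated against.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .events import (
    BEHAVIOURS,
    DEFAULT_N_SEGMENTS,
    DEFAULT_UNIVERSE_SIZE,
    DyadSeries,
    SelectionEvent,
)

#: Share of events per behaviour (toddler handle, parent handle, parent
#: talk), proportional to the roughly equal engagement of the three
#: streams in free play; normalized at use.
DEFAULT_BEHAVIOUR_MIX = (0.40, 0.33, 0.37)


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic dyad generator.

    events_per_segment_rate:
        Poisson mean of coded events per 5-s segment (2.4 leaves ~91% of
        segments non-empty, matching the near-continuous engagement of
        real sessions).
    novelty_alpha:
        Probability weight of switching the focal draw to a
        never-selected toy (scaled by the fraction of toys still
        unplayed).
    reinforcement_gamma:
        Exponent on past selection counts in the focal urn; 1 is linear
        "more-gets-more" preferential reinforcement.
    persistence_rho:
        Probability that the focal toy carries over into the next
        segment, producing bursty same-toy runs.
    coupling_kappa:
        Probability that a parent act targets the toddler's focal toy of
        the current or previous segment rather than drawing on its own.
    focus_prob:
        Probability that an individual event lands on the focal toy
        rather than a fresh urn draw (off-focal events create
        within-segment diversity and D transitions).
    """

    n_toys: int = DEFAULT_UNIVERSE_SIZE
    n_segments: int = DEFAULT_N_SEGMENTS
    events_per_segment_rate: float = 2.4
    novelty_alpha: float = 0.2
    reinforcement_gamma: float = 0.25
    persistence_rho: float = 0.65
    coupling_kappa: float = 0.5
    focus_prob: float = 0.5
    behaviour_mix: tuple[float, float, float] = DEFAULT_BEHAVIOUR_MIX
    initial_toy: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("novelty_alpha", "persistence_rho", "coupling_kappa", "focus_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.events_per_segment_rate < 0:
            raise ValueError("events_per_segment_rate must be >= 0")
        if self.reinforcement_gamma < 0:
            raise ValueError("reinforcement_gamma must be >= 0")
        if self.n_toys < 1 or self.n_segments < 1:
            raise ValueError("n_toys and n_segments must be positive")
        if self.initial_toy is not None and not 0 <= self.initial_toy < self.n_toys:
            raise ValueError("initial_toy must index a toy")
        if any(w < 0 for w in self.behaviour_mix) or sum(self.behaviour_mix) <= 0:
            raise ValueError("behaviour_mix must be non-negative with positive sum")


def _toy_names(n: int) -> list[str]:
    return [f"toy{i:02d}" for i in range(1, n + 1)]


def _urn_draw(
    counts: np.ndarray, alpha: float, gamma: float, rng: np.random.Generator
) -> int:
    """Reinforced urn with novelty: new toy with weight ~ alpha, else count^gamma."""
    unselected = np.flatnonzero(counts == 0)
    if unselected.size == counts.size:
        return int(rng.choice(unselected))
    p_new = alpha * unselected.size / counts.size
    if unselected.size and rng.random() < p_new:
        return int(rng.choice(unselected))
    w = counts.astype(float) ** gamma
    w[counts == 0] = 0.0
    if w.sum() == 0:  # gamma == 0 edge: uniform over selected toys
        w[counts > 0] = 1.0
    return int(rng.choice(counts.size, p=w / w.sum()))


def simulate_dyad(
    params: GeneratorParams = GeneratorParams(),
    *,
    seed: int | None = None,
    dyad_id: str = "sim",
) -> DyadSeries:
    """Generate one coherent dyad series.

    A pure function of (params, seed): the same inputs always yield the
    identical series.  ``seed`` overrides ``params.seed`` when given.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    toys = _toy_names(params.n_toys)
    counts = np.zeros(params.n_toys, dtype=np.int64)
    mix = np.asarray(params.behaviour_mix, dtype=float)
    mix = mix / mix.sum()
    focal = params.initial_toy
    prev_focal = focal
    events: set[SelectionEvent] = set()
    for seg in range(1, params.n_segments + 1):
        if focal is None or rng.random() >= params.persistence_rho:
            new_focal = _urn_draw(counts, params.novelty_alpha,
                                  params.reinforcement_gamma, rng)
            prev_focal, focal = focal, new_focal
        else:
            prev_focal = focal
        n_events = rng.poisson(params.events_per_segment_rate)
        for _ in range(n_events):
            beh = BEHAVIOURS[rng.choice(3, p=mix)]
            if beh != "toddler_handle" and rng.random() < params.coupling_kappa:
                # parent follows the toddler's current or just-previous focus
                target = focal if (prev_focal is None or rng.random() < 0.5) else prev_focal
            elif rng.random() < params.focus_prob:
                # parents trail the focus by a segment: the toddler leads
                # toy introductions and the parent echoes them
                if beh == "toddler_handle" or prev_focal is None:
                    target = focal
                else:
                    target = prev_focal
            else:
                target = _urn_draw(counts, params.novelty_alpha,
                                   params.reinforcement_gamma, rng)
            agent, act = beh.split("_")
            events.add(SelectionEvent(toy=toys[target], agent=agent, act=act, segment=seg))
            counts[target] += 1
    return DyadSeries(
        dyad_id=dyad_id,
        events=tuple(events),
        n_segments=params.n_segments,
        toy_universe=tuple(toys),
    )


def simulate_null(
    freqs: Mapping[str, float] | Sequence[float],
    *,
    n_segments: int = DEFAULT_N_SEGMENTS,
    rate: float = 2.4,
    seed: int | None = None,
    dyad_id: str = "null",
    behaviour_mix: tuple[float, float, float] = DEFAULT_BEHAVIOUR_MIX,
) -> DyadSeries:
    """Memoryless null series: selections i.i.d. across segments.

    ``freqs`` gives the per-toy selection probabilities (must sum to 1).
    Every temporal statistic of the output is exchangeable across
    segments, so it should sit squarely inside its own permutation
    baseline.
    """
    if isinstance(freqs, Mapping):
        toys = list(freqs)
        p = np.array([freqs[t] for t in toys], dtype=float)
    else:
        p = np.asarray(freqs, dtype=float)
        toys = _toy_names(p.size)
    if p.size == 0 or np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("freqs must be non-negative and sum to 1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    mix = np.asarray(behaviour_mix, dtype=float)
    mix = mix / mix.sum()
    events: set[SelectionEvent] = set()
    for seg in range(1, n_segments + 1):
        for _ in range(rng.poisson(rate)):
            beh = BEHAVIOURS[rng.choice(3, p=mix)]
            toy = toys[rng.choice(p.size, p=p)]
            agent, act = beh.split("_")
            events.add(SelectionEvent(toy=toy, agent=agent, act=act, segment=seg))
    return DyadSeries(
        dyad_id=dyad_id,
        events=tuple(events),
        n_segments=n_segments,
        toy_universe=tuple(toys),
    )


def simulate_cohort(
    n_dyads: int,
    params: GeneratorParams = GeneratorParams(),
    *,
    seed: int | None = None,
) -> list[DyadSeries]:
    """Generate a cohort of dyads with independent per-dyad streams."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_dyads)
    return [
        simulate_dyad(
            replace(params, seed=None),
            seed=int(child.generate_state(1)[0] % (2**31)),
            dyad_id=f"dyad{i + 1:02d}",
        )
        for i, child in enumerate(children)
    ]
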