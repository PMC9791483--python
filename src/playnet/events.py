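"""Domain types and I/O for dyadic toy-selection event series.

A play session is coded on a fixed grid of 5-second segments (121 by
default, covering a ten-minute session).  Each coded *selection event* is
a referential act on one toy: the toddler handling it, the parent
handling it, or the parent talking about it.  Toddler talk is not coded.
An event is the 4-tuple (toy, agent, act, segment) and is unique within a
dyad: the same toy handled by the same agent in the same segment is one
event, however long the handling lasted, while an act bridging two
segments is coded upstream as two events.

The long-format table interchange dialect is a UTF-8 delimited file with
header ``dyad,segment,agent,act,toy`` — one row per event.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AGENTS = ("toddler", "parent")
ACTS = ("handle", "talk")
#: The three coded selection behaviours, in canonical order.
BEHAVIOURS = ("toddler_handle", "parent_handle", "parent_talk")
#: Streams accepted by :func:`behaviour_stream`.
STREAMS = BEHAVIOURS + ("all",)

DEFAULT_N_SEGMENTS = 121
DEFAULT_UNIVERSE_SIZE = 32
SEGMENT_SECONDS = 5.0

REQUIRED_COLUMNS = ("dyad", "segment", "agent", "act", "toy")


class FormatError(ValueError):
    """A malformed event table (missing columns, bad dialect)."""


class ValidationError(ValueError):
    """An event that violates the coding scheme."""


class SelectionEvent(NamedTuple):
    """One referential act: (toy, agent, act, 1-based 5-s segment)."""

    toy: str
    agent: str
    act: str
    segment: int

    @property
    def behaviour(self) -> str:
        """Behaviour label, e.g. ``"parent_talk"``."""
        return behaviour_of(self.agent, self.act)


def behaviour_of(agent: str, act: str) -> str:
    """Map (agent, act) to a behaviour label, enforcing the coding scheme."""
    if agent not in AGENTS:
        raise ValidationError(f"unknown agent {agent!r}; expected one of {AGENTS}")
    if act not in ACTS:
        raise ValidationError(f"unknown act {act!r}; expected one of {ACTS}")
    if agent == "toddler" and act == "talk":
        raise ValidationError(
            "toddler talk is not a coded selection act "
            "(only toddler handling, parent handling and parent talk are coded)"
        )
    return f"{agent}_{act}"


def event_sort_key(e: SelectionEvent):
    """Canonical ordering of events: by (segment, agent, act, toy)."""
    return (e.segment, e.agent, e.act, e.toy)


def _pad_name(i: int) -> str:
    return f"__unselected_{i:02d}"


@dataclass(frozen=True)
class DyadSeries:
    """A dyad's full session: a deduplicated event set on a fixed segment grid.

    ``toy_universe`` lists all toys available in the room, not only the
    toys actually selected; when it is not given, the observed toys are
    padded with placeholder identifiers up to ``universe_size`` so that
    zero-count toys exist for whole-universe rank statistics.
    """

    dyad_id: str
    events: tuple[SelectionEvent, ...]
    n_segments: int = DEFAULT_N_SEGMENTS
    toy_universe: tuple[str, ...] = ()
    universe_size: int = DEFAULT_UNIVERSE_SIZE

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValidationError("n_segments must be a positive integer")
        events = tuple(
            sorted(set(SelectionEvent(*e) for e in self.events), key=event_sort_key)
        )
        for e in events:
            behaviour_of(e.agent, e.act)  # raises on toddler talk
            if not 1 <= e.segment <= self.n_segments:
                raise ValidationError(
                    f"segment {e.segment} out of range 1..{self.n_segments} "
                    f"for event {e!r} in dyad {self.dyad_id!r}"
                )
        object.__setattr__(self, "events", events)
        if not self.toy_universe:
            observed = sorted({e.toy for e in events})
            pads = [
                _pad_name(i) for i in range(1, max(0, self.universe_size - len(observed)) + 1)
            ]
            object.__setattr__(self, "toy_universe", tuple(observed + pads))
        else:
            object.__setattr__(self, "toy_universe", tuple(self.toy_universe))
        universe = set(self.toy_universe)
        if len(universe) != len(self.toy_universe):
            raise ValidationError("toy_universe contains duplicate identifiers")
        for e in events:
            if e.toy not in universe:
                raise ValidationError(
                    f"toy {e.toy!r} not in toy_universe for dyad {self.dyad_id!r}"
                )

    # -- basic derived quantities -------------------------------------------

    @property
    def total_events(self) -> int:
        return len(self.events)

    @property
    def toys_selected(self) -> tuple[str, ...]:
        return tuple(sorted({e.toy for e in self.events}))

    def counts(self, behaviour: str = "all") -> dict[str, int]:
        """Per-toy event counts for one behaviour stream over the full universe."""
        if behaviour not in STREAMS:
            raise ValueError(f"unknown behaviour {behaviour!r}; expected one of {STREAMS}")
        out = {toy: 0 for toy in self.toy_universe}
        for e in self.events:
            if behaviour == "all" or e.behaviour == behaviour:
                out[e.toy] += 1
        return out

    def first_selection(self) -> dict[str, int]:
        """Earliest segment in which each selected toy appears (any act)."""
        out: dict[str, int] = {}
        for e in self.events:  # events are segment-sorted
            out.setdefault(e.toy, e.segment)
        return out

    def segments_occupied(self) -> float:
        """Fraction of segments containing at least one selection event."""
        return len({e.segment for e in self.events}) / self.n_segments

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dyad": self.dyad_id,
                "segment": [e.segment for e in self.events],
                "agent": [e.agent for e in self.events],
                "act": [e.act for e in self.events],
                "toy": [e.toy for e in self.events],
            },
            columns=list(REQUIRED_COLUMNS),
        )


@dataclass(frozen=True)
class BehaviourStream:
    """Per-toy counts and proportions for one selection behaviour (or all)."""

    behaviour: str
    counts: Mapping[str, int]
    toy_universe: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def proportions(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {toy: 0.0 for toy in self.toy_universe}
        return {toy: self.counts[toy] / total for toy in self.toy_universe}

    def count_vector(self) -> np.ndarray:
        """Counts aligned on the ordered toy universe."""
        return np.array([self.counts[t] for t in self.toy_universe], dtype=float)

    def to_dict(self) -> dict:
        return {
            "behaviour": self.behaviour,
            "total": self.total,
            "counts": dict(self.counts),
            "proportions": self.proportions,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def behaviour_stream(series: DyadSeries, behaviour: str = "all") -> BehaviourStream:
    """Project a dyad series onto one behaviour stream.

    Zero-count toys are retained so streams from the same dyad share the
    full toy universe; the ``"all"`` stream is the event-wise union of the
    three coded behaviours.
    """
    return BehaviourStream(
        behaviour=behaviour,
        counts=series.counts(behaviour),
        toy_universe=series.toy_universe,
    )


# ---------------------------------------------------------------------------
# Table I/O


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_events(
    path: str | Path,
    *,
    sep: str | None = None,
    n_segments: int = DEFAULT_N_SEGMENTS,
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
    toy_universe: Sequence[str] | None = None,
) -> list[DyadSeries]:
    """Read a long-format event table into one :class:`DyadSeries` per dyad.

    Duplicate (dyad, toy, agent, act, segment) rows are collapsed with a
    logged warning.  Rows violating the coding scheme (toddler talk,
    out-of-range segments) raise :class:`ValidationError` naming the
    offending row; a missing column raises :class:`FormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        return []

    try:
        segments = df["segment"].astype(int)
    except ValueError as exc:
        raise ValidationError(f"non-integer segment value: {exc}") from exc
    bad = (segments < 1) | (segments > n_segments)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header line
        raise ValidationError(
            f"segment {segments[bad.idxmax()]} out of range 1..{n_segments} "
            f"at line {row} of {path.name}"
        )
    talk = (df["agent"] == "toddler") & (df["act"] == "talk")
    if talk.any():
        row = int(np.flatnonzero(talk.to_numpy())[0]) + 2
        raise ValidationError(
            f"toddler talk at line {row} of {path.name}: toddler talk is not a "
            "coded selection act"
        )

    df = df.assign(segment=segments)
    n_dup = int(df.duplicated(subset=list(REQUIRED_COLUMNS)).sum())
    if n_dup:
        logger.warning(
            "%s: collapsed %d duplicate event row(s)", path.name, n_dup
        )
        df = df.drop_duplicates(subset=list(REQUIRED_COLUMNS))

    out = []
    for dyad_id, grp in df.groupby("dyad", sort=True):
        events = tuple(
            SelectionEvent(toy=r.toy, agent=r.agent, act=r.act, segment=int(r.segment))
            for r in grp.itertuples()
        )
        out.append(
            DyadSeries(
                dyad_id=str(dyad_id),
                events=events,
                n_segments=n_segments,
                toy_universe=tuple(toy_universe) if toy_universe else (),
                universe_size=universe_size,
            )
        )
    return out


def write_events(
    series: DyadSeries | Iterable[DyadSeries],
    path: str | Path,
    *,
    sep: str | None = None,
) -> None:
    """Write dyad series back to the canonical delimited dialect.

    Rows are emitted deduplicated and canonically ordered (dyad, then
    segment, agent, act, toy) so a read/write round trip is byte-stable.
    """
    if isinstance(series, DyadSeries):
        series = [series]
    path = Path(path)
    frames = [s.to_frame() for s in sorted(series, key=lambda s: s.dyad_id)]
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    df.to_csv(path, sep=_sep_for(path, sep), index=False, lineterminator="\n")
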