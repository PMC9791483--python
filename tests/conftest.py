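"""Shared fixtures: the six-event worked example used throughout the docs.

The example session fragment covers three consecutive segments (here
10..12): the toddler handles the bucket while the parent handles and
talks about the hippo, then the toddler takes over the hippo while the
parent handles the giraffe, and the toddler keeps the hippo one more
segment.
"""

from __future__ import annotations

import pytest

from playnet import DyadSeries, SelectionEvent

N = 10  # first segment of the worked example


@pytest.fixture()
def table_events() -> tuple[SelectionEvent, ...]:
    return (
        SelectionEvent("bucket", "toddler", "handle", N),
        SelectionEvent("hippo", "parent", "handle", N),
        SelectionEvent("hippo", "parent", "talk", N),
        SelectionEvent("hippo", "toddler", "handle", N + 1),
        SelectionEvent("giraffe", "parent", "handle", N + 1),
        SelectionEvent("hippo", "toddler", "handle", N + 2),
    )


@pytest.fixture()
def table_series(table_events) -> DyadSeries:
    return DyadSeries("d1", table_events)


@pytest.fixture()
def table_csv(tmp_path, table_series):
    path = tmp_path / "events.csv"
    lines = ["dyad,segment,agent,act,toy"] + [
        f"d1,{e.segment},{e.agent},{e.act},{e.toy}" for e in table_series.events
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
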