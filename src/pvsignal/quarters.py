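"""Quarter labels of the form ``2015Q1`` and inclusive quarter windows.

Spontaneous-report databases are published as quarterly file drops; the
analysis window is defined at file granularity, so quarters are the only
time axis the pipeline knows about.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering

_QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")


@total_ordering
@dataclass(frozen=True)
class Quarter:
    year: int
    q: int

    def __post_init__(self) -> None:
        if not 1 <= self.q <= 4:
            raise ValueError(f"quarter index must be 1..4, got {self.q}")

    @classmethod
    def parse(cls, label: str) -> "Quarter":
        m = _QUARTER_RE.match(str(label).strip().upper())
        if m is None:
            raise ValueError(f"bad quarter label {label!r}; expected e.g. '2015Q1'")
        return cls(int(m.group(1)), int(m.group(2)))

    def __lt__(self, other: "Quarter") -> bool:
        return (self.year, self.q) < (other.year, other.q)

    def __str__(self) -> str:
        return f"{self.year}Q{self.q}"

    def next(self) -> "Quarter":
        return Quarter(self.year + 1, 1) if self.q == 4 else Quarter(self.year, self.q + 1)


@dataclass(frozen=True)
class QuarterWindow:
    """Inclusive [start, end] window of quarters."""

    start: Quarter
    end: Quarter

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"window end {self.end} precedes start {self.start}")

    @classmethod
    def parse(cls, start: str, end: str) -> "QuarterWindow":
        return cls(Quarter.parse(start), Quarter.parse(end))

    def __contains__(self, item: "Quarter | str") -> bool:
        q = Quarter.parse(item) if isinstance(item, str) else item
        return self.start <= q <= self.end

    def quarters(self) -> list[Quarter]:
        out, q = [], self.start
        while q <= self.end:
            out.append(q)
            q = q.next()
        return out


#: The study window used throughout: first marketed quarter of the drug class
#: through the latest complete quarter at analysis time.
DEFAULT_WINDOW = QuarterWindow.parse("2015Q1", "2022Q3")
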