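"""Post-merge SV filtering.

Three removal criteria are applied, in order, to canonical events:

1. **length** — drop events with a known length of at most ``min_length``
   bp (default 1 kbp, inclusive), keeping the focus on large variants;
   breakend events without a defined length are exempt;
2. **type** — drop insertions and non-canonical composite type tags
   (``INVDUP``, ``DEL/INV``, ``DUP/INS`` by default), which short-read
   cross-validation cannot confirm;
3. **blacklist** — drop events with a junction inside a blacklist region
   of systematically unreliable calls.

An event is attributed to the first criterion that removes it, so the
per-criterion counts plus the kept count always partition the input.
Blacklist overlap is tested on the junction points, not the full span: an
SV spanning a blacklisted region with both junctions in clean sequence is
still confidently placed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .events import SVEvent
from .model import Interval

DEFAULT_EXCLUDED_TYPES = frozenset({"INS", "INVDUP", "DEL/INV", "DUP/INS"})

CRITERION_LENGTH = "length"
CRITERION_TYPE = "type"
CRITERION_BLACKLIST = "blacklist"
CRITERIA = (CRITERION_LENGTH, CRITERION_TYPE, CRITERION_BLACKLIST)


@dataclass
class FilterConfig:
    min_length: int = 1000
    excluded_types: frozenset[str] = DEFAULT_EXCLUDED_TYPES
    blacklist: Sequence[Interval] = ()

    def __post_init__(self) -> None:
        if self.min_length < 0:
            raise ValueError("min_length must be >= 0")
        self.excluded_types = frozenset(self.excluded_types)


@dataclass
class FilterResult:
    kept: list[SVEvent]
    rejected: list[tuple[SVEvent, str]]
    counts: dict[str, int] = field(default_factory=dict)

    def write_tsv(self, stream: IO[str]) -> None:
        """Rejection report: one (event id, criterion) row per removal."""
        writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
        writer.writerow(["event_id", "criterion"])
        for ev, criterion in self.rejected:
            writer.writerow([ev.id, criterion])


def _blacklist_trees(blacklist: Sequence[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in blacklist:
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end)
    return trees


def classify_event(
    event: SVEvent,
    config: FilterConfig,
    trees: Optional[dict[str, IntervalTree]] = None,
) -> Optional[str]:
    """Return the first criterion removing ``event``, or None if kept."""
    if event.length is not None and 0 <= event.length <= config.min_length:
        return CRITERION_LENGTH
    if event.sv_type in config.excluded_types:
        return CRITERION_TYPE
    if trees is None:
        trees = _blacklist_trees(config.blacklist)
    for contig, pos in event.breakpoints():
        if contig in trees and trees[contig].overlaps_point(pos):
            return CRITERION_BLACKLIST
    return None


def filter_events(
    events: Iterable[SVEvent], config: Optional[FilterConfig] = None
) -> FilterResult:
    """Partition events into kept and rejected-with-criterion."""
    if config is None:
        config = FilterConfig()
    trees = _blacklist_trees(config.blacklist)
    kept: list[SVEvent] = []
    rejected: list[tuple[SVEvent, str]] = []
    counts = {c: 0 for c in CRITERIA}
    for ev in events:
        criterion = classify_event(ev, config, trees)
        if criterion is None:
            kept.append(ev)
        else:
            rejected.append((ev, criterion))
            counts[criterion] += 1
    return FilterResult(kept=kept, rejected=rejected, counts=counts)
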