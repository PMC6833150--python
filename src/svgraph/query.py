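"""Interval-induced subgraph extraction, caching, and gene lookup.

This is the backend-server contract: a client asks for a genomic
interval on a reference path and receives the restriction of the graph
to that neighborhood.  Variant paths touching the interval are included
*whole*, so the remote side of a translocation or a multi-megabase
inversion appears in the same response (its flanks are already bounded,
so subgraphs stay small).  Read and annotation paths are evidence, not
structure: they are restricted to the included nodes but never pull
additional nodes in.  Repeated interval requests are served from an LRU
cache without re-extraction.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import QueryError
from .model import Interval, Path, PathStep, VariationGraph
from .projections import Feature


@dataclass
class Subgraph:
    """An interval-induced restriction of a variation graph.

    Node ids are the parent's (``parent_map`` is the identity on the
    included ids, trivially injective); paths are broken into maximal
    contiguous runs over included nodes.
    """

    nodes: dict
    paths: list[Path]
    parent_map: dict[int, int]
    anchors: list[Interval] = field(default_factory=list)

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    def paths_by_class(self, path_class: str) -> list[Path]:
        return [p for p in self.paths if p.path_class == path_class]

    def validate(self) -> list[str]:
        report = []
        for path in self.paths:
            for step in path.steps:
                if step.node_id not in self.nodes:
                    report.append(
                        f"restriction-closure: path {path.name!r} step "
                        f"{step.node_id} not in subgraph"
                    )
        values = list(self.parent_map.values())
        if len(set(values)) != len(values):
            report.append("parent-map: not injective")
        return report


def _restrict_path(path: Path, included: set[int]) -> list[Path]:
    """Break a path into maximal step runs whose nodes are all included."""
    runs: list[list[PathStep]] = []
    current: list[PathStep] = []
    for step in path.steps:
        if step.node_id in included:
            current.append(step)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    if not runs:
        return []
    if len(runs) == 1:
        return [Path(path.name, path.path_class, runs[0], dict(path.metadata))]
    return [
        Path(f"{path.name}[{i}]", path.path_class, run, dict(path.metadata))
        for i, run in enumerate(runs)
    ]


def extract_subgraph(
    graph: VariationGraph, interval: Interval, padding: int = 0
) -> Subgraph:
    """Interval-induced subgraph.

    Includes (a) reference nodes overlapping the (optionally padded)
    interval, (b) every node of every variant path that touches (a), and
    (c) all paths restricted to the included node set.  An empty overlap
    yields an empty subgraph; an unknown contig is an error.
    """
    if interval.contig not in graph.contigs:
        raise QueryError(f"unknown contig {interval.contig!r}")
    start = max(0, interval.start - padding)
    end = min(graph.contigs[interval.contig].length, interval.end + padding)
    core = {n.id for n in graph.nodes_in(interval.contig, start, end)} if start < end else set()

    included = set(core)
    for path in graph.paths:
        if path.path_class != "variant":
            continue
        if any(step.node_id in core for step in path.steps):
            included.update(step.node_id for step in path.steps)

    paths: list[Path] = []
    for path in graph.paths:
        paths.extend(_restrict_path(path, included))

    return Subgraph(
        nodes={i: graph.nodes[i] for i in sorted(included)},
        paths=paths,
        parent_map={i: i for i in sorted(included)},
        anchors=[interval],
    )


class QueryCache:
    """LRU cache of subgraphs keyed on the exact (contig, start, end) triple."""

    def __init__(self, capacity: int = 128):
        if capacity < 1:
            raise ValueError("cache capacity must be >= 1")
        self.capacity = capacity
        self._store: "OrderedDict[tuple, Subgraph]" = OrderedDict()
        self.hits = 0
        self.misses = 0
        self.evictions = 0

    def __len__(self) -> int:
        return len(self._store)

    def get(self, key: tuple) -> Optional[Subgraph]:
        if key in self._store:
            self._store.move_to_end(key)
            self.hits += 1
            return self._store[key]
        self.misses += 1
        return None

    def put(self, key: tuple, value: Subgraph) -> None:
        self._store[key] = value
        self._store.move_to_end(key)
        if len(self._store) > self.capacity:
            self._store.popitem(last=False)
            self.evictions += 1


def cached_query(
    cache: QueryCache,
    graph: VariationGraph,
    interval: Interval,
    padding: int = 0,
) -> Subgraph:
    """Serve a subgraph query through the cache (transparent on content)."""
    key = (interval.contig, interval.start, interval.end, padding)
    hit = cache.get(key)
    if hit is not None:
        return hit
    sub = extract_subgraph(graph, interval, padding=padding)
    cache.put(key, sub)
    return sub


def gene_to_interval(
    name_prefix: str, features: Sequence[Feature]
) -> tuple[list[str], Optional[Interval]]:
    """Autocomplete a gene-name prefix and resolve an exact unique match.

    Matching is case-insensitive; completions are sorted.  The resolved
    interval is returned only when exactly one feature bears the name.
    """
    prefix = name_prefix.lower()
    completions = sorted(
        {f.name for f in features if f.name.lower().startswith(prefix)},
        key=str.lower,
    )
    exact = [f for f in features if f.name.lower() == prefix] if name_prefix else []
    resolved = exact[0].interval if len(exact) == 1 else None
    return completions, resolved


@dataclass
class DeckSummary:
    """One-line result for one queued interval."""

    interval: Interval
    kept: bool
    node_count: int = 0
    variant_paths: int = 0
    error: Optional[str] = None

    def line(self) -> str:
        if self.error:
            return f"{self.interval}\tERROR\t{self.error}"
        verdict = "keep" if self.kept else "discard"
        return (
            f"{self.interval}\t{verdict}\tnodes={self.node_count}"
            f"\tvariant_paths={self.variant_paths}"
        )


def deck_run(
    graph: VariationGraph,
    intervals: Sequence[Interval],
    decisions: Optional[Sequence[bool]] = None,
    cache: Optional[QueryCache] = None,
    padding: int = 0,
) -> tuple[list[Interval], list[DeckSummary]]:
    """Batch-evaluate a queue of intervals (the card-deck workflow).

    Each interval is queried through the cache; per-interval errors are
    collected, never aborting the batch.  Returns the kept intervals in
    original order plus a summary per interval.
    """
    if decisions is None:
        decisions = [True] * len(intervals)
    if len(decisions) != len(intervals):
        raise ValueError("decisions must match intervals one-to-one")
    if cache is None:
        cache = QueryCache()

    kept: list[Interval] = []
    summaries: list[DeckSummary] = []
    for interval, keep in zip(intervals, decisions):
        try:
            sub = cached_query(cache, graph, interval, padding=padding)
        except QueryError as exc:
            summaries.append(DeckSummary(interval, kept=False, error=str(exc)))
            continue
        summaries.append(
            DeckSummary(
                interval,
                kept=bool(keep),
                node_count=sub.node_count,
                variant_paths=len(sub.paths_by_class("variant")),
            )
        )
        if keep:
            kept.append(interval)
    return kept, summaries
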