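"""Variation-graph construction from a reference genome and SV events.

The build follows a six-step breakpoint-splitting procedure:

1. collect the junction boundaries of all events (the breakpoint list);
2. start with one node per chromosome;
3. split nodes at a fixed pitch (1 Mbp by default) to bound node size;
4. split the node containing each breakpoint at the breakpoint;
5. add one forward reference path per chromosome;
6. add one variant path per event, creating a new node for each
   insertion's sequence.

Steps 2–4 reduce to computing the sorted union of pitch multiples and
breakpoints per contig, which also makes the split order immaterial.
Node ids are assigned densely in ascending reference order (contigs in
input order), then insertion nodes continue from max+1 — identical inputs
always produce identical ids and step lists.

Every variant path carries flanking sequence on each side of each
junction so the defining edge is witnessed by a node adjacency: the flank
extends to the farthest existing node boundary within ``max_flank`` of
the junction (the pitch guarantees one exists), truncated at contig ends.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import GraphBuildError
from .events import SIDE_LEFT, SIDE_RIGHT, Breakend, SVEvent, events_to_breakpoints
from .model import (
    FORWARD,
    MAX_NODE_LENGTH,
    REVERSE,
    Contig,
    Node,
    Path,
    PathStep,
    VariationGraph,
)


@dataclass
class BuildConfig:
    #: split reference nodes at this pitch (bp)
    max_node_length: int = MAX_NODE_LENGTH
    #: maximum reference extent of the flank on each side of a junction (bp)
    max_flank: int = MAX_NODE_LENGTH

    def __post_init__(self) -> None:
        if self.max_node_length < 1 or self.max_flank < 1:
            raise ValueError("max_node_length and max_flank must be >= 1")


def path_name_for_event(event: SVEvent) -> str:
    """Stable variant-path name: ``{TYPE}_{id}_{contig}:{1-based pos}``."""
    a = event.breakend_a
    return f"{event.sv_type}_{event.id}_{a.contig}:{a.pos + 1}"


def _check_events(genome: Sequence[Contig], events: Sequence[SVEvent]) -> None:
    lengths = {c.name: c.length for c in genome}
    for ev in events:
        for contig, pos in ev.breakpoints():
            if contig not in lengths:
                raise GraphBuildError(
                    f"event {ev.id}: breakend on unknown contig {contig!r}"
                )
            if not 0 <= pos <= lengths[contig]:
                raise GraphBuildError(
                    f"event {ev.id}: breakend {contig}:{pos} outside "
                    f"[0, {lengths[contig]}]"
                )
        if ev.sv_type == "INS" and ev.inserted_sequence is None and ev.length is None:
            raise GraphBuildError(
                f"event {ev.id}: insertion without sequence or length"
            )


def contig_boundaries(
    length: int, breakpoints: Sequence[int], pitch: int
) -> list[int]:
    """Sorted node start positions for one contig (steps 2-4 collapsed)."""
    cuts = set(range(0, length, pitch))
    cuts.update(bp for bp in breakpoints if 0 < bp < length)
    cuts.add(0)
    return sorted(cuts)


def build_graph(
    genome: Sequence[Contig],
    events: Sequence[SVEvent] = (),
    config: Optional[BuildConfig] = None,
) -> VariationGraph:
    """Construct the variation graph for ``genome`` with ``events``."""
    if config is None:
        config = BuildConfig()
    _check_events(genome, events)
    breakpoints = events_to_breakpoints(events)

    graph = VariationGraph(genome)
    next_id = 1
    for contig in genome:
        starts = contig_boundaries(
            contig.length, breakpoints.get(contig.name, ()), config.max_node_length
        )
        ends = starts[1:] + [contig.length]
        steps = []
        for start, end in zip(starts, ends):
            seq = contig.sequence[start:end] if contig.sequence is not None else None
            graph.add_node(
                Node(
                    id=next_id,
                    length=end - start,
                    sequence=seq,
                    origin=(contig.name, start, end),
                )
            )
            steps.append(PathStep(next_id, FORWARD))
            next_id += 1
        graph.add_path(Path(name=contig.name, path_class="reference", steps=steps))

    # insertion nodes, then variant paths, in deterministic event order
    order = sorted(
        range(len(events)),
        key=lambda i: (
            events[i].breakend_a.sort_key(),
            events[i].sv_type,
            events[i].id,
        ),
    )
    ins_nodes: dict[int, int] = {}
    for i in order:
        ev = events[i]
        if ev.sv_type == "INS":
            seq = ev.inserted_sequence
            if seq is None:
                seq = "N" * int(ev.length or 0)
            if not seq:
                raise GraphBuildError(f"event {ev.id}: empty insertion sequence")
            node = graph.add_node(Node(id=next_id, length=len(seq), sequence=seq))
            ins_nodes[i] = node.id
            next_id += 1
    for i in order:
        ev = events[i]
        path = make_sv_path(graph, ev, config, insertion_node=ins_nodes.get(i))
        graph.add_path(path)
    return graph


# ---------------------------------------------------------------------------
# variant-path synthesis


def _flank_start(graph: VariationGraph, contig: str, pos: int, max_flank: int) -> int:
    """Farthest node boundary at most ``max_flank`` left of ``pos``.

    When no boundary other than ``pos`` itself lies within range (possible
    only if ``max_flank`` is below the node pitch), fall back to the single
    adjacent node so the junction edge is still witnessed.
    """
    bounds = graph.boundaries(contig)
    i = bisect_left(bounds, max(0, pos - max_flank))
    if bounds[i] == pos and i > 0:
        return bounds[i - 1]
    return bounds[i]


def _flank_end(graph: VariationGraph, contig: str, pos: int, max_flank: int) -> int:
    """Farthest node boundary at most ``max_flank`` right of ``pos``."""
    bounds = graph.boundaries(contig)
    limit = min(bounds[-1], pos + max_flank)
    i = bisect_right(bounds, limit) - 1
    if bounds[i] == pos and i + 1 < len(bounds):
        return bounds[i + 1]
    return bounds[i]


def _steps(
    graph: VariationGraph, contig: str, start: int, end: int, orientation: str = FORWARD
) -> list[PathStep]:
    """Steps over the reference nodes tiling ``[start, end)``.

    ``start``/``end`` must be node boundaries.  Reverse orientation yields
    the nodes in reversed order with reverse steps.
    """
    if start >= end:
        return []
    nodes = graph.nodes_in(contig, start, end)
    for n in nodes:
        _, n_start, n_end = n.origin  # type: ignore[misc]
        if n_start < start or n_end > end:
            raise GraphBuildError(
                f"interval [{start},{end}) on {contig} is not node-aligned "
                f"(node {n.id} spans [{n_start},{n_end}))"
            )
    steps = [PathStep(n.id, orientation) for n in nodes]
    return steps if orientation == FORWARD else steps[::-1]


def _bnd_half(
    graph: VariationGraph, be: Breakend, max_flank: int, entering: bool
) -> list[PathStep]:
    """Steps for one side of a breakend junction.

    ``entering`` selects the half that runs *into* the junction; otherwise
    the half *leaving* it.  A retained left flank is traversed forward, a
    retained right flank reverse — so the junction always sits between the
    two halves of the path.
    """
    if be.side == SIDE_LEFT:
        seg = _steps(
            graph, be.contig, _flank_start(graph, be.contig, be.pos, max_flank), be.pos
        )
        if entering:
            return seg
        return [s.flipped() for s in reversed(seg)]
    seg = _steps(
        graph, be.contig, be.pos, _flank_end(graph, be.contig, be.pos, max_flank)
    )
    if entering:
        return [s.flipped() for s in reversed(seg)]
    return seg


def make_sv_path(
    graph: VariationGraph,
    event: SVEvent,
    config: Optional[BuildConfig] = None,
    insertion_node: Optional[int] = None,
) -> Path:
    """Synthesize the variant-class path for one canonical event.

    Requires every junction boundary of the event to be a node boundary in
    ``graph`` (guaranteed by :func:`build_graph`).
    """
    if config is None:
        config = BuildConfig()
    mf = config.max_flank
    a, b = event.breakend_a, event.breakend_b
    meta = {"sv_type": event.sv_type, "event_id": event.id}
    if event.support is not None:
        meta["support"] = event.support

    if event.sv_type == "DEL":
        up = _steps(graph, a.contig, _flank_start(graph, a.contig, a.pos, mf), a.pos)
        down = _steps(graph, b.contig, b.pos, _flank_end(graph, b.contig, b.pos, mf))
        steps = up + down
    elif event.sv_type == "INV":
        up = _steps(graph, a.contig, _flank_start(graph, a.contig, a.pos, mf), a.pos)
        middle = _steps(graph, a.contig, a.pos, b.pos, REVERSE)
        down = _steps(graph, b.contig, b.pos, _flank_end(graph, b.contig, b.pos, mf))
        steps = up + middle + down
    elif event.sv_type == "DUP":
        up = _steps(graph, a.contig, _flank_start(graph, a.contig, a.pos, mf), a.pos)
        body = _steps(graph, a.contig, a.pos, b.pos)
        down = _steps(graph, b.contig, b.pos, _flank_end(graph, b.contig, b.pos, mf))
        steps = up + body + body + down
    elif event.sv_type == "INS":
        if insertion_node is None:
            raise GraphBuildError(
                f"event {event.id}: insertion path requires its sequence node"
            )
        up = _steps(graph, a.contig, _flank_start(graph, a.contig, a.pos, mf), a.pos)
        down = _steps(graph, a.contig, a.pos, _flank_end(graph, a.contig, a.pos, mf))
        steps = up + [PathStep(insertion_node, FORWARD)] + down
    elif event.sv_type == "BND":
        steps = _bnd_half(graph, a, mf, entering=True) + _bnd_half(
            graph, b, mf, entering=False
        )
    else:
        raise GraphBuildError(
            f"event {event.id}: cannot build a path for SV type {event.sv_type!r}"
        )

    if not steps:
        raise GraphBuildError(f"event {event.id}: produced an empty path")
    return Path(
        name=path_name_for_event(event),
        path_class="variant",
        steps=steps,
        metadata=meta,
    )
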