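"""In-memory variation-graph model.

A variation graph here is a set of sequence *nodes* plus embedded *paths*;
edges are never stored explicitly, they are implied by adjacent steps in
paths.  Four path classes are distinguished:

``reference``
    one per chromosome, spelling the linear reference forward;
``variant``
    one per structural-variant call, with flanking sequence on each side
    of every junction so the defining edge is witnessed by an adjacency;
``read``
    projected read alignments (split reads become multi-segment walks);
``annotation``
    genes, repeats and other linear-coordinate features.

All internal coordinates are 0-based half-open.  Reference-origin nodes of
a contig tile ``[0, length)`` without gap or overlap, which makes position
lookup a binary search over node starts.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Mapping, Optional, Sequence

from .errors import CoordinateError, SvGraphError

FORWARD = "+"
REVERSE = "-"
Orientation = Literal["+", "-"]

#: path classes, in canonical serialization order
PATH_CLASSES = ("reference", "variant", "read", "annotation")

#: default upper bound on node length (bp); nodes are split at this pitch
MAX_NODE_LENGTH = 1_000_000


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval — the universal query currency."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @classmethod
    def from_1based_closed(cls, contig: str, start: int, end: int) -> "Interval":
        """Build from 1-based closed coordinates as printed in browsers."""
        return cls(contig, start - 1, end)

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos < self.end

    def __str__(self) -> str:  # 1-based closed, the browser convention
        return f"{self.contig}:{self.start + 1}-{self.end}"


def interval_distance(a: Interval, b: Interval) -> int:
    """Gap in bp between two intervals on the same contig (0 if they touch).

    Half-open intervals that abut (``a.end == b.start``) have distance 0.
    """
    if a.contig != b.contig:
        raise CoordinateError(
            f"interval_distance requires one contig, got {a.contig!r} and {b.contig!r}"
        )
    return max(0, max(a.start, b.start) - min(a.end, b.end))


@dataclass
class Contig:
    """A reference chromosome or scaffold; sequence is optional."""

    name: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("contig name must be non-empty")
        if self.length < 1:
            raise ValueError(f"contig {self.name}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.name}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass
class Node:
    """A piece of genomic sequence.

    ``origin`` is a ``(contig, start, end)`` reference interval for nodes cut
    from the reference, or ``None`` for inserted sequence.  ``sequence`` may
    be withheld (length-only graphs) when the reference FASTA is not loaded.
    """

    id: int
    length: int
    sequence: Optional[str] = None
    origin: Optional[tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        if self.id < 1:
            raise ValueError(f"node id must be a positive integer, got {self.id}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"node {self.id}: sequence length {len(self.sequence)} != {self.length}"
            )

    @property
    def is_reference(self) -> bool:
        return self.origin is not None


@dataclass(frozen=True)
class PathStep:
    """One oriented traversal of a node."""

    node_id: int
    orientation: Orientation = FORWARD

    def flipped(self) -> "PathStep":
        return PathStep(self.node_id, REVERSE if self.orientation == FORWARD else FORWARD)

    def __str__(self) -> str:
        return f"{self.node_id}{self.orientation}"


@dataclass
class Path:
    """A named, classed walk of oriented node steps."""

    name: str
    path_class: str
    steps: list[PathStep]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.path_class not in PATH_CLASSES:
            raise ValueError(f"unknown path class {self.path_class!r}")
        if not self.steps:
            raise ValueError(f"path {self.name!r}: steps must be non-empty")

    def edges(self) -> Iterator[tuple[PathStep, PathStep]]:
        """Yield the implicit edges: every ordered adjacent step pair."""
        for a, b in zip(self.steps, self.steps[1:]):
            yield a, b


class VariationGraph:
    """Nodes, paths and a per-contig reference coordinate index."""

    def __init__(self, contigs: Iterable[Contig] = ()):
        self.contigs: dict[str, Contig] = {}
        self.nodes: dict[int, Node] = {}
        self.paths: list[Path] = []
        # per contig: parallel sorted lists of node starts and node ids
        self._starts: dict[str, list[int]] = {}
        self._tiling: dict[str, list[int]] = {}
        for c in contigs:
            self.add_contig(c)

    # -- construction -----------------------------------------------------

    def add_contig(self, contig: Contig) -> None:
        if contig.name in self.contigs:
            raise ValueError(f"duplicate contig name {contig.name!r}")
        self.contigs[contig.name] = contig
        self._starts[contig.name] = []
        self._tiling[contig.name] = []

    def add_node(self, node: Node) -> Node:
        if node.id in self.nodes:
            raise ValueError(f"duplicate node id {node.id}")
        self.nodes[node.id] = node
        if node.origin is not None:
            contig, start, end = node.origin
            if end - start != node.length:
                raise ValueError(
                    f"node {node.id}: origin span {end - start} != length {node.length}"
                )
            if contig not in self.contigs:
                raise ValueError(f"node {node.id}: unknown origin contig {contig!r}")
            starts = self._starts[contig]
            ids = self._tiling[contig]
            starts.append(start)
            ids.append(node.id)
            if len(starts) > 1 and starts[-1] < starts[-2]:
                # out-of-order insert (e.g. GFA input): re-sort the index
                order = sorted(range(len(starts)), key=starts.__getitem__)
                self._starts[contig] = [starts[i] for i in order]
                self._tiling[contig] = [ids[i] for i in order]
        return node

    def add_path(self, path: Path) -> Path:
        for step in path.steps:
            if step.node_id not in self.nodes:
                raise ValueError(
                    f"path {path.name!r}: step references missing node {step.node_id}"
                )
        self.paths.append(path)
        return path

    def next_node_id(self) -> int:
        return max(self.nodes, default=0) + 1

    # -- coordinate index -------------------------------------------------

    def locate(self, contig: str, pos: int) -> tuple[int, int]:
        """Map a reference position to ``(node id, offset within node)``."""
        if contig not in self.contigs:
            raise CoordinateError(f"unknown contig {contig!r}")
        if not (0 <= pos < self.contigs[contig].length):
            raise CoordinateError(
                f"position {pos} out of range for {contig} "
                f"(length {self.contigs[contig].length})"
            )
        starts = self._starts[contig]
        i = bisect_right(starts, pos) - 1
        if i < 0:
            raise SvGraphError(f"no reference node covers {contig}:{pos}")
        node_id = self._tiling[contig][i]
        return node_id, pos - starts[i]

    def boundaries(self, contig: str) -> list[int]:
        """Sorted node boundaries of a contig, including 0 and its length."""
        if contig not in self.contigs:
            raise CoordinateError(f"unknown contig {contig!r}")
        return self._starts[contig] + [self.contigs[contig].length]

    def reference_nodes(self, contig: str) -> list[Node]:
        """Reference-origin nodes of a contig in ascending order."""
        return [self.nodes[i] for i in self._tiling.get(contig, [])]

    def nodes_in(self, contig: str, start: int, end: int) -> list[Node]:
        """Reference nodes overlapping ``[start, end)``, in reference order."""
        if contig not in self.contigs:
            raise CoordinateError(f"unknown contig {contig!r}")
        starts = self._starts[contig]
        ids = self._tiling[contig]
        lo = max(0, bisect_right(starts, start) - 1)
        out: list[Node] = []
        for i in range(lo, len(ids)):
            node = self.nodes[ids[i]]
            n_start = node.origin[1]  # type: ignore[index]
            n_end = node.origin[2]  # type: ignore[index]
            if n_start >= end:
                break
            if n_end > start:
                out.append(node)
        return out

    # -- views ------------------------------------------------------------

    def paths_by_class(self, path_class: str) -> list[Path]:
        return [p for p in self.paths if p.path_class == path_class]

    def reference_path(self, contig: str) -> Optional[Path]:
        for p in self.paths:
            if p.path_class == "reference" and p.name == contig:
                return p
        return None

    def edges(self) -> set[tuple[int, str, int, str]]:
        """Distinct directed edges implied by all paths."""
        out: set[tuple[int, str, int, str]] = set()
        for path in self.paths:
            for a, b in path.edges():
                out.add((a.node_id, a.orientation, b.node_id, b.orientation))
        return out

    def node_sequence(self, node: Node) -> Optional[str]:
        """Node sequence, pulling from the contig when not stored per node."""
        if node.sequence is not None:
            return node.sequence
        if node.origin is not None:
            contig, start, end = node.origin
            seq = self.contigs[contig].sequence
            if seq is not None:
                return seq[start:end]
        return None

    def contig_sequence_from_path(self, contig: str) -> Optional[str]:
        """Concatenate reference-path node sequences for a contig."""
        path = self.reference_path(contig)
        if path is None:
            return None
        parts = []
        for step in path.steps:
            seq = self.node_sequence(self.nodes[step.node_id])
            if seq is None:
                return None
            parts.append(seq)
        return "".join(parts)


def canonical_edge(a: PathStep, b: PathStep) -> tuple[int, str, int, str]:
    """Orientation-insensitive edge identity.

    Traversing an adjacency forward (``x+ -> y+``) and in reverse
    complement (``y- -> x-``) witnesses the same physical junction; both
    map to one canonical tuple.
    """
    fwd = (a.node_id, a.orientation, b.node_id, b.orientation)
    rev = (
        b.node_id,
        REVERSE if b.orientation == FORWARD else FORWARD,
        a.node_id,
        REVERSE if a.orientation == FORWARD else FORWARD,
    )
    return min(fwd, rev)


def path_edge_set(path: Path) -> set[tuple[int, str, int, str]]:
    """Canonical edges witnessed by a path."""
    return {canonical_edge(a, b) for a, b in path.edges()}


def validate_graph(
    graph: VariationGraph, max_node_length: int = MAX_NODE_LENGTH
) -> list[str]:
    """Check every structural invariant; return violations (empty == valid).

    Violations are data, not exceptions: each entry names the invariant and
    the offending object so reports can be logged or asserted on.
    """
    report: list[str] = []

    for node in graph.nodes.values():
        if node.length < 1:
            report.append(f"node-length: node {node.id} has length {node.length} < 1")
        if node.length > max_node_length:
            report.append(
                f"node-length-bound: node {node.id} has length {node.length} "
                f"> {max_node_length}"
            )
        if node.origin is not None:
            contig, start, end = node.origin
            if end - start != node.length:
                report.append(
                    f"origin-span: node {node.id} origin [{start},{end}) "
                    f"!= length {node.length}"
                )

    # tiling: reference-origin nodes cover [0, length) without gap/overlap
    for name, contig in graph.contigs.items():
        nodes = sorted(
            (n for n in graph.nodes.values() if n.origin and n.origin[0] == name),
            key=lambda n: n.origin[1],  # type: ignore[index]
        )
        if not nodes:
            continue
        cursor = 0
        ok = True
        for n in nodes:
            _, start, end = n.origin  # type: ignore[misc]
            if start != cursor:
                report.append(
                    f"tiling: contig {name} gap/overlap at {cursor} "
                    f"(node {n.id} starts at {start})"
                )
                ok = False
                cursor = end
                continue
            cursor = end
        if ok and cursor != contig.length:
            report.append(
                f"tiling: contig {name} tiled to {cursor}, length is {contig.length}"
            )

    seen_names: dict[str, set[str]] = {c: set() for c in PATH_CLASSES}
    for path in graph.paths:
        if path.name in seen_names.get(path.path_class, set()):
            report.append(
                f"path-name: duplicate {path.path_class} path name {path.name!r}"
            )
        seen_names.setdefault(path.path_class, set()).add(path.name)
        for step in path.steps:
            if step.node_id not in graph.nodes:
                report.append(
                    f"path-step: path {path.name!r} references missing node "
                    f"{step.node_id}"
                )
        if path.path_class == "reference":
            if any(s.orientation == REVERSE for s in path.steps):
                report.append(
                    f"reference-orientation: reference path {path.name!r} "
                    "contains a reverse step"
                )

    # reference paths must walk the tiling in order
    for name in graph.contigs:
        path = graph.reference_path(name)
        if path is None:
            continue
        expected = [n.id for n in graph.reference_nodes(name)]
        actual = [s.node_id for s in path.steps]
        if expected and actual != expected:
            report.append(
                f"reference-walk: path {name!r} does not traverse the tiling in order"
            )
        seq = graph.contigs[name].sequence
        if seq is not None:
            rebuilt = graph.contig_sequence_from_path(name)
            if rebuilt is not None and rebuilt != seq:
                report.append(
                    f"sequence-conservation: reference path {name!r} does not "
                    "reproduce the contig sequence"
                )

    return report
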