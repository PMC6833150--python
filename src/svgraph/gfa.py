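"""Serialization: GFA1 for graphs, JSON for subgraphs, CSV for event lists.

GFA1 carries the whole graph: one ``S`` line per node (sequence, or ``*``
with an ``LN`` tag for length-only graphs), one ``P`` line per path, and
one ``L`` line per distinct adjacent-step pair with a ``0M`` overlap —
edges are derived from paths, never stored independently.  Reference
origin travels on ``SN``/``SO`` tags (contig name / 0-based offset, as in
rGFA); path class on a ``PC`` tag and metadata on an ``MD`` JSON tag.
Output ordering is deterministic (nodes by id; paths by class, then
name), so a graph serializes byte-identically every time.

Machine-facing JSON uses 0-based half-open coordinates; the CSV event
table is 1-based for human consumption.
"""

from __future__ import annotations

import csv
import io
import json
from pathlib import Path as FilePath
from typing import IO, Iterable, Optional, Sequence, Union

from .errors import GfaError
from .events import SVEvent
from .model import (
    FORWARD,
    PATH_CLASSES,
    Contig,
    Node,
    Path,
    PathStep,
    VariationGraph,
)
from .query import Subgraph

GFA_VERSION = "1.0"

#: above this node length, S lines are emitted length-only (LN tag, no sequence)
DEFAULT_SEQUENCE_THRESHOLD: Optional[int] = None


def _open(stream_or_path, mode: str):
    if isinstance(stream_or_path, (str, FilePath)):
        return open(stream_or_path, mode), True
    return stream_or_path, False


def _path_sort_key(path: Path):
    return (PATH_CLASSES.index(path.path_class), path.name)


def write_gfa(
    graph: VariationGraph,
    stream_or_path: Union[str, FilePath, IO[str]],
    sequence_threshold: Optional[int] = DEFAULT_SEQUENCE_THRESHOLD,
) -> None:
    """Write the graph as GFA1 (S, then L, then P lines, all sorted)."""
    out, should_close = _open(stream_or_path, "w")
    try:
        out.write(f"H\tVN:Z:{GFA_VERSION}\n")
        for node_id in sorted(graph.nodes):
            node = graph.nodes[node_id]
            seq = graph.node_sequence(node)
            if seq is None or (
                sequence_threshold is not None and node.length > sequence_threshold
            ):
                fields = ["S", str(node_id), "*", f"LN:i:{node.length}"]
            else:
                fields = ["S", str(node_id), seq, f"LN:i:{node.length}"]
            if node.origin is not None:
                contig, start, _end = node.origin
                fields.append(f"SN:Z:{contig}")
                fields.append(f"SO:i:{start}")
            out.write("\t".join(fields) + "\n")
        for a_id, a_or, b_id, b_or in sorted(graph.edges()):
            out.write(f"L\t{a_id}\t{a_or}\t{b_id}\t{b_or}\t0M\n")
        for path in sorted(graph.paths, key=_path_sort_key):
            steps = ",".join(f"{s.node_id}{s.orientation}" for s in path.steps)
            fields = ["P", path.name, steps, "*", f"PC:Z:{path.path_class}"]
            if path.metadata:
                fields.append(
                    "MD:Z:" + json.dumps(path.metadata, sort_keys=True, separators=(",", ":"))
                )
            out.write("\t".join(fields) + "\n")
    finally:
        if should_close:
            out.close()


def gfa_string(graph: VariationGraph, **kwargs) -> str:
    buf = io.StringIO()
    write_gfa(graph, buf, **kwargs)
    return buf.getvalue()


def _parse_tags(fields: Sequence[str], lineno: int) -> dict[str, str]:
    tags: dict[str, str] = {}
    for raw in fields:
        parts = raw.split(":", 2)
        if len(parts) != 3:
            raise GfaError(f"malformed tag {raw!r}", lineno)
        tags[parts[0]] = parts[2]
    return tags


def read_gfa(stream_or_path: Union[str, FilePath, IO[str]]) -> VariationGraph:
    """Parse GFA1 with P lines back into a variation graph.

    Round-trips the writer's output exactly.  For GFA from other
    producers (no SN/SO origin tags, no PC class tags), untagged paths
    are taken as reference paths and node origins are reconstructed from
    their cumulative walk, so the coordinate index still works.
    """
    fh, should_close = _open(stream_or_path, "r")
    try:
        seqs: dict[int, Optional[str]] = {}
        lengths: dict[int, int] = {}
        origins: dict[int, tuple[str, int]] = {}
        raw_paths: list[tuple[str, list[PathStep], str, dict, int]] = []
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "H":
                continue
            if kind == "S":
                if len(fields) < 3:
                    raise GfaError("S line needs id and sequence", lineno)
                try:
                    node_id = int(fields[1])
                except ValueError:
                    raise GfaError(f"non-integer segment name {fields[1]!r}", lineno)
                seq = fields[2]
                tags = _parse_tags(fields[3:], lineno)
                if seq == "*":
                    if "LN" not in tags:
                        raise GfaError(
                            f"segment {node_id}: no sequence and no LN tag", lineno
                        )
                    seqs[node_id] = None
                    lengths[node_id] = int(tags["LN"])
                else:
                    seqs[node_id] = seq
                    lengths[node_id] = len(seq)
                if "SN" in tags and "SO" in tags:
                    origins[node_id] = (tags["SN"], int(tags["SO"]))
            elif kind == "L":
                if len(fields) < 6:
                    raise GfaError("L line needs 5 fields", lineno)
                for ref in (fields[1], fields[3]):
                    if int(ref) not in lengths:
                        raise GfaError(
                            f"L line references missing segment {ref}", lineno
                        )
            elif kind == "P":
                if len(fields) < 4:
                    raise GfaError("P line needs name, steps, overlaps", lineno)
                name = fields[1]
                steps = []
                for token in fields[2].split(","):
                    if not token or token[-1] not in "+-":
                        raise GfaError(f"malformed path step {token!r}", lineno)
                    steps.append(PathStep(int(token[:-1]), token[-1]))
                tags = _parse_tags(fields[4:], lineno)
                path_class = tags.get("PC", "reference")
                metadata = json.loads(tags["MD"]) if "MD" in tags else {}
                raw_paths.append((name, steps, path_class, metadata, lineno))
        return _assemble(seqs, lengths, origins, raw_paths)
    finally:
        if should_close:
            fh.close()


def _assemble(seqs, lengths, origins, raw_paths) -> VariationGraph:
    # reconstruct origins from reference walks when SN/SO tags are absent
    if not origins:
        for name, steps, path_class, _meta, lineno in raw_paths:
            if path_class != "reference":
                continue
            offset = 0
            for step in steps:
                if step.node_id not in lengths:
                    raise GfaError(
                        f"path {name!r} references missing segment {step.node_id}",
                        lineno,
                    )
                origins[step.node_id] = (name, offset)
                offset += lengths[step.node_id]

    contig_len: dict[str, int] = {}
    contig_seq: dict[str, list] = {}
    for node_id, (contig, start) in origins.items():
        end = start + lengths[node_id]
        contig_len[contig] = max(contig_len.get(contig, 0), end)
        if seqs.get(node_id) is not None:
            contig_seq.setdefault(contig, []).append((start, seqs[node_id]))

    graph = VariationGraph()
    for contig, length in sorted(contig_len.items()):
        pieces = sorted(contig_seq.get(contig, []))
        sequence = None
        if pieces and sum(len(s) for _, s in pieces) == length:
            sequence = "".join(s for _, s in pieces)
        graph.add_contig(Contig(contig, length, sequence))
    for node_id in sorted(lengths):
        origin = None
        if node_id in origins:
            contig, start = origins[node_id]
            origin = (contig, start, start + lengths[node_id])
        graph.add_node(
            Node(id=node_id, length=lengths[node_id], sequence=seqs[node_id], origin=origin)
        )
    for name, steps, path_class, metadata, lineno in raw_paths:
        for step in steps:
            if step.node_id not in graph.nodes:
                raise GfaError(
                    f"path {name!r} references missing segment {step.node_id}", lineno
                )
        graph.add_path(Path(name, path_class, steps, metadata))
    return graph


# ---------------------------------------------------------------------------
# subgraph JSON


def subgraph_to_dict(sub: Subgraph) -> dict:
    """JSON-ready representation (0-based half-open coordinates)."""
    nodes = []
    for node_id in sorted(sub.nodes):
        node = sub.nodes[node_id]
        entry: dict = {"id": node.id, "length": node.length}
        if node.sequence is not None:
            entry["sequence"] = node.sequence
        if node.origin is not None:
            contig, start, end = node.origin
            entry["origin"] = {"contig": contig, "start": start, "end": end}
        nodes.append(entry)
    paths = [
        {
            "name": p.name,
            "class": p.path_class,
            "steps": [[s.node_id, s.orientation] for s in p.steps],
            "metadata": p.metadata,
        }
        for p in sorted(sub.paths, key=_path_sort_key)
    ]
    return {
        "coordinates": "0-based half-open",
        "nodes": nodes,
        "paths": paths,
        "anchors": [
            {"contig": iv.contig, "start": iv.start, "end": iv.end}
            for iv in sub.anchors
        ],
        "parent_map": {str(k): v for k, v in sorted(sub.parent_map.items())},
    }


def write_subgraph_json(sub: Subgraph, stream_or_path) -> None:
    out, should_close = _open(stream_or_path, "w")
    try:
        json.dump(subgraph_to_dict(sub), out, indent=2)
        out.write("\n")
    finally:
        if should_close:
            out.close()


# ---------------------------------------------------------------------------
# event table (CSV, 1-based for human consumption)


def _display_pos(event: SVEvent) -> tuple[int, int]:
    a, b = event.breakend_a, event.breakend_b
    if event.sv_type == "INS":
        return a.pos, a.pos
    if event.sv_type == "BND":
        pa = a.pos if a.side == "left" else a.pos + 1
        pb = b.pos if b.side == "left" else b.pos + 1
        return pa, pb
    return a.pos + 1, b.pos  # first and last affected base, 1-based


def write_event_table(events: Iterable[SVEvent], stream_or_path) -> None:
    out, should_close = _open(stream_or_path, "w")
    try:
        writer = csv.writer(out, lineterminator="\n")
        writer.writerow(
            ["id", "type", "contig_a", "pos_a", "contig_b", "pos_b",
             "length", "support", "source"]
        )
        for ev in events:
            pa, pb = _display_pos(ev)
            writer.writerow(
                [
                    ev.id,
                    ev.sv_type,
                    ev.breakend_a.contig,
                    pa,
                    ev.breakend_b.contig,
                    pb,
                    "" if ev.length is None else ev.length,
                    "" if ev.support is None else ev.support,
                    ev.source,
                ]
            )
    finally:
        if should_close:
            out.close()
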