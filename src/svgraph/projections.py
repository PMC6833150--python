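"""Projection of linear-coordinate annotations and read alignments.

Features (genes, repeats) and read alignments live in reference
coordinates; projecting them onto the graph turns each into a path over
the reference-origin nodes its interval overlaps.  Reads aligned to the
linear reference never traverse insertion nodes — placing reads on novel
sequence would need graph-aware alignment, which is out of scope here —
but split reads (primary + supplementary segments) concatenate into one
walk, so a read spanning a deletion produces exactly the junction step
pair that the deletion's variant path carries.  Base-level alignment
detail (CIGAR) is not retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Iterable, Optional, Sequence, Union

import pysam

from .errors import CoordinateError, QueryError
from .model import FORWARD, REVERSE, Interval, Path, PathStep, VariationGraph

logger = logging.getLogger(__name__)


@dataclass
class Feature:
    """A named linear-genome annotation (gene, repeat, ...)."""

    interval: Interval
    name: str
    strand: str = "."
    kind: str = "other"


@dataclass
class AlignmentSegment:
    """One aligned block of a read against the linear reference."""

    read_name: str
    interval: Interval
    strand: str = "+"
    role: str = "primary"
    query_start: Optional[int] = None


def _overlap_steps(
    graph: VariationGraph, interval: Interval, orientation: str = FORWARD
) -> list[PathStep]:
    nodes = graph.nodes_in(interval.contig, interval.start, interval.end)
    steps = [PathStep(n.id, orientation) for n in nodes]
    return steps if orientation == FORWARD else steps[::-1]


def project_feature(graph: VariationGraph, feature: Feature) -> Path:
    """Annotation-class path over the nodes the feature overlaps.

    Steps are always forward in reference order; the strand is metadata.
    Partial overlap with the terminal nodes is recorded as offsets
    (``start_offset`` into the first node, ``end_offset`` into the last)
    rather than splitting nodes.
    """
    iv = feature.interval
    if iv.contig not in graph.contigs:
        raise QueryError(f"feature {feature.name!r}: unknown contig {iv.contig!r}")
    nodes = graph.nodes_in(iv.contig, iv.start, iv.end)
    if not nodes:
        raise QueryError(f"feature {feature.name!r}: no nodes overlap {iv}")
    first_start = nodes[0].origin[1]  # type: ignore[index]
    last_start = nodes[-1].origin[1]  # type: ignore[index]
    return Path(
        name=feature.name,
        path_class="annotation",
        steps=[PathStep(n.id, FORWARD) for n in nodes],
        metadata={
            "strand": feature.strand,
            "kind": feature.kind,
            "start_offset": iv.start - first_start,
            "end_offset": iv.end - last_start,
            "interval": str(iv),
        },
    )


def _segment_sort_key(seg: AlignmentSegment):
    # query-position order when known; else primary first, then reference order
    if seg.query_start is not None:
        return (0, seg.query_start, seg.interval.start)
    return (1, 0 if seg.role == "primary" else 1, seg.interval.start)


def project_alignments(
    graph: VariationGraph, segments: Iterable[AlignmentSegment]
) -> list[Path]:
    """Read-class paths, one per read, concatenating its segments.

    Segments of one read are ordered by query position (reconstructing the
    biological traversal of split reads); minus-strand segments contribute
    their nodes in reversed order with reverse orientation.  Segments on
    contigs absent from the graph are skipped with a log entry.
    """
    by_read: dict[str, list[AlignmentSegment]] = {}
    for seg in segments:
        by_read.setdefault(seg.read_name, []).append(seg)

    paths: list[Path] = []
    for read_name, segs in by_read.items():
        segs = sorted(segs, key=_segment_sort_key)
        steps: list[PathStep] = []
        used = 0
        for seg in segs:
            if seg.interval.contig not in graph.contigs:
                logger.warning(
                    "read %s: segment on unknown contig %s skipped",
                    read_name,
                    seg.interval.contig,
                )
                continue
            orientation = FORWARD if seg.strand == "+" else REVERSE
            steps.extend(_overlap_steps(graph, seg.interval, orientation))
            used += 1
        if not steps:
            continue
        paths.append(
            Path(
                name=read_name,
                path_class="read",
                steps=steps,
                metadata={"n_segments": used},
            )
        )
    return paths


# ---------------------------------------------------------------------------
# readers


def read_features_bed(path: Union[str, FilePath], kind: str = "other") -> list[Feature]:
    """Load BED (0-based half-open) records as features."""
    features: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CoordinateError(f"BED line with fewer than 3 fields: {line!r}")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else f"{contig}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 else "."
            features.append(
                Feature(Interval(contig, start, end), name=name, strand=strand, kind=kind)
            )
    return features


def read_intervals_bed(path: Union[str, FilePath]) -> list[Interval]:
    """Load plain intervals (e.g. a blacklist) from BED."""
    return [f.interval for f in read_features_bed(path)]


def read_features_gff3(
    path: Union[str, FilePath], feature_types: Sequence[str] = ("gene",)
) -> list[Feature]:
    """Load GFF3 (1-based closed, converted) records of the given types."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[Feature] = []
    for ftype in feature_types:
        for f in db.features_of_type(ftype):
            name = (
                f.attributes.get("Name", [None])[0]
                or f.attributes.get("gene_name", [None])[0]
                or f.id
            )
            features.append(
                Feature(
                    Interval(f.seqid, f.start - 1, f.end),
                    name=name,
                    strand=f.strand or ".",
                    kind="gene" if ftype == "gene" else ftype,
                )
            )
    return features


def read_alignments(path: Union[str, FilePath]) -> list[AlignmentSegment]:
    """Load aligned segments from SAM/BAM, honoring strand/supplementary flags."""
    segments: list[AlignmentSegment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary:
                continue
            cig = read.cigartuples or []
            # clip lengths give the segment's offset in the original read
            lead = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
            tail = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
            query_start = tail if read.is_reverse else lead
            segments.append(
                AlignmentSegment(
                    read_name=read.query_name,
                    interval=Interval(
                        read.reference_name, read.reference_start, read.reference_end
                    ),
                    strand="-" if read.is_reverse else "+",
                    role="supplementary" if read.is_supplementary else "primary",
                    query_start=query_start,
                )
            )
    return segments
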