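"""Canonical structural-variant events and dialect normalization.

SV callers encode the same physical variant in divergent VCF shapes; the
worst case is an inversion, which in the wild arrives as any of

1. a single inversion record covering both ends,
2. two inversion records, one at each end,
3. two breakend (BND) records, one at each end (a mate pair), or
4. four breakend records (both ends x both strands).

:func:`canonicalize` collapses all four to one ``INV`` event so that graph
construction sees exactly one path per physical variant.

Coordinate convention: every :class:`Breakend` carries the 0-based
half-open *junction boundary* (the coordinate between two bases where the
novel adjacency sits) plus which flank of that boundary the event retains.
A deletion of 0-based ``[2000, 3000)`` therefore has boundaries 2000 and
3000, and splitting reference nodes at those two coordinates realizes the
junction as a node adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .errors import SvGraphError

#: canonical SV type tags understood by graph construction
CANONICAL_TYPES = ("DEL", "INS", "INV", "DUP", "BND")

#: which flank of the junction boundary the breakend retains
SIDE_LEFT = "left"
SIDE_RIGHT = "right"

#: default pairing tolerance for reciprocal BND records without MATEID (bp)
BND_PAIR_TOLERANCE = 10


@dataclass(frozen=True)
class Breakend:
    """One side of a novel adjacency.

    ``pos`` is the 0-based half-open junction boundary.  ``side`` says which
    flank of the boundary belongs to this event's sequence: ``"left"`` means
    the sequence left of the boundary runs into the junction (as in the VCF
    ALT ``t[p[``), ``"right"`` means the right flank does.
    """

    contig: str
    pos: int
    side: str = SIDE_LEFT

    def __post_init__(self) -> None:
        if self.side not in (SIDE_LEFT, SIDE_RIGHT):
            raise ValueError(f"breakend side must be left/right, got {self.side!r}")
        if self.pos < 0:
            raise ValueError(f"breakend position must be >= 0, got {self.pos}")

    def sort_key(self) -> tuple:
        return (self.contig, self.pos, self.side)

    def near(self, other: "Breakend", tolerance: int) -> bool:
        """Same contig and side, positions within ``tolerance`` bp."""
        return (
            self.contig == other.contig
            and self.side == other.side
            and abs(self.pos - other.pos) <= tolerance
        )


@dataclass
class SVEvent:
    """A caller-independent structural-variant event.

    For ``DEL``/``INV``/``DUP``, ``breakend_a.pos < breakend_b.pos`` on one
    contig and the affected reference interval is
    ``[breakend_a.pos, breakend_b.pos)``.  For ``INS`` both breakends sit on
    the insertion point.  ``BND`` events may join different contigs and have
    no defined length.
    """

    id: str
    sv_type: str
    breakend_a: Breakend
    breakend_b: Breakend
    inserted_sequence: Optional[str] = None
    length: Optional[int] = None
    support: Optional[int] = None
    source: str = ""
    mate_id: Optional[str] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # any intra-contig interval type (incl. caller tags like INVDUP)
        if self.sv_type not in ("INS", "BND"):
            if self.breakend_a.contig != self.breakend_b.contig:
                raise ValueError(
                    f"event {self.id}: {self.sv_type} breakends must share a contig"
                )
            if not self.breakend_a.pos < self.breakend_b.pos:
                raise ValueError(
                    f"event {self.id}: {self.sv_type} requires "
                    "breakend_a.pos < breakend_b.pos"
                )
            if self.length is None:
                self.length = self.breakend_b.pos - self.breakend_a.pos
        elif self.sv_type == "INS":
            if self.breakend_a.pos != self.breakend_b.pos:
                raise ValueError(f"event {self.id}: INS breakends must coincide")
            if self.length is None and self.inserted_sequence is not None:
                self.length = len(self.inserted_sequence)

    @property
    def span(self) -> Optional[tuple[str, int, int]]:
        """Affected reference interval for intra-contig symbolic types."""
        if self.sv_type in ("DEL", "INV", "DUP"):
            return (self.breakend_a.contig, self.breakend_a.pos, self.breakend_b.pos)
        return None

    def breakpoints(self) -> list[tuple[str, int]]:
        """Junction boundaries contributed to the graph, per contig."""
        if self.sv_type == "INS":
            return [(self.breakend_a.contig, self.breakend_a.pos)]
        return [
            (self.breakend_a.contig, self.breakend_a.pos),
            (self.breakend_b.contig, self.breakend_b.pos),
        ]

    def signature(self) -> tuple:
        """Identity up to record id — used for deduplication grouping."""
        return (
            self.sv_type,
            self.breakend_a.sort_key(),
            self.breakend_b.sort_key(),
        )


def _ordered(a: Breakend, b: Breakend) -> tuple[Breakend, Breakend]:
    return (a, b) if a.sort_key() <= b.sort_key() else (b, a)


def _merge_support(x: Optional[int], y: Optional[int]) -> Optional[int]:
    if x is None:
        return y
    if y is None:
        return x
    return max(x, y)


def _is_inverted_intra(ev: SVEvent) -> bool:
    """A paired intra-contig BND whose two sides match joins strands head-to-head
    or tail-to-tail: the signature of an inversion end."""
    return (
        ev.sv_type == "BND"
        and ev.breakend_a.contig == ev.breakend_b.contig
        and ev.breakend_a.side == ev.breakend_b.side
        and ev.breakend_a.pos != ev.breakend_b.pos
    )


def _bnd_to_inv(ev: SVEvent) -> SVEvent:
    a, b = _ordered(ev.breakend_a, ev.breakend_b)
    lo, hi = a.pos, b.pos
    return SVEvent(
        id=ev.id,
        sv_type="INV",
        breakend_a=Breakend(a.contig, lo),
        breakend_b=Breakend(a.contig, hi),
        length=hi - lo,
        support=ev.support,
        source=ev.source,
        metadata={**ev.metadata, "derived_from": "BND"},
    )


def _pair_bnd_mates(
    events: list[SVEvent], tolerance: int
) -> tuple[list[SVEvent], list[str]]:
    """Merge reciprocal BND mate records into single adjacencies.

    Each BND record already names both its own breakend and its partner's
    (from the bracket ALT); its mate record states the same adjacency from
    the other end.  Pairing is by MATEID when present, else by coordinate
    reciprocity within ``tolerance``.
    """
    log: list[str] = []
    bnds = [e for e in events if e.sv_type == "BND"]
    others = [e for e in events if e.sv_type != "BND"]
    by_id = {e.id: e for e in bnds}
    consumed: set[str] = set()
    merged: list[SVEvent] = []

    for ev in bnds:
        if ev.id in consumed:
            continue
        mate: Optional[SVEvent] = None
        if ev.mate_id and ev.mate_id in by_id and ev.mate_id not in consumed:
            cand = by_id[ev.mate_id]
            if cand is not ev:
                mate = cand
        if mate is None:
            for cand in bnds:
                if cand is ev or cand.id in consumed:
                    continue
                if cand.breakend_a.near(ev.breakend_b, tolerance) and cand.breakend_b.near(
                    ev.breakend_a, tolerance
                ):
                    mate = cand
                    break
        consumed.add(ev.id)
        if mate is not None:
            consumed.add(mate.id)
            log.append(f"paired BND records {ev.id} and {mate.id}")
        a, b = _ordered(ev.breakend_a, ev.breakend_b)
        merged.append(
            replace(
                ev,
                breakend_a=a,
                breakend_b=b,
                support=_merge_support(ev.support, mate.support if mate else None),
                mate_id=None,
            )
        )
    return others + merged, log


def _dedupe(
    events: list[SVEvent], tolerance: int
) -> tuple[list[SVEvent], list[str]]:
    """Collapse events of the same type with breakends within tolerance.

    The survivor keeps the highest read support; ids resolve to the
    lexicographically smallest so the result is input-order independent.
    """
    log: list[str] = []
    out: list[SVEvent] = []
    for ev in events:
        match = None
        for kept in out:
            if (
                kept.sv_type == ev.sv_type
                and kept.breakend_a.near(ev.breakend_a, tolerance)
                and kept.breakend_b.near(ev.breakend_b, tolerance)
            ):
                match = kept
                break
        if match is None:
            out.append(ev)
        else:
            log.append(f"deduplicated {ev.id} into {match.id}")
            match.support = _merge_support(match.support, ev.support)
            if ev.id < match.id:
                match.id = ev.id
    return out, log


def canonicalize(
    events: Sequence[SVEvent],
    tolerance: int = BND_PAIR_TOLERANCE,
    log: Optional[list[str]] = None,
) -> list[SVEvent]:
    """Normalize parsed events to one canonical event per physical variant.

    Steps: (1) pair reciprocal BND mate records into single adjacencies,
    (2) promote intra-contig inverted-orientation adjacencies to ``INV``,
    (3) deduplicate events whose type and breakends agree within
    ``tolerance`` bp, keeping the highest support.  The result is sorted
    deterministically and the operation is idempotent.
    """
    if log is None:
        log = []
    paired, plog = _pair_bnd_mates(list(events), tolerance)
    log.extend(plog)

    promoted: list[SVEvent] = []
    for ev in paired:
        if _is_inverted_intra(ev):
            log.append(f"promoted inverted intra-contig adjacency {ev.id} to INV")
            promoted.append(_bnd_to_inv(ev))
        else:
            promoted.append(ev)

    unique, dlog = _dedupe(promoted, tolerance)
    log.extend(dlog)

    unique.sort(key=lambda e: (e.breakend_a.sort_key(), e.sv_type, e.id))
    return unique


def events_to_breakpoints(events: Iterable[SVEvent]) -> dict[str, list[int]]:
    """Per-contig sorted unique junction boundaries of all events."""
    acc: dict[str, set[int]] = {}
    for ev in events:
        for contig, pos in ev.breakpoints():
            acc.setdefault(contig, set()).add(pos)
    return {contig: sorted(ps) for contig, ps in sorted(acc.items())}
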