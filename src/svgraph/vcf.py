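"""VCF structural-variant parsing across caller dialects.

Supported dialects are ``sniffles``, ``survivor``, ``longranger`` and
``generic_bnd``; they share one record interpreter and differ only in
which INFO keys carry read support and how permissive symbolic-type
handling is.  File access goes through :mod:`cyvcf2` (htslib), so plain
and bgzip-compressed VCFs both work; cyvcf2 is used rather than pysam's
variant reader because it exposes the raw ``INFO/END`` value, which SV
dialect arbitration needs verbatim.

Coordinate handling.  VCF is 1-based; internally everything is 0-based
half-open junction boundaries.  For symbolic records two POS conventions
circulate: POS as the first affected base (affected = ``[POS-1, END)``)
and POS as the padding base before the event (affected = ``[POS, END)``).
When SVLEN is present it arbitrates: ``|SVLEN| == END - POS`` selects the
padding-base reading, otherwise the first-affected-base reading is used.
Both map real caller output and hand-written fixtures to the same
interval.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Optional, Sequence, Union

from cyvcf2 import VCF

from .errors import VcfParseError
from .events import SIDE_LEFT, SIDE_RIGHT, Breakend, SVEvent
from .model import Contig

DIALECTS = ("sniffles", "survivor", "longranger", "generic_bnd")

#: per-dialect priority of INFO keys carrying the supporting-read count
_SUPPORT_KEYS = {
    "sniffles": ("RE", "SUPPORT", "DV"),
    "survivor": ("SUPP", "RE", "SUPPORT"),
    "longranger": ("PAIRS", "SUPPORT", "RE"),
    "generic_bnd": ("SUPPORT", "RE", "SUPP", "DV"),
}

_BND_ALT = re.compile(
    r"^(?P<before>[A-Za-z*.]*)"
    r"(?P<open>[\[\]])(?P<contig>[^\[\]:]+):(?P<pos>\d+)(?P<close>[\[\]])"
    r"(?P<after>[A-Za-z*.]*)$"
)

_SYMBOLIC_ALT = re.compile(r"^<(?P<tag>[^<>]+)>$")


@dataclass
class ParseReport:
    """Parsed events plus everything that was skipped and why."""

    events: list[SVEvent] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    skipped_contigs: dict[str, int] = field(default_factory=dict)
    contig_renames: dict[str, str] = field(default_factory=dict)
    n_records: int = 0

    def lines(self) -> list[str]:
        out = [f"records read: {self.n_records}", f"events parsed: {len(self.events)}"]
        for contig, n in sorted(self.skipped_contigs.items()):
            out.append(f"skipped {n} record(s) on unknown contig {contig}")
        for old, new in sorted(self.contig_renames.items()):
            out.append(f"renamed contig {old} -> {new} to match the genome")
        out.extend(f"error: {e}" for e in self.errors)
        return out


def _normalize_contig(
    name: str, known: Optional[set[str]], renames: dict[str, str]
) -> Optional[str]:
    """Reconcile chr-prefixed vs bare contig names against the genome."""
    if known is None or name in known:
        return name
    alt = name[3:] if name.startswith("chr") else f"chr{name}"
    if alt in known:
        renames.setdefault(name, alt)
        return alt
    return None


def parse_bnd_alt(
    chrom: str, pos1: int, alt: str
) -> tuple[Breakend, Breakend, Optional[str]]:
    """Decode a VCF 4.2 bracket ALT into (own breakend, partner, inserted seq).

    The four bracket forms, with ``q = pos1 - 1`` (own base, 0-based) and
    ``p`` the partner position (1-based):

    ========  ===========================  ===========================
    form      own breakend                 partner breakend
    ========  ===========================  ===========================
    t[p[      boundary q+1, side left      boundary p-1, side right
    t]p]      boundary q+1, side left      boundary p,   side left
    ]p]t      boundary q,   side right     boundary p,   side left
    [p[t      boundary q,   side right     boundary p-1, side right
    ========  ===========================  ===========================

    Same-side pairs are inverted joins (the partner strand flips).
    """
    m = _BND_ALT.match(alt)
    if not m:
        raise VcfParseError(f"malformed breakend ALT {alt!r}")
    if m.group("open") != m.group("close"):
        raise VcfParseError(f"malformed breakend ALT {alt!r}: mismatched brackets")
    bracket = m.group("open")
    before, after = m.group("before"), m.group("after")
    if bool(before) == bool(after):
        raise VcfParseError(
            f"malformed breakend ALT {alt!r}: anchor base must flank one side"
        )
    partner_contig = m.group("contig")
    p = int(m.group("pos"))
    q = pos1 - 1

    if before:  # anchor first: own left flank is retained
        own = Breakend(chrom, q + 1, SIDE_LEFT)
        inserted = before[1:] or None
        if bracket == "[":  # t[p[ : partner continues forward from p
            partner = Breakend(partner_contig, p - 1, SIDE_RIGHT)
        else:  # t]p] : partner's left flank joins, reverse strand
            partner = Breakend(partner_contig, p, SIDE_LEFT)
    else:  # anchor last: own right flank is retained
        own = Breakend(chrom, q, SIDE_RIGHT)
        inserted = after[:-1] or None
        if bracket == "]":  # ]p]t : partner's left flank joins forward
            partner = Breakend(partner_contig, p, SIDE_LEFT)
        else:  # [p[t : partner continues from p, reverse strand
            partner = Breakend(partner_contig, p - 1, SIDE_RIGHT)
    return own, partner, inserted


def _info_int(rec, *keys: str) -> Optional[int]:
    for key in keys:
        val = rec.INFO.get(key)
        if val is None:
            continue
        if isinstance(val, (tuple, list)):
            val = val[0]
        try:
            return int(val)
        except (TypeError, ValueError):
            continue
    return None


def _info_str(rec, key: str) -> Optional[str]:
    val = rec.INFO.get(key)
    if val is None:
        return None
    if isinstance(val, (tuple, list)):
        val = val[0]
    return str(val)


_STRAND_SIDE = {"+": SIDE_LEFT, "-": SIDE_RIGHT}


def _symbolic_event(
    rec, sv_type: str, chrom: str, alt: str, event_id: str, support, dialect: str
) -> SVEvent:
    """Interpret a symbolic-ALT record (SVTYPE + END/SVLEN INFO)."""
    svlen = _info_int(rec, "SVLEN")
    # raw INFO END: 1-based inclusive == 0-based exclusive numerically
    end = _info_int(rec, "END")
    pos0 = rec.POS - 1  # 0-based POS

    chr2 = _info_str(rec, "CHR2")
    if sv_type in ("BND", "TRA") or (chr2 is not None and chr2 != chrom):
        # translocation-style symbolic record: junction between two contigs
        if end is None:
            raise VcfParseError(f"record {event_id}: translocation without END")
        strands = _info_str(rec, "STRANDS") or "+-"
        side_a = _STRAND_SIDE.get(strands[0], SIDE_LEFT)
        side_b = _STRAND_SIDE.get(strands[-1], SIDE_RIGHT)
        a = Breakend(chrom, pos0 + 1 if side_a == SIDE_LEFT else pos0, side_a)
        # END names the partner base (1-based); boundary sits after it for a
        # left-side join, before it for a right-side join
        b = Breakend(chr2 or chrom, end if side_b == SIDE_LEFT else end - 1, side_b)
        return SVEvent(
            id=event_id, sv_type="BND", breakend_a=a, breakend_b=b,
            support=support, source=dialect,
        )

    if sv_type == "INS":
        boundary = pos0 + 1  # insertion lands after the POS base
        seq = None
        m = _SYMBOLIC_ALT.match(alt)
        if not m:  # sequence-resolved ALT: padding base + inserted sequence
            seq = alt[1:] or None
        if seq is None:
            seq = _info_str(rec, "SEQ")
        if seq is None:
            if svlen is None:
                raise VcfParseError(
                    f"record {event_id}: INS without sequence or SVLEN"
                )
            seq = "N" * abs(svlen)
        be = Breakend(chrom, boundary)
        return SVEvent(
            id=event_id, sv_type="INS", breakend_a=be, breakend_b=be,
            inserted_sequence=seq, length=len(seq), support=support, source=dialect,
        )

    # interval types: DEL / INV / DUP and caller-specific tags (INVDUP, ...)
    if end is None and svlen is not None:
        end = pos0 + abs(svlen)  # first-affected-base reading
    if end is None or end <= pos0:
        raise VcfParseError(f"record {event_id}: {sv_type} without usable END")
    if svlen is not None and abs(svlen) == end - pos0 - 1:
        start = pos0 + 1  # padding-base convention (POS is the base before)
    else:
        start = pos0  # POS is the first affected base
    length = abs(svlen) if svlen is not None else end - start
    if sv_type in ("DEL", "INV", "DUP"):
        return SVEvent(
            id=event_id, sv_type=sv_type,
            breakend_a=Breakend(chrom, start), breakend_b=Breakend(chrom, end),
            length=length, support=support, source=dialect,
        )
    # non-canonical tag (INVDUP, DEL/INV, DUP/INS, ...): keep for filtering
    return SVEvent(
        id=event_id, sv_type=sv_type,
        breakend_a=Breakend(chrom, min(start, end)),
        breakend_b=Breakend(chrom, max(start, end, start + 1)),
        length=length, support=support, source=dialect,
    )


def parse_vcf(
    path: Union[str, FilePath],
    dialect: str = "sniffles",
    genome: Optional[Sequence[Contig]] = None,
    strict: bool = False,
) -> ParseReport:
    """Parse SV records into :class:`~svgraph.events.SVEvent` objects.

    One event is emitted per ALT allele (multi-allelic records are split).
    BND records come out unpaired — mate resolution happens in
    :func:`~svgraph.events.canonicalize`.  Records on contigs absent from
    ``genome`` (when given) are counted and skipped; malformed records are
    collected in the report, or raised when ``strict`` is true.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    report = ParseReport()
    known = {c.name for c in genome} if genome is not None else None
    support_keys = _SUPPORT_KEYS[dialect]

    vf = VCF(str(path))
    try:
        for rec in vf:
            report.n_records += 1
            chrom = _normalize_contig(rec.CHROM, known, report.contig_renames)
            if chrom is None:
                report.skipped_contigs[rec.CHROM] = (
                    report.skipped_contigs.get(rec.CHROM, 0) + 1
                )
                continue
            alts = rec.ALT or []
            for ai, alt in enumerate(alts):
                event_id = rec.ID or f"{rec.CHROM}_{rec.POS}"
                if len(alts) > 1:
                    event_id = f"{event_id}.{ai + 1}"
                try:
                    ev = _parse_allele(rec, chrom, alt, event_id, support_keys, dialect)
                except VcfParseError as exc:
                    if strict:
                        raise
                    report.errors.append(str(exc))
                    continue
                if ev is not None:
                    _check_bounds(ev, genome, report, strict)
                    report.events.append(ev)
    finally:
        vf.close()
    return report


def _parse_allele(rec, chrom, alt, event_id, support_keys, dialect) -> Optional[SVEvent]:
    support = _info_int(rec, *support_keys)
    sv_type = _info_str(rec, "SVTYPE")
    if alt and ("[" in alt or "]" in alt):
        own, partner, inserted = parse_bnd_alt(chrom, rec.POS, alt)
        return SVEvent(
            id=event_id, sv_type="BND", breakend_a=own, breakend_b=partner,
            inserted_sequence=inserted, support=support, source=dialect,
            mate_id=_info_str(rec, "MATEID"),
        )
    if sv_type is None:
        m = _SYMBOLIC_ALT.match(alt or "")
        if m:
            sv_type = m.group("tag").split(":")[0]
        else:
            raise VcfParseError(
                f"record {event_id}: no SVTYPE and ALT {alt!r} is not a "
                "breakend or symbolic allele"
            )
    if sv_type == "BND":
        raise VcfParseError(
            f"record {event_id}: SVTYPE=BND but ALT {alt!r} has no bracket notation"
        )
    return _symbolic_event(rec, sv_type, chrom, alt or "", event_id, support, dialect)


def _check_bounds(ev, genome, report, strict) -> None:
    if genome is None:
        return
    lengths = {c.name: c.length for c in genome}
    for contig, pos in ev.breakpoints():
        if contig in lengths and not (0 <= pos <= lengths[contig]):
            msg = (
                f"event {ev.id}: breakend {contig}:{pos} outside contig "
                f"bounds [0, {lengths[contig]}]"
            )
            if strict:
                raise VcfParseError(msg)
            report.errors.append(msg)


# ---------------------------------------------------------------------------
# writing helpers (shared with the synthetic-data generator)


def bnd_alt_string(own: Breakend, partner: Breakend, anchor_base: str = "N") -> str:
    """Format the bracket ALT describing ``own`` joined to ``partner``."""
    p1 = partner.pos + 1 if partner.side == SIDE_RIGHT else partner.pos
    loc = f"{partner.contig}:{p1}"
    if own.side == SIDE_LEFT:
        if partner.side == SIDE_RIGHT:
            return f"{anchor_base}[{loc}["
        return f"{anchor_base}]{loc}]"
    if partner.side == SIDE_LEFT:
        return f"]{loc}]{anchor_base}"
    return f"[{loc}[{anchor_base}"
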