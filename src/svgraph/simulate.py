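"""Synthetic reference genomes, implanted SVs, and error-free alignments.

Everything downstream of an SV caller can be exercised without any
download: :func:`make_genome` draws uniform-random genomes,
:func:`implant_svs` writes a truth event set as VCF in any supported
encoding (including all four wild-type inversion encodings), and
:func:`simulate_alignments` samples error-free reads from the rearranged
haplotype so that split-read evidence patterns over SV junctions can be
reproduced.  All generators are seed-deterministic.

Reads are error-free by design: the graph layer never inspects base-level
mismatches, so a sequencing-error model would add nothing the tests could
observe.  Zygosity defaults to heterozygous (half the reads drawn from
the reference haplotype), matching the evidence pattern where
junction-spanning and reference-spanning alignments coexist.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path as FilePath
from typing import IO, Optional, Sequence, Union

import numpy as np
import pysam

from .errors import SimulationError
from .events import SIDE_LEFT, SIDE_RIGHT, Breakend, SVEvent
from .model import Contig, Interval
from .projections import AlignmentSegment
from .vcf import bnd_alt_string

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: inversion encodings from the wild: one record, two records, one BND mate
#: pair, or four BND records (both ends x both strands)
INV_ENCODINGS = ("single", "double", "bnd_pair", "bnd_quad")


def make_genome(
    n_contigs: int = 1,
    lengths: Sequence[int] = (1_000_000,),
    seed: int = 0,
    names: Optional[Sequence[str]] = None,
) -> list[Contig]:
    """Uniform-random A/C/G/T contigs, deterministic for a fixed seed."""
    if len(lengths) != n_contigs:
        raise SimulationError(
            f"expected {n_contigs} lengths, got {len(lengths)}"
        )
    if any(l < 1 for l in lengths):
        raise SimulationError("contig lengths must be >= 1")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"c{i + 1}" for i in range(n_contigs)]
    contigs = []
    for name, length in zip(names, lengths):
        idx = rng.integers(0, 4, size=int(length))
        contigs.append(Contig(name, int(length), _BASES[idx].tobytes().decode()))
    return contigs


def write_fasta(genome: Sequence[Contig], path: Union[str, FilePath]) -> None:
    with open(path, "w") as fh:
        for contig in genome:
            fh.write(f">{contig.name}\n")
            seq = contig.sequence or ""
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def load_fasta(path: Union[str, FilePath]) -> list[Contig]:
    """Read a reference genome (plain or bgzipped FASTA, .fai honored)."""
    contigs = []
    with pysam.FastaFile(str(path)) as fa:
        for name, length in zip(fa.references, fa.lengths):
            contigs.append(Contig(name, length, fa.fetch(name)))
    return contigs


# ---------------------------------------------------------------------------
# SV placement


@dataclass(frozen=True)
class SVPlacement:
    """One SV to implant: type, contig, 0-based boundaries, optional sequence.

    For interval types ``start``/``end`` delimit the affected reference
    interval; for ``INS`` the insertion point is ``start`` (== ``end``)
    and ``sequence`` holds the inserted bases.
    """

    sv_type: str
    contig: str
    start: int
    end: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sv_type in ("DEL", "INV", "DUP") and not self.start < self.end:
            raise SimulationError(
                f"{self.sv_type} placement requires start < end"
            )
        if self.sv_type == "INS":
            if self.start != self.end:
                raise SimulationError("INS placement requires start == end")
            if not self.sequence:
                raise SimulationError("INS placement requires a sequence")


def random_placements(
    genome: Sequence[Contig],
    n: int,
    seed: int = 0,
    sv_types: Sequence[str] = ("DEL", "INV", "DUP"),
    min_length: int = 1500,
    max_length: int = 20_000,
    margin: int = 5000,
    spacing: int = 2000,
) -> list[SVPlacement]:
    """Draw ``n`` non-overlapping SV placements, ``spacing`` bp apart."""
    rng = np.random.default_rng(seed)
    placed: dict[str, list[tuple[int, int]]] = {c.name: [] for c in genome}
    weights = np.array([c.length for c in genome], dtype=float)
    weights /= weights.sum()
    out: list[SVPlacement] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise SimulationError(
                f"could not place {n} non-overlapping SVs; genome too small"
            )
        contig = genome[rng.choice(len(genome), p=weights)]
        sv_type = sv_types[int(rng.integers(0, len(sv_types)))]
        length = int(rng.integers(min_length, max_length + 1))
        if sv_type == "INS":
            lo, hi = margin, contig.length - margin
            if hi <= lo:
                continue
            pos = int(rng.integers(lo, hi))
            start, end, footprint = pos, pos, (pos - spacing, pos + spacing)
        else:
            hi = contig.length - margin - length
            if hi <= margin:
                continue
            start = int(rng.integers(margin, hi))
            end = start + length
            footprint = (start - spacing, end + spacing)
        if any(
            footprint[0] < e and s < footprint[1] for s, e in placed[contig.name]
        ):
            continue
        placed[contig.name].append(footprint)
        seq = None
        if sv_type == "INS":
            idx = rng.integers(0, 4, size=length)
            seq = _BASES[idx].tobytes().decode()
        out.append(SVPlacement(sv_type, contig.name, start, end, seq))
    out.sort(key=lambda p: (p.contig, p.start))
    return out


def placements_to_events(
    placements: Sequence[SVPlacement], support: int = 10
) -> list[SVEvent]:
    """The truth event set corresponding to a placement list."""
    events = []
    for i, p in enumerate(placements):
        be_a = Breakend(p.contig, p.start)
        be_b = Breakend(p.contig, p.end if p.sv_type != "INS" else p.start)
        events.append(
            SVEvent(
                id=f"sv{i}",  # matches the ids the VCF writer emits
                sv_type=p.sv_type,
                breakend_a=be_a,
                breakend_b=be_b,
                inserted_sequence=p.sequence,
                support=support,
                source="simulated",
            )
        )
    return events


# ---------------------------------------------------------------------------
# VCF emission (the dialect writer)


def _vcf_header(genome: Sequence[Contig], source: str) -> list[str]:
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=SEQ,Number=1,Type=String,Description="Inserted sequence">',
        '##INFO=<ID=RE,Number=1,Type=Integer,Description="Supporting reads">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
        '##INFO=<ID=CHR2,Number=1,Type=String,Description="Partner contig">',
        '##INFO=<ID=STRANDS,Number=1,Type=String,Description="Junction strands">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=INS,Description="Insertion">',
        '##ALT=<ID=INV,Description="Inversion">',
        '##ALT=<ID=DUP,Description="Duplication">',
    ]
    lines.extend(
        f"##contig=<ID={c.name},length={c.length}>" for c in genome
    )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return lines


def _symbolic_record(
    p: SVPlacement, rid: str, support: int, sv_type: Optional[str] = None
) -> tuple[str, int, str]:
    sv_type = sv_type or p.sv_type
    if p.sv_type == "INS":
        pos1 = p.start  # boundary as 1-based POS of the base before the insert
        info = (
            f"SVTYPE=INS;END={p.start};SVLEN={len(p.sequence or '')};"
            f"SEQ={p.sequence};RE={support}"
        )
        return (p.contig, pos1, f"{p.contig}\t{pos1}\t{rid}\tN\t<INS>\t.\tPASS\t{info}")
    length = p.end - p.start
    svlen = -length if sv_type == "DEL" else length
    pos1 = p.start + 1  # first affected base, 1-based
    info = f"SVTYPE={sv_type};END={p.end};SVLEN={svlen};RE={support}"
    return (
        p.contig,
        pos1,
        f"{p.contig}\t{pos1}\t{rid}\tN\t<{sv_type}>\t.\tPASS\t{info}",
    )


def _bnd_record(
    contig: str, own: Breakend, partner: Breakend, rid: str, mate_id: str, support: int
) -> tuple[str, int, str]:
    pos1 = own.pos if own.side == SIDE_LEFT else own.pos + 1
    alt = bnd_alt_string(own, partner)
    info = f"SVTYPE=BND;MATEID={mate_id};RE={support}"
    return (contig, pos1, f"{contig}\t{pos1}\t{rid}\tN\t{alt}\t.\tPASS\t{info}")


def _inversion_records(
    p: SVPlacement, rid: str, support: int, encoding: str
) -> list[tuple[str, int, str]]:
    a, b = p.start, p.end
    if encoding == "single":
        return [_symbolic_record(p, rid, support)]
    if encoding == "double":
        return [
            _symbolic_record(p, f"{rid}_5p", support),
            _symbolic_record(p, f"{rid}_3p", support),
        ]
    j1 = (Breakend(p.contig, a, SIDE_LEFT), Breakend(p.contig, b, SIDE_LEFT))
    j2 = (Breakend(p.contig, a, SIDE_RIGHT), Breakend(p.contig, b, SIDE_RIGHT))
    records = [
        _bnd_record(p.contig, j1[0], j1[1], f"{rid}_j1a", f"{rid}_j1b", support),
        _bnd_record(p.contig, j1[1], j1[0], f"{rid}_j1b", f"{rid}_j1a", support),
    ]
    if encoding == "bnd_quad":
        records += [
            _bnd_record(p.contig, j2[0], j2[1], f"{rid}_j2a", f"{rid}_j2b", support),
            _bnd_record(p.contig, j2[1], j2[0], f"{rid}_j2b", f"{rid}_j2a", support),
        ]
    elif encoding != "bnd_pair":
        raise SimulationError(f"unknown inversion encoding {encoding!r}")
    return records


def implant_svs(
    genome: Sequence[Contig],
    placements: Sequence[SVPlacement],
    inv_encoding: str = "single",
    support: int = 10,
    source: str = "svgraph-simulate",
) -> tuple[list[SVEvent], str]:
    """Truth events plus VCF text encoding them in the chosen style.

    ``inv_encoding`` selects how each inversion is written; all four
    encodings normalize back to the same canonical truth event.
    Placements must be non-overlapping and in bounds.
    """
    lengths = {c.name: c.length for c in genome}
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for p in placements:
        if p.contig not in lengths:
            raise SimulationError(f"placement on unknown contig {p.contig!r}")
        if not (0 < p.start <= p.end <= lengths[p.contig]):
            raise SimulationError(
                f"placement {p.sv_type} {p.contig}:{p.start}-{p.end} out of bounds"
            )
        span = (p.start, max(p.end, p.start + 1))
        if any(span[0] < e and s < span[1] for s, e in by_contig.get(p.contig, [])):
            raise SimulationError(
                f"overlapping placement {p.sv_type} {p.contig}:{p.start}-{p.end}"
            )
        by_contig.setdefault(p.contig, []).append(span)

    records: list[tuple[str, int, str]] = []
    for i, p in enumerate(placements):
        rid = f"sv{i}"
        if p.sv_type == "INV":
            records.extend(_inversion_records(p, rid, support, inv_encoding))
        else:
            records.append(_symbolic_record(p, rid, support))
    order = {c.name: i for i, c in enumerate(genome)}
    records.sort(key=lambda r: (order.get(r[0], len(order)), r[1]))
    vcf_text = "\n".join(
        _vcf_header(genome, source) + [r[2] for r in records]
    ) + "\n"
    return placements_to_events(placements, support=support), vcf_text


# ---------------------------------------------------------------------------
# alignment simulation


def _haplotype_blocks(
    contig: Contig, events: Sequence[SVEvent]
) -> list[tuple]:
    """ALT-haplotype layout as ('ref', start, end, strand) / ('ins', seq) blocks."""
    evs = sorted(
        (e for e in events if e.breakend_a.contig == contig.name
         and e.sv_type in ("DEL", "INS", "INV", "DUP")),
        key=lambda e: e.breakend_a.pos,
    )
    blocks: list[tuple] = []
    cursor = 0
    for ev in evs:
        a, b = ev.breakend_a.pos, ev.breakend_b.pos
        if a < cursor:
            raise SimulationError(f"event {ev.id} overlaps a previous event")
        if ev.sv_type == "DEL":
            if a > cursor:
                blocks.append(("ref", cursor, a, "+"))
            cursor = b
        elif ev.sv_type == "INV":
            if a > cursor:
                blocks.append(("ref", cursor, a, "+"))
            blocks.append(("ref", a, b, "-"))
            cursor = b
        elif ev.sv_type == "DUP":
            if b > cursor:
                blocks.append(("ref", cursor, b, "+"))
            blocks.append(("ref", a, b, "+"))
            cursor = b
        else:  # INS
            if a > cursor:
                blocks.append(("ref", cursor, a, "+"))
            blocks.append(("ins", ev.inserted_sequence or "N" * int(ev.length or 1)))
            cursor = a
    if cursor < contig.length:
        blocks.append(("ref", cursor, contig.length, "+"))
    return blocks


def _block_length(block: tuple) -> int:
    return len(block[1]) if block[0] == "ins" else block[2] - block[1]


def _read_segments(
    contig_name: str,
    blocks: list[tuple],
    read_start: int,
    read_len: int,
    read_name: str,
    min_segment: int = 50,
) -> list[AlignmentSegment]:
    """Map a haplotype-coordinate read back to reference-aligned segments."""
    segments: list[AlignmentSegment] = []
    offset = 0
    read_end = read_start + read_len
    for block in blocks:
        blen = _block_length(block)
        b_lo, b_hi = offset, offset + blen
        offset = b_hi
        x, y = max(read_start, b_lo), min(read_end, b_hi)
        if x >= y:
            continue
        if block[0] == "ins":
            continue  # inserted sequence has no linear-reference alignment
        _, rs, re_, strand = block
        if strand == "+":
            ref_lo, ref_hi = rs + (x - b_lo), rs + (y - b_lo)
        else:
            ref_lo, ref_hi = re_ - (y - b_lo), re_ - (x - b_lo)
        if ref_hi - ref_lo < min_segment:
            continue
        segments.append(
            AlignmentSegment(
                read_name=read_name,
                interval=Interval(contig_name, ref_lo, ref_hi),
                strand=strand,
                role="supplementary",
                query_start=x - read_start,
            )
        )
    # merge adjacent co-linear segments (e.g. across a DUP body boundary)
    merged: list[AlignmentSegment] = []
    for seg in segments:
        if (
            merged
            and merged[-1].strand == seg.strand == "+"
            and merged[-1].interval.end == seg.interval.start
        ):
            prev = merged[-1]
            merged[-1] = AlignmentSegment(
                read_name, Interval(contig_name, prev.interval.start, seg.interval.end),
                "+", prev.role, prev.query_start,
            )
        else:
            merged.append(seg)
    if merged:
        merged[0].role = "primary"
    return merged


def simulate_alignments(
    genome: Sequence[Contig],
    events: Sequence[SVEvent],
    coverage: float = 20.0,
    read_length: int = 2000,
    seed: int = 0,
    zygosity: str = "het",
) -> list[AlignmentSegment]:
    """Error-free reads from the rearranged haplotype, as aligned segments.

    A read crossing a deletion junction yields two segments flanking the
    deleted interval; one crossing an inversion junction gets a
    strand-flipped middle segment.  With ``zygosity="het"`` half the
    reads come from the unrearranged reference haplotype, so
    junction-spanning and reference-spanning evidence coexist.  Only
    intra-contig event types shape the haplotype; breakend fusions are
    not simulated.
    """
    if coverage <= 0:
        raise SimulationError("coverage must be > 0")
    if zygosity not in ("het", "hom"):
        raise SimulationError("zygosity must be 'het' or 'hom'")
    rng = np.random.default_rng(seed)
    segments: list[AlignmentSegment] = []
    read_idx = 0
    for contig in genome:
        alt_blocks = _haplotype_blocks(contig, events)
        ref_blocks = [("ref", 0, contig.length, "+")]
        haplotypes = [alt_blocks, ref_blocks] if zygosity == "het" else [alt_blocks]
        for hap_i, blocks in enumerate(haplotypes):
            hap_len = sum(_block_length(b) for b in blocks)
            n_reads = int(round(coverage * hap_len / read_length / len(haplotypes)))
            for _ in range(n_reads):
                rl = min(read_length, hap_len)
                start = int(rng.integers(0, max(1, hap_len - rl + 1)))
                name = f"read_{contig.name}_{hap_i}_{read_idx}"
                read_idx += 1
                segs = _read_segments(contig.name, blocks, start, rl, name)
                if rng.integers(0, 2):  # sequenced in reverse orientation
                    segs = _flip_read(segs, rl)
                segments.extend(segs)
    return segments


def _flip_read(
    segs: list[AlignmentSegment], read_len: int
) -> list[AlignmentSegment]:
    """Reverse-complement a simulated read: strands toggle, query order flips."""
    flipped = []
    for seg in reversed(segs):
        q = seg.query_start or 0
        flipped.append(
            AlignmentSegment(
                read_name=seg.read_name,
                interval=seg.interval,
                strand="-" if seg.strand == "+" else "+",
                role="supplementary",
                query_start=read_len - (q + seg.interval.length),
            )
        )
    if flipped:
        flipped[0].role = "primary"
    return flipped


def write_sam(
    segments: Sequence[AlignmentSegment],
    genome: Sequence[Contig],
    path: Union[str, FilePath],
) -> None:
    """Write segments as SAM with strand/supplementary flags set."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c.name, "LN": c.length} for c in genome],
    }
    tid = {c.name: i for i, c in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for seg in segments:
            a = pysam.AlignedSegment()
            a.query_name = seg.read_name
            a.reference_id = tid[seg.interval.contig]
            a.reference_start = seg.interval.start
            a.mapping_quality = 60
            flag = 0
            if seg.strand == "-":
                flag |= 16
            if seg.role == "supplementary":
                flag |= 2048
            a.flag = flag
            span = seg.interval.length
            clip = seg.query_start or 0
            cigar = []
            if clip:
                cigar.append((4, clip))
            cigar.append((0, span))
            if seg.strand == "-" and clip:
                cigar.reverse()  # clip leads in query, trails in reference
            a.cigartuples = cigar
            out.write(a)
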