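"""VCF dialect parsing and normalization to canonical events."""

import pathlib

import pytest

import svgraph as sg
from svgraph.events import SIDE_LEFT, SIDE_RIGHT
from svgraph.simulate import SVPlacement
from svgraph.vcf import bnd_alt_string, parse_bnd_alt

HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">
##INFO=<ID=END,Number=1,Type=Integer,Description="t">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="t">
##INFO=<ID=RE,Number=1,Type=Integer,Description="t">
##INFO=<ID=MATEID,Number=1,Type=String,Description="t">
##contig=<ID=c1,length=10000>
##contig=<ID=c2,length=10000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(tmp_path, body: str) -> pathlib.Path:
    p = tmp_path / "in.vcf"
    p.write_text(HEADER + body)
    return p


class TestParseVcf:
    def test_symbolic_del_coordinates(self, tmp_path):
        p = write_vcf(tmp_path, "c1\t2001\t.\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=3000;SVLEN=-1000\n")
        rep = sg.parse_vcf(p, dialect="sniffles")
        (ev,) = rep.events
        assert ev.sv_type == "DEL"
        assert (ev.breakend_a.pos, ev.breakend_b.pos) == (2000, 3000)
        assert ev.length == 1000

    def test_padding_base_convention_maps_to_same_interval(self, tmp_path):
        # POS names the base before the event; SVLEN == END - POS
        p = write_vcf(tmp_path, "c1\t2000\t.\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=3000;SVLEN=-1000\n")
        (ev,) = sg.parse_vcf(p).events
        assert (ev.breakend_a.pos, ev.breakend_b.pos) == (2000, 3000)

    def test_empty_body_any_dialect(self, tmp_path):
        for dialect in ("sniffles", "survivor", "longranger", "generic_bnd"):
            rep = sg.parse_vcf(write_vcf(tmp_path, ""), dialect=dialect)
            assert rep.events == []

    def test_bnd_record_breakends(self, tmp_path):
        p = write_vcf(tmp_path, "c1\t500\tbnd1\tN\tN[c2:700[\t.\t.\tSVTYPE=BND\n")
        (ev,) = sg.parse_vcf(p, dialect="generic_bnd").events
        assert ev.sv_type == "BND"
        # junction boundary after 0-based base 499, left flank retained
        assert ev.breakend_a == sg.Breakend("c1", 500, SIDE_LEFT)
        # partner continues forward from 0-based 699
        assert ev.breakend_b == sg.Breakend("c2", 699, SIDE_RIGHT)

    def test_missing_svtype_collected_not_raised(self, tmp_path):
        p = write_vcf(tmp_path, "c1\t100\t.\tA\tT\t.\t.\t.\n")
        rep = sg.parse_vcf(p)
        assert rep.events == []
        assert len(rep.errors) == 1
        with pytest.raises(sg.VcfParseError):
            sg.parse_vcf(p, strict=True)

    def test_unknown_contig_skipped_and_reported(self, tmp_path):
        genome = sg.make_genome(1, [10_000], seed=1)
        p = write_vcf(tmp_path, "c2\t2001\t.\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=3000\n")
        rep = sg.parse_vcf(p, genome=genome)
        assert rep.events == []
        assert rep.skipped_contigs == {"c2": 1}

    def test_chr_prefix_reconciled(self, tmp_path):
        genome = [sg.Contig("chrc1", 10_000)]
        p = write_vcf(tmp_path, "c1\t2001\t.\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=3000\n")
        rep = sg.parse_vcf(p, genome=genome)
        assert rep.events[0].breakend_a.contig == "chrc1"
        assert rep.contig_renames == {"c1": "chrc1"}

    def test_ins_without_sequence_uses_svlen_run_of_n(self, tmp_path):
        p = write_vcf(tmp_path, "c1\t2000\t.\tN\t<INS>\t.\t.\tSVTYPE=INS;END=2000;SVLEN=5\n")
        (ev,) = sg.parse_vcf(p).events
        assert ev.inserted_sequence == "NNNNN"
        assert ev.breakend_a.pos == 2000

    def test_ins_without_sequence_or_svlen_is_an_error(self, tmp_path):
        p = write_vcf(tmp_path, "c1\t2000\t.\tN\t<INS>\t.\t.\tSVTYPE=INS;END=2000\n")
        rep = sg.parse_vcf(p)
        assert rep.events == [] and len(rep.errors) == 1


class TestBracketNotation:
    """The four bracket forms of the VCF breakend truth table."""

    @pytest.mark.parametrize(
        "alt,own,partner",
        [
            ("N[c2:700[", ("c1", 500, SIDE_LEFT), ("c2", 699, SIDE_RIGHT)),
            ("N]c2:700]", ("c1", 500, SIDE_LEFT), ("c2", 700, SIDE_LEFT)),
            ("]c2:700]N", ("c1", 499, SIDE_RIGHT), ("c2", 700, SIDE_LEFT)),
            ("[c2:700[N", ("c1", 499, SIDE_RIGHT), ("c2", 699, SIDE_RIGHT)),
        ],
    )
    def test_truth_table(self, alt, own, partner):
        o, p, _ = parse_bnd_alt("c1", 500, alt)
        assert o == sg.Breakend(*own)
        assert p == sg.Breakend(*partner)

    @pytest.mark.parametrize("alt", ["N[c2:700", "N[c2:700]", "[c2:700[", "NN"])
    def test_malformed_brackets_raise(self, alt):
        with pytest.raises(sg.VcfParseError):
            parse_bnd_alt("c1", 500, alt)

    def test_writer_parser_round_trip(self):
        for own_side in (SIDE_LEFT, SIDE_RIGHT):
            for partner_side in (SIDE_LEFT, SIDE_RIGHT):
                own = sg.Breakend("c1", 500, own_side)
                partner = sg.Breakend("c2", 700, partner_side)
                pos1 = own.pos if own_side == SIDE_LEFT else own.pos + 1
                o, p, _ = parse_bnd_alt("c1", pos1, bnd_alt_string(own, partner))
                assert (o, p) == (own, partner)


class TestCanonicalize:
    def _inv_events(self, genome, encoding, tmp_path):
        truth, vcf_text = sg.implant_svs(
            genome, [SVPlacement("INV", "c1", 2000, 3000)], inv_encoding=encoding
        )
        p = tmp_path / f"{encoding}.vcf"
        p.write_text(vcf_text)
        return truth, sg.canonicalize(sg.parse_vcf(p, genome=genome).events)

    @pytest.mark.parametrize("encoding", ["single", "double", "bnd_pair", "bnd_quad"])
    def test_every_inversion_encoding_collapses_to_one_inv(
        self, toy_genome, encoding, tmp_path
    ):
        truth, canon = self._inv_events(toy_genome, encoding, tmp_path)
        assert len(canon) == 1
        ev = canon[0]
        assert ev.sv_type == "INV"
        assert (ev.breakend_a.pos, ev.breakend_b.pos) == (2000, 3000)

    def test_single_inv_record_is_unchanged(self):
        ev = sg.SVEvent(
            id="i1", sv_type="INV",
            breakend_a=sg.Breakend("c1", 2000), breakend_b=sg.Breakend("c1", 3000),
        )
        assert sg.canonicalize([ev]) == [ev]

    def test_reciprocal_pair_found_by_brute_force_oracle(self, toy_genome, tmp_path):
        """Pairing agrees with exhaustive search over all event pairs."""
        _, canon = self._inv_events(toy_genome, "bnd_quad", tmp_path)
        raw = sg.parse_vcf(tmp_path / "bnd_quad.vcf", genome=toy_genome).events
        # oracle: count unordered reciprocal pairs among raw BND events
        pairs = 0
        for i in range(len(raw)):
            for j in range(i + 1, len(raw)):
                a, b = raw[i], raw[j]
                if a.breakend_a.near(b.breakend_b, 10) and a.breakend_b.near(
                    b.breakend_a, 10
                ):
                    pairs += 1
        assert pairs == 2  # two adjacencies, each stated from both ends
        assert len(canon) == 1

    def test_idempotent(self, toy_genome, tmp_path):
        for encoding in ("single", "bnd_quad"):
            _, canon = self._inv_events(toy_genome, encoding, tmp_path)
            assert sg.canonicalize(canon) == canon

    def test_dedup_keeps_highest_support(self):
        a = sg.SVEvent(id="a", sv_type="DEL", support=3,
                       breakend_a=sg.Breakend("c1", 2000),
                       breakend_b=sg.Breakend("c1", 3000))
        b = sg.SVEvent(id="b", sv_type="DEL", support=9,
                       breakend_a=sg.Breakend("c1", 2004),
                       breakend_b=sg.Breakend("c1", 2996))
        (kept,) = sg.canonicalize([a, b])
        assert kept.support == 9

    def test_unmatched_bnd_remains(self):
        ev = sg.SVEvent(id="b1", sv_type="BND",
                        breakend_a=sg.Breakend("c1", 500, SIDE_LEFT),
                        breakend_b=sg.Breakend("c2", 700, SIDE_RIGHT))
        (kept,) = sg.canonicalize([ev])
        assert kept.sv_type == "BND"

    def test_no_coordinate_invented(self, toy_genome, tmp_path):
        """Every output breakend position appears in some input record."""
        raw_pos = set()
        _, canon = self._inv_events(toy_genome, "bnd_quad", tmp_path)
        for ev in sg.parse_vcf(tmp_path / "bnd_quad.vcf", genome=toy_genome).events:
            raw_pos.update(p for _, p in ev.breakpoints())
        for ev in canon:
            for _, p in ev.breakpoints():
                assert p in raw_pos


def _ev(sv_type, start, end, event_id="e"):
    return sg.SVEvent(
        id=event_id, sv_type=sv_type,
        breakend_a=sg.Breakend("c1", start), breakend_b=sg.Breakend("c1", end),
    )


class TestEventsToBreakpoints:
    def test_single_del(self):
        assert sg.events_to_breakpoints([_ev("DEL", 2000, 3000)]) == {
            "c1": [2000, 3000]
        }

    def test_shared_boundary_deduplicated(self):
        events = [_ev("DEL", 2000, 3000, "d"), _ev("INV", 3000, 5000, "i")]
        # set-union oracle over all breakend positions
        expected = sorted({p for e in events for _, p in e.breakpoints()})
        assert sg.events_to_breakpoints(events) == {"c1": expected}
        assert expected == [2000, 3000, 5000]

    def test_empty(self):
        assert sg.events_to_breakpoints([]) == {}

    def test_ins_contributes_one_position(self):
        ins = sg.SVEvent(
            id="i", sv_type="INS", inserted_sequence="ACGT",
            breakend_a=sg.Breakend("c1", 2000), breakend_b=sg.Breakend("c1", 2000),
        )
        assert sg.events_to_breakpoints([ins]) == {"c1": [2000]}
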