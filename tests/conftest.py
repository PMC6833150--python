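"""Shared fixtures: toy graphs and genomes built fresh per test."""

from __future__ import annotations

import pytest
from hypothesis import settings

import svgraph as sg
from svgraph.simulate import SVPlacement

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def toy_genome():
    """One 10 kb uniform-random contig named c1."""
    return sg.make_genome(1, [10_000], seed=7)


@pytest.fixture
def two_contig_genome():
    """Two 10 kb contigs c1, c2 (for breakend fusions)."""
    return sg.make_genome(2, [10_000, 10_000], seed=11)


def del_event(contig="c1", start=2000, end=3000, event_id="d1"):
    return sg.SVEvent(
        id=event_id,
        sv_type="DEL",
        breakend_a=sg.Breakend(contig, start),
        breakend_b=sg.Breakend(contig, end),
    )


@pytest.fixture
def toy_del_graph(toy_genome):
    """10 kb contig with one 1 kb deletion at [2000, 3000): 3 nodes."""
    return sg.build_graph(toy_genome, [del_event()])


@pytest.fixture
def toy_three_node_graph(toy_genome):
    """Same 3-node tiling, no variant path (split induced by a dummy DEL
    whose path we drop is avoided — we just build with the DEL and use
    the tiling)."""
    return sg.build_graph(toy_genome, [del_event()])


def implant(genome, placements, **kwargs):
    """implant_svs + write the VCF to a temp-free round trip helper."""
    return sg.implant_svs(genome, placements, **kwargs)


@pytest.fixture
def mixed_truth(toy_genome):
    placements = [
        SVPlacement("DEL", "c1", 1000, 2500),
        SVPlacement("INV", "c1", 4000, 6000),
        SVPlacement("DUP", "c1", 7000, 8000),
    ]
    return sg.placements_to_events(placements)
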