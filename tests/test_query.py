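"""Interval subgraph extraction, LRU caching, gene lookup, deck batches."""

import random

import pytest

import svgraph as sg
from svgraph.events import SIDE_LEFT, SIDE_RIGHT
from svgraph.projections import Feature
from svgraph.query import DeckSummary, QueryCache, deck_run


def steps_of(path):
    return [str(s) for s in path.steps]


class TestExtractSubgraph:
    def test_del_neighborhood_pulls_in_whole_variant_path(self, toy_del_graph):
        sub = sg.extract_subgraph(toy_del_graph, sg.Interval("c1", 2100, 2900))
        # n2 overlaps; DEL path (1+,3+) does not touch n2, so only n2 + ref
        assert sorted(sub.nodes) == [2]
        (ref,) = sub.paths
        assert steps_of(ref) == ["2+"]

    def test_junction_interval_includes_flanks(self, toy_del_graph):
        sub = sg.extract_subgraph(toy_del_graph, sg.Interval("c1", 1900, 2100))
        # n1 and n2 overlap; DEL path touches n1 -> pulls in n3 as well
        assert sorted(sub.nodes) == [1, 2, 3]
        by_class = {p.path_class for p in sub.paths}
        assert by_class == {"reference", "variant"}
        (del_path,) = sub.paths_by_class("variant")
        assert steps_of(del_path) == ["1+", "3+"]

    def test_no_sv_region_is_reference_fragment_only(self, toy_genome):
        g = sg.build_graph(toy_genome, [])
        sub = sg.extract_subgraph(g, sg.Interval("c1", 0, 500))
        assert sorted(sub.nodes) == [1]
        assert [p.path_class for p in sub.paths] == ["reference"]

    def test_bnd_query_reaches_partner_contig(self, two_contig_genome):
        bnd = sg.SVEvent(
            id="t1", sv_type="BND",
            breakend_a=sg.Breakend("c1", 5000, SIDE_LEFT),
            breakend_b=sg.Breakend("c2", 7000, SIDE_RIGHT),
        )
        g = sg.build_graph(two_contig_genome, [bnd])
        sub = sg.extract_subgraph(g, sg.Interval("c1", 4900, 5100))
        contigs = {g.nodes[i].origin[0] for i in sub.nodes if g.nodes[i].origin}
        assert contigs == {"c1", "c2"}

    def test_soundness_no_unrelated_node(self, toy_genome):
        events = [
            sg.SVEvent(id="d", sv_type="DEL",
                       breakend_a=sg.Breakend("c1", 1000, "left"),
                       breakend_b=sg.Breakend("c1", 2500, "left")),
            sg.SVEvent(id="i", sv_type="INV",
                       breakend_a=sg.Breakend("c1", 7000, "left"),
                       breakend_b=sg.Breakend("c1", 8000, "left")),
        ]
        g = sg.build_graph(toy_genome, events)
        sub = sg.extract_subgraph(g, sg.Interval("c1", 7100, 7900))
        variant_nodes = set()
        for p in g.paths_by_class("variant"):
            if p.metadata["event_id"] == "i":
                variant_nodes.update(s.node_id for s in p.steps)
        core = {n.id for n in g.nodes_in("c1", 7100, 7900)}
        assert set(sub.nodes) <= core | variant_nodes

    def test_restriction_closure(self, toy_del_graph):
        for iv in [(0, 500), (1900, 2100), (2100, 2900), (0, 10_000)]:
            sub = sg.extract_subgraph(toy_del_graph, sg.Interval("c1", *iv))
            assert sub.validate() == []

    def test_unknown_contig_and_empty_overlap(self, toy_del_graph):
        with pytest.raises(sg.QueryError):
            sg.extract_subgraph(toy_del_graph, sg.Interval("cX", 0, 10))

    def test_read_paths_never_trigger_inclusion(self, toy_del_graph):
        from svgraph.projections import AlignmentSegment

        segs = [
            AlignmentSegment("r1", sg.Interval("c1", 500, 900), "+", query_start=0),
            AlignmentSegment("r1", sg.Interval("c1", 5000, 5400), "+", query_start=400),
        ]
        for p in sg.project_alignments(toy_del_graph, segs):
            toy_del_graph.add_path(p)
        sub = sg.extract_subgraph(toy_del_graph, sg.Interval("c1", 500, 900))
        # the read jumps to node 3's territory, but reads are evidence:
        # only n1 (overlap) and the DEL path's nodes appear
        assert sorted(sub.nodes) == [1, 3]
        read_fragments = sub.paths_by_class("read")
        for frag in read_fragments:
            assert {s.node_id for s in frag.steps} <= {1, 3}


class TestQueryCache:
    def test_hit_returns_same_object_without_extraction(self, toy_del_graph):
        cache = QueryCache(capacity=4)
        iv = sg.Interval("c1", 2100, 2900)
        first = sg.cached_query(cache, toy_del_graph, iv)
        second = sg.cached_query(cache, toy_del_graph, iv)
        assert second is first
        assert (cache.hits, cache.misses) == (1, 1)

    def test_lru_eviction_of_oldest(self, toy_del_graph):
        cache = QueryCache(capacity=2)
        ivs = [sg.Interval("c1", s, s + 100) for s in (0, 1000, 4000)]
        for iv in ivs:
            sg.cached_query(cache, toy_del_graph, iv)
        assert cache.evictions == 1
        sg.cached_query(cache, toy_del_graph, ivs[0])  # evicted -> miss
        assert cache.misses == 4

    def test_transparency_against_uncached(self, toy_del_graph):
        """Randomized query stream: cached result always equals uncached."""
        rng = random.Random(42)
        cache = QueryCache(capacity=4)
        for _ in range(200):
            s = rng.randrange(0, 9_000)
            iv = sg.Interval("c1", s, s + rng.randrange(1, 1000))
            cached = sg.cached_query(cache, toy_del_graph, iv)
            plain = sg.extract_subgraph(toy_del_graph, iv)
            assert sorted(cached.nodes) == sorted(plain.nodes)
            assert [(p.name, steps_of(p)) for p in cached.paths] == [
                (p.name, steps_of(p)) for p in plain.paths
            ]

    def test_lru_matches_reference_simulation(self, toy_del_graph):
        """Hit/miss stream equals an independent OrderedDict LRU model."""
        from collections import OrderedDict

        rng = random.Random(7)
        capacity = 3
        cache = QueryCache(capacity=capacity)
        model: OrderedDict = OrderedDict()
        expected_hits = 0
        for _ in range(300):
            s = rng.randrange(0, 20) * 400
            iv = sg.Interval("c1", s, s + 100)
            key = ("c1", iv.start, iv.end, 0)
            if key in model:
                expected_hits += 1
                model.move_to_end(key)
            else:
                model[key] = True
                if len(model) > capacity:
                    model.popitem(last=False)
            sg.cached_query(cache, toy_del_graph, iv)
            assert cache.hits == expected_hits


class TestGeneLookup:
    FEATURES = [
        Feature(sg.Interval("chr10", 59_786_747, 59_908_656), "CCDC6", "-", "gene"),
        Feature(sg.Interval("chr10", 43_075_068, 43_132_349), "RET", "+", "gene"),
        Feature(sg.Interval("chr7", 1000, 2000), "CCDC7", "+", "gene"),
    ]

    def test_prefix_completion_and_unique_resolution(self):
        completions, resolved = sg.gene_to_interval("CCDC6", self.FEATURES)
        assert completions == ["CCDC6"]
        assert resolved == sg.Interval("chr10", 59_786_747, 59_908_656)

    def test_prefix_lists_all_matches_without_resolving(self):
        completions, resolved = sg.gene_to_interval("CCDC", self.FEATURES)
        assert completions == ["CCDC6", "CCDC7"]
        assert resolved is None

    def test_empty_prefix_lists_everything(self):
        completions, resolved = sg.gene_to_interval("", self.FEATURES)
        assert completions == ["CCDC6", "CCDC7", "RET"]
        assert resolved is None

    def test_no_match(self):
        assert sg.gene_to_interval("ZZZZ", self.FEATURES) == ([], None)

    def test_case_insensitive(self):
        completions, resolved = sg.gene_to_interval("ret", self.FEATURES)
        assert completions == ["RET"]
        assert resolved is not None


class TestDeckRun:
    def test_keep_discard_order(self, toy_del_graph):
        ivs = [sg.Interval("c1", s, s + 100) for s in (0, 1000, 4000)]
        kept, summaries = deck_run(toy_del_graph, ivs, [True, False, True])
        assert kept == [ivs[0], ivs[2]]
        assert all(isinstance(s, DeckSummary) for s in summaries)
        assert len(summaries) == 3

    def test_second_pass_fully_cached(self, toy_del_graph):
        ivs = [sg.Interval("c1", s, s + 100) for s in range(0, 5000, 500)]
        cache = QueryCache(capacity=len(ivs))
        deck_run(toy_del_graph, ivs, cache=cache)
        misses_after_first = cache.misses
        deck_run(toy_del_graph, ivs, cache=cache)
        assert cache.misses == misses_after_first

    def test_errors_collected_not_raised(self, toy_del_graph):
        ivs = [sg.Interval("cX", 0, 10), sg.Interval("c1", 0, 100)]
        kept, summaries = deck_run(toy_del_graph, ivs)
        assert kept == [ivs[1]]
        assert summaries[0].error is not None

    def test_empty_deck(self, toy_del_graph):
        assert deck_run(toy_del_graph, []) == ([], [])
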