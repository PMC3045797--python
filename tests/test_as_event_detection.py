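"""Event classification, comparison windows, reference clustering."""
import numpy as np
import pytest

from splicetrap.alignment_filter import AlignedAsset
from splicetrap.as_event_detection import (
    ASEvent,
    classify_events,
    cluster_with_references,
    comparison_window,
    detect_cluster_events,
    flag_intronless_overlap,
    summarize_events,
)
from splicetrap.genomic_model import GenomicInterval
from splicetrap.synthetic import random_chain_pair

from conftest import make_model
from oracles import oracle_classify


def as_set(events):
    return {(e.event_type, e.start, e.end, e.size) for e in events}


class TestClassifyEvents:
    def test_exon_skipping_toy(self):
        a = make_model([(0, 100), (200, 300)], tid="a")
        b = make_model([(0, 100), (140, 160), (200, 300)], tid="b")
        events = classify_events(a, b)
        assert as_set(events) == {("exon_skipping", 140, 160, 20)}

    def test_intron_retention_toy(self):
        a = make_model([(0, 300)], tid="a")
        b = make_model([(0, 100), (200, 300)], tid="b")
        window = GenomicInterval("chr1", 0, 300)
        events = classify_events(a, b, window)
        assert as_set(events) == {("intron_retention", 100, 200, 100)}

    def test_alt_5ss_elongating_an_exon_by_117(self):
        # one variant uses a donor 117 nt downstream inside the intron,
        # elongating the upstream exon; shared acceptor at 500
        a = make_model([(0, 217), (500, 600)], tid="a")
        b = make_model([(0, 100), (500, 600)], tid="b")
        events = classify_events(a, b)
        assert as_set(events) == {("alt_5ss", 100, 217, 117)}

    def test_alt_3ss_shared_donor(self):
        a = make_model([(0, 100), (300, 400)], tid="a")
        b = make_model([(0, 100), (350, 400)], tid="b")
        events = classify_events(a, b)
        assert as_set(events) == {("alt_3ss", 300, 350, 50)}

    def test_identical_chains_are_silent(self):
        a = make_model([(0, 100), (200, 300)], tid="a")
        b = make_model([(0, 100), (200, 300)], tid="b")
        assert classify_events(a, b) == []

    def test_symmetry_in_the_two_chains(self):
        a = make_model([(0, 100), (200, 300), (420, 500)], tid="a")
        b = make_model([(0, 120), (200, 300), (400, 500)], tid="b")
        assert as_set(classify_events(a, b)) == as_set(classify_events(b, a))

    def test_minus_strand_swaps_alt_site_labels(self):
        # same genomic geometry, opposite strands: the shared boundary at
        # 500 is an acceptor on + (alt 5') but a donor on - (alt 3')
        a_plus = make_model([(0, 217), (500, 600)], tid="a")
        b_plus = make_model([(0, 100), (500, 600)], tid="b")
        a_minus = make_model([(0, 217), (500, 600)], strand="-", tid="a")
        b_minus = make_model([(0, 100), (500, 600)], strand="-", tid="b")
        (ev_plus,) = classify_events(a_plus, b_plus)
        (ev_minus,) = classify_events(a_minus, b_minus)
        assert ev_plus.event_type == "alt_5ss"
        assert ev_minus.event_type == "alt_3ss"
        assert (ev_plus.start, ev_plus.end) == (ev_minus.start, ev_minus.end)

    def test_skipping_not_double_counted_as_alt_sites(self):
        a = make_model([(0, 100), (400, 500)], tid="a")
        b = make_model([(0, 100), (200, 300), (400, 500)], tid="b")
        events = classify_events(a, b)
        assert [e.event_type for e in events] == ["exon_skipping"]

    def test_different_strand_raises(self):
        a = make_model([(0, 100), (200, 300)], tid="a")
        b = make_model([(0, 100), (200, 300)], strand="-", tid="b")
        with pytest.raises(ValueError):
            classify_events(a, b)

    def test_window_excludes_outside_introns(self):
        a = make_model([(0, 100), (200, 300), (400, 500)], tid="a")
        b = make_model([(0, 100), (250, 300), (400, 500)], tid="b")
        window = GenomicInterval("chr1", 350, 500)
        assert classify_events(a, b, window) == []

    def test_random_pairs_match_brute_force_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(300):
            a, b = random_chain_pair(rng)
            window = comparison_window(a, b)
            got = as_set(classify_events(a, b, window))
            assert got == oracle_classify(a, b, window)


class TestComparisonWindow:
    def test_identical_chains_window_is_shared_span(self):
        a = make_model([(0, 100), (200, 300)], tid="a")
        b = make_model([(0, 100), (200, 300)], tid="b")
        w = comparison_window(a, b)
        assert (w.start, w.end) == (0, 300)

    def test_partial_asset_window(self):
        ref = make_model([(i * 200, i * 200 + 100) for i in range(6)], tid="ref")
        asset = make_model([(250, 300), (400, 500), (600, 700)], tid="as")
        w = comparison_window(asset, ref)
        # first overlap begins inside reference exon 2 (at 250), last ends
        # with the asset's final exon overlap (at 700)
        assert (w.start, w.end) == (250, 700)

    def test_disjoint_chains_raise(self):
        a = make_model([(0, 100)], tid="a")
        b = make_model([(200, 300)], tid="b")
        with pytest.raises(ValueError):
            comparison_window(a, b)

    def test_window_equals_all_pairs_intersection_extrema(self, rng):
        for _ in range(50):
            a, b = random_chain_pair(rng)
            w = comparison_window(a, b)
            inters = [
                (max(ea.start, eb.start), min(ea.end, eb.end))
                for ea in a.exons
                for eb in b.exons
                if max(ea.start, eb.start) < min(ea.end, eb.end)
            ]
            assert w.start == min(lo for lo, _ in inters)
            assert w.end == max(hi for _, hi in inters)


def _asset(chain):
    return AlignedAsset(chain.transcript_id, chain, 100, 100, 100)


class TestClusterWithReferences:
    def test_overlapping_asset_and_reference_cluster_together(self):
        asset = _asset(make_model([(50, 150)], tid="as1"))
        ref = make_model([(100, 200), (300, 400)], tid="ref1")
        (cluster,) = cluster_with_references([asset], [ref])
        assert len(cluster.assets) == 1 and len(cluster.references) == 1
        assert cluster.has_reference

    def test_opposite_strands_do_not_cluster(self):
        asset = _asset(make_model([(50, 150)], tid="as1"))
        ref = make_model([(100, 200)], strand="-", tid="ref1")
        (cluster,) = cluster_with_references([asset], [ref])
        assert cluster.references == []

    def test_intron_only_overlap_does_not_link(self):
        # the asset sits wholly inside the reference's intron
        asset = _asset(make_model([(120, 180)], tid="as1"))
        ref = make_model([(0, 100), (200, 300)], tid="ref1")
        (cluster,) = cluster_with_references([asset], [ref])
        assert cluster.references == []

    def test_partition_matches_connected_components_oracle(self, rng):
        import networkx as nx

        chains = []
        for i in range(40):
            start = int(rng.integers(0, 3000))
            n = int(rng.integers(1, 4))
            exons = []
            pos = start
            for _ in range(n):
                length = int(rng.integers(20, 120))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(10, 200))
            chains.append(make_model(exons, tid=f"c{i}"))
        assets = [_asset(c) for c in chains[:20]]
        refs = chains[20:]
        clusters = cluster_with_references(assets, refs)

        g = nx.Graph()
        g.add_nodes_from(range(len(chains)))
        for i, a in enumerate(chains):
            for j, b in enumerate(chains):
                if i < j and any(ea.overlaps(eb) for ea in a.exons for eb in b.exons):
                    g.add_edge(i, j)
        expected = {
            frozenset(chains[i].transcript_id for i in comp)
            for comp in nx.connected_components(g)
            if any(i < 20 for i in comp)
        }
        got = {
            frozenset(
                [a.asset_id for a in c.assets]
                + [r.transcript_id for r in c.references]
            )
            for c in clusters
        }
        # reference-only members of mixed components are kept; pure
        # reference components are dropped by the implementation
        assert got == expected


class TestSummaries:
    def test_percentages_of_composed_count_vector(self):
        events = []
        for t, n in (("alt_5ss", 62), ("alt_3ss", 55),
                     ("exon_skipping", 13), ("intron_retention", 8)):
            for i in range(n):
                events.append(ASEvent(t, "chr1", 10 * i + 1, 10 * i + 5, "+", 4,
                                      asset_id=f"as{i % 39}"))
        s = summarize_events(events)
        assert s["total"] == 138
        assert s["percentages"] == {
            "alt_5ss": 44.9, "alt_3ss": 39.9,
            "exon_skipping": 9.4, "intron_retention": 5.8,
        }
        assert s["assets_with_events"] == 39

    def test_empty_event_list(self):
        s = summarize_events([])
        assert s["total"] == 0
        assert all(v == 0.0 for v in s["percentages"].values())

    def test_dedup_switch_collapses_repeated_coords(self):
        asset = _asset(make_model([(0, 100), (200, 300)], tid="as1"))
        ref_a = make_model([(0, 100), (140, 160), (200, 300)], tid="refA")
        ref_b = make_model([(0, 100), (140, 160), (200, 300)], tid="refB")
        (cluster,) = cluster_with_references([asset], [ref_a, ref_b])
        deduped = detect_cluster_events(cluster, dedup=True)
        raw = detect_cluster_events(cluster, dedup=False)
        assert len(deduped) == 1
        assert len(raw) == 2


class TestIntronlessOverlap:
    def test_printed_ratio(self):
        spans = [GenomicInterval("chr1", i * 10, i * 10 + 5) for i in range(96)]
        events = [GenomicInterval("chr1", i * 10, i * 10 + 5) for i in range(63)]
        n_hit, n_total, pct = flag_intronless_overlap(spans, events)
        assert (n_hit, n_total, pct) == (63, 96, 65.6)

    def test_no_events_means_zero(self):
        spans = [GenomicInterval("chr1", 0, 50)]
        assert flag_intronless_overlap(spans, [])[2] == 0.0

    def test_matches_interval_intersection_oracle(self, rng):
        spans = []
        events = []
        for _ in range(50):
            s = int(rng.integers(0, 5000))
            spans.append(GenomicInterval("chr1", s, s + int(rng.integers(10, 200))))
        for _ in range(20):
            s = int(rng.integers(0, 5000))
            events.append(GenomicInterval("chr1", s, s + int(rng.integers(5, 100))))
        n_hit, _, _ = flag_intronless_overlap(spans, events)
        brute = sum(
            1
            for sp in spans
            if any(sp.start < ev.end and ev.start < sp.end for ev in events)
        )
        assert n_hit == brute
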