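"""Assembly-graph parsing, marker flagging, context extraction, colocation."""

import heapq
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from magnetag.graph import (
    AssemblyGraph,
    BinAssignment,
    GfaParseError,
    GraphLink,
    MarkerHitSet,
    MarkerHit,
    AlignmentRecord,
    Unitig,
    align_fragments,
    colocate_bins,
    export_gfa,
    extract_context_subgraph,
    flag_marker_unitigs,
    interval_union_breadth,
    parse_gfa,
)


def chain_graph(n=5, length=3000, overlap=0):
    ids = [chr(ord("A") + i) for i in range(n)]
    unitigs = [Unitig(i, length) for i in ids]
    links = [GraphLink(a, b, "+", "+", overlap) for a, b in zip(ids[:-1], ids[1:])]
    return AssemblyGraph(unitigs, links), ids


class TestParseGfa:
    def test_counts_records(self, tmp_path):
        p = tmp_path / "g.gfa"
        p.write_text("H\tVN:Z:1.0\nS\tu1\tACGTACGT\nS\tu2\tTTTT\nL\tu1\t+\tu2\t-\t0M\n")
        g = parse_gfa(p)
        assert len(g.unitigs) == 2 and len(g.links) == 1
        assert g.unitigs["u1"].length == 8

    def test_star_sequence_uses_ln_tag(self, tmp_path):
        p = tmp_path / "g.gfa"
        p.write_text("S\tu1\t*\tLN:i:500\tdp:f:12.5\n")
        g = parse_gfa(p)
        assert g.unitigs["u1"].length == 500
        assert g.unitigs["u1"].sequence is None
        assert g.unitigs["u1"].depth == 12.5

    def test_unknown_line_types_warn(self, tmp_path):
        p = tmp_path / "g.gfa"
        p.write_text("S\tu1\tACGT\nP\tpath1\tu1+\t*\n")
        with pytest.warns(UserWarning, match="skipped"):
            parse_gfa(p)

    def test_malformed_s_line_names_line_number(self, tmp_path):
        p = tmp_path / "g.gfa"
        p.write_text("S\tu1\tACGT\nS\tonlyname\n")
        with pytest.raises(GfaParseError, match="line 2"):
            parse_gfa(p)

    def test_link_to_unknown_id_is_structural_error(self, tmp_path):
        p = tmp_path / "g.gfa"
        p.write_text("S\tu1\tACGT\nL\tu1\t+\tghost\t+\t0M\n")
        with pytest.raises(GfaParseError, match="ghost"):
            parse_gfa(p)

    def test_round_trip_of_generated_graph(self, assembly, tmp_path):
        out = tmp_path / "rt.gfa"
        export_gfa(assembly.graph, out)
        g2 = parse_gfa(out)
        assert set(g2.unitigs) == set(assembly.graph.unitigs)
        for uid, u in assembly.graph.unitigs.items():
            assert g2.unitigs[uid].length == u.length
            assert g2.unitigs[uid].sequence == u.sequence
        orig = {(l.from_id, l.to_id, l.overlap) for l in assembly.graph.links}
        back = {(l.from_id, l.to_id, l.overlap) for l in g2.links}
        assert orig == back

    def test_export_subgraph_record_counts(self, tmp_path):
        g, ids = chain_graph(5)
        out = tmp_path / "sub.gfa"
        export_gfa(g, out, members={"A", "B", "C"})
        lines = out.read_text().splitlines()
        assert sum(l.startswith("S") for l in lines) == 3
        assert sum(l.startswith("L") for l in lines) == 2  # only induced links

    def test_export_empty_subgraph_is_header_only(self, tmp_path):
        g, _ = chain_graph(3)
        out = tmp_path / "empty.gfa"
        export_gfa(g, out, members=set())
        assert out.read_text().splitlines() == ["H\tVN:Z:1.0"]


class TestFlagMarkerUnitigs:
    def make_graph(self, ids):
        return AssemblyGraph([Unitig(i, 5000) for i in ids])

    def test_breadth_of_planted_fragments(self):
        # fragments [0,1500), [1400,3000), [3500,4500) of a 4500 bp reference:
        # union covers 3000 + 1000 bases
        g = self.make_graph(["a", "b", "c"])
        alns = [
            AlignmentRecord("a", 1.0, 0, 1500, 1500),
            AlignmentRecord("b", 1.0, 1400, 3000, 1600),
            AlignmentRecord("c", 1.0, 3500, 4500, 1000),
        ]
        hits = flag_marker_unitigs(g, alns, 0.98, 500, 4500)
        assert len(hits.hits) == 3
        assert hits.breadth == pytest.approx(4000 / 4500)

    def test_identity_below_threshold_excluded(self):
        g = self.make_graph(["a"])
        alns = [AlignmentRecord("a", 0.90, 0, 1000, 1000)]
        hits = flag_marker_unitigs(g, alns, 0.98, 500, 4500)
        assert hits.hits == [] and hits.breadth == 0.0

    def test_short_alignment_excluded(self):
        g = self.make_graph(["a"])
        alns = [AlignmentRecord("a", 1.0, 0, 300, 300)]
        assert flag_marker_unitigs(g, alns, 0.98, 500, 4500).hits == []

    def test_unknown_unitig_listed(self):
        g = self.make_graph(["a"])
        with pytest.raises(GfaParseError, match="ghost"):
            flag_marker_unitigs(g, [AlignmentRecord("ghost", 1.0, 0, 1000, 1000)],
                                0.98, 500, 4500)

    def test_nonpositive_ref_length_rejected(self):
        g = self.make_graph(["a"])
        with pytest.raises(ValueError):
            flag_marker_unitigs(g, [], 0.98, 500, 0)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 400), st.integers(1, 200)), max_size=20))
    def test_breadth_matches_boolean_array_oracle(self, raw):
        intervals = [(s, s + l) for s, l in raw]
        ref_len = 500
        mask = np.zeros(ref_len, dtype=bool)
        for s, e in intervals:
            mask[s:min(e, ref_len)] = True
        assert interval_union_breadth(intervals, ref_len) == pytest.approx(
            mask.sum() / ref_len)


class TestAlignFragments:
    def test_exact_substring_identity_one(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=2000))
        q = ref[300:1200]
        (rec,) = align_fragments(ref, {"q": q})
        assert rec.identity == 1.0
        assert (rec.ref_start, rec.ref_end) == (300, 1200)
        assert rec.aln_len == 900

    def test_substitutions_lower_identity_by_count(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=1000))
        q = list(ref[100:600])
        for i in (50, 250):  # 2 substitutions over 500 columns
            q[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[i]]
        (rec,) = align_fragments(ref, {"q": "".join(q)})
        assert rec.identity == pytest.approx(1 - 2 / 500)

    def test_reverse_complement_found_on_forward_reference(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=1500))
        rc = ref[200:900].translate(str.maketrans("ACGT", "TGCA"))[::-1]
        (rec,) = align_fragments(ref, {"q": rc})
        assert rec.identity == 1.0 and rec.strand == "-"
        assert (rec.ref_start, rec.ref_end) == (200, 900)

    def test_agrees_with_independent_dp_oracle(self, rng):
        # unit-cost semi-global DP oracle (query infix of reference)
        def oracle_distance(q, r):
            prev = [0] * (len(r) + 1)
            for i in range(1, len(q) + 1):
                cur = [i] + [0] * len(r)
                for j in range(1, len(r) + 1):
                    cur[j] = min(prev[j - 1] + (q[i - 1] != r[j - 1]),
                                 prev[j] + 1, cur[j - 1] + 1)
                prev = cur
            return min(prev)

        rc = str.maketrans("ACGT", "TGCA")
        for _ in range(5):
            ref = "".join(rng.choice(list("ACGT"), size=300))
            q = "".join(rng.choice(list("ACGT"), size=120))
            (rec,) = align_fragments(ref, {"q": q})
            dist = round((1 - rec.identity) * rec.aln_len)
            both = min(oracle_distance(q, ref),
                       oracle_distance(q.translate(rc)[::-1], ref))
            assert dist == both

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_fragments("", {"q": "ACGT"})
        with pytest.raises(ValueError):
            align_fragments("ACGT", {"q": ""})


def brute_force_distances(graph, seeds, radius):
    """Independent oracle: enumerate all simple paths, score intervening unitigs."""
    adj = graph.adjacency()
    best = {s: 0 for s in seeds}
    for seed in seeds:
        stack = [(seed, [seed], 0)]
        while stack:
            node, path, cost = stack.pop()
            for nxt, ov in adj[node].items():
                if nxt in path:
                    continue
                step = 0 if node in seeds else max(0, graph.length_of(node) - ov)
                nc = cost + step
                if nc <= radius and nc < best.get(nxt, nc + 1):
                    best[nxt] = nc
                if nc <= radius:
                    stack.append((nxt, path + [nxt], nc))
    return best


class TestContextSubgraph:
    def test_isolated_seed(self):
        g = AssemblyGraph([Unitig("s", 1000)])
        sub = extract_context_subgraph(g, ["s"], 10000)
        assert sub.member_ids == {"s"} and sub.distances == {"s": 0}

    def test_chain_radius_2000(self):
        g, _ = chain_graph(5, length=3000)
        sub = extract_context_subgraph(g, ["C"], 2000)
        assert sub.member_ids == {"B", "C", "D"}
        assert sub.distances == {"B": 0, "C": 0, "D": 0}

    def test_chain_radius_5000_reaches_all(self):
        g, ids = chain_graph(5, length=3000)
        sub = extract_context_subgraph(g, ["C"], 5000)
        assert sub.member_ids == set(ids)
        assert sub.distances["A"] == 3000 and sub.distances["E"] == 3000

    def test_overlap_shortens_distance(self):
        g, _ = chain_graph(5, length=3000, overlap=500)
        sub = extract_context_subgraph(g, ["C"], 2500)
        assert sub.distances["A"] == 2500  # 3000 - 500 overlap

    def test_membership_monotone_in_radius(self, assembly):
        seeds = list(assembly.truth.operon_intervals)[:2]
        prev = set()
        for r in (0, 2000, 10000, 50000):
            members = extract_context_subgraph(assembly.graph, seeds, r).member_ids
            assert prev <= members
            prev = members

    def test_errors(self):
        g, _ = chain_graph(3)
        with pytest.raises(ValueError):
            extract_context_subgraph(g, [], 1000)
        with pytest.raises(ValueError):
            extract_context_subgraph(g, ["ghost"], 1000)
        with pytest.raises(ValueError):
            extract_context_subgraph(g, ["A"], -1)

    def test_agrees_with_brute_force_on_random_small_graphs(self, rng):
        for trial in range(50):
            n = int(rng.integers(2, 9))
            ids = [f"u{i}" for i in range(n)]
            unitigs = [Unitig(i, int(rng.integers(100, 5000))) for i in ids]
            links = []
            for a, b in itertools.combinations(range(n), 2):
                if rng.random() < 0.35:
                    ov = int(rng.integers(0, min(unitigs[a].length, unitigs[b].length)))
                    links.append(GraphLink(ids[a], ids[b], "+", "+", ov))
            g = AssemblyGraph(unitigs, links)
            seeds = {ids[int(rng.integers(0, n))]}
            radius = int(rng.integers(0, 8000))
            sub = extract_context_subgraph(g, seeds, radius)
            assert sub.distances == brute_force_distances(g, seeds, radius)


class TestColocateBins:
    def test_empty_subgraph(self):
        g, _ = chain_graph(3)
        from magnetag.graph import ContextSubgraph

        sub = ContextSubgraph(set(), {"A"}, 0, {})
        rep = colocate_bins(g, sub, BinAssignment({"A": "b1"}))
        assert rep.rows == []

    def test_enumeration(self):
        g, _ = chain_graph(4, length=1000)
        from magnetag.graph import ContextSubgraph

        sub = ContextSubgraph({"A", "B", "C", "D"}, {"A"}, 0,
                              {k: 0 for k in "ABCD"})
        bins = BinAssignment({"A": "bin17", "B": "bin17", "C": "bin70"})
        rep = colocate_bins(g, sub, bins)
        assert [(r.bin_id, r.n_members, r.member_bp) for r in rep.rows] == [
            ("bin17", 2, 2000), ("bin70", 1, 1000)]
        assert rep.unbinned_count == 1 and rep.unbinned_bp == 1000

    def test_planted_bin_always_colocated(self, assembly, operon_alignments):
        hits = flag_marker_unitigs(assembly.graph, operon_alignments, 0.98, 500,
                                   len(assembly.reference))
        sub = extract_context_subgraph(assembly.graph, hits.unitig_ids, 0)
        rep = colocate_bins(assembly.graph, sub, assembly.bins)
        assert assembly.truth.target_bin in rep.bin_ids


class TestBinAssignment:
    def test_min_contig_length_filter(self, tmp_path):
        p = tmp_path / "bins.tsv"
        p.write_text("c1\tbin1\nc2\tbin1\nc3\tbin2\n")
        ba = BinAssignment.from_tsv(p, lengths={"c1": 2000, "c2": 500, "c3": 1500},
                                    min_contig_len=1000)
        assert ba.mapping == {"c1": "bin1", "c3": "bin2"}

    def test_conflicting_assignment_rejected(self, tmp_path):
        p = tmp_path / "bins.tsv"
        p.write_text("c1\tbin1\nc1\tbin2\n")
        with pytest.raises(ValueError, match="two bins"):
            BinAssignment.from_tsv(p)
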