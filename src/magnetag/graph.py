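"""Assembly-graph context around a reference ribosomal marker.

A fragmented eukaryotic genome leaves its multi-copy rDNA operon scattered
over short unitigs that rarely bin well.  The operations here anchor a
candidate genome to those unitigs: parse the GFA1 assembly graph, flag
unitigs with high-identity alignments to the reference operon, extract the
sequence-distance neighbourhood around the flagged seeds, and report which
bins colocate with them on the graph.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

__all__ = [
    "Unitig",
    "GraphLink",
    "AssemblyGraph",
    "AlignmentRecord",
    "MarkerHit",
    "MarkerHitSet",
    "ContextSubgraph",
    "BinAssignment",
    "GfaParseError",
    "parse_gfa",
    "export_gfa",
    "flag_marker_unitigs",
    "align_fragments",
    "extract_context_subgraph",
    "colocate_bins",
]


class GfaParseError(ValueError):
    """Raised for malformed or structurally inconsistent GFA input."""


@dataclass
class Unitig:
    """A node of the assembly graph.

    ``depth`` is the assembler's mean k-mer or read depth when the GFA
    carries a ``dp``/``DP`` float tag or a ``KC`` k-mer count tag
    (converted to per-base depth).
    """

    id: str
    length: int
    sequence: str | None = None
    depth: float | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"unitig {self.id}: length must be >= 1, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"unitig {self.id}: sequence length {len(self.sequence)} != length field {self.length}"
            )


@dataclass(frozen=True)
class GraphLink:
    """An overlap edge between two oriented unitig ends."""

    from_id: str
    to_id: str
    from_orient: str
    to_orient: str
    overlap: int = 0


class AssemblyGraph:
    """Unitigs plus overlap links; undirected for traversal, oriented for export."""

    def __init__(self, unitigs: list[Unitig] | None = None, links: list[GraphLink] | None = None):
        self.unitigs: dict[str, Unitig] = {}
        self.links: list[GraphLink] = []
        for u in unitigs or []:
            self.add_unitig(u)
        for l in links or []:
            self.add_link(l)

    def add_unitig(self, u: Unitig) -> None:
        if u.id in self.unitigs:
            raise GfaParseError(f"duplicate unitig id {u.id!r}")
        self.unitigs[u.id] = u

    def add_link(self, l: GraphLink) -> None:
        for end in (l.from_id, l.to_id):
            if end not in self.unitigs:
                raise GfaParseError(f"link references unknown unitig {end!r}")
        m = min(self.unitigs[l.from_id].length, self.unitigs[l.to_id].length)
        if not 0 <= l.overlap < m:
            raise GfaParseError(
                f"link {l.from_id}-{l.to_id}: overlap {l.overlap} outside [0, {m})"
            )
        self.links.append(l)

    def __len__(self) -> int:
        return len(self.unitigs)

    def __contains__(self, uid: str) -> bool:
        return uid in self.unitigs

    def length_of(self, uid: str) -> int:
        return self.unitigs[uid].length

    def adjacency(self) -> dict[str, dict[str, int]]:
        """Undirected adjacency with the minimal overlap per unitig pair."""
        adj: dict[str, dict[str, int]] = {uid: {} for uid in self.unitigs}
        for l in self.links:
            if l.from_id == l.to_id:
                continue
            for a, b in ((l.from_id, l.to_id), (l.to_id, l.from_id)):
                prev = adj[a].get(b)
                if prev is None or l.overlap < prev:
                    adj[a][b] = l.overlap
        return adj


# ---------------------------------------------------------------------------
# GFA1 I/O


def _parse_tags(fields: list[str]) -> dict[str, str]:
    tags = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = parts[2]
    return tags


def _cigar_overlap(cigar: str) -> int:
    if cigar in ("*", ""):
        return 0
    total, num = 0, ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise ValueError(f"bad CIGAR {cigar!r}")
            if ch in "MID=X":
                total += int(num)
            num = ""
    return total


def parse_gfa(path, load_sequences: bool = True) -> AssemblyGraph:
    """Parse a GFA1 file into an :class:`AssemblyGraph`.

    S records become unitigs (length from the sequence, or the ``LN`` tag
    when the sequence is ``*``); L records become links with the overlap
    taken from the CIGAR.  Other record types are skipped with a warning.
    """
    graph = AssemblyGraph()
    pending_links: list[tuple[int, GraphLink]] = []
    skipped: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rec = line.split("\t")
            kind = rec[0]
            if kind == "H":
                continue
            if kind == "S":
                if len(rec) < 3:
                    raise GfaParseError(f"line {lineno}: S record needs name and sequence")
                name, seq = rec[1], rec[2]
                tags = _parse_tags(rec[3:])
                if seq == "*":
                    if "LN" not in tags:
                        raise GfaParseError(f"line {lineno}: S {name!r} has no sequence and no LN tag")
                    length, sequence = int(tags["LN"]), None
                else:
                    length, sequence = len(seq), (seq.upper() if load_sequences else None)
                depth = None
                if "dp" in tags or "DP" in tags:
                    depth = float(tags.get("dp", tags.get("DP")))
                elif "KC" in tags:
                    depth = float(tags["KC"]) / length
                try:
                    graph.add_unitig(Unitig(name, length, sequence, depth))
                except ValueError as e:
                    raise GfaParseError(f"line {lineno}: {e}") from e
            elif kind == "L":
                if len(rec) < 6:
                    raise GfaParseError(f"line {lineno}: L record needs 6 fields")
                try:
                    link = GraphLink(rec[1], rec[3], rec[2], rec[4], _cigar_overlap(rec[5]))
                except ValueError as e:
                    raise GfaParseError(f"line {lineno}: {e}") from e
                pending_links.append((lineno, link))
            else:
                skipped.add(kind)
    for lineno, link in pending_links:
        try:
            graph.add_link(link)
        except GfaParseError as e:
            raise GfaParseError(f"line {lineno}: {e}") from e
    if skipped:
        warnings.warn(f"skipped GFA record types: {sorted(skipped)}", stacklevel=2)
    return graph


def export_gfa(graph: AssemblyGraph, path, members: set[str] | None = None,
               colors: dict[str, str] | None = None) -> None:
    """Write GFA1 restricted to ``members`` (all unitigs if None).

    ``colors`` maps unitig id to a color string emitted as a ``CL:z`` tag,
    which Bandage-style viewers pick up for visual bin inspection.
    """
    if members is None:
        members = set(graph.unitigs)
    unknown = members - set(graph.unitigs)
    if unknown:
        raise ValueError(f"members not in graph: {sorted(unknown)[:5]}")
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for uid in sorted(members):
            u = graph.unitigs[uid]
            seq = u.sequence if u.sequence is not None else "*"
            fields = ["S", uid, seq]
            if u.sequence is None:
                fields.append(f"LN:i:{u.length}")
            if u.depth is not None:
                fields.append(f"dp:f:{u.depth:g}")
            if colors and uid in colors:
                fields.append(f"CL:z:{colors[uid]}")
            fh.write("\t".join(fields) + "\n")
        for l in graph.links:
            if l.from_id in members and l.to_id in members:
                fh.write(f"L\t{l.from_id}\t{l.from_orient}\t{l.to_id}\t{l.to_orient}\t{l.overlap}M\n")


# ---------------------------------------------------------------------------
# Marker flagging


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment of a unitig against the reference operon.

    Coordinates are 0-based half-open on the forward reference strand.
    """

    unitig_id: str
    identity: float
    ref_start: int
    ref_end: int
    aln_len: int
    strand: str = "+"


@dataclass(frozen=True)
class MarkerHit:
    unitig_id: str
    identity: float
    ref_start: int
    ref_end: int
    aln_len: int


@dataclass
class MarkerHitSet:
    """Unitigs flagged as carrying reference-operon sequence.

    ``breadth`` is the fraction of the reference covered by the union of
    hit intervals — overlapping hits are never double counted.
    """

    hits: list[MarkerHit]
    ref_length: int
    breadth: float = field(init=False)

    def __post_init__(self) -> None:
        self.breadth = interval_union_breadth(
            [(h.ref_start, h.ref_end) for h in self.hits], self.ref_length
        )

    @property
    def unitig_ids(self) -> list[str]:
        seen, out = set(), []
        for h in self.hits:
            if h.unitig_id not in seen:
                seen.add(h.unitig_id)
                out.append(h.unitig_id)
        return out


def interval_union_breadth(intervals: list[tuple[int, int]], ref_length: int) -> float:
    """|union of [start, end) intervals clipped to the reference| / ref_length."""
    if ref_length <= 0:
        raise ValueError("ref_length must be positive")
    ivs = sorted((max(0, s), min(ref_length, e)) for s, e in intervals if e > s)
    covered, cur_s, cur_e = 0, None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / ref_length


def flag_marker_unitigs(graph: AssemblyGraph, alignments: list[AlignmentRecord],
                        min_identity: float = 0.98, min_aln_len: int = 500,
                        ref_length: int | None = None) -> MarkerHitSet:
    """Flag unitigs whose alignments to the reference operon pass thresholds.

    The default identity floor of 0.98 targets near-exact operon fragments;
    the 500 bp length floor suppresses spurious hits from short conserved
    rRNA stretches shared across distant taxa.
    """
    if ref_length is None or ref_length <= 0:
        raise ValueError("ref_length must be a positive integer")
    missing = sorted({a.unitig_id for a in alignments} - set(graph.unitigs))
    if missing:
        raise GfaParseError(f"alignments reference unitigs absent from graph: {missing[:10]}")
    hits = [
        MarkerHit(a.unitig_id, a.identity, a.ref_start, a.ref_end, a.aln_len)
        for a in alignments
        if a.identity >= min_identity and a.aln_len >= min_aln_len
    ]
    hits.sort(key=lambda h: (h.ref_start, h.unitig_id))
    return MarkerHitSet(hits=hits, ref_length=ref_length)


def align_fragments(reference: str, queries: dict[str, str],
                    min_report_identity: float = 0.0) -> list[AlignmentRecord]:
    """Semi-global alignment of each query inside the reference operon.

    Exact unit-cost edit-distance DP (edlib); each query is aligned as an
    infix of the reference on both strands and the better strand reported.
    Identity is matches / alignment columns.  Intended for sequences up to
    ~20 kbp; genome-scale mapping belongs to an external aligner whose
    PAF/SAM is read instead.
    """
    import edlib

    if not reference:
        raise ValueError("empty reference sequence")
    ref = reference.upper()
    rc = str.maketrans("ACGTN", "TGCAN")
    out = []
    for qid, qseq in queries.items():
        if not qseq:
            raise ValueError(f"empty query sequence {qid!r}")
        best = None
        for strand, seq in (("+", qseq.upper()), ("-", qseq.upper().translate(rc)[::-1])):
            res = edlib.align(seq, ref, mode="HW", task="path")
            if best is None or res["editDistance"] < best[1]["editDistance"]:
                best = (strand, res)
        strand, res = best
        loc = res["locations"][0]
        ref_start, ref_end = loc[0], loc[1] + 1
        cols = _cigar_columns(res["cigar"])
        identity = 1.0 - res["editDistance"] / cols if cols else 0.0
        if identity >= min_report_identity:
            out.append(AlignmentRecord(qid, identity, ref_start, ref_end, cols, strand))
    return out


def _cigar_columns(cigar: str) -> int:
    total, num = 0, ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            total += int(num)
            num = ""
    return total


# ---------------------------------------------------------------------------
# Context subgraph


@dataclass
class ContextSubgraph:
    """Unitigs within a sequence-length radius of the marker seeds.

    ``distances[u]`` is the minimal total intervening sequence (bp of
    unitigs strictly between a seed and ``u``, each discounted by the
    overlap of the link used to leave it) over all paths.  Seeds and their
    direct neighbours sit at distance 0: no sequence intervenes.
    """

    member_ids: set[str]
    seed_ids: set[str]
    radius: int
    distances: dict[str, int]


def extract_context_subgraph(graph: AssemblyGraph, seeds, radius: int) -> ContextSubgraph:
    """Extract all unitigs whose near end lies within ``radius`` bp of a seed."""
    seeds = set(seeds)
    if not seeds:
        raise ValueError("empty seed set")
    unknown = seeds - set(graph.unitigs)
    if unknown:
        raise ValueError(f"unknown seed ids: {sorted(unknown)}")
    if radius < 0:
        raise ValueError("radius must be >= 0")

    adj = graph.adjacency()
    dist: dict[str, int] = {s: 0 for s in seeds}
    pq = [(0, s) for s in sorted(seeds)]
    heapq.heapify(pq)
    while pq:
        d, u = heapq.heappop(pq)
        if d > dist.get(u, d):
            continue
        for v, overlap in adj[u].items():
            # leaving a seed costs nothing: no sequence intervenes yet
            step = 0 if u in seeds else max(0, graph.length_of(u) - overlap)
            nd = d + step
            if nd <= radius and nd < dist.get(v, nd + 1):
                dist[v] = nd
                heapq.heappush(pq, (nd, v))
    members = set(dist)
    return ContextSubgraph(member_ids=members, seed_ids=seeds, radius=radius, distances=dist)


# ---------------------------------------------------------------------------
# Bin colocation


@dataclass
class BinAssignment:
    """contig/unitig id -> bin id; ids below ``min_contig_len`` excluded on load."""

    mapping: dict[str, str]
    min_contig_len: int = 0

    @classmethod
    def from_tsv(cls, path, lengths: dict[str, int] | None = None,
                 min_contig_len: int = 0) -> "BinAssignment":
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path} line {lineno}: expected contig<TAB>bin")
                cid, bid = parts[0], parts[1]
                if cid in mapping and mapping[cid] != bid:
                    raise ValueError(f"{path} line {lineno}: contig {cid!r} assigned to two bins")
                if lengths is not None and lengths.get(cid, min_contig_len) < min_contig_len:
                    continue
                mapping[cid] = bid
        return cls(mapping=mapping, min_contig_len=min_contig_len)

    def bin_of(self, contig_id: str) -> str | None:
        return self.mapping.get(contig_id)

    def members(self, bin_id: str) -> list[str]:
        return sorted(c for c, b in self.mapping.items() if b == bin_id)


@dataclass(frozen=True)
class BinColocation:
    bin_id: str
    n_members: int
    member_bp: int


@dataclass
class ColocationReport:
    """Bins colocated with the marker context, plus the unbinned remainder."""

    rows: list[BinColocation]
    unbinned_count: int
    unbinned_bp: int

    @property
    def bin_ids(self) -> list[str]:
        return [r.bin_id for r in self.rows]


def colocate_bins(graph: AssemblyGraph, subgraph: ContextSubgraph,
                  bins: BinAssignment) -> ColocationReport:
    """Report each bin with at least one unitig in the context subgraph."""
    per_bin: dict[str, list[str]] = {}
    unbinned_count = unbinned_bp = 0
    for uid in subgraph.member_ids:
        bid = bins.bin_of(uid)
        if bid is None:
            unbinned_count += 1
            unbinned_bp += graph.length_of(uid)
        else:
            per_bin.setdefault(bid, []).append(uid)
    rows = [
        BinColocation(bid, len(uids), sum(graph.length_of(u) for u in uids))
        for bid, uids in per_bin.items()
    ]
    rows.sort(key=lambda r: (-r.member_bp, r.bin_id))
    return ColocationReport(rows=rows, unbinned_count=unbinned_count, unbinned_bp=unbinned_bp)
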