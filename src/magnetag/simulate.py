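"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates (i) a fragmented target genome carrying a multi-copy ribosomal
operon, laid out as a GFA assembly graph with decoy genomes and a bin
table; (ii) 12-sample coverage profiles in which exactly one marker taxon
is linearly proportional to the target bin, with the proportionality
constant playing the role of the rDNA copy number; (iii) SNV tables under
a strain-diversity (uniform-frequency) or diploid-like (0.5-centred)
regime; and (iv) lifestyle-stratified annotation tables with known group
means.  Every generator is seeded and emits a truth record; identical
seed and parameters reproduce outputs bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import AssemblyGraph, BinAssignment, GraphLink, Unitig, export_gfa

__all__ = [
    "SimulationTruth",
    "SimulatedAssembly",
    "SimulatedCoverage",
    "gen_assembly",
    "gen_coverage",
    "gen_snvs",
    "gen_annotations",
    "DEFAULT_ANNOTATION_DESIGN",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n, dtype=np.uint8)].tobytes().decode()


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside every synthetic data set."""

    seed: int
    target_bin: str = "bin_17"
    target_contigs: list[str] = field(default_factory=list)
    marker_taxon: str = "consensus_all_seqs_0_16"
    slope: float | None = None
    operon_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    snv_regime: str | None = None
    low_count_taxa: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Assembly graph


def _fragment(rng: np.random.Generator, length: int, n50: int,
              forced: list[int] | None = None) -> list[tuple[int, int]]:
    """Fragment [0, length) with exponential segment lengths tuned so the
    realised N50 approximates the request; ``forced`` breakpoints are kept."""
    # for Exp(lam) fragment lengths the length-weighted median solves
    # (1 + lam*L) * exp(-lam*L) = 1/2 at lam*L ~= 1.6783
    mean = max(200.0, n50 / 1.6783)
    cuts: list[int] = []
    pos = 0.0
    while True:
        pos += rng.exponential(mean)
        if pos >= length:
            break
        cuts.append(int(pos))
    forced = sorted(set(forced or []))
    cuts = [c for c in cuts if all(abs(c - f) > 300 for f in forced)]
    points = sorted(set([0, length] + cuts + forced))
    return [(a, b) for a, b in zip(points[:-1], points[1:]) if b > a]


@dataclass
class SimulatedAssembly:
    graph: AssemblyGraph
    reference: str
    bins: BinAssignment
    truth: SimulationTruth

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {uid: u.length for uid, u in self.graph.unitigs.items()}

    @property
    def contig_sequences(self) -> dict[str, str]:
        return {uid: u.sequence for uid, u in self.graph.unitigs.items()}

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        export_gfa(self.graph, outdir / "assembly.gfa")
        with open(outdir / "contigs.fasta", "w") as fh:
            for uid in sorted(self.graph.unitigs):
                fh.write(f">{uid}\n{self.graph.unitigs[uid].sequence}\n")
        with open(outdir / "reference_operon.fasta", "w") as fh:
            fh.write(f">reference_operon\n{self.reference}\n")
        with open(outdir / "bins.tsv", "w") as fh:
            for cid in sorted(self.bins.mapping):
                fh.write(f"{cid}\t{self.bins.mapping[cid]}\n")
        self.truth.to_json(outdir / "truth.json")


def gen_assembly(seed: int, genome_length: int = 500_000, fragment_n50: int = 5000,
                 rdna_copies: int = 3, operon_length: int = 4500,
                 n_decoy_genomes: int = 3, decoy_length: int = 150_000,
                 misassignment_rate: float = 0.0) -> SimulatedAssembly:
    """Simulate a fragmented target genome with an embedded multi-copy
    ribosomal operon, plus disconnected decoy genomes.

    Each operon copy is split over at least two unitigs (a forced interior
    breakpoint), emulating the chronic failure of rDNA to assemble into
    substantial contigs.  Bins follow the true genome partition, optionally
    perturbed by a misassignment rate.
    """
    if rdna_copies < 1:
        raise ValueError("rdna_copies must be >= 1")
    if operon_length >= genome_length:
        raise ValueError("operon_length must be smaller than genome_length")
    if 3 * rdna_copies * operon_length > genome_length:
        raise ValueError(
            f"{rdna_copies} operon copies of {operon_length} bp do not fit sparsely "
            f"in a {genome_length} bp genome; enlarge the genome or reduce copies"
        )
    rng = np.random.default_rng(seed)
    reference = _random_seq(rng, operon_length)

    genome = bytearray(_random_seq(rng, genome_length), "ascii")
    slot = genome_length // rdna_copies
    starts = []
    for i in range(rdna_copies):
        lo = i * slot + operon_length // 2
        hi = (i + 1) * slot - 3 * operon_length // 2
        starts.append(int(rng.integers(lo, max(lo + 1, hi))))
    for s in starts:
        genome[s:s + operon_length] = reference.encode()

    forced = []
    for s in starts:
        interior = s + int(rng.integers(int(0.3 * operon_length), int(0.7 * operon_length)))
        forced += [s, interior, s + operon_length]
    frags = _fragment(rng, genome_length, fragment_n50, forced=forced)

    truth = SimulationTruth(seed=seed)
    unitigs, links = [], []
    prev = None
    gstr = genome.decode()
    for i, (a, b) in enumerate(frags):
        uid = f"tig_t{i:04d}"
        unitigs.append(Unitig(uid, b - a, gstr[a:b]))
        truth.target_contigs.append(uid)
        if prev is not None:
            links.append(GraphLink(prev, uid, "+", "+", 0))
        prev = uid
        for s in starts:
            lo, hi = max(a, s), min(b, s + operon_length)
            if hi - lo > 0:
                truth.operon_intervals[uid] = (lo - s, hi - s)

    mapping = {uid: truth.target_bin for uid in truth.target_contigs}
    decoy_bins = []
    for k in range(n_decoy_genomes):
        dseq = _random_seq(rng, decoy_length)
        dbins = f"bin_d{k:02d}"
        decoy_bins.append(dbins)
        prev = None
        for i, (a, b) in enumerate(_fragment(rng, decoy_length, fragment_n50)):
            uid = f"tig_d{k}_{i:04d}"
            unitigs.append(Unitig(uid, b - a, dseq[a:b]))
            mapping[uid] = dbins
            if prev is not None:
                links.append(GraphLink(prev, uid, "+", "+", 0))
            prev = uid

    if misassignment_rate > 0:
        all_bins = [truth.target_bin] + decoy_bins
        for uid in sorted(mapping):
            if rng.random() < misassignment_rate:
                mapping[uid] = all_bins[rng.integers(0, len(all_bins))]

    graph = AssemblyGraph(unitigs, links)
    return SimulatedAssembly(graph, reference, BinAssignment(mapping), truth)


# ---------------------------------------------------------------------------
# Coverage


@dataclass
class SimulatedCoverage:
    depth: pd.DataFrame            # contig x sample mapped bases
    taxa_counts: pd.DataFrame      # taxon x sample reads
    sample_totals: pd.Series
    contig_lengths: dict[str, int]
    bins: BinAssignment
    truth: SimulationTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        long = self.depth.stack().reset_index()
        long.columns = ["contig", "sample", "mapped_bases"]
        long.to_csv(outdir / "depth.tsv", sep="\t", header=False, index=False)
        self.taxa_counts.to_csv(outdir / "taxa_counts.tsv", sep="\t")
        self.sample_totals.to_csv(outdir / "sample_totals.tsv", sep="\t", header=False)
        with open(outdir / "contig_lengths.tsv", "w") as fh:
            for cid in sorted(self.contig_lengths):
                fh.write(f"{cid}\t{self.contig_lengths[cid]}\n")
        self.truth.to_json(outdir / "truth.json")


def gen_coverage(seed: int, assembly: SimulatedAssembly | None = None,
                 n_samples: int = 12, bin_depth_range: tuple[float, float] = (1.0, 568.0),
                 slope: float = 63.0, noise_cv: float = 0.10,
                 n_decoy_taxa: int = 250, n_low_decoys: int = 20,
                 min_reads_floor: int = 10) -> SimulatedCoverage:
    """Simulate multi-sample depth and marker-taxon count tables.

    The target bin's per-sample depth is log-uniform over the study's
    observed 1-568x range; the planted taxon's normalised coverage is
    ``slope`` times the bin's, under multiplicative lognormal noise of the
    given CV.  Decoy taxa are independent of the bin, and ``n_low_decoys``
    of them are kept below ``min_reads_floor`` total reads to exercise the
    low-count filter.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n_samples < 3:
        raise ValueError("need >= 3 samples")
    if n_low_decoys > n_decoy_taxa:
        raise ValueError("n_low_decoys cannot exceed n_decoy_taxa")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]

    if assembly is not None:
        lengths = assembly.contig_lengths
        bins = assembly.bins
        truth = SimulationTruth(**{**asdict(assembly.truth)})
        truth.operon_intervals = dict(assembly.truth.operon_intervals)
    else:
        # stand-alone mode: a bare bin layout with the study's shape
        truth = SimulationTruth(seed=seed)
        lengths = {}
        mapping = {}
        truth.target_contigs = []
        for i in range(20):
            cid = f"tig_t{i:04d}"
            lengths[cid] = int(rng.integers(1500, 9000))
            mapping[cid] = truth.target_bin
            truth.target_contigs.append(cid)
        for k in range(3):
            for i in range(15):
                cid = f"tig_d{k}_{i:04d}"
                lengths[cid] = int(rng.integers(1500, 9000))
                mapping[cid] = f"bin_d{k:02d}"
        bins = BinAssignment(mapping)
    truth.seed = seed
    truth.slope = slope

    lo, hi = bin_depth_range
    per_bin_depth = {}
    for bid in sorted(set(bins.mapping.values())):
        per_bin_depth[bid] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))

    sigma_c = 0.05  # small per-contig mapping noise
    rows = {}
    for cid in sorted(bins.mapping):
        d = per_bin_depth[bins.mapping[cid]]
        noise = rng.lognormal(-sigma_c**2 / 2, sigma_c, size=n_samples)
        rows[cid] = d * lengths[cid] * noise
    depth = pd.DataFrame(rows, index=samples).T

    totals = pd.Series(
        rng.integers(15_000_000, 25_000_000, size=n_samples).astype(float),
        index=samples, name="total",
    )

    # planted taxon: counts chosen so its normalised profile is slope x bin's
    members = bins.members(truth.target_bin)
    bin_raw = depth.loc[members].sum(axis=0) / sum(lengths[c] for c in members)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    noise = rng.lognormal(-sigma**2 / 2, sigma, size=n_samples) if noise_cv > 0 else np.ones(n_samples)
    planted = np.round(slope * bin_raw.values * noise).astype(int)

    taxa = {truth.marker_taxon: planted}
    low_ids = []
    for j in range(n_decoy_taxa):
        tid = f"taxon_{j:04d}"
        if j < n_low_decoys:
            counts = np.zeros(n_samples, dtype=int)
            k = int(rng.integers(0, min_reads_floor))
            for _ in range(k):
                counts[rng.integers(0, n_samples)] += 1
            low_ids.append(tid)
        else:
            lam = np.exp(rng.uniform(np.log(2.0), np.log(500.0)))
            scale = totals.values / totals.values.mean()
            counts = rng.poisson(lam * scale * rng.lognormal(0, 0.5, size=n_samples))
            if counts.sum() < min_reads_floor:  # keep retained decoys above the floor
                counts += 1
        taxa[tid] = counts
    taxa_counts = pd.DataFrame(taxa, index=samples).T
    truth.low_count_taxa = low_ids
    return SimulatedCoverage(depth, taxa_counts, totals, dict(lengths), bins, truth)


# ---------------------------------------------------------------------------
# SNVs


def gen_snvs(seed: int, regime: str, n_snvs: int = 1000,
             contig_lengths: dict[str, int] | None = None,
             mean_depth: float = 150.0) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate an SNV table under a strain-diversity or diploid-like regime.

    strain-uniform: allele frequencies ~ Uniform(0.05, 0.95);
    diploid-central: ~ Normal(0.5, 0.05) truncated to (0, 1).
    """
    if n_snvs <= 0:
        raise ValueError("n_snvs must be positive")
    if regime not in ("strain-uniform", "diploid-central"):
        raise ValueError("regime must be 'strain-uniform' or 'diploid-central'")
    rng = np.random.default_rng(seed)
    if regime == "strain-uniform":
        freqs = rng.uniform(0.05, 0.95, size=n_snvs)
    else:
        freqs = rng.normal(0.5, 0.05, size=n_snvs)
        bad = (freqs <= 0) | (freqs >= 1)
        while bad.any():
            freqs[bad] = rng.normal(0.5, 0.05, size=int(bad.sum()))
            bad = (freqs <= 0) | (freqs >= 1)
    if contig_lengths is None:
        contig_lengths = {f"tig_t{i:04d}": 5000 for i in range(20)}
    cids = sorted(contig_lengths)
    lens = np.array([contig_lengths[c] for c in cids], dtype=float)
    which = rng.choice(len(cids), size=n_snvs, p=lens / lens.sum())
    pos = np.array([rng.integers(1, contig_lengths[cids[w]] + 1) for w in which])
    dp = rng.poisson(mean_depth, size=n_snvs) + 20
    alt = np.clip(np.round(freqs * dp).astype(int), 1, dp - 1)
    df = pd.DataFrame({
        "contig": [cids[w] for w in which],
        "pos": pos,
        "ref_depth": dp - alt,
        "alt_depth": alt,
    })
    df["freq"] = df["alt_depth"] / (df["ref_depth"] + df["alt_depth"])
    truth = SimulationTruth(seed=seed, snv_regime=regime)
    return df, truth


def write_snv_vcf(df: pd.DataFrame, path, sample: str = "MAG") -> None:
    """Write SNVs as a minimal VCF with per-sample AD (ref,alt) depths."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for c in sorted(df["contig"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for _, r in df.iterrows():
            fh.write(f"{r['contig']}\t{int(r['pos'])}\t.\tA\tG\t.\tPASS\t.\tAD\t"
                     f"{int(r['ref_depth'])},{int(r['alt_depth'])}\n")


# ---------------------------------------------------------------------------
# Annotations

# Group means seeded from the study's lifestyle summaries where stated
# (CAZymes: G-AMF 175, ECM 240, ERM 629; lipases: G-AMF 189, ECM 238,
# SAP 263, OCM 268; proteases: ERM 457, G-AMF 305, ECM 286, SAP 271;
# transporters: G-AMF 3900); the remainder are plausible fill-ins.
DEFAULT_ANNOTATION_DESIGN: dict[str, dict] = {
    "G-AMF": {"n_genomes": 12, "means": {"CAZyme": 175, "lipase": 189, "protease": 305,
                                          "transporter": 3900, "SSP": 20}},
    "ECM": {"n_genomes": 12, "means": {"CAZyme": 240, "lipase": 238, "protease": 286,
                                        "transporter": 2500, "SSP": 25}},
    "ERM": {"n_genomes": 4, "means": {"CAZyme": 629, "lipase": 400, "protease": 457,
                                       "transporter": 3500, "SSP": 30}},
    "OCM": {"n_genomes": 3, "means": {"CAZyme": 215, "lipase": 268, "protease": 300,
                                       "transporter": 2300, "SSP": 25}},
    "SAP": {"n_genomes": 12, "means": {"CAZyme": 300, "lipase": 263, "protease": 271,
                                        "transporter": 2500, "SSP": 25}},
}

# identifiers for the hallmark pathways (see data/pathways.json)
_ALL_PATHWAY_ECS = ["3.2.1.4", "3.2.1.21", "3.2.1.91", "3.2.1.14", "3.2.1.52",
                    "3.5.1.41", "2.5.1.3", "2.7.1.49", "2.3.1.86", "2.7.1.35",
                    "1.4.3.5", "1.1.1.65"]
# capabilities absent from Glomeromycotina-like genomes by construction:
# beta-glucosidase, thiamine biosynthesis, cytosolic FAS, pyridoxine kinase
_GAMF_MISSING_ECS = {"3.2.1.21", "2.5.1.3", "2.7.1.49", "2.3.1.86", "2.7.1.35"}

_TRANSPORTER_WEIGHTS = {
    "phosphate": 0.006, "calcium": 0.016, "copper": 0.005, "nitrate": 0.002,
    "ammonium": 0.003, "glycine": 0.001,
}


def gen_annotations(seed: int, design: dict | None = None, dispersion: float = 8.0
                    ) -> tuple[pd.DataFrame, pd.Series, SimulationTruth]:
    """Simulate lifestyle-stratified per-genome annotation tables.

    Category counts are negative-binomial around the group means (counts
    across lifestyles are overdispersed); ``dispersion`` is the NB size
    parameter (variance = m + m^2/size), with ``inf`` giving the Poisson
    limit.  G-AMF-like genomes omit beta-glucosidase, thiamine enzymes,
    cytosolic FAS and pyridoxine kinase by construction, so pathway scoring
    has a known truth.
    """
    from .funcprofile import LIFESTYLES, default_substrate_map

    if design is None:
        design = DEFAULT_ANNOTATION_DESIGN
    for ls in design:
        if ls not in LIFESTYLES:
            raise ValueError(f"unknown lifestyle {ls!r}; vocabulary: {list(LIFESTYLES)}")
        if any(m <= 0 for m in design[ls]["means"].values()):
            raise ValueError(f"means must be positive ({ls})")
    rng = np.random.default_rng(seed)
    families = sorted(default_substrate_map().families)
    tsubs = list(_TRANSPORTER_WEIGHTS)
    tprobs = np.array(list(_TRANSPORTER_WEIGHTS.values()))
    rows = []
    lifestyles = {}
    for ls in sorted(design):
        spec_ = design[ls]
        for gi in range(spec_["n_genomes"]):
            gid = f"{ls}_{gi:03d}"
            lifestyles[gid] = ls
            pid = 0
            ecs = [e for e in _ALL_PATHWAY_ECS
                   if not (ls == "G-AMF" and e in _GAMF_MISSING_ECS)]
            for cat in sorted(spec_["means"]):
                m = spec_["means"][cat]
                if np.isinf(dispersion):
                    n = int(rng.poisson(m))
                else:
                    p = dispersion / (dispersion + m)
                    n = int(rng.negative_binomial(dispersion, p))
                for _ in range(n):
                    fam = families[rng.integers(0, len(families))] if cat == "CAZyme" else ""
                    sub = ""
                    if cat == "transporter":
                        u = rng.random()
                        acc = 0.0
                        sub = "other"
                        for name, w in zip(tsubs, tprobs):
                            acc += w
                            if u < acc:
                                sub = name
                                break
                    ec = ""
                    if cat == "protease" and ecs:
                        ec = ecs.pop(0)
                    rows.append((gid, f"p{pid:06d}", cat, fam, ec, sub))
                    pid += 1
            # guarantee the hallmark identifiers survive even tiny count draws
            for ec in ecs:
                rows.append((gid, f"p{pid:06d}", "protease", "", ec, ""))
                pid += 1
    table = pd.DataFrame(rows, columns=["genome", "protein", "category",
                                        "cazy_family", "ec_numbers", "substrate"])
    truth = SimulationTruth(seed=seed)
    return table, pd.Series(lifestyles, name="lifestyle"), truth
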