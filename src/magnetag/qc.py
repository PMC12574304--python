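"""Quality and identity diagnostics for a candidate eukaryotic MAG.

Assembly statistics, BUSCO-style effective completion, the SNV
allele-frequency spectrum (strain diversity vs diploid-like haplotypes),
the per-ORF coverage distribution (single-copy dominance), and the
root-colonisation bookkeeping ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssemblyStats",
    "CompletionReport",
    "SnvSpectrum",
    "OrfCoverageDistribution",
    "assembly_stats",
    "n50",
    "gc_content",
    "effective_completion",
    "parse_busco_summary",
    "snv_spectrum",
    "read_snv_table",
    "read_snv_vcf",
    "orf_coverage_distribution",
    "fre_colonisation_proportion",
]


# ---------------------------------------------------------------------------
# Assembly statistics


def n50(lengths) -> int:
    """Smallest length L such that contigs of length >= L hold >= half the bases."""
    ls = sorted((int(x) for x in lengths), reverse=True)
    if not ls:
        raise ValueError("empty length set")
    half = sum(ls) / 2
    acc = 0
    for l in ls:
        acc += l
        if acc >= half:
            return l
    return ls[-1]


def gc_content(sequences) -> float:
    """(G+C) / (A+C+G+T) over all sequences; N and ambiguity codes excluded."""
    gc = at = 0
    for seq in sequences:
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    denom = gc + at
    if denom == 0:
        raise ValueError("no unambiguous bases")
    return gc / denom


@dataclass
class AssemblyStats:
    total_length: int
    n_contigs: int
    n50: int
    gc: float | None = None
    coverage_range: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __str__(self) -> str:
        mbp = self.total_length / 1e6
        gc = f"{self.gc * 100:.1f}%" if self.gc is not None else "n/a"
        return (f"assembly: {mbp:.2f} Mbp in {self.n_contigs} contigs, "
                f"N50 {self.n50}, GC {gc}")


def assembly_stats(contigs, depth: pd.DataFrame | None = None) -> AssemblyStats:
    """Assembly statistics from a FASTA path, {id: sequence} dict, or length list.

    With only lengths, GC is omitted.  ``depth`` (contig x sample mean
    depth) adds per-sample min/max coverage of the contig set.
    """
    sequences: list[str] | None = None
    if isinstance(contigs, (str, bytes)) or hasattr(contigs, "read"):
        from Bio import SeqIO

        sequences = [str(rec.seq) for rec in SeqIO.parse(contigs, "fasta")]
        lengths = [len(s) for s in sequences]
    elif isinstance(contigs, dict):
        sequences = [str(s) for s in contigs.values()]
        lengths = [len(s) for s in sequences]
    else:
        lengths = [int(x) for x in contigs]
    if not lengths:
        raise ValueError("no contigs")
    cov = {}
    if depth is not None:
        for sample in depth.columns:
            col = depth[sample]
            cov[sample] = (float(col.min()), float(col.max()))
    return AssemblyStats(
        total_length=sum(lengths),
        n_contigs=len(lengths),
        n50=n50(lengths),
        gc=gc_content(sequences) if sequences else None,
        coverage_range=cov,
    )


# ---------------------------------------------------------------------------
# Completion


@dataclass
class CompletionReport:
    """BUSCO-style marker fractions, all in percent.

    ``duplicated`` doubles as the contamination proxy; ``effective_completion``
    counts fragmented markers as present: complete + fragmented.
    """

    complete: float
    duplicated: float
    fragmented: float
    missing: float
    effective_completion: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("complete", "duplicated", "fragmented", "missing"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        self.effective_completion = self.complete + self.fragmented

    @property
    def contamination(self) -> float:
        return self.duplicated

    def display(self) -> str:
        return (f"complete {self.complete:.1f}%  fragmented {self.fragmented:.1f}%  "
                f"missing {self.missing:.1f}%  contamination {self.duplicated:.1f}%  "
                f"effective completion {round(self.effective_completion, 1):.1f}%")


def effective_completion(complete: float, fragmented: float, duplicated: float = 0.0,
                         missing: float | None = None) -> CompletionReport:
    if missing is None:
        missing = max(0.0, 100.0 - complete - fragmented)
    return CompletionReport(complete=complete, duplicated=duplicated,
                            fragmented=fragmented, missing=missing)


def parse_busco_summary(path) -> CompletionReport:
    """Parse a BUSCO short-summary text file (the C/S/D/F/M percentage line)."""
    import json
    import re

    text = open(path).read()
    try:
        obj = json.loads(text)
        res = obj.get("results", obj)
        return CompletionReport(
            complete=float(res["Complete"]),
            duplicated=float(res.get("Multi copy", res.get("Duplicated", 0.0))),
            fragmented=float(res["Fragmented"]),
            missing=float(res["Missing"]),
        )
    except (json.JSONDecodeError, KeyError):
        pass
    m = re.search(
        r"C:\s*([\d.]+)%\s*\[S:\s*([\d.]+)%,\s*D:\s*([\d.]+)%\]\s*,?\s*F:\s*([\d.]+)%\s*,?\s*M:\s*([\d.]+)%",
        text,
    )
    if not m:
        raise ValueError(f"{path}: no BUSCO percentage line found")
    c, _s, d, f, miss = map(float, m.groups())
    return CompletionReport(complete=c, duplicated=d, fragmented=f, missing=miss)


# ---------------------------------------------------------------------------
# SNV spectrum


@dataclass
class SnvSpectrum:
    """Allele-frequency spectrum diagnostics.

    A population of closely related strains spreads variant frequencies
    roughly evenly over the detectable range, whereas a diploid (or
    two-haplotype) genome concentrates them near 0.5.  The label combines a
    KS uniformity test on the detectable range with the fraction of
    frequencies in the central window.
    """

    frequencies: np.ndarray
    histogram: tuple[np.ndarray, np.ndarray]
    ks_statistic: float
    ks_p: float
    central_mode_score: float
    label: str
    n_rejected: int = 0
    density_per_contig: pd.Series | None = None


def read_snv_table(path) -> pd.DataFrame:
    """TSV ``contig  pos  ref_depth  alt_depth`` -> frame with an ``freq`` column."""
    df = pd.read_csv(path, sep="\t")
    need = {"contig", "pos", "ref_depth", "alt_depth"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: columns must include {sorted(need)}")
    df["freq"] = df["alt_depth"] / (df["ref_depth"] + df["alt_depth"])
    return df


def read_snv_vcf(path) -> pd.DataFrame:
    """VCF -> contig/pos/freq frame; frequency from AD (alt/(ref+alt)) or FREQ."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(path):
        freq = None
        try:
            ad = v.format("AD")
            if ad is not None:
                ref, alt = float(ad[0][0]), float(ad[0][1])
                if ref + alt > 0:
                    freq = alt / (ref + alt)
        except KeyError:
            pass
        if freq is None:
            try:
                raw = v.format("FREQ")
                if raw is not None:
                    freq = float(str(raw[0]).strip("%'b\" ")) / 100.0
            except (KeyError, ValueError):
                pass
        if freq is not None:
            rows.append((v.CHROM, v.POS, freq))
    return pd.DataFrame(rows, columns=["contig", "pos", "freq"])


def snv_spectrum(snvs, bins: int = 50, f_range: tuple[float, float] = (0.05, 0.95),
                 alpha: float = 0.01, central_window: tuple[float, float] = (0.4, 0.6),
                 central_threshold: float = 0.5,
                 contig_lengths: dict[str, int] | None = None) -> SnvSpectrum:
    """Classify the allele-frequency spectrum as strain-diversity-like,
    haplotype-like, or ambiguous.

    ``snvs`` is a frame with a ``freq`` column (and optionally ``contig``)
    or a plain array of frequencies in (0, 1).
    """
    if isinstance(snvs, pd.DataFrame):
        freqs = snvs["freq"].to_numpy(dtype=float)
        contigs = snvs["contig"] if "contig" in snvs else None
    else:
        freqs = np.asarray(snvs, dtype=float)
        contigs = None
    ok = (freqs > 0) & (freqs < 1)
    n_rejected = int((~ok).sum())
    freqs = freqs[ok]
    if freqs.size == 0:
        raise ValueError("no SNV frequencies strictly inside (0, 1)")

    fmin, fmax = f_range
    inside = freqs[(freqs >= fmin) & (freqs <= fmax)]
    if inside.size >= 3:
        ks_stat, ks_p = stats.kstest(inside, "uniform", args=(fmin, fmax - fmin))
    else:
        ks_stat, ks_p = np.nan, 0.0

    lo, hi = central_window
    central = float(np.mean((freqs >= lo) & (freqs <= hi)))
    if central >= central_threshold:
        label = "haplotype-like"
    elif ks_p >= alpha:
        label = "strain-diversity-like"
    else:
        label = "ambiguous"

    density = None
    if contigs is not None and contig_lengths:
        counts = contigs[ok].value_counts()
        density = pd.Series(
            {c: counts.get(c, 0) / (l / 1000.0) for c, l in contig_lengths.items()},
            name="snvs_per_kbp",
        )
    hist = np.histogram(freqs, bins=bins, range=(0.0, 1.0))
    return SnvSpectrum(freqs, hist, float(ks_stat), float(ks_p), central, label,
                       n_rejected, density)


# ---------------------------------------------------------------------------
# ORF coverage


@dataclass
class OrfCoverageDistribution:
    mode: float
    dispersion: float
    single_copy_fraction: float
    label: str
    n_orfs: int


def orf_coverage_distribution(depths, bins: int = 50) -> OrfCoverageDistribution:
    """Per-ORF depth distribution: histogram mode, dispersion, and the
    fraction of ORFs within +/-50% of the mode.

    Single-copy genes cluster at the genome's base depth; duplicated genes
    sit at multiples of it.  The label is single-copy-dominant when a
    strict majority of ORFs lie within the mode window.
    """
    d = np.asarray(depths, dtype=float)
    if d.size < 10:
        raise ValueError("need >= 10 ORF depths")
    if (d < 0).any():
        raise ValueError("depths must be non-negative")
    if not np.any(d > 0):
        raise ValueError("all ORF depths are zero")
    counts, edges = np.histogram(d, bins=bins)
    peak = int(np.argmax(counts))
    mode = float((edges[peak] + edges[peak + 1]) / 2)
    frac = float(np.mean((d >= 0.5 * mode) & (d <= 1.5 * mode)))
    label = "single-copy-dominant" if frac > 0.5 else "multi-modal"
    return OrfCoverageDistribution(
        mode=mode,
        dispersion=float(np.std(d) / np.mean(d)),
        single_copy_fraction=frac,
        label=label,
        n_orfs=int(d.size),
    )


# ---------------------------------------------------------------------------
# Root colonisation bookkeeping


def fre_colonisation_proportion(fre_percent: float, gamf_percent: float) -> float:
    """Proportion of AM colonisation attributable to fine root endophytes:
    100 * FRE / (FRE + G-AMF), in percent."""
    if fre_percent < 0 or gamf_percent < 0:
        raise ValueError("percentages must be non-negative")
    total = fre_percent + gamf_percent
    if total == 0:
        raise ValueError("both colonisation percentages are zero; proportion undefined")
    return 100.0 * fre_percent / total
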