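"""Multi-sample coverage linking of a genome bin to a ribosomal marker taxon.

The discriminating signal is that a bin and the rRNA marker of the genome
it came from rise and fall together across samples.  Because the rDNA
operon is tandem-repeated, the marker's depth is a multiple of the bin's:
the through-origin regression slope of marker coverage on bin coverage
estimates the per-genome operon copy number.

The model/results pair :class:`BinTaxonLink` / :class:`BinTaxonLinkResults`
carries the correlation screen over all candidate taxa and the copy-number
regression for the best hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "CoverageMatrix",
    "TaxaFilterReport",
    "bin_coverage_profile",
    "filter_and_normalise_taxa",
    "BinTaxonLink",
    "BinTaxonLinkResults",
    "LinkResult",
    "CopyNumberEstimate",
    "link_bin_to_taxa",
    "estimate_copy_number",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20251029


class CoverageMatrix:
    """Entities (bins or taxa) x samples, normalised per million units.

    ``normalised = raw / sample_total * 1e6``.  The normalisation scale
    cancels in Pearson r; the copy-number slope is only meaningful when the
    bin and taxon matrices share a unit, which the ``unit`` label enforces.
    """

    def __init__(self, raw: pd.DataFrame, sample_totals: pd.Series, unit: str = "per-million"):
        missing = [s for s in raw.columns if s not in sample_totals.index]
        if missing:
            raise ValueError(f"sample totals missing for {missing}")
        totals = sample_totals.loc[raw.columns].astype(float)
        if (totals <= 0).any():
            raise ValueError("sample totals must be positive")
        if (raw.values < 0).any():
            raise ValueError("raw coverage values must be non-negative")
        self.raw = raw.astype(float)
        self.sample_totals = totals
        self.unit = unit
        self.normalised = self.raw.div(totals, axis=1) * 1e6

    @property
    def entities(self) -> list[str]:
        return list(self.raw.index)

    @property
    def samples(self) -> list[str]:
        return list(self.raw.columns)

    def row(self, entity: str) -> pd.Series:
        return self.normalised.loc[entity]

    def __repr__(self) -> str:
        return (f"<CoverageMatrix {len(self.raw)} entities x {len(self.raw.columns)} "
                f"samples, unit={self.unit!r}>")


def bin_coverage_profile(depth: pd.DataFrame, bins, contig_lengths: dict[str, int],
                         sample_totals: pd.Series, unit: str = "per-million") -> CoverageMatrix:
    """Bin x sample coverage from per-contig mapped-base totals.

    Per bin and sample: (sum of mapped bases over member contigs) divided by
    (total member contig length), then normalised by the sample total.
    Bins with zero total length are dropped with a warning.
    """
    mapping = bins.mapping if hasattr(bins, "mapping") else dict(bins)
    missing = [c for c in mapping if c not in contig_lengths]
    if missing:
        raise KeyError(f"contig lengths missing for binned contigs: {missing[:10]}")
    rows = {}
    for bid in sorted(set(mapping.values())):
        members = [c for c, b in mapping.items() if b == bid]
        total_len = sum(contig_lengths[c] for c in members)
        if total_len == 0:
            log.warning("bin %s has zero total contig length; excluded", bid)
            continue
        present = [c for c in members if c in depth.index]
        summed = depth.loc[present].sum(axis=0) if present else pd.Series(0.0, index=depth.columns)
        rows[bid] = summed / total_len
    return CoverageMatrix(pd.DataFrame(rows).T.reindex(columns=depth.columns), sample_totals, unit)


@dataclass
class TaxaFilterReport:
    retained: int
    removed: int
    removed_ids: list[str]


def filter_and_normalise_taxa(counts: pd.DataFrame, sample_totals: pd.Series,
                              min_total_reads: int = 10,
                              unit: str = "per-million") -> tuple[CoverageMatrix, TaxaFilterReport]:
    """Drop taxa with fewer than ``min_total_reads`` reads across all samples,
    then normalise survivors per sample."""
    if min_total_reads < 0:
        raise ValueError("min_total_reads must be >= 0")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = counts.sum(axis=1)
    keep = row_sums >= min_total_reads
    report = TaxaFilterReport(
        retained=int(keep.sum()),
        removed=int((~keep).sum()),
        removed_ids=list(counts.index[~keep]),
    )
    return CoverageMatrix(counts.loc[keep], sample_totals, unit), report


# ---------------------------------------------------------------------------
# Model / Results


@dataclass(frozen=True)
class LinkResult:
    """Correlation link between the candidate bin and one marker taxon."""

    taxon_id: str
    pearson_r: float
    p_value: float
    adjusted_p: float
    slope: float
    n_samples: int


@dataclass
class CopyNumberEstimate:
    """Through-origin regression slope of taxon on bin coverage.

    slope = sum(x*y) / sum(x^2); at zero intercept the slope reads directly
    as the rDNA operon copy number.  The CI is a seeded bootstrap percentile
    interval over samples.
    """

    slope: float
    ci_low: float
    ci_high: float
    n_samples: int
    nearest_int: int

    def __str__(self) -> str:
        return (f"copy number {self.slope:.2f} "
                f"(~{self.nearest_int}; 95% CI {self.ci_low:.2f}-{self.ci_high:.2f}, "
                f"n={self.n_samples})")


def _origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    sx2 = float(np.dot(x, x))
    if sx2 == 0:
        raise ValueError("bin profile is all zero")
    return float(np.dot(x, y)) / sx2


def estimate_copy_number(taxon_profile, bin_profile, n_boot: int = 1000,
                         seed: int = DEFAULT_SEED, ci: float = 0.95,
                         fit_intercept: bool = False) -> CopyNumberEstimate:
    """Estimate rDNA operon copy number as the regression slope of the marker
    taxon's normalised coverage on the bin's."""
    x = np.asarray(bin_profile, dtype=float)
    y = np.asarray(taxon_profile, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need >= 3 paired samples")
    if fit_intercept:
        slope = float(np.polyfit(x, y, 1)[0])
    else:
        slope = _origin_slope(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if not np.any(xb):
            continue
        boots.append(np.polyfit(xb, yb, 1)[0] if fit_intercept else _origin_slope(xb, yb))
    alpha = (1 - ci) / 2
    lo, hi = (np.quantile(boots, [alpha, 1 - alpha]) if boots else (np.nan, np.nan))
    return CopyNumberEstimate(slope, float(lo), float(hi), n, int(round(slope)))


class BinTaxonLink:
    """Model linking one bin's coverage profile to a matrix of marker taxa.

    Parameters
    ----------
    bin_profile
        Normalised coverage of the candidate bin, indexed by sample.
    taxa
        CoverageMatrix (or normalised DataFrame) of marker taxa over the
        same samples.
    """

    def __init__(self, bin_profile: pd.Series, taxa):
        taxa_norm = taxa.normalised if isinstance(taxa, CoverageMatrix) else pd.DataFrame(taxa)
        shared = [s for s in bin_profile.index if s in taxa_norm.columns]
        if len(shared) < 3:
            raise ValueError("need >= 3 shared samples between bin and taxa")
        if taxa_norm.empty:
            raise ValueError("taxa matrix is empty")
        self.bin_profile = bin_profile.loc[shared].astype(float)
        self.taxa = taxa_norm.loc[:, shared].astype(float)
        if np.ptp(self.bin_profile.values) == 0:
            raise ValueError("bin profile has zero variance; correlation undefined")

    def fit(self, adjust: str = "fdr_bh", seed: int = DEFAULT_SEED) -> "BinTaxonLinkResults":
        x = self.bin_profile.values
        results, excluded = [], []
        for taxon, row in self.taxa.iterrows():
            y = row.values
            if np.ptp(y) == 0:
                excluded.append(taxon)
                continue
            r, p = stats.pearsonr(x, y)
            results.append((taxon, float(r), float(p), _origin_slope(x, y)))
        if excluded:
            log.info("excluded %d zero-variance taxa from ranking", len(excluded))
        if not results:
            raise ValueError("no taxa with non-constant profiles")
        raw_p = [p for _, _, p, _ in results]
        adj = multipletests(raw_p, method=adjust)[1]
        table = [
            LinkResult(t, r, p, float(ap), s, len(x))
            for (t, r, p, s), ap in zip(results, adj)
        ]
        table.sort(key=lambda lr: (-lr.pearson_r, lr.taxon_id))
        return BinTaxonLinkResults(self, table, excluded, adjust, seed)


class BinTaxonLinkResults:
    """Ranked correlation links plus the best hit's copy-number estimate."""

    def __init__(self, model: BinTaxonLink, table: list[LinkResult],
                 excluded: list[str], adjust: str, seed: int):
        self.model = model
        self.links = table
        self.excluded_taxa = excluded
        self.adjust_method = adjust
        self.seed = seed

    @property
    def best(self) -> LinkResult:
        return self.links[0]

    def copy_number(self, taxon_id: str | None = None, **kw) -> CopyNumberEstimate:
        taxon_id = taxon_id or self.best.taxon_id
        kw.setdefault("seed", self.seed)
        return estimate_copy_number(self.model.taxa.loc[taxon_id],
                                    self.model.bin_profile, **kw)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([lr.__dict__ for lr in self.links])
        df["rank"] = np.arange(1, len(df) + 1)
        return df.set_index("taxon_id")

    def summary(self, top: int = 10) -> str:
        best = self.best
        lines = [
            "Bin-taxon coverage link",
            "=" * 55,
            f"taxa tested: {len(self.links)}   excluded (constant): {len(self.excluded_taxa)}",
            f"samples: {best.n_samples}   p adjustment: {self.adjust_method}",
            f"best hit: {best.taxon_id}  r={best.pearson_r:.3f}  "
            f"p_adj={best.adjusted_p:.2e}  slope={best.slope:.1f}",
            "-" * 55,
            f"{'taxon':<28}{'r':>7}{'p_adj':>11}{'slope':>9}",
        ]
        for lr in self.links[:top]:
            lines.append(f"{lr.taxon_id:<28}{lr.pearson_r:>7.3f}{lr.adjusted_p:>11.2e}{lr.slope:>9.1f}")
        return "\n".join(lines)

    def plot(self, taxon_id: str | None = None, ax=None):
        """Scatter of taxon vs bin coverage with the through-origin fit."""
        import matplotlib.pyplot as plt

        taxon_id = taxon_id or self.best.taxon_id
        if ax is None:
            _, ax = plt.subplots()
        x = self.model.bin_profile.values
        y = self.model.taxa.loc[taxon_id].values
        ax.scatter(x, y, s=25)
        slope = _origin_slope(x, y)
        xs = np.linspace(0, x.max() * 1.05, 50)
        ax.plot(xs, slope * xs, "--", label=f"slope = {slope:.1f}")
        ax.set_xlabel("bin coverage (normalised)")
        ax.set_ylabel(f"{taxon_id} coverage (normalised)")
        ax.legend()
        return ax


def link_bin_to_taxa(bin_profile: pd.Series, taxa, adjust: str = "fdr_bh") -> list[LinkResult]:
    """Functional wrapper: ranked LinkResults for one bin against all taxa."""
    return BinTaxonLink(bin_profile, taxa).fit(adjust=adjust).links
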