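"""Readers for external-aligner and tabular inputs.

Read mapping and operon alignment are done by external tools (bwa,
minimap2); their PAF/SAM output is consumed here.  All coordinates are
converted to 0-based half-open on the forward reference strand.
"""

from __future__ import annotations

import pandas as pd

from .graph import AlignmentRecord

__all__ = [
    "read_paf",
    "read_sam",
    "read_depth_table",
    "read_counts_table",
    "read_sample_totals",
]


def read_paf(path) -> list[AlignmentRecord]:
    """Read 12-column PAF; identity = residue matches (col 10) / block length (col 11).

    PAF here maps the reference operon (query) against unitigs (target) or
    vice versa; the convention expected is query = unitig, target = reference,
    so target coordinates are the reference interval.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path} line {lineno}: PAF needs >= 12 columns")
            try:
                matches, block = int(f[9]), int(f[10])
                records.append(
                    AlignmentRecord(
                        unitig_id=f[0],
                        identity=matches / block if block else 0.0,
                        ref_start=int(f[7]),
                        ref_end=int(f[8]),
                        aln_len=block,
                        strand=f[4],
                    )
                )
            except ValueError as e:
                raise ValueError(f"{path} line {lineno}: {e}") from e
    return records


def read_sam(path) -> list[AlignmentRecord]:
    """Read SAM alignments of unitigs against the reference operon.

    Identity is derived from the NM tag: (aligned columns - NM) / columns,
    with columns counted over M/=/X/I/D CIGAR operations.  1-based SAM
    positions are converted to 0-based half-open.
    """
    import pysam

    records = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            cols = sum(n for op, n in aln.cigartuples if op in (0, 1, 2, 7, 8))
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            records.append(
                AlignmentRecord(
                    unitig_id=aln.query_name,
                    identity=(cols - nm) / cols if cols else 0.0,
                    ref_start=aln.reference_start,
                    ref_end=aln.reference_end,
                    aln_len=cols,
                    strand="-" if aln.is_reverse else "+",
                )
            )
    return records


def read_depth_table(path) -> pd.DataFrame:
    """Long-form depth TSV ``contig<TAB>sample<TAB>mapped_bases`` -> contig x sample frame."""
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "sample", "mapped_bases"],
                     dtype={"contig": str, "sample": str})
    wide = df.pivot_table(index="contig", columns="sample", values="mapped_bases",
                          aggfunc="sum", fill_value=0.0)
    wide.columns.name = None
    wide.index.name = None
    return wide


def read_counts_table(path) -> pd.DataFrame:
    """Taxon x sample read-count matrix with a header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def read_sample_totals(path) -> pd.Series:
    """Sample totals TSV ``sample<TAB>total`` -> Series indexed by sample."""
    s = pd.read_csv(path, sep="\t", header=None, names=["sample", "total"],
                    index_col=0)["total"]
    if (s <= 0).any():
        bad = s.index[s <= 0].tolist()
        raise ValueError(f"{path}: non-positive totals for samples {bad}")
    return s
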