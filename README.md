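# magnetag

Marker-anchored recovery and validation of eukaryotic metagenome-assembled
genomes (MAGs).

## The problem

Symbiotic fungi such as the Mucoromycotina "fine root endophyte" (FRE)
arbuscular mycorrhizae resist culturing, so their genomes must be fished out
of root metagenomes. Standard binning struggles to *identify* which bin, if
any, is the target organism: the multi-copy ribosomal operon — the one locus
with a reference sequence — fragments into short unitigs that rarely land in
any bin. `magnetag` implements the culture-independent identification and
validation chain that solves this:

1. **Graph anchoring** — flag assembly-graph unitigs with high-identity
   (default ≥ 98%, ≥ 500 bp) alignments to the reference rRNA operon, extract
   the subgraph within a sequence radius (default 10 kbp) of those seeds, and
   report which bins colocate on it.
2. **Coverage linking** — across the multi-sample depth profiles, correlate
   the candidate bin against every small-subunit rRNA marker taxon
   (Pearson r, Benjamini–Hochberg adjusted p). The genome and its own rRNA
   marker rise and fall together across samples; decoys do not.
3. **Copy-number estimation** — because the rDNA operon is tandem-repeated,
   the through-origin regression slope of marker coverage *y* on bin
   coverage *x*, `β̂ = Σxᵢyᵢ / Σxᵢ²`, estimates the per-genome operon copy
   number (with a seeded bootstrap CI).
4. **MAG QC** — assembly statistics (N50, GC), BUSCO-style effective
   completion (complete + fragmented), the SNV allele-frequency spectrum
   (strain diversity vs diploid-like haplotypes), and per-ORF coverage
   (single-copy dominance).
5. **Comparative function** — per-genome CAZyme/lipase/protease/transporter
   profiles, CAZy-family substrate classification (plant vs microbial
   cell-wall degrading enzymes), hallmark pathway-completeness scoring
   (cellulose, chitin, thiamine, fatty-acid synthesis, vitamin B6), and
   lifestyle comparison via Kruskal–Wallis + Dunn post-hoc with a compact
   letter display.

A fully seeded synthetic-data module (`magnetag.simulate`) generates
assembly graphs with a planted fragmented genome, proportional coverage
profiles, SNV tables and lifestyle-stratified annotation tables, so the
whole pipeline is testable end to end without any download.

## Worked example

```python
from magnetag import simulate as sim
from magnetag.graph import (align_fragments, flag_marker_unitigs,
                            extract_context_subgraph, colocate_bins)
from magnetag.coverage import (BinTaxonLink, bin_coverage_profile,
                               filter_and_normalise_taxa)

asm = sim.gen_assembly(seed=1)                       # planted genome + decoys
alns = align_fragments(asm.reference, asm.contig_sequences, 0.5)
hits = flag_marker_unitigs(asm.graph, alns, 0.98, 500, len(asm.reference))
sub = extract_context_subgraph(asm.graph, hits.unitig_ids, radius=10_000)
print(colocate_bins(asm.graph, sub, asm.bins).rows[0].bin_id)   # bin_17

cov = sim.gen_coverage(seed=2)                       # 12 samples, 250 decoys
taxa, _ = filter_and_normalise_taxa(cov.taxa_counts, cov.sample_totals, 10)
bins = bin_coverage_profile(cov.depth, cov.bins, cov.contig_lengths,
                            cov.sample_totals)
res = BinTaxonLink(bins.row("bin_17"), taxa).fit()
print(res.summary(top=1))
print(res.copy_number())
```

prints

```
bin_17
Bin-taxon coverage link
=======================================================
taxa tested: 231   excluded (constant): 0
samples: 12   p adjustment: fdr_bh
best hit: consensus_all_seqs_0_16  r=0.989  p_adj=2.75e-07  slope=60.7
-------------------------------------------------------
taxon                             r      p_adj    slope
consensus_all_seqs_0_16       0.989   2.75e-07     60.7
copy number 60.69 (~61; 95% CI 55.98-65.57, n=12)
```

The graph stage recovers the planted bin; the coverage stage ranks the
planted marker taxon first out of 231 candidates (r = 0.989 after
multiplicative 10%-CV noise) and recovers the planted rDNA copy number of 63
to within the bootstrap interval.

The same operations are available from a shell:

```sh
magnetag simulate assembly --seed 1 --out sim/
magnetag flag --graph sim/assembly.gfa --aln ops.paf --ref-length 4500 --out hits.tsv
magnetag qc completion --busco short_summary.txt
```

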