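# Methods

This note documents the models and procedures `magnetag` implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the package's numerical conventions and limitations.

## Graph anchoring

An assembly graph (GFA1; S and L records, other record types skipped with a
warning) is searched for unitigs carrying reference rRNA-operon sequence.
Alignments come either from an external aligner (PAF, 12 columns, identity =
residue matches / block length; or SAM, identity from the NM tag) or from
the built-in `align_fragments`, an exact unit-cost semi-global
edit-distance alignment (edlib) that places each query as an infix of the
reference on either strand and reports identity = matches / alignment
columns. The built-in aligner is intended for unitig-vs-operon screening
(≤ ~20 kbp); genome-scale mapping is left to external tools.

**Flagging thresholds.** Identity ≥ 0.98 and alignment length ≥ 500 bp by
default. The identity floor targets near-exact operon fragments of the
focal organism rather than homologs; the length floor suppresses spurious
hits from short strongly conserved rRNA stretches shared across distant
taxa. Breadth of reference coverage is computed on the union of hit
intervals (0-based half-open throughout; overlapping hits never double
counted).

**Context radius.** The neighbourhood around the flagged seeds is defined by
sequence distance, not hop count: the distance of a unitig is the minimal
total length of *intervening* unitigs between any seed and its near end,
each intervening unitig discounted by the overlap of the link through which
it is exited. Seeds and their direct neighbours therefore sit at distance
0, and "all of 10 kbp around the seeds" reads as: everything reachable
through at most 10 kbp of intervening sequence. Distances are computed by
Dijkstra (source-dependent edge weights, non-negative). An alternative
convention would count overlap-shared bases twice (no discount); on typical
short-overlap graphs the difference is a few dozen bp per step and does not
change membership at a 10 kbp radius.

**Colocation.** Every bin with at least one unitig in the context subgraph
is reported, sorted by member bp (ties broken lexicographically); unbinned
members are tallied separately. Bin tables are contig→bin TSVs with an
optional minimum-contig-length filter (the binning convention upstream used
1000 bp).

## Coverage linking and copy number

Coverage matrices hold entities × samples. Bin coverage per sample is the
length-weighted mean depth: (Σ mapped bases over member contigs) / (Σ member
contig lengths). Marker-taxon read counts are filtered by total reads
across samples (default ≥ 10, the boundary retained) before use. Both
matrices are normalised per sample as raw / sample-total × 10⁶
("per-million"). The scale cancels in correlation; the copy-number slope is
only meaningful when both matrices share a unit, which the `unit` label
enforces. Whether the sample total is reads or bases is a configuration
choice that must simply be consistent across tables.

`BinTaxonLink.fit()` computes Pearson r and a two-sided p per taxon against
the bin profile, adjusts p across all tested taxa (Benjamini–Hochberg by
default — the conventional choice when nothing else is specified; Holm etc.
available via `adjust=`), and ranks by r. Zero-variance taxa have undefined
correlation and are excluded from the ranking (logged) rather than assigned
r = 0; a zero-variance bin profile is an error.

**Copy number.** The rDNA operon is tandem-repeated, so the marker's depth
is (copy number) × (genome depth). We fit taxon-on-bin through the origin,
β̂ = Σxy / Σx², because the copy-number interpretation presumes a zero
intercept; a free-intercept fit is available behind `fit_intercept=True`.
Uncertainty is a seeded bootstrap percentile interval over samples (default
1000 resamples, seed 20251029 unless overridden). With multiplicative
noise and a wide depth range the estimate is dominated by the deepest
samples; on the default synthetic regime (below) it recovers the planted
slope within ±15% in ≈ 97% of replicates.

## MAG QC

* **N50**: smallest length L such that contigs ≥ L hold at least half the
  assembly (descending cumulative scan). **GC**: (G+C)/(A+C+G+T), ambiguity
  codes excluded from the denominator.
* **Effective completion** = complete% + fragmented% from a BUSCO-style
  report (text short-summary or JSON). Fragmented markers are present in
  the assembly, merely broken, so they count toward an "effective" recovery
  figure; the duplicated fraction doubles as the contamination proxy.
  Display rounds to one decimal; computation keeps full precision.
* **SNV spectrum**: allele frequencies (from AD-style depths, or a varScan
  FREQ tag) strictly inside (0,1). A Kolmogorov–Smirnov test against
  Uniform(0.05, 0.95) — the range avoids detection-limit edge effects — and
  a central-mode score (fraction of frequencies in [0.4, 0.6]) yield the
  label: *haplotype-like* when the central score ≥ 0.5 (a diploid or
  two-haplotype genome piles variants near 0.5), *strain-diversity-like*
  when uniformity is not rejected at α = 0.01 and the central score is
  below threshold, else *ambiguous*. All windows and α are configurable;
  the underlying criterion is qualitative, so the defaults are documented
  choices, not fitted values.
* **ORF coverage**: histogram mode (50 bins), coefficient of variation, and
  the fraction of ORFs within ±50% of the mode. The label
  *single-copy-dominant* requires a strict majority (> 0.5) inside the mode
  window — strict so that an exactly balanced bimodal depth profile (half
  the genes duplicated) is not called single-copy.
* **Colonisation bookkeeping**: the FRE share of arbuscular-mycorrhizal
  colonisation is 100 · FRE/(FRE + G-AMF) on root-length percentages.

## Comparative functional profiles

Annotation tables are per-protein rows (genome, protein, category ∈
{CAZyme, lipase, protease, transporter, SSP}, CAZy family iff CAZyme,
semicolon-joined EC numbers, transporter substrate). Category counting and
transporter-substrate counting are plain tallies with schema validation
(duplicate (genome, protein, category) rows rejected with the offenders
listed).

**Substrates.** The shipped family→substrate map (`data/substrate_map.json`)
seeds every pairing named in the narrative it models (AA9/GH9/AA3 →
cellulose; GH31/GH5_7/GH29/GH95 → hemicellulose; AA1/AA1_2/AA2 → lignin;
GH35/GH2/PL1_7/GH28 → pectin; CE4/GH18 → chitin; GH92/GH125/GH76/CE17 →
mannan; GH151 → other). It is deliberately an editable config: family
assignments drift with CAZy releases, and fuller coverage is a data
concern, not code. Unmapped families count as *unclassified*. A protein in
k groups contributes a copy to each group, but PCWDE/MCWDE side totals
count unique proteins by default (per-group sums behind
`side_counting="per-group"`), so multi-substrate enzymes do not inflate the
side totals.

**Pathways.** A pathway is a list of roles; a role is satisfied when any of
its alternatives is fully present, where an alternative is a conjunction of
EC numbers/family codes (trailing-dash EC components act as wildcards,
since annotation tools emit partial ECs). The shipped defaults
(`data/pathways.json`) cover cellulose degradation (endoglucanase,
β-glucosidase, exoglucanase), a chitin suite, thiamine biosynthesis,
cytosolic fatty-acid synthase, and vitamin-B6 metabolism — where the
missing pyridoxine 4-dehydrogenase may be substituted by the three-step
pyridoxal→pyridoxine bypass, encoded as an alternative satisfier.
Completeness is monotone: adding identifiers can never un-complete a
pathway.

**Group tests.** Kruskal–Wallis (scipy, tie-corrected) across lifestyles
with ≥ 2 genomes, at α = 0.01. When significant, Dunn's post-hoc z tests on
the pooled ranks with tie correction, pairwise p adjusted (BH default, Holm
available), at α = 0.05. The compact letter display uses the
insert-and-absorb construction: start with one letter covering all groups,
split it at each significant pair, absorb subsets; letters are assigned in
descending median order. By construction two groups share a letter iff
their adjusted p ≥ α, which the tests audit exhaustively.

## Synthetic data

The generators emulate the study regime the pipeline targets; their
defaults are the analysis conditions, not tuning knobs.

* **Assembly** (`gen_assembly`): a 500 kb target genome (desk-scale
  stand-in for a ~37 Mb fungal MAG) fragmented by a Poisson breakpoint
  process tuned to an N50 of 5 kb (realised N50 within roughly a factor of
  two; exact matching is not attempted), with 3 copies of a 4.5 kb operon
  embedded and each copy forcibly split over ≥ 2 unitigs — emulating the
  chronic failure of rDNA to assemble. Links follow fragment adjacency;
  3 decoy genomes of 150 kb form disconnected components; bins are the true
  genome partition with an optional misassignment rate.
* **Coverage** (`gen_coverage`): 12 samples; target-bin depth log-uniform
  over 1–568×; the planted taxon's normalised coverage is slope × bin
  coverage under mean-one lognormal noise (CV 0.10 default; slope 63);
  250 decoy taxa with independent profiles, of which 20 are kept below the
  10-read floor to exercise the filter. Per-contig mapping noise is
  lognormal, CV 0.05.
* **SNVs** (`gen_snvs`): frequencies Uniform(0.05, 0.95) (strain regime) or
  truncated Normal(0.5, 0.05) (diploid regime); positions length-weighted
  over contigs; depths Poisson(150)+20 so that read-count discretisation
  does not distort the spectrum.
* **Annotations** (`gen_annotations`): negative-binomial category counts
  (size 8 default; counts across lifestyles are overdispersed) around group
  means taken from the modelled study where stated (CAZymes: G-AMF 175,
  ECM 240, ERM 629; lipases: G-AMF 189, ECM 238, SAP 263, OCM 268;
  proteases: ERM 457, G-AMF 305, ECM 286, SAP 271; transporters:
  G-AMF 3900) and plausible fill-ins elsewhere; genome numbers are
  desk-scaled (12/12/4/3/12 for G-AMF/ECM/ERM/OCM/SAP) rather than the full
  database. G-AMF-like genomes omit β-glucosidase, thiamine enzymes,
  cytosolic FAS and pyridoxine kinase by construction, giving pathway
  scoring a known truth.

What the generators do **not** emulate: read-level error, chimeric
misassembly, host contamination, compositional (k-mer) signal, phylogenetic
correlation among genomes, and real CAZy family frequency profiles. Passing
closed-loop tests therefore demonstrates the statistical machinery under
the assumed generative structure, not robustness to every artefact of real
metagenomes.

## Determinism and numerics

Every stochastic operation takes an explicit seed (package default
20251029); generators write truth JSON alongside outputs and reproduce
byte-identically under a fixed seed. Sorted outputs use stable sorts with
lexicographic id tie-breaks. Coordinates are 0-based half-open everywhere
internally (PAF native; SAM converted on read). Degenerate inputs
(zero-variance profiles, all-zero bins, empty seed sets, frequencies at 0
or 1) raise or are excluded with a report rather than propagating NaNs.

## Verification sizes

The test suite and `scripts/acceptance.py` run the closed-loop coverage
recovery at 200 seeded replicates, SNV classification at 200 replicates per
regime (n = 1000 SNVs), oracle-equivalence checks at 1000 random instances
per statistic, and the Kruskal–Wallis null calibration at 2000 simulations —
the sizes at which the reported rates (top-rank ≈ 1.0, slope-within-15%
≈ 0.97–0.99, classification ≥ 0.98, type-I rate ≈ 0.005–0.015) are stable.
Assembly statistics are cross-checked against an independent external tool
(seqkit) on a MAG-scale synthetic contig set; checking them against the
deposited MAG itself requires downloading the deposit and is not part of
the offline suite.

## Known limitations

* The built-in aligner scores with unit costs; affine-gap or custom scoring
  requires an external aligner (PAF/SAM input).
* Through-origin slope estimation is depth-weighted; a handful of deep
  samples dominate, which is statistically efficient under multiplicative
  noise on proportional profiles but sensitive to an outlier in the deepest
  sample. The bootstrap CI reflects this.
* Compact letter displays are not unique in general; the insert-and-absorb
  construction is deterministic but other valid letterings exist.
* The GFA parser handles GFA1 S/L records only (the dialect produced by the
  assemblers this workflow consumes); GFA2, paths and containments are out
  of scope.
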