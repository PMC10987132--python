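# Methods

This note documents the models and rules `virocat` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Viral calling

Each contig carries an evidence record of detector outputs consumed as a
table (the detectors themselves — VirSorter/VirFinder-class scorers,
reference BLAST, phage-orthologue searches, CheckV completeness — are out
of scope and never run here). The call is:

*viral* ⟺ circular ∨ |criteria| ≥ 2 ∨ (|criteria| = 1 ∧ completeness ≥ 90 %),

with criteria C1 score ≥ 0.7, C2 score > 0.6, C3 score > 0.7, C4 identity
> 50 % ∧ coverage > 90 %, C5 ≥ 3 ORF hits ∧ ≥ 2 per 10 kb. Comparator
strictness follows the printed rules exactly (≥ for C1, strict > for
C2–C4). A missing detector output never satisfies a criterion: the tools
run independently per contig, so absence of a score is informative, not an
error. Decontamination removes called contigs whose merged ≥ 90 %-identity
hits against a prophage-masked bacterial catalogue cover ≥ 50 % of the
contig; both comparators are read inclusively, the conservative direction
for contamination removal. Coverage is computed on merged intervals, so
the decision is invariant to how an aligned region is split into HSPs.
The length filter is strict (> 5000 bp). Prophage masking excises 0-based
half-open intervals, merging overlaps first — one interval convention is
used in every table in the package.

## Circularity

Two independent routes:

* **Terminal repeat.** The maximal L ≥ 30 with `seq[:L] == seq[-L:]`,
  scanned from ⌊n/2⌋ downward so prefix and suffix cannot overlap; the
  first hit is the maximum. Matching is exact; repeats containing N are
  rejected (N never matches anywhere in the package). No E-value is
  computed: at 100 % identity and L ≥ 30 the chance terminal-repeat
  probability is ~4⁻³⁰ per length, which the acceptance suite confirms
  empirically (0 calls in 1000 random 10-kb genomes).
* **Junction reads.** A read supports circularity when, on one strand, it
  has distinct alignment segments of ≥ 50 bp, one ending within 100 bp of
  the contig end and one starting within 100 bp of the start; ≥ 2 such
  reads call the genome circular. The 100-bp terminal window
  (`circ_end_window`) is a package choice — the smallest round window
  consistent with ≥ 50-bp terminal hits; it is configurable. Requiring the
  two segments on the same strand is likewise a package decision (a
  genuine junction read stays on one strand).

## Homology engine

Ungapped seed-and-extend local alignment: exact 15-mer anchors (both
strands), grouped by diagonal, extended left and right under an X-drop
rule (match +1, mismatch −2, drop 20), with same-diagonal overlapping
segments merged and seeds inside already-extended intervals skipped.
Identity is matched bases over segment length. k = 15 with this scoring is
sensitive above ~90 % identity — at 10 % divergence an exact 15-mer occurs
every ~5 positions in expectation — and everything downstream (95 %
dereplication, 95/70 novelty cuts, 90 % cluster-graph filter) lives above
that regime, which is why gaps are not modelled in the engine; the test
suite checks it against a gapped Smith–Waterman oracle (Biopython
PairwiseAligner) on planted regions, requiring boundary agreement within
±5 bp and zero invented regions. E-values are not computed anywhere: every
search in scope carries identity/length thresholds that dominate the
conventional E-value cutoffs, avoiding Karlin–Altschul calibration.

**ANI.** "ANI" is operationalised as merged-region coverage: project HSPs
with identity ≥ 95 % and length ≥ 500 bp onto the query, merge overlaps,
and divide covered bases by query length (×100). This is the only reading
consistent with thresholding that same quantity at 95/70 for the
identical/partial/novel classes. It is deliberately asymmetric
(query-normalised); novelty classification always uses the catalogue
sequence as query, and the best reference across all catalogues decides
the class. An identity-weighted variant can be obtained by scaling covered
bases by HSP identity, but coverage is the default.

**Dereplication.** Greedy longest-first clustering: visit contigs by
descending length (ties by id); a contig joins the first representative
with global identity ≥ 0.95, else founds a cluster. Global identity is
CD-HIT's definition — matched bases of the best HSP chain divided by the
shorter sequence length — computed by claiming query intervals in
descending HSP-score order so overlapping HSPs are not double-counted.
The published description of this step ("100 % consistency for 95 % of
the shorter genome") is ambiguous against the stated 95 %-identity
parameterisation; the 95 %-identity-over-shorter reading is implemented.

**Source groups.** A long/hybrid-assembled representative is `long_read`
unless some short-read contig anywhere in the workspace (including
dereplication discards) shares ≥ 95 %-identity regions covering > 50 % of
its length (`both`); symmetric for short-read representatives. All
workspace contigs are consulted, not only the vOTU's own sample.

## Viral clusters

Edges require merged ≥ 90 %-identity coverage > 70 % of the larger and
> 90 % of the smaller genome (no minimum segment length in this filter).
MCL runs on the unweighted graph with unit self-loops: column-normalise;
iterate expansion (matrix square) then inflation (entrywise power 4.0,
renormalise) with pruning of entries < 1e-6 until the maximum entry change
is < 1e-8 or 200 iterations; clusters are the connected components of the
limit matrix's support, which assigns every node exactly once and provably
never merges disconnected components. Pruning/convergence constants are
canonical MCL practice; inflation 4.0 is the catalogue setting. Unit
weights match the described input (filtered BLAST pairs, unweighted);
coverage-weighted edges are possible but not default. VC labels are
`VC_k` by descending size, ties by smallest member id. Clade labelling by
co-clustering runs the same procedure on the union of vOTUs and labelled
reference genomes.

## Quantification

Presence: breadth > 0.5 ∧ mean depth > 4, both strict, with depth averaged
over the whole contig (not only covered positions). RPKM = reads /
(length/1000) / (total/10⁶). Relative abundance zeroes absent vOTUs
*before* renormalising, so each row with ≥ 1 present vOTU sums to 1 and a
high-RPKM but absent vOTU contributes nothing. VC abundance sums members;
VC presence is any-member presence. Shannon uses natural log (nats).
Bray–Curtis is 1 − 2Σmin/(Σa+Σb), undefined (error) for two all-zero
rows. Rarefaction draws 10 random k-subsets per k without replacement and
reports mean and SD of the union-set size, seeded.

## Lifestyle, clades, enrichment

Lifestyle bins partition [0,1]: ≤ 0.3 temperate, (0.3, 0.5] uncertain
temperate, (0.5, 0.7] uncertain virulent, > 0.7 virulent. The V/T ratio
pools the uncertain bins with their side by default (the strict-bins
variant is a flag); an all-virulent taxon is reported *undefined*, never
infinite. The packaged worked example divides the published virulent-side
counts by the catalogue size (21,499), matching the printed percentage —
note the published per-category counts sum to 21,569, slightly above the
catalogue size, so the denominator choice matters and the published one is
used. crAssphage calls need length > 70 kb plus either a significant
marker-protein hit (consumed as a flagged table; an in-repo six-frame
translation utility exists for protein-space work) or ≥ 95 % nucleotide
identity over ≥ 80 % of the contig. COG enrichment uses Pearson chi-square
without continuity correction on per-category 2×2 tables, requiring
p < 0.001 *and* the novel-side proportion to exceed the other side;
zero-margin categories are skipped with a warning.

## Host assignment

Spacer matching is exact full-length substring search on both strands
(a ≤ 1-mismatch mode exists behind a flag); exactness gives a clean
false-positive bound (~L·4⁻²⁵ per 25-bp spacer). Spacers shorter than
20 bp are matched but flagged and can never raise a link to high
confidence. tRNA matching is a sliding ungapped Hamming scan of the viral
gene against every full-length window of the bacterial gene, both strands,
at ≥ 95 % identity — a deliberate departure from the k-mer engine, whose
15-mer seeds are unreliable at 95 % identity on 70–90 bp genes, while the
scan is exact for the 100 %-of-length rule. Evidence is aggregated per
(virus, host species) with distinctness by spacer *sequence* and viral
tRNA gene id; ≥ 2 spacers, ≥ 2 tRNAs or ≥ 1 + ≥ 1 gives high confidence.
Host range is the rank of the LCA over the (high-confidence by default)
host set on the rank-labelled taxonomy. The exported network keeps only
high-confidence links, collapsed to (VC, host genus) pairs, with VC
majority-lifestyle and genus-phylum attribute tables.

## Synthetic generator

The generator is the package's study-conditions definition, not a tuning
surface. Defaults: 60 contigs and 5 samples per workspace; cluster
founders 6–15 kb (one 72-kb crAssphage-like genome); members at 1–3 %
substitution-only divergence (no indels by default, so realised identity
is analytically known); mosaics share 75 % of a reference-only donor;
terminal repeats 35–90 bp on five founders; lognormal(0, 1) abundances
renormalised per sample; present genomes tiled to ~0.88 breadth at 8–30X
(safely clear of the > 0.5/> 4 thresholds), absent ones given no or sparse
sub-threshold reads; detector evidence generated at noise 0 so planted
truth is exactly recoverable, with a noise parameter to degrade it;
spacers 25–45 bp (one planted 18-bp spacer exercises the low-confidence
path); a balanced seven-rank taxonomy over 10 species; one bacterial
genome carrying a planted prophage that would cause a false contaminant
removal if masking failed. Read placements are emitted as a simplified
TSV (sample, read, contig, start, end, strand), not SAM — the pipeline
consumes mapping summaries, not raw alignments.

What the generator does **not** emulate: sequencing error and quality,
real read-length distributions, assembly fragmentation and chimerism,
strain microdiversity, GC- or abundance-dependent coverage bias, gapped
divergence (indels), and real detector score distributions. Passing the
truth-recovery suites therefore demonstrates that the *rules* are
implemented correctly and are recoverable under clean planted conditions;
it does not measure how the rules perform on real sequencing data.

## Problem sizes and determinism

The shipped analyses and validation suites run at desk scale — 60-contig
communities, 20-cluster dereplication, ≤ 300-bp oracle alignments, 1000
random genomes for the false-positive bound — chosen so the whole suite
completes in minutes on one CPU while still exercising every rule at its
thresholds. Every random draw flows from an explicit seed through
`numpy.random.default_rng`; pipeline outputs are byte-identical across
reruns with the same inputs, config and seed, and the TSV writers fix
column order and float formatting to keep diffs exact.

## Known limitations

* The ungapped engine understates ANI for indel-rich homology; at the
  thresholds used this changes classes only near the 70/95 boundaries.
* Dereplication is greedy and order-dependent by construction (longest
  first, ties by id), matching CD-HIT semantics rather than an optimal
  clustering.
* `assign_source_group` scans all workspace contigs per vOTU, which is
  quadratic at catalogue scale; fine at desk scale.
* Taxonomy handling assumes a single rooted tree with the seven canonical
  ranks; unranked or multi-root taxonomies are rejected rather than
  coerced.
* The report's headline fractions are computed over the final catalogue
  only; no uncertainty is attached to them.
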