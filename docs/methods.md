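# Methods notes

## The analysis in brief

Differential RNA-seq (dRNA-seq) compares libraries treated with
terminator-5′-phosphate-dependent exonuclease (TEX), which degrades
processed 5′-monophosphate transcripts, against untreated libraries.
Primary transcript 5′ ends therefore appear as TEX-enriched steps in
5′-end coverage. The package calls such transcription start sites (TSSs)
per condition, unifies them per species, classifies them positionally
against ORFs, and then asks two comparative questions for a pair of
related genomes: (i) which TSSs of single-copy orthologous genes are
*positionally orthologous* (≤35 alignment columns apart after relocating
TSSs into UTR or codon alignments), and (ii) which orthologous TSS pairs
change transcription level *consistently* between two growth conditions in
both species.

## TSS caller: a documented stand-in

The original workflow used TSSpredator, whose step-height/step-factor
machinery and parameters are not public in the source material beyond the
clustering distance. The caller here is the minimal rule with the same
intent, and is configurable:

- step: `cov⁺(p) − cov⁺(p_upstream) ≥ min_step` (default 5 normalized
  units; `p_upstream` is `p−1` on the plus strand, `p+1` on the minus
  strand; at the replicon edge the step is defined as 0),
- enrichment: `(cov⁺(p)+1)/(cov⁻(p)+1) ≥ min_enrich` (default 2; the
  pseudocount avoids division by zero).

Within-condition clustering (30 bp) and cross-condition unification (35 bp
window) are both chain-linkage: consecutive sorted positions join a cluster
while gaps stay within the distance, and the highest-step member represents
the cluster (ties → smaller coordinate). Chain linkage is the fixed-point
of a sliding window of that size over sorted positions; after reduction all
surviving TSSs are pairwise farther apart than the distance, which makes
unification idempotent.

"Transcript level" is not operationally defined in the source beyond being
quantified per TSS and condition; the package records both the step height
and the normalized TEX(+) coverage at the representative position per
condition, and uses the latter for fold changes (a TSS detected in only one
condition still gets a level, possibly 0, read from the other condition's
track).

## Classification

The genic (g) window is the fixed operational 1000 nt rule;
`derive_utr_threshold` provides the species-specific alternative (mean
intergenic distance; the published genome-scale values, ~1100–1250 bp, need
the real genomes and are not reproducible on the synthetic world). A gTSS
associates only with the *nearest* qualifying downstream same-strand ORF,
so each gTSS defines a single UTR — this keeps orthologous UTR matching
well defined when ORFs are nested or close. Internal/antisense classes
associate with the containing ORF. A TSS may hold several classes
(giTSS etc.) and participates in each class's comparative matching
independently.

## Orthology

BLAST and MCL are not executed. The desk-scale equivalent is an all-vs-all
Needleman–Wunsch score matrix (Biopython's pairwise aligner; BLOSUM62, gap
open 10 / extend 0.5, free end gaps — EMBOSS needle defaults), a score
floor calibrated so that 300 residue-shuffled cross-species pairs all fall
below it (the search-engine-agnostic replacement for an e-value cutoff),
reciprocal best hits, removal of any gene attaining its best score against
more than one partner (the single-copy constraint), and the 30% global
identity filter. Externally computed tabular (outfmt-6-like) hits can be
ingested for fidelity runs on real proteomes.

Codon alignments expand each protein-alignment column into three nucleotide
columns; UTR alignments cover the 1000 nt (edge-truncated) upstream of each
start codon, 5′→3′ on the gene strand.

## Comparative matching choices (genuinely open points)

- **Column distance counts gap columns.** "≤35 bp in the alignment" is read
  as alignment-column distance — the only definition invariant to which row
  carries the gaps.
- **Greedy nearest-first one-to-one matching**, ties broken toward the
  smaller species-A column: the source defines no multi-candidate
  resolution; greedy-by-distance is deterministic and mirror-symmetric in
  the two species.
- **Antisense TSSs map through the sense ORF's codon alignment** (the
  column of the complementary nucleotide), so one alignment per ortholog
  pair serves all classes.
- **TSS loci** are ±35 nt windows (71 nt; truncated at replicon edges, so a
  TSS at position 10 gets a 45 nt window), aligned with the nucleotide
  scorer; identity is over the full alignment length.

## Differential screening

Fold change is `log2(level_branchless / level_true_branching)`, defined
only when both levels are positive — zero levels are excluded, never
smoothed. The "5% most extreme" rule is operationalized as: among all
orthologous TSS pairs with defined fold changes in both species (each
physical pair counted once even when multi-class), flag the
`ceil(0.05·n)` pairs with the largest `|fc_a + fc_b|`, restricted to
same-sign (quadrant I/III) pairs; the ranking statistic is configurable
(sum | min | product). Whether the 5% applies globally or per class is not
stated in the source; global-n is the default here.

## Statistics

- Fisher exact (two-sided) on ortholog/singleton × class 2×2 tables, BH
  correction over the three pairwise class comparisons; zero-margin tables
  get p = 1 by convention.
- Cochran–Armitage χ²-test for linear trend with equally spaced scores over
  protein-identity bins (default seven 10-point bins over 30–100%; no
  binning is stated in the source). On the default synthetic world nearly
  all pairs fall in one identity bin, so the pipeline reports the trend
  test as undefined there — the test itself is validated on constructed
  bins.
- Wilcoxon signed-rank (two-sided, zeros dropped, exact distribution up to
  25 informative pairs) for locus-vs-protein conservation.
- The summary table counts an ortholog gene pair toward a class when it has
  ≥1 TSS of that class in *either* species; this reading reproduces the
  published mean-TSS-per-pair arithmetic exactly (e.g. 5112/2264 = 2.26),
  whereas an "in both species" reading does not.

## Synthetic world: what it does and does not emulate

Defaults are the stated scenario: 200 single-copy ortholog gene pairs,
nucleotide divergence 0.05, four libraries per species (TEX± × two
conditions) of ~1e5 5′ ends each, one fixed seed for everything.

Structure: one linear replicon per species; genes of 100–250 codons with
250–600 nt intergenic spacers, non-overlapping by construction; a gene
desert at the end hosts intergenic (n) TSSs, because with compact spacers
every intergenic position would fall inside some ORF's 1000 nt genic
window. Divergence is substitution-only (codon substitutions that would
create internal stops are reverted), so orthologous coordinates are
directly homologous and alignment columns equal sequence offsets — this is
what makes the ±35-column ground truth well defined. Per ortholog gene
pair one TSS is planted per species, orthologous (same gene-relative
offset, same class) with probability `fraction_ortho_tss` = 0.5;
100 additional lineage-specific TSSs per species draw classes uniformly
from {g, a, i, n}. Planted TSSs keep ≥60 nt spacing within a species and
≥50-offset separation within a (gene, class) across species so that truth
assignments stay unambiguous under the 30/35 bp clustering.

Signal: TSS heights are log-uniform on 80–800 normalized units; condition
effects are truncated-normal log2 fold changes (sd 0.5, |fc| ≤ 1);
4% of planted orthologous pairs instead get an extreme consistent fold
change (|log2 fc| = 4, lower level 80) — large enough that, given Poisson
counting noise, the extremes separate from the background tail by
construction. Reads get truncated-Gaussian 5′-end jitter (sd 1 nt, ±2),
TEX(−) signal is the TEX(+) level divided by the enrichment factor
(default 10), and a uniform Poisson background (0.15 per position and
strand) models nonspecific 5′ ends. Counts are Poisson by default,
multinomial when exact library sizes are requested, and rounded intensities
in the deterministic zero-noise mode used by exactness tests.

Not emulated: replicate variance (the original design pools three
biological replicates into one library per condition and TEX state, so the
simulator emits exactly one library each and no replicate-aware confidence
is possible); rRNA operons; read-sequence-level errors (alignments are
emitted directly); genome rearrangements and indels; realistic operon
structure. A green parameter-recovery test therefore establishes that the
pipeline's inference, matching and screening logic is correct under the
assumed noise model — not that the caller's sensitivity matches real
dRNA-seq libraries.

## Numerical conventions

Coordinates are 1-based inclusive throughout (GFF3); BedGraph output is
0-based half-open as the format requires. Poly-A/T clipping removes the
entire offending homopolymer run (the run is a ligation artifact, no part
of it is trusted as genomic) and the thresholds are the longest A/T runs
observed in the genome. Depth normalization multiplies each library by
min(size)/size. Percentages in the summary table round half-up, with the
singleton percentage defined as the complement of the orthologous one so
the two always sum to 100. All tie-breaks (cluster representatives, greedy
matching, candidate ranking) resolve toward smaller coordinates/ids, making
every stage deterministic given the seed.

## Known limitations

- The caller is a stand-in; TSSpredator parameters cannot be reproduced.
- The internal similarity search does not emulate BLAST soft-masking or
  Smith–Waterman options used for orthology detection at genome scale;
  published genome-scale counts (2805 ortholog pairs, 5112/4082/3382 TSSs
  per class, 91%/96% condition overlap) require the real genomes and raw
  reads and are out of desk-scale reach by design.
- Three-species (inter-generic) comparison is supported structurally by the
  pairwise machinery but not separately validated.
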