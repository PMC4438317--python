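# Methods

This note records the models, conventions and parameter choices behind
`amdscope`, and what the synthetic benchmarks do and do not demonstrate.

## The problem setting

A low-diversity community — one dominant taxon above 90% relative abundance,
several rare taxa below 1% — sequenced twice from the same sample: shotgun
DNA (community composition and gene dosage) and cDNA (community
transcription). The pipeline recovers genomes from the contig pool without
references, then asks, per taxon, which functions are transcribed beyond
their gene dosage and which functions a taxon dominates community-wide.

## Synthetic community generator

The generator is first-class, tested code: it defines the conditions every
downstream stage is validated under.

**Genomes.** Each genome is drawn from its own Markov chain of order *m*
(default 3) over {A,C,G,T}. Per-context transition probabilities are
lognormal perturbations (σ = 0.7) of the target base composition
((1−GC)/2, GC/2, GC/2, (1−GC)/2), then iteratively rescaled so the chain's
stationary base composition equals the requested GC (fixed-point correction
on the 4^m-context chain, tolerance 1e-10). Order 3 gives each seed a
distinct tetranucleotide signature at matched GC — the property TNF binning
needs; realized GC is within ±0.02 of target at 100 kb. Default fixtures
span GC 0.38–0.67, the spread observed between coexisting AMD taxa.

**Community.** Abundances are a dominant fraction (default 0.91) plus equal
rare fractions summing to 1. Genes (default 50 per genome, 600–1200 bp) are
placed uniformly without overlap; strands are random. Gene *i* carries KO
label `K{i+1:05d}` in every genome, so KOs form cross-genome orthologous
groups, and each KO maps to one of 8 functional categories. Expression
weights are i.i.d. log-normal(μ = 0, σ = 1) — a skewed transcript pool in
which IQR-fence outliers exist; the real community's expression distribution
is unknown, so this is a modelling stand-in, not an inference. Explicit
weight vectors can be supplied to plant known signals.

**Reads.** DNA pairs are 2×101 bp, FR-oriented, insert ~ N(500, 50²) clipped
to [read length, genome length]; a pair comes from genome *g* with
probability ∝ abundance × length, so with equal genome lengths the expected
read fraction equals the abundance (fixtures that assert abundance recovery
use equal lengths for this reason). Substitution errors are i.i.d. per base
(default 0); there is no indel or quality-dependent error model. cDNA reads
are single-end, drawn from gene intervals with probability ∝ abundance ×
weight × gene length; the exact per-gene sampling probabilities are returned
as ground truth. FASTQ qualities are constant Q30 — quality filtering is not
a contribution of this pipeline and is reduced to a length rule.

**Contigs.** Assembly internals are out of scope; `fragment_genomes` tiles
each genome into exact-substring contigs (default 5–7.5 kb) carrying their
true origin and a coverage of abundance × depth-constant with multiplicative
lognormal noise (σ = 0.1) — enough spread to make coverage refinement
non-trivial. Consequences: passing binning tests show signature separation
at these fragment sizes, not robustness to chimeric or error-laden
assemblies.

## Read partitioning

Canonical k-mers (lexicographic min of a window and its reverse complement;
k odd to avoid self-complementary ambiguity) are counted exactly in a hash
table; windows containing non-ACGT symbols are skipped, as conventional
counters do. The per-read statistic is the **median** canonical k-mer count
— the convention of khmer-style abundance partitioning, robust to single
erroneous k-mers; a pair is scored by the max of its mates' medians so mates
stay together (splitting mates would destroy insert information). The depth
rule is median ≥ 15 (the threshold's strictness is not documented in the
tools this mirrors; ≥ is used and recorded here). Mates shorter than 63 bp
are unscorable; reads with no scorable mate are discarded. The table is
exact (dict-backed) so brute-force oracle tests can demand equality;
~10⁷ distinct 31-mers fit comfortably in memory at these scales.

## Dereplication and overlap merging

Identity is computed from edit distance (edlib) as 1 − distance/span; only
the contractual thresholds (98% identity; 40 bp minimum overlap; full
containment of the shorter sequence) are normative, matching the CD-hit
`-c 0.98 -aS 1 -g 1 -r 1` and Newbler `-mi 98 -ml 40` / Minimus2 98%
settings these stages reproduce. Dereplication is greedy longest-first
(ties by input order) and idempotent. Merging anchors candidate overlaps by
16-mer seeds at three offsets, verifies each candidate with a global
alignment of the overlapping windows, and repeatedly merges the longest
qualifying overlap (ties: identity, then input order) until no pair
qualifies; both strands are considered. Overlap disagreements take the
longer contig's bases (higher expected coverage). Self-merges are never
attempted, so overlap cycles terminate by contig-count decrease. The
<2000 bp / ≥2000 bp length split mirrors the two-pool assembly convention;
the boundary length 2000 itself goes to the long pool.

## Genome binning

**TNF.** 136 canonical tetranucleotide classes (each 4-mer pooled with its
reverse complement), counted over all ACGT windows and normalized; contigs
under 3 kb are rejected (composition estimates are too noisy below that).
Profiles are strand-invariant by construction.

**Clustering.** Ward linkage on Euclidean distances over raw TNF
frequencies (no standardization — the frequencies are already on a common
scale). The bin count is chosen by **mean silhouette width** over tree cuts
in a configurable range; the original workflow selected the count by visual
NMDS inspection, which is not testable, so the ordination (non-metric SMACOF
with isotonic regression; Kruskal stress-1) is retained as a diagnostic and
the silhouette supplies the automated criterion. The chosen k can be
overridden (`fix_k`). Known failure mode, asserted in tests: genomes with
indistinguishable signatures (same generator seed and GC) merge, so the
selected k undercounts such communities.

**Refinement.** Within each bin, coverage is summarized by median and MAD; a
contig deviating by more than 3×MAD, or whose taxonomy label conflicts with
the bin majority, is divergent. Taxonomy conflicts force a move to the
nearest-bin-mean-TNF bin with compatible coverage and taxonomy, or to
unbinned if none qualifies. Coverage-only flags move a contig **only if**
some compatible bin is a strictly better TNF match than its current bin:
with small bins the MAD is a noisy spread estimate, and evicting
composition-consistent contigs on coverage alone degraded otherwise-perfect
assignments; the guard keeps refinement strictly non-harmful in that regime
while still rescuing genuinely misplaced contigs (which by construction sit
nearer their true bin's TNF mean). Bin statistics are computed on the input
assignment, making the pass order-independent and deterministic.

**Chimera flagging.** A simplified self-comparison: non-overlapping 500 bp
windows aligned pairwise (both orientations); a pair at ≥ 98% identity flags
the contig with the span covering both copies. This targets the repeat-borne
chimeras that self-alignment screens catch; a chance 500 bp match at 98%
between random windows is vanishingly improbable, so random contigs are
never flagged.

**Completeness and abundance.** Completeness is the fraction of a supplied
core-gene set observed in a bin (set semantics; duplicates count once).
Relative abundance is the fraction of reads mapped to a bin's contigs;
unmapped reads (including those on unbinned contigs) are reported separately
so the fractions sum to 1.

## Read mapping (synthetic regime)

Reads are placed by exact canonical 31-mer seeds indexed at every reference
position; ambiguous seeds are skipped and several offsets are tried, so a
read overhanging a contig end still maps by its clean side. A read counts
for a gene when its mapped midpoint lies inside the gene. This is a
deterministic stand-in appropriate for error-free or low-error synthetic
reads — it is not a general-purpose aligner and degrades with error rate
(each seed offset tolerates no mismatches within the seed).

## Transcriptional statistics

**Totals.** A genome's total is by default the sum of its feature-mapped
reads; genome-wide mapped totals (including intergenic DNA) are available
as an option. Genomes with a zero DNA or cDNA total are excluded with a
warning, mirroring the exclusion of taxa with too little transcriptome
information.

**RTA.** RTA = cDNA share / DNA share. If the DNA count is zero but cDNA is
positive, 0.5 is added to both counts and the entry flagged
(`pseudocount`); if both are zero the value is NaN (`undefined`). Under the
generator's null (uniform weights), per-genome median RTA is ~1.

**Outliers.** Per genome, quartiles of the cDNA counts over all its KOs use
linear interpolation between order statistics (the common default; the
flags depend on this convention). The default rule is the boxplot fence,
count > Q3 + 1.5×IQR; the literal reading "count > 1.5×IQR" is implemented
behind `mode="literal"` since the prose rule is ambiguous between the two.
Genomes with fewer than 4 KOs are skipped with a warning.

**Indicator Values.** IV(a,b) = 100 × cDNA share of KO *a* in genome *b*
divided by the summed share over all *g* genomes — the concentration form
of an indicator statistic: rows sum to 100 for expressed KOs, a KO
expressed in one genome scores 100 there, and an indicator KO is an
expression outlier with IV **strictly** above 50 (IV = 50 exactly is not an
indicator).

**Rank-sum contrasts.** For each functional category and genome, the
genome's RTA values in the category are contrasted against all other
genomes' values by the two-sided Wilcoxon rank-sum test: exact null when
both samples have n ≤ 12 and no ties, otherwise the normal approximation
with continuity correction and tie-corrected variance (the classical
large-sample form; it matches R's `wilcox.test(correct = TRUE)` to ~1e-12).
A category is flagged enriched in a genome when p < 0.05 and the genome's
median is higher. No multiple-testing correction is applied, matching the
workflow this reproduces. Zero-variance inputs return p = 1.

**Profiles and rankings.** Category × taxon activity matrices are the mean
RTA over the category's features, z-scored per row with the population
(n-denominator) standard deviation — the taxa are a fixed set, not a
sample; zero-variance rows become zeros and are flagged. Top-N rankings
sort by RTA, breaking ties by higher cDNA count then feature id, so output
is deterministic.

## Pipeline and reproducibility

All stage seeds derive from one config seed; the manifest records the
config, record counts and SHA-256 checksums of every output file — never
wall-clock times, which go to the log — so two runs of one config are
byte-identical. The demo configuration uses 5 genomes of 80 kb, 50 genes
each, 20 000 DNA pairs and 20 000 cDNA reads: sizes chosen so the full
pipeline and its tests run in seconds to minutes on a laptop while leaving
every statistic comfortably above its noise floor (the dedicated
recovery benchmarks in `scripts/acceptance.py` use 100 000 reads and 300 kb
genomes where precision demands it).

## Limitations

- Genomes are Markov-chain text, not biology: no repeats, mobile elements,
  rRNA operons, strain variation, or conserved inter-genome homology —
  dereplication and chimera flagging therefore face no hard cases here.
- No assembler is run; contigs are exact substrings. Binning results bound
  what composition can do under ideal contigs, not assembly artifacts.
- The seed mapper requires (near-)exact reads; with realistic error rates a
  production aligner should replace it behind the same counting interface.
- The expression model draws reads independently per gene; operonic
  structure, rRNA carry-over and library-preparation biases are absent.
- Equal-length genomes are used where read fractions must equal abundances;
  with unequal lengths the two differ by the length weighting, as in real
  read-mapping abundance estimates.
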