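# amdscope

Tools for reconstructing and profiling genomes from combined metagenomic and
metatranscriptomic sequencing of **low-diversity microbial communities** —
the situation typical of acid-mine-drainage (AMD) habitats, where one taxon
can exceed 90% relative abundance while the remaining taxa each sit below 1%.
Recovering those rare genomes, and asking which functions each taxon actually
*transcribes*, requires a handful of bespoke computations that this package
implements as a tested, reusable pipeline:

1. **"Divide and conquer" read partitioning** — canonical k-mer counting
   (k = 31) and splitting of the read pool at a per-read median k-mer depth
   of 15, so that the dominant and the rare genomes can be assembled
   separately (reads under 63 bp are dropped).
2. **Contig dereplication and overlap merging** — scaffolds are broken at
   N-runs; contigs contained in a longer contig at ≥ 98% identity are
   removed; contigs sharing a suffix/prefix overlap of ≥ 40 bp at ≥ 98%
   identity are greedily merged to a fixpoint.
3. **Tetranucleotide-frequency (TNF) genome binning** — contigs ≥ 3 kb are
   profiled by 136 reverse-complement-pooled 4-mer frequencies, clustered by
   Ward-linkage agglomeration on Euclidean distances, with the bin count
   selected by silhouette maximization (non-metric MDS stress reported as an
   ordination diagnostic), then refined by robust coverage statistics
   (median ± 3×MAD) and optional taxonomy labels. Per-bin relative abundance
   is the fraction of reads mapping to the bin's contigs.
4. **Per-taxon transcriptional statistics** — for a feature *a* (gene, KO or
   COG) in genome *b*:

   - relative abundance: `cDNA_ab` (resp. `DNA_ab`) is the share of genome
     *b*'s cDNA (DNA) reads matching *a*;
   - **Relative Transcriptional Activity**: `RTA_ab = cDNA_ab / DNA_ab`
     (RTA = 1 ⇔ transcription proportional to gene dosage);
   - **expression outliers**: KOs whose cDNA count exceeds the IQR fence
     `Q3 + 1.5×IQR` within their genome;
   - **Indicator Value**: `IV_ab = 100 · cDNA_ab / Σ_{j=1..g} cDNA_aj` over
     the *g* genomes; an outlier with `IV > 50` (strict) is an
     **indicator KO** of that taxon;
   - Wilcoxon rank-sum contrasts of RTA per functional category across taxa
     (*P* < 0.05), z-scored per-category activity profiles, and top-10
     most-active feature rankings per taxon.

Because real AMD datasets are enormous and tied to external databases, the
package ships a first-class **synthetic community generator**: order-3
Markov-chain genomes with prescribed GC (distinct, distinguishable 4-mer
signatures), a dominant-plus-rare abundance profile, paired-end 2×101 bp DNA
reads drawn proportionally to abundance, and cDNA reads drawn from known
per-gene expression weights — so every downstream stage can be scored
against exact ground truth.

## Worked example

Run the bundled 5-genome demo (dominant genome at 91%, four rare genomes,
20 000 read pairs) and score it against its own ground truth:

```sh
amdscope run --seed 1 --out-dir demo_run
amdscope evaluate --run-dir demo_run --seed 1
```

which prints:

```
             metric    value
            bin_ari 1.000000
         bin_purity 1.000000
abundance_max_error 0.025500
       rta_spearman 0.826353
indicator_precision 0.900000
   indicator_recall 0.692308
```

Reading this: TNF binning reassembled the five genomes perfectly
(`bin_ari`/`bin_purity` = 1.0); read-mapping abundance is within 2.6
percentage points of the true profile at this modest read depth (reads
landing on the sub-3 kb contig tails stay unbinned and count as unmapped);
RTA rank-correlates with the true expression weights at ρ ≈ 0.83 (rare
genomes receive few cDNA reads at 20 000 total — the correlation rises above
0.95 at the 100 000-read depth used by `scripts/acceptance.py`); and 9 of 10
indicator calls match the calls derived from the exact expected counts.

`demo_run/` contains per-stage outputs: truth tables and FASTQ under
`synth/`, the high/low/discarded split under `partition/`, the dereplicated
and merged contigs under `contigs/`, bin membership/diagnostics/abundance
under `bins/`, RTA/outlier/IV/indicator/contrast tables under `expression/`,
and a checksummed `manifest.json` (two runs of the same config are
byte-identical).

Every stage is also a library call (`amdscope.partition`, `amdscope.merge`,
`amdscope.binning`, `amdscope.expression`, `amdscope.synthetic`) and a CLI
subcommand (`amdscope synth|partition|merge|bin|express|run|evaluate`).

## Layout

```
src/amdscope/
  synthetic.py    community generator with ground truth
  partition.py    canonical k-mer counting and depth partitioning
  merge.py        scaffold splitting, dereplication, overlap merging
  binning.py      TNF profiles, Ward clustering, NMDS, refinement
  mapping.py      exact-seed read mapper for synthetic reads
  expression.py   RTA, outliers, Indicator Values, rank-sum contrasts
  pipeline.py     orchestration, config, manifest, truth-based evaluation
  cli.py          `amdscope` command group
docs/methods.md   model, assumptions, parameter choices, limitations
```

See `docs/methods.md` for the statistical model, the synthetic-data
assumptions, and the numerical conventions (quantile interpolation, IQR
fence vs literal threshold, pseudocount policy, tie-breaking).
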