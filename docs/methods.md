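# Methods

## Genomic partition

All coordinates are 0-based half-open internally; GTF input (1-based closed)
is converted on read, BED12 passes through. Interval union merges *touching*
intervals — under the half-open convention `[0,100)+[100,200)` is 200
contiguous bases — so feature lengths used as RPKM denominators are never
split or double counted.

Three disjoint feature spaces are derived per chromosome:

* **merged exons**, per gene: union of all transcripts' exon intervals;
* **non-overlapping introns**, per gene: the gaps between the gene's merged
  exons minus the merged exons of *every* gene on the chromosome
  (subtract-semantics as in `bedtools subtract`). This prevents an exon of
  gene B inside an intron of gene A from being counted as intronic space;
* **intergenic**: complement of gene spans (min exon start to max exon end).
  Introns of other genes are *not* excluded from gene spans, so intergenic
  space is the strict between-genes complement; the alternative reading
  (complement of exonic space only) would silently re-label intronic signal
  as intergenic.

An invariant test asserts per-base disjointness of the three spaces on toy
chromosomes.

## Read classification

One label per read (mate), applied in precedence order: mitochondrial
chromosome; rRNA-gene exon overlap; any merged-exon overlap (≥ 1 bp of any
aligned block — junction-spanning reads are exonic); all blocks completely
inside one gene's introns; all blocks completely inside intergenic space;
otherwise unclassified. The asymmetry is deliberate: exon assignment needs
only overlap, intron/intergenic assignment needs full containment, so reads
straddling an exon boundary count as exonic and reads straddling a gene
boundary count as neither.

Ties: a read overlapping exons of several genes goes to the gene with the
most overlapping bases; exact ties break lexicographically on gene id and
are counted (`AnnotationIndex.tie_break_count`). A read contained in the
introns of more than one gene (possible for overlapping genes) goes to the
lexicographically smallest gene id.

The counting unit is the single read — each mate classified independently —
with pair-collapsed fragment counting available (`count_unit: fragment`,
mates merged by query name, strand taken from the first mate). MAPQ
threshold defaults to 1 (≥ 1 passes); secondary/supplementary/unmapped
records are always skipped. CIGAR N splits aligned blocks; D extends the
current block; I/S/H/P consume no reference.

Transcription strand: under `fr_firststrand` (dUTP chemistry) the first
mate aligns antisense to the transcript, so first-mate strand is flipped and
second-mate strand taken as-is; `fr_secondstrand` mirrors this; `unstranded`
yields unknown, which orientation accounting treats as sense.

The production classifier (interval trees + bisection on sorted disjoint
intervals) is validated against `exintron.naive`, a deliberately slow
per-base reference implementation that decides every label by set membership
of covered bases. The two routes agree on 100% of 20,000 random fragments
across 20 random toy instances in the acceptance suite.

## Expression measures

RPKM = count / (merged length / 1000) / (library size / 1e6), where library
size is *all* MAPQ-passing reads (including rRNA, mitochondrial, intergenic)
and counts are sense-orientation hits only, consistent with strand-specific
chemistry. Exonic and intronic RPKM use the same library size and their own
merged lengths, making the two directly comparable within a sample. Zero
lengths or library sizes raise instead of returning 0. Genes at exactly the
0.5 RPKM detection threshold are called expressed (inclusive bound).

Coverage: per-gene depth vectors over the concatenated merged feature, from
sense reads only. `covered_fraction` = bases with depth ≥ 1 / merged length.
Gene-body profiles cut the feature into 10 bins (remainder spread over the
leading bins), reversed for minus-strand genes so bin 1 is the biological
5' end; a conservation test checks Σ(bin mean × bin width) equals total
depth. Across-gene mean profiles weight genes equally after scaling each
profile to unit mean, so long or highly expressed genes do not dominate the
shape.

GLog: the generalized logarithm glog(x) = log2(x + sqrt(x² + 1)) — zero at
zero, strictly monotone, asymptotically log2(2x). This particular functional
form is a reconstruction of a standard variance-stabilising transform, not a
verbatim formula from any source; correlation and PCA operate on
glog(RPKM) by default with a raw-RPKM mode available.

Pearson correlation of glog(exon RPKM) vs glog(intron RPKM) is restricted
by default to genes with both feature lengths positive; degenerate variance
returns None (flagged undefined) rather than a number.

## Cross-sample comparison

Sample matrices are genes × samples of glog(RPKM) over a shared gene
universe (absent expression is 0 RPKM before transform; mismatched universes
are an error, not an implicit join). PCA is a centred SVD with a fixed sign
convention (largest-magnitude loading positive per component).

Non-poly(A) coding filter: mean(ribo) − mean(polyA) > 5 RPKM *and*
mean(ribo)/mean(polyA) > 2, both arms strict, fold change computed as the
ratio of replicate means (not mean of ratios); a poly(A)+ mean of exactly
zero passes the fold-change arm outright — no pseudocount, the rule stays
exactly testable. lncRNA filter: polyA RPKM < 0.5 (strict) and ribo RPKM
≥ 1 (inclusive), over the lncRNA biotypes only. Detection overlap is plain
set algebra over RPKM ≥ 0.5 calls. Statistical differential-expression
models are out of scope; an external DE call list (gene_id, probability)
can be consumed through a plug-point.

## Splice junctions

Junctions come from consecutive exons of annotated transcripts, keyed by
genome position (chrom, donor_end, acceptor_start) — junctions shared
between transcripts collapse to one. A read supports a junction when two
*consecutive* blocks bridge exactly the annotated intron (exact gap match,
the stricter deterministic reading) and anchor ≥ 5 bases on each side. A
read spanning two junctions counts once in the per-sample junction-read
fraction but increments both junctions. De-novo junction discovery is out
of scope.

## Synthetic data generator

Each library is an i.i.d. mixture over fragments:

| parameter | default | meaning |
|---|---|---|
| `premrna_fraction` | 0.2 | weight of unspliced pre-mRNA (the nuclear-RNA knob) among gene-derived fragments |
| `sense_fraction` | 0.82 | orientation fidelity of pre-mRNA fragments |
| `rrna_fraction` | 0.003 | rRNA carry-over (poly(A)+-like default) |
| `mito_fraction` | 0.03 | mitochondrial fragments (chrM) |
| `intergenic_fraction` | 0.025 | fragments inside intergenic intervals |
| `read_len` / `fragment_len` | 51 / 180 | paired 51-base mates at the fragment ends |
| `polyA_mode` + `leakage_rate` | off / 0.05 | poly(A)+ selection: designated non-poly(A) genes down-weighted to the leakage rate |
| expression profile | log-normal, 2^N(1, 1.5) | per-gene abundance spanning several orders of magnitude |

Mature fragments are drawn uniformly along the spliced transcript and mapped
back with N-split CIGARs; pre-mRNA fragments uniformly along the unspliced
gene span; rRNA fragments from a dedicated rRNA-biotype gene; mitochondrial
and intergenic fragments uniformly in their spaces. Orientation flips are
applied per *fragment* (both mates carry the same cDNA strand) and to
pre-mRNA fragments only — mature mRNA keeps its true orientation, which is
what makes the classified intronic sense fraction estimate the parameter.
Reads are emitted as already-aligned SAM (alignment itself is outside the
pipeline's scope; FASTQ export exists but is untested against aligners),
MAPQ fixed at 60, deterministic under the seed. Every read carries a truth
row (source gene, class, strand, spanned junctions).

`expected_class_fractions` is the closed-form oracle: pre-mRNA mate
positions are integer-uniform, so the probability a mate lies completely
inside an intron is an exact ratio of interval counts, evaluated per gene
with boolean position arrays and mixed with the class/gene weights.
`with_variance=True` additionally returns the exact standard deviation of
the measured intronic read fraction, computed per fragment because mates of
one fragment are correlated. A calibration check (30 independent
seeds) gives z-scores with mean ≈ 0 and sd ≈ 1.00, i.e. the 3σ acceptance
band is exact — and therefore stochastically fails about 1% of runs by
construction; that is the honest behaviour of a calibrated statistic, not a
defect.

What the generator does *not* emulate: sequencing errors and quality
scores, PCR duplicates, GC/length bias, multi-mapping ambiguity,
alternative isoforms (one transcript per gene in generated references;
multi-transcript aggregation is exercised through hand-written GTF
fixtures), overlapping genes, and fragment-length variation (fixed length,
which keeps the mixture oracle exact). Passing tests therefore demonstrate
correctness of the counting semantics and estimator behaviour under the
stated generative model, not robustness to alignment artefacts in real
libraries.

## Problem sizes

The validation scenarios run at desk scale, chosen to make binomial error
bands tight while keeping the whole acceptance pass around three minutes on
one CPU: 20 toy instances × 1,000 fragments for oracle agreement; 200,000
reads per point on the pre-mRNA grid {0, 0.2, 0.4, 0.7, 1.0}; 160,000 reads
(≈ 90,000 intronic) for sense-fraction recovery; 540 genes × 1,000,000 reads
× 2 replicates × 2 conditions for the planted non-poly(A) screen; 500,000
reads per replicate for reproducibility. The six-condition study in
`analysis/` uses 100,000 reads per replicate on a 40-gene reference — the
condition knobs (pre-mRNA weights 0.07–0.72, sense fidelity 0.70–0.90)
mirror the qualitative contrasts between poly(A)+/rRNA-depleted libraries
on TRIzol/silica-column/cytoplasmic/nuclear inputs.

## Known limitations

* Intergenic space is the complement of gene spans; annotations with genes
  nested inside other genes' introns shrink intergenic space accordingly.
* rRNA detection is annotation-biotype based; libraries aligned without an
  rRNA-bearing annotation will report rRNA reads as ordinary exonic hits.
* `unstranded` protocol collapses orientation to sense; sense/antisense
  splits are then not meaningful.
* The per-base reference classifier is O(genome) in memory and intended for
  toy instances only.
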