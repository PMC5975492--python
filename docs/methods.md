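# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `chlorotrace`. Coordinates are 1-based inclusive throughout
(GenBank convention); conversion to 0-based half-open happens only when BED
is emitted.

## Synthetic study system

The synthetic-data generator defines the conditions under which everything
else is validated.

**Genome model.** A circular quadripartite sequence LSC + IRa + SSC + IRb
with IRb exactly the reverse complement of IRa. Region GC defaults are the
*Populus* plastome values (LSC 34.47%, IR 41.97%, SSC 30.54%). Bases are
i.i.d. within a region — no genes, no tandem repeats beyond chance, no
codon structure. The study-scale instance used by the acceptance script is
LSC 10 kb, IR 3 kb, SSC 2 kb (18 kb total), a deliberate ~1:8.7 scale-down
of the ~157 kb plastome that preserves the region proportions and every
qualitative phenomenon (IR collapse, junction ambiguity, boundary
detection) while keeping a pure-Python pipeline fast; unit tests use a
3.6 kb instance.

**Trio model.** Variants are planted in four transmission classes: shared
(all three clones), mother-private (mother and offspring — the offspring
genome *is* the maternal genome plus de novo edits), father-private
(father only), and offspring de novo. Defaults for the acceptance runs:
10 shared, 5 + 5 parent-private, 2 de novo, half SNPs and half 1–10 bp
InDels, all in single-copy regions. Planting rules that keep the truth
table unambiguous:

- positions at least 20 bp apart (planted edits never interact);
- no variant inside or adjacent to a homopolymer of 5+ bases, and InDels
  are stored left-aligned, so each edit has exactly one normalized
  representation;
- a 150 bp margin from region boundaries, so junction k-mer context is
  never disturbed;
- IR variants (off by default, since genotype-differing loci are expected
  in single-copy regions) are SNPs only, planted in IRa and mirrored as
  the complementary base at the mirrored IRb position — IR symmetry is an
  invariant of every generated genome. InDels in the IR would require
  coordinated double edits that shift the mirror coordinate frame
  mid-edit; restricting IR planting to SNPs keeps the truth exact.

**Read model.** Fragment starts uniform on the circle (reads may span the
origin), insert length normal (default 300 ± 30), read 2 the reverse
complement of the fragment end, mate order randomized, i.i.d. substitution
errors at a configurable rate, a configurable fraction of pairs duplicated
verbatim, and constant Phred-35 qualities. The model deliberately omits
quality-score decay along the read, indel sequencing errors, optical
duplicates and GC-coverage bias; passing tests therefore demonstrate
correctness of the pipeline's logic, not robustness to every real-data
artifact. Error/insert parameters are explicit configuration, not
inferences about any particular instrument.

**Split reads.** Every w-bp window at s-bp steps (defaults w=100, s=1);
linear mode yields L−w+1 fragments, circular mode L.

All generators are pure functions of (arguments, seed).

## Read preparation and genome-size estimation

Trimming scans from the 3′ end and truncates at the first base with
quality below the threshold (default Phred 20); a pair is dropped when
either mate falls below 30 bp. Duplicate removal treats a pair as
duplicate iff both mates are sequence-identical (first occurrence kept) —
alignment positions are not consulted.

K-mers are canonical (the lexicographic minimum of the k-mer and its
reverse complement; k odd, so no palindromes). Canonicalization is what
makes the two IR copies — reverse complements of each other — contribute
identical k-mers.

Genome size is estimated from the k-mer spectrum as the **number of
distinct canonical k-mers above the error valley**, where the valley is
the first local minimum of the multiplicity histogram (ties toward lower
multiplicity) and the coverage peak is the spectrum mode above the valley.
Sequencing-error k-mers pile up at low multiplicity; genomic k-mers sit
near the per-copy k-mer coverage. On a quadripartite genome the estimate
converges to total length minus one IR (the IR k-mers are counted once),
which is exactly the ~83% signature the merged assemblies also show. A
"total instances ÷ coverage peak" estimator was considered and rejected:
it counts IR k-mers at double weight and converges to the full circle
length, contradicting the observed collapse. Estimation fails explicitly
(raises) when no peak separates from the error mode (roughly, coverage
below a few ×).

## Mapping

A seed-and-extend mapper: canonical 21-mers of the reference are indexed
(circular references are indexed over the sequence plus a 300 bp overhang
so origin-spanning seeds resolve); read seeds vote for (strand, implied
start), votes are folded modulo the circle length, and the best-voted
candidate (ties: leftmost reference position, then + strand) is aligned
with edlib against a ±10 bp window. Identity is **gap-compressed**
(mismatches + number of indel runs, over the read length), so a 10 bp
InDel costs one difference, not ten; a read maps iff identity ≥ 0.95 —
mirroring the 95%-identity feasibility threshold used for reference
selection. One best alignment per read is reported: reads from the IR
therefore map deterministically to the leftmost (IRa) copy, the same
collapse real short-read mappers exhibit, which is why IR variant calls
are interpreted via the comparison strategy.

Pair extraction keeps a pair when at least one mate maps (a both-mates
mode exists). Depth is per-base from CIGAR reference spans, with circular
wrap-around; zero-coverage runs are merged into gap intervals.

## Assembly

A strand-canonical de Bruijn graph: nodes are canonical k-mers with
multiplicity ≥ `min_count`; **edges carry their own evidence** as
canonical (k+1)-mers, so two nodes that merely overlap by k−1 bases are
not linked unless a read spans the junction (without this, spurious
junctions shatter small-k graphs). Unitigs are maximal non-branching
paths, emitted once in canonical orientation, deterministically ordered
(longest first, then lexicographic); isolated simple cycles — a
repeat-free circular genome assembles into one — are broken at their
smallest k-mer. There is no tip clipping or bubble popping: instead, the
multiplicity floor is chosen from the data. At realistic depth (50×, 1%
error) the same error recurs at the same site often enough that a fixed
floor of 2 leaves error branch points; the pipeline therefore sets
`min_count` to the k-mer spectrum's error valley + 1 per dataset (the
standard coverage-cutoff choice), falling back to 2 when no valley exists
(error-free data). The multi-k sweep (defaults 25/31/41; the full odd
19–63 sweep is supported) records per-k failures without aborting.

On a quadripartite genome the unitigs are, structurally, an LSC piece, a
single collapsed IR piece and an SSC piece, with k−1 overhangs across the
junctions — total assembled bases ≈ total − IR.

## Evaluation metrics and selection

Nx uses the "first reaches ≥ x% of totalSum" convention and Lx is the
contig count in that prefix. CoverRatio anchors each contig to the
reference (k-mer diagonal blocks bridged across ≤100 bp interruptions,
edlib-scored, best collinear chain; chain ties resolve to the leftmost
reference locus then + strand — the IR-collapse tie-break again) and
measures the union of anchored reference intervals. A contig whose chained
anchors imply loci more than 1 kb apart is flagged misassembled and
excluded from coverage. Mismatches per 100 kbp come from anchor identities
over aligned bases.

Screening keeps assemblies with total bases above 80% of the reference
length and fewer than 100 contigs — at a 157 kb reference these are
literally the ">126 kbp, <100 contigs" thresholds, expressed as a fraction
so toy genomes exercise the same rule. Optimum selection implements both
rules: plain argmax-N50 (ties: higher CoverRatio, fewer contigs, first
seen), and the coverage-sensitive two-branch rule that restricts to
candidates with CoverRatio > 0.85 when any exceeds it and otherwise falls
back to plain argmax-N50.

## Merging and IR correction

Each contig is oriented by its best anchor chain (reverse-complemented if
the chain is on −), trimmed to its collinear span (unitig overhangs into
the far IR copy are non-collinear and drop out), and projected
column-by-column onto reference coordinates via a global edlib alignment.
Contigs whose layouts overlap by ≥ `min_overlap` columns at ≥ 99%
agreement chain into super contigs; each output column is decided by
majority vote over the contributing contigs, with ties (including
base-vs-deletion ties) resolved to the reference base — the only situation
in which merging can introduce a base absent from every contig. Insertions
are voted the same way per junction. The pipeline sets `min_overlap` to
min(k)−1 because adjacent unitigs from a k-DBG overlap by exactly k−1
bases; the API default of 100 suits contigs from independent assemblies
with staggered breakpoints.

Quadripartite structure is detected as the maximal pair of disjoint
intervals (X before Y) on the doubled circle where revcomp(Y) matches X at
≥ 99% identity and length ≥ `min_ir` (1 kb at real scale, configurable to
100 bp for toys; the SSC must exceed k + 50 bp for the two IR blocks to
separate); the longer flanked single-copy stretch is LSC, and the call is
reported on the canonical rotation (LSC first). Detection is invariant
under rotation and strand flip of the input circle.

IRb completion takes the merged core (LSC+IRa+SSC plus any IRb stub),
boundaries projected from the reference through the alignment (so clone
InDels shift them correctly), verifies any assembled IRb stub against
revcomp(IRa) at ≥ 99.5% identity (assembled bases are kept; conflicts
refuse completion with coordinates), and appends the missing tail as the
reverse complement of the corresponding IRa bases. The completion report
records which interval was inferred rather than assembled.

## Variant discovery and reconciliation

**Comparison strategy.** Maximal exact matches ≥ 20 bp between a clone
assembly and the reference are chained collinearly (maximum total anchor
length, ties leftmost); anchor overlaps (up to k−1 around InDels) are
trimmed; inter-anchor gaps are aligned globally with affine-gap scoring
(match +1, mismatch −1, gap open −2, gap extend −1; Biopython
`PairwiseAligner`); columns become SNPs, query-only runs insertions,
reference-only runs deletions, all anchored and left-normalized.
Comparison fails explicitly when the chain covers under 50% of the
reference.

**Mapping strategy.** Per-dataset pileup from the mapper's alignments
under a haploid organelle model: a call needs depth ≥ 10 and alt fraction
≥ 0.8; alleles between 0.2 and 0.8 are returned as heteroplasmy suspects,
flagged but never genotyped. Per-clone cleaning: a locus (by position) is
poor-repeatability when called in fewer than 90% of that clone's datasets
(configurable; with fewer than two datasets repeatability is undefined and
skipped with a warning); positions whose datasets disagree on the
reference allele are inconsistent; loci in homopolymers ≥ 5 bp, in
low-complexity windows (dinucleotide Shannon entropy < 1.0 bits over
20 bp) or with InDels > 5 bp are context-flagged and kept only when the
comparison strategy confirms them.

**Integration.** Loci merge by (position, ref allele, alt allele) after
normalization. Genotypes come from the comparison strategy wherever it
reported the locus anywhere (it covers every clone genome-wide); mapping
fills in only comparison-absent loci. One deliberate rule deserves
emphasis: per-read unit-cost alignment can split a long InDel into
several smaller ones scattered over a window as wide as the InDel itself
(co-optimal paths), and such records can never unify with the comparison
record by allele identity. Mapping-only records whose reference span
overlaps a comparison record's span — widened by the comparison InDel's
own length on both sides — are therefore absorbed by the comparison
record. Same-position records with genuinely different alleles are kept
separately and flagged for review.

**Annotation.** Region from the quadripartite boundaries; CDS SNPs
translated with the plastid/bacterial genetic code (table 11) into
synonymous / missense / nonsense; CDS InDels labeled frameshift (length
change not divisible by 3) or inframe; non-CDS loci labeled intron (inside
a gene) or upstream/downstream of the nearest gene, strand-aware. The gene
model is an input (GFF3 or constructed features); de novo annotation is
out of scope.

**Trio classification.** Each fully genotyped locus is classed by pairwise
equality: identical, mother=father (offspring de novo), father=offspring,
mother=offspring, or all-distinct; loci with missing genotypes are
excluded and counted. The verdict is maternal iff the offspring equals the
mother at every parent-informative locus (paternal for the mirror image,
inconsistent otherwise); de novo loci are listed separately and do not
break the verdict. Note that both mother=offspring *and*
father=offspring classes arise under purely maternal transmission — the
latter are the mother's private mutations, at which the offspring carries
the (pre-mutation) allele the father also carries only when transmission
preceded the mutation; in the simulator mother-private variants are
inherited by the offspring, so father=offspring loci do not occur in
maternal simulations, and their presence in real data reflects somatic
divergence of clonally propagated parents.

No multiple-testing control is applied anywhere: all calls are rule-based
thresholds, not hypothesis tests.

## Numerical and degenerate-input choices

- Ties are total everywhere randomness is absent: vote ties (leftmost,
  then + strand), chain ties (leftmost locus, then +), selection ties
  (CoverRatio, then contig count, then first seen), consensus ties
  (reference base), unitig ordering (longest, then lexicographic), cycle
  breaking (smallest k-mer).
- Empty inputs are values, not errors, wherever that is meaningful: an
  empty read dataset assembles to an empty graph, extraction of an empty
  dataset warns and reports ratio 0, an unmappable read returns
  `mapped=False`.
- Hard failures are reserved for contract violations (even k, window
  longer than the sequence, k above read length, boundaries out of order)
  and for states the science cannot interpret (no spectrum peak, no
  inverted repeat, comparison chain below half the reference,
  IRb-vs-IRa conflict above tolerance).

## Problem sizes

The default test and acceptance configuration — 18 kb genome, 4,500 read
pairs (~50×) per dataset, two datasets per clone, three k values — was
chosen so the whole suite exercises every stage, including the 1%-error
arm, in about a minute and a half of pure-Python compute; the algorithms
themselves have no scale assumptions beyond memory for the k-mer tables,
and the k sweep extends to the full odd 19–63 range unchanged.

## Known limitations

- The read simulator's error model is substitution-only with flat
  qualities; quality-aware trimming is exercised by constructed cases
  rather than by the simulator.
- The assembler resolves no repeats beyond the IR collapse it is designed
  to exhibit; genomes with long non-IR repeats would fragment.
- The mapper reports one best alignment, has no paired-end rescue, and no
  quality-aware scoring.
- Merging assumes a colinear, near-identical reference guide; structural
  rearrangements between clone and reference (e.g. SSC orientation flips)
  are not resolved — flip-isomers are treated as equivalent by comparison
  code rather than normalized.
- Heteroplasmy is flagged, never quantified.
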