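# chlorotrace

Reference-assisted chloroplast genome construction and mother-to-offspring
cpDNA variant transmission analysis, as a self-contained, fully tested
Python pipeline exercised end-to-end on synthetic data.

## The problem

Land-plant chloroplast genomes (cpDNA, ~156–157 kbp in *Populus*) are
circles with a quadripartite layout: a large single-copy region (LSC,
~84 kbp) and a small single-copy region (SSC, ~16 kbp) separated by a pair
of inverted repeats (IRa, IRb, ~27 kbp each) with IRb the reverse
complement of IRa at near-100% identity. Because organelle genomes are
maternally inherited in angiosperms, comparing the chloroplast genomes of a
full-sib family — mother, father, and F1 offspring — at single-base
resolution reveals how cpDNA variants are transmitted, information directly
useful in hybrid tree breeding.

Building those genomes from whole-genome shotgun short reads runs into a
characteristic obstacle: short-read assemblers and k-mer genome-size
estimators count the two near-identical IR copies once (**IR collapse**),
so assemblies and size estimates converge to LSC + IRa + SSC — about 82–83%
of the circle — and the second IR must be restored afterwards.

`chlorotrace` implements the whole four-step construction strategy
(**Simulation → Assembly → Merging → Correction**) plus the downstream
hybrid variant analysis:

1. **Simulation** (`chlorotrace.simulate`) — quadripartite genomes with
   region-specific GC content, mutated trios with a planted-variant truth
   table (maternal inheritance as ground truth), Illumina-like paired-end
   reads, and deterministic split-read datasets.
2. **Read preparation** (`chlorotrace.readprep`) — 3′-end quality trimming,
   exact duplicate-pair removal, canonical k-mer histograms, and
   spectrum-based genome-size estimation.
3. **Mapping** (`chlorotrace.mapping`) — a seed-and-extend read mapper for
   cpDNA read extraction, mappability checks, per-base depth, and pileup
   input (SAM/BEDGRAPH/BED output).
4. **Assembly** (`chlorotrace.assembly`) — a strand-canonical de Bruijn
   unitig assembler with (k+1)-mer edge evidence and a multi-k sweep.
5. **Evaluation** (`chlorotrace.metrics`) — num/totalSum/mean/max, the
   Nx/Lx family (N80/N50/N20, L80/L50/L20), reference genome fraction
   (CoverRatio), mismatches per 100 kbp, misassembly flagging, screening,
   and the two optimum-assembly selection rules.
6. **Merging & correction** (`chlorotrace.merge`) — reference-guided
   contig merging with per-column majority voting, quadripartite-structure
   detection by maximal inverted-repeat matching, and IRb completion from
   the assembled IRa.
7. **Variants** (`chlorotrace.variants`) — whole-genome comparison calling
   (exact-match anchor chaining + affine-gap alignment of inter-anchor
   gaps), haploid pileup calling, problematic-variant filtering
   (repeatability, reference-allele consistency, homopolymer /
   low-complexity / large-InDel context), integration of the two
   strategies, region and coding-effect annotation (plastid code,
   table 11), and trio classification.

Notation used throughout: for contigs sorted longest-first, **Nx** is the
length of the contig at which the cumulative length first reaches x% of
the total assembly size and **Lx** is the number of contigs in that
prefix; **CoverRatio** is the fraction of reference bases covered by at
least one aligned contig block; a trio verdict is **maternal** iff the
offspring genotype equals the mother's at every locus where the parents
differ (offspring de novo mutations are reported separately and do not
break the verdict).

## Worked example

`examples/` contains one short script per capability. Running
`python examples/04_assemble_and_merge.py` (a 3.6 kb toy genome, ~50×
error-free reads from the simulated mother clone) prints:

```
mother.Set1.k25: 3 contigs, 3100 bp, N50 2052
mother.Set1.k31: 3 contigs, 3124 bp, N50 2064
mother.Set1.k41: 3 contigs, 3164 bp, N50 2084

3/3 assemblies pass screening (total bases > 80% of reference, < 100 contigs)
merged core super contig spans reference 1-3040
IRb bases inferred from IRa: interval (3045, 3604)
reconstructed genome == true mother genome: True
```

The three contigs per k are the LSC, collapsed-IR and SSC unitigs; merging
them against the reference guide yields a single super contig spanning
LSC+IRa+SSC (positions 1–3040 of the 3600 bp reference — the IR-collapse
signature), and the missing IRb tail (positions 3045–3604 of the
reconstruction) is inferred as the reverse complement of the assembled
IRa, after which the reconstruction equals the true clone genome
base-for-base. `python examples/05_trio_variants.py` then recovers all 9
planted variants with no false calls and prints the verdict
`maternal (4/4 informative loci; 1 de novo offspring loci)`.

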