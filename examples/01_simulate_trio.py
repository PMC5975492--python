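"""Simulate a quadripartite chloroplast genome, a mother/father/offspring
trio with maternal cpDNA inheritance, and an Illumina-like read dataset.

The trio generator plants variants of four transmission classes (shared,
mother-private, father-private, offspring de novo) and returns a truth
table; the offspring genome is the maternal genome plus the de novo edits.
"""

import chlorotrace as ct

reference = ct.build_genome(2000, 600, 400, seed=7, name="ref")
print(f"reference: {reference.length} bp "
      f"(LSC {reference.lsc_end}, IR {reference.ir_length}, "
      f"SSC {len(reference.ssc)})")
print(f"IRb == revcomp(IRa): {reference.ir_symmetric()}")

spec = ct.TrioSpec(n_shared_vs_reference=4, n_mother_private=2,
                   n_father_private=2, n_de_novo_offspring=1, seed=3)
mother, father, offspring, truth = ct.make_trio(reference, spec)
print("\nplanted truth table:")
print(truth[["pos", "ref", "alt", "vtype", "var_class", "region"]]
      .to_string(index=False))

reads = ct.simulate_reads(mother, n_pairs=900, read_length=100,
                          error_rate=0.01, duplicate_rate=0.05, seed=1,
                          dataset_id="mother.Set1")
print(f"\nsimulated {reads.n_pairs} read pairs from the mother "
      f"(~{2 * 100 * 900 // reference.length}x coverage, "
      f"1% error, 5% duplicates)")
dedup, frac = ct.dedup_pairs(reads)
print(f"duplicate pairs removed: {frac:.3f} "
      f"(expected ~ 0.05/1.05 = {0.05 / 1.05:.3f})")
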