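"""Split-read mapping, chloroplast-read extraction from a mixed pool, and
per-base depth.

The deterministic split-read dataset (every 100-bp window at 1-bp steps)
checks reference mappability; extraction pulls cpDNA pairs out of a
simulated whole-genome pool the way real chloroplast reads are isolated
from total-DNA sequencing.
"""

import numpy as np

import chlorotrace as ct
from chlorotrace.simulate import ReadDataset, random_sequence

genome = ct.build_genome(2000, 600, 400, seed=7)
index = ct.build_index(genome, seed_k=21)

frags = ct.split_reads(genome, window=100, step=1)
mapped = sum(ct.map_read(f, index).mapped for f in frags[::10])
print(f"split reads: {len(frags)} fragments; "
      f"self-mapping of every 10th: {mapped}/{len(frags[::10])}")

# 95:5 nuclear:chloroplast read pool
rng = np.random.default_rng(0)
nuclear_decoy = random_sequence(20_000, 0.37, rng)
cp = ct.simulate_reads(genome, 50, seed=1, dataset_id="cp")
nuc = ct.simulate_reads(nuclear_decoy, 950, seed=2, dataset_id="nuc")
pool = ReadDataset("pool", cp.pairs + nuc.pairs, 100)
extracted, ratio = ct.extract_cp_reads(pool, index)
print(f"cpDNA read extraction: {100 * ratio:.1f}% of {pool.n_pairs} pairs "
      "(5% of the pool is chloroplast)")

alignments = ct.map_dataset(extracted, index)
profile = ct.depth_profile(alignments, genome.length)
print(f"depth over the reference: min {profile.min}, "
      f"mean {profile.mean:.1f}, max {profile.max}; "
      f"zero-coverage intervals: {len(profile.zero_intervals)}")
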