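import pytest

import chlorotrace as ct
from chlorotrace.simulate import ReadDataset, ReadPair


@pytest.fixture(scope="session")
def toy_genome():
    """Small quadripartite genome: LSC 2000, IR 600, SSC 400 (3600 bp)."""
    return ct.build_genome(2000, 600, 400, seed=7)


@pytest.fixture(scope="session")
def toy_trio(toy_genome):
    spec = ct.TrioSpec(
        n_shared_vs_reference=4,
        n_mother_private=2,
        n_father_private=2,
        n_de_novo_offspring=1,
        seed=3,
    )
    return ct.make_trio(toy_genome, spec)


@pytest.fixture(scope="session")
def toy_reads(toy_genome):
    """~50x error-free paired reads of the toy genome."""
    return ct.simulate_reads(toy_genome, n_pairs=900, read_length=100,
                             seed=5, dataset_id="toy.1")


@pytest.fixture(scope="session")
def toy_index(toy_genome):
    return ct.build_index(toy_genome)


def dataset_from_reads(seqs, dataset_id="manual"):
    """Wrap plain read sequences into a ReadDataset (arbitrary pairing)."""
    if len(seqs) % 2:
        seqs = list(seqs) + [seqs[-1]]
    pairs = [
        ReadPair(a, "D" * len(a), b, "D" * len(b), f"{dataset_id}:{i}")
        for i, (a, b) in enumerate(zip(seqs[::2], seqs[1::2]))
    ]
    rl = max((len(s) for s in seqs), default=0)
    return ReadDataset(dataset_id=dataset_id, pairs=pairs, read_length=rl)
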