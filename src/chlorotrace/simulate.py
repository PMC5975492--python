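"""Synthetic data generation: quadripartite genomes, mutated trios,
Illumina-like paired-end reads, and deterministic split-read datasets.

Every generator is a pure function of its inputs and the seed, so all
downstream stages of the pipeline can be tested without any external data.
The trio generator encodes maternal organelle inheritance as ground truth:
the offspring genome is the maternal genome plus a small number of de novo
edits, and a truth table of every planted variant is returned alongside the
sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genome import QuadripartiteGenome, revcomp

# Region GC fractions of the Populus plastome: LSC 34.47%, IR 41.97%,
# SSC 30.54%.
DEFAULT_GC = {"LSC": 0.3447, "IR": 0.4197, "SSC": 0.3054}

#: Planting margin from region boundaries, so junction k-mer context stays
#: unambiguous for assembly and alignment.
BOUNDARY_MARGIN = 150

#: Minimum spacing between planted variants (anchors never overlap).
MIN_SPACING = 20

_BASES = np.array(list("ACGT"))


def random_sequence(n: int, gc: float, rng: np.random.Generator) -> str:
    """Random DNA of length ``n`` with expected GC fraction ``gc``."""
    if not 0 < gc < 1:
        raise ValueError("gc fraction must be in (0, 1)")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def build_genome(
    length_lsc: int,
    length_ir: int,
    length_ssc: int,
    gc_by_region: dict[str, float] | None = None,
    seed: int = 0,
    name: str = "sim",
) -> QuadripartiteGenome:
    """Build a random circular quadripartite genome.

    The genome is ``LSC + IRa + SSC + IRb`` with IRb exactly the reverse
    complement of IRa.  Total length is ``length_lsc + 2*length_ir +
    length_ssc``.  The same seed always yields the identical sequence.
    """
    for nm, v in (("length_lsc", length_lsc), ("length_ir", length_ir),
                  ("length_ssc", length_ssc)):
        if v <= 0:
            raise ValueError(f"{nm} must be positive, got {v}")
    gc = dict(DEFAULT_GC)
    if gc_by_region:
        gc.update(gc_by_region)
    if length_ir < 42:  # 2 * default seed k-mer size
        warnings.warn(
            "IR shorter than twice the default k-mer size; the inverted "
            "repeat will be undetectable downstream",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    lsc = random_sequence(length_lsc, gc["LSC"], rng)
    ira = random_sequence(length_ir, gc["IR"], rng)
    ssc = random_sequence(length_ssc, gc["SSC"], rng)
    seq = lsc + ira + ssc + revcomp(ira)
    return QuadripartiteGenome(
        name=name,
        sequence=seq,
        lsc_end=length_lsc,
        ira_end=length_lsc + length_ir,
        ssc_end=length_lsc + length_ir + length_ssc,
    )


@dataclass(frozen=True)
class TrioSpec:
    """How many variants of each transmission class to plant in a trio.

    ``n_shared_vs_reference`` variants are planted identically in all three
    clones; parent-private variants are private to the mother (and hence
    inherited by the offspring) or to the father; de novo variants appear
    only in the offspring.  ``snp_indel_ratio`` is the fraction of planted
    variants that are SNPs; the remainder are 1-10 bp InDels.
    ``region_weights`` gives sampling weights for placing a variant in the
    single-copy regions versus the IR (IR variants are SNPs, mirrored into
    both copies so IR symmetry is preserved).
    """

    n_shared_vs_reference: int = 10
    n_mother_private: int = 5
    n_father_private: int = 5
    n_de_novo_offspring: int = 2
    snp_indel_ratio: float = 0.5
    region_weights: dict[str, float] = field(
        default_factory=lambda: {"single_copy": 1.0, "ir": 0.0}
    )
    #: allow de novo offspring variants inside the IR (negative-control only)
    de_novo_in_ir: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("n_shared_vs_reference", "n_mother_private",
                   "n_father_private", "n_de_novo_offspring"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if not 0 <= self.snp_indel_ratio <= 1:
            raise ValueError("snp_indel_ratio must be in [0, 1]")
        w = self.region_weights
        if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
            raise ValueError("region weights must be >= 0 and not all zero")


class ReadPair(NamedTuple):
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    pair_id: str


@dataclass
class ReadDataset:
    """A named collection of paired-end reads from one sequencing pass."""

    dataset_id: str
    pairs: list[ReadPair]
    read_length: int
    insert_mean: float = 0.0
    insert_sd: float = 0.0
    error_rate: float = 0.0
    duplicate_rate: float = 0.0

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def reads(self):
        """Iterate over (read_id, sequence, qualities) for both mates."""
        for p in self.pairs:
            yield p.pair_id + "/1", p.seq1, p.qual1
            yield p.pair_id + "/2", p.seq2, p.qual2


def _has_homopolymer(seq: str, start: int, end: int, run: int = 5) -> bool:
    """True if seq[start:end] (0-based) contains a homopolymer >= run."""
    window = seq[max(0, start) : min(len(seq), end)]
    count = 1
    for a, b in zip(window, window[1:]):
        count = count + 1 if a == b else 1
        if count >= run:
            return True
    return False


def _left_aligned(seq: str, pos: int, ref: str, alt: str) -> bool:
    """True iff an anchored indel at 1-based ``pos`` cannot shift left."""
    if len(ref) == len(alt):
        return True
    longer = ref if len(ref) > len(alt) else alt
    # shifting left requires the last base of the inserted/deleted run to
    # equal the anchor base
    return pos == 1 or longer[-1] != seq[pos - 1]


def _single_copy_intervals(g: QuadripartiteGenome) -> list[tuple[int, int]]:
    m = BOUNDARY_MARGIN
    return [
        (1 + m, g.lsc_end - m),
        (g.ira_end + 1 + m, g.ssc_end - m),
    ]


def _ir_interval(g: QuadripartiteGenome) -> tuple[int, int]:
    m = BOUNDARY_MARGIN
    return (g.lsc_end + 1 + m, g.ira_end - m)


def _draw_variant(
    g: QuadripartiteGenome,
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    in_ir: bool,
    snp_ratio: float,
    max_tries: int = 2000,
):
    """Draw one non-overlapping, left-aligned variant outside homopolymers."""
    seq = g.sequence
    intervals = [_ir_interval(g)] if in_ir else _single_copy_intervals(g)
    intervals = [(a, b) for a, b in intervals if b > a]
    if not intervals:
        raise ValueError("region too small for the requested planting margin")
    for _ in range(max_tries):
        lo, hi = intervals[rng.integers(len(intervals))]
        pos = int(rng.integers(lo, hi + 1))
        is_snp = in_ir or rng.random() < snp_ratio
        size = 0 if is_snp else int(rng.integers(1, 11))
        span = (pos - MIN_SPACING, pos + size + MIN_SPACING)
        if any(a <= span[1] and span[0] <= b for a, b in occupied):
            continue
        if _has_homopolymer(seq, pos - 6, pos + size + 6):
            continue
        refbase = seq[pos - 1]
        if is_snp:
            alt = str(rng.choice([b for b in "ACGT" if b != refbase]))
            ref = refbase
            vtype = "SNP"
        elif rng.random() < 0.5:  # insertion
            ins = "".join(rng.choice(_BASES, size=size))
            ref = refbase
            alt = refbase + ins
            vtype = "insertion"
            if not _left_aligned(seq, pos, ref, alt):
                continue
        else:  # deletion
            if pos + size > len(seq):
                continue
            ref = seq[pos - 1 : pos + size]
            alt = refbase
            vtype = "deletion"
            if not _left_aligned(seq, pos, ref, alt):
                continue
        occupied.append((pos, pos + size))
        return pos, ref, alt, vtype
    raise ValueError(
        "could not place the requested number of non-overlapping variants"
    )


def _apply_edits(seq: str, edits: list[tuple[int, str, str]]) -> str:
    """Apply anchored (pos, ref, alt) edits, highest position first."""
    out = seq
    for pos, ref, alt in sorted(edits, reverse=True):
        assert out[pos - 1 : pos - 1 + len(ref)] == ref, (
            f"edit ref mismatch at {pos}"
        )
        out = out[: pos - 1] + alt + out[pos - 1 + len(ref) :]
    return out


def _shift_boundary(boundary: int, edits: list[tuple[int, str, str]]) -> int:
    return boundary + sum(
        len(alt) - len(ref) for pos, ref, alt in edits if pos <= boundary
    )


def make_trio(
    reference: QuadripartiteGenome,
    spec: TrioSpec,
    mother: str = "mother",
    father: str = "father",
    offspring: str = "offspring",
) -> tuple[QuadripartiteGenome, QuadripartiteGenome, QuadripartiteGenome, pd.DataFrame]:
    """Plant variants into a reference to produce a mother/father/offspring
    trio with maternal cpDNA inheritance.

    Returns the three genomes and a truth table with one row per planted
    edit: 1-based reference position, anchored ref/alt alleles, type,
    transmission class, carrier clones and region.  SNPs planted in the IR
    are mirrored into both copies (two rows) so IR symmetry is preserved.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.region_weights
    p_ir = w.get("ir", 0.0) / (w.get("single_copy", 0.0) + w.get("ir", 0.0))

    classes = (
        ["shared"] * spec.n_shared_vs_reference
        + ["mother_private"] * spec.n_mother_private
        + ["father_private"] * spec.n_father_private
        + ["de_novo"] * spec.n_de_novo_offspring
    )
    carrier_map = {
        "shared": (mother, father, offspring),
        "mother_private": (mother, offspring),
        "father_private": (father,),
        "de_novo": (offspring,),
    }

    occupied: list[tuple[int, int]] = []
    rows = []
    for cls in classes:
        in_ir = rng.random() < p_ir
        if cls == "de_novo" and not spec.de_novo_in_ir:
            in_ir = False
        pos, ref, alt, vtype = _draw_variant(
            reference, rng, occupied, in_ir, spec.snp_indel_ratio
        )
        region = reference.region_of(pos)
        carriers = carrier_map[cls]
        rows.append((pos, ref, alt, vtype, cls, ",".join(carriers), region, False))
        if region == "IRa":
            mpos = reference.mirror_ir_position(pos)
            mref = reference.sequence[mpos - 1]
            malt = revcomp(alt)
            rows.append(
                (mpos, mref, malt, vtype, cls, ",".join(carriers), "IRb", True)
            )
            occupied.append((mpos - 1, mpos + 1))

    truth = pd.DataFrame(
        rows,
        columns=["pos", "ref", "alt", "vtype", "var_class", "carriers",
                 "region", "mirrored"],
    ).sort_values("pos", ignore_index=True)

    def _edits_for(clone: str) -> list[tuple[int, str, str]]:
        return [
            (int(r.pos), r.ref, r.alt)
            for r in truth.itertuples()
            if clone in r.carriers.split(",")
        ]

    genomes = {}
    for clone in (mother, father, offspring):
        edits = _edits_for(clone)
        seq = _apply_edits(reference.sequence, edits)
        genomes[clone] = QuadripartiteGenome(
            name=clone,
            sequence=seq,
            lsc_end=_shift_boundary(reference.lsc_end, edits),
            ira_end=_shift_boundary(reference.ira_end, edits),
            ssc_end=_shift_boundary(reference.ssc_end, edits),
        )
    return genomes[mother], genomes[father], genomes[offspring], truth


def simulate_reads(
    genome: QuadripartiteGenome | str,
    n_pairs: int,
    read_length: int = 100,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    error_rate: float = 0.0,
    duplicate_rate: float = 0.0,
    seed: int = 0,
    dataset_id: str | None = None,
) -> ReadDataset:
    """Simulate Illumina-like paired-end reads from a (circular) genome.

    Fragment start positions are uniform over the circle; read 2 is the
    reverse complement of the fragment end; substitution errors are i.i.d.
    per base; a ``duplicate_rate`` fraction of pairs is emitted twice
    verbatim (PCR-style duplicates).  Qualities encode Phred 35 throughout.
    """
    if read_length > insert_mean:
        raise ValueError("read_length must not exceed insert_mean")
    if isinstance(genome, QuadripartiteGenome):
        seq = genome.sequence
        circular = genome.circular
        src = genome.name
    else:
        seq, circular, src = genome, True, "seq"
    L = len(seq)
    if dataset_id is None:
        dataset_id = f"{src}.Set1"
    rng = np.random.default_rng(seed)
    qual = chr(35 + 33) * read_length
    doubled = seq + seq if circular else seq
    pairs: list[ReadPair] = []

    def _mutate(read: str, rng: np.random.Generator) -> str:
        n_err = rng.binomial(len(read), error_rate)
        if n_err == 0:
            return read
        positions = rng.choice(len(read), size=n_err, replace=False)
        chars = list(read)
        for i in positions:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
        return "".join(chars)

    for i in range(n_pairs):
        insert = int(round(rng.normal(insert_mean, insert_sd)))
        insert = max(read_length, min(insert, L))
        start = int(rng.integers(0, L if circular else L - insert + 1))
        frag = doubled[start : start + insert]
        r1 = frag[:read_length]
        r2 = revcomp(frag[-read_length:])
        if rng.random() < 0.5:
            r1, r2 = r2, r1
        if error_rate > 0:
            r1, r2 = _mutate(r1, rng), _mutate(r2, rng)
        pairs.append(ReadPair(r1, qual, r2, qual, f"{dataset_id}:{i}"))

    n_dup = int(round(duplicate_rate * n_pairs))
    if n_dup:
        idx = rng.choice(n_pairs, size=n_dup, replace=False)
        for j in sorted(idx):
            p = pairs[j]
            pairs.append(ReadPair(p.seq1, p.qual1, p.seq2, p.qual2,
                                  p.pair_id + ".dup"))

    return ReadDataset(
        dataset_id=dataset_id,
        pairs=pairs,
        read_length=read_length,
        insert_mean=insert_mean,
        insert_sd=insert_sd,
        error_rate=error_rate,
        duplicate_rate=duplicate_rate,
    )


def split_reads(
    genome: QuadripartiteGenome | str,
    window: int = 100,
    step: int = 1,
    circular: bool | None = None,
) -> list[str]:
    """Deterministic split-read dataset: every ``window``-bp fragment of the
    sequence at ``step``-bp offsets.

    Linear mode yields ``L - window + 1`` fragments (for step 1); circular
    mode yields ``L`` fragments, including origin-spanning ones.
    """
    if isinstance(genome, QuadripartiteGenome):
        seq = genome.sequence
        if circular is None:
            circular = genome.circular
    else:
        seq = genome
        if circular is None:
            circular = False
    L = len(seq)
    if window > L:
        raise ValueError(f"window {window} exceeds sequence length {L}")
    if circular:
        doubled = seq + seq[: window - 1]
        return [doubled[i : i + window] for i in range(0, L, step)]
    return [seq[i : i + window] for i in range(0, L - window + 1, step)]
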