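"""Lightweight k-mer seed-and-extend read mapper.

Used for cpDNA read extraction from mixed read pools, split-read mapping
feasibility checks, per-base depth profiles, and as the input to pileup
variant calling.  One best alignment is reported per read; reads from the
inverted repeat therefore map deterministically to the leftmost IR copy —
the same collapse short-read mappers exhibit on real plastomes.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np

from .genome import QuadripartiteGenome, revcomp
from .simulate import ReadDataset, ReadPair

_CIG_RE = re.compile(r"(\d+)([=XIDMSH])")

#: CIGAR ops that consume reference bases
_REF_OPS = frozenset("MDN=X")


def cigar_ref_span(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string."""
    return sum(int(n) for n, op in _CIG_RE.findall(cigar) if op in _REF_OPS)


@dataclass
class ReadAlignment:
    read_id: str
    ref_name: str
    ref_start: int  # 1-based; 0 when unmapped
    strand: str  # '+' or '-'
    cigar: str  # extended ops (=, X, I, D); '*' when unmapped
    n_mismatch: int
    mapped: bool
    edit_distance: int = 0
    identity: float = 0.0
    #: read sequence in reference orientation (reverse-complemented for '-')
    aligned_seq: str = ""


class SeedIndex:
    """Exact-match lookup from canonical seed k-mers to reference loci.

    Circular references are indexed over ``sequence + sequence[:overhang]``
    so origin-spanning seeds are found; reported positions stay in
    ``[1, L]``.
    """

    def __init__(
        self,
        reference: QuadripartiteGenome | str,
        seed_k: int = 21,
        name: str | None = None,
        circular: bool | None = None,
        overhang: int = 300,
    ) -> None:
        if isinstance(reference, QuadripartiteGenome):
            seq = reference.sequence
            self.ref_name = name or reference.name
            self.circular = reference.circular if circular is None else circular
        else:
            seq = reference
            self.ref_name = name or "ref"
            self.circular = bool(circular)
        if seed_k > len(seq):
            raise ValueError("seed_k exceeds the reference length")
        self.seq = seq
        self.length = len(seq)
        self.seed_k = seed_k
        self.overhang = min(overhang, self.length) if self.circular else 0
        self.ext = seq + seq[: self.overhang]
        index: dict[str, list[tuple[int, int]]] = {}
        n = self.length if self.circular else self.length - seed_k + 1
        for i in range(n):
            km = self.ext[i : i + seed_k]
            rc = revcomp(km)
            if km <= rc:
                index.setdefault(km, []).append((i, 1))
            else:
                index.setdefault(rc, []).append((i, -1))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        """Hits for a (forward-oriented) k-mer: (0-based pos, strand ±1)
        where strand is relative to the query k-mer's orientation."""
        rc = revcomp(kmer)
        if kmer <= rc:
            canon, orient = kmer, 1
        else:
            canon, orient = rc, -1
        return [(pos, s * orient) for pos, s in self._index.get(canon, [])]


def build_index(
    reference: QuadripartiteGenome | str, seed_k: int = 21, **kw
) -> SeedIndex:
    return SeedIndex(reference, seed_k=seed_k, **kw)


def map_read(
    read: str,
    index: SeedIndex,
    min_identity: float = 0.95,
    read_id: str = "read",
    seed_stride: int = 4,
    band: int = 10,
) -> ReadAlignment:
    """Map one read by seed voting plus banded edlib extension.

    Candidate loci are scored by seed votes (best-voted implied start wins;
    ties broken by leftmost position, then + strand); the candidate window
    is aligned with edlib and the read is mapped iff the alignment identity
    is at least ``min_identity``.
    """
    k = index.seed_k
    L = len(read)
    unmapped = ReadAlignment(read_id, index.ref_name, 0, "+", "*", 0, False)
    if L < k:
        return unmapped
    votes: Counter[tuple[int, int]] = Counter()
    offsets = list(range(0, L - k + 1, seed_stride))
    if offsets[-1] != L - k:
        offsets.append(L - k)
    for o in offsets:
        for pos, strand in index.lookup(read[o : o + k]):
            if strand == 1:
                start = pos - o
            else:
                start = pos - (L - o - k)
            if index.circular:
                start %= index.length  # fold origin-equivalent starts
            votes[(strand, start)] += 1
    if not votes:
        return unmapped
    best = max(votes.items(), key=lambda kv: (kv[1], -kv[0][1], kv[0][0]))
    (strand, start), _ = best
    query = read if strand == 1 else revcomp(read)
    lo = max(0, start - band)
    hi = min(len(index.ext), start + L + band)
    if hi - lo < L:
        if index.circular:
            lo = max(0, min(lo, len(index.ext) - L - band))
            hi = len(index.ext)
        else:
            lo, hi = max(0, lo), min(len(index.ext), hi)
    window = index.ext[lo:hi]
    res = edlib.align(query, window, task="path", mode="HW")
    ed = res["editDistance"]
    if ed < 0 or not res["locations"]:
        return unmapped
    t_start = res["locations"][0][0]
    cigar = res["cigar"] or "*"
    ref_start0 = lo + t_start
    if index.circular:
        ref_start0 %= index.length
    ops = _CIG_RE.findall(cigar)
    n_mm = sum(int(n) for n, op in ops if op == "X")
    # one InDel run counts as a single difference (gap-compressed
    # identity), so a short InDel does not unmap an otherwise exact read
    n_gap_runs = sum(1 for _, op in ops if op in "ID")
    identity = 1.0 - (n_mm + n_gap_runs) / L
    return ReadAlignment(
        read_id=read_id,
        ref_name=index.ref_name,
        ref_start=ref_start0 + 1,
        strand="+" if strand == 1 else "-",
        cigar=cigar,
        n_mismatch=n_mm,
        mapped=identity >= min_identity,
        edit_distance=ed,
        identity=identity,
        aligned_seq=query,
    )


def map_dataset(
    dataset: ReadDataset, index: SeedIndex, min_identity: float = 0.95
) -> list[ReadAlignment]:
    """Map every read (both mates) of a dataset; deterministic order."""
    return [
        map_read(seq, index, min_identity=min_identity, read_id=rid)
        for rid, seq, _ in dataset.reads()
    ]


def extract_cp_reads(
    dataset: ReadDataset,
    index: SeedIndex,
    min_identity: float = 0.95,
    require_both: bool = False,
) -> tuple[ReadDataset, float]:
    """Extract the chloroplast read pairs from a (possibly mixed) dataset.

    A pair is retained iff at least one mate maps to the chloroplast
    reference (``require_both=True`` demands both mates).  Returns the
    extracted dataset and the extraction ratio.
    """
    kept = []
    for p in dataset.pairs:
        a1 = map_read(p.seq1, index, min_identity=min_identity,
                      read_id=p.pair_id + "/1")
        a2 = map_read(p.seq2, index, min_identity=min_identity,
                      read_id=p.pair_id + "/2")
        hit = (a1.mapped and a2.mapped) if require_both else (a1.mapped or a2.mapped)
        if hit:
            kept.append(p)
    n = len(dataset.pairs)
    if n == 0:
        warnings.warn("empty dataset: extraction ratio reported as 0",
                      stacklevel=2)
        ratio = 0.0
    else:
        ratio = len(kept) / n
    out = ReadDataset(
        dataset_id=dataset.dataset_id + ".cp",
        pairs=kept,
        read_length=dataset.read_length,
        insert_mean=dataset.insert_mean,
        insert_sd=dataset.insert_sd,
        error_rate=dataset.error_rate,
        duplicate_rate=dataset.duplicate_rate,
    )
    return out, ratio


@dataclass
class DepthProfile:
    depth: np.ndarray  # per-base coverage, index 0 == position 1
    min: int
    mean: float
    max: int
    zero_intervals: list[tuple[int, int]]  # 1-based inclusive


def depth_profile(
    alignments: list[ReadAlignment],
    ref_length: int,
    circular: bool = True,
) -> DepthProfile:
    """Per-base coverage from alignments, plus merged zero-coverage gaps."""
    depth = np.zeros(ref_length, dtype=np.int64)
    for aln in alignments:
        if not aln.mapped:
            continue
        span = cigar_ref_span(aln.cigar)
        s = aln.ref_start - 1
        e = s + span
        if e <= ref_length:
            depth[s:e] += 1
        elif circular:
            depth[s:] += 1
            depth[: e - ref_length] += 1
        else:
            raise ValueError(
                f"alignment at {aln.ref_start} (+{span}) runs past a "
                "non-circular reference end"
            )
    zero = []
    in_gap = False
    for i, d in enumerate(depth):
        if d == 0 and not in_gap:
            start = i + 1
            in_gap = True
        elif d != 0 and in_gap:
            zero.append((start, i))
            in_gap = False
    if in_gap:
        zero.append((start, ref_length))
    return DepthProfile(
        depth=depth,
        min=int(depth.min()),
        mean=float(depth.mean()),
        max=int(depth.max()),
        zero_intervals=zero,
    )
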