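"""Read QC and k-mer genome-size estimation.

Covers the pre-assembly steps of the pipeline: 3'-end quality trimming,
exact duplicate-pair removal, canonical k-mer histogram construction, and
k-mer-spectrum genome-size estimation.  On a quadripartite genome the size
estimate converges to LSC + IRa + SSC (one IR copy collapses), because the
canonical k-mers of the two inverted-repeat copies are identical.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .genome import revcomp
from .simulate import ReadDataset, ReadPair


class SizeEstimationError(RuntimeError):
    """Raised when no coverage peak is separable from the error mode."""


def trim_low_quality_ends(
    dataset: ReadDataset,
    quality_threshold: int = 20,
    min_length: int = 30,
) -> ReadDataset:
    """Trim low-quality 3' ends; drop pairs where either mate gets too short.

    Each read is truncated at the first position, scanning from the 3' end,
    whose Phred quality falls below ``quality_threshold``.
    """

    def _trim(seq: str, qual: str) -> tuple[str, str]:
        end = len(qual)
        while end > 0 and ord(qual[end - 1]) - 33 < quality_threshold:
            end -= 1
        return seq[:end], qual[:end]

    kept = []
    for p in dataset.pairs:
        s1, q1 = _trim(p.seq1, p.qual1)
        s2, q2 = _trim(p.seq2, p.qual2)
        if len(s1) >= min_length and len(s2) >= min_length:
            kept.append(ReadPair(s1, q1, s2, q2, p.pair_id))
    return ReadDataset(
        dataset_id=dataset.dataset_id,
        pairs=kept,
        read_length=dataset.read_length,
        insert_mean=dataset.insert_mean,
        insert_sd=dataset.insert_sd,
        error_rate=dataset.error_rate,
        duplicate_rate=dataset.duplicate_rate,
    )


def dedup_pairs(dataset: ReadDataset) -> tuple[ReadDataset, float]:
    """Remove exact duplicate pairs (both mates sequence-identical).

    One representative per duplicate group is retained (the first seen).
    Returns the deduplicated dataset and the removed-pair fraction.
    Idempotent.
    """
    seen: set[tuple[str, str]] = set()
    kept = []
    for p in dataset.pairs:
        key = (p.seq1, p.seq2)
        if key in seen:
            continue
        seen.add(key)
        kept.append(p)
    n_in = len(dataset.pairs)
    frac = (n_in - len(kept)) / n_in if n_in else 0.0
    out = ReadDataset(
        dataset_id=dataset.dataset_id,
        pairs=kept,
        read_length=dataset.read_length,
        insert_mean=dataset.insert_mean,
        insert_sd=dataset.insert_sd,
        error_rate=dataset.error_rate,
        duplicate_rate=0.0,
    )
    return out, frac


def canonical_kmers(seq: str, k: int):
    """Yield canonical (strand-collapsed) k-mers of a sequence, skipping
    any window containing a non-ACGT symbol."""
    valid = set("ACGT")
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if set(km) <= valid:
            yield min(km, revcomp(km))


@dataclass
class KmerHistogram:
    """Multiplicity spectrum of canonical k-mers from a read dataset."""

    k: int
    counts: dict[int, int]  # multiplicity -> number of distinct k-mers
    n_distinct: int

    @property
    def total_instances(self) -> int:
        return sum(m * c for m, c in self.counts.items())


def kmer_histogram(dataset: ReadDataset, k: int) -> KmerHistogram:
    """Canonical k-mer multiplicity histogram over both mates of all pairs."""
    if k % 2 == 0:
        raise ValueError("k must be odd (odd k-mers have no palindromes)")
    if k > dataset.read_length:
        raise ValueError("k exceeds the read length")
    table: Counter[str] = Counter()
    for _, seq, _ in dataset.reads():
        table.update(canonical_kmers(seq, k))
    spectrum = Counter(table.values())
    return KmerHistogram(k=k, counts=dict(spectrum), n_distinct=len(table))


@dataclass
class SizeEstimate:
    estimated_size: int
    k_used: int
    coverage_peak: int
    error_valley: int


def estimate_genome_size(hist: KmerHistogram) -> SizeEstimate:
    """Estimate genome size from a k-mer spectrum.

    Sequencing-error k-mers pile up at low multiplicity; genomic k-mers form
    a peak near the per-copy k-mer coverage.  The error valley is located as
    the first local minimum of the spectrum (ties toward lower
    multiplicity); the estimate is the number of distinct canonical k-mers
    above the valley.  For a genome carrying two identical IR copies the
    estimate converges to total length minus one IR, because both copies
    contribute the same canonical k-mers.
    """
    if hist.n_distinct == 0:
        raise SizeEstimationError("empty histogram")
    max_mult = max(hist.counts)
    arr = np.zeros(max_mult + 2, dtype=np.int64)
    for m, c in hist.counts.items():
        arr[m] = c
    valley = None
    for m in range(1, max_mult + 1):
        if arr[m] <= arr[m + 1]:
            valley = m
            break
    if valley is None or valley >= max_mult:
        raise SizeEstimationError(
            "no coverage peak separable from the error mode "
            "(coverage too low?)"
        )
    peak = valley + 1 + int(np.argmax(arr[valley + 1 :]))
    if arr[peak] == 0:
        raise SizeEstimationError("no k-mer mass above the error valley")
    size = int(sum(c for m, c in hist.counts.items() if m > valley))
    if size <= 0:
        raise SizeEstimationError("estimate collapsed to zero")
    return SizeEstimate(
        estimated_size=size, k_used=hist.k, coverage_peak=peak,
        error_valley=valley,
    )
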