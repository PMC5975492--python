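"""Exact-match anchoring of a query sequence onto a reference.

Shared machinery behind contig evaluation, reference-guided merging,
inverted-repeat detection and whole-genome comparison: k-mer hits are
grouped by (strand, diagonal) into match blocks, blocks may be bridged
across small interruptions (substitutions), and block identity is scored
with edlib.  Coordinates in the public ``Anchor`` record are 1-based
inclusive, like everything else in this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .genome import revcomp


@dataclass
class Anchor:
    q_start: int  # 1-based inclusive, on the query as given
    q_end: int
    r_start: int  # 1-based inclusive, on the reference forward strand
    r_end: int
    strand: str  # '+': query matches reference; '-': query matches revcomp
    identity: float

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_start + 1

    @property
    def offset(self) -> int:
        """Implied reference offset of query position 1 (strand '+')."""
        return self.r_start - self.q_start


def _hits_by_diagonal(query: str, ref_index: dict[str, list[int]], k: int):
    """Group query k-mer hits into {(strand, diagonal): sorted [q_pos0]}."""
    groups: dict[tuple[str, int], list[int]] = {}
    for i in range(len(query) - k + 1):
        km = query[i : i + k]
        for p in ref_index.get(km, ()):  # forward hits: diag = p - i
            groups.setdefault(("+", p - i), []).append(i)
        for p in ref_index.get(revcomp(km), ()):  # inverted: antidiag = p + i
            groups.setdefault(("-", p + i), []).append(i)
    return groups


def build_ref_index(ref: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for p in range(len(ref) - k + 1):
        index.setdefault(ref[p : p + k], []).append(p)
    return index


def _blocks_from_runs(positions: list[int], k: int, max_gap: int):
    """Merge sorted hit positions into blocks; a new block starts when the
    jump between consecutive hits exceeds ``k + max_gap``."""
    blocks = []
    start = prev = positions[0]
    for i in positions[1:]:
        if i - prev > k + max_gap:
            blocks.append((start, prev + k - 1))
            start = i
        prev = i
    blocks.append((start, prev + k - 1))
    return blocks


def anchor_query(
    query: str,
    reference: str,
    k: int = 21,
    max_gap: int = 0,
    min_length: int | None = None,
    min_identity: float = 0.0,
    ref_index: dict[str, list[int]] | None = None,
) -> list[Anchor]:
    """Find match blocks between query and reference on both strands.

    With ``max_gap=0`` blocks are exact matches (maximal runs of adjacent
    shared k-mers).  With ``max_gap > 0`` blocks bridge short interruptions
    such as substitutions; bridged blocks get an edlib identity score.
    Anchors are sorted by query start, then reference start.
    """
    if ref_index is None:
        ref_index = build_ref_index(reference, k)
    min_length = k if min_length is None else min_length
    anchors: list[Anchor] = []
    for (strand, diag), positions in _hits_by_diagonal(
        query, ref_index, k
    ).items():
        positions.sort()
        for q0, q1 in _blocks_from_runs(positions, k, max_gap):
            if q1 - q0 + 1 < min_length:
                continue
            if strand == "+":
                r0, r1 = diag + q0, diag + q1
            else:
                # q1 is a base end-coordinate; k-mer starts run to q1-(k-1)
                r0 = diag - q1 + (k - 1)
                r1 = diag - q0 + (k - 1)
            qseq = query[q0 : q1 + 1]
            rseq = reference[r0 : r1 + 1]
            if strand == "-":
                rseq = revcomp(rseq)
            if qseq == rseq:
                ident = 1.0
            else:
                ed = edlib.align(qseq, rseq, mode="NW")["editDistance"]
                ident = 1.0 - ed / max(len(qseq), len(rseq))
            if ident < min_identity:
                continue
            anchors.append(
                Anchor(q0 + 1, q1 + 1, r0 + 1, r1 + 1, strand, ident)
            )
    anchors.sort(key=lambda a: (a.q_start, a.r_start))
    return anchors


def chain_anchors(anchors: list[Anchor], strand: str = "+") -> list[Anchor]:
    """Longest collinear chain (by total anchor length) of same-strand
    anchors, query and reference coordinates both increasing ('+') or
    query increasing while reference decreases ('-').  Ties prefer the
    leftmost (smaller reference start) chain.
    """
    cand = [a for a in anchors if a.strand == strand]
    cand.sort(key=lambda a: (a.q_start, a.r_start))
    n = len(cand)
    if n == 0:
        return []
    best_len = [a.q_len for a in cand]
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            a, b = cand[i], cand[j]
            if strand == "+":
                ok = a.q_end < b.q_end and a.r_end < b.r_end and (
                    a.q_start < b.q_start and a.r_start < b.r_start
                )
            else:
                ok = a.q_end < b.q_end and a.r_start > b.r_start
            if ok and best_len[i] + b.q_len > best_len[j]:
                best_len[j] = best_len[i] + b.q_len
                prev[j] = i
    j = max(range(n), key=lambda i: (best_len[i], -cand[i].r_start))
    chain = []
    while j >= 0:
        chain.append(cand[j])
        j = prev[j]
    chain.reverse()
    return chain


def best_chain(anchors: list[Anchor]) -> tuple[list[Anchor], str]:
    """Best collinear chain over both strands.

    Ties (e.g. a collapsed inverted-repeat contig that matches one repeat
    copy forward and the other reversed, with equal support) prefer the
    leftmost reference locus, then the '+' strand — the deterministic
    repeat collapse short-read mappers exhibit."""
    fwd = chain_anchors(anchors, "+")
    rev = chain_anchors(anchors, "-")

    def score(chain, strand):
        total = sum(a.q_len for a in chain)
        start = min((a.r_start for a in chain), default=0)
        return (total, -start, strand == "+")

    if not rev:
        return fwd, "+"
    if not fwd:
        return rev, "-"
    return max(((fwd, "+"), (rev, "-")), key=lambda cs: score(*cs))


def trim_chain_overlaps(chain: list[Anchor]) -> list[Anchor]:
    """Trim successive '+'-strand chain anchors so neither query nor
    reference intervals overlap (overlaps of up to k-1 arise around
    InDels)."""
    out: list[Anchor] = []
    for a in chain:
        a = Anchor(**vars(a))
        if out:
            p = out[-1]
            cut = max(p.q_end - a.q_start + 1, p.r_end - a.r_start + 1, 0)
            if cut:
                a.q_start += cut
                a.r_start += cut
            if a.q_start > a.q_end or a.r_start > a.r_end:
                continue
        out.append(a)
    return out
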