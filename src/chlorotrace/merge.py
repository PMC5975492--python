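"""Reference-guided contig merging, quadripartite-structure detection and
IRb completion.

Short-read assemblies of a plastome cover LSC + IRa + SSC but lose the
second inverted-repeat copy (IR collapse).  This module rebuilds a complete
circular genome: contigs from many assembly runs are anchored to a related
reference, oriented and ordered, merged by per-column majority vote
(ties resolved toward the reference base), the quadripartite structure is
located via maximal inverted-repeat matching, and the missing IRb stretch
is inferred as the reverse complement of the assembled IRa.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import edlib

from .anchors import anchor_query, best_chain
from .assembly import Assembly
from .genome import QuadripartiteGenome, revcomp

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


class StructureNotFound(RuntimeError):
    """No inverted repeat of the required size/identity was found."""


class CompletionRefused(RuntimeError):
    """Assembled IRb conflicts with the IRa-derived sequence."""


@dataclass
class QuadripartiteCall:
    """Quadripartite boundaries on the canonical rotation of a circle.

    ``sequence`` is the input rotated so LSC starts at position 1; the four
    intervals partition [1, length]; ``ir_identity`` is the identity between
    IRb and the reverse complement of IRa.
    """

    sequence: str
    lsc_end: int
    ira_end: int
    ssc_end: int
    ir_identity: float
    rotation_offset: int = 0  # bases the input was rotated left

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def ir_length(self) -> int:
        return self.ira_end - self.lsc_end

    def intervals(self) -> dict[str, tuple[int, int]]:
        return {
            "LSC": (1, self.lsc_end),
            "IRa": (self.lsc_end + 1, self.ira_end),
            "SSC": (self.ira_end + 1, self.ssc_end),
            "IRb": (self.ssc_end + 1, self.length),
        }


@dataclass
class _Projection:
    """One contig laid out in reference coordinates."""

    r_lo: int  # 1-based inclusive
    r_hi: int
    cols: list[str]  # per reference position: base or '-' (deleted)
    ins: dict[int, str]  # insertion after reference position


def _project(contig: str, ref: str, k: int = 21) -> _Projection | None:
    """Orient a contig by its anchor chain and lay it out column-by-column
    in reference coordinates.  Non-collinear tails (e.g. unitig overhangs
    into the far IR copy) are trimmed.  Returns None when the contig does
    not anchor."""
    anchors = anchor_query(contig, ref, k=k, max_gap=100, min_identity=0.90)
    chain, strand = best_chain(anchors)
    if not chain:
        return None
    if strand == "-":
        contig = revcomp(contig)
        anchors = anchor_query(contig, ref, k=k, max_gap=100,
                               min_identity=0.90)
        chain, strand = best_chain(anchors)
        if not chain or strand != "+":
            return None
    q_lo, q_hi = chain[0].q_start, chain[-1].q_end
    r_lo, r_hi = chain[0].r_start, chain[-1].r_end
    query = contig[q_lo - 1 : q_hi]
    target = ref[r_lo - 1 : r_hi]
    res = edlib.align(query, target, task="path", mode="NW")
    cols: list[str] = []
    ins: dict[int, str] = {}
    qi = 0
    rpos = r_lo - 1  # last consumed reference position
    for n, op in _CIG_RE.findall(res["cigar"]):
        n = int(n)
        if op in "=XM":
            cols.extend(query[qi : qi + n])
            qi += n
            rpos += n
        elif op == "I":
            ins[rpos] = ins.get(rpos, "") + query[qi : qi + n]
            qi += n
        elif op == "D":
            cols.extend("-" * n)
            rpos += n
    return _Projection(r_lo=r_lo, r_hi=rpos, cols=cols, ins=ins)


def _consensus(group: list[_Projection], ref: str) -> str:
    """Per-column majority over contributing contigs; ties (including
    base-vs-deletion ties) resolve to the reference base."""
    gs = min(p.r_lo for p in group)
    ge = max(p.r_hi for p in group)
    out: list[str] = []
    for pos in range(gs, ge + 1):
        votes = Counter()
        ins_votes = Counter()
        for p in group:
            if p.r_lo <= pos <= p.r_hi:
                votes[p.cols[pos - p.r_lo]] += 1
                if pos < p.r_hi:
                    ins_votes[p.ins.get(pos, "")] += 1
        if not votes:
            out.append(ref[pos - 1])  # interior gap closed from reference
        else:
            top = votes.most_common()
            winners = [b for b, c in top if c == top[0][1]]
            base = winners[0] if len(winners) == 1 else ref[pos - 1]
            if base != "-":
                out.append(base)
        if ins_votes:
            itop = ins_votes.most_common()
            iwin = [s for s, c in itop if c == itop[0][1]]
            if len(iwin) == 1 and iwin[0]:
                out.append(iwin[0])
    return "".join(out)


def _overlap_identity(group: list[_Projection], nxt: _Projection) -> float:
    """Identity between a new contig and the group plurality over the
    overlapping reference columns."""
    ge = max(p.r_hi for p in group)
    lo, hi = nxt.r_lo, min(ge, nxt.r_hi)
    if hi < lo:
        return 0.0
    same = total = 0
    for pos in range(lo, hi + 1):
        votes = Counter()
        for p in group:
            if p.r_lo <= pos <= p.r_hi:
                votes[p.cols[pos - p.r_lo]] += 1
        if not votes:
            continue
        total += 1
        if votes.most_common(1)[0][0] == nxt.cols[pos - nxt.r_lo]:
            same += 1
    return same / total if total else 0.0


def merge_contigs(
    selected_assemblies: list[Assembly],
    reference: QuadripartiteGenome | str,
    min_overlap: int = 100,
    min_overlap_identity: float = 0.99,
    k: int = 21,
) -> Assembly:
    """Merge contigs from many assemblies into reference-ordered super
    contigs.

    Contigs are anchored to the reference, oriented, ordered by reference
    start, and chained into super contigs wherever adjacent layouts overlap
    by at least ``min_overlap`` columns at ``min_overlap_identity``
    agreement; disagreeing columns are resolved by majority vote with ties
    going to the reference base.  Misassembled contigs should be removed by
    the caller beforehand; contigs that fail to anchor are excluded with a
    logged reason in the provenance.
    """
    ref = (reference.sequence
           if isinstance(reference, QuadripartiteGenome) else reference)
    projections: list[_Projection] = []
    excluded: list[str] = []
    for asm in selected_assemblies:
        for i, contig in enumerate(asm.contigs):
            proj = _project(contig, ref, k=k)
            if proj is None:
                excluded.append(f"{asm.run_id}[{i}]: no consistent anchoring")
            else:
                projections.append(proj)
    projections.sort(key=lambda p: (p.r_lo, p.r_hi))
    supers: list[str] = []
    spans: list[tuple[int, int]] = []
    group: list[_Projection] = []
    for proj in projections:
        if not group:
            group = [proj]
            continue
        ge = max(p.r_hi for p in group)
        overlap = ge - proj.r_lo + 1
        if overlap >= min_overlap and _overlap_identity(
            group, proj
        ) >= min_overlap_identity:
            group.append(proj)
        elif overlap >= min_overlap:
            excluded.append(
                f"contig at ref {proj.r_lo}: overlap identity below "
                f"{min_overlap_identity}"
            )
        else:
            supers.append(_consensus(group, ref))
            spans.append((min(p.r_lo for p in group), ge))
            group = [proj]
    if group:
        supers.append(_consensus(group, ref))
        spans.append(
            (min(p.r_lo for p in group), max(p.r_hi for p in group))
        )
    return Assembly(
        run_id="merged",
        contigs=supers,
        provenance={"spans": spans, "excluded": excluded},
    )


def detect_quadripartite(
    sequence: str,
    min_ir: int = 1000,
    min_identity: float = 0.99,
    k: int | None = None,
) -> QuadripartiteCall:
    """Locate the LSC/IRa/SSC/IRb structure of a circular sequence.

    Finds the maximal pair of disjoint intervals (X before Y) where the
    reverse complement of Y matches X at ``min_identity``; the longer
    flanked single-copy stretch is LSC, the shorter SSC.  The call is
    reported on the canonical rotation (LSC first).  Raises
    ``StructureNotFound`` when no inverted repeat of at least ``min_ir``
    bases exists — e.g. for a bare single-copy fragment.
    """
    L = len(sequence)
    if L < 4 * min_ir // 2:
        raise StructureNotFound("sequence shorter than the minimum layout")
    if k is None:
        k = 21 if min_ir >= 200 else 11
    doubled = sequence + sequence
    anchors = anchor_query(doubled, doubled, k=k, max_gap=50,
                           min_identity=min_identity)
    best = None
    for a in anchors:
        if a.strand != "-" or a.q_len < min_ir:
            continue
        x = (a.q_start, a.q_end)
        y = (a.r_start, a.r_end)
        if x >= y:
            continue  # keep the X-before-Y representative only
        if x[1] >= y[0]:
            continue  # overlapping (palindromic centre), not an IR pair
        if y[1] - x[0] + 1 > L:
            continue  # spans more than one period of the doubled circle
        if best is None or (a.q_len, -x[0]) > (best.q_len, -best.q_start):
            best = a
    if best is None:
        raise StructureNotFound(
            f"no inverted repeat >= {min_ir} bp at identity "
            f">= {min_identity}"
        )
    x1, x2, y1, y2 = best.q_start, best.q_end, best.r_start, best.r_end
    ir_len = best.q_len
    mid_gap = y1 - x2 - 1
    wrap_gap = L - 2 * ir_len - mid_gap
    if wrap_gap >= mid_gap:
        lsc_len, ssc_len = wrap_gap, mid_gap
        start = y2 + 1  # rotation: [wrap][X=IRa][mid][Y=IRb]
    else:
        lsc_len, ssc_len = mid_gap, wrap_gap
        start = x2 + 1  # rotation: [mid][Y=IRa][wrap][X=IRb]
    offset = (start - 1) % L
    canonical = sequence[offset:] + sequence[:offset]
    call = QuadripartiteCall(
        sequence=canonical,
        lsc_end=lsc_len,
        ira_end=lsc_len + ir_len,
        ssc_end=lsc_len + ir_len + ssc_len,
        ir_identity=best.identity,
        rotation_offset=offset,
    )
    return call


def infer_partial_boundaries(
    partial: str, reference: QuadripartiteGenome
) -> tuple[int, int, int]:
    """Project the reference LSC/IRa/SSC boundaries onto a partial
    (LSC + IRa + SSC [+ IRb stub]) assembly via alignment."""
    target = partial
    res = edlib.align(
        reference.sequence[: reference.ssc_end], target, task="path",
        mode="HW",
    )
    if res["editDistance"] < 0:
        raise ValueError("partial assembly does not align to the reference")
    t0 = res["locations"][0][0]
    wanted = {reference.lsc_end, reference.ira_end, reference.ssc_end}
    mapping: dict[int, int] = {}
    q = 0  # consumed reference (query) bases
    t = t0  # consumed partial (target) bases
    for n, op in _CIG_RE.findall(res["cigar"]):
        n = int(n)
        if op in "=XM":
            for boundary in wanted:
                if q < boundary <= q + n:
                    mapping[boundary] = t + (boundary - q)
            q += n
            t += n
        elif op == "I":  # reference-only bases
            q += n
        elif op == "D":  # partial-only bases
            t += n
    try:
        return (
            mapping[reference.lsc_end],
            mapping[reference.ira_end],
            mapping[reference.ssc_end],
        )
    except KeyError as exc:
        raise ValueError(
            "could not project all region boundaries onto the partial "
            "assembly"
        ) from exc


def complete_irb(
    partial: str,
    boundaries: tuple[int, int, int],
    name: str = "completed",
    min_overlap_identity: float = 0.995,
) -> tuple[QuadripartiteGenome, dict]:
    """Complete the missing IRb stretch from the assembled IRa.

    ``boundaries`` are the (lsc_end, ira_end, ssc_end) coordinates on the
    partial assembly (see :func:`infer_partial_boundaries`).  Any assembled
    IRb prefix beyond ``ssc_end`` must match the reverse complement of IRa
    at ``min_overlap_identity``, else completion refuses; assembled bases
    are kept as-is and only the missing tail is inferred.
    """
    lsc_end, ira_end, ssc_end = boundaries
    if not 1 <= lsc_end < ira_end < ssc_end <= len(partial):
        raise ValueError("invalid boundaries for the partial assembly")
    ira = partial[lsc_end:ira_end]
    expected_irb = revcomp(ira)
    present = partial[ssc_end:]
    if len(present) > len(expected_irb):
        raise CompletionRefused(
            "assembled IRb is longer than the IRa-derived sequence"
        )
    n_mismatch = 0
    if present:
        res = edlib.align(present, expected_irb[: len(present)], mode="NW")
        n_mismatch = res["editDistance"]
        identity = 1.0 - n_mismatch / len(present)
        if identity < min_overlap_identity:
            raise CompletionRefused(
                f"assembled IRb conflicts with revcomp(IRa) over partial "
                f"positions {ssc_end + 1}-{len(partial)} "
                f"(identity {identity:.4f} < {min_overlap_identity})"
            )
    completed = partial + expected_irb[len(present) :]
    genome = QuadripartiteGenome(
        name=name,
        sequence=completed,
        lsc_end=lsc_end,
        ira_end=ira_end,
        ssc_end=ssc_end,
    )
    report = {
        "inferred_interval": (ssc_end + len(present) + 1, len(completed))
        if len(present) < len(expected_irb) else None,
        "assembled_irb_bases": len(present),
        "overlap_mismatches": n_mismatch,
    }
    return genome, report


def collect_irb_spanning_contigs(
    all_assemblies: list[Assembly],
    reference: QuadripartiteGenome,
    k: int = 21,
    **merge_kw,
) -> Assembly:
    """Select contigs whose anchored layout intersects the reference IRb
    interval and merge them into the longest achievable IRb-overlapping
    contig.  Returns an empty assembly when no contig reaches into IRb
    (triggering the IRa-based completion fallback)."""
    irb_lo = reference.ssc_end + 1
    picked: list[Assembly] = []
    for asm in all_assemblies:
        keep = []
        for contig in asm.contigs:
            anchors = anchor_query(contig, reference.sequence, k=k,
                                   max_gap=100, min_identity=0.90)
            chain, _ = best_chain(anchors)
            if chain and chain[-1].r_end >= irb_lo:
                keep.append(contig)
        if keep:
            picked.append(Assembly(run_id=asm.run_id + ".irb", contigs=keep))
    if not picked:
        return Assembly(run_id="irb", contigs=[])
    merged = merge_contigs(picked, reference, **merge_kw)
    spans = merged.provenance.get("spans", [])
    keep = [
        (c, s) for c, s in zip(merged.contigs, spans) if s[1] >= irb_lo
    ]
    if not keep:
        return Assembly(run_id="irb", contigs=[])
    keep.sort(key=lambda cs: -len(cs[0]))
    return Assembly(
        run_id="irb",
        contigs=[keep[0][0]],
        provenance={"span": keep[0][1]},
    )
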