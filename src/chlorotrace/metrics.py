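"""Assembly metrics and optimum-assembly selection.

Implements the alignment-free contiguity statistics (num, totalSum, mean,
max, N80/N50/N20 and L80/L50/L20), reference-based genome fraction
(CoverRatio), per-100-kb mismatch rate and misassembly flagging, the
screening rule for eligible assemblies, and the two selection rules used to
pick the optimum assembly per dataset.

Nx is the length of the contig at which the cumulative length of contigs
sorted in decreasing order first reaches x% of the total assembly length;
Lx is the number of contigs in that prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .anchors import anchor_query, best_chain
from .assembly import Assembly
from .genome import QuadripartiteGenome


@dataclass
class AssemblyMetrics:
    num: int
    total: int
    mean: float
    max: int
    n80: int
    n50: int
    n20: int
    l80: int
    l50: int
    l20: int
    cover_ratio: float | None = None
    mismatches_per_100kb: float | None = None
    misassembled: list[int] = field(default_factory=list)  # contig indices


def _nx_lx(lengths: list[int], x: float) -> tuple[int, int]:
    total = sum(lengths)
    cum = 0
    for i, ln in enumerate(sorted(lengths, reverse=True)):
        cum += ln
        if cum >= x * total:
            return ln, i + 1
    return lengths[-1], len(lengths)


def basic_metrics(assembly: Assembly) -> AssemblyMetrics:
    """Alignment-free contiguity statistics."""
    lengths = [len(c) for c in assembly.contigs]
    if not lengths:
        raise ValueError("cannot compute metrics of an empty assembly")
    n80, l80 = _nx_lx(lengths, 0.80)
    n50, l50 = _nx_lx(lengths, 0.50)
    n20, l20 = _nx_lx(lengths, 0.20)
    return AssemblyMetrics(
        num=len(lengths),
        total=sum(lengths),
        mean=sum(lengths) / len(lengths),
        max=max(lengths),
        n80=n80, n50=n50, n20=n20, l80=l80, l50=l50, l20=l20,
    )


def _contig_chain(contig: str, reference: str, k: int = 21):
    """Best collinear anchor chain of one contig against the reference."""
    anchors = anchor_query(contig, reference, k=k, max_gap=100,
                           min_identity=0.90)
    return best_chain(anchors)


def reference_metrics(
    assembly: Assembly,
    reference: QuadripartiteGenome | str,
    k: int = 21,
    misassembly_gap: int = 1000,
) -> AssemblyMetrics:
    """Reference-based metrics: CoverRatio, mismatch rate, misassemblies.

    Contigs are anchored to the reference; CoverRatio is the fraction of
    reference bases under at least one aligned block of a consistently
    placed contig.  A contig is flagged misassembled when its chained
    anchors imply reference loci more than ``misassembly_gap`` apart
    (jumping off a common diagonal); such contigs do not contribute to
    coverage.
    """
    ref = reference.sequence if isinstance(reference, QuadripartiteGenome) else reference
    m = basic_metrics(assembly)
    covered: list[tuple[int, int]] = []
    mismatches = 0
    aligned = 0
    misassembled = []
    for idx, contig in enumerate(assembly.contigs):
        chain, strand = _contig_chain(contig, ref, k=k)
        if not chain:
            continue
        offsets = [
            a.r_start - a.q_start if strand == "+" else a.r_end + a.q_start
            for a in chain
        ]
        if max(offsets) - min(offsets) > misassembly_gap:
            misassembled.append(idx)
            continue
        for a in chain:
            covered.append((a.r_start, a.r_end))
            span = max(a.q_len, a.r_end - a.r_start + 1)
            aligned += span
            mismatches += round((1.0 - a.identity) * span)
    covered.sort()
    union = 0
    cur_s, cur_e = None, None
    for s, e in covered:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                union += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        union += cur_e - cur_s + 1
    m.cover_ratio = union / len(ref)
    m.mismatches_per_100kb = (mismatches / aligned * 1e5) if aligned else 0.0
    m.misassembled = misassembled
    return m


def screen_assemblies(
    assemblies: list[Assembly],
    reference_length: int,
    min_total_fraction: float = 0.80,
    max_contigs: int = 100,
) -> list[Assembly]:
    """Keep assemblies with total bases above ``min_total_fraction`` of the
    reference and fewer than ``max_contigs`` contigs; order preserved.

    At full plastome scale (157 kb reference) the defaults reproduce the
    '> 126 kbp and < 100 contigs' screening rule.
    """
    out = []
    for asm in assemblies:
        if asm.failed or not asm.contigs:
            continue
        if (asm.total_length > min_total_fraction * reference_length
                and len(asm.contigs) < max_contigs):
            out.append(asm)
    return out


def select_optimum(
    candidates: list[tuple[Assembly, AssemblyMetrics]],
    tool_class: str = "default",
    cover_ratio_floor: float = 0.85,
) -> Assembly:
    """Pick the optimum assembly among candidate runs of one dataset.

    ``default``: the assembly with the greatest N50 (ties: higher
    CoverRatio, then fewer contigs, then first seen).  ``coverage-
    sensitive``: restrict to candidates with CoverRatio above
    ``cover_ratio_floor`` when any candidate exceeds it, then apply the
    default rule; otherwise fall back to the plain greatest-N50 rule.
    """
    if not candidates:
        raise ValueError("no candidate assemblies")
    if tool_class not in ("default", "coverage-sensitive"):
        raise ValueError(f"unknown tool_class {tool_class!r}")
    pool = candidates
    if tool_class == "coverage-sensitive":
        above = [
            c for c in candidates
            if c[1].cover_ratio is not None
            and c[1].cover_ratio > cover_ratio_floor
        ]
        if above:
            pool = above
    best = max(
        enumerate(pool),
        key=lambda ic: (
            ic[1][1].n50,
            ic[1][1].cover_ratio or 0.0,
            -ic[1][1].num,
            -ic[0],
        ),
    )
    return best[1][0]
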