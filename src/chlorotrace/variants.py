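"""Dual-strategy variant discovery and trio inheritance classification.

Variants are discovered two ways and reconciled: whole-genome comparison of
each clone assembly against the reference (anchor chaining plus affine-gap
alignment of inter-anchor gaps), and read-pileup calling from mapped
datasets under a haploid organelle model.  Mapping-derived calls with poor
cross-dataset repeatability, inconsistent reference alleles, or
homopolymer / low-complexity / large-InDel context are treated as
problematic and corrected against the comparison strategy.  The unified
per-clone variant table is then region- and effect-annotated and used to
classify each locus by pairwise genotype equality across a
mother/father/offspring trio, yielding a genome-wide inheritance verdict.
"""

from __future__ import annotations

import math
import re
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .anchors import anchor_query, chain_anchors, trim_chain_overlaps
from .genome import QuadripartiteGenome, revcomp
from .mapping import ReadAlignment

_CIG_RE = re.compile(r"(\d+)([=XIDM])")

MISSING = "."


class ComparisonFailed(RuntimeError):
    """No collinear anchor chain covers enough of the reference."""


@dataclass
class Variant:
    """One locus on the reference, with anchored left-aligned alleles."""

    ref_pos: int
    ref_allele: str
    alt_allele: str
    vtype: str  # SNP | insertion | deletion
    region: str = ""
    context_flags: set[str] = field(default_factory=set)
    source: set[str] = field(default_factory=set)
    per_clone_genotype: dict[str, str] = field(default_factory=dict)
    support: dict = field(default_factory=dict)
    effect: str = ""
    flags: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.ref_pos, self.ref_allele, self.alt_allele)


def classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNP"
    return "insertion" if len(alt) > len(ref) else "deletion"


def left_normalize(seq: str, pos: int, ref: str, alt: str):
    """Left-align an anchored variant against the reference sequence
    (1-based ``pos``), using the classic shift-left normalization:
    truncate shared trailing bases (extending left from the reference
    whenever an allele would empty), then trim shared leading bases."""
    if len(ref) == 1 and len(alt) == 1:
        return pos, ref, alt
    while ref and alt and ref[-1] == alt[-1]:
        if (len(ref) == 1 or len(alt) == 1) and pos == 1:
            break  # cannot extend left past the first base
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            pos -= 1
            base = seq[pos - 1]
            ref, alt = base + ref, base + alt
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# comparison strategy


def _gap_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -1
    return a


def _emit_gap_variants(rseq: str, r0: int, rgap: str, qgap: str, out: list):
    """Variants from an inter-anchor gap; ``r0`` is the 1-based reference
    position of the base preceding the gap."""
    if not rgap and not qgap:
        return
    if not rgap:  # pure insertion after r0
        out.append((r0, rseq[r0 - 1], rseq[r0 - 1] + qgap))
        return
    if not qgap:  # pure deletion of rgap after r0
        out.append((r0, rseq[r0 - 1] + rgap, rseq[r0 - 1]))
        return
    aln = _gap_aligner().align(rgap, qgap)[0]
    rblocks, qblocks = aln.aligned
    prev_r, prev_q = 0, 0
    for (rs, re_), (qs, qe) in zip(rblocks, qblocks):
        dr, dq = rgap[prev_r:rs], qgap[prev_q:qs]
        if dr or dq:
            anchor = r0 + prev_r
            out.append((anchor, rseq[anchor - 1] + dr, rseq[anchor - 1] + dq))
        for i in range(re_ - rs):
            if rgap[rs + i] != qgap[qs + i]:
                out.append((r0 + rs + i + 1, rgap[rs + i], qgap[qs + i]))
        prev_r, prev_q = re_, qe
    dr, dq = rgap[prev_r:], qgap[prev_q:]
    if dr or dq:
        anchor = r0 + prev_r
        out.append((anchor, rseq[anchor - 1] + dr, rseq[anchor - 1] + dq))


def compare_genomes(
    query: QuadripartiteGenome | str,
    reference: QuadripartiteGenome | str,
    clone: str | None = None,
    anchor_min: int = 20,
    min_chain_cover: float = 0.5,
) -> list[Variant]:
    """Variants of a clone genome against the reference by whole-genome
    comparison (source = 'comparison').

    Maximal exact matches of at least ``anchor_min`` bp are chained
    collinearly (longest total anchor length, ties leftmost); inter-anchor
    gaps are resolved by affine-gap global alignment (match +1, mismatch
    -1, gap open -2, gap extend -1).  InDels are anchored and
    left-normalized.
    """
    qseq = query.sequence if isinstance(query, QuadripartiteGenome) else query
    rseq = (reference.sequence
            if isinstance(reference, QuadripartiteGenome) else reference)
    clone = clone or (query.name if isinstance(query, QuadripartiteGenome)
                      else "query")
    anchors = anchor_query(qseq, rseq, k=anchor_min, max_gap=0,
                           min_length=anchor_min)
    chain = trim_chain_overlaps(chain_anchors(anchors, "+"))
    cover = sum(a.r_end - a.r_start + 1 for a in chain)
    if cover < min_chain_cover * len(rseq):
        raise ComparisonFailed(
            f"anchor chain covers {cover}/{len(rseq)} reference bases"
        )
    raw: list[tuple[int, str, str]] = []
    for a, b in zip(chain, chain[1:]):
        rgap = rseq[a.r_end : b.r_start - 1]
        qgap = qseq[a.q_end : b.q_start - 1]
        _emit_gap_variants(rseq, a.r_end, rgap, qgap, raw)
    variants = []
    seen = set()
    for pos, ref, alt in raw:
        pos, ref, alt = left_normalize(rseq, pos, ref, alt)
        if ref == alt:
            continue
        key = (pos, ref, alt)
        if key in seen:
            continue
        seen.add(key)
        variants.append(
            Variant(
                ref_pos=pos, ref_allele=ref, alt_allele=alt,
                vtype=classify_alleles(ref, alt),
                source={"comparison"},
                per_clone_genotype={clone: alt},
            )
        )
    variants.sort(key=lambda v: v.key)
    return variants


# ---------------------------------------------------------------------------
# mapping (pileup) strategy


def pileup_call(
    alignments: list[ReadAlignment],
    reference: QuadripartiteGenome | str,
    min_depth: int = 10,
    min_alt_fraction: float = 0.8,
    suspect_fraction: float = 0.2,
    clone: str | None = None,
    dataset_id: str = "",
) -> tuple[list[Variant], list[Variant]]:
    """Haploid pileup variant calling from one dataset's alignments
    (source = 'mapping').

    A call requires column depth >= ``min_depth`` and alt fraction >=
    ``min_alt_fraction``; alleles with fraction in (``suspect_fraction``,
    ``min_alt_fraction``) are returned separately as heteroplasmy
    suspects, not calls.  Returns (calls, suspects).
    """
    if isinstance(reference, QuadripartiteGenome):
        rseq, circular = reference.sequence, reference.circular
    else:
        rseq, circular = reference, True
    L = len(rseq)
    base_counts: defaultdict[int, Counter] = defaultdict(Counter)
    ins_counts: defaultdict[int, Counter] = defaultdict(Counter)
    del_counts: Counter[tuple[int, int]] = Counter()
    depth: Counter[int] = Counter()
    for aln in alignments:
        if not aln.mapped:
            continue
        q = aln.aligned_seq
        qi = 0
        rp = aln.ref_start - 1  # 0-based next reference position
        for n, op in _CIG_RE.findall(aln.cigar):
            n = int(n)
            if op in "=XM":
                for j in range(n):
                    col = (rp + j) % L + 1
                    base_counts[col][q[qi + j]] += 1
                    depth[col] += 1
                qi += n
                rp += n
            elif op == "I":
                col = (rp - 1) % L + 1
                ins_counts[col][q[qi : qi + n]] += 1
                qi += n
            elif op == "D":
                col = (rp - 1) % L + 1
                del_counts[(col, n)] += 1
                for j in range(n):
                    depth[(rp + j) % L + 1] += 1
                rp += n
    calls: list[Variant] = []
    suspects: list[Variant] = []

    def _push(pos, ref, alt, count, d):
        pos, ref, alt = left_normalize(rseq, pos, ref, alt)
        v = Variant(
            ref_pos=pos, ref_allele=ref, alt_allele=alt,
            vtype=classify_alleles(ref, alt), source={"mapping"},
            support={(clone or "clone", dataset_id): (d, count / d)},
        )
        if clone:
            v.per_clone_genotype[clone] = alt
        frac = count / d
        if frac >= min_alt_fraction:
            calls.append(v)
        elif frac > suspect_fraction:
            v.flags.add("heteroplasmy_suspect")
            v.per_clone_genotype.clear()
            suspects.append(v)

    for col, counts in sorted(base_counts.items()):
        d = depth[col]
        if d < min_depth:
            continue
        refbase = rseq[col - 1]
        alt, cnt = counts.most_common(1)[0]
        if alt != refbase:
            _push(col, refbase, alt, cnt, d)
    for col, counts in sorted(ins_counts.items()):
        d = depth[col]
        if d < min_depth:
            continue
        ins, cnt = counts.most_common(1)[0]
        _push(col, rseq[col - 1], rseq[col - 1] + ins, cnt, d)
    for (col, dlen), cnt in sorted(del_counts.items()):
        d = depth[col]
        if d < min_depth or col + dlen > L:
            continue
        _push(col, rseq[col - 1 : col + dlen], rseq[col - 1], cnt, d)
    calls.sort(key=lambda v: v.key)
    suspects.sort(key=lambda v: v.key)
    return calls, suspects


# ---------------------------------------------------------------------------
# problematic-variant filtering


def dinucleotide_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the dinucleotide composition."""
    pairs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    if not pairs:
        return 0.0
    counts = Counter(pairs)
    n = len(pairs)
    return -sum(c / n * math.log2(c / n) for c in counts.values())


def context_flags(
    rseq: str, v: Variant, homopolymer_run: int = 5,
    entropy_window: int = 20, entropy_min: float = 1.0,
    large_indel: int = 5,
) -> set[str]:
    """Sequence-context flags for a variant locus."""
    flags: set[str] = set()
    span = max(len(v.ref_allele), len(v.alt_allele))
    lo = max(0, v.ref_pos - 1 - homopolymer_run)
    hi = min(len(rseq), v.ref_pos - 1 + span + homopolymer_run)
    window = rseq[lo:hi]
    run = 1
    for a, b in zip(window, window[1:]):
        run = run + 1 if a == b else 1
        if run >= homopolymer_run:
            flags.add("homopolymer")
            break
    wlo = max(0, v.ref_pos - 1 - entropy_window // 2)
    if dinucleotide_entropy(rseq[wlo : wlo + entropy_window]) < entropy_min:
        flags.add("low_complexity")
    if v.vtype != "SNP" and abs(len(v.ref_allele) - len(v.alt_allele)) > large_indel:
        flags.add("large_indel")
    return flags


def flag_problematic(
    call_sets: dict[str, list[Variant]],
    comparison_set: list[Variant],
    reference: QuadripartiteGenome | str,
    repeatability_min: float = 0.9,
) -> tuple[list[Variant], list[tuple[Variant, str]]]:
    """Partition one clone's mapping calls into clean and problematic.

    ``call_sets`` maps dataset id -> that dataset's calls.  A locus is
    poor-repeatability when called in fewer than ``repeatability_min`` of
    the clone's datasets; loci where datasets disagree on the reference
    allele at a position are inconsistent; context-flagged loci
    (homopolymer, low-complexity, large InDel) are kept only when the
    comparison strategy confirms them.
    """
    rseq = (reference.sequence
            if isinstance(reference, QuadripartiteGenome) else reference)
    n_sets = len(call_sets)
    if n_sets < 2:
        warnings.warn(
            "fewer than 2 datasets: repeatability is undefined; only "
            "context/consistency filtering applied",
            stacklevel=2,
        )
    comp_keys = {v.key for v in comparison_set}
    by_key: dict[tuple, list[Variant]] = defaultdict(list)
    pos_datasets: dict[int, set[str]] = defaultdict(set)
    for ds_id, calls in call_sets.items():
        for v in calls:
            by_key[v.key].append(v)
            pos_datasets[v.ref_pos].add(ds_id)
    ref_by_pos: dict[int, set[str]] = defaultdict(set)
    for key in by_key:
        ref_by_pos[key[0]].add(key[1])
    clean: list[Variant] = []
    problematic: list[tuple[Variant, str]] = []
    for key in sorted(by_key):
        found = by_key[key]
        # repeatability is a property of the locus (position), so a locus
        # whose datasets disagree on allele representation is judged on
        # how often the position is called at all
        rep = len(pos_datasets[key[0]]) / n_sets
        merged = Variant(
            ref_pos=key[0], ref_allele=key[1], alt_allele=key[2],
            vtype=found[0].vtype, source={"mapping"},
        )
        for v in found:
            merged.support.update(v.support)
            merged.per_clone_genotype.update(v.per_clone_genotype)
        merged.context_flags = context_flags(rseq, merged)
        if n_sets >= 2 and rep < repeatability_min:
            problematic.append((merged, "poor_repeatability"))
            continue
        if len(ref_by_pos[key[0]]) > 1:
            problematic.append((merged, "inconsistent_reference"))
            continue
        if merged.context_flags and key not in comp_keys:
            problematic.append(
                (merged, "context:" + ",".join(sorted(merged.context_flags)))
            )
            continue
        clean.append(merged)
    return clean, problematic


# ---------------------------------------------------------------------------
# integration


def integrate(
    comparison_sets: dict[str, list[Variant]],
    mapping_sets: dict[str, list[Variant]],
) -> list[Variant]:
    """Merge per-clone comparison and cleaned mapping call sets into one
    unified variant table.

    Loci are merged by (position, ref allele, alt allele) after
    normalization; per-clone genotypes come from the comparison strategy
    wherever it is available (it covers every clone genome-wide) and from
    mapping only for loci the comparison strategy did not report anywhere.
    Same-position records with conflicting alleles are kept separately and
    flagged for review.
    """
    clones = sorted(set(comparison_sets) | set(mapping_sets))
    comp_carriers: dict[tuple, set[str]] = defaultdict(set)
    map_carriers: dict[tuple, set[str]] = defaultdict(set)
    proto: dict[tuple, Variant] = {}
    for clone, vs in comparison_sets.items():
        for v in vs:
            comp_carriers[v.key].add(clone)
            rec = proto.setdefault(
                v.key,
                Variant(v.ref_pos, v.ref_allele, v.alt_allele, v.vtype),
            )
            rec.source.add("comparison")
    for clone, vs in mapping_sets.items():
        for v in vs:
            map_carriers[v.key].add(clone)
            rec = proto.setdefault(
                v.key,
                Variant(v.ref_pos, v.ref_allele, v.alt_allele, v.vtype),
            )
            rec.source.add("mapping")
            rec.support.update(v.support)
    # Mapping-only records whose reference span overlaps a comparison
    # record are alternative alignment representations of the same locus:
    # per-read unit-cost alignment can split one long InDel into several
    # smaller ones scattered over a window as wide as the InDel itself.
    # The comparison strategy takes precedence and absorbs them.
    comp_spans = []
    for k, rec in proto.items():
        if "comparison" in rec.source:
            delta = abs(len(k[2]) - len(k[1]))
            comp_spans.append(
                (k[0] - 1 - delta, k[0] + len(k[1]) + delta)
            )
    for key in list(proto):
        rec = proto[key]
        if "comparison" in rec.source:
            continue
        lo, hi = key[0], key[0] + len(key[1]) - 1
        if any(lo <= e and s <= hi for s, e in comp_spans):
            del proto[key]
    unified = []
    for key, rec in proto.items():
        if "comparison" in rec.source:
            carriers = comp_carriers[key]
        else:
            carriers = map_carriers[key]
        for clone in clones:
            rec.per_clone_genotype[clone] = (
                rec.alt_allele if clone in carriers else rec.ref_allele
            )
        unified.append(rec)
    by_pos: dict[int, list[Variant]] = defaultdict(list)
    for v in unified:
        by_pos[v.ref_pos].append(v)
    for pos, vs in by_pos.items():
        if len(vs) > 1:
            for v in vs:
                v.flags.add("review:multiallelic")
    unified.sort(key=lambda v: v.key)
    return unified


# ---------------------------------------------------------------------------
# annotation


@dataclass(frozen=True)
class GeneFeature:
    gene: str
    kind: str  # 'CDS' or 'gene'
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    phase: int = 0


def parse_gff3(path) -> list[GeneFeature]:
    """Minimal GFF3 gene-model reader (gene and CDS rows)."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            kind = f[2]
            if kind not in ("gene", "CDS"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or "?"
            phase = int(f[7]) if f[7].isdigit() else 0
            feats.append(
                GeneFeature(name, kind, int(f[3]), int(f[4]), f[6], phase)
            )
    return feats


_PLASTID_TABLE = CodonTable.unambiguous_dna_by_id[11]


def _snp_cds_effect(rseq: str, pos: int, alt: str, cds: GeneFeature) -> str:
    if cds.strand == "+":
        offset = pos - cds.start - cds.phase
        if offset < 0:
            return "upstream"
        codon_start = cds.start + cds.phase + (offset // 3) * 3
        codon = rseq[codon_start - 1 : codon_start + 2]
        idx = pos - codon_start
        mut = codon[:idx] + alt + codon[idx + 1 :]
    else:
        offset = cds.end - cds.phase - pos
        if offset < 0:
            return "downstream"
        codon_end = cds.end - cds.phase - (offset // 3) * 3
        codon = revcomp(rseq[codon_end - 3 : codon_end])
        idx = codon_end - pos
        mut = codon[:idx] + revcomp(alt) + codon[idx + 1 :]
    if len(codon) < 3 or len(mut) < 3:
        return "partial_codon"
    aa_ref = str(Seq(codon).translate(table=_PLASTID_TABLE))
    aa_alt = str(Seq(mut).translate(table=_PLASTID_TABLE))
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


def annotate(
    variants: list[Variant],
    quad,
    gene_model: list[GeneFeature],
    ref_sequence: str | None = None,
) -> list[Variant]:
    """Assign region (LSC/IRa/SSC/IRb) and coding effect to each variant.

    ``quad`` is any object with ``lsc_end``, ``ira_end``, ``ssc_end`` and a
    sequence (a :class:`QuadripartiteGenome` or ``QuadripartiteCall``).
    CDS SNPs are translated with the plastid/bacterial code (table 11) into
    synonymous / missense / nonsense; CDS InDels become frameshift or
    inframe; other loci are labeled intron (inside a gene), upstream or
    downstream of the nearest gene.
    """
    rseq = ref_sequence or quad.sequence
    L = len(rseq)
    for f in gene_model:
        if not 1 <= f.start <= f.end <= L:
            raise ValueError(f"gene feature {f.gene} outside the reference")
    cds = [f for f in gene_model if f.kind == "CDS"]
    genes = [f for f in gene_model if f.kind == "gene"] or cds

    def region_of(pos: int) -> str:
        if pos <= quad.lsc_end:
            return "LSC"
        if pos <= quad.ira_end:
            return "IRa"
        if pos <= quad.ssc_end:
            return "SSC"
        return "IRb"

    for v in variants:
        v.region = region_of(v.ref_pos)
        v.context_flags |= context_flags(rseq, v)
        hit_cds = next(
            (f for f in cds if f.start <= v.ref_pos <= f.end), None
        )
        if hit_cds is not None:
            if v.vtype == "SNP":
                v.effect = _snp_cds_effect(
                    rseq, v.ref_pos, v.alt_allele, hit_cds
                )
            else:
                delta = abs(len(v.ref_allele) - len(v.alt_allele))
                v.effect = "frameshift" if delta % 3 else "inframe"
            continue
        hit_gene = next(
            (f for f in genes if f.start <= v.ref_pos <= f.end), None
        )
        if hit_gene is not None:
            v.effect = "intron"
            continue
        if not genes:
            v.effect = "intergenic"
            continue
        nearest = min(
            genes,
            key=lambda f: min(abs(v.ref_pos - f.start), abs(v.ref_pos - f.end)),
        )
        before = v.ref_pos < nearest.start
        if nearest.strand == "+":
            v.effect = "upstream" if before else "downstream"
        else:
            v.effect = "downstream" if before else "upstream"
    return variants


# ---------------------------------------------------------------------------
# trio classification


@dataclass
class TrioClassification:
    per_locus: list[tuple[tuple[int, str, str], str]]  # (key, class)
    counts: dict[str, int]
    inheritance_verdict: str  # maternal | paternal | inconsistent
    n_informative: int  # loci where mother != father
    n_supporting: int  # informative loci consistent with the verdict
    de_novo: list[tuple[int, str, str]]
    n_missing: int


def classify_trio(
    variants: list[Variant],
    mother: str,
    father: str,
    offspring: str,
) -> TrioClassification:
    """Group each locus by pairwise genotype equality and derive the
    genome-wide inheritance verdict.

    Classes: ``identical`` (all three equal), ``mother=father`` (offspring
    de novo), ``father=offspring``, ``mother=offspring`` and
    ``all_distinct``.  The verdict is maternal iff the offspring matches
    the mother at every locus where the parents differ (paternal for the
    mirror image); de novo offspring loci do not break the verdict.
    """
    names = {mother, father, offspring}
    if variants and not names <= set(variants[0].per_clone_genotype):
        raise ValueError(
            f"clone ids {sorted(names)} not all present in the genotype table"
        )
    per_locus = []
    counts: Counter[str] = Counter()
    de_novo = []
    n_missing = 0
    n_informative = 0
    n_maternal = 0
    n_paternal = 0
    for v in variants:
        g = v.per_clone_genotype
        gm, gf, go = g.get(mother), g.get(father), g.get(offspring)
        if MISSING in (gm, gf, go) or None in (gm, gf, go):
            n_missing += 1
            continue
        if gm == gf == go:
            cls = "identical"
        elif gm == gf:
            cls = f"{mother}={father}"
            de_novo.append(v.key)
        elif gf == go:
            cls = f"{father}={offspring}"
        elif gm == go:
            cls = f"{mother}={offspring}"
        else:
            cls = "all_distinct"
        per_locus.append((v.key, cls))
        counts[cls] += 1
        if gm != gf:
            n_informative += 1
            if go == gm:
                n_maternal += 1
            elif go == gf:
                n_paternal += 1
    if n_informative and n_maternal == n_informative:
        verdict, support = "maternal", n_maternal
    elif n_informative and n_paternal == n_informative:
        verdict, support = "paternal", n_paternal
    else:
        verdict, support = "inconsistent", max(n_maternal, n_paternal)
    return TrioClassification(
        per_locus=per_locus,
        counts=dict(counts),
        inheritance_verdict=verdict,
        n_informative=n_informative,
        n_supporting=support,
        de_novo=de_novo,
        n_missing=n_missing,
    )
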