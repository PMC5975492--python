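"""On-disk formats: FASTA/FASTQ via Biopython, plus the pipeline's plain
text reports (truth tables, SAM, BEDGRAPH/BED, k-mer histograms, VCF 4.2
and the per-clone genotype TSV)."""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mapping import DepthProfile, ReadAlignment, cigar_ref_span
from .readprep import KmerHistogram
from .simulate import ReadDataset, ReadPair
from .variants import TrioClassification, Variant


def write_fasta(records: dict[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="")
         for name, seq in records.items()),
        path,
        "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(path, "fasta")}


def write_fastq_pair(dataset: ReadDataset, prefix: str) -> tuple[str, str]:
    """Write the two mates as ``<prefix>_1.fastq`` / ``<prefix>_2.fastq``."""
    paths = (f"{prefix}_1.fastq", f"{prefix}_2.fastq")
    for mate, path in enumerate(paths, start=1):
        recs = []
        for p in dataset.pairs:
            seq = p.seq1 if mate == 1 else p.seq2
            qual = p.qual1 if mate == 1 else p.qual2
            rec = SeqRecord(Seq(seq), id=f"{p.pair_id}/{mate}",
                            description="")
            rec.letter_annotations["phred_quality"] = [
                ord(c) - 33 for c in qual
            ]
            recs.append(rec)
        SeqIO.write(recs, path, "fastq")
    return paths


def read_fastq_pair(path1, path2, dataset_id: str = "loaded") -> ReadDataset:
    r1 = list(SeqIO.parse(path1, "fastq"))
    r2 = list(SeqIO.parse(path2, "fastq"))
    if len(r1) != len(r2):
        raise ValueError("mate files differ in read count")
    pairs = []
    for a, b in zip(r1, r2):
        qa = "".join(chr(q + 33) for q in a.letter_annotations["phred_quality"])
        qb = "".join(chr(q + 33) for q in b.letter_annotations["phred_quality"])
        pairs.append(ReadPair(str(a.seq), qa, str(b.seq), qb,
                              a.id.rsplit("/", 1)[0]))
    rl = max((len(p.seq1) for p in pairs), default=0)
    return ReadDataset(dataset_id=dataset_id, pairs=pairs, read_length=rl)


def write_truth_table(truth: pd.DataFrame, path, chrom: str = "cp") -> None:
    out = truth.rename(
        columns={"pos": "POS", "ref": "REF", "alt": "ALT",
                 "vtype": "TYPE", "carriers": "CARRIERS"}
    )
    out.insert(0, "CHROM", chrom)
    out[["CHROM", "POS", "REF", "ALT", "TYPE", "CARRIERS"]].to_csv(
        path, sep="\t", index=False
    )


def write_histogram_tsv(hist: KmerHistogram, path) -> None:
    pd.DataFrame(
        sorted(hist.counts.items()), columns=["multiplicity", "count"]
    ).to_csv(path, sep="\t", index=False)


def write_sam(
    alignments: Iterable[ReadAlignment], ref_name: str, ref_length: int, path
) -> None:
    """Minimal unsorted plain-text SAM (mandatory columns only)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{ref_name}\tLN:{ref_length}\n")
        for a in alignments:
            if a.mapped:
                flag = 16 if a.strand == "-" else 0
                fh.write(
                    f"{a.read_id}\t{flag}\t{a.ref_name}\t{a.ref_start}\t"
                    f"60\t{a.cigar}\t*\t0\t0\t{a.aligned_seq}\t*\n"
                )
            else:
                fh.write(f"{a.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")


def write_bedgraph(profile: DepthProfile, ref_name: str, path) -> None:
    with open(path, "w") as fh:
        depth = profile.depth
        start = 0
        for i in range(1, len(depth) + 1):
            if i == len(depth) or depth[i] != depth[start]:
                fh.write(f"{ref_name}\t{start}\t{i}\t{depth[start]}\n")
                start = i


def write_gaps_bed(profile: DepthProfile, ref_name: str, path) -> None:
    """Zero-coverage intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for s, e in profile.zero_intervals:
            fh.write(f"{ref_name}\t{s - 1}\t{e}\n")


def write_regions_bed(quad, ref_name: str, path) -> None:
    with open(path, "w") as fh:
        for region, (s, e) in quad.intervals().items():
            fh.write(f"{ref_name}\t{s - 1}\t{e}\t{region}\n")


def write_vcf(
    variants: list[Variant],
    clones: list[str],
    ref_name: str,
    ref_length: int,
    path,
) -> None:
    """Unified variant table as VCF 4.2 with one haploid sample column per
    clone and INFO keys SRC, REGION, EFF, FLAGS."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref_name},length={ref_length}>\n")
        fh.write('##INFO=<ID=SRC,Number=.,Type=String,'
                 'Description="Discovery strategy">\n')
        fh.write('##INFO=<ID=REGION,Number=1,Type=String,'
                 'Description="Quadripartite region">\n')
        fh.write('##INFO=<ID=EFF,Number=1,Type=String,'
                 'Description="Coding effect">\n')
        fh.write('##INFO=<ID=FLAGS,Number=.,Type=String,'
                 'Description="Context and review flags">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Haploid genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(clones) + "\n")
        for v in sorted(variants, key=lambda v: v.key):
            info = [f"SRC={','.join(sorted(v.source)) or '.'}"]
            if v.region:
                info.append(f"REGION={v.region}")
            if v.effect:
                info.append(f"EFF={v.effect}")
            flags = sorted(v.context_flags | v.flags)
            if flags:
                info.append(f"FLAGS={','.join(flags)}")
            gts = []
            for c in clones:
                g = v.per_clone_genotype.get(c, ".")
                gts.append("." if g == "." else
                           ("1" if g == v.alt_allele else "0"))
            fh.write(
                f"{ref_name}\t{v.ref_pos}\t.\t{v.ref_allele}\t"
                f"{v.alt_allele}\t.\tPASS\t{';'.join(info)}\tGT\t"
                + "\t".join(gts) + "\n"
            )


_TYPE_LABEL = {"SNP": "Replace", "insertion": "Insert", "deletion": "Delete"}


def variants_to_frame(variants: list[Variant], clones: list[str]) -> pd.DataFrame:
    rows = []
    for v in sorted(variants, key=lambda v: v.key):
        row = {
            "position": v.ref_pos,
            "reference_base": v.ref_allele,
            "alternative_base": v.alt_allele,
            "type": _TYPE_LABEL[v.vtype],
            "region": v.region,
            "effect": v.effect,
            "source": ",".join(sorted(v.source)),
        }
        for c in clones:
            row[c] = v.per_clone_genotype.get(c, ".")
        rows.append(row)
    return pd.DataFrame(rows)


def write_variant_tsv(variants: list[Variant], clones: list[str], path) -> None:
    variants_to_frame(variants, clones).to_csv(path, sep="\t", index=False)


def write_classification_report(trio: TrioClassification, path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tcount\n")
        for cls, n in sorted(trio.counts.items()):
            fh.write(f"{cls}\t{n}\n")
        fh.write(f"\ninheritance_verdict\t{trio.inheritance_verdict}\n")
        fh.write(f"informative_loci\t{trio.n_informative}\n")
        fh.write(f"supporting_loci\t{trio.n_supporting}\n")
        fh.write(f"de_novo_loci\t{len(trio.de_novo)}\n")
        fh.write(f"missing_genotype_loci\t{trio.n_missing}\n")
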