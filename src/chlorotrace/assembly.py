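"""Minimal strand-canonical de Bruijn unitig assembler with a multi-k sweep.

Stands in for the battery of short-read assemblers a practitioner would run:
k-mers below a multiplicity floor are dropped (error filtering), maximal
non-branching paths are emitted as unitigs, and a sweep over odd k values
emulates parameter diversity.  No bubble popping or tip clipping is done
beyond the multiplicity filter, which keeps the assembler auditable at the
genome sizes this package targets.

Two near-identical repeat copies (the plastome IR pair) collapse onto the
same canonical k-mers, so assemblies of a quadripartite genome contain the
IR once — the collapse that downstream merging and IRb completion must
repair.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .genome import revcomp
from .simulate import ReadDataset


@dataclass
class DeBruijnGraph:
    k: int
    nodes: dict[str, int]  # canonical k-mer -> multiplicity (>= min_count)
    edges: dict[str, int]  # canonical (k+1)-mer -> multiplicity
    min_count: int = 2


@dataclass
class Assembly:
    """Contigs from one (parameter, dataset) assembly run."""

    run_id: str
    contigs: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def failed(self) -> bool:
        return bool(self.provenance.get("failed"))


def build_graph(
    dataset: ReadDataset, k: int, min_count: int = 2
) -> DeBruijnGraph:
    """Count canonical k-mers over all reads and drop those below
    ``min_count`` (sequencing-error filtering).

    Edges carry their own read evidence as canonical (k+1)-mers, so two
    nodes that happen to overlap by k-1 bases are not linked unless some
    read actually spans the junction."""
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if dataset.pairs and k > max(
        len(p.seq1) for p in dataset.pairs
    ):
        raise ValueError("k exceeds the read length")
    counts: Counter[str] = Counter()
    edge_counts: Counter[str] = Counter()
    valid = set("ACGT")
    for _, seq, _ in dataset.reads():
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if set(km) <= valid:
                counts[min(km, revcomp(km))] += 1
        for i in range(len(seq) - k):
            em = seq[i : i + k + 1]
            if set(em) <= valid:
                edge_counts[min(em, revcomp(em))] += 1
    nodes = {km: c for km, c in counts.items() if c >= min_count}
    edges = {em: c for em, c in edge_counts.items() if c >= min_count}
    return DeBruijnGraph(k=k, nodes=nodes, edges=edges,
                         min_count=min_count)


def _succs(oriented: str, graph: DeBruijnGraph) -> list[str]:
    suf = oriented[1:]
    out = []
    for b in "ACGT":
        nxt = suf + b
        if min(nxt, revcomp(nxt)) not in graph.nodes:
            continue
        em = oriented + b
        if min(em, revcomp(em)) in graph.edges:
            out.append(nxt)
    return out


def _indeg(oriented: str, graph: DeBruijnGraph) -> int:
    # predecessors of an oriented k-mer == successors of its reverse
    # complement, mirrored
    return len(_succs(revcomp(oriented), graph))


def extract_unitigs(
    graph: DeBruijnGraph, min_contig_length: int = 200
) -> Assembly:
    """Emit maximal non-branching paths (unitigs) as contigs.

    Each unitig is reported once, in its canonical orientation (the
    lexicographically smaller of the two strands); isolated simple cycles
    (e.g. a repeat-free circular genome) are broken deterministically at
    their smallest k-mer.  Contigs shorter than ``min_contig_length`` are
    dropped; output is sorted longest first, then lexicographically.
    """
    visited: set[str] = set()
    unitigs: list[str] = []

    def canon(km: str) -> str:
        return min(km, revcomp(km))

    def walk(start: str) -> str:
        path = [start]
        visited.add(canon(start))
        cur = start
        while True:
            ss = _succs(cur, graph)
            if len(ss) != 1:
                break
            nxt = ss[0]
            if _indeg(nxt, graph) != 1 or canon(nxt) in visited:
                break
            path.append(nxt)
            visited.add(canon(nxt))
            cur = nxt
        return path[0] + "".join(p[-1] for p in path[1:])

    ordered = sorted(graph.nodes)
    for km in ordered:
        if km in visited:
            continue
        for oriented in (km, revcomp(km)):
            if canon(oriented) in visited:
                break
            indeg = _indeg(oriented, graph)
            pred_branches = True
            if indeg == 1:
                pred = revcomp(_succs(revcomp(oriented), graph)[0])
                pred_branches = len(_succs(pred, graph)) != 1
            if indeg != 1 or pred_branches:
                unitigs.append(walk(oriented))
                break
    # remaining k-mers sit on isolated simple cycles
    for km in ordered:
        if km not in visited:
            unitigs.append(walk(km))

    contigs = sorted(
        {min(u, revcomp(u)) for u in unitigs if len(u) >= min_contig_length},
        key=lambda s: (-len(s), s),
    )
    return Assembly(
        run_id=f"k{graph.k}",
        contigs=contigs,
        provenance={"k": graph.k, "min_count": graph.min_count},
    )


def assemble(
    dataset: ReadDataset,
    k: int,
    min_count: int = 2,
    min_contig_length: int = 200,
) -> Assembly:
    """Build the graph and extract unitigs in one call."""
    asm = extract_unitigs(
        build_graph(dataset, k, min_count=min_count),
        min_contig_length=min_contig_length,
    )
    asm.run_id = f"{dataset.dataset_id}.k{k}"
    asm.provenance["dataset_id"] = dataset.dataset_id
    return asm


def multi_k_sweep(
    dataset: ReadDataset,
    k_values: list[int],
    min_count: int = 2,
    min_contig_length: int = 200,
) -> list[Assembly]:
    """One assembly per k; individual failures are recorded, not fatal."""
    if not k_values:
        raise ValueError("k_values must be non-empty")
    out = []
    for k in k_values:
        try:
            out.append(
                assemble(dataset, k, min_count=min_count,
                         min_contig_length=min_contig_length)
            )
        except (ValueError, RuntimeError) as exc:
            out.append(
                Assembly(
                    run_id=f"{dataset.dataset_id}.k{k}",
                    contigs=[],
                    provenance={"k": k, "failed": True, "error": str(exc)},
                )
            )
    if all(a.failed for a in out):
        raise RuntimeError("every k value failed to assemble")
    return out
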