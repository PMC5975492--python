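"""End-to-end orchestration: Simulation - Assembly - Merging - Correction,
then dual-strategy variant calling and trio classification.

These convenience functions wire the per-module operations together the way
the four-step construction strategy prescribes: multi-k de Bruijn assembly
of deduplicated reads, metric screening, reference-guided merging of the
screened assemblies, boundary projection and IRb completion, and finally
genome comparison plus per-dataset pileup calling reconciled into one
variant table and a trio inheritance verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .assembly import Assembly, multi_k_sweep
from .genome import QuadripartiteGenome
from .mapping import build_index, map_dataset
from .merge import complete_irb, infer_partial_boundaries, merge_contigs
from .metrics import basic_metrics, screen_assemblies
from .readprep import (
    SizeEstimationError,
    dedup_pairs,
    estimate_genome_size,
    kmer_histogram,
)
from .simulate import ReadDataset
from .variants import (
    TrioClassification,
    Variant,
    annotate,
    classify_trio,
    compare_genomes,
    flag_problematic,
    integrate,
    pileup_call,
)

DEFAULT_K_VALUES = (25, 31, 41)


@dataclass
class ReconstructionResult:
    genome: QuadripartiteGenome
    merged: Assembly
    assemblies: list[Assembly]
    completion_report: dict
    core_span: tuple[int, int]


def reconstruct_genome(
    datasets: list[ReadDataset],
    reference: QuadripartiteGenome,
    k_values: tuple[int, ...] = DEFAULT_K_VALUES,
    min_count: int | None = None,
    min_contig_length: int = 200,
    name: str | None = None,
) -> ReconstructionResult:
    """Reconstruct a complete quadripartite genome from short reads.

    Reads are deduplicated and assembled at every k; assemblies are
    screened on total bases and contig count; the screened contigs are
    merged against the reference guide (adjacent unitigs from a k-DBG
    overlap by exactly k-1 bases, so the merge overlap floor is set to
    ``min(k_values) - 1``); the reference region boundaries are projected
    onto the merged core (LSC+IRa+SSC) super contig and the missing IRb
    tail is inferred from IRa.

    ``min_count=None`` derives the k-mer multiplicity floor per dataset
    from the k-mer spectrum's error valley (valley + 1, minimum 2), the
    standard coverage-cutoff choice; sequencing-error k-mers recur at
    realistic depths, so a fixed floor of 2 only suits error-free reads.
    """
    assemblies: list[Assembly] = []
    for ds in datasets:
        ds, _ = dedup_pairs(ds)
        mc = min_count
        if mc is None:
            try:
                est = estimate_genome_size(
                    kmer_histogram(ds, min(k_values))
                )
                mc = max(2, est.error_valley + 1)
            except SizeEstimationError:
                mc = 2
        assemblies.extend(
            multi_k_sweep(ds, list(k_values), min_count=mc,
                          min_contig_length=min_contig_length)
        )
    screened = screen_assemblies(
        assemblies, reference_length=reference.length
    )
    if not screened:
        raise RuntimeError("no assembly passed screening")
    merged = merge_contigs(
        screened,
        reference,
        min_overlap=min(k_values) - 1,
        min_overlap_identity=0.99,
    )
    if not merged.contigs:
        raise RuntimeError("merging produced no super contigs")
    spans = merged.provenance["spans"]
    core_i = max(range(len(merged.contigs)),
                 key=lambda i: len(merged.contigs[i]))
    core = merged.contigs[core_i]
    boundaries = infer_partial_boundaries(core, reference)
    genome, report = complete_irb(
        core, boundaries, name=name or f"{datasets[0].dataset_id}.genome"
    )
    return ReconstructionResult(
        genome=genome,
        merged=merged,
        assemblies=assemblies,
        completion_report=report,
        core_span=spans[core_i],
    )


@dataclass
class TrioVariantResult:
    unified: list[Variant]
    comparison_sets: dict[str, list[Variant]]
    mapping_clean: dict[str, list[Variant]]
    mapping_problematic: dict[str, list]
    classification: TrioClassification


def call_trio_variants(
    clone_genomes: dict[str, QuadripartiteGenome],
    clone_datasets: dict[str, list[ReadDataset]],
    reference: QuadripartiteGenome,
    mother: str,
    father: str,
    offspring: str,
    gene_model: list | None = None,
    min_depth: int = 10,
    min_alt_fraction: float = 0.8,
    repeatability_min: float = 0.9,
) -> TrioVariantResult:
    """Dual-strategy variant discovery and inheritance classification.

    ``clone_genomes`` are the (reconstructed) clone assemblies compared
    against the reference; ``clone_datasets`` are each clone's read
    datasets, mapped and pileup-called independently so repeatability can
    be assessed.  Mapping calls are cleaned against the comparison sets,
    the two strategies are integrated, annotated, and the trio verdict is
    derived.
    """
    comparison_sets = {
        clone: compare_genomes(g, reference, clone=clone)
        for clone, g in clone_genomes.items()
    }
    index = build_index(reference)
    mapping_clean: dict[str, list[Variant]] = {}
    mapping_problematic: dict[str, list] = {}
    for clone, datasets in clone_datasets.items():
        call_sets = {}
        for ds in datasets:
            alignments = map_dataset(ds, index)
            calls, _suspects = pileup_call(
                alignments, reference, min_depth=min_depth,
                min_alt_fraction=min_alt_fraction, clone=clone,
                dataset_id=ds.dataset_id,
            )
            call_sets[ds.dataset_id] = calls
        clean, problematic = flag_problematic(
            call_sets, comparison_sets[clone], reference,
            repeatability_min=repeatability_min,
        )
        mapping_clean[clone] = clean
        mapping_problematic[clone] = problematic
    unified = integrate(comparison_sets, mapping_clean)
    annotate(unified, reference, gene_model or [],
             ref_sequence=reference.sequence)
    classification = classify_trio(unified, mother, father, offspring)
    return TrioVariantResult(
        unified=unified,
        comparison_sets=comparison_sets,
        mapping_clean=mapping_clean,
        mapping_problematic=mapping_problematic,
        classification=classification,
    )
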