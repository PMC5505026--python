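"""Reference + VCF input and phased-haplotype import.

Haplotype import walks each sample's phased genotypes along the reference
node chain, substituting alternate-allele nodes where the genotype says so.
Wherever a haplotype cannot be continued as a single valid walk — consecutive
chosen alleles not joined by an edge, loss of phasing at a heterozygous site,
a haploid or missing call, or conflicting alternate calls at one position —
the current piece is emitted and a new thread begun.  No semantic
reconciliation of conflicting records is attempted: splitting is the only
fallback, and every emitted piece validates against the graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio import SeqIO

from .graph import (
    AlleleMap,
    BidirectedGraph,
    GraphError,
    VariantSpec,
    left_side,
    right_side,
)
from .threads import Thread, from_node_path


class ImportError_(GraphError):
    pass


def read_reference(path: str, name: str | None = None) -> str:
    """First FASTA record's sequence, or the record matching ``name``."""
    for record in SeqIO.parse(path, "fasta"):
        if name is None or record.id == name:
            return str(record.seq).upper()
    raise ImportError_(
        f"no FASTA record {name!r} in {path}" if name else f"no records in {path}"
    )


def variants_from_vcf(path: str) -> list[VariantSpec]:
    """VCF records as biallelic VariantSpecs (multiallelics split per alt).

    Positions convert from VCF 1-based to internal 0-based offsets.  Split
    alts of one record share a reference interval, which the graph builder
    treats as one reference-allele node with several alternates.
    """
    import pysam

    specs: list[VariantSpec] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            for alt in rec.alts or ():
                if set(alt.upper()) - set("ACGTN"):
                    raise ImportError_(
                        f"symbolic/breakend alt {alt!r} at {rec.pos} not supported"
                    )
                specs.append(VariantSpec(rec.start, rec.ref, alt))
    return specs


@dataclass
class HaplotypeImportReport:
    """Tallies from one phased-VCF import."""

    n_samples: int = 0
    n_haplotypes: int = 0
    n_threads_emitted: int = 0
    n_splits: int = 0
    split_reasons: dict[str, int] = field(default_factory=dict)

    def _record_split(self, reason: str) -> None:
        self.n_splits += 1
        self.split_reasons[reason] = self.split_reasons.get(reason, 0) + 1


# Per-site resolution for one haplotype: a node id, or a split marker.
_GAP_UNPHASED = "unphased"
_GAP_MISSING = "missing"
_GAP_HAPLOID = "haploid"
_GAP_CONFLICT = "other"


def import_phased_vcf(
    path: str,
    g: BidirectedGraph,
    alleles: AlleleMap,
    variants: Sequence[VariantSpec],
) -> tuple[list[Thread], HaplotypeImportReport]:
    """Import phased genotypes as threads over a reference+variants build.

    ``variants`` must be the list the graph was built from (parallel to
    ``alleles.variant_nodes``); records are matched back to it by
    (0-based position, ref, alt).  Returns the emitted threads (two
    haplotypes per sample, possibly split into pieces) plus a report of the
    split events and their reasons.
    """
    import pysam

    key_to_variant = {
        (v.ref_start, v.ref_allele.upper(), v.alt_allele.upper()): i
        for i, v in enumerate(variants)
    }
    report = HaplotypeImportReport()
    threads: list[Thread] = []

    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        report.n_samples = len(samples)
        report.n_haplotypes = 2 * len(samples)
        # site decisions: (sample, hap) -> {chain position: node id or gap reason}
        decisions: dict[tuple[str, int], dict[int, int | str]] = {
            (s, h): {} for s in samples for h in (0, 1)
        }
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            alt_variant = {}
            ref_variant = None
            for alt in rec.alts or ():
                vi = key_to_variant.get((rec.start, rec.ref.upper(), alt.upper()))
                if vi is None:
                    raise ImportError_(
                        f"variant {rec.ref}->{alt} at VCF pos {rec.pos} has no "
                        "mapped allele node in the graph"
                    )
                alt_variant[rec.alleles.index(alt)] = vi
                ref_variant = vi
            if ref_variant is None:
                continue  # record without alts contributes nothing
            pos = alleles.chain_position[ref_variant]
            ref_node = alleles.variant_nodes[ref_variant][0]
            for sample in samples:
                call = rec.samples[sample]
                gt = call.get("GT") or ()
                for h in (0, 1):
                    prior = decisions[(sample, h)].get(pos)
                    choice: int | str
                    if len(gt) < 2:
                        choice = _GAP_HAPLOID
                    elif h >= len(gt) or gt[h] is None:
                        choice = _GAP_MISSING
                    else:
                        allele_ix = gt[h]
                        is_het = len(set(a for a in gt if a is not None)) > 1
                        if is_het and not call.phased:
                            choice = _GAP_UNPHASED
                        elif allele_ix == 0:
                            choice = ref_node
                        elif allele_ix in alt_variant:
                            choice = alleles.variant_nodes[alt_variant[allele_ix]][1]
                        else:
                            raise ImportError_(
                                f"allele index {allele_ix} at VCF pos {rec.pos} "
                                "has no mapped node"
                            )
                    # Reconcile with other records at the same chain position
                    # (split multiallelics): alt beats ref; two alts conflict.
                    if prior is None or prior == ref_node:
                        decisions[(sample, h)][pos] = choice
                    elif isinstance(choice, int) and choice != ref_node and prior != choice:
                        decisions[(sample, h)][pos] = _GAP_CONFLICT

    variant_positions = set(alleles.chain_position)
    for sample in samples:
        for h in (0, 1):
            chosen = decisions[(sample, h)]
            path_nodes: list[int] = []
            for pos, ref_node in enumerate(alleles.chain):
                node: int | str
                if pos in variant_positions:
                    node = chosen.get(pos, ref_node)
                else:
                    node = ref_node
                if isinstance(node, str):  # gap: end the piece, skip the site
                    report._record_split(node)
                    if path_nodes:
                        threads.append(_to_thread(path_nodes, g))
                        path_nodes = []
                    continue
                if path_nodes and not g.has_edge(
                    right_side(path_nodes[-1]), left_side(node)
                ):
                    report._record_split("no_edge")
                    threads.append(_to_thread(path_nodes, g))
                    path_nodes = []
                path_nodes.append(node)
            if path_nodes:
                threads.append(_to_thread(path_nodes, g))

    report.n_threads_emitted = len(threads)
    return threads, report


def _to_thread(nodes: list[int], g: BidirectedGraph) -> Thread:
    return Thread.from_orientation(from_node_path([(n, True) for n in nodes], g))
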