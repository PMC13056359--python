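"""Operon delineation around target genes.

An operon is approximated as the maximal contiguous same-strand gene chain
containing the target in which every consecutive junction has an
intergenic distance of at most 300 bp (genes may overlap by up to 50 bp),
extended at most 15 genes on each side of the target. All thresholds are
parameters (:class:`~operonscan.model.OperonParams`).

The gap rule is chainwise: it constrains each junction between consecutive
members, not the distance of each member to the target. Extension on a
side stops at the first gene that fails any rule (no skipping), and the
reason is recorded. An oversized overlap breaks the chain exactly like an
oversized gap — skipping past it would produce a non-contiguous "operon".
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .model import (
    BoundaryReason,
    GeneRecord,
    Operon,
    OperonParams,
    TargetRecord,
    normalize_accession,
    target_key,
)

logger = logging.getLogger(__name__)


def intergenic_distance(prev: GeneRecord, nxt: GeneRecord) -> int:
    """Signed intergenic distance in bp between two genes on one contig.

    With 1-based inclusive coordinates this is ``nxt.start - prev.end - 1``:
    0 for abutting genes, negative for an overlap of ``|value|`` bp.
    """
    if prev.contig_id != nxt.contig_id or prev.assembly_id != nxt.assembly_id:
        raise ValueError(
            f"genes on different contigs: {prev.contig_id} vs {nxt.contig_id}"
        )
    return nxt.start - prev.end - 1


def _junction_reason(
    inner: GeneRecord, outer: GeneRecord, target_strand: str, params: OperonParams
) -> BoundaryReason | None:
    """Check one junction (chain member ``inner`` to candidate ``outer``,
    in start order); return the failure reason or None if the candidate
    joins. Distance rules are checked before the strand rule."""
    left, right = (inner, outer) if inner.start <= outer.start else (outer, inner)
    d = intergenic_distance(left, right)
    if d > params.max_intergenic_bp:
        return BoundaryReason.gap_exceeded
    if d < -params.max_overlap_bp:
        return BoundaryReason.overlap_exceeded
    if params.require_same_strand and outer.strand != target_strand:
        return BoundaryReason.strand_change
    return None


def call_operon(
    contig_genes: Sequence[GeneRecord],
    target: GeneRecord,
    params: OperonParams = OperonParams(),
) -> Operon:
    """Delineate the operon around ``target`` on its contig.

    ``contig_genes`` must be the full gene list of one contig, ordered by
    ``gene_index``. The target itself is always a member; a size-1 operon
    is the no-neighbor case.
    """
    try:
        t = next(
            i
            for i, g in enumerate(contig_genes)
            if g.gene_index == target.gene_index and g is target
        )
    except StopIteration:
        # fall back to equality in case the caller rebuilt records
        matches = [i for i, g in enumerate(contig_genes) if g == target]
        if not matches:
            raise ValueError(
                f"target {target.protein_accession!r} not among contig_genes"
            )
        t = matches[0]

    def extend(direction: int) -> Tuple[int, BoundaryReason]:
        index = t
        added = 0
        while True:
            nxt = index + direction
            if nxt < 0 or nxt >= len(contig_genes):
                return index, BoundaryReason.contig_end
            if added >= params.max_genes_each_side:
                return index, BoundaryReason.gene_limit
            reason = _junction_reason(
                contig_genes[index], contig_genes[nxt], target.strand, params
            )
            if reason is not None:
                return index, reason
            index = nxt
            added += 1

    left, left_reason = extend(-1)
    right, right_reason = extend(+1)
    return Operon(
        target_accession=(
            normalize_accession(target.protein_accession)
            if target.protein_accession
            else ""
        ),
        members=list(contig_genes[left : right + 1]),
        left_boundary_reason=left_reason,
        right_boundary_reason=right_reason,
    )


def call_all_operons(
    linked_targets: Iterable[Tuple[TargetRecord, GeneRecord]],
    gene_records: Iterable[GeneRecord],
    params: OperonParams = OperonParams(),
) -> Dict[tuple, Operon]:
    """Call one operon per linked target.

    Returns a map keyed by ``(assembly_id, accession)`` (accessions can
    recur across assemblies). Targets sharing a contig are processed
    independently; their operons may overlap.
    """
    by_contig: Dict[Tuple[str, str], List[GeneRecord]] = {}
    for record in gene_records:
        by_contig.setdefault((record.assembly_id, record.contig_id), []).append(record)
    for genes in by_contig.values():
        genes.sort(key=lambda g: g.gene_index)

    operons: Dict[tuple, Operon] = {}
    for target, record in linked_targets:
        contig_genes = by_contig.get((record.assembly_id, record.contig_id))
        if contig_genes is None:
            raise ValueError(
                f"no gene records for contig {record.contig_id} of "
                f"{record.assembly_id}"
            )
        operons[target_key(target)] = call_operon(contig_genes, record, params)
    return operons


def write_operons(operons: Dict[tuple, Operon], path) -> None:
    """Write operons as TSV: one row per (target, member) with the junction
    distance to the previous member and the boundary reasons."""
    rows = []
    for (assembly_id, accession), operon in sorted(operons.items()):
        prev = None
        for member in operon.members:
            rows.append(
                {
                    "assembly_id": assembly_id,
                    "target_accession": accession,
                    "member_accession": member.protein_accession or ".",
                    "contig_id": member.contig_id,
                    "gene_index": member.gene_index,
                    "start": member.start,
                    "end": member.end,
                    "strand": member.strand,
                    "distance_to_previous": (
                        intergenic_distance(prev, member) if prev is not None else "."
                    ),
                    "is_target": int(
                        member.protein_accession is not None
                        and normalize_accession(member.protein_accession) == accession
                    ),
                    "operon_size": operon.size,
                    "left_boundary_reason": operon.left_boundary_reason.value,
                    "right_boundary_reason": operon.right_boundary_reason.value,
                }
            )
            prev = member
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
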