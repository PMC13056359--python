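"""Sequence- and linkage-level curation filters applied before
neighborhood analysis.

Three filters: a minimum amino-acid length (default 400, strictly below is
removed), exact-duplicate sequence removal (first occurrence kept), and the
requirement that each target can be located among the CDS annotations of
its stated assembly. Identity clustering at sub-100% thresholds is not
performed here; inputs are assumed pre-clustered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from .model import (
    GeneRecord,
    TargetRecord,
    ValidationError,
    normalize_accession,
    target_key,
)

logger = logging.getLogger(__name__)


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read a protein FASTA into (accession, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def filter_by_length(
    sequences: Sequence[Tuple[str, str]], min_length_aa: int = 400
) -> List[Tuple[str, str]]:
    """Keep sequences of length >= ``min_length_aa`` ("below" is strict:
    length 400 is kept at the default threshold). Order is preserved."""
    for accession, seq in sequences:
        if not seq.isalpha():
            raise ValidationError(
                f"{accession}: sequence contains non-alphabetic characters"
            )
    kept = [(a, s) for a, s in sequences if len(s) >= min_length_aa]
    removed = len(sequences) - len(kept)
    if removed:
        logger.info(
            "length filter (<%d aa): removed %d of %d sequences",
            min_length_aa,
            removed,
            len(sequences),
        )
    return kept


def deduplicate_exact(
    sequences: Sequence[Tuple[str, str]]
) -> List[Tuple[str, str]]:
    """Remove exact amino-acid duplicates, keeping the first occurrence.

    The removed->kept accession mapping is logged.
    """
    seen: Dict[str, str] = {}
    kept: List[Tuple[str, str]] = []
    for accession, seq in sequences:
        if seq in seen:
            logger.info("duplicate sequence: %s removed (kept %s)", accession, seen[seq])
            continue
        seen[seq] = accession
        kept.append((accession, seq))
    return kept


@dataclass
class LinkResult:
    """Outcome of linking targets to genome annotations."""

    linked: List[Tuple[TargetRecord, GeneRecord]] = field(default_factory=list)
    dropped: List[TargetRecord] = field(default_factory=list)
    #: targets found in an assembly other than the one they state
    mismatches: List[Tuple[TargetRecord, List[str]]] = field(default_factory=list)


def link_targets_to_annotations(
    targets: Iterable[TargetRecord], gene_records: Iterable[GeneRecord]
) -> LinkResult:
    """Link each target to the CDS record of its stated assembly.

    A target is linked iff its (normalized) accession occurs among the gene
    records of its stated assembly; otherwise it is dropped. A target whose
    accession exists only in *other* assemblies is still dropped but also
    flagged in the mismatch report rather than silently relinked.
    """
    by_assembly: Dict[Tuple[str, str], GeneRecord] = {}
    assemblies_by_accession: Dict[str, set] = {}
    for record in gene_records:
        if record.protein_accession is None:
            continue
        accession = normalize_accession(record.protein_accession)
        by_assembly.setdefault((record.assembly_id, accession), record)
        assemblies_by_accession.setdefault(accession, set()).add(record.assembly_id)

    result = LinkResult()
    for target in targets:
        assembly, accession = target_key(target)
        record = by_assembly.get((assembly, accession))
        if record is not None:
            result.linked.append((target, record))
        else:
            result.dropped.append(target)
            elsewhere = sorted(assemblies_by_accession.get(accession, ()))
            if elsewhere:
                result.mismatches.append((target, elsewhere))
    logger.info(
        "target linkage: %d linked, %d dropped (%d assembly mismatches)",
        len(result.linked),
        len(result.dropped),
        len(result.mismatches),
    )
    return result


def write_dropped_report(result: LinkResult, path) -> None:
    """Write dropped targets (with any mismatching assemblies) as TSV."""
    elsewhere = {target_key(t): assemblies for t, assemblies in result.mismatches}
    rows = [
        {
            "protein_accession": t.protein_accession,
            "family": t.family,
            "clade_label": t.clade_label,
            "assembly_id": t.assembly_id,
            "found_in_other_assemblies": ",".join(elsewhere.get(target_key(t), [])) or ".",
        }
        for t in result.dropped
    ]
    pd.DataFrame(
        rows,
        columns=[
            "protein_accession",
            "family",
            "clade_label",
            "assembly_id",
            "found_in_other_assemblies",
        ],
    ).to_csv(path, sep="\t", index=False)
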