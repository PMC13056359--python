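"""Shared data model for gene-neighborhood analysis.

Coordinates follow the GFF3 convention: 1-based, inclusive on both ends.
All intergenic-gap arithmetic in the package is defined on this convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

CODH_CLADES = ("A", "B", "C", "D", "E", "F")
HCP_CLASSES = ("I", "II", "III")

#: Valid clade/class vocabulary per family.
FAMILY_LABELS = {"CODH": CODH_CLADES, "HCP": HCP_CLASSES}

_VERSION_SUFFIX = re.compile(r"\.\d+$")


class ValidationError(ValueError):
    """Input violates a documented invariant (bad strand, bad label, ...)."""


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


def normalize_accession(accession: str) -> str:
    """Strip an NCBI-style version suffix (``WP_123.1`` -> ``WP_123``).

    This is the single normalization point used before every accession map
    lookup; NCBI tables mix versioned and unversioned forms.
    """
    return _VERSION_SUFFIX.sub("", accession.strip())


@dataclass(frozen=True, order=True)
class GeneRecord:
    """One annotated CDS on a contig.

    ``gene_index`` is the ordinal of the gene among all genes on its contig
    after sorting by (start, end) — the unit the neighbor window is counted
    over. Genes without a protein product keep their slot in the order.
    """

    assembly_id: str
    contig_id: str
    gene_index: int
    start: int
    end: int
    strand: str
    protein_accession: Optional[str] = None
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"end ({self.end}) < start ({self.start}) for "
                f"{self.protein_accession or self.contig_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.gene_index < 0:
            raise ValidationError("gene_index must be non-negative")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TargetRecord:
    """A gene-family member (CODH or HCP) with its clade/class label."""

    protein_accession: str
    family: str
    clade_label: str
    assembly_id: str
    organism_taxid: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILY_LABELS:
            raise ValidationError(f"unknown family {self.family!r}")
        if self.clade_label not in FAMILY_LABELS[self.family]:
            raise ValidationError(
                f"label {self.clade_label!r} is not valid for family "
                f"{self.family} (expected one of {FAMILY_LABELS[self.family]})"
            )
        if not self.assembly_id:
            raise ValidationError("assembly_id must be non-empty")


class AnnotationSource(str, Enum):
    eggnog = "eggnog"
    ncbi_product = "ncbi_product"
    manual = "manual"


@dataclass(frozen=True)
class FunctionAnnotation:
    """A functional annotation for one protein, from one source."""

    protein_accession: str
    description: Optional[str] = None
    ortholog_group: Optional[str] = None
    source: AnnotationSource = AnnotationSource.ncbi_product

    def __post_init__(self) -> None:
        if not self.description and not self.ortholog_group:
            raise ValidationError(
                f"{self.protein_accession}: at least one of description/"
                "ortholog_group must be present"
            )


class BoundaryReason(str, Enum):
    """Why operon extension stopped on one side of the target."""

    gap_exceeded = "gap_exceeded"
    overlap_exceeded = "overlap_exceeded"
    strand_change = "strand_change"
    gene_limit = "gene_limit"
    contig_end = "contig_end"


@dataclass(frozen=True)
class OperonParams:
    """Operon-chain rule thresholds.

    Defaults: at most 15 genes on each side of the target, junction gaps of
    at most 300 bp, junction overlaps of at most 50 bp, and a same-strand
    requirement (a strand flip breaks the chain).
    """

    max_genes_each_side: int = 15
    max_intergenic_bp: int = 300
    max_overlap_bp: int = 50
    require_same_strand: bool = True

    def __post_init__(self) -> None:
        for name in ("max_genes_each_side", "max_intergenic_bp", "max_overlap_bp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def max_operon_size(self) -> int:
        return 2 * self.max_genes_each_side + 1


@dataclass
class Operon:
    """The maximal same-operon gene chain around one target gene."""

    target_accession: str
    members: list  # list[GeneRecord], ordered by start
    left_boundary_reason: BoundaryReason
    right_boundary_reason: BoundaryReason

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def member_accessions(self) -> tuple:
        return tuple(
            m.protein_accession for m in self.members if m.protein_accession
        )


@dataclass(frozen=True)
class CurationParams:
    min_length_aa: int = 400
    dedup_exact: bool = True

    def __post_init__(self) -> None:
        if self.min_length_aa < 1:
            raise ValidationError("min_length_aa must be >= 1")


@dataclass(frozen=True)
class ProfileParams:
    """Reporting thresholds for per-clade operon-content profiles.

    With ``cutoff_strict`` (default) a category is reported only when its
    proportion is strictly greater than ``report_cutoff``.
    """

    report_cutoff: float = 0.10
    cutoff_strict: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.report_cutoff <= 1.0:
            raise ValidationError("report_cutoff must be in [0, 1]")


def target_key(target: TargetRecord) -> tuple:
    """Unique key for a target: protein accessions can recur across
    assemblies (identical proteins share one accession), so targets are
    keyed by (assembly_id, accession)."""
    return (target.assembly_id, normalize_accession(target.protein_accession))
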