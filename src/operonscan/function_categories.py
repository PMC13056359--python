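"""Functional categorization of operon members.

Each gene receives exactly one category from a fixed vocabulary via
prioritized, case-insensitive regular-expression rules applied to its
annotation text (NCBI product strings and/or imported ortholog-database
descriptions), with curated per-accession overrides taking precedence over
every rule. The default rule set ships as an editable TSV data file: it is
a best-effort reconstruction of common product-name conventions, not a
frozen piece of logic.

Priorities are specific-before-generic: the maturases CooC/CooT/CooJ
before generic regulators, ferredoxin before the generic iron-sulfur
category (every ferredoxin is an FeS protein), hydrogenase maturation
machinery before hydrogenase, ABC transporters before generic
transporters. Lower priority number wins; ties break by rule-file order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import pandas as pd

from .model import (
    AnnotationSource,
    FormatError,
    FunctionAnnotation,
    GeneRecord,
    Operon,
    ValidationError,
    normalize_accession,
)

logger = logging.getLogger(__name__)

#: Category vocabulary, in reporting order; "other" is always last.
CATEGORY_VOCABULARY = (
    "one_carbon_pool",
    "cooC",
    "cooT",
    "cooJ",
    "ferredoxin",
    "fes_protein",
    "hydrogenase",
    "hydrogenase_maturase",
    "nadp_fad_oxidoreductase",
    "transcription_regulation",
    "other_regulation",
    "abc_transporter",
    "transporter",
    "other",
)

OTHER = "other"

#: The two regulation subtypes merge into this name for coarse reporting.
REGULATION_MERGED = "regulation"
REGULATION_SUBTYPES = ("transcription_regulation", "other_regulation")


@dataclass(frozen=True)
class CategoryRule:
    category: str
    priority: int
    pattern: str
    scope: str = "any"  # any | eggnog | ncbi_product
    order: int = 0  # position in the rule file, tie-break

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_VOCABULARY:
            raise ValidationError(f"unknown category {self.category!r}")
        try:
            re.compile(self.pattern, re.IGNORECASE)
        except re.error as exc:
            raise ValidationError(
                f"rule for {self.category}: pattern does not compile: {exc}"
            )

    @property
    def regex(self) -> re.Pattern:
        return re.compile(self.pattern, re.IGNORECASE)


def load_rules(path=None) -> List[CategoryRule]:
    """Load categorization rules from a TSV (category, priority, pattern,
    scope); with no path, the packaged default rule set."""
    if path is None:
        with resources.files("operonscan.data").joinpath(
            "default_rules.tsv"
        ).open("r", encoding="utf-8") as handle:
            frame = pd.read_csv(handle, sep="\t", dtype=str, keep_default_na=False)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"category", "priority", "pattern"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"rules file: missing columns {sorted(missing)}")
    rules = [
        CategoryRule(
            category=row.category,
            priority=int(row.priority),
            pattern=row.pattern,
            scope=getattr(row, "scope", "any") or "any",
            order=i,
        )
        for i, row in enumerate(frame.itertuples(index=False))
    ]
    return sorted(rules, key=lambda r: (r.priority, r.order))


def load_overrides(path) -> Dict[str, str]:
    """Load curated accession->category overrides (TSV: protein_accession,
    category). Accessions are version-normalized on load."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in ("protein_accession", "category"):
        if column not in frame.columns:
            raise FormatError(f"overrides file: missing column {column!r}")
    overrides: Dict[str, str] = {}
    for row in frame.itertuples(index=False):
        if row.category not in CATEGORY_VOCABULARY:
            raise ValidationError(
                f"override {row.protein_accession}: unknown category "
                f"{row.category!r}"
            )
        overrides[normalize_accession(row.protein_accession)] = row.category
    return overrides


def _gather_texts(
    gene: GeneRecord,
    annotations: Mapping[str, FunctionAnnotation],
) -> Dict[str, str]:
    """Collect annotation text per source for one gene."""
    texts: Dict[str, List[str]] = {}
    if gene.product:
        texts.setdefault("ncbi_product", []).append(gene.product)
    if gene.protein_accession:
        annotation = annotations.get(normalize_accession(gene.protein_accession))
        if annotation is not None:
            source = annotation.source.value
            if annotation.description:
                texts.setdefault(source, []).append(annotation.description)
            if annotation.ortholog_group:
                texts.setdefault(source, []).append(annotation.ortholog_group)
    return {source: " | ".join(parts) for source, parts in texts.items()}


def assign_category(
    gene: GeneRecord,
    annotations: Mapping[str, FunctionAnnotation],
    rules: List[CategoryRule],
    overrides: Optional[Mapping[str, str]] = None,
) -> Tuple[str, str]:
    """Assign one category to a gene; returns (category, provenance).

    Precedence: accession override > lowest-priority matching rule >
    ``other``. The function is total: genes without accession or without
    any annotation text fall through to ``other``.
    """
    if overrides and gene.protein_accession:
        category = overrides.get(normalize_accession(gene.protein_accession))
        if category is not None:
            return category, "override"
    texts = _gather_texts(gene, annotations)
    if texts:
        combined = " | ".join(texts[s] for s in sorted(texts))
        for rule in rules:  # pre-sorted by (priority, order)
            haystack = combined if rule.scope == "any" else texts.get(rule.scope, "")
            if haystack and rule.regex.search(haystack):
                return rule.category, f"rule:{rule.category}:{rule.pattern}"
    return OTHER, "fallback"


def assign_all(
    gene_records: Iterable[GeneRecord],
    annotations: Mapping[str, FunctionAnnotation],
    rules: Optional[List[CategoryRule]] = None,
    overrides: Optional[Mapping[str, str]] = None,
) -> Dict[tuple, Tuple[str, str]]:
    """Assign categories to every gene record; keyed by
    (assembly_id, contig_id, gene_index) so accession-less genes are covered."""
    if rules is None:
        rules = load_rules()
    assignments = {}
    for gene in gene_records:
        assignments[(gene.assembly_id, gene.contig_id, gene.gene_index)] = (
            assign_category(gene, annotations, rules, overrides)
        )
    return assignments


def categorize_operon(
    operon: Operon, assignments: Mapping[tuple, Tuple[str, str]]
) -> Set[str]:
    """Category-presence set of an operon's non-target members.

    The target member is excluded, as is its own category among the other
    members, and ``other`` never appears in the set (it marks absence of a
    recognized function, not a function). A size-1 operon yields the empty
    set.
    """
    target_category = None
    member_categories: List[str] = []
    for member in operon.members:
        key = (member.assembly_id, member.contig_id, member.gene_index)
        if key not in assignments:
            raise ValidationError(
                f"operon member {member.protein_accession or key} has no "
                "category assignment"
            )
        category = assignments[key][0]
        is_target = (
            member.protein_accession is not None
            and normalize_accession(member.protein_accession)
            == operon.target_accession
        )
        if is_target:
            target_category = category
        else:
            member_categories.append(category)
    present = set(member_categories)
    present.discard(OTHER)
    if target_category is not None:
        present.discard(target_category)
    return present


def merge_regulation(categories: Set[str]) -> Set[str]:
    """Collapse the two regulation subtypes into one ``regulation`` label
    (union semantics)."""
    merged = set(categories)
    if merged & set(REGULATION_SUBTYPES):
        merged -= set(REGULATION_SUBTYPES)
        merged.add(REGULATION_MERGED)
    return merged


def write_assignments(
    gene_records: Iterable[GeneRecord],
    assignments: Mapping[tuple, Tuple[str, str]],
    path,
) -> None:
    rows = []
    for gene in gene_records:
        key = (gene.assembly_id, gene.contig_id, gene.gene_index)
        category, provenance = assignments[key]
        rows.append(
            {
                "assembly_id": gene.assembly_id,
                "contig_id": gene.contig_id,
                "gene_index": gene.gene_index,
                "protein_accession": gene.protein_accession or ".",
                "category": category,
                "provenance": provenance,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
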