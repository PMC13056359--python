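"""Reading and writing genome annotations and tabular inputs/outputs.

GFF3 is read through gffutils' line parser; only CDS features are kept and
multi-segment CDS (one gene model split over several feature lines sharing
an ID) are merged to their min-start/max-end envelope. Tables are plain
UTF-8 TSV with ``.`` (or empty) for missing values.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import pandas as pd
from gffutils.feature import feature_from_line

from .model import (
    AnnotationSource,
    FormatError,
    FunctionAnnotation,
    GeneRecord,
    TargetRecord,
    ValidationError,
    normalize_accession,
)

logger = logging.getLogger(__name__)

MISSING = "."

GENE_TABLE_COLUMNS = [
    "assembly_id",
    "contig_id",
    "gene_index",
    "start",
    "end",
    "strand",
    "protein_accession",
    "product",
]

TARGET_TABLE_COLUMNS = ["protein_accession", "family", "clade_label", "assembly_id"]


def _infer_assembly_id(path) -> str:
    stem = Path(path).name
    for suffix in (".gz", ".gff3", ".gff", ".tsv"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    return stem


def read_gff3(path, assembly_id: Optional[str] = None) -> List[GeneRecord]:
    """Read CDS features from a GFF3 file into sorted :class:`GeneRecord` s.

    Per contig, records are sorted by (start, end) — ties broken by
    accession for determinism — and ``gene_index`` is assigned 0..n-1.
    The protein accession comes from the ``protein_id`` attribute when
    present, falling back to ``ID``; the product from ``product``.
    """
    if assembly_id is None:
        assembly_id = _infer_assembly_id(path)

    # key -> dict with contig/strand/start/end/accession/product
    segments: Dict[tuple, dict] = {}
    anonymous = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##FASTA"):
                break
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if fields[2] != "CDS":
                continue
            feature = feature_from_line(line)
            if feature.strand not in ("+", "-"):
                raise ValidationError(
                    f"{path}: line {lineno}: unknown strand symbol "
                    f"{feature.strand!r}"
                )
            start, end = feature.start, feature.end
            if end < start:
                raise ValidationError(
                    f"{path}: line {lineno}: end ({end}) < start ({start})"
                )
            accession = None
            for attr in ("protein_id", "ID"):
                if attr in feature.attributes:
                    accession = feature.attributes[attr][0]
                    break
            product = (
                feature.attributes["product"][0]
                if "product" in feature.attributes
                else None
            )
            if accession is None:
                anonymous += 1
                key = (feature.seqid, f"__anon_{anonymous}")
            else:
                key = (feature.seqid, accession)
            seg = segments.get(key)
            if seg is None:
                segments[key] = {
                    "contig": feature.seqid,
                    "strand": feature.strand,
                    "start": start,
                    "end": end,
                    "accession": accession,
                    "product": product,
                }
            else:
                # multi-segment CDS: merge to the envelope
                seg["start"] = min(seg["start"], start)
                seg["end"] = max(seg["end"], end)
                if seg["product"] is None:
                    seg["product"] = product

    records: List[GeneRecord] = []
    by_contig: Dict[str, list] = {}
    for seg in segments.values():
        by_contig.setdefault(seg["contig"], []).append(seg)
    for contig in sorted(by_contig):
        genes = sorted(
            by_contig[contig],
            key=lambda s: (s["start"], s["end"], s["accession"] or ""),
        )
        for index, seg in enumerate(genes):
            accession = seg["accession"]
            records.append(
                GeneRecord(
                    assembly_id=assembly_id,
                    contig_id=contig,
                    gene_index=index,
                    start=seg["start"],
                    end=seg["end"],
                    strand=seg["strand"],
                    protein_accession=(
                        None
                        if accession is None or accession.startswith("__anon")
                        else accession
                    ),
                    product=seg["product"],
                )
            )
    return records


def read_gff3_directory(directory) -> List[GeneRecord]:
    """Read every ``*.gff3``/``*.gff`` file in a directory; the assembly id
    is the file stem."""
    records: List[GeneRecord] = []
    paths = sorted(
        p for p in Path(directory).iterdir() if p.suffix in (".gff3", ".gff")
    )
    for path in paths:
        records.extend(read_gff3(path))
    return records


def write_gene_records(records: Iterable[GeneRecord], path) -> None:
    """Write gene records to the internal TSV form (round-trip safe)."""
    rows = [
        {
            "assembly_id": r.assembly_id,
            "contig_id": r.contig_id,
            "gene_index": r.gene_index,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "protein_accession": r.protein_accession or MISSING,
            "product": r.product or MISSING,
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_gene_records(path) -> List[GeneRecord]:
    """Read the internal gene-record TSV written by :func:`write_gene_records`."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(GENE_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            GeneRecord(
                assembly_id=row.assembly_id,
                contig_id=row.contig_id,
                gene_index=int(row.gene_index),
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                protein_accession=(
                    None if row.protein_accession in (MISSING, "") else row.protein_accession
                ),
                product=None if row.product in (MISSING, "") else row.product,
            )
        )
    return records


def read_targets(path) -> List[TargetRecord]:
    """Read the target-gene table (TSV with header).

    Required columns: protein_accession, family, clade_label, assembly_id;
    optional: organism_taxid. Duplicate (accession, assembly) rows collapse
    to the first occurrence with a warning. A clade label outside its
    family's vocabulary raises :class:`ValidationError` listing the rows.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(TARGET_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns: {sorted(missing)}")

    targets: List[TargetRecord] = []
    seen = set()
    bad_rows = []
    duplicates = 0
    for pos, row in enumerate(frame.itertuples(index=False), start=2):
        taxid = getattr(row, "organism_taxid", MISSING)
        try:
            record = TargetRecord(
                protein_accession=row.protein_accession,
                family=row.family,
                clade_label=row.clade_label,
                assembly_id=row.assembly_id,
                organism_taxid=(
                    None if taxid in (MISSING, "") else int(taxid)
                ),
            )
        except ValidationError as exc:
            bad_rows.append(f"row {pos}: {exc}")
            continue
        key = (normalize_accession(record.protein_accession), record.assembly_id)
        if key in seen:
            duplicates += 1
            continue
        seen.add(key)
        targets.append(record)
    if bad_rows:
        raise ValidationError(
            f"{path}: invalid target rows:\n" + "\n".join(bad_rows)
        )
    if duplicates:
        logger.warning("%s: collapsed %d duplicate target rows", path, duplicates)
    return targets


def write_targets(targets: Iterable[TargetRecord], path) -> None:
    rows = [
        {
            "protein_accession": t.protein_accession,
            "family": t.family,
            "clade_label": t.clade_label,
            "assembly_id": t.assembly_id,
            "organism_taxid": t.organism_taxid if t.organism_taxid else MISSING,
        }
        for t in targets
    ]
    pd.DataFrame(rows, columns=TARGET_TABLE_COLUMNS + ["organism_taxid"]).to_csv(
        path, sep="\t", index=False
    )


_EGGNOG_QUERY = "#query"
_EGGNOG_DESCRIPTION = "Description"
_EGGNOG_OG = "eggNOG_OGs"


def read_function_annotations(
    path, source: AnnotationSource | str
) -> Dict[str, FunctionAnnotation]:
    """Read a functional-annotation table into an accession-keyed map.

    ``source='eggnog'`` expects the eggNOG-mapper ``.annotations`` dialect:
    ``##`` comment lines, a header line starting with ``#query``, and
    tab-separated fields including a Description and an OG column. Other
    sources expect a plain TSV with ``protein_accession`` and
    ``description`` columns. Later duplicates overwrite earlier entries
    with a warning. Keys are stored exactly as given — version-suffix
    normalization is the caller's job.
    """
    source = AnnotationSource(source)
    annotations: Dict[str, FunctionAnnotation] = {}
    overwritten = 0

    if source is AnnotationSource.eggnog:
        header = None
        data_rows = []
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line or line.startswith("##"):
                    continue
                if line.startswith(_EGGNOG_QUERY):
                    header = line.split("\t")
                    continue
                if header is None:
                    raise FormatError(
                        f"{path}: data before the '{_EGGNOG_QUERY}' header line"
                    )
                data_rows.append(line.split("\t"))
        if header is None:
            if data_rows:
                raise FormatError(f"{path}: no '{_EGGNOG_QUERY}' header line")
            return {}
        for column in (_EGGNOG_QUERY, _EGGNOG_DESCRIPTION):
            if column not in header:
                raise FormatError(f"{path}: missing required column {column!r}")
        iq = header.index(_EGGNOG_QUERY)
        idesc = header.index(_EGGNOG_DESCRIPTION)
        iog = header.index(_EGGNOG_OG) if _EGGNOG_OG in header else None
        for fields in data_rows:
            accession = fields[iq]
            description = fields[idesc] if idesc < len(fields) else ""
            og = fields[iog] if iog is not None and iog < len(fields) else ""
            if accession in annotations:
                overwritten += 1
            annotations[accession] = FunctionAnnotation(
                protein_accession=accession,
                description=description or None,
                ortholog_group=og or None,
                source=source,
            )
    else:
        frame = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, comment=None
        )
        for column in ("protein_accession", "description"):
            if column not in frame.columns:
                raise FormatError(f"{path}: missing required column {column!r}")
        for row in frame.itertuples(index=False):
            accession = row.protein_accession
            if accession in annotations:
                overwritten += 1
            annotations[accession] = FunctionAnnotation(
                protein_accession=accession,
                description=row.description or None,
                source=source,
            )
    if overwritten:
        logger.warning(
            "%s: %d duplicate accessions, later entries kept", path, overwritten
        )
    return annotations


def write_function_annotations(
    annotations: Dict[str, FunctionAnnotation], path
) -> None:
    rows = [
        {
            "protein_accession": a.protein_accession,
            "description": a.description or MISSING,
        }
        for a in annotations.values()
    ]
    pd.DataFrame(rows, columns=["protein_accession", "description"]).to_csv(
        path, sep="\t", index=False
    )
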