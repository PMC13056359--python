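"""Synthetic multi-assembly genome annotations with known ground truth.

The generator emulates the data regime of a prokaryotic gene-neighborhood
study: many genome assemblies, each carrying zero or more target-family
genes (CODH clades A-F, HCP classes I-III) whose presence, copy number and
operon content follow configurable probabilities. Each target sits in an
operon-structured gene run (within-operon junction gaps uniform on
[-50, 300] bp by default) flanked by distractor genes whose first junction
always violates the chain rule (oversized gap, or a strand flip within gap
range), so the true operon membership is known exactly. Neighbor function
is encoded in the emitted product strings, drawn from the language of the
default categorization rules, so rule-engine behaviour can be separated
from parsing behaviour; an optional annotation-noise fraction replaces
products with "hypothetical protein" to exercise the fallback path.

Not simulated: nucleotide/amino-acid sequences, phylogenies, taxonomy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .model import (
    CODH_CLADES,
    HCP_CLASSES,
    FAMILY_LABELS,
    AnnotationSource,
    BoundaryReason,
    FunctionAnnotation,
    GeneRecord,
    OperonParams,
    TargetRecord,
    ValidationError,
)
from .function_categories import CATEGORY_VOCABULARY, OTHER

#: Product-string templates per category, written in the vocabulary the
#: default rule set recognizes (no commas/semicolons: GFF3 attribute text).
PRODUCT_TEMPLATES: Dict[str, Tuple[str, ...]] = {
    "one_carbon_pool": (
        "formate dehydrogenase subunit alpha",
        "acetyl-CoA synthase subunit beta",
        "methylenetetrahydrofolate reductase",
        "formate--tetrahydrofolate ligase",
        "corrinoid/iron-sulfur protein methyltransferase",
    ),
    "cooC": (
        "CO dehydrogenase maturation factor",
        "carbon monoxide dehydrogenase accessory protein CooC",
    ),
    "cooT": ("nickel-binding protein CooT",),
    "cooJ": ("nickel chaperone CooJ",),
    "ferredoxin": ("4Fe-4S ferredoxin", "ferredoxin"),
    "fes_protein": (
        "iron-sulfur cluster-binding protein CooF",
        "4Fe-4S dicluster domain-containing protein",
    ),
    "hydrogenase": (
        "Ni/Fe-hydrogenase III large subunit",
        "hydrogenase large subunit",
    ),
    "hydrogenase_maturase": (
        "hydrogenase maturation protein HypD",
        "hydrogenase expression/formation protein HypE",
    ),
    "nadp_fad_oxidoreductase": (
        "NAD(P)/FAD-dependent oxidoreductase",
        "FAD-dependent oxidoreductase",
    ),
    "transcription_regulation": (
        "Rrf2 family transcriptional regulator",
        "LysR family transcriptional regulator",
    ),
    "other_regulation": ("response regulator", "anti-sigma factor antagonist"),
    "abc_transporter": (
        "ABC transporter ATP-binding protein",
        "ABC-type nickel transport system permease",
    ),
    "transporter": ("MFS transporter", "nickel/cobalt efflux transporter"),
    OTHER: ("hypothetical protein", "DUF1284 domain-containing protein"),
}

FAMILY_PRODUCTS = {
    "CODH": "carbon monoxide dehydrogenase",
    "HCP": "hydroxylamine reductase hybrid cluster protein",
}

HYPOTHETICAL = "hypothetical protein"

#: Default per-label assembly presence probabilities: the approximate
#: marginal rates of the clades/classes across assemblies in the kind of
#: survey this package targets (E is the largest CODH clade, B the
#: smallest; HCP classes are individually common).
DEFAULT_PRESENCE: Dict[str, float] = {
    "A": 0.13, "B": 0.14, "C": 0.18, "D": 0.26, "E": 0.45, "F": 0.26,
    "I": 0.35, "II": 0.30, "III": 0.25,
}

#: Copy-number distributions given presence (probabilities over 1..k).
#: Clades A, E, F often carry several same-clade isoforms; B, C, D and the
#: HCP classes almost always occur once.
DEFAULT_COPIES: Dict[str, Tuple[float, ...]] = {
    "A": (0.70, 0.22, 0.08), "E": (0.70, 0.22, 0.08), "F": (0.70, 0.22, 0.08),
    "B": (0.97, 0.03), "C": (0.97, 0.03), "D": (0.97, 0.03),
    "I": (0.95, 0.05), "II": (0.95, 0.05), "III": (0.95, 0.05),
}

#: Per-clade probabilities that a target's operon contains >=1 gene of a
#: category — the clade-specific neighborhood regimes (maturase-rich A/E/F,
#: transporter-dominated B, redox-partner-rich C, sparse D).
DEFAULT_NEIGHBOR_MODEL: Dict[str, Dict[str, float]] = {
    "A": {"one_carbon_pool": 0.93, "cooC": 0.62, "fes_protein": 0.31},
    "B": {"abc_transporter": 0.64, "transcription_regulation": 0.12},
    "C": {
        "fes_protein": 0.72,
        "nadp_fad_oxidoreductase": 0.71,
        "transcription_regulation": 0.58,
        "other_regulation": 0.10,
    },
    "D": {"transcription_regulation": 0.099, "other_regulation": 0.095},
    "E": {
        "cooC": 0.59,
        "one_carbon_pool": 0.49,
        "fes_protein": 0.29,
        "nadp_fad_oxidoreductase": 0.22,
        "transcription_regulation": 0.17,
        "cooT": 0.16,
        "cooJ": 0.12,
    },
    "F": {
        "cooC": 0.68,
        "fes_protein": 0.53,
        "nadp_fad_oxidoreductase": 0.42,
        "one_carbon_pool": 0.37,
        "transcription_regulation": 0.35,
        "hydrogenase": 0.25,
        "hydrogenase_maturase": 0.17,
        "transporter": 0.11,
        "cooT": 0.061,
        "cooJ": 0.05,
    },
    "I": {"fes_protein": 0.40, "transcription_regulation": 0.25},
    "II": {"fes_protein": 0.30, "nadp_fad_oxidoreductase": 0.25},
    "III": {"fes_protein": 0.35, "transcription_regulation": 0.20},
}


def _default_size_probs() -> Tuple[float, ...]:
    # truncated geometric over operon sizes 2..16: small operons dominate
    weights = np.array([0.5 ** k for k in range(15)])
    return tuple(float(w) for w in weights / weights.sum())


@dataclass
class SimulationConfig:
    """Study-condition knobs for the generator. Defaults describe the
    data regime the package was designed around; see docs for rationale."""

    n_assemblies: int = 200
    clade_presence: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRESENCE)
    )
    copies_given_present: Dict[str, Tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COPIES)
    )
    neighbor_model: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_NEIGHBOR_MODEL.items()}
    )
    #: probabilities over operon sizes 2, 3, ... given >=1 neighbor
    operon_size_probs: Tuple[float, ...] = field(
        default_factory=_default_size_probs
    )
    within_operon_gap: Tuple[int, int] = (-50, 300)
    flank_gap: Tuple[int, int] = (301, 3000)
    gene_length_bp: Tuple[int, int] = (300, 3000)
    #: probability that a flanking distractor flips strand (and then sits
    #: within gap range, so the strand rule is what blocks it)
    strand_flip_prob: float = 0.3
    n_distractor_genes: int = 6
    #: fraction of neighbor products replaced by "hypothetical protein"
    annotation_noise: float = 0.0
    #: place all copies of one label on a single contig (far apart)
    multi_target_contigs: bool = False
    operon_params: OperonParams = field(default_factory=OperonParams)
    seed: int = 0

    def validate(self) -> None:
        params = self.operon_params
        for label, p in self.clade_presence.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"presence[{label}] not in [0,1]")
            if label not in DEFAULT_COPIES and label not in self.copies_given_present:
                raise ValidationError(f"no copy distribution for label {label}")
        for label, model in self.neighbor_model.items():
            for category, p in model.items():
                if category not in CATEGORY_VOCABULARY:
                    raise ValidationError(f"unknown category {category!r}")
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(f"neighbor p[{label}][{category}] not in [0,1]")
        lo, hi = self.within_operon_gap
        if lo < -params.max_overlap_bp or hi > params.max_intergenic_bp:
            raise ValidationError(
                "within_operon_gap support must lie in "
                f"[-{params.max_overlap_bp}, {params.max_intergenic_bp}]"
            )
        if self.flank_gap[0] <= params.max_intergenic_bp:
            raise ValidationError(
                "flank_gap must strictly exceed max_intergenic_bp"
            )
        max_size = 1 + len(self.operon_size_probs)
        if max_size > params.max_operon_size:
            raise ValidationError(
                f"operon size support up to {max_size} exceeds the "
                f"{params.max_operon_size}-gene window"
            )
        if not 0.0 <= self.annotation_noise <= 1.0:
            raise ValidationError("annotation_noise not in [0,1]")
        if not 0.0 <= self.strand_flip_prob <= 1.0:
            raise ValidationError("strand_flip_prob not in [0,1]")
        if self.multi_target_contigs and self.n_distractor_genes < 1:
            raise ValidationError(
                "multi_target_contigs requires at least one distractor gene "
                "between loci"
            )


@dataclass(frozen=True)
class OperonTruth:
    """True operon of one simulated target."""

    assembly_id: str
    target_accession: str
    member_accessions: Tuple[str, ...]
    category_set: frozenset
    size: int
    left_reason: BoundaryReason
    right_reason: BoundaryReason


@dataclass
class GroundTruth:
    operons: Dict[tuple, OperonTruth]
    clade_counts: Dict[str, Counter]
    config: SimulationConfig


@dataclass
class SimulationResult:
    gene_records: List[GeneRecord]
    targets: List[TargetRecord]
    annotations: Dict[str, FunctionAnnotation]
    ground_truth: GroundTruth


def _label_family(label: str) -> str:
    for family, labels in FAMILY_LABELS.items():
        if label in labels:
            return family
    raise ValidationError(f"label {label!r} belongs to no known family")


def _ordered_labels(presence: Mapping[str, float]) -> List[str]:
    order = list(CODH_CLADES) + list(HCP_CLASSES)
    known = [label for label in order if label in presence]
    extra = sorted(set(presence) - set(known))
    return known + extra


class _ContigBuilder:
    """Lays out one contig left-to-right with explicit junction gaps."""

    def __init__(self, assembly_id: str, contig_id: str, rng: np.random.Generator,
                 config: SimulationConfig):
        self.assembly_id = assembly_id
        self.contig_id = contig_id
        self.rng = rng
        self.config = config
        self.entries: List[dict] = []  # {strand, product, accession, gap_before}

    def add(self, accession: str, product: str, strand: str, gap_before: Optional[int]):
        self.entries.append(
            {
                "accession": accession,
                "product": product,
                "strand": strand,
                "gap_before": gap_before,
            }
        )

    def build(self) -> List[GeneRecord]:
        records = []
        pos = 1000
        lo, hi = self.config.gene_length_bp
        for index, entry in enumerate(self.entries):
            if index > 0:
                pos = records[-1].end + 1 + entry["gap_before"]
            length = int(self.rng.integers(lo, hi + 1))
            records.append(
                GeneRecord(
                    assembly_id=self.assembly_id,
                    contig_id=self.contig_id,
                    gene_index=index,
                    start=pos,
                    end=pos + length - 1,
                    strand=entry["strand"],
                    protein_accession=entry["accession"],
                    product=entry["product"],
                )
            )
        return records


def simulate(
    config: SimulationConfig, out_dir: Optional[Path] = None
) -> SimulationResult:
    """Generate assemblies, targets, annotations and exact ground truth.

    Deterministic: identical config (including seed) gives identical
    in-memory objects and byte-identical files. With ``out_dir`` the
    GFF3/TSV dialects read by the ingestion module are written there.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    params = config.operon_params
    labels = _ordered_labels(config.clade_presence)

    gene_records: List[GeneRecord] = []
    targets: List[TargetRecord] = []
    truth_operons: Dict[tuple, OperonTruth] = {}
    clade_counts: Dict[str, Counter] = {}
    serial = 0

    for a in range(config.n_assemblies):
        assembly_id = f"SYN_{a:05d}"
        clade_counts[assembly_id] = Counter()
        contig_serial = 0
        for label in labels:
            if rng.random() >= config.clade_presence[label]:
                continue
            copy_probs = np.array(config.copies_given_present[label], dtype=float)
            copies = 1 + int(rng.choice(len(copy_probs), p=copy_probs / copy_probs.sum()))
            clade_counts[assembly_id][label] += copies
            family = _label_family(label)
            builder: Optional[_ContigBuilder] = None
            for copy in range(copies):
                if builder is None or not config.multi_target_contigs:
                    contig_serial += 1
                    builder = _ContigBuilder(
                        assembly_id, f"ctg_{a:05d}_{contig_serial:03d}", rng, config
                    )
                    first_on_contig = True
                else:
                    first_on_contig = False
                serial, target, truth_entry = _emit_target_locus(
                    builder, rng, config, label, family, serial, first_on_contig
                )
                targets.append(target)
                truth_operons[(assembly_id, target.protein_accession)] = truth_entry
                if not config.multi_target_contigs or copy == copies - 1:
                    gene_records.extend(builder.build())
                    if not config.multi_target_contigs:
                        builder = None

    truth = GroundTruth(
        operons=truth_operons, clade_counts=clade_counts, config=config
    )
    annotations = {
        r.protein_accession: FunctionAnnotation(
            protein_accession=r.protein_accession,
            description=r.product,
            source=AnnotationSource.ncbi_product,
        )
        for r in gene_records
        if r.protein_accession
    }
    result = SimulationResult(
        gene_records=gene_records,
        targets=targets,
        annotations=annotations,
        ground_truth=truth,
    )
    if out_dir is not None:
        write_simulation(result, Path(out_dir))
    return result


def _emit_target_locus(
    builder: _ContigBuilder,
    rng: np.random.Generator,
    config: SimulationConfig,
    label: str,
    family: str,
    serial: int,
    first_on_contig: bool,
) -> Tuple[int, TargetRecord, OperonTruth]:
    """Append one target operon plus flanking distractors to the builder."""
    params = config.operon_params
    model = config.neighbor_model.get(label, {})
    emitted = [
        category
        for category in CATEGORY_VOCABULARY
        if category in model and rng.random() < model[category]
    ]

    if emitted:
        size_probs = np.array(config.operon_size_probs, dtype=float)
        size = 2 + int(rng.choice(len(size_probs), p=size_probs / size_probs.sum()))
        size = max(size, len(emitted) + 1)
        size = min(size, params.max_operon_size)
    else:
        size = 1

    n_neighbors = size - 1
    neighbor_categories = list(emitted) + [OTHER] * (n_neighbors - len(emitted))
    neighbor_categories = [
        neighbor_categories[i] for i in rng.permutation(n_neighbors)
    ]
    side_cap = params.max_genes_each_side
    left_count = int(
        rng.integers(max(0, n_neighbors - side_cap), min(side_cap, n_neighbors) + 1)
    )
    target_strand = "+" if rng.random() < 0.5 else "-"

    def fresh_accession() -> str:
        nonlocal serial
        serial += 1
        return f"SWP_{serial:07d}"

    def neighbor_product(category: str) -> Tuple[str, str]:
        """(product, realized category) after annotation noise."""
        if category != OTHER and rng.random() < config.annotation_noise:
            return HYPOTHETICAL, OTHER
        templates = PRODUCT_TEMPLATES[category]
        return str(templates[int(rng.integers(len(templates)))]), category

    def flank_entry() -> Tuple[str, int, BoundaryReason]:
        """Distractor (strand, gap, blocking reason) for a boundary junction."""
        if rng.random() < config.strand_flip_prob:
            strand = "-" if target_strand == "+" else "+"
            gap = int(
                rng.integers(config.within_operon_gap[0], config.within_operon_gap[1] + 1)
            )
            return strand, gap, BoundaryReason.strand_change
        gap = int(rng.integers(config.flank_gap[0], config.flank_gap[1] + 1))
        return target_strand, gap, BoundaryReason.gap_exceeded

    def within_gap() -> int:
        return int(
            rng.integers(config.within_operon_gap[0], config.within_operon_gap[1] + 1)
        )

    n_flank = config.n_distractor_genes
    # left reason as the operon caller will report it
    if left_count >= side_cap and (n_flank > 0 or not first_on_contig):
        left_reason = BoundaryReason.gene_limit
    elif n_flank == 0:
        # no distractors: either the contig starts here or the previous
        # locus sits across an oversized (7 kb) spacer
        left_reason = (
            BoundaryReason.contig_end
            if first_on_contig
            else BoundaryReason.gap_exceeded
        )
    else:
        left_reason = None  # set by the boundary junction draw

    # left distractors, left-to-right; only the junction adjacent to the
    # operon (the last one here) must violate; earlier junctions get flank
    # gaps too so distractors never chain into the operon implicitly.
    boundary_left = None
    gap_pending: Optional[int] = 7000 if not first_on_contig else None
    for i in range(n_flank):
        strand, gap_after, reason = flank_entry()
        builder.add(fresh_accession(), HYPOTHETICAL, strand, gap_pending)
        gap_pending = gap_after
        boundary_left = reason
    if left_reason is None:
        left_reason = boundary_left if n_flank > 0 else BoundaryReason.contig_end

    # operon members
    member_accessions: List[str] = []
    realized: List[str] = []
    target_accession = None
    neighbor_iter = iter(neighbor_categories)
    for position in range(size):
        accession = fresh_accession()
        member_accessions.append(accession)
        if position == left_count:
            target_accession = accession
            product = FAMILY_PRODUCTS[family]
        else:
            category = next(neighbor_iter)
            product, category = neighbor_product(category)
            realized.append(category)
        builder.add(
            accession,
            product,
            target_strand,
            gap_pending if position == 0 else within_gap(),
        )
        gap_pending = None

    # right distractors
    right_count = n_neighbors - left_count
    if right_count >= side_cap and n_flank > 0:
        right_reason = BoundaryReason.gene_limit
    elif n_flank == 0:
        right_reason = BoundaryReason.contig_end
    else:
        right_reason = None
    for i in range(n_flank):
        strand, _, reason = flank_entry()
        if i == 0:
            # the junction adjacent to the operon carries the blocking draw
            gap = (
                within_gap()
                if reason is BoundaryReason.strand_change
                else int(rng.integers(config.flank_gap[0], config.flank_gap[1] + 1))
            )
            if right_reason is None:
                right_reason = reason
        else:
            gap = int(rng.integers(config.flank_gap[0], config.flank_gap[1] + 1))
        builder.add(fresh_accession(), HYPOTHETICAL, strand, gap)
    if right_reason is None:
        right_reason = BoundaryReason.contig_end

    category_set = frozenset(c for c in realized if c != OTHER)
    target = TargetRecord(
        protein_accession=target_accession,
        family=family,
        clade_label=label,
        assembly_id=builder.assembly_id,
    )
    truth_entry = OperonTruth(
        assembly_id=builder.assembly_id,
        target_accession=target_accession,
        member_accessions=tuple(member_accessions),
        category_set=category_set,
        size=size,
        left_reason=left_reason,
        right_reason=right_reason,
    )
    return serial, target, truth_entry


# --------------------------------------------------------------------------
# serialization

def write_gff3(records: Sequence[GeneRecord], path: Path) -> None:
    """Write gene records for ONE assembly as GFF3 CDS features."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("##gff-version 3\n")
        by_contig: Dict[str, List[GeneRecord]] = {}
        for record in records:
            by_contig.setdefault(record.contig_id, []).append(record)
        for contig in sorted(by_contig):
            for gene in sorted(by_contig[contig], key=lambda g: g.gene_index):
                attributes = [f"ID=cds-{gene.protein_accession}"]
                attributes.append(f"protein_id={gene.protein_accession}")
                if gene.product:
                    attributes.append(f"product={gene.product}")
                handle.write(
                    "\t".join(
                        [
                            contig,
                            "operonscan_sim",
                            "CDS",
                            str(gene.start),
                            str(gene.end),
                            ".",
                            gene.strand,
                            "0",
                            ";".join(attributes),
                        ]
                    )
                    + "\n"
                )


def write_simulation(result: SimulationResult, out_dir: Path) -> None:
    """Write the simulated dataset in the dialects the pipeline reads."""
    from . import annotation_io  # local import to avoid a cycle

    out_dir = Path(out_dir)
    assemblies_dir = out_dir / "assemblies"
    assemblies_dir.mkdir(parents=True, exist_ok=True)
    by_assembly: Dict[str, List[GeneRecord]] = {}
    for record in result.gene_records:
        by_assembly.setdefault(record.assembly_id, []).append(record)
    for assembly_id in sorted(by_assembly):
        write_gff3(by_assembly[assembly_id], assemblies_dir / f"{assembly_id}.gff3")
    annotation_io.write_targets(result.targets, out_dir / "targets.tsv")
    annotation_io.write_function_annotations(
        result.annotations, out_dir / "annotations.tsv"
    )
    write_ground_truth(result.ground_truth, out_dir)


def write_ground_truth(truth: GroundTruth, out_dir: Path) -> None:
    import pandas as pd

    rows = []
    for (assembly_id, accession), entry in sorted(truth.operons.items()):
        rows.append(
            {
                "assembly_id": assembly_id,
                "target_accession": accession,
                "member_accessions": ",".join(entry.member_accessions),
                "categories": ",".join(sorted(entry.category_set)) or ".",
                "size": entry.size,
                "left_reason": entry.left_reason.value,
                "right_reason": entry.right_reason.value,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "assembly_id",
            "target_accession",
            "member_accessions",
            "categories",
            "size",
            "left_reason",
            "right_reason",
        ],
    ).to_csv(out_dir / "ground_truth_operons.tsv", sep="\t", index=False)

    clade_rows = []
    for assembly_id in sorted(truth.clade_counts):
        for label, count in sorted(truth.clade_counts[assembly_id].items()):
            clade_rows.append(
                {"assembly_id": assembly_id, "label": label, "count": count}
            )
    pd.DataFrame(
        clade_rows, columns=["assembly_id", "label", "count"]
    ).to_csv(out_dir / "ground_truth_clades.tsv", sep="\t", index=False)

    import json

    # via JSON to coerce tuples/enums into plain YAML-safe types
    config = json.loads(json.dumps(asdict(truth.config), default=str))
    with open(out_dir / "config.yaml", "w", encoding="utf-8") as handle:
        yaml.safe_dump(config, handle, sort_keys=True)


# --------------------------------------------------------------------------
# randomized contigs for oracle testing

def random_oracle_contig(
    rng: np.random.Generator,
    params: OperonParams = OperonParams(),
    max_genes: int = 40,
) -> Tuple[List[GeneRecord], GeneRecord]:
    """A random contig stressing the chain rule: junction gaps mixed over
    boundary-adjacent values (±1 around the gap and overlap thresholds),
    random strand flips, and a random target. For oracle-equivalence tests."""
    n = int(rng.integers(1, max_genes + 1))
    boundary_gaps = [
        -params.max_overlap_bp - 1,
        -params.max_overlap_bp,
        -params.max_overlap_bp + 1,
        0,
        params.max_intergenic_bp - 1,
        params.max_intergenic_bp,
        params.max_intergenic_bp + 1,
    ]
    genes: List[GeneRecord] = []
    pos = 500
    for i in range(n):
        if i > 0:
            if rng.random() < 0.6:
                gap = int(boundary_gaps[int(rng.integers(len(boundary_gaps)))])
            else:
                gap = int(
                    rng.integers(
                        -params.max_overlap_bp - 20, params.max_intergenic_bp + 200
                    )
                )
            pos = genes[-1].end + 1 + gap
        length = int(rng.integers(200, 1500))
        genes.append(
            GeneRecord(
                assembly_id="RNDASM",
                contig_id="rnd",
                gene_index=i,
                start=pos,
                end=pos + length - 1,
                strand="+" if rng.random() < 0.75 else "-",
                protein_accession=f"RND_{i:04d}",
                product=HYPOTHETICAL,
            )
        )
    target = genes[int(rng.integers(n))]
    return genes, target


# --------------------------------------------------------------------------
# deterministic edge-case fixtures

@dataclass(frozen=True)
class EdgeCaseFixture:
    name: str
    genes: Tuple[GeneRecord, ...]
    targets: Tuple[GeneRecord, ...]
    #: expected operon membership, target accession -> member accessions
    expected: Mapping[str, Tuple[str, ...]]


def _fixture_contig(
    name: str,
    gaps: Sequence[int],
    strands: Optional[Sequence[str]] = None,
    length: int = 500,
) -> List[GeneRecord]:
    n = len(gaps) + 1
    strands = strands or ["+"] * n
    genes = []
    pos = 1000
    for i in range(n):
        if i > 0:
            pos = genes[-1].end + 1 + gaps[i - 1]
        genes.append(
            GeneRecord(
                assembly_id=f"FIX_{name}",
                contig_id=f"fix_{name}",
                gene_index=i,
                start=pos,
                end=pos + length - 1,
                strand=strands[i],
                protein_accession=f"{name}_{i:02d}",
                product=HYPOTHETICAL,
            )
        )
    return genes


def edge_case_suite() -> List[EdgeCaseFixture]:
    """Deterministic fixtures exercising every rule boundary: junction gaps
    {299, 300, 301}, overlaps {49, 50, 51}, side lengths {14, 15, 16},
    strand flips at each offset, a size-1 operon, two targets sharing one
    operon, and a maturase gene on the opposite strand (excluded despite a
    small gap)."""
    fixtures: List[EdgeCaseFixture] = []

    def acc(name, *indices):
        return tuple(f"{name}_{i:02d}" for i in indices)

    for gap, joins in ((299, True), (300, True), (301, False)):
        name = f"gap{gap}"
        genes = _fixture_contig(name, [100, gap])
        expected = acc(name, 0, 1, 2) if joins else acc(name, 0, 1)
        fixtures.append(
            EdgeCaseFixture(name, tuple(genes), (genes[1],), {genes[1].protein_accession: expected})
        )

    for overlap, joins in ((49, True), (50, True), (51, False)):
        name = f"ovl{overlap}"
        genes = _fixture_contig(name, [-overlap])
        expected = acc(name, 0, 1) if joins else acc(name, 0)
        fixtures.append(
            EdgeCaseFixture(name, tuple(genes), (genes[0],), {genes[0].protein_accession: expected})
        )

    for side in (14, 15, 16):
        name = f"side{side}"
        genes = _fixture_contig(name, [0] * side)  # target first, `side` genes right
        kept = min(side, 15)
        expected = acc(name, *range(kept + 1))
        fixtures.append(
            EdgeCaseFixture(name, tuple(genes), (genes[0],), {genes[0].protein_accession: expected})
        )

    for flip_at in (1, 3, 4):
        name = f"flip{flip_at}"
        strands = ["+"] * 5
        strands[flip_at] = "-"
        genes = _fixture_contig(name, [10] * 4, strands)
        target = genes[2]
        left = flip_at + 1 if flip_at < 2 else 0
        right = flip_at - 1 if flip_at > 2 else 4
        expected = acc(name, *range(left, right + 1))
        fixtures.append(
            EdgeCaseFixture(name, tuple(genes), (target,), {target.protein_accession: expected})
        )

    name = "single"
    genes = _fixture_contig(name, [])
    fixtures.append(
        EdgeCaseFixture(
            name, tuple(genes), (genes[0],), {genes[0].protein_accession: acc(name, 0)}
        )
    )

    name = "shared"
    genes = _fixture_contig(name, [0, 0, 0])
    expected_all = acc(name, 0, 1, 2, 3)
    fixtures.append(
        EdgeCaseFixture(
            name,
            tuple(genes),
            (genes[1], genes[2]),
            {
                genes[1].protein_accession: expected_all,
                genes[2].protein_accession: expected_all,
            },
        )
    )

    # a CooC-like maturase just outside the operon on the opposite strand:
    # near in bp, but excluded by the strand rule
    name = "antisense_maturase"
    genes = _fixture_contig(name, [20, 30], strands=["+", "+", "-"])
    target = genes[0]
    fixtures.append(
        EdgeCaseFixture(
            name, tuple(genes), (target,), {target.protein_accession: acc(name, 0, 1)}
        )
    )
    return fixtures
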