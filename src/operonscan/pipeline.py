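"""Stage orchestration over the TSV interfaces.

Each stage reads the files a previous stage (or the simulator) wrote into
a run directory and writes its own outputs there under fixed names, so
stages compose identically whether run one-by-one or via ``all``. A run
manifest (tool version, resolved parameters, input digests, seed, record
counts) is written at the end of every invocation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__
from . import annotation_io, cooccurrence, curation, function_categories
from . import context_profiles, operon_caller
from .model import (
    CODH_CLADES,
    HCP_CLASSES,
    CurationParams,
    OperonParams,
    ProfileParams,
    target_key,
)

logger = logging.getLogger(__name__)

FILENAMES = {
    "targets": "targets.tsv",
    "annotations": "annotations.tsv",
    "assemblies": "assemblies",
    "gene_records": "gene_records.tsv",
    "linked_targets": "linked_targets.tsv",
    "dropped_targets": "dropped_targets.tsv",
    "operons": "operons.tsv",
    "categories": "categories.tsv",
    "counts_codh": "assembly_counts_codh.tsv",
    "counts_hcp": "assembly_counts_hcp.tsv",
    "isoform_frequency": "isoform_frequency.tsv",
    "matrix_long": "cooccurrence_long.tsv",
    "matrix_wide": "cooccurrence_wide.tsv",
    "cross_long": "cooccurrence_cross_family_long.tsv",
    "cross_wide": "cooccurrence_cross_family_wide.tsv",
    "profiles": "clade_profiles.tsv",
    "report": "clade_profiles_report.tsv",
    "size_histogram": "operon_size_histogram.tsv",
    "manifest": "run_manifest.json",
}


def _missing_input(path: Path, producing_stage: str) -> FileNotFoundError:
    return FileNotFoundError(
        f"required input {path} not found; run the '{producing_stage}' stage "
        "first (or point --run-dir at a directory produced by it)"
    )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


class PipelineRun:
    """One run directory plus resolved parameters."""

    def __init__(
        self,
        run_dir,
        operon_params: OperonParams = OperonParams(),
        curation_params: CurationParams = CurationParams(),
        profile_params: ProfileParams = ProfileParams(),
        rules_path=None,
        overrides_path=None,
        seed: Optional[int] = None,
    ):
        self.run_dir = Path(run_dir)
        self.operon_params = operon_params
        self.curation_params = curation_params
        self.profile_params = profile_params
        self.rules_path = rules_path
        self.overrides_path = overrides_path
        self.seed = seed
        self.counts: Dict[str, int] = {}
        self.input_digests: Dict[str, str] = {}

    def path(self, key: str) -> Path:
        return self.run_dir / FILENAMES[key]

    # -- stages ------------------------------------------------------------

    def curate(self) -> None:
        """Link targets to the assemblies' CDS annotations; write linked and
        dropped tables and a consolidated gene-record table."""
        targets_path = self.path("targets")
        assemblies = self.path("assemblies")
        if not targets_path.exists():
            raise _missing_input(targets_path, "simulate")
        if not assemblies.is_dir():
            raise _missing_input(assemblies, "simulate")
        self.input_digests["targets"] = _sha256(targets_path)

        targets = annotation_io.read_targets(targets_path)
        records = annotation_io.read_gff3_directory(assemblies)
        annotation_io.write_gene_records(records, self.path("gene_records"))
        link = curation.link_targets_to_annotations(targets, records)
        annotation_io.write_targets(
            [t for t, _ in link.linked], self.path("linked_targets")
        )
        curation.write_dropped_report(link, self.path("dropped_targets"))
        self.counts.update(
            targets_total=len(targets),
            targets_linked=len(link.linked),
            targets_dropped=len(link.dropped),
            gene_records=len(records),
        )

    def _load_linked(self):
        linked_path = self.path("linked_targets")
        genes_path = self.path("gene_records")
        for path in (linked_path, genes_path):
            if not path.exists():
                raise _missing_input(path, "curate")
        targets = annotation_io.read_targets(linked_path)
        records = annotation_io.read_gene_records(genes_path)
        link = curation.link_targets_to_annotations(targets, records)
        return link.linked, records

    def call_operons(self) -> None:
        linked, records = self._load_linked()
        operons = operon_caller.call_all_operons(linked, records, self.operon_params)
        operon_caller.write_operons(operons, self.path("operons"))
        self.counts["operons"] = len(operons)

    def classify(self) -> None:
        annotations_path = self.path("annotations")
        if not annotations_path.exists():
            raise _missing_input(annotations_path, "simulate")
        self.input_digests["annotations"] = _sha256(annotations_path)
        _, records = self._load_linked()
        annotations = {
            annotation_io.normalize_accession(k): v
            for k, v in annotation_io.read_function_annotations(
                annotations_path, "ncbi_product"
            ).items()
        }
        rules = function_categories.load_rules(self.rules_path)
        overrides = (
            function_categories.load_overrides(self.overrides_path)
            if self.overrides_path
            else None
        )
        assignments = function_categories.assign_all(
            records, annotations, rules, overrides
        )
        function_categories.write_assignments(
            records, assignments, self.path("categories")
        )
        self.counts["categorized_genes"] = len(assignments)

    def cooccur(self) -> None:
        linked, _ = self._load_linked()
        targets = [t for t, _ in linked]
        codh = cooccurrence.count_by_assembly(
            [t for t in targets if t.family == "CODH"], labels=CODH_CLADES
        )
        hcp = cooccurrence.count_by_assembly(
            [t for t in targets if t.family == "HCP"], labels=HCP_CLASSES
        )
        codh.to_csv(self.path("counts_codh"), sep="\t")
        hcp.to_csv(self.path("counts_hcp"), sep="\t")

        import pandas as pd

        frequency_rows = []
        for family, counts in (("CODH", codh), ("HCP", hcp)):
            for label, freq in cooccurrence.isoform_frequency(counts).items():
                for k, n in freq.items():
                    frequency_rows.append(
                        {"family": family, "label": label, "copies": k, "n_assemblies": n}
                    )
        pd.DataFrame(
            frequency_rows, columns=["family", "label", "copies", "n_assemblies"]
        ).to_csv(self.path("isoform_frequency"), sep="\t", index=False)

        matrix = cooccurrence.conditional_probability(codh)
        cooccurrence.write_matrix(
            matrix, self.path("matrix_long"), self.path("matrix_wide")
        )
        cross = cooccurrence.cross_family_matrix(codh, hcp)
        cooccurrence.write_matrix(
            cross, self.path("cross_long"), self.path("cross_wide")
        )
        self.counts["assemblies_with_codh"] = int((codh.sum(axis=1) >= 1).sum())
        self.counts["assemblies_with_hcp"] = int((hcp.sum(axis=1) >= 1).sum())

    def profile(self) -> None:
        operons_path = self.path("operons")
        categories_path = self.path("categories")
        if not operons_path.exists():
            raise _missing_input(operons_path, "call-operons")
        if not categories_path.exists():
            raise _missing_input(categories_path, "classify")

        linked, records = self._load_linked()
        operons = operon_caller.call_all_operons(
            linked, records, self.operon_params
        )
        import pandas as pd

        table = pd.read_csv(categories_path, sep="\t", dtype=str)
        assignments = {
            (row.assembly_id, row.contig_id, int(row.gene_index)): (
                row.category,
                row.provenance,
            )
            for row in table.itertuples(index=False)
        }
        category_sets = {
            key: function_categories.categorize_operon(operon, assignments)
            for key, operon in operons.items()
        }
        targets = [t for t, _ in linked]
        profiles = []
        for family, labels in (("CODH", CODH_CLADES), ("HCP", HCP_CLASSES)):
            family_targets = [t for t in targets if t.family == family]
            for label in labels:
                if any(t.clade_label == label for t in family_targets):
                    profiles.append(
                        context_profiles.clade_profile(
                            operons, category_sets, family_targets, label
                        )
                    )
        context_profiles.write_profiles(
            profiles,
            self.profile_params,
            self.path("profiles"),
            self.path("report"),
            self.path("size_histogram"),
        )
        self.counts["profiled_labels"] = len(profiles)

    def write_manifest(self, stages: List[str]) -> None:
        manifest = {
            "tool": "operonscan",
            "version": __version__,
            "stages": stages,
            "seed": self.seed,
            "parameters": {
                "operon": asdict(self.operon_params),
                "curation": asdict(self.curation_params),
                "profile": asdict(self.profile_params),
                "rules_path": str(self.rules_path) if self.rules_path else "default",
                "overrides_path": (
                    str(self.overrides_path) if self.overrides_path else None
                ),
            },
            "input_digests": self.input_digests,
            "record_counts": self.counts,
            # wall-clock provenance; the one field that varies between
            # otherwise byte-identical runs
            "generated_at": datetime.now(timezone.utc).isoformat(),
        }
        with open(self.path("manifest"), "w", encoding="utf-8") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
            handle.write("\n")

    def run(self, stages: List[str]) -> None:
        dispatch = {
            "curate": self.curate,
            "call-operons": self.call_operons,
            "classify": self.classify,
            "cooccur": self.cooccur,
            "profile": self.profile,
        }
        for stage in stages:
            logger.info("stage: %s", stage)
            dispatch[stage]()
        self.write_manifest(stages)


ALL_STAGES = ["curate", "call-operons", "classify", "cooccur", "profile"]
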