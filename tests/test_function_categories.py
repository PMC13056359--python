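import pytest

from operonscan import function_categories as fc
from operonscan.model import (
    AnnotationSource,
    FunctionAnnotation,
    GeneRecord,
    ValidationError,
)
from operonscan.operon_caller import call_operon

from helpers import make_contig

# Curated table of real-world-style product strings and the category each
# should receive under the shipped default rules.
PRODUCT_FIXTURE = [
    ("CO dehydrogenase accessory protein CooC", "cooC"),
    ("CO dehydrogenase maturation factor", "cooC"),
    ("carbon monoxide dehydrogenase accessory protein", "cooC"),
    ("CooC1 nickel-insertion ATPase", "cooC"),
    ("nickel-binding protein CooT", "cooT"),
    ("CooT family protein", "cooT"),
    ("nickel chaperone CooJ", "cooJ"),
    ("4Fe-4S ferredoxin", "ferredoxin"),
    ("ferredoxin", "ferredoxin"),
    ("flavodoxin family protein", "ferredoxin"),
    ("iron-sulfur cluster-binding protein CooF", "fes_protein"),
    ("4Fe-4S dicluster domain-containing protein", "fes_protein"),
    ("2Fe-2S iron-sulfur cluster binding domain protein", "fes_protein"),
    ("Ni/Fe-hydrogenase III large subunit", "hydrogenase"),
    ("energy-converting hydrogenase subunit EchE", "hydrogenase"),
    ("hydrogenase maturation protease HycI", "hydrogenase_maturase"),
    ("hydrogenase expression/formation protein HypE", "hydrogenase_maturase"),
    ("hydrogenase nickel incorporation protein HypA", "hydrogenase_maturase"),
    ("NAD(P)/FAD-dependent oxidoreductase", "nadp_fad_oxidoreductase"),
    ("FAD-dependent oxidoreductase", "nadp_fad_oxidoreductase"),
    ("NADH:quinone oxidoreductase subunit", "nadp_fad_oxidoreductase"),
    ("Rrf2 family transcriptional regulator", "transcription_regulation"),
    ("LysR family transcriptional regulator", "transcription_regulation"),
    ("response regulator", "other_regulation"),
    ("anti-sigma factor antagonist", "other_regulation"),
    ("ABC transporter ATP-binding protein", "abc_transporter"),
    ("ABC-type nickel transport system permease", "abc_transporter"),
    ("MFS transporter", "transporter"),
    ("nickel/cobalt efflux transporter RcnA", "transporter"),
    ("formate dehydrogenase subunit alpha", "one_carbon_pool"),
    ("acetyl-CoA synthase subunit beta", "one_carbon_pool"),
    ("acetyl-CoA decarbonylase/synthase complex subunit delta", "one_carbon_pool"),
    ("methylenetetrahydrofolate reductase", "one_carbon_pool"),
    ("formate--tetrahydrofolate ligase", "one_carbon_pool"),
    ("corrinoid/iron-sulfur protein methyltransferase", "one_carbon_pool"),
    ("carbon monoxide dehydrogenase", "other"),
    ("hypothetical protein", "other"),
    ("DUF1284 domain-containing protein", "other"),
]


def gene_with_product(product, accession="WP_1", index=0):
    return GeneRecord(
        assembly_id="ASM",
        contig_id="c1",
        gene_index=index,
        start=100 + 1000 * index,
        end=700 + 1000 * index,
        strand="+",
        protein_accession=accession,
        product=product,
    )


class TestAssignCategory:
    @pytest.mark.parametrize("product,expected", PRODUCT_FIXTURE)
    def test_default_rules_on_product_strings(self, product, expected, default_rules):
        category, _ = fc.assign_category(
            gene_with_product(product), {}, default_rules
        )
        assert category == expected

    def test_override_beats_rules(self, default_rules):
        gene = gene_with_product("hypothetical protein", accession="WP_COOJ.1")
        category, provenance = fc.assign_category(
            gene, {}, default_rules, overrides={"WP_COOJ": "cooJ"}
        )
        assert (category, provenance) == ("cooJ", "override")

    def test_no_annotation_falls_back_to_other(self, default_rules):
        gene = GeneRecord("ASM", "c1", 0, 100, 700, "+", "WP_9", None)
        category, provenance = fc.assign_category(gene, {}, default_rules)
        assert (category, provenance) == ("other", "fallback")

    def test_eggnog_description_used_when_product_absent(self, default_rules):
        gene = GeneRecord("ASM", "c1", 0, 100, 700, "+", "WP_9", None)
        annotations = {
            "WP_9": FunctionAnnotation(
                "WP_9", description="4Fe-4S ferredoxin", source=AnnotationSource.eggnog
            )
        }
        category, _ = fc.assign_category(gene, annotations, default_rules)
        assert category == "ferredoxin"

    def test_lowest_priority_wins_on_multi_match(self, default_rules):
        # matches both the one-carbon rule (corrinoid) and the FeS rule
        category, _ = fc.assign_category(
            gene_with_product("corrinoid/iron-sulfur protein"), {}, default_rules
        )
        assert category == "one_carbon_pool"

    def test_deterministic(self, default_rules):
        gene = gene_with_product("ABC transporter permease")
        results = {
            fc.assign_category(gene, {}, default_rules)[0] for _ in range(5)
        }
        assert len(results) == 1


class TestRuleLoading:
    def test_default_rules_sorted_by_priority(self, default_rules):
        priorities = [r.priority for r in default_rules]
        assert priorities == sorted(priorities)

    def test_bad_category_rejected(self, tmp_path):
        path = tmp_path / "rules.tsv"
        path.write_text("category\tpriority\tpattern\nnot_a_category\t1\tx\n")
        with pytest.raises(ValidationError):
            fc.load_rules(path)

    def test_override_unknown_category_rejected(self, tmp_path):
        path = tmp_path / "ovr.tsv"
        path.write_text("protein_accession\tcategory\nWP_1\tbogus\n")
        with pytest.raises(ValidationError):
            fc.load_overrides(path)


class TestCategorizeOperon:
    def _operon_with_products(self, products, target_index):
        genes = make_contig([10] * (len(products) - 1), assembly="ASM")
        genes = [
            GeneRecord(
                g.assembly_id, g.contig_id, g.gene_index, g.start, g.end,
                g.strand, g.protein_accession, product,
            )
            for g, product in zip(genes, products)
        ]
        operon = call_operon(genes, genes[target_index])
        assignments = fc.assign_all(genes, {})
        return operon, assignments

    def test_size_one_operon_empty_set(self):
        operon, assignments = self._operon_with_products(
            ["carbon monoxide dehydrogenase"], 0
        )
        assert fc.categorize_operon(operon, assignments) == set()

    def test_other_excluded_target_excluded(self):
        operon, assignments = self._operon_with_products(
            [
                "CO dehydrogenase accessory protein CooC",
                "hypothetical protein",
                "4Fe-4S dicluster domain-containing protein",
                "carbon monoxide dehydrogenase",
            ],
            3,
        )
        assert fc.categorize_operon(operon, assignments) == {"cooC", "fes_protein"}

    def test_duplicate_category_counted_once(self):
        operon, assignments = self._operon_with_products(
            [
                "CO dehydrogenase accessory protein CooC",
                "CO dehydrogenase maturation factor",
                "carbon monoxide dehydrogenase",
            ],
            2,
        )
        assert fc.categorize_operon(operon, assignments) == {"cooC"}

    def test_missing_assignment_rejected(self):
        operon, assignments = self._operon_with_products(
            ["hypothetical protein", "carbon monoxide dehydrogenase"], 1
        )
        assignments.pop(("ASM", "ctg_T", 0))
        with pytest.raises(ValidationError):
            fc.categorize_operon(operon, assignments)


def test_merge_regulation_union_semantics():
    merged = fc.merge_regulation({"transcription_regulation", "cooC"})
    assert merged == {"regulation", "cooC"}
    both = fc.merge_regulation({"transcription_regulation", "other_regulation"})
    assert both == {"regulation"}
    assert fc.merge_regulation({"cooC"}) == {"cooC"}
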