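import pytest

from operonscan import curation, function_categories, operon_caller
from operonscan import synthetic_data as sd


@pytest.fixture(scope="session")
def sim_result():
    """A medium simulated dataset shared across read-only tests."""
    config = sd.SimulationConfig(n_assemblies=120, seed=11)
    return sd.simulate(config)


@pytest.fixture(scope="session")
def sim_pipeline(sim_result):
    """Operons, category assignments and category sets for sim_result."""
    link = curation.link_targets_to_annotations(
        sim_result.targets, sim_result.gene_records
    )
    operons = operon_caller.call_all_operons(link.linked, sim_result.gene_records)
    assignments = function_categories.assign_all(
        sim_result.gene_records, sim_result.annotations
    )
    category_sets = {
        key: function_categories.categorize_operon(operon, assignments)
        for key, operon in operons.items()
    }
    return {
        "linked": link.linked,
        "operons": operons,
        "assignments": assignments,
        "category_sets": category_sets,
    }


@pytest.fixture(scope="session")
def default_rules():
    return function_categories.load_rules()
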