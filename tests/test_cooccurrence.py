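import math

import numpy as np
import pytest
from scipy.stats import binomtest

from operonscan import cooccurrence as co
from operonscan.model import TargetRecord


def targets(*pairs):
    return [
        TargetRecord(f"WP_{i}", "CODH", label, assembly)
        for i, (assembly, label) in enumerate(pairs)
    ]


class TestCountByAssembly:
    def test_hand_count(self):
        counts = co.count_by_assembly(
            targets(("GCA_1", "A"), ("GCA_1", "A"), ("GCA_2", "E"))
        )
        assert counts.loc["GCA_1", "A"] == 2
        assert counts.loc["GCA_2", "E"] == 1
        assert counts.loc["GCA_2", "A"] == 0

    def test_empty(self):
        assert co.count_by_assembly([]).empty

    def test_single_target(self):
        counts = co.count_by_assembly(targets(("GCA_1", "B")))
        assert counts.values.sum() == 1

    def test_every_target_counted_once(self, sim_result):
        counts = co.count_by_assembly(sim_result.targets)
        assert counts.values.sum() == len(sim_result.targets)


class TestIsoformFrequency:
    def test_hand_count(self):
        counts = co.count_by_assembly(
            targets(("a1", "A"), ("a1", "A"), ("a2", "A"), ("a3", "A"))
        )
        assert co.isoform_frequency(counts)["A"] == {1: 2, 2: 1}

    def test_absent_label_empty(self):
        counts = co.count_by_assembly(targets(("a1", "A")), labels=["A", "B"])
        assert co.isoform_frequency(counts)["B"] == {}

    def test_five_copies_single_assembly(self):
        counts = co.count_by_assembly(targets(*[("a1", "A")] * 5))
        assert co.isoform_frequency(counts)["A"] == {5: 1}

    def test_frequencies_sum_to_n_label(self, sim_result):
        counts = co.count_by_assembly(sim_result.targets)
        freq = co.isoform_frequency(counts)
        for label in counts.columns:
            assert sum(freq[label].values()) == int((counts[label] >= 1).sum())


class TestConditionalProbability:
    @pytest.fixture
    def three_assembly_matrix(self):
        # presence sets: a1={A,E}, a2={A}, a3={E,F}
        return co.count_by_assembly(
            targets(("a1", "A"), ("a1", "E"), ("a2", "A"), ("a3", "E"), ("a3", "F"))
        )

    def test_hand_enumeration(self, three_assembly_matrix):
        m = co.conditional_probability(three_assembly_matrix)
        assert m.p.loc["A", "E"] == 0.5
        assert m.p.loc["E", "A"] == 0.5
        assert m.p.loc["F", "E"] == 0.5
        assert m.p.loc["A", "F"] == 0.0

    def test_self_conditioning_is_one(self, three_assembly_matrix):
        m = co.conditional_probability(three_assembly_matrix)
        for label in ("A", "E", "F"):
            assert m.p.loc[label, label] == 1.0

    def test_empty_marginal_is_missing_not_zero(self, three_assembly_matrix):
        m = co.conditional_probability(
            three_assembly_matrix, labels_y=["A", "B"], labels_x=["A", "E"]
        )
        assert m.p["B"].isna().all()
        long = co.to_long_frame(m)
        assert "B" not in set(long["Y"])

    def test_asymmetry_with_unequal_marginals(self, three_assembly_matrix):
        m = co.conditional_probability(three_assembly_matrix)
        # N_E=2, N_F=1: P(F|E) = 1/2 but P(E|F) = 1
        assert m.p.loc["E", "F"] == 1.0
        assert m.p.loc["F", "E"] == 0.5

    def test_integer_identity_exact(self, sim_result):
        counts = co.count_by_assembly(sim_result.targets)
        m = co.conditional_probability(counts)
        for x in m.labels_x:
            for y in m.labels_y:
                n_y, n_x = int(m.n_y[y]), int(m.n_y[x])
                if n_y == 0 or n_x == 0:
                    continue
                n_xy = int(m.n_xy.loc[x, y])
                assert m.p.loc[x, y] * n_y == pytest.approx(n_xy)
                assert m.p.loc[y, x] * n_x == pytest.approx(n_xy)
                assert int(m.n_xy.loc[y, x]) == n_xy

    def test_probabilities_bounded(self, sim_result):
        counts = co.count_by_assembly(sim_result.targets)
        m = co.conditional_probability(counts)
        values = m.p.values[~np.isnan(m.p.values)]
        assert ((values >= 0) & (values <= 1)).all()


class TestCrossFamily:
    def test_hand_enumeration(self):
        codh = co.count_by_assembly(
            [TargetRecord("W1", "CODH", "A", "a1"), TargetRecord("W2", "CODH", "A", "a2")]
        )
        hcp = co.count_by_assembly([TargetRecord("W3", "HCP", "I", "a2")])
        m = co.cross_family_matrix(codh, hcp)
        assert m.p.loc["I", "A"] == 0.5
        assert m.p.loc["A", "I"] == 1.0

    def test_disjoint_assemblies_zero(self):
        codh = co.count_by_assembly([TargetRecord("W1", "CODH", "A", "a1")])
        hcp = co.count_by_assembly([TargetRecord("W2", "HCP", "I", "a2")])
        m = co.cross_family_matrix(codh, hcp)
        assert m.p.loc["I", "A"] == 0.0 and m.p.loc["A", "I"] == 0.0

    def test_identical_presence_all_one(self):
        codh = co.count_by_assembly([TargetRecord("W1", "CODH", "A", "a1")])
        hcp = co.count_by_assembly([TargetRecord("W2", "HCP", "I", "a1")])
        m = co.cross_family_matrix(codh, hcp)
        assert m.p.loc["I", "A"] == 1.0 and m.p.loc["A", "I"] == 1.0


class TestParameterRecovery:
    def test_independent_presence_within_binomial_ci(self):
        # independent per-clade presence: estimated P(X|Y) must sit inside
        # the exact (Clopper-Pearson) 95% CI of the generator value
        from operonscan import synthetic_data as sd

        presence = {"A": 0.3, "E": 0.5, "F": 0.2}
        config = sd.SimulationConfig(
            n_assemblies=600,
            clade_presence=presence,
            copies_given_present={k: (1.0,) for k in presence},
            neighbor_model={},
            n_distractor_genes=1,
            seed=99,
        )
        result = sd.simulate(config)
        counts = co.count_by_assembly(result.targets)
        m = co.conditional_probability(counts)
        for x in presence:
            for y in presence:
                n_y = int(m.n_y[y])
                n_xy = int(m.n_xy.loc[x, y])
                truth = 1.0 if x == y else presence[x]
                ci = binomtest(n_xy, n_y).proportion_ci(0.95, method="exact")
                assert ci.low <= truth <= ci.high


def test_multi_copy_fraction():
    counts = co.count_by_assembly(
        targets(("a1", "A"), ("a1", "E"), ("a2", "A"), ("a3", "F"))
    )
    assert co.multi_copy_fraction(counts) == pytest.approx(1 / 3)
    assert math.isnan(co.multi_copy_fraction(co.count_by_assembly([])))
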