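import numpy as np
import pandas as pd
import pytest

from holodev.expression_io import ExpressionMatrix, log_transform, stage_average
from holodev.synthetic_data import CLASS_TEMPLATES, SimulationConfig, simulate_dataset
from holodev.trajectory_clustering import (
    ZIGZAG_STRICT_IDS,
    assign_trajectories,
    enumerate_templates,
    hierarchical_profile_clustering,
    select_zigzag_clusters,
    select_zigzag_genes,
)

from conftest import make_samples, stage_matrix_from
from test_similarity import spearman_oracle


class TestEnumerateTemplates:
    def test_exactly_27_distinct_templates(self):
        templates = enumerate_templates()
        assert len(templates) == 27
        assert len({t.id for t in templates}) == 27

    def test_levels_are_cumulative_sums(self):
        by_id = {t.id: t for t in enumerate_templates()}
        np.testing.assert_array_equal(by_id["+++"].levels, [0, 1, 2, 3])
        np.testing.assert_array_equal(by_id["000"].levels, [0, 0, 0, 0])
        np.testing.assert_array_equal(by_id["+-+"].levels, [0, 1, 0, 1])
        for t in by_id.values():
            np.testing.assert_array_equal(np.diff(t.levels), t.steps)

    def test_exactly_two_strict_zigzag_templates(self):
        ids = {t.id for t in enumerate_templates()}
        strict = set(ZIGZAG_STRICT_IDS)
        assert strict <= ids
        assert len(strict) == 2


class TestAssignTrajectories:
    def test_exact_zigzag_profile(self):
        asg = assign_trajectories(stage_matrix_from([[1.0, 10.0, 1.0, 10.0]]))
        template, score = asg.assignments["g0"]
        assert template == "+-+"
        assert score == pytest.approx(1.0)

    def test_exact_monotone_profile(self):
        asg = assign_trajectories(stage_matrix_from([[1.0, 2.0, 3.0, 4.0]]))
        assert asg.assignments["g0"] == ("+++", pytest.approx(1.0))

    def test_constant_gene_goes_to_flat_template(self):
        asg = assign_trajectories(stage_matrix_from([[5.0, 5.0, 5.0, 5.0]]))
        assert asg.assignments["g0"][0] == "000"

    def test_affine_transform_invariance(self):
        """Correlation scoring ignores a gene's offset and positive scale
        (for genes above the flatness gate in both versions)."""
        rng = np.random.default_rng(0)
        values = rng.normal(size=(50, 4))
        base = assign_trajectories(stage_matrix_from(values))
        scaled = assign_trajectories(stage_matrix_from(3.5 * values + 11.0))
        for i, g in enumerate(sorted(base.assignments)):
            if np.ptp(values[int(g[1:])]) > 0.5:
                assert base.assignments[g][0] == scaled.assignments[g][0]

    def test_wrong_column_count_rejected(self):
        m = ExpressionMatrix(
            pd.DataFrame(
                [[1.0, 2.0, 3.0]],
                index=["g0"],
                columns=["embryo", "larva", "pupa"],
            ),
            scale="log",
        )
        with pytest.raises(ValueError, match="4 stage columns"):
            assign_trajectories(m)

    @pytest.mark.parametrize(
        "noise_sd,min_accuracy", [(0.1, 0.95), (0.5, 0.5)]
    )
    def test_truth_recovery_degrades_with_noise(self, noise_sd, min_accuracy):
        config = SimulationConfig(
            n_genes=500,
            class_fractions={
                "monotone_up": 0.25, "monotone_down": 0.25, "zigzag_up": 0.25,
                "zigzag_down": 0.25, "constant": 0.0, "random": 0.0,
            },
            noise_sd=noise_sd,
            seed=20,
        )
        matrix, samples, _, truth = simulate_dataset(config)
        stage_means = stage_average(log_transform(matrix), samples)
        asg = assign_trajectories(stage_means)
        correct = sum(
            asg.assignments[g][0] == CLASS_TEMPLATES[truth.gene_class[g]]
            for g in matrix.gene_ids
        )
        assert correct / len(matrix.gene_ids) >= min_accuracy


class TestSelectZigzagGenes:
    def test_strict_criterion_covers_exactly_two_templates(self):
        templates = enumerate_templates()
        strict = [t for t in templates if t.id in ZIGZAG_STRICT_IDS]
        assert len(strict) == 2
        # both have embryo level equal to pupa level
        for t in strict:
            assert t.levels[0] == t.levels[2]
            assert t.levels[1] != t.levels[0]

    def test_monotone_gene_excluded(self):
        asg = assign_trajectories(
            stage_matrix_from([[1.0, 2.0, 3.0, 4.0], [1.0, 8.0, 1.0, 8.0]])
        )
        zig = select_zigzag_genes(asg)
        assert zig == {"g1"}

    def test_planted_zigzag_recovered_at_low_noise(self):
        config = SimulationConfig(
            n_genes=300,
            noise_sd=0.02,
            seed=21,
        )
        matrix, samples, _, truth = simulate_dataset(config)
        stage_means = stage_average(log_transform(matrix), samples)
        zig = select_zigzag_genes(assign_trajectories(stage_means))
        planted = set(truth.genes_of_class("zigzag_up")) | set(
            truth.genes_of_class("zigzag_down")
        )
        assert planted <= zig

    def test_loose_family_contains_strict(self):
        rng = np.random.default_rng(22)
        asg = assign_trajectories(stage_matrix_from(rng.normal(size=(100, 4))))
        strict = select_zigzag_genes(asg, "strict_alternating")
        loose = select_zigzag_genes(asg, "embryo_pupa_family")
        assert strict <= loose


def time_course_matrix(profiles, n_points):
    genes = [f"g{i}" for i in range(len(profiles))]
    cols = [f"t{j}" for j in range(n_points)]
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(profiles, float), index=genes, columns=cols),
        scale="log",
    )


class TestHierarchicalClustering:
    def test_two_planted_families_recovered(self):
        rng = np.random.default_rng(30)
        t = np.linspace(0, 2 * np.pi, 8)
        fam_a = np.sin(t) + rng.normal(0, 0.01, size=(15, 8))
        fam_b = -np.sin(t) + rng.normal(0, 0.01, size=(15, 8))
        m = time_course_matrix(np.vstack([fam_a, fam_b]), 8)
        labels, means, excluded = hierarchical_profile_clustering(m, K=2)
        assert excluded == []
        assert labels.iloc[:15].nunique() == 1
        assert labels.iloc[15:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[15]

    def test_k_equals_genes_gives_singletons(self):
        rng = np.random.default_rng(31)
        m = time_course_matrix(rng.normal(size=(8, 6)), 6)
        labels, means, _ = hierarchical_profile_clustering(m, K=8)
        assert labels.nunique() == 8

    def test_distances_match_pairwise_spearman_oracle(self):
        """The implied correlation structure equals a brute-force loop."""
        rng = np.random.default_rng(32)
        values = rng.normal(size=(12, 7))
        m = time_course_matrix(values, 7)
        labels, means, _ = hierarchical_profile_clustering(m, K=3)
        # recompute the oracle distances and check co-clustered genes are
        # closer on average than cross-cluster genes
        n = 12
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                d[i, j] = 1 - spearman_oracle(values[i], values[j])
        same, cross = [], []
        lab = labels.to_numpy()
        for i in range(n):
            for j in range(i + 1, n):
                (same if lab[i] == lab[j] else cross).append(d[i, j])
        assert np.mean(same) < np.mean(cross)

    def test_constant_profiles_excluded_with_report(self):
        rng = np.random.default_rng(33)
        values = np.vstack([rng.normal(size=(6, 6)), np.ones((2, 6))])
        m = time_course_matrix(values, 6)
        labels, _, excluded = hierarchical_profile_clustering(m, K=2)
        assert excluded == ["g6", "g7"]
        assert set(labels.index) == {f"g{i}" for i in range(6)}


class TestSelectZigzagClusters:
    @pytest.fixture
    def samples(self):
        return make_samples({"embryo": 1, "larva": 1, "pupa": 1, "adult": 1})

    def _means(self, rows):
        return pd.DataFrame(
            rows,
            index=[f"c{i}" for i in range(len(rows))],
            columns=["embryo_1", "larva_1", "pupa_1", "adult_1"],
        )

    def test_zigzag_monotone_and_flat_profiles(self, samples):
        means = self._means(
            [
                [0.9, -1.1, 0.9, -0.7],  # embryo ~ pupa, larva departs
                [-1.2, -0.4, 0.4, 1.2],  # monotone
                [0.0, 0.0, 0.0, 0.0],  # flat
            ]
        )
        selected = select_zigzag_clusters(
            means, samples, delta=0.5, epsilon=1.0
        )
        assert selected == ["c0"]
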