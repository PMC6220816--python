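"""Toroid SOM training, height matrices and watershed cluster extraction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from genefunc import (
    SomConfig,
    SynthSpec,
    build_matrix,
    extract_clusters,
    generate_annotations,
    generate_ontology,
    ora,
    pmatrix,
    toroid_distance,
    train,
    umatrix,
    ustar,
)
from genefunc.esom import HeightGrid, TrainedSom
from genefunc.feature_matrix import GeneProcessMatrix


def planted_matrix(n_modules: int, seed: int) -> tuple[GeneProcessMatrix, dict[str, int]]:
    """Feature matrix over planted module genes plus the true labels."""
    spec = SynthSpec(n_modules=n_modules, seed=seed)
    onto = generate_ontology(spec)
    store, truth = generate_annotations(onto, spec)
    query = {g for gs in truth.module_genes.values() for g in gs}
    sig = [r for r in ora(query, store) if r.significant]
    matrix = build_matrix(query & store.universe, sig, store)
    return matrix, truth.gene_labels()


class TestToroidDistance:
    def test_row_wrap(self):
        assert toroid_distance((0, 0), (24, 0), (25, 35)) == 1.0

    def test_col_wrap(self):
        assert toroid_distance((0, 0), (0, 34), (25, 35)) == 1.0

    def test_interior_wrap_arithmetic(self):
        # both deltas stay below the wrap midpoint: 12 = min(12, 13), 17 = min(17, 18)
        assert toroid_distance((0, 0), (12, 17), (25, 35)) == pytest.approx(
            np.hypot(12, 17)
        )

    def test_symmetry(self):
        for a, b in [((3, 4), (20, 30)), ((0, 0), (12, 18))]:
            assert toroid_distance(a, b, (25, 35)) == toroid_distance(b, a, (25, 35))


class TestTraining:
    def test_identical_vectors_attract_all_weights(self):
        frame = pd.DataFrame(
            np.tile([1.0, 0.0, 1.0], (5, 1)), index=[f"g{i}" for i in range(5)],
            columns=list("abc"),
        )
        som = train(GeneProcessMatrix(frame=frame), SomConfig(rows=6, cols=8, epochs=10, seed=0))
        err = np.abs(som.weights - np.array([1.0, 0.0, 1.0])).max()
        assert err < 0.01  # all neurons collapse onto the single data point

    def test_same_seed_is_bit_identical(self):
        matrix, _ = planted_matrix(2, seed=5)
        cfg = SomConfig(rows=10, cols=14, epochs=5, seed=5)
        a = train(matrix, cfg)
        b = train(matrix, SomConfig(rows=10, cols=14, epochs=5, seed=5))
        assert np.array_equal(a.weights, b.weights)
        assert a.bmu_map == b.bmu_map

    def test_module_genes_map_closer_than_cross_module(self):
        matrix, labels = planted_matrix(3, seed=7)
        som = train(matrix, SomConfig(seed=7))
        within, between = [], []
        genes = list(matrix.genes)
        for i, g in enumerate(genes):
            for h in genes[i + 1:]:
                d = toroid_distance(som.bmu_map[g], som.bmu_map[h], som.shape)
                (within if labels[g] == labels[h] else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_zero_columns_hard_error(self):
        frame = pd.DataFrame(index=["g1"], columns=[], dtype=float)
        with pytest.raises(ValueError):
            train(GeneProcessMatrix(frame=frame), SomConfig(rows=4, cols=4, epochs=1))

    def test_small_grid_warns(self):
        frame = pd.DataFrame(
            np.eye(5), index=[f"g{i}" for i in range(5)], columns=list("abcde")
        )
        with pytest.warns(UserWarning, match="emergent"):
            train(GeneProcessMatrix(frame=frame), SomConfig(rows=2, cols=2, epochs=1))


def _som_from_weights(weights: np.ndarray) -> TrainedSom:
    return TrainedSom(weights=weights, bmu_map={}, config=SomConfig(rows=max(weights.shape[0], 2), cols=max(weights.shape[1], 2)))


class TestUMatrix:
    def test_two_neuron_grid_heights_equal_weight_distance(self):
        w = np.array([[[0.0, 0.0], [3.0, 4.0]]])  # 1 x 2 grid
        u = umatrix(_som_from_weights(w))
        assert u.values.tolist() == [[5.0, 5.0]]

    def test_identical_weights_give_zero(self):
        w = np.ones((4, 5, 3))
        assert umatrix(_som_from_weights(w)).values.max() == 0.0

    def test_nonnegative_on_trained_som(self):
        matrix, _ = planted_matrix(2, seed=1)
        som = train(matrix, SomConfig(rows=8, cols=10, epochs=3, seed=1))
        assert (umatrix(som).values >= 0).all()

    def test_invariant_under_global_translation(self):
        matrix, _ = planted_matrix(2, seed=2)
        cfg = SomConfig(rows=8, cols=10, epochs=3, seed=2)
        u1 = umatrix(train(matrix, cfg))
        shifted = GeneProcessMatrix(frame=matrix.frame + 5)
        u2 = umatrix(train(shifted, cfg))
        assert np.allclose(u1.values, u2.values)


class TestPMatrix:
    def _matrix_1d(self, values):
        return GeneProcessMatrix(
            frame=pd.DataFrame({"x": values}, index=[f"g{i}" for i in range(len(values))])
        )

    def test_counts_points_in_sphere(self):
        som = _som_from_weights(np.array([[[0.0], [10.0]]]))
        p = pmatrix(som, self._matrix_1d([0.0, 0.5, 10.0]), r=1.0)
        assert p.values[0, 0] == 2.0

    def test_zero_radius_without_coincidence_counts_nothing(self):
        som = _som_from_weights(np.array([[[0.25], [7.0]]]))
        p = pmatrix(som, self._matrix_1d([0.0, 0.5, 10.0]), r=0.0)
        assert (p.values == 0).all()

    def test_infinite_radius_counts_everything(self):
        som = _som_from_weights(np.array([[[0.0], [10.0]]]))
        p = pmatrix(som, self._matrix_1d([0.0, 0.5, 10.0]), r=np.inf)
        assert (p.values == 3).all()

    def test_auto_radius_recorded(self):
        matrix, _ = planted_matrix(2, seed=3)
        som = train(matrix, SomConfig(rows=8, cols=10, epochs=2, seed=3))
        p = pmatrix(som, matrix, r="auto")
        assert p.radius is not None and p.radius >= 0


class TestUStar:
    def test_uniform_density_flattens_everything(self):
        u = HeightGrid(values=np.arange(12.0).reshape(3, 4), kind="U")
        p = HeightGrid(values=np.full((3, 4), 9.0), kind="P")
        assert (ustar(u, p).values == 0).all()

    def test_scale_falls_from_median_to_max(self):
        u = HeightGrid(values=np.ones((1, 3)), kind="U")
        p = HeightGrid(values=np.array([[0.0, 2.0, 4.0]]), kind="P")
        out = ustar(u, p)
        assert out.values.tolist() == [[1.0, 1.0, 0.0]]

    def test_shape_mismatch_raises(self):
        u = HeightGrid(values=np.ones((2, 2)), kind="U")
        p = HeightGrid(values=np.ones((3, 3)), kind="P")
        with pytest.raises(ValueError):
            ustar(u, p)

    def test_ridge_outlives_dense_valleys_on_planted_data(self):
        matrix, _ = planted_matrix(2, seed=3)
        som = train(matrix, SomConfig(seed=3))
        us = ustar(umatrix(som), pmatrix(som, matrix))
        bmu_heights = [us.values[r, c] for r, c in som.bmu_map.values()]
        assert us.values.max() > max(bmu_heights)  # ridge is off the data


class TestExtractClusters:
    def test_planted_two_modules_recovered_exactly(self):
        matrix, labels = planted_matrix(2, seed=3)
        som = train(matrix, SomConfig(seed=3))
        us = ustar(umatrix(som), pmatrix(som, matrix))
        cl = extract_clusters(som, us, matrix)
        assert cl.n_clusters == 2
        truth = [labels[g] for g in matrix.genes]
        pred = [cl.labels[g] for g in matrix.genes]
        assert adjusted_rand_score(truth, pred) == pytest.approx(1.0)

    def test_identical_data_single_cluster(self):
        frame = pd.DataFrame(
            np.tile([1.0, 0.0], (6, 1)), index=[f"g{i}" for i in range(6)], columns=list("ab")
        )
        matrix = GeneProcessMatrix(frame=frame)
        som = train(matrix, SomConfig(rows=6, cols=8, epochs=10, seed=0))
        with pytest.warns(UserWarning, match="flat"):
            cl = extract_clusters(som, umatrix(som), matrix)
        assert cl.n_clusters == 1
        assert set(cl.labels.values()) == {1}

    def test_partition_invariant_to_input_order(self):
        matrix, _ = planted_matrix(2, seed=4)
        som = train(matrix, SomConfig(rows=12, cols=16, epochs=8, seed=4))
        us = ustar(umatrix(som), pmatrix(som, matrix))
        a = extract_clusters(som, us, matrix)
        # row order of the matrix is canonical, so feeding a permuted gene
        # set through the same build yields the identical partition
        shuffled = GeneProcessMatrix(frame=matrix.frame.sample(frac=1, random_state=1).sort_index())
        b = extract_clusters(som, us, shuffled)
        assert a.labels == b.labels
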