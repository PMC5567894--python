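import numpy as np
import pandas as pd
import pytest

from meld import FeatureSpace, MeldDataset, load_dataset, load_result, save_result
from meld.core import MeldConfig, MeldResult, TfceParams, save_dataset


class TestFeatureSpace:
    def test_lattice_edge_list_matches_manual_grid(self):
        fs = FeatureSpace((2, 3))
        edges = set(map(tuple, fs.edge_list()))
        expected = {(0, 1), (1, 2), (3, 4), (4, 5), (0, 3), (1, 4), (2, 5)}
        assert edges == expected

    def test_explicit_adjacency_is_symmetrized_and_deduplicated(self):
        fs = FeatureSpace((4,), adjacency=np.array([[1, 0], [0, 1], [2, 3]]))
        assert fs.edge_list().tolist() == [[0, 1], [2, 3]]

    @pytest.mark.parametrize(
        "shape,adj",
        [((0,), "lattice-orthogonal"), ((2, 2), "hexagonal"), ((3,), [[0, 0]]), ((3,), [[0, 5]])],
    )
    def test_invalid_construction_rejected(self, shape, adj):
        with pytest.raises(ValueError):
            FeatureSpace(shape, adj)

    def test_diagonal_lattice_has_more_edges(self):
        orth = FeatureSpace((3, 3), "lattice-orthogonal").edge_list()
        diag = FeatureSpace((3, 3), "lattice-diagonal").edge_list()
        assert len(diag) > len(orth)


class TestMeldDataset:
    def test_canonical_sort_is_stable_within_subject(self):
        design = pd.DataFrame(
            {"subject": ["b", "a", "b", "a"], "item": ["1", "2", "3", "4"]}
        )
        Y = np.arange(8, dtype=float).reshape(4, 2)
        ds = MeldDataset(design, Y, FeatureSpace((2,)))
        assert ds.design["subject"].tolist() == ["a", "a", "b", "b"]
        # within-subject original order preserved
        assert ds.design["item"].tolist() == ["2", "4", "1", "3"]
        assert ds.Y[:, 0].tolist() == [2.0, 6.0, 0.0, 4.0]

    def test_row_count_mismatch_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="rows"):
            MeldDataset(toy_dataset.design, toy_dataset.Y[:-1], toy_dataset.feature_space)

    def test_shape_product_mismatch_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="features"):
            MeldDataset(toy_dataset.design, toy_dataset.Y, FeatureSpace((4, 4)))

    def test_missing_subject_column_rejected(self, toy_dataset):
        design = toy_dataset.design.rename(columns={"subject": "participant"})
        with pytest.raises(ValueError, match="subject"):
            MeldDataset(design, toy_dataset.Y, toy_dataset.feature_space)

    def test_subject_slices_partition_trials(self, toy_dataset):
        slices = toy_dataset.subject_slices()
        assert [s.stop - s.start for s in slices] == [10, 10, 10]


class TestIO:
    def test_dataset_roundtrip_identity(self, toy_dataset, tmp_path):
        save_dataset(toy_dataset, tmp_path / "d.csv", tmp_path / "y.h5")
        back = load_dataset(tmp_path / "d.csv", tmp_path / "y.h5", (3, 5))
        np.testing.assert_array_equal(back.Y, toy_dataset.Y)
        assert back.design["subject"].tolist() == toy_dataset.design["subject"].tolist()

    def test_load_validates_before_compute(self, toy_dataset, tmp_path):
        toy_dataset.design.iloc[:-1].to_csv(tmp_path / "d.csv", index=False)
        np.save(tmp_path / "y.npy", toy_dataset.Y)
        with pytest.raises(ValueError, match="rows"):
            load_dataset(tmp_path / "d.csv", tmp_path / "y.npy", (3, 5))

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_dataset(tmp_path / "nope.csv", tmp_path / "nope.h5", (3, 5))

    def test_result_roundtrip_bitwise(self, tmp_path):
        rng = np.random.default_rng(0)
        res = MeldResult(
            terms=["beh"],
            t_map=rng.standard_normal((1, 15)),
            perm_max_t=rng.standard_normal((20, 1)),
            p_term=rng.uniform(size=(1, 15)),
            min_p_null=rng.uniform(size=20),
            p=rng.uniform(size=(1, 15)),
            mask=rng.uniform(size=(1, 15)) < 0.1,
            feature_shape=(3, 5),
            alpha=0.05,
            seed=3,
            n_permutations=20,
            degenerate_perms=np.zeros(20, dtype=bool),
        )
        save_result(res, tmp_path / "r.h5")
        back = load_result(tmp_path / "r.h5")
        for name in ("t_map", "perm_max_t", "p_term", "min_p_null", "p", "mask"):
            np.testing.assert_array_equal(getattr(back, name), getattr(res, name))
        assert back.terms == res.terms and back.feature_shape == res.feature_shape

    def test_save_into_missing_directory_fails(self, tmp_path):
        res = MeldResult(
            terms=["beh"], t_map=np.zeros((1, 1)), perm_max_t=np.zeros((1, 1)),
            p_term=np.ones((1, 1)), min_p_null=np.ones(1), p=np.ones((1, 1)),
            mask=np.zeros((1, 1), dtype=bool), feature_shape=(1,), alpha=0.05,
            seed=0, n_permutations=1, degenerate_perms=np.zeros(1, dtype=bool),
        )
        with pytest.raises(FileNotFoundError):
            save_result(res, tmp_path / "missing" / "r.h5")


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"stability_alpha": 0.0},
            {"alpha": 1.0},
            {"n_permutations": 0},
            {"n_bootstraps": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MeldConfig(**kwargs)

    def test_invalid_tfce_params_rejected(self):
        with pytest.raises(ValueError):
            TfceParams(dt=0.0)
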