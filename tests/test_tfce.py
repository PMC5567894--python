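import numpy as np
import pytest

from meld import FeatureSpace, TfceParams, label_clusters, tfce_enhance

PARAMS = TfceParams(E=2.0 / 3.0, H=2.0, dt=0.05)


def naive_tfce(values, params, fs):
    """Independent per-pixel oracle: breadth-first flood fill per threshold."""
    values = np.asarray(values, dtype=float)
    n = values.size
    neighbors = [[] for _ in range(n)]
    for a, b in fs.edge_list():
        neighbors[a].append(b)
        neighbors[b].append(a)
    out = np.zeros(n)
    for sign in (1, -1):
        mags = np.where(sign * values > 0, sign * values, 0.0)
        hmax = mags.max()
        k = 1
        while k * params.dt <= hmax + params.dt * 1e-9:
            h = k * params.dt
            above = mags >= h - params.dt * 1e-9
            seen = np.zeros(n, dtype=bool)
            for start in range(n):
                if not above[start] or seen[start]:
                    continue
                # flood fill
                comp, queue = [], [start]
                seen[start] = True
                while queue:
                    u = queue.pop()
                    comp.append(u)
                    for v in neighbors[u]:
                        if above[v] and not seen[v]:
                            seen[v] = True
                            queue.append(v)
                for u in comp:
                    out[u] += sign * len(comp) ** params.E * h**params.H * params.dt
            k += 1
    return out


class TestClosedForms:
    def test_all_zero_map_stays_zero(self):
        fs = FeatureSpace((10, 10))
        assert not tfce_enhance(np.zeros(100), PARAMS, fs).any()

    def test_isolated_pixel_closed_form(self):
        # sum_{k=1..20} 1^(2/3) * (0.05k)^2 * 0.05 = 0.05^3 * 2870 = 0.35875
        fs = FeatureSpace((10, 10))
        m = np.zeros(100)
        m[55] = 1.0
        out = tfce_enhance(m, PARAMS, fs)
        assert abs(out[55] - 0.35875) < 1e-10
        assert np.count_nonzero(out) == 1

    def test_two_adjacent_pixels_closed_form(self):
        fs = FeatureSpace((10, 10))
        m = np.zeros(100)
        m[44] = m[45] = 1.0  # orthogonal neighbors in row 4
        out = tfce_enhance(m, PARAMS, fs)
        expected = 2 ** (2.0 / 3.0) * 0.35875
        np.testing.assert_allclose(out[[44, 45]], expected, atol=1e-10)


class TestProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_oracle_on_random_maps(self, seed):
        fs = FeatureSpace((20, 20))
        rng = np.random.default_rng(seed)
        values = rng.standard_normal(400) * (rng.uniform(size=400) < 0.4)
        fast = tfce_enhance(values, PARAMS, fs)
        slow = naive_tfce(values, PARAMS, fs)
        np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_oddness(self, rng):
        fs = FeatureSpace((12, 12))
        m = rng.standard_normal(144)
        np.testing.assert_allclose(
            tfce_enhance(-m, PARAMS, fs), -tfce_enhance(m, PARAMS, fs), atol=1e-12
        )

    def test_sign_preserved_per_feature(self, rng):
        fs = FeatureSpace((12, 12))
        m = rng.standard_normal(144)
        out = tfce_enhance(m, PARAMS, fs)
        nonzero = out != 0
        assert np.all(np.sign(out[nonzero]) == np.sign(m[nonzero]))

    def test_monotone_under_scaling(self, rng):
        fs = FeatureSpace((10, 10))
        m = np.abs(rng.standard_normal(100)) * (rng.uniform(size=100) < 0.5)
        low = tfce_enhance(m, PARAMS, fs)
        high = tfce_enhance(1.7 * m, PARAMS, fs)
        assert np.all(high >= low - 1e-12)

    def test_explicit_adjacency_equals_lattice(self, rng):
        shape = (9, 11)
        lattice = FeatureSpace(shape)
        explicit = FeatureSpace(shape, adjacency=lattice.edge_list())
        m = rng.standard_normal(99)
        np.testing.assert_allclose(
            tfce_enhance(m, PARAMS, lattice),
            tfce_enhance(m, PARAMS, explicit),
            atol=1e-12,
        )

    def test_empty_explicit_adjacency_rejected(self):
        fs = FeatureSpace((3,), adjacency=np.empty((0, 2), dtype=int))
        with pytest.raises(ValueError, match="no edges"):
            tfce_enhance(np.ones(3), PARAMS, fs)


class TestLabelClusters:
    def test_checkerboard_all_singletons(self):
        fs = FeatureSpace((6, 6))
        mask = (np.add.outer(np.arange(6), np.arange(6)) % 2 == 0).ravel()
        labels, n = label_clusters(mask, fs)
        assert n == mask.sum()

    def test_full_lattice_single_cluster(self):
        labels, n = label_clusters(np.ones(9, dtype=bool), FeatureSpace((3, 3)))
        assert n == 1 and np.all(labels == 1)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_sizes_match_flood_fill_oracle(self, seed):
        fs = FeatureSpace((20, 20))
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=400) < 0.45
        labels, n = label_clusters(mask, fs)
        # oracle sizes via the naive enhancer's flood fill at a single threshold
        oracle = naive_tfce(mask.astype(float), TfceParams(E=1.0, H=0.0, dt=1.0), fs)
        sizes_by_label = np.bincount(labels[mask])
        np.testing.assert_allclose(sizes_by_label[labels[mask]], oracle[mask])

    def test_explicit_graph_labels_deterministic(self):
        fs = FeatureSpace((5,), adjacency=np.array([[0, 1], [3, 4]]))
        labels, n = label_clusters(np.array([1, 1, 0, 1, 1], dtype=bool), fs)
        assert n == 2
        assert labels.tolist() == [1, 1, 0, 2, 2]
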