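"""The 17 weights specifications: kernels, sanitisation, standardisation."""

import numpy as np
import pytest

import bymweights as bw
from bymweights.weights import A2_ORDER_WEIGHTS


@pytest.fixture(scope="module")
def chain4():
    return bw.contiguity(bw.grid_lattice(1, 4), include_vertex=False)


class TestAdjacencyWeights:
    def test_first_order_binary(self, lattice3):
        g = bw.contiguity(lattice3)
        wm = bw.adjacency_weights(g, n=1, order_weights=(1.0,))
        assert set(np.unique(wm.w)) <= {0.0, 1.0}
        assert wm.w[4, 0] == 1.0  # queen: centre touches corner
        assert wm.w.sum() / 2 == 20  # undirected queen edges on 3x3

    def test_third_order_chain(self, chain4):
        wm = bw.adjacency_weights(chain4, n=3, order_weights=A2_ORDER_WEIGHTS)
        assert wm.w[0, 3] == pytest.approx(np.exp(-1), abs=1e-12)
        assert wm.w[0, 1] == pytest.approx(1.0)
        assert wm.w[0, 2] == pytest.approx(np.exp(-0.5))

    def test_beyond_neighbourhood_zero(self):
        g = bw.contiguity(bw.grid_lattice(1, 5), include_vertex=False)
        wm = bw.adjacency_weights(g, n=3, order_weights=A2_ORDER_WEIGHTS)
        assert wm.w[0, 4] == 0.0  # order 4 > n

    def test_omega_length_mismatch(self, chain4):
        with pytest.raises(ValueError, match="length"):
            bw.adjacency_weights(chain4, n=3, order_weights=(1.0, 0.5))

    def test_a1_equals_a2_first_order(self, lattice3):
        g = bw.contiguity(lattice3)
        a1 = bw.adjacency_weights(g, n=1, order_weights=(1.0,))
        a2 = bw.adjacency_weights(g, n=3, order_weights=A2_ORDER_WEIGHTS)
        order = bw.adjacency_order(g, 3)
        assert np.array_equal(a1.w == 1.0, order == 1)
        assert np.allclose(a2.w[order == 1], 1.0)


class TestKernels:
    def test_inverse_power_values(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert bw.inverse_power_weights(d, 1)[0, 1] == pytest.approx(0.5)
        assert bw.inverse_power_weights(d, 5)[0, 1] == pytest.approx(0.03125)

    def test_inverse_power_zero_distance_nonfinite(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = 1.0
        raw = bw.inverse_power_weights(d, 2)
        assert not np.isfinite(raw[0, 2])
        assert np.all(np.diag(raw) == 0)

    def test_decay_scale_constant_distances(self):
        d = np.full((3, 3), 2.0)
        np.fill_diagonal(d, 0.0)
        lam, b = bw.decay_scale(d)
        assert lam == pytest.approx(5.0)
        assert b == pytest.approx(0.2)

    def test_decay_scale_homogeneity(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        lam1, _ = bw.decay_scale(d)
        lam2, _ = bw.decay_scale(3.0 * d)
        assert lam2 == pytest.approx(lam1 / 3.0)

    def test_decay_scale_brute_force_oracle(self, lattice12):
        d = bw.pairwise_centroid_distance(lattice12)
        lam, b = bw.decay_scale(d)
        # independent double-loop mean over ordered pairs
        tot, cnt = 0.0, 0
        for i in range(144):
            for j in range(144):
                if i != j:
                    tot += d[i, j]
                    cnt += 1
        assert lam == pytest.approx(10.0 / (tot / cnt), rel=1e-12)
        assert b == pytest.approx(1.0 / lam, rel=1e-12)

    def test_exponential_decay(self):
        d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 2.0], [1.0, 2.0, 0.0]])
        w = bw.exponential_decay_weights(d, 5.0)
        assert w[0, 1] == pytest.approx(1.0)      # zero distance off-diagonal
        assert w[0, 2] == pytest.approx(np.exp(-5))
        assert w[0, 2] > w[1, 2]                  # decreasing in distance
        with pytest.raises(ValueError):
            bw.exponential_decay_weights(d, 0.0)

    def test_gaussian_decay(self):
        b = 1.5
        d = np.array([[0.0, b, 2 * b], [b, 0.0, 0.0], [2 * b, 0.0, 0.0]])
        w = bw.gaussian_decay_weights(d, b)
        assert w[0, 1] == pytest.approx(np.exp(-0.5))
        assert w[0, 2] == pytest.approx(np.exp(-2))
        assert w[1, 2] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            bw.gaussian_decay_weights(d, -1.0)

    def test_covariate_distances(self):
        delta = bw.covariate_distances([1.0, 4.0, 4.0])
        assert delta[0, 1] == 3.0
        assert delta[1, 2] == 0.0
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        dd = bw.covariate_distances(x)
        assert np.array_equal(dd, dd.T)
        assert np.all(np.diag(dd) == 0)

    def test_hybrid_distances(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        delta = np.array([[0.0, 3.0], [3.0, 0.0]])
        assert bw.hybrid_distances(d, delta)[0, 1] == 6.0
        with pytest.raises(ValueError, match="shape"):
            bw.hybrid_distances(d, np.zeros((3, 3)))


class TestSanitiseSymmetrise:
    def test_row_max_replacement(self):
        raw = np.array([[0.0, np.inf, 0.8, 0.1],
                        [np.inf, 0.0, 0.2, 0.3],
                        [0.8, 0.2, 0.0, 0.4],
                        [0.1, 0.3, 0.4, 0.0]])
        wm = bw.sanitise_symmetrise(raw)
        assert wm.w[0, 1] == 0.8  # max finite in row 0
        assert wm.w[1, 0] == 0.8  # lower triangle from upper

    def test_finite_symmetric_unchanged(self):
        rng = np.random.default_rng(3)
        a = np.abs(rng.normal(size=(5, 5)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        assert np.allclose(bw.sanitise_symmetrise(a).w, a)

    def test_output_symmetric(self):
        rng = np.random.default_rng(4)
        a = np.abs(rng.normal(size=(6, 6)))
        a[rng.random(size=(6, 6)) < 0.2] = np.inf
        np.fill_diagonal(a, 0.0)
        w = bw.sanitise_symmetrise(a).w
        assert np.array_equal(w, w.T)
        assert np.all(np.isfinite(w))

    def test_unrecoverable_row(self):
        raw = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError, match="no finite"):
            bw.sanitise_symmetrise(raw)


class TestRowStandardise:
    def test_binary_row_equal_shares(self, lattice3):
        wm = bw.build_weights("A1", lattice3)
        std = bw.row_standardise(wm)
        assert std.standardised
        assert np.allclose(std.w[4][std.w[4] > 0], 1 / 8)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        a = np.abs(rng.normal(size=(7, 7)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        std = bw.row_standardise(bw.sanitise_symmetrise(a))
        assert np.allclose(std.w.sum(axis=1), 1.0, atol=1e-12)

    def test_island_row_untouched(self, caplog):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.0
        wm = bw.sanitise_symmetrise(a)
        with caplog.at_level("WARNING"):
            std = bw.row_standardise(wm)
        assert np.all(std.w[2] == 0)
        assert "island" in caplog.text


class TestBuildWeights:
    @pytest.mark.parametrize("label", bw.SPEC_LABELS)
    def test_all_specs_valid(self, label, lattice3):
        x = np.arange(9.0) * 0.3
        wm = bw.build_weights(label, lattice3, x)
        assert np.array_equal(wm.w, wm.w.T)
        assert np.all(np.isfinite(wm.w))
        assert np.all(wm.w >= 0)
        assert np.all(np.diag(wm.w) == 0)
        assert not wm.standardised

    def test_a1_queen_edge_count(self, lattice3):
        wm = bw.build_weights("A1", lattice3)
        assert wm.w.sum() / 2 == 20

    def test_covariate_required_for_c_and_h(self, lattice3):
        for label in ("C1", "H4"):
            with pytest.raises(ValueError, match="covariate"):
                bw.build_weights(label, lattice3)

    def test_d4_c4_share_kernel(self, lattice3):
        # same kernel applied to different distances with recomputed decay
        x = np.linspace(0, 2, 9)
        d4 = bw.build_weights("D4", lattice3, x)
        c4 = bw.build_weights("C4", lattice3, x)
        dgeo = bw.pairwise_centroid_distance(lattice3)
        dcov = bw.covariate_distances(x)
        lam_geo, _ = bw.decay_scale(dgeo)
        lam_cov, _ = bw.decay_scale(dcov)
        assert d4.w[0, 1] == pytest.approx(np.exp(-lam_geo * dgeo[0, 1]))
        assert c4.w[0, 1] == pytest.approx(np.exp(-lam_cov * dcov[0, 1]))

    def test_h1_duplicate_covariate_sanitised(self, lattice3):
        x = np.ones(9)
        x[0] = 2.0  # all other pairs have zero covariate distance
        wm = bw.build_weights("H1", lattice3, x)
        assert np.all(np.isfinite(wm.w))

    def test_inverse_power_constant_distance(self):
        # distances all equal c -> constant off-diagonal 1/c for k=1
        geom = bw.ArealGeometry(["a", "b", "c"],
                                np.array([[0.0, 0.0], [2.0, 0.0], [1.0, np.sqrt(3)]]))
        d = bw.pairwise_centroid_distance(geom)
        w = bw.inverse_power_weights(d, 1)
        off = w[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.5, atol=1e-12)

    @pytest.mark.parametrize("label", ["D4", "D5"])
    def test_decay_scale_invariance(self, label):
        # rescaling all geographic distances leaves D4/D5 unchanged
        rng = np.random.default_rng(6)
        cents = rng.normal(size=(10, 2))
        x = rng.normal(size=10)
        g1 = bw.ArealGeometry([f"a{i}" for i in range(10)], cents)
        g2 = bw.ArealGeometry([f"a{i}" for i in range(10)], cents * 37.5)
        w1 = bw.build_weights(label, g1, x)
        w2 = bw.build_weights(label, g2, x)
        assert np.allclose(w1.w, w2.w, atol=1e-12)

    def test_unknown_label(self, lattice3):
        with pytest.raises(ValueError, match="unknown"):
            bw.build_weights("Z9", lattice3)


class TestNeighbourProfile:
    def test_requires_standardised(self, lattice3):
        wm = bw.build_weights("A1", lattice3)
        with pytest.raises(ValueError, match="standardised"):
            bw.neighbour_profile(wm, [0.1])

    def test_a1_zero_threshold_mean_degree(self, lattice3):
        std = bw.row_standardise(bw.build_weights("A1", lattice3))
        prof = bw.neighbour_profile(std, [0.0])
        degrees = [len(s) for s in bw.contiguity(lattice3).neighbour_sets]
        assert prof[0] == pytest.approx(np.mean(degrees))

    def test_monotone_and_vanishing(self, lattice3):
        x = np.linspace(0, 1, 9)
        std = bw.row_standardise(bw.build_weights("D2", lattice3, x))
        thresholds = [0.0, 0.05, 0.1, 0.2, 1.1]
        prof = bw.neighbour_profile(std, thresholds)
        assert np.all(np.diff(prof) <= 0)
        assert prof[-1] == 0.0  # above every row maximum
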