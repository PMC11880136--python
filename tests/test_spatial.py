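"""Nearest-neighbour statistics and Ripley K/L with envelopes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from deltaosc import (
    CellTable,
    Window,
    envelope,
    gen_cell_field,
    k_function,
    l_function,
    label_positives,
    make_radii,
    nn_distances,
    relative_min_distance,
)
from conftest import oracle_k_function, oracle_nn_distances


class TestNNDistances:
    def test_collinear_points(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        np.testing.assert_allclose(nn_distances(pts), [1.0, 1.0, 2.0])

    def test_coincident_points(self):
        pts = np.array([[2.0, 2.0], [2.0, 2.0]])
        np.testing.assert_allclose(nn_distances(pts), [0.0, 0.0])

    def test_rejects_single_point(self):
        with pytest.raises(ValueError):
            nn_distances(np.array([[0.0, 0.0]]))

    def test_matches_bruteforce_oracle(self, csr_field):
        np.testing.assert_allclose(
            nn_distances(csr_field), oracle_nn_distances(csr_field), rtol=1e-12
        )


class TestRelativeMinDistance:
    def test_all_positive_gives_unit_ratios(self, csr_field):
        cells = label_positives(csr_field, len(csr_field), "random", seed=0)
        stats = relative_min_distance(cells)
        np.testing.assert_allclose(stats.values, 1.0)
        assert stats.cv == 0.0

    def test_checkerboard_ratio_is_sqrt2(self):
        i, j = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        pts = np.column_stack([i.ravel(), j.ravel()]).astype(float)
        positive = ((i + j) % 2 == 0).ravel().astype(int)
        stats = relative_min_distance(CellTable.from_arrays(pts, positive=positive))
        np.testing.assert_allclose(stats.values, np.sqrt(2.0))
        assert stats.cv == pytest.approx(0.0, abs=1e-12)

    def test_requires_two_positives(self, csr_field):
        cells = label_positives(csr_field, 1, "random", seed=0)
        with pytest.raises(ValueError):
            relative_min_distance(cells)

    def test_epithelial_substrate_cv_near_rayleigh(self, unit_window):
        # random labelling on a regular (jittered-grid) substrate: the
        # denominator is nearly constant, so the ratio cv tracks the Rayleigh
        # nearest-neighbour cv of the sparse positives
        cvs = []
        for s in range(25):
            field = gen_cell_field(2500, unit_window, "jittered_grid", seed=s)
            cells = label_positives(field, 250, "random", seed=s + 1)
            cvs.append(relative_min_distance(cells).cv)
        assert 0.45 <= np.mean(cvs) <= 0.60

    @given(
        shift=st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
        angle=st.floats(0, 2 * np.pi),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_similarity_invariance(self, shift, angle, scale, csr_field):
        # ratios are scale-free: rigid motion + uniform scaling preserve them
        cells = label_positives(csr_field, 30, "random", seed=3)
        base = relative_min_distance(cells).values
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = (csr_field @ rot.T) * scale + np.asarray(shift)
        cells2 = CellTable.from_arrays(moved, positive=cells.df["positive"].to_numpy())
        np.testing.assert_allclose(
            np.sort(relative_min_distance(cells2).values), np.sort(base), rtol=1e-9
        )


class TestKFunction:
    def test_two_point_worked_example_uncorrected(self):
        # A=4, n(n-1)=2: K jumps from 0 to 4 at the pair distance
        pts = np.array([[0.5, 1.0], [1.5, 1.0]])
        w = Window(0, 2, 0, 2)
        k = k_function(pts, w, np.array([0.5, 0.99, 1.0, 1.5]), edge_correction="none")
        np.testing.assert_allclose(k, [0.0, 0.0, 4.0, 4.0])

    def test_zero_below_minimum_pair_distance(self, csr_field, unit_window):
        dmin = nn_distances(csr_field).min()
        k = k_function(csr_field, unit_window, np.array([dmin * 0.5]))
        assert k[0] == 0.0

    @pytest.mark.parametrize("edge_correction", ["none", "translation"])
    def test_matches_bruteforce_oracle(self, unit_window, edge_correction):
        pts = gen_cell_field(60, unit_window, seed=21)
        radii = np.linspace(2, 40, 8)
        np.testing.assert_allclose(
            k_function(pts, unit_window, radii, edge_correction),
            oracle_k_function(pts, unit_window, radii, edge_correction),
            rtol=1e-12,
        )

    @given(seed=st.integers(0, 10_000), n=st.integers(5, 60))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_monotone_nondecreasing(self, seed, n, unit_window):
        pts = gen_cell_field(n, unit_window, seed=seed)
        k = k_function(pts, unit_window, make_radii(unit_window, 30))
        assert (np.diff(k) >= -1e-9).all()


class TestLFunction:
    def test_known_values(self):
        np.testing.assert_allclose(l_function(np.array([0.0, np.pi])), [0.0, 1.0])

    def test_rejects_negative_k(self):
        with pytest.raises(ValueError):
            l_function(np.array([-1.0]))

    def test_csr_l_tracks_identity(self, unit_window):
        # CSR closed form: K = pi r^2, so L(r) = r
        radii = np.linspace(2, 10, 9)
        ls = np.mean(
            [
                l_function(k_function(gen_cell_field(500, unit_window, seed=s), unit_window, radii))
                for s in range(10)
            ],
            axis=0,
        )
        np.testing.assert_allclose(ls, radii, rtol=0.05)


class TestMakeRadii:
    def test_stated_grid_arithmetic(self):
        w = Window(0, 100, 0, 40)
        radii = make_radii(w, 100)
        assert len(radii) == 100
        assert radii[0] == pytest.approx(0.4)
        assert radii[-1] == pytest.approx(20.0)
        np.testing.assert_allclose(np.diff(radii), (20 - 0.4) / 99)

    def test_single_radius_is_half_span(self):
        assert make_radii(Window(0, 10, 0, 30), 1)[0] == pytest.approx(5.0)

    def test_strictly_increasing(self, unit_window):
        assert (np.diff(make_radii(unit_window)) > 0).all()


class TestEnvelope:
    def test_null_labelling_classified_random(self, unit_window):
        fracs = []
        for s in range(10):
            field = gen_cell_field(150, unit_window, seed=100 + s)
            cells = label_positives(field, 30, "random", seed=200 + s)
            env = envelope(cells, unit_window, n_sim=80, level=0.99, seed=300 + s)
            fracs.append(env.fraction("random"))
        assert np.mean(fracs) >= 0.95

    def test_cluster_control_detected(self, unit_window):
        field = gen_cell_field(200, unit_window, seed=31)
        cells = label_positives(field, 40, "max_cluster", seed=32)
        env = envelope(cells, unit_window, n_sim=80, level=0.99, seed=33)
        half = len(env.radii) // 2
        assert (env.classification[:half] == "clustered").any()

    def test_regular_control_detected(self, unit_window):
        field = gen_cell_field(200, unit_window, seed=41)
        cells = label_positives(field, 40, "max_regular", seed=42)
        env = envelope(cells, unit_window, n_sim=80, level=0.99, seed=43)
        half = len(env.radii) // 2
        assert (env.classification[:half] == "regular").any()

    def test_all_positive_degenerates_to_random_with_warning(self, csr_field, unit_window):
        cells = label_positives(csr_field, len(csr_field), "random", seed=0)
        with pytest.warns(UserWarning, match="all cells are positive"):
            env = envelope(cells, unit_window, n_sim=10, seed=1)
        assert env.fraction("random") == 1.0

    def test_pointwise_exceedance_matches_level(self, unit_window):
        # under the null, the observed curve should leave the 99% envelope at
        # roughly 1-2% of radii (interpolated quantiles of 80 simulations sit
        # slightly inside the extremes, so ~0.025 is the theoretical rate)
        rng = np.random.default_rng(0)
        field = gen_cell_field(80, unit_window, seed=5)
        radii = make_radii(unit_window, 20)
        exceed = []
        for _ in range(400):
            cells = label_positives(field, 16, "random", seed=int(rng.integers(2**31)))
            env = envelope(
                cells, unit_window, radii=radii, n_sim=80, level=0.99,
                seed=int(rng.integers(2**31)),
            )
            exceed.append(1.0 - env.fraction("random"))
        assert abs(np.mean(exceed) - 0.01) <= 0.02

    def test_envelope_bounds_ordered_and_deterministic(self, labelled_cells, unit_window):
        a = envelope(labelled_cells, unit_window, n_sim=20, seed=7)
        b = envelope(labelled_cells, unit_window, n_sim=20, seed=7)
        assert (a.env_lo <= a.env_hi).all()
        np.testing.assert_array_equal(a.l_sims, b.l_sims)
        np.testing.assert_array_equal(a.classification, b.classification)
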