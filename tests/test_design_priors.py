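"""B-spline bases, RW2/GMRF penalties, design-block assembly."""

import numpy as np
import pytest

import geoprobit as gp
from geoprobit.design_priors import (
    DesignError,
    ModelSpec,
    SmoothTerm,
    bspline_basis,
    build_designs,
    gmrf_precision,
    rw2_penalty,
)


class TestBsplineBasis:
    def test_partition_of_unity(self, rng):
        w = rng.uniform(6, 59, size=300)
        B = bspline_basis(w)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_default_dimension_is_22(self, rng):
        # twenty equidistant knots, cubic: D = 20 + 3 - 1
        B = bspline_basis(rng.uniform(0, 1, 50), n_knots=20, degree=3)
        assert B.shape[1] == 22

    def test_degree_zero_indicator_basis(self):
        w = np.array([0.05, 0.4, 0.6, 0.99])
        B = bspline_basis(w, n_knots=4, degree=0)
        assert B.shape[1] == 3
        assert set(np.unique(B)) <= {0.0, 1.0}
        np.testing.assert_array_equal((B == 1).sum(axis=1), 1)

    def test_boundary_points_included(self):
        B = bspline_basis(np.array([6.0, 59.0, 32.5]))
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_constant_covariate_raises(self):
        with pytest.raises(DesignError):
            bspline_basis(np.full(10, 3.0))


class TestRw2Penalty:
    def test_annihilates_constants_and_linear(self):
        K = rw2_penalty(12)
        np.testing.assert_allclose(K @ np.ones(12), 0.0, atol=1e-12)
        np.testing.assert_allclose(K @ np.arange(1.0, 13.0), 0.0, atol=1e-12)

    def test_rank_deficiency_is_two(self):
        K = rw2_penalty(10)
        assert np.linalg.matrix_rank(K, tol=1e-10) == 8

    def test_explicit_d4_matrix(self):
        expected = np.array(
            [[1, -2, 1, 0], [-2, 5, -4, 1], [1, -4, 5, -2], [0, 1, -2, 1]], dtype=float
        )
        np.testing.assert_array_equal(rw2_penalty(4), expected)

    def test_too_small_raises(self):
        with pytest.raises(DesignError):
            rw2_penalty(2)


class TestGmrfPrecision:
    def test_single_edge(self):
        g = gp.AdjacencyGraph(regions=["A", "B"], neighbours=[[1], [0]])
        np.testing.assert_array_equal(gmrf_precision(g), [[1, -1], [-1, 1]])

    def test_path_degrees(self):
        g = gp.AdjacencyGraph(regions=["A", "B", "C"], neighbours=[[1], [0, 2], [1]])
        K = gmrf_precision(g)
        np.testing.assert_array_equal(np.diag(K), [1, 2, 1])

    def test_lattice_rank_is_s_minus_one(self, lattice44):
        K = gmrf_precision(lattice44)
        assert np.linalg.matrix_rank(K, tol=1e-8) == 15
        np.testing.assert_allclose(K.sum(axis=1), 0.0, atol=1e-12)

    def test_island_zero_row(self):
        g = gp.AdjacencyGraph(regions=["A", "B", "C"], neighbours=[[1], [0], []])
        K = gmrf_precision(g)
        np.testing.assert_array_equal(K[2], 0.0)


@pytest.fixture(scope="module")
def ds_graph():
    g = gp.make_lattice_map(3, 3)
    effects = gp.sample_true_effects(g, "linear_only", 1)
    return gp.simulate_dataset(g, effects, n=400, seed=2), g


class TestBuildDesigns:
    def test_wealth_gives_four_dummies(self, ds_graph):
        ds, g = ds_graph
        blocks = build_designs(ds, ModelSpec.from_terms(["wealth"], [], spatial=False), g)
        lin = blocks["mu1"][0]
        assert lin.colnames == [
            "intercept",
            "wealth[middle]",
            "wealth[poorer]",
            "wealth[richer]",
            "wealth[richest]",
        ]

    def test_dummy_columns_sum_to_category_counts(self, ds_graph):
        ds, g = ds_graph
        blocks = build_designs(ds, ModelSpec.from_terms(["wealth"], [], spatial=False), g)
        lin = blocks["mu1"][0]
        counts = ds.frame["wealth"].value_counts()
        for i, name in enumerate(lin.colnames[1:], start=1):
            level = name.split("[")[1].rstrip("]")
            assert lin.Z[:, i].sum() == counts[level]

    def test_spatial_rows_are_region_indicators(self, ds_graph):
        ds, g = ds_graph
        blocks = build_designs(ds, ModelSpec.from_terms([], [], spatial=True), g)
        sp = blocks["mu2"][-1]
        assert sp.kind == "spatial"
        np.testing.assert_array_equal(sp.Z.sum(axis=1), 1.0)
        i = 5
        assert sp.Z[i, g.index(ds.region.iloc[i])] == 1.0

    def test_full_structure(self, ds_graph):
        ds, g = ds_graph
        spec = ModelSpec.from_terms(
            list(ds.categorical), [SmoothTerm(c) for c in ds.continuous], spatial=True
        )
        blocks = build_designs(ds, spec, g)
        for param in ("mu1", "mu2", "rho"):
            kinds = [b.kind for b in blocks[param]]
            assert kinds == ["linear", "spline", "spline", "spatial"]

    def test_penalties_are_psd(self, ds_graph):
        ds, g = ds_graph
        spec = ModelSpec.from_terms([], [SmoothTerm("child_age_months")], spatial=True)
        blocks = build_designs(ds, spec, g)
        for b in blocks["mu1"]:
            if b.penalized:
                ev = np.linalg.eigvalsh(b.Kr)
                assert ev.min() >= -1e-10

    def test_reduced_basis_satisfies_constraint(self, ds_graph):
        ds, g = ds_graph
        spec = ModelSpec.from_terms([], [SmoothTerm("child_age_months")], spatial=True)
        blocks = build_designs(ds, spec, g)
        for b in blocks["mu1"][1:]:
            A = np.atleast_2d(b.constraint)
            np.testing.assert_allclose(A @ b.T, 0.0, atol=1e-10)

    def test_intercept_shift_invariance(self, ds_graph):
        """Moving a constant from a centred spline into the intercept leaves eta fixed."""
        ds, g = ds_graph
        spec = ModelSpec.from_terms([], [SmoothTerm("child_age_months")], spatial=False)
        blocks = build_designs(ds, spec, g)
        lin, spl = blocks["mu1"]
        rng = np.random.default_rng(0)
        beta_lin = rng.normal(size=lin.dim)
        beta_spl = rng.normal(size=spl.dim)
        c = 0.37
        eta = lin.Z @ beta_lin + spl.Z @ beta_spl
        beta_lin2 = beta_lin.copy()
        beta_lin2[0] -= c
        eta2 = lin.Z @ beta_lin2 + spl.Z @ (beta_spl + c)  # partition of unity
        np.testing.assert_allclose(eta, eta2, atol=1e-10)

    def test_unknown_smooth_column(self, ds_graph):
        ds, g = ds_graph
        spec = ModelSpec.from_terms([], [SmoothTerm("not_a_column")], spatial=False)
        with pytest.raises(Exception):
            build_designs(ds, spec, g)

    def test_island_effect_constrained_to_zero(self):
        g = gp.AdjacencyGraph(
            regions=["A", "B", "C"], neighbours=[[1], [0], []]
        )
        import pandas as pd

        frame = pd.DataFrame(
            {"region": ["A", "B", "C", "A"], "child_age_months": [10, 20, 30, 40.0]}
        )
        ds = gp.Dataset(
            y1=np.array([0, 1, 0, 1]),
            y2=np.array([1, 0, 0, 1]),
            frame=frame,
            categorical={},
            continuous=("child_age_months",),
        )
        blocks = build_designs(ds, ModelSpec.from_terms([], [], spatial=True), g)
        sp = blocks["mu1"][-1]
        # every representable coefficient vector has a zero island entry
        island_row = np.abs(sp.T[2])
        np.testing.assert_allclose(island_row, 0.0, atol=1e-12)
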