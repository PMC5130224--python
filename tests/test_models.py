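"""Model specifications, design matrices, and precision structures."""

import numpy as np
import pytest
import scipy.sparse as sp

import pesticar as pc
from pesticar.models import (
    ar1_coefficients,
    ar1_pattern_matrices,
    spacetime_constraints,
    spacetime_rank,
)

from conftest import make_toy_panel


@pytest.fixture
def grid_graph():
    graph, _ = pc.make_grid_lattice(2, 2)
    return graph


class TestModelSpecs:
    def test_model1_has_no_latent_blocks(self, toy_panel):
        spec = pc.make_model_spec(1, toy_panel)
        assert spec.latent_blocks == ()
        assert len(spec.fixed_terms) == 8  # intercept + 7 covariates

    def test_model5_block_set(self, toy_panel, grid_graph):
        spec = pc.make_model_spec(5, toy_panel, grid_graph)
        kinds = sorted(b.kind for b in spec.latent_blocks)
        assert kinds == ["icar_ar1_slope", "iid_county", "iid_year"]
        slope = next(b for b in spec.latent_blocks if b.kind == "icar_ar1_slope")
        assert slope.covariate == "x_crop"

    def test_model6_block_set(self, toy_panel, grid_graph):
        spec = pc.make_model_spec(6, toy_panel, grid_graph)
        kinds = sorted(b.kind for b in spec.latent_blocks)
        assert kinds == ["icar_ar1_intercept", "iid_county", "iid_year"]

    def test_unknown_model_rejected(self, toy_panel):
        with pytest.raises(ValueError):
            pc.make_model_spec(7, toy_panel)

    def test_spatial_models_require_graph(self, toy_panel):
        for m in (5, 6):
            with pytest.raises(ValueError, match="graph"):
                pc.make_model_spec(m, toy_panel)

    def test_prior_defaults(self, toy_panel):
        spec = pc.make_model_spec(4, toy_panel)
        intercept = spec.fixed_terms[0]
        assert intercept.prior_precision == 0.0
        assert all(t.prior_precision == 0.001 for t in spec.fixed_terms[1:])
        assert all(b.precision_prior == (1.0, 0.00005) for b in spec.latent_blocks)
        assert spec.error_precision_prior == (1.0, 0.00005)

    def test_yaml_round_trip(self, tmp_path, toy_panel, grid_graph):
        spec = pc.make_model_spec(6, toy_panel, grid_graph)
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        back = pc.ModelSpec.from_yaml(path)
        assert back == spec
        assert back.spec_hash() == spec.spec_hash()


class TestDesignMatrix:
    def test_model1_shape_and_order(self, toy_panel):
        panel = pc.center_covariates(make_toy_panel())
        spec = pc.make_model_spec(1, panel)
        x, names, prec = pc.build_design_matrix(spec, panel)
        assert x.shape == (8, 8)
        assert names[0] == "intercept"
        assert names[1:] == list(pc.COVARIATES)
        assert prec[0] == 0.0 and (prec[1:] == 0.001).all()

    def test_model2_reference_coding(self):
        rows = []
        for cid, st_id in [("A", "S1"), ("B", "S2"), ("C", "S3")]:
            for year in (1997, 2002, 2007, 2012):
                rows.append(dict(county_id=cid, state_id=st_id, year=year,
                                 y=0.2, x_corn=0.3, x_cov=0.05, x_sw=0.2,
                                 x_income=0.5, x_size=1.0, x_gdd=3.0, x_crop=0.4))
        panel = pc.center_covariates(make_toy_panel(rows))
        spec = pc.make_model_spec(2, panel)
        x, names, _ = pc.build_design_matrix(spec, panel)
        # 8 base terms + 2 non-reference state columns + 1 year column
        assert x.shape[1] == 11
        assert "state[S1]" not in names  # first sorted state is the reference
        assert {"state[S2]", "state[S3]", "year"} <= set(names)
        yc = x[:, names.index("year")]
        assert sorted(set(yc)) == [-7.5, -2.5, 2.5, 7.5]

    def test_model3_interactions_are_products(self):
        rows = []
        for cid, st_id in [("A", "S1"), ("B", "S2")]:
            for k, year in enumerate((1997, 2002, 2007, 2012)):
                rows.append(dict(county_id=cid, state_id=st_id, year=year,
                                 y=0.2, x_corn=0.3, x_cov=0.05, x_sw=0.2,
                                 x_income=0.5, x_size=1.0, x_gdd=3.0,
                                 x_crop=0.1 * (k + 1)))
        with pytest.warns(UserWarning, match="< 3 counties"):
            panel = pc.center_covariates(make_toy_panel(rows))
            spec = pc.make_model_spec(3, panel)
            x, names, _ = pc.build_design_matrix(spec, panel)
        z = x[:, names.index("x_crop")]
        ind = x[:, names.index("state[S2]")]
        yc = x[:, names.index("year")]
        np.testing.assert_allclose(x[:, names.index("state[S2]:x_crop")], ind * z)
        np.testing.assert_allclose(x[:, names.index("year:x_crop")], yc * z)
        np.testing.assert_allclose(
            x[:, names.index("state[S2]:year:x_crop")], ind * yc * z)

    def test_all_zero_column_warns(self, toy_panel):
        panel = toy_panel.copy()
        panel.data["x_cov"] = 0.0
        spec = pc.make_model_spec(1, panel)
        with pytest.warns(UserWarning, match="all-zero"):
            pc.build_design_matrix(spec, panel)

    def test_missing_covariate_errors(self, toy_panel):
        spec = pc.make_model_spec(1, toy_panel)
        panel = toy_panel.copy()
        panel.data = panel.data.drop(columns=["x_gdd"])
        with pytest.raises(KeyError):
            pc.build_design_matrix(spec, panel)


class TestIcarStructure:
    def test_path_of_three(self, toy_panel):
        g = pc.AdjacencyGraph(node_ids=("a", "b", "c"),
                              edges=((0, 1), (1, 2)),
                              components=((0, 1, 2),))
        w = pc.build_icar_structure(g).toarray()
        np.testing.assert_allclose(w, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_row_sums_zero_and_rank(self):
        graph, _ = pc.make_grid_lattice(2, 2)
        w = pc.build_icar_structure(graph)
        np.testing.assert_allclose(np.asarray(w.sum(axis=1)).ravel(), 0.0, atol=1e-12)
        assert np.linalg.matrix_rank(w.toarray()) == 3

    def test_ones_vector_in_null_space(self):
        graph, _ = pc.make_grid_lattice(3, 4)
        w = pc.build_icar_structure(graph)
        np.testing.assert_allclose(w @ np.ones(12), 0.0, atol=1e-12)


class TestAr1Precision:
    def test_rho_zero_is_identity(self):
        q = pc.build_ar1_precision(3, 0.0).toarray()
        np.testing.assert_allclose(q, np.eye(3))

    def test_two_point_hand_case(self):
        q = pc.build_ar1_precision(2, 0.5).toarray()
        np.testing.assert_allclose(q, [[4 / 3, -2 / 3], [-2 / 3, 4 / 3]])

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize("rho", [-0.8, -0.3, 0.0, 0.4, 0.9])
    def test_inverse_is_ar1_covariance(self, n, rho):
        tau = 2.5
        q = pc.build_ar1_precision(n, rho, tau).toarray()
        cov = np.array([[rho ** abs(i - j) / tau for j in range(n)]
                        for i in range(n)])
        np.testing.assert_allclose(np.linalg.inv(q), cov, atol=1e-12)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            pc.build_ar1_precision(3, 1.0)

    def test_pattern_decomposition_matches(self):
        e_end, e_int, e_off = ar1_pattern_matrices(4)
        c = ar1_coefficients(0.6)
        q = (c[0] * e_end + c[1] * e_int + c[2] * e_off).toarray()
        np.testing.assert_allclose(q, pc.build_ar1_precision(4, 0.6).toarray())


class TestSpacetimePrecision:
    def test_rho_zero_is_block_diagonal_icar(self):
        graph, _ = pc.make_grid_lattice(2, 2)
        q, _ = pc.build_spacetime_precision(graph, 3, 0.0, tau=2.0)
        w = pc.build_icar_structure(graph).toarray()
        expected = np.kron(np.eye(3), 2.0 * w)
        np.testing.assert_allclose(q.toarray(), expected)

    def test_path3_by_2years_hand_assembly(self):
        g = pc.AdjacencyGraph(node_ids=("a", "b", "c"),
                              edges=((0, 1), (1, 2)),
                              components=((0, 1, 2),))
        rho, tau = 0.5, 1.5
        q, c = pc.build_spacetime_precision(g, 2, rho, tau)
        w = np.array([[1, -1, 0], [-1, 2, -1], [0, -1, 1]])
        p = np.array([[4 / 3, -2 / 3], [-2 / 3, 4 / 3]])
        np.testing.assert_allclose(q.toarray(), tau * np.kron(p, w))
        assert q.shape == (6, 6)
        assert c.shape == (2, 6)

    def test_null_space_dimension_and_constraints(self):
        graph, _ = pc.make_grid_lattice(2, 2)
        n_years = 3
        q, c = pc.build_spacetime_precision(graph, n_years, 0.7)
        vals = np.linalg.eigvalsh(q.toarray())
        n_null = int(np.sum(np.abs(vals) < 1e-9))
        assert n_null == graph.n_components * n_years
        # augmented with the constraints the form is full rank
        aug = np.vstack([q.toarray(), c.toarray()])
        assert np.linalg.matrix_rank(aug) == q.shape[0]
        assert spacetime_rank(graph, n_years) == q.shape[0] - n_null

    def test_homogeneous_in_tau(self):
        graph, _ = pc.make_grid_lattice(2, 3)
        q1, _ = pc.build_spacetime_precision(graph, 2, 0.4, tau=1.0)
        q3, _ = pc.build_spacetime_precision(graph, 2, 0.4, tau=3.0)
        np.testing.assert_allclose(q3.toarray(), 3.0 * q1.toarray())

    def test_symmetry(self):
        graph, _ = pc.make_grid_lattice(3, 3)
        q, _ = pc.build_spacetime_precision(graph, 4, 0.708)
        assert (q != q.T).nnz == 0


class TestGridLattice:
    @pytest.mark.parametrize("rows,cols,nodes,edges", [
        (2, 2, 4, 4), (1, 5, 5, 4), (3, 3, 9, 12),
    ])
    def test_counts(self, rows, cols, nodes, edges):
        graph, cent = pc.make_grid_lattice(rows, cols)
        assert graph.n_nodes == nodes
        assert graph.n_edges == edges
        assert graph.n_components == 1
        assert len(cent) == nodes

    def test_degree_pattern_3x3(self):
        graph, _ = pc.make_grid_lattice(3, 3)
        deg = graph.degrees()
        assert deg[0] == 2 and deg[4] == 4  # corner vs center

    def test_bad_dimensions_rejected(self):
        with pytest.raises(ValueError):
            pc.make_grid_lattice(0, 3)
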