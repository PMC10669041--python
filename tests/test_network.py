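import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import wetlandbn as w
from wetlandbn.copula import normal_scores
from wetlandbn.errors import ConstantColumnError, SchemaError, StructureError
from wetlandbn.network import (
    NetworkArc,
    NetworkNode,
    NetworkStructure,
    extract_arc_partials,
    implied_correlation_matrix,
)
from wetlandbn.synthetic import MarginSpec, SyntheticSpec
from wetlandbn.validation import determinant_product


class TestStructure:
    def test_default_structure_has_ten_nodes_one_target(self):
        s = w.default_structure()
        assert len(s.nodes) == 10
        assert s.target == "number of species"
        assert s.ordering[-1] == "number of species"

    def test_two_cycle_rejected(self):
        with pytest.raises(StructureError, match="cycle"):
            NetworkStructure(
                (NetworkNode("species", "target"), NetworkNode("salinity", "hydrological")),
                (NetworkArc("species", "salinity"), NetworkArc("salinity", "species")),
            )

    def test_unknown_node_in_arc_rejected(self):
        with pytest.raises(StructureError, match="Water colour"):
            NetworkStructure(
                (NetworkNode("a", "spatial"), NetworkNode("t", "target")),
                (NetworkArc("Water colour", "t"),),
            )

    def test_zero_or_two_targets_rejected(self):
        with pytest.raises(StructureError):
            NetworkStructure((NetworkNode("a", "spatial"),), ())
        with pytest.raises(StructureError):
            NetworkStructure(
                (NetworkNode("a", "target"), NetworkNode("b", "target")), ()
            )

    def test_target_with_outgoing_arc_rejected(self):
        with pytest.raises(StructureError, match="outgoing"):
            NetworkStructure(
                (NetworkNode("t", "target"), NetworkNode("a", "spatial")),
                (NetworkArc("t", "a"),),
            )

    def test_load_structure_round_trip(self, tmp_path):
        s = w.default_structure()
        import json

        path = tmp_path / "s.json"
        path.write_text(json.dumps(s.to_dict()))
        loaded = w.load_structure(path)
        assert loaded.node_names == s.node_names
        assert loaded.arcs == s.arcs

    def test_load_structure_missing_file(self, tmp_path):
        with pytest.raises(SchemaError):
            w.load_structure(tmp_path / "nope.yaml")


class TestPartialCorrelation:
    def test_empty_conditioning_set_is_raw_correlation(self):
        R = pd.DataFrame(
            [[1, 0.3, 0.2], [0.3, 1, 0.5], [0.2, 0.5, 1.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        assert w.partial_correlation(R, "a", "b") == pytest.approx(0.3)

    def test_conditional_independence_construction_gives_zero(self):
        # R[i,j] = R[i,k] * R[j,k] makes i and j independent given k
        rik, rjk = 0.6, 0.4
        R = pd.DataFrame(
            [[1, rik * rjk, rik], [rik * rjk, 1, rjk], [rik, rjk, 1.0]],
            index=list("ijk"),
            columns=list("ijk"),
        )
        assert w.partial_correlation(R, "i", "j", ["k"]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_regression_residual_oracle(self):
        """Partial correlation equals the correlation of regression residuals."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            A = rng.standard_normal((6, 9))
            C = np.corrcoef(A)
            names = list("abcdef")
            R = pd.DataFrame(C, index=names, columns=names)
            given = ["c", "d", "e"]
            # residual oracle on a large sample drawn from C
            L = np.linalg.cholesky(C + 1e-9 * np.eye(6))
            Z = rng.standard_normal((60_000, 6)) @ L.T
            idx = {n: i for i, n in enumerate(names)}
            G = Z[:, [idx[g] for g in given]]
            beta_a, *_ = np.linalg.lstsq(G, Z[:, idx["a"]], rcond=None)
            beta_b, *_ = np.linalg.lstsq(G, Z[:, idx["b"]], rcond=None)
            resid_corr = np.corrcoef(
                Z[:, idx["a"]] - G @ beta_a, Z[:, idx["b"]] - G @ beta_b
            )[0, 1]
            assert w.partial_correlation(R, "a", "b", given) == pytest.approx(
                resid_corr, abs=0.03
            )

    def test_overlapping_sets_rejected(self):
        R = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            w.partial_correlation(R, "a", "b", ["a"])


class TestImpliedMatrix:
    def test_all_zero_partials_give_identity(self, chain_structure):
        R = implied_correlation_matrix(chain_structure, {("a", "b"): 0.0, ("b", "c"): 0.0})
        np.testing.assert_allclose(R.to_numpy(), np.eye(3), atol=1e-14)

    def test_single_arc(self):
        s = NetworkStructure(
            (NetworkNode("a", "spatial"), NetworkNode("t", "target")),
            (NetworkArc("a", "t"),),
        )
        R = implied_correlation_matrix(s, {("a", "t"): 0.45})
        assert R.loc["a", "t"] == pytest.approx(0.45)

    def test_chain_product_rule(self, chain_structure):
        """Zero partial across the chain forces rho_ac = rho_ab * rho_bc."""
        R = implied_correlation_matrix(chain_structure, {("a", "b"): 0.6, ("b", "c"): 0.5})
        assert R.loc["a", "c"] == pytest.approx(0.3, abs=1e-12)
        # sampling oracle
        model = w.GaussianCopulaModel(tuple(R.columns), R.to_numpy())
        u = w.sample_gaussian_copula(model, 100_000, seed=0)
        z = np.column_stack([normal_scores(u[:, j]) for j in range(3)])
        assert np.corrcoef(z[:, 0], z[:, 2])[0, 1] == pytest.approx(0.3, abs=0.02)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_round_trip_arc_partials(self, seed):
        """Re-extracting arc partials from the implied matrix reproduces them."""
        rng = np.random.default_rng(seed)
        s = NetworkStructure(
            (
                NetworkNode("a", "spatial"),
                NetworkNode("b", "anthropic"),
                NetworkNode("c", "hydrological"),
                NetworkNode("t", "target"),
            ),
            (
                NetworkArc("a", "b"),
                NetworkArc("a", "t"),
                NetworkArc("b", "t"),
                NetworkArc("c", "t"),
            ),
        )
        truth = {arc: float(rng.uniform(-0.85, 0.85)) for arc in
                 [("a", "b"), ("a", "t"), ("b", "t"), ("c", "t")]}
        R = implied_correlation_matrix(s, truth)
        assert np.linalg.eigvalsh(R.to_numpy()).min() > 0
        back = extract_arc_partials(R, s)
        for arc, rho in truth.items():
            assert back[arc] == pytest.approx(rho, abs=1e-10)


class TestFit:
    def test_chain_parameter_recovery(self, chain_structure):
        """bn_constrained fit on data from a known chain recovers partials."""
        truth = {("a", "b"): 0.6, ("b", "c"): 0.5}
        R = implied_correlation_matrix(chain_structure, truth)
        margins = {n: MarginSpec("continuous", 0.0, 1.0) for n in "abc"}
        spec = SyntheticSpec(10_000, R, margins, seed=8)
        model = w.fit(w.generate(spec), chain_structure)
        for arc, rho in truth.items():
            assert model.arc_partials[arc] == pytest.approx(rho, abs=0.05)

    def test_independent_columns_give_null_partials(self, chain_structure):
        margins = {n: MarginSpec("continuous", 0.0, 1.0) for n in "abc"}
        spec = SyntheticSpec(
            10_000,
            pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc")),
            margins,
            seed=9,
        )
        model = w.fit(w.generate(spec), chain_structure)
        for rho in model.arc_partials.values():
            assert abs(rho) < 0.05

    def test_saturated_two_nodes_equals_normal_rank_matrix(self):
        s = NetworkStructure(
            (NetworkNode("a", "spatial"), NetworkNode("t", "target")),
            (NetworkArc("a", "t"),),
        )
        margins = {"a": MarginSpec("continuous", 0, 1), "t": MarginSpec("continuous", 0, 1)}
        R = pd.DataFrame([[1, 0.5], [0.5, 1.0]], index=["a", "t"], columns=["a", "t"])
        table = w.generate(SyntheticSpec(200, R, margins, seed=1))
        model = w.fit(table, s, mode="saturated")
        expected = w.normal_rank_corr_matrix(table.data)
        np.testing.assert_allclose(model.copula.R, expected.to_numpy(), atol=1e-12)

    def test_fit_round_trip_through_implied_matrix(self, model22):
        back = extract_arc_partials(model22.copula.as_frame(), model22.structure)
        for arc, rho in model22.arc_partials.items():
            assert back[arc] == pytest.approx(rho, abs=1e-10)

    def test_fitted_determinant_in_unit_interval(self, model22):
        det = np.linalg.det(model22.copula.R)
        assert 0 < det <= 1
        assert det < 1  # dependence present

    def test_sign_recovery_on_default_synthetic_data(self, model22):
        """Arc partials into the target match the conceptual-model signs."""
        target = model22.target
        for driver, expected in [
            ("tourism pressure", -1),
            ("anthropization", -1),
            ("water discharges", -1),
            ("water salinity", -1),
            ("mean water level", -1),
            ("water diversions", +1),
        ]:
            rho = model22.arc_partials[(driver, target)]
            assert np.sign(rho) == expected, (driver, rho)

    def test_saturated_determinant_product_identity(self, table22):
        """For a complete ordering the partial product equals det(R)."""
        names = ["wetland size", "water salinity", "tourism pressure", "number of species"]
        nodes = tuple(
            NetworkNode(n, "target" if n == "number of species" else "spatial")
            for n in names
        )
        arcs = tuple(
            NetworkArc(names[i], names[j]) for j in range(len(names)) for i in range(j)
        )
        s = NetworkStructure(nodes, arcs)
        sub = table22.data[names]
        model = w.fit(w.WetlandTable(sub, [table22.schema_for(n) for n in names]), s,
                      mode="saturated")
        det = np.linalg.det(model.copula.R)
        assert determinant_product(model.arc_partials) == pytest.approx(det, abs=1e-10)

    def test_missing_column_and_constant_column_errors(self, table22):
        with pytest.raises(SchemaError):
            w.fit(
                w.WetlandTable(
                    table22.data[["wetland size", "number of species"]],
                    [table22.schema_for("wetland size"), table22.schema_for("number of species")],
                )
            )
        frame = table22.data.copy()
        frame["water salinity"] = 2
        with pytest.raises(ConstantColumnError, match="water salinity"):
            w.fit(w.WetlandTable(frame, table22.schema))

    def test_too_few_rows_rejected(self, table22):
        small = w.WetlandTable(table22.data.iloc[:4].copy(), table22.schema)
        with pytest.raises(ValueError):
            w.fit(small)

    def test_model_json_round_trip(self, model22, tmp_path):
        path = tmp_path / "model.json"
        model22.to_json(path)
        loaded = w.FittedModel.from_json(path)
        np.testing.assert_allclose(loaded.copula.R, model22.copula.R, atol=1e-12)
        assert loaded.arc_partials.keys() == model22.arc_partials.keys()
        assert loaded.n_wetlands == model22.n_wetlands
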