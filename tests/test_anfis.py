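import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardiofuzz import (
    FuzzyRule,
    ModelSchemaError,
    TrapezoidalMF,
    UncoveredInputError,
    build_default_model,
    firing_strengths,
    load_model,
    normalize_strengths,
    predict,
    predict_batch,
    rule_consequent,
    save_model,
    trapezoid_membership,
)
from cardiofuzz.anfis import model_to_dict, with_coefficients
from oracles import trap, weighted_average_output

#: A point sitting on all three "normal" plateaus of the default partition.
PLATEAU_POINT = (0.45, 0.70, 0.40)


class TestTrapezoid:
    def test_plateau(self):
        mf = TrapezoidalMF(0.1, 0.3, 0.6, 0.8)
        for x in (0.3, 0.45, 0.6):
            assert trapezoid_membership(x, mf) == 1.0

    def test_outside_support(self):
        mf = TrapezoidalMF(0.1, 0.3, 0.6, 0.8)
        for x in (0.0, 0.1, 0.8, 1.0):
            assert trapezoid_membership(x, mf) == 0.0

    def test_rising_edge_midpoint(self):
        mf = TrapezoidalMF(0.2, 0.4, 0.6, 0.8)
        assert trapezoid_membership(0.3, mf) == pytest.approx(0.5)

    def test_degenerate_left_edge_is_step(self):
        mf = TrapezoidalMF(0.3, 0.3, 0.6, 0.8)
        assert trapezoid_membership(0.3, mf) == 1.0  # plateau side
        assert trapezoid_membership(0.29, mf) == 0.0

    def test_degenerate_right_edge_is_step(self):
        mf = TrapezoidalMF(0.1, 0.3, 0.6, 0.6)
        assert trapezoid_membership(0.6, mf) == 1.0
        assert trapezoid_membership(0.61, mf) == 0.0

    def test_unordered_breakpoints_rejected(self):
        with pytest.raises(ValueError, match="a<=b<=c<=d"):
            TrapezoidalMF(0.5, 0.3, 0.6, 0.8)

    def test_non_finite_input(self):
        with pytest.raises(ValueError):
            trapezoid_membership(float("nan"), TrapezoidalMF(0, 0.2, 0.5, 0.7))

    @given(st.floats(min_value=0, max_value=1))
    def test_matches_oracle(self, x):
        mf = TrapezoidalMF(0.1, 0.25, 0.55, 0.9)
        assert trapezoid_membership(x, mf) == pytest.approx(trap(x, 0.1, 0.25, 0.55, 0.9))


class TestBuildDefaultModel:
    def test_rule_count(self, default_model):
        assert len(default_model.rules) == 27

    def test_antecedents_unique_and_exhaustive(self, default_model):
        ants = {r.antecedent for r in default_model.rules}
        assert len(ants) == 27
        assert all(i in (1, 2, 3) for a in ants for i in a)

    def test_normal_plateau_from_band_edges(self, default_model):
        normal = default_model.input_mfs["k"][1]
        assert normal.b == pytest.approx(0.25, abs=1e-12)  # 0.20 + s
        assert normal.c == pytest.approx(0.55, abs=1e-12)  # 0.60 - s

    @pytest.mark.parametrize("var", ["ntprobnp", "na", "k"])
    def test_ruspini_partition_sums_to_one(self, default_model, var):
        xs = np.linspace(0, 1, 200)
        total = sum(trapezoid_membership(xs, mf) for mf in default_model.input_mfs[var])
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_na_upper_edge_at_domain_limit(self, default_model):
        # band upper edge 1.00: the ramp is shortened instead of leaving [0, 1]
        high = default_model.input_mfs["na"][2]
        assert high.d == 1.0

    def test_bad_band_edges_rejected(self):
        with pytest.raises(ValueError, match="band edges"):
            build_default_model(band_edges={"k": (0.7, 0.3)})
        with pytest.raises(ValueError, match="shoulder"):
            build_default_model(band_edges={"k": (0.40, 0.42)})

    def test_initial_coefficients(self, default_model):
        for r in default_model.rules:
            assert r.coefficients == (1 / 3, 1 / 3, 1 / 3)
            assert r.bias is None


class TestFiringStrengths:
    def test_plateau_point_fires_single_rule(self, default_model):
        w = firing_strengths(PLATEAU_POINT, default_model)
        idx = [r.antecedent for r in default_model.rules].index((2, 2, 2))
        assert w[idx] == 1.0
        assert np.count_nonzero(w) == 1

    def test_matches_product_oracle(self, reference_model, rng):
        from oracles import rule_strength

        for _ in range(100):
            x = rng.uniform(0, 1, 3)
            w = firing_strengths(x, reference_model)
            expected = [rule_strength(x, reference_model, r) for r in reference_model.rules]
            assert np.allclose(w, expected, atol=1e-14)

    def test_min_tnorm(self, rng):
        model = build_default_model(tnorm="min")
        from oracles import rule_strength

        for _ in range(50):
            x = rng.uniform(0, 1, 3)
            w = firing_strengths(x, model)
            expected = [rule_strength(x, model, r) for r in model.rules]
            assert np.allclose(w, expected, atol=1e-14)


class TestNormalizeStrengths:
    def test_single_active_rule(self):
        w = np.zeros(27)
        w[0] = 1.0
        assert np.array_equal(normalize_strengths(w), w)

    def test_symmetry(self):
        wbar = normalize_strengths(np.ones(27))
        assert np.allclose(wbar, 1 / 27)

    def test_matches_division_oracle(self, rng):
        w = rng.uniform(0.01, 5.0, 27)
        assert np.allclose(normalize_strengths(w), w / w.sum(), atol=1e-15)

    def test_all_zero_raises(self):
        with pytest.raises(UncoveredInputError):
            normalize_strengths(np.zeros(27))

    def test_sums_to_one(self, rng):
        for _ in range(20):
            w = rng.uniform(0, 1, 27)
            assert normalize_strengths(w).sum() == pytest.approx(1.0, abs=1e-9)


class TestRuleConsequent:
    def test_zero_coefficients(self):
        rule = FuzzyRule((1, 1, 1), (0.0, 0.0, 0.0))
        assert rule_consequent((0.3, 0.9, 0.1), rule) == 0.0

    def test_projection(self):
        rule = FuzzyRule((1, 1, 1), (1.0, 0.0, 0.0))
        assert rule_consequent((0.3, 0.9, 0.1), rule) == pytest.approx(0.3)

    def test_matches_dot_oracle(self, rng):
        for _ in range(50):
            c = rng.normal(size=3)
            x = rng.uniform(0, 1, 3)
            rule = FuzzyRule((2, 3, 1), tuple(c), bias=0.25)
            expected = c[0] * x[0] + c[1] * x[1] + c[2] * x[2] + 0.25
            assert rule_consequent(x, rule) == pytest.approx(expected, abs=1e-14)


class TestPredict:
    def test_constant_consequents_give_constant_output(self, rng):
        model = build_default_model()
        # every rule returns the same value for any x only via bias-free equal coeffs
        model = with_coefficients(model, np.full((27, 3), 0.0), bias=np.full(27, 0.42))
        for _ in range(10):
            p = predict(rng.uniform(0, 1, 3), model)
            assert p.y_norm == pytest.approx(0.42, abs=1e-12)

    def test_single_rule_plateau(self, reference_model):
        p = predict(PLATEAU_POINT, reference_model)
        rule = next(r for r in reference_model.rules if r.antecedent == (2, 2, 2))
        assert p.y_norm == pytest.approx(rule_consequent(PLATEAU_POINT, rule), abs=1e-14)

    def test_matches_closed_form_oracle(self, reference_model, rng):
        for _ in range(200):
            x = rng.uniform(0, 1, 3)
            got = predict(x, reference_model).y_norm
            assert got == pytest.approx(weighted_average_output(x, reference_model), abs=1e-10)

    def test_activations_sum_to_one(self, reference_model, rng):
        for _ in range(50):
            p = predict(rng.uniform(0, 1, 3), reference_model)
            assert p.rule_activations.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rule_permutation_invariance(self, reference_model, rng):
        shuffled = reference_model.copy()
        order = rng.permutation(27)
        shuffled.rules = [reference_model.rules[i] for i in order]
        for _ in range(25):
            x = rng.uniform(0, 1, 3)
            assert predict(x, shuffled).y_norm == pytest.approx(
                predict(x, reference_model).y_norm, abs=1e-12
            )

    def test_continuity_lipschitz(self, reference_model):
        # finite differences along each axis stay below the coefficient/ramp bound
        cmax = np.abs(reference_model.coefficient_matrix).sum(axis=1).max()
        slope = max(
            1.0 / (mf.b - mf.a) if mf.b > mf.a else 0.0
            for mfs in reference_model.input_mfs.values()
            for mf in mfs
        )
        L = 3 * cmax * (1 + slope)
        grid = np.linspace(0, 1, 101)
        h = grid[1] - grid[0]
        for axis in range(3):
            x = np.full((101, 3), 0.5)
            x[:, axis] = grid
            y, _ = predict_batch(reference_model, x)
            assert np.max(np.abs(np.diff(y))) <= L * h + 1e-12

    def test_product_and_min_agree_on_plateau(self, rng):
        coeffs = rng.uniform(0, 1, size=(27, 3))
        prod_model = with_coefficients(build_default_model(tnorm="product"), coeffs)
        min_model = with_coefficients(build_default_model(tnorm="min"), coeffs)
        assert predict(PLATEAU_POINT, prod_model).y_norm == pytest.approx(
            predict(PLATEAU_POINT, min_model).y_norm, abs=1e-14
        )

    def test_uncovered_input_propagates(self, default_model):
        broken = default_model.copy()
        gap = TrapezoidalMF(0.0, 0.0, 0.1, 0.2)
        broken.input_mfs["k"] = (gap, gap, gap)  # mutation bypasses validation
        with pytest.raises(UncoveredInputError):
            predict((0.5, 0.5, 0.9), broken)

    def test_physical_output(self, default_model):
        p = predict(PLATEAU_POINT, default_model)
        lo, hi = default_model.output_params.vmin, default_model.output_params.vmax
        assert p.y_physical == pytest.approx(lo + p.y_norm * (hi - lo))


class TestSerialization:
    def test_round_trip_predicts_identically(self, reference_model, tmp_path, rng):
        path = tmp_path / "model.json"
        save_model(reference_model, path)
        loaded = load_model(path)
        for _ in range(50):
            x = rng.uniform(0, 1, 3)
            assert predict(x, loaded).y_norm == predict(x, reference_model).y_norm

    def test_missing_rule_rejected(self, reference_model, tmp_path):
        payload = model_to_dict(reference_model)
        payload["rules"] = payload["rules"][:26]
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelSchemaError, match="27"):
            load_model(path)

    def test_unordered_breakpoints_rejected(self, reference_model, tmp_path):
        payload = model_to_dict(reference_model)
        payload["inputs"][0]["mfs"][0]["a"] = 0.9
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="a<=b<=c<=d"):
            load_model(path)

    def test_wrong_schema_version(self, reference_model, tmp_path):
        payload = model_to_dict(reference_model)
        payload["schema_version"] = 99
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelSchemaError, match="schema_version"):
            load_model(path)

    def test_invalid_json(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ModelSchemaError, match="JSON"):
            load_model(path)
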