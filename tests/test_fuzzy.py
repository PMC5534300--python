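import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from traceret.core import TraceElement
from traceret.fuzzy import (
    FuzzyConfig,
    GaussianMF,
    LinearIndexCoefficients,
    RuleBase,
    RuleWeights,
    build_rule_base,
    calibrate_sigma,
    fuzzify_inputs,
    infer_retention,
    linear_retention_index,
    membership,
    sugeno0_retention,
)

ZN = TraceElement.Zn

# Consequents implied by the default 0.5 / 0.2 / 0.3 weight scheme,
# recomputed by hand: s(w)*0.5 + s(b)*0.2 - s(u)*0.3, s(1)=+1, s(0)=-1.
EXPECTED_CONSEQUENTS = {
    (0, 0, 0): -0.4,
    (0, 0, 1): -1.0,
    (0, 1, 0): 0.0,
    (0, 1, 1): -0.6,
    (1, 0, 0): 0.6,
    (1, 0, 1): 0.0,
    (1, 1, 0): 1.0,
    (1, 1, 1): 0.4,
}

EXPECTED_LABELS = {
    (0, 0, 0): "Moderately low",
    (0, 0, 1): "Minimal",
    (0, 1, 0): "Equilibrium state",
    (0, 1, 1): "Low",
    (1, 0, 0): "High",
    (1, 0, 1): "Equilibrium state",
    (1, 1, 0): "Maximal",
    (1, 1, 1): "Moderately high",
}


class TestMembership:
    def test_peak_at_center(self):
        assert membership(0.5, GaussianMF(0.5, 0.1)) == 1.0

    def test_one_sigma(self):
        assert membership(0.6, GaussianMF(0.5, 0.1)) == pytest.approx(math.exp(-0.5))

    def test_three_sigma(self):
        assert membership(0.2, GaussianMF(0.5, 0.1)) == pytest.approx(math.exp(-4.5))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            GaussianMF(0.5, 0.0)

    @given(c=st.floats(-5, 5), s=st.floats(0.01, 5), d=st.floats(0, 10))
    def test_symmetry(self, c, s, d):
        mf = GaussianMF(c, s)
        assert membership(c + d, mf) == pytest.approx(membership(c - d, mf), rel=1e-12)


class TestRuleBase:
    def test_eight_rules(self, rulebase):
        assert len(rulebase) == 8

    @pytest.mark.parametrize("antecedent,consequent", sorted(EXPECTED_CONSEQUENTS.items()))
    def test_default_consequents(self, rulebase, antecedent, consequent):
        assert rulebase.consequent(antecedent) == pytest.approx(consequent)

    @pytest.mark.parametrize("antecedent,label", sorted(EXPECTED_LABELS.items()))
    def test_linguistic_labels(self, rulebase, antecedent, label):
        rule = next(r for r in rulebase if r.antecedent == antecedent)
        assert rule.label == label

    def test_consequents_sum_to_zero(self, rulebase):
        assert sum(r.consequent for r in rulebase) == pytest.approx(0.0, abs=1e-12)

    def test_complement_antisymmetry(self, rulebase):
        for r in rulebase:
            comp = tuple(1 - a for a in r.antecedent)
            assert rulebase.consequent(comp) == pytest.approx(-r.consequent)

    def test_custom_weights(self):
        rb = build_rule_base(RuleWeights(w_water=0.4, w_blood=0.4, w_urine=0.2))
        assert rb.consequent((1, 1, 1)) == pytest.approx(0.6)
        assert rb.consequent((0, 0, 0)) == pytest.approx(-0.6)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            RuleWeights(w_water=-0.5)

    def test_file_roundtrip(self, rulebase, tmp_path):
        path = tmp_path / "rules.yaml"
        rulebase.to_file(path)
        loaded = RuleBase.from_file(path)
        for r in rulebase:
            assert loaded.consequent(r.antecedent) == r.consequent


class TestFuzzifyInputs:
    def test_membership_one_at_low_center(self, centers):
        mu = fuzzify_inputs(ZN, 0.016, 0.7, 0.3, centers)
        assert mu["water"][0] == 1.0

    def test_symmetric_at_midpoint(self, centers):
        mu = fuzzify_inputs(ZN, 0.019, 0.7, 0.3, centers)
        assert mu["water"][0] == pytest.approx(mu["water"][1], rel=1e-12)

    def test_zero_urine_prefers_low(self, centers):
        mu = fuzzify_inputs(ZN, 0.019, 0.7, 0.0, centers)
        assert mu["urine"][0] > mu["urine"][1]

    def test_negative_concentration_rejected(self, centers):
        with pytest.raises(ValueError):
            fuzzify_inputs(ZN, -0.01, 0.7, 0.3, centers)

    def test_unknown_element_rejected(self, centers):
        with pytest.raises(KeyError):
            fuzzify_inputs("Hg", 0.02, 0.7, 0.3, centers)


def _midpoints(centers, element):
    return tuple((sum(centers.pair(element, comp)) / 2.0) for comp in ("water", "serum", "urine"))


ELEMENTS = list(TraceElement)


class TestInferRetention:
    @pytest.mark.parametrize("element", ELEMENTS, ids=[e.value for e in ELEMENTS])
    def test_midpoint_inputs_give_zero(self, element, centers, rulebase):
        w, s, u = _midpoints(centers, element)
        r = infer_retention(element, w, s, u, centers, rulebase, FuzzyConfig())
        assert r.value == pytest.approx(0.0, abs=1e-12)

    def test_output_bounds(self, centers, rulebase, rng):
        for _ in range(200):
            w = rng.uniform(0, 0.06)
            s = rng.uniform(0, 1.5)
            u = rng.uniform(0, 1.0)
            for defuzz in ("singleton_height", "centroid_gaussian"):
                r = infer_retention(ZN, w, s, u, centers, rulebase, FuzzyConfig(defuzz=defuzz))
                assert -1.0 <= r.value <= 1.0

    def test_continuity_across_centres(self, centers, rulebase):
        # Dense sweep across the water centres: successive outputs move
        # by less than a bound proportional to the step.
        grid = np.linspace(0.005, 0.035, 601)
        vals = [
            infer_retention(ZN, w, 0.7, 0.3, centers, rulebase, FuzzyConfig()).value for w in grid
        ]
        diffs = np.abs(np.diff(vals))
        assert diffs.max() < 0.02

    def test_antisymmetry_mirrored_inputs(self, centers, rulebase, rng):
        cfg = FuzzyConfig()
        mids = _midpoints(centers, ZN)
        for _ in range(100):
            w = rng.uniform(0.01, 0.028)
            s = rng.uniform(0.5, 0.95)
            u = rng.uniform(0.1, 0.6)
            mirrored = [2 * m - x for m, x in zip(mids, (w, s, u))]
            r = infer_retention(ZN, w, s, u, centers, rulebase, cfg)
            rm = infer_retention(ZN, *mirrored, centers, rulebase, cfg)
            assert rm.value == pytest.approx(-r.value, abs=1e-9)

    def test_extreme_inputs_do_not_underflow(self, centers, rulebase):
        # Far outside all centres every raw activation underflows in
        # floats; the log-space path must still produce a valid output.
        r = infer_retention(ZN, 10.0, 50.0, 0.0, centers, rulebase, FuzzyConfig(sigma_scale=0.2))
        assert -1.0 <= r.value <= 1.0

    def test_min_and_operator_supported(self, centers, rulebase):
        r = infer_retention(ZN, 0.04, 0.892, 0.433, centers, rulebase, FuzzyConfig(and_operator="min"))
        assert -1.0 <= r.value <= 1.0


class TestSugenoEquivalence:
    def test_identical_to_singleton_mamdani_randomized(self, centers, rulebase, rng):
        cfg = FuzzyConfig(defuzz="singleton_height")
        for _ in range(1000):
            w = rng.uniform(0, 0.06)
            s = rng.uniform(0, 1.5)
            u = rng.uniform(0, 1.0)
            a = infer_retention(ZN, w, s, u, centers, rulebase, cfg).value
            b = sugeno0_retention(ZN, w, s, u, centers, rulebase, cfg).value
            assert abs(a - b) <= 1e-12

    @pytest.mark.parametrize("element", ELEMENTS, ids=[e.value for e in ELEMENTS])
    def test_midpoints_give_zero(self, element, centers, rulebase):
        w, s, u = _midpoints(centers, element)
        r = sugeno0_retention(element, w, s, u, centers, rulebase)
        assert r.value == pytest.approx(0.0, abs=1e-12)


class TestLinearRetentionIndex:
    def test_intercept(self):
        assert linear_retention_index(0, 0, 0) == pytest.approx(0.327)

    def test_all_ones(self):
        assert linear_retention_index(1, 1, 1) == pytest.approx(0.707)

    def test_urine_coefficient(self):
        base = linear_retention_index(0, 0, 0)
        assert linear_retention_index(0, 0, 1) - base == pytest.approx(-0.33)

    @given(
        rw=st.floats(-3, 3),
        rb=st.floats(-3, 3),
        ru=st.floats(-3, 3),
        d=st.floats(0.1, 2),
    )
    def test_gradient_everywhere(self, rw, rb, ru, d):
        f = linear_retention_index
        assert (f(rw + d, rb, ru) - f(rw, rb, ru)) / d == pytest.approx(0.52, rel=1e-9)
        assert (f(rw, rb + d, ru) - f(rw, rb, ru)) / d == pytest.approx(0.19, rel=1e-9)
        assert (f(rw, rb, ru + d) - f(rw, rb, ru)) / d == pytest.approx(-0.33, rel=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            linear_retention_index(float("nan"), 0, 0)

    def test_custom_coefficients(self):
        coef = LinearIndexCoefficients(intercept=0.0, coef_water=1.0, coef_blood=0.0, coef_urine=0.0)
        assert linear_retention_index(2.0, 5.0, 7.0, coef) == pytest.approx(2.0)


WORKED_EXAMPLES = [
    ((ZN, 0.04, 0.892, 0.433), 0.407),
    ((ZN, 0.04, 0.867, 0.0), 0.708),
    ((ZN, 0.017, 0.778, 0.527), -0.463),
]


class TestCalibrateSigma:
    def test_reference_cases_fit_within_tolerance(self, centers, rulebase):
        cfg, residuals = calibrate_sigma(
            WORKED_EXAMPLES,
            FuzzyConfig(defuzz="centroid_gaussian", output_sigma=0.15),
            centers=centers,
            rulebase=rulebase,
        )
        assert len(residuals) == 3
        assert all(abs(r) <= 0.05 for r in residuals)
        assert cfg.sigma_scale > 0

    def test_exact_match_at_unit_scale_returns_one(self, centers, rulebase):
        template = FuzzyConfig()
        target = infer_retention(ZN, 0.02, 0.7, 0.3, centers, rulebase, template).value
        cfg, residuals = calibrate_sigma(
            [((ZN, 0.02, 0.7, 0.3), target)], template, centers=centers, rulebase=rulebase
        )
        assert cfg.sigma_scale == pytest.approx(1.0, abs=1e-3)
        assert abs(residuals[0]) < 1e-6

    def test_degenerate_bounds(self, centers, rulebase):
        cfg, _ = calibrate_sigma(
            WORKED_EXAMPLES, FuzzyConfig(), centers=centers, rulebase=rulebase, bounds=(2.5, 2.5)
        )
        assert cfg.sigma_scale == 2.5

    def test_empty_examples_rejected(self):
        with pytest.raises(ValueError):
            calibrate_sigma([], FuzzyConfig())


class TestFuzzyConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sigma_scale=0.0),
            dict(and_operator="sum"),
            dict(defuzz="bisector"),
            dict(engine="anfis"),
            dict(output_sigma=-1),
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FuzzyConfig(**kwargs)

    def test_dict_roundtrip(self):
        cfg = FuzzyConfig(sigma_scale=0.9, defuzz="centroid_gaussian")
        assert FuzzyConfig.from_dict(cfg.to_dict()) == cfg
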