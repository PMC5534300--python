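"""Fuzzy retention assessment.

Gaussian fuzzification of water/serum/urine concentrations against the
packaged membership centres, a weighted 8-rule base over the three
binary linguistic levels, Mamdani and zero-order Takagi-Sugeno
inference, the linear excess-rate retention index, and deterministic
calibration of the global membership-width scale against reference
input/output pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml

from traceret.core import (
    Compartment,
    COMPARTMENTS,
    MembershipCenters,
    RetentionResult,
    TraceElement,
    label_retention,
)

__all__ = [
    "FuzzyConfig",
    "FuzzyRule",
    "GaussianMF",
    "LinearIndexCoefficients",
    "RuleBase",
    "RuleWeights",
    "build_rule_base",
    "calibrate_sigma",
    "fuzzify_inputs",
    "infer_retention",
    "linear_retention_index",
    "membership",
    "sugeno0_retention",
]


@dataclass(frozen=True)
class GaussianMF:
    """Gaussian membership function: exp(-(x - center)² / (2 sigma²))."""

    center: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def __call__(self, x: float) -> float:
        return membership(x, self)

    def log_membership(self, x: float) -> float:
        """Log-membership; avoids underflow far from the centre."""
        z = (x - self.center) / self.sigma
        return -0.5 * z * z


def membership(x: float, mf: GaussianMF) -> float:
    """Degree of membership of x in a Gaussian fuzzy set; 1 iff x is at
    the centre, symmetric about it, strictly positive in exact
    arithmetic."""
    if not (mf.sigma > 0):
        raise ValueError(f"sigma must be positive, got {mf.sigma}")
    return math.exp(mf.log_membership(x))


@dataclass(frozen=True)
class RuleWeights:
    """Per-compartment weights of the rule consequent arithmetic.

    Defaults encode the 5 : 2 : 3 water : blood : urine ratio.
    """

    w_water: float = 0.5
    w_blood: float = 0.2
    w_urine: float = 0.3

    def __post_init__(self) -> None:
        for name in ("w_water", "w_blood", "w_urine"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")


Antecedent = tuple[int, int, int]  # (water, serum, urine), each 0=low / 1=high


@dataclass(frozen=True)
class FuzzyRule:
    antecedent: Antecedent
    consequent: float
    label: str


class RuleBase:
    """Exactly eight rules, one per antecedent combination."""

    def __init__(self, rules: Sequence[FuzzyRule]):
        if len(rules) != 8:
            raise ValueError(f"rule base must contain 8 rules, got {len(rules)}")
        self._by_antecedent = {r.antecedent: r for r in rules}
        if len(self._by_antecedent) != 8:
            raise ValueError("duplicate antecedents in rule base")
        self.rules = tuple(sorted(rules, key=lambda r: r.antecedent))

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def consequent(self, antecedent: Antecedent) -> float:
        return self._by_antecedent[antecedent].consequent

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "rules": [
                {
                    "water": r.antecedent[0],
                    "serum": r.antecedent[1],
                    "urine": r.antecedent[2],
                    "consequent": r.consequent,
                    "label": r.label,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RuleBase":
        rules = [
            FuzzyRule(
                antecedent=(int(r["water"]), int(r["serum"]), int(r["urine"])),
                consequent=float(r["consequent"]),
                label=str(r["label"]),
            )
            for r in payload["rules"]
        ]
        return cls(rules)

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "RuleBase":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_rule_base(weights: RuleWeights = RuleWeights()) -> RuleBase:
    """Construct the 8-rule base from the compartment weight scheme.

    The consequent for antecedent (a_w, a_b, a_u) is
    s(a_w)·w_water + s(a_b)·w_blood - s(a_u)·w_urine with s(1)=+1 and
    s(0)=-1: high intake and high blood level push retention up, high
    urinary excretion pushes it down.
    """
    sign = {0: -1.0, 1: 1.0}
    rules = []
    for aw in (0, 1):
        for ab in (0, 1):
            for au in (0, 1):
                c = sign[aw] * weights.w_water + sign[ab] * weights.w_blood - sign[au] * weights.w_urine
                c = round(c, 12)
                rules.append(FuzzyRule((aw, ab, au), c, label_retention(max(-1.0, min(1.0, c)))))
    return RuleBase(rules)


@dataclass(frozen=True)
class FuzzyConfig:
    """Engine settings left open by the rule/centre constants.

    Membership widths are sigma = sigma_scale · (high_center -
    low_center) / 2 per variable; a single global scale keeps
    calibration to one free parameter.  ``output_sigma`` is the width of
    the output-level Gaussians used by centroid defuzzification.
    """

    sigma_scale: float = 1.0
    and_operator: Literal["product", "min"] = "product"
    defuzz: Literal["singleton_height", "centroid_gaussian"] = "singleton_height"
    engine: Literal["mamdani", "sugeno0"] = "mamdani"
    output_sigma: float = 0.15

    def __post_init__(self) -> None:
        if not (self.sigma_scale > 0):
            raise ValueError(f"sigma_scale must be positive, got {self.sigma_scale}")
        if self.and_operator not in ("product", "min"):
            raise ValueError(f"unknown and_operator {self.and_operator!r}")
        if self.defuzz not in ("singleton_height", "centroid_gaussian"):
            raise ValueError(f"unknown defuzz {self.defuzz!r}")
        if self.engine not in ("mamdani", "sugeno0"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if not (self.output_sigma > 0):
            raise ValueError(f"output_sigma must be positive, got {self.output_sigma}")

    def to_dict(self) -> dict:
        return {
            "sigma_scale": self.sigma_scale,
            "and_operator": self.and_operator,
            "defuzz": self.defuzz,
            "engine": self.engine,
            "output_sigma": self.output_sigma,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FuzzyConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in payload.items() if k in known})


@dataclass(frozen=True)
class LinearIndexCoefficients:
    """Coefficients of the linear excess-rate retention regression."""

    intercept: float = 0.327
    coef_water: float = 0.52
    coef_blood: float = 0.19
    coef_urine: float = -0.33


def linear_retention_index(
    r_water: float,
    r_blood: float,
    r_urine: float,
    coef: LinearIndexCoefficients = LinearIndexCoefficients(),
) -> float:
    """Linear retention index from the three excess-rate indices."""
    for name, v in (("r_water", r_water), ("r_blood", r_blood), ("r_urine", r_urine)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    return coef.intercept + coef.coef_water * r_water + coef.coef_blood * r_blood + coef.coef_urine * r_urine


def input_mfs(
    element: TraceElement,
    centers: MembershipCenters,
    config: FuzzyConfig,
) -> dict[Compartment, tuple[GaussianMF, GaussianMF]]:
    """The (low, high) membership function pair per compartment, with
    sigma = sigma_scale · (high - low) / 2."""
    element = TraceElement.from_code(element)
    out = {}
    for comp in COMPARTMENTS:
        lo, hi = centers.pair(element, comp)
        sigma = config.sigma_scale * (hi - lo) / 2.0
        out[comp] = (GaussianMF(lo, sigma), GaussianMF(hi, sigma))
    return out


def fuzzify_inputs(
    element: TraceElement,
    c_water: float,
    c_serum: float,
    c_urine: float,
    centers: MembershipCenters,
    config: FuzzyConfig = FuzzyConfig(),
) -> dict[Compartment, tuple[float, float]]:
    """Degrees of membership (low, high) per compartment for one
    subject's three concentrations."""
    mfs = input_mfs(element, centers, config)
    values = {"water": c_water, "serum": c_serum, "urine": c_urine}
    for comp, v in values.items():
        if v < 0:
            raise ValueError(f"{comp} concentration must be non-negative, got {v}")
    return {
        comp: (membership(values[comp], mfs[comp][0]), membership(values[comp], mfs[comp][1]))
        for comp in COMPARTMENTS
    }


def _log_activations(
    element: TraceElement,
    values: dict[Compartment, float],
    centers: MembershipCenters,
    rulebase: RuleBase,
    config: FuzzyConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-rule log-activation and consequent arrays, in rule order.

    Log-space keeps extreme inputs well-defined: Gaussian memberships
    are strictly positive in exact arithmetic but underflow in floats.
    """
    mfs = input_mfs(element, centers, config)
    logmu = {
        comp: (mfs[comp][0].log_membership(values[comp]), mfs[comp][1].log_membership(values[comp]))
        for comp in COMPARTMENTS
    }
    log_acts = np.empty(len(rulebase))
    consequents = np.empty(len(rulebase))
    for i, rule in enumerate(rulebase):
        aw, ab, au = rule.antecedent
        parts = (logmu["water"][aw], logmu["serum"][ab], logmu["urine"][au])
        log_acts[i] = sum(parts) if config.and_operator == "product" else min(parts)
        consequents[i] = rule.consequent
    return log_acts, consequents


def _defuzz_singleton(log_acts: np.ndarray, consequents: np.ndarray) -> float:
    # Shift in log-space: the weighted mean is invariant and the
    # strongest rule never underflows.
    acts = np.exp(log_acts - log_acts.max())
    total = acts.sum()
    assert total > 0, "rule activations vanished despite log-space guard"
    return float(np.dot(acts, consequents) / total)


_CENTROID_GRID = np.linspace(-1.5, 1.5, 3001)


def _defuzz_centroid(log_acts: np.ndarray, consequents: np.ndarray, output_sigma: float) -> float:
    # Mamdani with Gaussian output sets: min-implication (clipping),
    # max-aggregation, centroid of the aggregated set.
    acts = np.exp(np.maximum(log_acts, -745.0))
    if acts.max() < 1e-12:  # all clipped sets numerically flat: renormalize heights
        acts = np.exp(log_acts - log_acts.max())
    y = _CENTROID_GRID
    agg = np.zeros_like(y)
    for act, c in zip(acts, consequents):
        out_mf = np.exp(-((y - c) ** 2) / (2.0 * output_sigma**2))
        np.maximum(agg, np.minimum(act, out_mf), out=agg)
    total = agg.sum()
    assert total > 0, "aggregated output set vanished"
    return float((y * agg).sum() / total)


def infer_retention(
    element: TraceElement,
    c_water: float,
    c_serum: float,
    c_urine: float,
    centers: MembershipCenters,
    rulebase: RuleBase,
    config: FuzzyConfig = FuzzyConfig(),
) -> RetentionResult:
    """Mamdani retention inference for one subject and element.

    With ``defuzz='singleton_height'`` the crisp output is the
    activation-weighted average of the rule consequents (identical to
    zero-order Takagi-Sugeno).  With ``defuzz='centroid_gaussian'`` the
    output is the centroid of the max-aggregated, min-clipped Gaussian
    output sets centred at the consequents.
    """
    for name, v in (("c_water", c_water), ("c_serum", c_serum), ("c_urine", c_urine)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    values: dict[Compartment, float] = {"water": c_water, "serum": c_serum, "urine": c_urine}
    log_acts, consequents = _log_activations(
        TraceElement.from_code(element), values, centers, rulebase, config
    )
    if config.defuzz == "singleton_height":
        value = _defuzz_singleton(log_acts, consequents)
    else:
        value = _defuzz_centroid(log_acts, consequents, config.output_sigma)
    value = max(-1.0, min(1.0, value))  # numeric round-off guard only
    return RetentionResult(value=value, label=label_retention(value))


def sugeno0_retention(
    element: TraceElement,
    c_water: float,
    c_serum: float,
    c_urine: float,
    centers: MembershipCenters,
    rulebase: RuleBase,
    config: FuzzyConfig = FuzzyConfig(),
) -> RetentionResult:
    """Zero-order Takagi-Sugeno inference: activation-weighted average
    of the constant rule consequents.

    Algebraically identical to :func:`infer_retention` with
    singleton-height defuzzification.
    """
    cfg = replace(config, defuzz="singleton_height", engine="sugeno0")
    return infer_retention(element, c_water, c_serum, c_urine, centers, rulebase, cfg)


def calibrate_sigma(
    worked_examples: Iterable[tuple[tuple, float]],
    config_template: FuzzyConfig = FuzzyConfig(defuzz="centroid_gaussian"),
    centers: MembershipCenters | None = None,
    rulebase: RuleBase | None = None,
    bounds: tuple[float, float] = (0.1, 10.0),
    coarse_points: int = 199,
) -> tuple[FuzzyConfig, list[float]]:
    """Fit the global membership-width scale to reference outputs.

    ``worked_examples`` is a sequence of ((element, c_water, c_serum,
    c_urine), target_value) pairs.  A deterministic coarse grid scan
    over ``bounds`` brackets the optimum, followed by golden-section
    refinement; the loss is the sum of squared output residuals.
    Returns the calibrated config and the per-example residuals.
    """
    examples = list(worked_examples)
    if not examples:
        raise ValueError("at least one worked example is required")
    lo, hi = bounds
    if not (0 < lo <= hi):
        raise ValueError(f"invalid bounds {bounds}")
    centers = centers or MembershipCenters.default()
    rulebase = rulebase or build_rule_base()

    def residuals(kappa: float) -> list[float]:
        cfg = replace(config_template, sigma_scale=kappa)
        out = []
        for (element, cw, cs, cu), target in examples:
            r = infer_retention(element, cw, cs, cu, centers, rulebase, cfg)
            out.append(r.value - target)
        return out

    def loss(kappa: float) -> float:
        return sum(r * r for r in residuals(kappa))

    if hi == lo:
        best = lo
    else:
        grid = np.linspace(lo, hi, coarse_points)
        losses = [loss(k) for k in grid]
        i = int(np.argmin(losses))
        if losses[i] == 0.0:
            best = float(grid[i])
        else:
            a = float(grid[max(i - 1, 0)])
            b = float(grid[min(i + 1, len(grid) - 1)])
            best = _golden_section(loss, a, b)
            if loss(float(grid[i])) < loss(best):
                best = float(grid[i])
    cfg = replace(config_template, sigma_scale=float(best))
    return cfg, residuals(best)


def _golden_section(f, a: float, b: float, tol: float = 1e-6, max_iter: int = 200) -> float:
    """Deterministic golden-section minimizer on [a, b]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0
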