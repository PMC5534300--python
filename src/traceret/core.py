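"""Domain types, anthropometry, excess-rate indices, and packaged
membership-centre constants shared by all other modules.

Concentrations are mg/l throughout; heights cm, weights kg, daily
diuresis ml, body surface area m².
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Optional

import yaml

__all__ = [
    "Compartment",
    "COMPARTMENTS",
    "MembershipCenters",
    "RETENTION_ANCHORS",
    "RetentionResult",
    "SubjectRecord",
    "TraceElement",
    "body_surface_area",
    "excess_rate_index",
    "label_retention",
]


class TraceElement(enum.Enum):
    """The six trace elements the model covers."""

    Zn = "Zn"
    Cu = "Cu"
    Fe = "Fe"
    Pb = "Pb"
    Cr = "Cr"
    Sr = "Sr"

    @classmethod
    def from_code(cls, code: "str | TraceElement") -> "TraceElement":
        """Total lookup by symbol, case-insensitive on the first letter."""
        if isinstance(code, cls):
            return code
        norm = str(code).strip().capitalize()
        try:
            return cls(norm)
        except ValueError:
            valid = ", ".join(e.value for e in cls)
            raise KeyError(f"unknown trace element {code!r}; expected one of {valid}") from None


Compartment = Literal["water", "serum", "urine"]
COMPARTMENTS: tuple[Compartment, ...] = ("water", "serum", "urine")


def body_surface_area(height: float, weight: float) -> float:
    """Body surface area (m²) from height (cm) and weight (kg).

    Mosteller form: sqrt(height * weight / 3600).  Strictly increasing
    in both arguments.
    """
    if not (height > 0):
        raise ValueError(f"height must be positive, got {height}")
    if not (weight > 0):
        raise ValueError(f"weight must be positive, got {weight}")
    return math.sqrt(height * weight / 3600.0)


def excess_rate_index(
    value: float,
    series_median: float,
    mode: Literal["ratio", "relative"] = "ratio",
) -> float:
    """Dimensionless excess-rate index of a concentration against the
    median of its measurement series.

    ``ratio`` (default) returns value / median, equal to 1 at the median.
    ``relative`` returns (value - median) / median, equal to 0 at the
    median.
    """
    if not (series_median > 0):
        raise ValueError(f"series median must be positive, got {series_median}")
    if value < 0:
        raise ValueError(f"concentration must be non-negative, got {value}")
    if mode == "ratio":
        return value / series_median
    if mode == "relative":
        return (value - series_median) / series_median
    raise ValueError(f"unknown mode {mode!r}")


#: Rule-consequent anchors and their linguistic levels.
RETENTION_ANCHORS: tuple[tuple[float, str], ...] = (
    (-1.0, "Minimal"),
    (-0.6, "Low"),
    (-0.4, "Moderately low"),
    (0.0, "Equilibrium state"),
    (0.4, "Moderately high"),
    (0.6, "High"),
    (1.0, "Maximal"),
)


def label_retention(value: float) -> str:
    """Linguistic level of a retention intensity in [-1, 1].

    Returns the label of the nearest anchor in ``RETENTION_ANCHORS``;
    exact ties go to the anchor of smaller absolute value.
    """
    if not (-1.0 <= value <= 1.0):
        raise ValueError(f"retention value must lie in [-1, 1], got {value}")
    # Nearest anchor; ties (within float tolerance, so exact midpoints
    # like -0.8 resolve consistently) go to the anchor closer to
    # equilibrium.
    distances = [abs(value - a) for a, _ in RETENTION_ANCHORS]
    best = min(distances)
    candidates = [
        (abs(anchor), label)
        for (anchor, label), d in zip(RETENTION_ANCHORS, distances)
        if d <= best + 1e-9
    ]
    return min(candidates)[1]


@dataclass(frozen=True)
class RetentionResult:
    """Crisp retention intensity plus its linguistic level."""

    value: float
    label: str

    def __post_init__(self) -> None:
        if not (-1.0 <= self.value <= 1.0):
            raise ValueError(f"retention value must lie in [-1, 1], got {self.value}")


def _conc_map(conc: Optional[Mapping]) -> Optional[dict]:
    if conc is None:
        return None
    out = {}
    for key, val in conc.items():
        el = TraceElement.from_code(key)
        v = float(val)
        if v < 0:
            raise ValueError(f"concentration for {el.value} must be non-negative, got {v}")
        out[el] = v
    return out


@dataclass
class SubjectRecord:
    """Anthropometrics and measured/estimated concentrations for one
    individual.

    ``water_conc`` is required; ``serum_conc`` and ``urine_conc`` are
    optional (they may be estimated by the cascade stage).  All
    concentration mappings are keyed by :class:`TraceElement`.
    """

    height: float
    weight: float
    daily_diuresis: float
    water_conc: Mapping[TraceElement, float] = field(default_factory=dict)
    serum_conc: Optional[Mapping[TraceElement, float]] = None
    urine_conc: Optional[Mapping[TraceElement, float]] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.height > 0):
            raise ValueError(f"height must be positive, got {self.height}")
        if not (self.weight > 0):
            raise ValueError(f"weight must be positive, got {self.weight}")
        if self.daily_diuresis < 0:
            raise ValueError(f"daily diuresis must be non-negative, got {self.daily_diuresis}")
        self.water_conc = _conc_map(self.water_conc) or {}
        self.serum_conc = _conc_map(self.serum_conc)
        self.urine_conc = _conc_map(self.urine_conc)

    @property
    def body_surface_area(self) -> float:
        return body_surface_area(self.height, self.weight)

    def concentration(self, compartment: Compartment, element: TraceElement) -> Optional[float]:
        store = {
            "water": self.water_conc,
            "serum": self.serum_conc,
            "urine": self.urine_conc,
        }[compartment]
        if store is None:
            return None
        return store.get(element)


class MembershipCenters:
    """Low/high Gaussian membership centres (mg/l) per element and
    compartment.

    The packaged defaults ship as a YAML data file; user files of the
    same schema can override them via :meth:`from_file`.
    """

    def __init__(self, centers: Mapping[Compartment, Mapping[TraceElement, tuple[float, float]]]):
        self._centers: dict[Compartment, dict[TraceElement, tuple[float, float]]] = {}
        for comp in COMPARTMENTS:
            if comp not in centers:
                raise ValueError(f"missing compartment {comp!r}")
            self._centers[comp] = {}
            for el in TraceElement:
                if el not in centers[comp]:
                    raise ValueError(f"missing centres for {el.value} in {comp}")
                low, high = (float(v) for v in centers[comp][el])
                if not (0 < low < high):
                    raise ValueError(
                        f"{el.value}/{comp}: centres must satisfy 0 < low < high, got ({low}, {high})"
                    )
                self._centers[comp][el] = (low, high)

    def low(self, element: TraceElement, compartment: Compartment) -> float:
        return self._centers[compartment][TraceElement.from_code(element)][0]

    def high(self, element: TraceElement, compartment: Compartment) -> float:
        return self._centers[compartment][TraceElement.from_code(element)][1]

    def pair(self, element: TraceElement, compartment: Compartment) -> tuple[float, float]:
        return self._centers[compartment][TraceElement.from_code(element)]

    @classmethod
    def from_dict(cls, payload: Mapping) -> "MembershipCenters":
        raw = payload["centers"] if "centers" in payload else payload
        centers: dict = {}
        for comp, per_el in raw.items():
            centers[comp] = {}
            for code, pair in per_el.items():
                el = TraceElement.from_code(code)
                if isinstance(pair, Mapping):
                    centers[comp][el] = (pair["low"], pair["high"])
                else:
                    centers[comp][el] = tuple(pair)
        return cls(centers)

    @classmethod
    def from_file(cls, path) -> "MembershipCenters":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "MembershipCenters":
        """The packaged default centres."""
        ref = resources.files("traceret").joinpath("data/membership_centers.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "centers": {
                comp: {
                    el.value: {"low": lo, "high": hi}
                    for el, (lo, hi) in per_el.items()
                }
                for comp, per_el in self._centers.items()
            },
        }
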