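"""Seeded synthetic-cohort generator.

Drinking-water concentrations are log-normal with parameters solved so
the population Q1/Q3 hit the packaged membership centres; serum follows
a saturating response to the intake (water concentration normalized by
body surface area); urine follows serum scaled by an excretion fraction
and a diuresis coupling.  Latent (noise-free) serum/urine values are
retained so generated cohorts double as oracles for the regression
stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from traceret.core import (
    MembershipCenters,
    SubjectRecord,
    TraceElement,
    body_surface_area,
)

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate_cohort", "worked_example_fixtures"]

#: Standard normal upper-quartile deviate; Q3 of lognormal(mu, s) is exp(mu + Z75·s).
_Z75 = 0.6744897501960817


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the cohort generator.

    Quartile targets default to the packaged membership centres; the
    serum/urine map parameters are solved from them at generation time.
    Anthropometric ranges default to a child/adolescent population.
    """

    n_subjects: int = 2000
    elements: tuple[TraceElement, ...] = tuple(TraceElement)
    seed: int = 0
    water_quartiles: Optional[Mapping[TraceElement, tuple[float, float]]] = None
    serum_quartiles: Optional[Mapping[TraceElement, tuple[float, float]]] = None
    urine_quartiles: Optional[Mapping[TraceElement, tuple[float, float]]] = None
    noise_water: float = 0.0
    noise_serum: float = 0.05
    noise_urine: float = 0.05
    bsa_exponent: float = 0.4
    diuresis_exponent: float = 0.5
    height_range: tuple[float, float] = (120.0, 180.0)
    weight_range: tuple[float, float] = (25.0, 80.0)
    diuresis_range: tuple[float, float] = (500.0, 2000.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        for name in ("noise_water", "noise_serum", "noise_urine"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("height_range", "weight_range", "diuresis_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid {name}: {(lo, hi)}")
        object.__setattr__(self, "elements", tuple(TraceElement.from_code(e) for e in self.elements))

    def quartile_targets(self, compartment: str) -> dict[TraceElement, tuple[float, float]]:
        """Configured (Q1, Q3) targets for one compartment; defaults to
        the packaged centres."""
        override = {
            "water": self.water_quartiles,
            "serum": self.serum_quartiles,
            "urine": self.urine_quartiles,
        }[compartment]
        defaults = MembershipCenters.default()
        out = {}
        for el in self.elements:
            pair = None
            if override is not None:
                raw = {TraceElement.from_code(k): v for k, v in override.items()}
                pair = raw.get(el)
            if pair is None:
                pair = defaults.pair(el, compartment)  # type: ignore[arg-type]
            q1, q3 = (float(v) for v in pair)
            if not (0 < q1 < q3):
                raise ValueError(f"{compartment}/{el.value}: quartile targets must satisfy 0 < Q1 < Q3")
            out[el] = (q1, q3)
        return out

    def to_dict(self) -> dict:
        def qmap(m):
            if m is None:
                return None
            return {TraceElement.from_code(k).value: list(v) for k, v in m.items()}

        return {
            "n_subjects": self.n_subjects,
            "elements": [e.value for e in self.elements],
            "seed": self.seed,
            "water_quartiles": qmap(self.water_quartiles),
            "serum_quartiles": qmap(self.serum_quartiles),
            "urine_quartiles": qmap(self.urine_quartiles),
            "noise_water": self.noise_water,
            "noise_serum": self.noise_serum,
            "noise_urine": self.noise_urine,
            "bsa_exponent": self.bsa_exponent,
            "diuresis_exponent": self.diuresis_exponent,
            "height_range": list(self.height_range),
            "weight_range": list(self.weight_range),
            "diuresis_range": list(self.diuresis_range),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "GeneratorConfig":
        payload = dict(payload)
        for key in ("height_range", "weight_range", "diuresis_range"):
            if key in payload:
                payload[key] = tuple(payload[key])
        if "elements" in payload:
            payload["elements"] = tuple(TraceElement.from_code(e) for e in payload["elements"])
        for key in ("water_quartiles", "serum_quartiles", "urine_quartiles"):
            if payload.get(key) is not None:
                payload[key] = {
                    TraceElement.from_code(k): tuple(v) for k, v in payload[key].items()
                }
        known = set(cls.__dataclass_fields__)
        return cls(**{k: v for k, v in payload.items() if k in known})


@dataclass
class SyntheticCohort:
    """Generated subjects plus provenance and the latent noise-free
    serum/urine values."""

    frame: pd.DataFrame
    provenance: dict
    latent: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[SubjectRecord]:
        out = []
        for _, row in self.frame.iterrows():
            els = self.provenance["config"]["elements"]
            out.append(
                SubjectRecord(
                    height=row["height"],
                    weight=row["weight"],
                    daily_diuresis=row["daily_diuresis"],
                    water_conc={e: row[f"water_{e}"] for e in els},
                    serum_conc={e: row[f"serum_{e}"] for e in els},
                    urine_conc={e: row[f"urine_{e}"] for e in els},
                    subject_id=str(row["subject_id"]),
                )
            )
        return out

    def to_csv(self, path, sidecar_path=None) -> None:
        self.frame.to_csv(path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w", encoding="utf-8") as fh:
                json.dump(self.provenance, fh, indent=2)


def _solve_lognormal(q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal whose quartiles are exactly (q1, q3)."""
    mu = 0.5 * (math.log(q1) + math.log(q3))
    sigma = (math.log(q3) - math.log(q1)) / (2.0 * _Z75)
    return mu, sigma


def _saturating(u: np.ndarray, half: float) -> np.ndarray:
    return u / (u + half)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a reproducible synthetic cohort.

    Per element: water ~ lognormal anchored at the configured Q1/Q3;
    latent serum = baseline + gain · sat(intake), where the intake is
    the water concentration scaled by (BSA_ref / BSA)^bsa_exponent and
    sat is Michaelis-Menten with half-saturation at the median intake;
    latent urine = excretion_fraction · serum · (diuresis / median)^
    diuresis_exponent.  Map parameters are solved so the latent maps
    carry the water quartiles onto the serum/urine quartile targets at
    reference anthropometrics.  Observed values add truncated Gaussian
    noise with the configured relative scales.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    height = rng.uniform(*config.height_range, size=n)
    weight = rng.uniform(*config.weight_range, size=n)
    diuresis = rng.uniform(*config.diuresis_range, size=n)
    bsa = np.sqrt(height * weight / 3600.0)
    bsa_ref = body_surface_area(
        0.5 * sum(config.height_range), 0.5 * sum(config.weight_range)
    )
    d_ref = 0.5 * sum(config.diuresis_range)

    water_targets = config.quartile_targets("water")
    serum_targets = config.quartile_targets("serum")
    urine_targets = config.quartile_targets("urine")

    data: dict[str, np.ndarray] = {
        "subject_id": np.array([f"S{i:05d}" for i in range(n)]),
        "height": height,
        "weight": weight,
        "daily_diuresis": diuresis,
    }
    latent: dict[str, np.ndarray] = {"subject_id": data["subject_id"]}

    for el in config.elements:
        wq1, wq3 = water_targets[el]
        sq1, sq3 = serum_targets[el]
        uq1, uq3 = urine_targets[el]
        mu, sigma = _solve_lognormal(wq1, wq3)
        water = rng.lognormal(mu, sigma, size=n)
        if config.noise_water > 0:
            water = np.clip(water * (1 + config.noise_water * rng.standard_normal(n)), 0, None)

        # Saturating serum map, solved so water Q1/Q3 land on serum Q1/Q3
        # at reference anthropometrics.
        half = math.exp(mu)
        s1, s3 = _saturating(np.array([wq1, wq3]), half)
        gain = (sq3 - sq1) / (s3 - s1)
        baseline = sq1 - gain * s1
        intake = water * (bsa_ref / bsa) ** config.bsa_exponent
        serum_latent = np.clip(baseline + gain * _saturating(intake, half), 0.0, None)

        # Urine map: power law in serum with the exponent solved so the
        # serum quartile spread maps onto the urine quartile spread;
        # coupling grows with diuresis.
        smid = math.sqrt(sq1 * sq3)
        umid = math.sqrt(uq1 * uq3)
        spread_exp = math.log(uq3 / uq1) / math.log(sq3 / sq1)
        coupling = (diuresis / d_ref) ** config.diuresis_exponent
        urine_latent = umid * (serum_latent / smid) ** spread_exp * coupling

        serum = serum_latent
        if config.noise_serum > 0:
            serum = np.clip(
                serum_latent * (1 + config.noise_serum * rng.standard_normal(n)), 0.0, None
            )
        urine = urine_latent
        if config.noise_urine > 0:
            urine = np.clip(
                urine_latent * (1 + config.noise_urine * rng.standard_normal(n)), 0.0, None
            )

        code = el.value
        data[f"water_{code}"] = water
        data[f"serum_{code}"] = serum
        data[f"urine_{code}"] = urine
        latent[f"serum_{code}"] = serum_latent
        latent[f"urine_{code}"] = urine_latent

    provenance = {"generator": "traceret.synth", "schema_version": 1, "config": config.to_dict()}
    return SyntheticCohort(
        frame=pd.DataFrame(data), provenance=provenance, latent=pd.DataFrame(latent)
    )


def worked_example_fixtures() -> list[SubjectRecord]:
    """The three packaged zinc reference subjects: anthropometrics plus
    water concentration measured, serum/urine as estimated upstream."""
    zn = TraceElement.Zn
    return [
        SubjectRecord(
            height=164.0,
            weight=40.15,
            daily_diuresis=750.0,
            water_conc={zn: 0.04},
            serum_conc={zn: 0.892},
            urine_conc={zn: 0.433},
            subject_id="fixture-1",
        ),
        SubjectRecord(
            height=170.0,
            weight=41.8,
            daily_diuresis=1300.0,
            water_conc={zn: 0.04},
            serum_conc={zn: 0.867},
            urine_conc={zn: 0.0},
            subject_id="fixture-2",
        ),
        SubjectRecord(
            height=159.0,
            weight=57.0,
            daily_diuresis=720.0,
            water_conc={zn: 0.017},
            serum_conc={zn: 0.778},
            urine_conc={zn: 0.527},
            subject_id="fixture-3",
        ),
    ]
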