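"""Parameterization of the overtreatment-governance game.

The model has three boundedly rational populations -- patients, medical
institutions, and government regulators -- whose pairwise incentives are
captured by fourteen nonnegative constants on a common arbitrary money-like
scale.  This module holds the validated parameter container, the population
strategy-frequency state, and plain-text (YAML/JSON) parameter file I/O.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "PARAM_NAMES",
    "ConfigurationError",
    "ValidationError",
    "GameParameters",
    "StrategyState",
    "validate_parameters",
    "load_parameters",
    "save_parameters",
]

#: Canonical symbol order used everywhere (arrays, files, reports).
PARAM_NAMES: tuple[str, ...] = (
    "Cm", "Ct", "Cp", "Ci",
    "Wm", "Wt", "Gf", "Gs", "Er", "Oc",
    "Eg", "Cr", "Gg", "Pg",
)


class ConfigurationError(Exception):
    """A parameter mapping or run configuration is structurally wrong."""


class ValidationError(ValueError):
    """A supplied value violates a model invariant."""


@dataclass(frozen=True)
class GameParameters:
    """The fourteen payoff/cost constants of the tripartite game.

    Patients
    --------
    Cm : cost of overmedicalization borne by the patient.
    Ct : benefit of appropriate diagnosis and treatment.
    Cp : complaint cost/probability weight for questioning an institution.
    Ci : compensation income when harmed by overtreatment.

    Medical institutions
    --------------------
    Wm : income from overtreatment (assumed to exceed Wt in the study).
    Wt : income from appropriate (reasonable) treatment.
    Gf : government fine imposed on overtreating institutions.
    Gs : government financial subsidy for reasonable treatment.
    Er : reputation benefit of reasonable treatment.
    Oc : operating cost of running medical services.

    Government regulators
    ---------------------
    Eg : social benefit when institutions comply under supervision.
    Cr : cost of regulatory oversight.
    Gg : remediation (rectification) cost.
    Pg : government credibility at stake under inadequate regulation.

    All values are nonnegative finite reals on one common scale; no currency
    conversion is performed.
    """

    Cm: float
    Ct: float
    Cp: float
    Ci: float
    Wm: float
    Wt: float
    Gf: float
    Gs: float
    Er: float
    Oc: float
    Eg: float
    Cr: float
    Gg: float
    Pg: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            try:
                value = float(value)
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"parameter {name!r} is not a real number: {value!r}") from exc
            if not math.isfinite(value):
                raise ValidationError(f"parameter {name!r} must be finite, got {value!r}")
            if value < 0:
                raise ValidationError(f"parameter {name!r} must be nonnegative, got {value!r}")
            object.__setattr__(self, name, value)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, float]) -> "GameParameters":
        missing = [name for name in PARAM_NAMES if name not in raw]
        if missing:
            raise ConfigurationError(f"missing parameter key(s): {', '.join(missing)}")
        extra = [key for key in raw if key not in PARAM_NAMES]
        if extra:
            raise ConfigurationError(f"unknown parameter key(s): {', '.join(sorted(extra))}")
        return cls(**{name: raw[name] for name in PARAM_NAMES})

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def replace(self, **changes: float) -> "GameParameters":
        unknown = [key for key in changes if key not in PARAM_NAMES]
        if unknown:
            raise ConfigurationError(f"unknown parameter key(s): {', '.join(sorted(unknown))}")
        return dataclasses.replace(self, **changes)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)


@dataclass(frozen=True)
class StrategyState:
    """Point (x, y, z) of the unit cube: population strategy frequencies.

    x : fraction of patients who recognize treatment outcomes.
    y : fraction of institutions providing reasonable treatment.
    z : fraction of regulators exercising strict supervision.
    """

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            value = float(getattr(self, name))
            if not math.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ValidationError(f"strategy frequency {name!r} must lie in [0, 1], got {value!r}")
            object.__setattr__(self, name, value)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StrategyState":
        x, y, z = np.asarray(arr, dtype=float)
        return cls(x, y, z)

    def __iter__(self) -> Iterator[float]:
        return iter((self.x, self.y, self.z))


def validate_parameters(raw: Mapping[str, float]) -> GameParameters:
    """Validate a name->value mapping of exactly the fourteen model symbols.

    Raises :class:`ConfigurationError` for a missing or unknown key and
    :class:`ValidationError` for a negative or non-finite value.
    """
    return GameParameters.from_mapping(raw)


def load_parameters(path: str | Path) -> GameParameters:
    """Read a flat symbol->value YAML or JSON parameter file."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"parameter file {path} must hold a flat key->value mapping")
    # Ignore bookkeeping keys written by save_parameters / scenario files.
    payload = {k: v for k, v in raw.items() if k in PARAM_NAMES or not str(k).startswith("_")}
    return validate_parameters(payload)


def save_parameters(params: GameParameters, path: str | Path, **metadata) -> Path:
    """Write a parameter file; extra metadata keys are stored under ``_meta``."""
    path = Path(path)
    doc: dict = dict(params.to_dict())
    if metadata:
        doc["_meta"] = metadata
    with open(path, "w") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False)
    return path
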