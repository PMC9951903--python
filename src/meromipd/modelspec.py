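"""Population-PK model specifications.

A :class:`ModelSpec` is the declarative description of one published (or
synthetic) nonlinear mixed-effects model: typical structural parameters
(theta), covariate relations, a between-subject variability covariance
(omega, on log-scale random effects) and a residual-error model (sigma).
Individual parameters are realised as

    p_i = (theta_i × Π multiplicative covariate factors + Σ additive shifts) × exp(eta_i),

the log-normal random-effect convention dominant in NONMEM practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import yaml

from .covariates import CovariateSet
from .errors import ConfigurationError, InvalidCovariateError
from .events import DoseEvent

PARAMETER_NAMES = ("cl", "vc", "q2", "vp2", "q3", "vp3")

RELATION_FORMS = (
    "linear_proportional",
    "power",
    "exponential",
    "additive_shift",
    "categorical_factor",
)

#: Covariates that encode renal function; used to flag renal-sensitive models.
RENAL_COVARIATES = frozenset({"crcl_cg", "egfr_ckdepi", "clcr_mdrd", "serum_creatinine"})


@dataclass(frozen=True)
class StructuralParams:
    """Structural PK parameters: clearances in L/h, volumes in L."""

    cl: float
    vc: float
    q2: Optional[float] = None
    vp2: Optional[float] = None
    q3: Optional[float] = None
    vp3: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.q2 is None) != (self.vp2 is None) or (self.q3 is None) != (self.vp3 is None):
            raise ConfigurationError("peripheral compartments need both Q and V")
        if self.q3 is not None and self.q2 is None:
            raise ConfigurationError("a third compartment requires a second")
        for name in PARAMETER_NAMES:
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")

    @property
    def n_compartments(self) -> int:
        return 1 + (self.q2 is not None) + (self.q3 is not None)

    def as_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in PARAMETER_NAMES if getattr(self, k) is not None}


@dataclass(frozen=True)
class CovariateRelation:
    """How one covariate scales one structural parameter.

    Forms: ``linear_proportional`` multiplies by (x/ref)·coefficient with
    coefficient defaulting to 1; ``power`` multiplies by (x/ref)^coefficient;
    ``exponential`` multiplies by exp(coefficient·(x − ref));
    ``additive_shift`` adds coefficient·(x − ref) to the parameter;
    ``categorical_factor`` multiplies by coefficient when the covariate is
    truthy (or equals ``category`` when given).
    """

    target: str
    covariate: str
    form: str
    reference_value: float = 1.0
    coefficient: float = 1.0
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.target not in PARAMETER_NAMES:
            raise ConfigurationError(f"unknown relation target {self.target!r}")
        if self.form not in RELATION_FORMS:
            raise ConfigurationError(f"unknown relation form {self.form!r}")
        if self.form in ("linear_proportional", "power") and self.reference_value <= 0:
            raise ConfigurationError("ratio forms need a positive reference_value")

    def factor(self, cov: CovariateSet) -> float:
        """Multiplicative factor (or additive shift for ``additive_shift``)."""
        x = cov.get(self.covariate)
        if self.form == "linear_proportional":
            return self.coefficient * x / self.reference_value
        if self.form == "power":
            return (x / self.reference_value) ** self.coefficient
        if self.form == "exponential":
            return math.exp(self.coefficient * (x - self.reference_value))
        if self.form == "additive_shift":
            return self.coefficient * (x - self.reference_value)
        # categorical_factor
        active = (x == self.category) if self.category is not None else bool(x)
        return self.coefficient if active else 1.0


@dataclass(frozen=True)
class ResidualErrorModel:
    """Residual unexplained variability: additive, proportional or combined.

    Variance at prediction f is sigma_add² + (sigma_prop·f)².
    """

    kind: str = "combined"
    sigma_add: float = 0.0
    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "proportional", "combined"):
            raise ConfigurationError(f"unknown residual error kind {self.kind!r}")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ConfigurationError("sigma components must be >= 0")
        if self.kind == "combined" and not (self.sigma_add > 0 and self.sigma_prop > 0):
            raise ConfigurationError("combined error requires both components > 0")
        if self.kind == "additive" and self.sigma_prop != 0:
            raise ConfigurationError("additive error must not carry a proportional part")
        if self.kind == "proportional" and self.sigma_add != 0:
            raise ConfigurationError("proportional error must not carry an additive part")

    def variance(self, f):
        """Residual variance at prediction(s) ``f`` (mg/L)."""
        f = np.asarray(f, dtype=float)
        return self.sigma_add ** 2 + (self.sigma_prop * f) ** 2

    def sample(self, f, rng: np.random.Generator):
        """Draw observed concentrations around prediction(s) ``f``."""
        f = np.asarray(f, dtype=float)
        out = f.copy()
        if self.sigma_prop > 0:
            out = f * (1.0 + rng.normal(0.0, self.sigma_prop, f.shape))
        if self.sigma_add > 0:
            out = out + rng.normal(0.0, self.sigma_add, f.shape)
        return out


@dataclass(frozen=True)
class EtaVector:
    """Log-scale individual deviations, aligned with a model's omega."""

    values: np.ndarray
    parameter_names: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.parameter_names),):
            raise ConfigurationError("eta length must match parameter_names")

    @classmethod
    def zeros(cls, parameter_names: Sequence[str]) -> "EtaVector":
        return cls(np.zeros(len(parameter_names)), tuple(parameter_names))


@dataclass
class ModelSpec:
    """Full parameterisation of one population-PK model."""

    name: str
    theta: StructuralParams
    relations: List[CovariateRelation] = field(default_factory=list)
    eta_names: tuple = ("cl", "vc")
    omega: np.ndarray = None
    residual: ResidualErrorModel = field(default_factory=lambda: ResidualErrorModel("combined", 0.5, 0.2))
    source_note: str = ""

    def __post_init__(self) -> None:
        self.eta_names = tuple(self.eta_names)
        if self.omega is None:
            self.omega = np.zeros((len(self.eta_names), len(self.eta_names)))
        self.omega = np.asarray(self.omega, dtype=float)
        d = len(self.eta_names)
        if self.omega.shape != (d, d):
            raise ConfigurationError(f"omega must be {d}x{d} for eta {self.eta_names}")
        if not np.allclose(self.omega, self.omega.T):
            raise ConfigurationError("omega must be symmetric")
        eigvals = np.linalg.eigvalsh(self.omega)
        if eigvals.min() < -1e-10 * max(eigvals.max(), 1.0):
            raise ConfigurationError("omega must be positive semi-definite")
        theta_params = self.theta.as_dict()
        for name in self.eta_names:
            if name not in theta_params:
                raise ConfigurationError(f"eta on {name!r} but theta has no such parameter")
        for rel in self.relations:
            if rel.target not in theta_params:
                raise ConfigurationError(
                    f"relation targets {rel.target!r}, absent from theta of {self.name!r}"
                )

    @property
    def n_compartments(self) -> int:
        return self.theta.n_compartments

    @property
    def n_etas(self) -> int:
        return len(self.eta_names)

    # -- parameter realisation -------------------------------------------

    def covariate_adjusted_params(self, cov: CovariateSet) -> StructuralParams:
        """Typical-individual parameters: theta scaled by covariate relations."""
        values = self.theta.as_dict()
        shifts: Dict[str, float] = {}
        for rel in self.relations:
            if rel.form == "additive_shift":
                shifts[rel.target] = shifts.get(rel.target, 0.0) + rel.factor(cov)
            else:
                values[rel.target] *= rel.factor(cov)
        for target, shift in shifts.items():
            values[target] += shift
        for name, value in values.items():
            if value <= 0:
                raise InvalidCovariateError(
                    f"covariate-adjusted {name} is non-positive ({value:.4g}) in {self.name!r}"
                )
        return StructuralParams(**values)

    def individual_params(self, cov: CovariateSet, eta: Union[EtaVector, np.ndarray, None] = None
                          ) -> StructuralParams:
        """Realised individual parameters at random-effect vector ``eta``."""
        base = self.covariate_adjusted_params(cov)
        if eta is None:
            return base
        values = np.asarray(eta.values if isinstance(eta, EtaVector) else eta, dtype=float)
        if values.shape != (self.n_etas,):
            raise ConfigurationError(
                f"eta has shape {values.shape}, model expects ({self.n_etas},)"
            )
        params = base.as_dict()
        for name, e in zip(self.eta_names, values):
            params[name] *= math.exp(e)
        return StructuralParams(**params)

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_compartments": self.n_compartments,
            "theta": self.theta.as_dict(),
            "relations": [
                {k: v for k, v in {
                    "target": r.target,
                    "covariate": r.covariate,
                    "form": r.form,
                    "reference_value": r.reference_value,
                    "coefficient": r.coefficient,
                    "category": r.category,
                }.items() if v is not None}
                for r in self.relations
            ],
            "eta_names": list(self.eta_names),
            "omega": [[float(v) for v in row] for row in self.omega],
            "residual": {
                "kind": self.residual.kind,
                "sigma_add": self.residual.sigma_add,
                "sigma_prop": self.residual.sigma_prop,
            },
            "source_note": self.source_note,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        theta = StructuralParams(**data["theta"])
        declared = data.get("n_compartments")
        if declared is not None and declared != theta.n_compartments:
            raise ConfigurationError(
                f"{data.get('name')!r} declares {declared} compartments but theta has "
                f"{theta.n_compartments}"
            )
        relations = [CovariateRelation(**r) for r in data.get("relations", [])]
        residual = ResidualErrorModel(**data.get("residual", {}))
        return cls(
            name=data["name"],
            theta=theta,
            relations=relations,
            eta_names=tuple(data.get("eta_names", ("cl", "vc"))),
            omega=np.asarray(data["omega"], dtype=float) if "omega" in data else None,
            residual=residual,
            source_note=data.get("source_note", ""),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_model(path: Union[str, Path]) -> ModelSpec:
    """Load one model configuration from a YAML document."""
    data = yaml.safe_load(Path(path).read_text())
    return ModelSpec.from_dict(data)


def uses_renal_covariate(spec: ModelSpec) -> bool:
    """True when any covariate relation reads a renal-function marker."""
    return any(rel.covariate in RENAL_COVARIATES for rel in spec.relations)
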