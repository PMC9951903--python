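"""Patient covariates and renal-function estimators.

Renal function drives meropenem clearance, so the three bedside estimators —
Cockcroft–Gault creatinine clearance (CG), the original MDRD study equation and
the CKD-EPI 2009 creatinine equation — are first-class operations here.  CG is
evaluated with serum creatinine in µmol/L (constant 0.815 in the denominator);
a conversion helper accepts mg/dL values, which some source models print.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Optional

from .errors import InvalidCovariateError, ConfigurationError, MissingCovariateError

#: µmol/L per mg/dL of creatinine
CREATININE_UMOL_PER_MGDL = 88.4

MALE = "male"
FEMALE = "female"

SEPSIS = "sepsis"
SEVERE_SEPSIS = "severe sepsis/septic shock"


def scr_mgdl_to_umol(scr_mgdl: float) -> float:
    """Convert serum creatinine from mg/dL to µmol/L."""
    return scr_mgdl * CREATININE_UMOL_PER_MGDL


@dataclass
class CovariateSet:
    """One patient's covariate record.

    Continuous covariates use the units the clinic reports: age in years,
    weights in kg, height in cm, serum creatinine in µmol/L, albumin in g/L,
    CRP in mg/L.  Renal-function summaries (``crcl_cg``, ``egfr_ckdepi``,
    ``clcr_mdrd``) may be supplied directly; when absent they are derived on
    demand from the underlying demographics.
    """

    age: Optional[float] = None
    sex: Optional[str] = None
    weight_total: Optional[float] = None
    weight_ideal: Optional[float] = None
    height: Optional[float] = None
    serum_creatinine: Optional[float] = None
    albumin: Optional[float] = None
    apache_ii: Optional[float] = None
    crp: Optional[float] = None
    rrt: bool = False
    sepsis_level: Optional[str] = None
    crcl_cg: Optional[float] = None
    egfr_ckdepi: Optional[float] = None
    clcr_mdrd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in (MALE, FEMALE):
            raise InvalidCovariateError(f"sex must be {MALE!r} or {FEMALE!r}, got {self.sex!r}")
        for name in ("weight_total", "weight_ideal", "height", "serum_creatinine"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise InvalidCovariateError(f"{name} must be positive, got {value}")

    def get(self, name: str) -> float:
        """Return covariate ``name``, deriving renal estimates when needed."""
        if name not in {f.name for f in fields(self)}:
            raise MissingCovariateError(f"unknown covariate {name!r}")
        value = getattr(self, name)
        if value is None:
            derivations = {"crcl_cg": crcl_cockcroft_gault,
                           "egfr_ckdepi": egfr_ckd_epi,
                           "clcr_mdrd": gfr_mdrd}
            if name not in derivations:
                raise MissingCovariateError(f"covariate {name!r} is missing")
            try:
                value = derivations[name](self)
            except MissingCovariateError as err:
                raise MissingCovariateError(
                    f"covariate {name!r} is missing and cannot be derived ({err})"
                ) from err
        return value


def _require(cov: CovariateSet, *names: str) -> None:
    for name in names:
        if getattr(cov, name) is None:
            raise MissingCovariateError(f"covariate {name!r} required but missing")


def crcl_cockcroft_gault(cov: CovariateSet) -> float:
    """Cockcroft–Gault creatinine clearance in mL/min.

    CRCL = (140 − age) · weight / (0.815 · SCr[µmol/L]), multiplied by 0.85
    for female patients.  A non-positive numerator (age ≥ 140) is degenerate:
    the estimate is clamped to 0 with a warning.
    """
    _require(cov, "age", "sex", "weight_total", "serum_creatinine")
    if cov.serum_creatinine <= 0 or cov.weight_total <= 0:
        raise InvalidCovariateError("creatinine and weight must be positive for CG")
    crcl = (140.0 - cov.age) * cov.weight_total / (0.815 * cov.serum_creatinine)
    if cov.sex == FEMALE:
        crcl *= 0.85
    if crcl <= 0:
        warnings.warn(
            f"degenerate Cockcroft-Gault estimate ({crcl:.3g} mL/min) for age {cov.age}",
            stacklevel=2,
        )
        return 0.0
    return crcl


def gfr_mdrd(cov: CovariateSet) -> float:
    """Original MDRD study equation, mL/min/1.73 m² (non-Black coefficients)."""
    _require(cov, "age", "sex", "serum_creatinine")
    if cov.serum_creatinine <= 0:
        raise InvalidCovariateError("creatinine must be positive for MDRD")
    scr_mgdl = cov.serum_creatinine / CREATININE_UMOL_PER_MGDL
    gfr = 186.0 * scr_mgdl ** -1.154 * cov.age ** -0.203
    if cov.sex == FEMALE:
        gfr *= 0.742
    return gfr


def egfr_ckd_epi(cov: CovariateSet) -> float:
    """CKD-EPI 2009 creatinine equation, mL/min/1.73 m² (non-Black coefficients)."""
    _require(cov, "age", "sex", "serum_creatinine")
    if cov.serum_creatinine <= 0:
        raise InvalidCovariateError("creatinine must be positive for CKD-EPI")
    scr_mgdl = cov.serum_creatinine / CREATININE_UMOL_PER_MGDL
    if cov.sex == FEMALE:
        kappa, alpha, sex_factor = 0.7, -0.329, 1.018
    else:
        kappa, alpha, sex_factor = 0.9, -0.411, 1.0
    ratio = scr_mgdl / kappa
    return 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209 * 0.993 ** cov.age * sex_factor


_RENAL_METHODS = {
    "CG": crcl_cockcroft_gault,
    "MDRD": gfr_mdrd,
    "CKD-EPI": egfr_ckd_epi,
}


def estimate_renal_function(cov: CovariateSet, method: str = "CG") -> float:
    """Dispatch to one of the published renal-function estimators.

    ``method`` is one of ``"CG"`` (mL/min), ``"MDRD"`` or ``"CKD-EPI"``
    (both mL/min/1.73 m²).
    """
    try:
        fn = _RENAL_METHODS[method]
    except KeyError:
        raise ConfigurationError(
            f"unknown renal-function method {method!r}; choose from {sorted(_RENAL_METHODS)}"
        ) from None
    return fn(cov)


def ideal_body_weight(height_cm: float, sex: str) -> float:
    """Devine ideal body weight (kg)."""
    base = 50.0 if sex == MALE else 45.5
    return base + 0.9 * max(height_cm - 152.0, 0.0)
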