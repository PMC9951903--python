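"""Dose and observation events and the per-patient course container."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List

import numpy as np

from .covariates import CovariateSet
from .errors import DomainError

OBSERVATION_LABELS = ("trough", "peak", "post1h", "post3h", "trough2", "other")


@dataclass(frozen=True)
class DoseEvent:
    """A zero-order intravenous infusion.

    time_start: hours since first dose; amount: mg; duration: infusion length
    in hours.  Overlapping infusions are allowed and their rates add.
    """

    time_start: float
    amount: float
    duration: float

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise DomainError(f"dose amount must be positive, got {self.amount}")
        if self.duration <= 0:
            raise DomainError(f"infusion duration must be positive, got {self.duration}")
        if self.time_start < 0:
            raise DomainError(f"dose time must be >= 0, got {self.time_start}")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h."""
        return self.amount / self.duration

    @property
    def time_end(self) -> float:
        return self.time_start + self.duration


@dataclass(frozen=True)
class ObservationEvent:
    """A measured plasma concentration (mg/L) at ``time`` hours since first dose."""

    time: float
    concentration: float
    below_lloq: bool = False
    label: str = "other"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DomainError(f"observation time must be >= 0, got {self.time}")
        if self.concentration < 0:
            raise DomainError(f"concentration must be >= 0, got {self.concentration}")
        if self.label not in OBSERVATION_LABELS:
            raise DomainError(f"unknown observation label {self.label!r}")


@dataclass
class PatientCourse:
    """Covariates plus the dose and observation history of one patient."""

    patient_id: str
    covariates: CovariateSet
    doses: List[DoseEvent] = field(default_factory=list)
    observations: List[ObservationEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.doses = sorted(self.doses, key=lambda d: d.time_start)
        self.observations = sorted(self.observations, key=lambda o: o.time)

    @property
    def observation_times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations], dtype=float)

    @property
    def observed_concentrations(self) -> np.ndarray:
        return np.array([o.concentration for o in self.observations], dtype=float)

    def time_after_infusion_end(self, t: float) -> float:
        """Hours since the most recent infusion ended before or at ``t``.

        Returns NaN when no infusion has finished by ``t`` (e.g. a sample
        drawn during the very first infusion).
        """
        ends = [d.time_end for d in self.doses if d.time_end <= t]
        if not ends:
            return math.nan
        return t - max(ends)
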