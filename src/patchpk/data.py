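"""Core domain containers for population-PK analysis of transdermal dosing.

Unit convention throughout the package: amounts in ng, volumes in mL, time in
hours, concentrations in ng/mL.  A 34.3 mg patch is therefore a dose of
3.43e7 ng.  Volumes and clearances are apparent (V/F, CL/F); bioavailability
is not a separate parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ThetaVector",
    "OmegaMatrix",
    "ResidualSpec",
    "IndividualParams",
    "DoseEvent",
    "ModelState",
    "Observation",
    "Subject",
    "Dataset",
    "StudyDesign",
    "DemographicsSpec",
]


def _require_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class ThetaVector:
    """Population typical values of the structural PK parameters.

    tvKa : first-order absorption rate constant from the patch depot, 1/h
    tvV  : apparent central volume of distribution, mL
    tvCL : apparent clearance, mL/h
    """

    tvKa: float
    tvV: float
    tvCL: float

    def __post_init__(self) -> None:
        _require_positive("tvKa", self.tvKa)
        _require_positive("tvV", self.tvV)
        _require_positive("tvCL", self.tvCL)

    def as_dict(self) -> dict[str, float]:
        return {"tvKa": self.tvKa, "tvV": self.tvV, "tvCL": self.tvCL}


@dataclass(frozen=True)
class OmegaMatrix:
    """Diagonal inter-individual variance matrix on the log scale.

    Each entry is the variance omega^2 of the normally distributed random
    effect eta for one parameter; a variance of exactly zero switches that
    random effect off.
    """

    omega2_Ka: float = 0.0
    omega2_V: float = 0.0
    omega2_CL: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")

    def as_dict(self) -> dict[str, float]:
        return {
            "omega2_Ka": self.omega2_Ka,
            "omega2_V": self.omega2_V,
            "omega2_CL": self.omega2_CL,
        }

    def diagonal(self) -> np.ndarray:
        return np.array([self.omega2_Ka, self.omega2_V, self.omega2_CL])

    def as_matrix(self) -> np.ndarray:
        return np.diag(self.diagonal())

    @property
    def active(self) -> tuple[bool, bool, bool]:
        """Which of (Ka, V, CL) carry a nonzero random effect."""
        d = self.diagonal()
        return tuple(bool(v > 0) for v in d)  # type: ignore[return-value]


_RESIDUAL_KINDS = ("additive", "proportional", "combined")


@dataclass(frozen=True)
class ResidualSpec:
    """Residual unexplained variability model for observed concentrations.

    additive      : Cobs = C + eps,            Var = sigma_add^2
    proportional  : Cobs = C * (1 + eps),      Var = (sigma_prop * C)^2
    combined      : both terms,                Var = sigma_add^2 + (sigma_prop * C)^2
    """

    kind: str = "additive"
    sigma_add: float | None = None
    sigma_prop: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _RESIDUAL_KINDS:
            raise ValueError(f"kind must be one of {_RESIDUAL_KINDS}, got {self.kind!r}")
        need_add = self.kind in ("additive", "combined")
        need_prop = self.kind in ("proportional", "combined")
        if need_add:
            if self.sigma_add is None:
                raise ValueError("sigma_add required for additive/combined residual model")
            _require_positive("sigma_add", self.sigma_add)
        elif self.sigma_add is not None:
            raise ValueError("sigma_add must be absent for a proportional residual model")
        if need_prop:
            if self.sigma_prop is None:
                raise ValueError("sigma_prop required for proportional/combined residual model")
            _require_positive("sigma_prop", self.sigma_prop)
        elif self.sigma_prop is not None:
            raise ValueError("sigma_prop must be absent for an additive residual model")

    def variance(self, pred: np.ndarray | float) -> np.ndarray:
        """Residual variance evaluated at model prediction ``pred`` (ng/mL)."""
        pred = np.asarray(pred, dtype=float)
        var = np.zeros_like(pred)
        if self.sigma_add is not None:
            var = var + self.sigma_add**2
        if self.sigma_prop is not None:
            var = var + (self.sigma_prop * pred) ** 2
        # floor guards against a zero variance at pred == 0 under proportional error
        return np.maximum(var, 1e-12)

    def param_names(self) -> tuple[str, ...]:
        if self.kind == "additive":
            return ("sigma_add",)
        if self.kind == "proportional":
            return ("sigma_prop",)
        return ("sigma_add", "sigma_prop")


@dataclass(frozen=True)
class IndividualParams:
    """One subject's realized PK parameters and the etas that produced them."""

    Ka: float
    V: float
    CL: float
    eta: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        _require_positive("Ka", self.Ka)
        _require_positive("V", self.V)
        _require_positive("CL", self.CL)

    @property
    def ke(self) -> float:
        """First-order elimination rate constant CL/V, 1/h."""
        return self.CL / self.V


@dataclass(frozen=True)
class DoseEvent:
    """A single patch application: loaded amount and wear interval.

    The depot is charged with ``amount`` ng at ``t_apply``; at ``t_remove``
    the patch comes off and (by default elsewhere in the package) the
    unabsorbed depot is discarded with it.
    """

    amount: float
    t_remove: float
    t_apply: float = 0.0

    def __post_init__(self) -> None:
        _require_positive("amount", self.amount)
        if not self.t_remove > self.t_apply:
            raise ValueError(
                f"t_remove ({self.t_remove}) must exceed t_apply ({self.t_apply})"
            )

    @property
    def wear_h(self) -> float:
        return self.t_remove - self.t_apply


@dataclass(frozen=True)
class ModelState:
    """Amounts in the depot (Aa), central compartment (A1) and eliminated (A0)."""

    Aa: float
    A1: float
    A0: float


@dataclass(frozen=True)
class Observation:
    """One concentration record.

    ``conc`` is None when the sample is below the lower limit of
    quantification (BLQ); ``nominal_time`` is the protocol design time used
    for predictive-check binning and defaults to the actual time.
    """

    time: float
    conc: float | None = None
    blq: bool = False
    nominal_time: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")
        if self.blq and self.conc is not None:
            raise ValueError("BLQ observations must not carry a concentration value")
        if not self.blq:
            if self.conc is None:
                raise ValueError("quantifiable observations require a concentration")
            if not math.isfinite(self.conc):
                raise ValueError(f"concentration must be finite, got {self.conc}")
            # slightly negative measured values are tolerated: they arise
            # under additive assay error when no quantification limit censors
            # the record, and dropping them would bias low-concentration fits
        if self.nominal_time is None:
            object.__setattr__(self, "nominal_time", self.time)


@dataclass
class Subject:
    """One individual: covariates, dosing and concentration records."""

    id: str
    dose: DoseEvent
    observations: list[Observation] = field(default_factory=list)
    covariates: dict[str, float] = field(default_factory=dict)
    study: str = ""
    eta_true: tuple[float, float, float] | None = None  # simulation provenance only

    def __post_init__(self) -> None:
        times = [o.time for o in self.observations]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"subject {self.id}: observation times must be sorted")

    @property
    def quantifiable(self) -> list[Observation]:
        return [o for o in self.observations if not o.blq]

    def times(self, include_blq: bool = False) -> np.ndarray:
        obs = self.observations if include_blq else self.quantifiable
        return np.array([o.time for o in obs], dtype=float)

    def dv(self) -> np.ndarray:
        return np.array([o.conc for o in self.quantifiable], dtype=float)


@dataclass
class Dataset:
    """A modelling dataset: a list of subjects with unique ids."""

    subjects: list[Subject] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_obs(self) -> int:
        """Number of quantifiable (non-BLQ) observations."""
        return sum(len(s.quantifiable) for s in self.subjects)

    def covariate_values(self, name: str) -> np.ndarray:
        return np.array([s.covariates[name] for s in self.subjects], dtype=float)

    def covariate_median(self, name: str) -> float:
        return float(np.median(self.covariate_values(name)))

    def signature(self) -> tuple:
        """Cheap identity token used to check two fits saw the same data."""
        ids = tuple(s.id for s in self.subjects)
        checksum = 0.0
        for s in self.subjects:
            checksum += float(np.sum(s.dv())) + float(np.sum(s.times()))
        return (ids, self.n_obs, round(checksum, 6))

    def subset(self, ids: Sequence[str]) -> "Dataset":
        wanted = set(ids)
        return Dataset([s for s in self.subjects if s.id in wanted])


@dataclass(frozen=True)
class StudyDesign:
    """One trial arm: subject count, dose, wear duration, sampling schedule."""

    code: str
    n_subjects: int
    dose_ng: float
    wear_h: float
    sampling_times_h: tuple[float, ...]

    def __post_init__(self) -> None:
        _require_positive("dose_ng", self.dose_ng)
        _require_positive("wear_h", self.wear_h)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        t = np.asarray(self.sampling_times_h, dtype=float)
        if t.size == 0:
            raise ValueError("sampling schedule must not be empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.n_subjects * len(self.sampling_times_h)

    def dose_event(self) -> DoseEvent:
        return DoseEvent(amount=self.dose_ng, t_apply=0.0, t_remove=self.wear_h)


@dataclass(frozen=True)
class DemographicsSpec:
    """Marginal demographic distributions for one study population.

    Continuous covariates are summarized as mean and SD (drawn from truncated
    normals at generation time); sex as the fraction of females.
    """

    age_mean: float
    age_sd: float
    weight_mean: float
    weight_sd: float
    height_mean: float
    height_sd: float
    bmi_mean: float
    bmi_sd: float
    female_fraction: float

    def __post_init__(self) -> None:
        for name in ("age_sd", "weight_sd", "height_sd", "bmi_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0, 1]")
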