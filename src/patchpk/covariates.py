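"""Covariate effect forms and stepwise covariate model building.

Continuous covariates act on a structural parameter through a power function
normalized by the population median, ``theta_i = theta_TV * (cov/median)^theta_x``;
categorical covariates (sex) through an indicator exponent,
``theta_i = theta_TV * exp(theta_x * [cov == k])``.  Candidate effects are
screened by stepwise forward inclusion (an OFV drop > 3.84, p < 0.05 for one
degree of freedom) followed by a stricter backward elimination (retained only
if removal raises the OFV by > 6.64, p < 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .data import Dataset, ThetaVector

__all__ = [
    "CovariateEffect",
    "StepwiseTrace",
    "TraceEntry",
    "apply_effect",
    "apply_effects",
    "default_candidates",
    "forward_step",
    "backward_step",
    "run_stepwise",
    "FORWARD_THRESHOLD",
    "BACKWARD_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: chi-square(1) critical values used as inclusion/retention gates
FORWARD_THRESHOLD = 3.84
BACKWARD_THRESHOLD = 6.64

_PARAMETERS = ("Ka", "V", "CL")
_CONTINUOUS = ("AGE", "WT", "HT", "BMI")
_CATEGORICAL = ("SEX",)


@dataclass(frozen=True)
class CovariateEffect:
    """A single multiplicative covariate effect on one structural parameter.

    ``form`` is "power" for continuous covariates (requires ``cov_median``)
    or "indicator" for categorical ones (``level`` holds the coded category,
    female = 1 by package convention).  ``theta_x`` is the effect
    coefficient; 0 means no effect.
    """

    parameter: str
    covariate: str
    form: str
    theta_x: float = 0.0
    cov_median: float | None = None
    level: float = 1.0

    def __post_init__(self) -> None:
        if self.parameter not in _PARAMETERS:
            raise ValueError(f"parameter must be one of {_PARAMETERS}, got {self.parameter!r}")
        if self.form not in ("power", "indicator"):
            raise ValueError(f"form must be 'power' or 'indicator', got {self.form!r}")
        if self.form == "power":
            if self.cov_median is None or self.cov_median <= 0:
                raise ValueError("power form requires cov_median > 0")

    @property
    def name(self) -> str:
        return f"beta_{self.parameter}_{self.covariate}"

    def multiplier(self, covariates: Mapping[str, float], theta_x: float | None = None) -> float:
        """Multiplicative adjustment for one subject's covariate values."""
        if self.covariate not in covariates:
            raise KeyError(f"subject lacks covariate {self.covariate!r}")
        tx = self.theta_x if theta_x is None else theta_x
        value = covariates[self.covariate]
        if self.form == "power":
            return float((value / self.cov_median) ** tx)
        return float(np.exp(tx * (value == self.level)))


def apply_effect(base_value: float, effect: CovariateEffect, covariates: Mapping[str, float]) -> float:
    """Adjust one parameter value for one subject per the effect's form."""
    return base_value * effect.multiplier(covariates)


def apply_effects(
    theta: ThetaVector,
    effects: Sequence[CovariateEffect],
    covariates: Mapping[str, float],
) -> ThetaVector:
    """Apply a set of covariate effects to the typical values for one subject."""
    if not effects:
        return theta
    vals = {"Ka": theta.tvKa, "V": theta.tvV, "CL": theta.tvCL}
    for eff in effects:
        vals[eff.parameter] = apply_effect(vals[eff.parameter], eff, covariates)
    return ThetaVector(tvKa=vals["Ka"], tvV=vals["V"], tvCL=vals["CL"])


def default_candidates(dataset: Dataset) -> list[CovariateEffect]:
    """The full screening grid: 5 covariates x 3 parameters.

    Continuous covariates take the power form with the median frozen from the
    dataset at grid-construction time; sex takes the indicator form.
    """
    grid: list[CovariateEffect] = []
    for par in _PARAMETERS:
        for cov in _CONTINUOUS:
            grid.append(
                CovariateEffect(par, cov, "power", 0.0, cov_median=dataset.covariate_median(cov))
            )
        for cov in _CATEGORICAL:
            grid.append(CovariateEffect(par, cov, "indicator", 0.0))
    return grid


@dataclass(frozen=True)
class TraceEntry:
    phase: str  # "forward" | "backward"
    effect: CovariateEffect
    ofv_before: float
    ofv_after: float
    decision: str  # "added" | "removed" | "rejected" | "retained" | "skipped"
    iiv_change: dict[str, float] = field(default_factory=dict)

    @property
    def delta_ofv(self) -> float:
        return self.ofv_before - self.ofv_after


@dataclass
class StepwiseTrace:
    """Ordered record of every candidate evaluation plus the final model."""

    entries: list[TraceEntry] = field(default_factory=list)
    final_effects: tuple[CovariateEffect, ...] = ()
    final_fit: object | None = None

    def to_frame(self):
        import pandas as pd

        rows = []
        for k, e in enumerate(self.entries):
            rows.append(
                {
                    "step": k,
                    "phase": e.phase,
                    "effect": e.effect.name,
                    "ofv_before": e.ofv_before,
                    "ofv_after": e.ofv_after,
                    "delta_ofv": e.delta_ofv,
                    "decision": e.decision,
                }
            )
        return pd.DataFrame(rows)


def _candidate_key(effect: CovariateEffect) -> tuple[str, str]:
    return (effect.parameter, effect.covariate)


def _refit_with_effects(dataset, base_fit, effects, settings):
    """Refit the model with a given effect set, warm-started from base_fit."""
    from .estimation import InitialEstimates, OneCompartmentPk, fit

    model = OneCompartmentPk(
        effects=tuple(effects),
        truncate_at_removal=base_fit.model.truncate_at_removal,
    )
    betas = {e.name: e.theta_x for e in effects}
    for e in effects:  # carry over previously estimated coefficients
        if e.name in base_fit.betas:
            betas[e.name] = base_fit.betas[e.name]
    init = InitialEstimates(
        theta=base_fit.theta, omega=base_fit.omega, residual=base_fit.residual, betas=betas
    )
    return fit(dataset, init, settings=settings, model=model)


def forward_step(current_fit, dataset: Dataset, candidates: Sequence[CovariateEffect], settings=None):
    """Try each remaining candidate; return (best fit or None, trace entries).

    The candidate with the largest OFV drop is added if the drop exceeds the
    forward threshold; ties break on larger drop, then lexicographic
    (parameter, covariate) order.  Candidates whose fit fails are skipped
    with a warning.
    """
    in_model = {_candidate_key(e) for e in current_fit.model.effects}
    entries: list[TraceEntry] = []
    best = None  # (delta, key, fit, effect)
    for cand in sorted(candidates, key=_candidate_key):
        if _candidate_key(cand) in in_model:
            continue
        try:
            cand_fit = _refit_with_effects(
                dataset, current_fit, tuple(current_fit.model.effects) + (cand,), settings
            )
        except Exception as exc:  # fit failure: skip, keep searching
            logger.warning("candidate %s skipped: %s", cand.name, exc)
            entries.append(TraceEntry("forward", cand, current_fit.ofv, float("nan"), "skipped"))
            continue
        delta = current_fit.ofv - cand_fit.ofv
        fitted = replace(cand, theta_x=cand_fit.betas[cand.name])
        entries.append(
            TraceEntry(
                "forward",
                fitted,
                current_fit.ofv,
                cand_fit.ofv,
                "candidate",
                iiv_change=_iiv_change(current_fit, cand_fit),
            )
        )
        if delta > FORWARD_THRESHOLD:
            key = _candidate_key(cand)
            if best is None or delta > best[0] or (delta == best[0] and key < best[1]):
                best = (delta, key, cand_fit, fitted)
    if best is None:
        return None, entries
    delta, key, cand_fit, fitted = best
    entries.append(
        TraceEntry("forward", fitted, current_fit.ofv, cand_fit.ofv, "added")
    )
    return cand_fit, entries


def backward_step(current_fit, dataset: Dataset, settings=None):
    """Drop the weakest effect whose removal raises OFV by <= the threshold.

    Returns (fit without that effect or None, trace entries); one removal per
    call, weakest (smallest OFV increase) first.
    """
    effects = tuple(current_fit.model.effects)
    if not effects:
        return None, []
    entries: list[TraceEntry] = []
    weakest = None  # (increase, key, fit, effect)
    for eff in sorted(effects, key=_candidate_key):
        reduced = tuple(e for e in effects if e is not eff)
        try:
            red_fit = _refit_with_effects(dataset, current_fit, reduced, settings)
        except Exception as exc:
            logger.warning("removal of %s skipped: %s", eff.name, exc)
            entries.append(TraceEntry("backward", eff, current_fit.ofv, float("nan"), "skipped"))
            continue
        increase = red_fit.ofv - current_fit.ofv
        entries.append(TraceEntry("backward", eff, current_fit.ofv, red_fit.ofv, "candidate"))
        if increase <= BACKWARD_THRESHOLD:
            key = _candidate_key(eff)
            if weakest is None or increase < weakest[0] or (increase == weakest[0] and key < weakest[1]):
                weakest = (increase, key, red_fit, eff)
    if weakest is None:
        for eff in effects:
            entries.append(TraceEntry("backward", eff, current_fit.ofv, current_fit.ofv, "retained"))
        return None, entries
    _, _, red_fit, eff = weakest
    entries.append(TraceEntry("backward", eff, current_fit.ofv, red_fit.ofv, "removed"))
    return red_fit, entries


def run_stepwise(
    dataset: Dataset,
    base_fit,
    candidates: Sequence[CovariateEffect] | None = None,
    settings=None,
) -> StepwiseTrace:
    """Full stepwise search: forward inclusion to exhaustion, then backward
    elimination to stability.  Deterministic given the dataset and fit
    settings."""
    if candidates is None:
        candidates = default_candidates(dataset)
    trace = StepwiseTrace()
    current = base_fit
    while True:
        nxt, entries = forward_step(current, dataset, candidates, settings=settings)
        trace.entries.extend(entries)
        if nxt is None:
            break
        current = nxt
    while current.model.effects:
        nxt, entries = backward_step(current, dataset, settings=settings)
        trace.entries.extend(entries)
        if nxt is None:
            break
        current = nxt
    trace.final_effects = tuple(
        replace(e, theta_x=current.betas[e.name]) for e in current.model.effects
    )
    trace.final_fit = current
    return trace


def _iiv_change(fit_before, fit_after) -> dict[str, float]:
    """Change in random-effect variances (diagnostic only, never a gate)."""
    before = fit_before.omega.as_dict()
    after = fit_after.omega.as_dict()
    return {k: after[k] - before[k] for k in before}
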