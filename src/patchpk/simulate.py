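"""Synthetic dataset generation mirroring the five GTDS clinical designs.

The granisetron patch program pooled four Caucasian healthy-volunteer trials
(112 subjects, 34.3 mg single application, wear 6-9 days, fixed nominal
sampling schedules) and one Chinese trial (24 male subjects, 6-day wear).
The raw concentration data are not public, so this module generates datasets
with the same statistical structure: the published designs and demographic
summaries, concentrations from the one-compartment transdermal model with
lognormal inter-individual variability, residual error, and censoring below
the lower limit of quantification.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import CovariateEffect, apply_effects
from .data import (
    Dataset,
    DemographicsSpec,
    Observation,
    OmegaMatrix,
    ResidualSpec,
    StudyDesign,
    Subject,
    ThetaVector,
)
from .model import individual_params, profile
from .reference import DEFAULT_LLOQ, PATCH_DOSE_NG, reference_model

__all__ = [
    "builtin_designs",
    "builtin_demographics",
    "caucasian_design_codes",
    "sample_demographics",
    "simulate_dataset",
    "scenario",
    "TRUNCATION_BOUNDS",
]

# physiologic truncation bounds for demographic draws (value ranges a healthy
# volunteer trial would plausibly enroll)
TRUNCATION_BOUNDS = {
    "AGE": (18.0, 85.0),
    "WT": (40.0, 150.0),
    "HT": (140.0, 210.0),
    "BMI": (16.0, 45.0),
}


def builtin_designs() -> dict[str, StudyDesign]:
    """The five trial designs: code -> StudyDesign.

    Wear duration follows the "(N days)" dosing regimen column; sampling
    schedules are the published nominal times including the pre-dose sample.
    The Chinese SP-0102 arm lists 14 nominal times; the derived per-study
    sample counts are n_subjects x n_times.
    """
    d = PATCH_DOSE_NG
    designs = [
        StudyDesign(
            "392MD/11/C", 12, d, 144.0, (0.0, 6, 12, 24, 48, 72, 96, 120)
        ),
        StudyDesign(
            "392MD/26/C", 24, d, 168.0, (0.0, 8, 24, 48, 72, 96, 120, 144, 168)
        ),
        StudyDesign(
            "392MD/40/C",
            60,
            d,
            216.0,
            (0.0, 8, 24, 48, 72, 96, 120, 144, 168, 192, 216),
        ),
        StudyDesign(
            "392MD/43/C",
            16,
            d,
            192.0,
            (
                0.0, 1, 2, 3, 4, 6, 8, 24, 25, 26, 27, 28, 30,
                48, 49, 50, 51, 52, 54, 72, 96, 120, 144, 168, 192,
            ),
        ),
        StudyDesign(
            "SP-0102",
            24,
            d,
            144.0,
            (0.0, 6, 12, 24, 48, 72, 96, 120, 144, 150, 168, 192, 216, 240),
        ),
    ]
    return {x.code: StudyDesign(x.code, x.n_subjects, x.dose_ng, x.wear_h, tuple(float(t) for t in x.sampling_times_h)) for x in designs}


def caucasian_design_codes() -> tuple[str, ...]:
    """The four Caucasian trial arms pooled for model building."""
    return ("392MD/11/C", "392MD/26/C", "392MD/40/C", "392MD/43/C")


def builtin_demographics() -> dict[str, DemographicsSpec]:
    """Published demographic summaries (mean, SD, female fraction) per study."""
    return {
        "392MD/43/C": DemographicsSpec(31.06, 7.86, 64.41, 9.73, 166.50, 7.4, 23.14, 2.24, 0.50),
        "392MD/40/C": DemographicsSpec(49.53, 20.6, 71.83, 19.0, 168.15, 9.5, 25.19, 5.43, 0.4667),
        "392MD/26/C": DemographicsSpec(37.63, 10.2, 68.27, 12.0, 170.63, 10.0, 23.32, 2.58, 0.50),
        "392MD/11/C": DemographicsSpec(37.08, 4.62, 76.84, 8.67, 178.08, 3.6, 24.24, 2.69, 0.0),
        "SP-0102": DemographicsSpec(27.13, 4.07, 65.07, 5.67, 169.88, 6.16, 22.56, 1.69, 0.0),
    }


def _truncnorm_draw(rng, mean, sd, lo, hi, n):
    """Truncated-normal draws whose mean equals the published summary mean.

    Truncating an off-center normal shifts its mean, so the location is
    moment-matched (1-D root find) before sampling; the realized SD shrinks
    slightly relative to the published value, which asymmetric physiologic
    bounds make unavoidable.
    """
    if sd == 0:
        return np.full(n, float(mean))

    def truncated_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    try:
        from scipy.optimize import brentq

        loc = brentq(lambda L: truncated_mean(L) - mean, mean - 6 * sd, mean + 6 * sd)
    except ValueError:
        loc = mean
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def sample_demographics(
    spec: DemographicsSpec,
    n: int,
    seed: int | np.random.Generator = 0,
    recompute_bmi: bool = False,
) -> pd.DataFrame:
    """Draw n subjects' covariates (AGE, WT, HT, BMI, SEX) from a study spec.

    Continuous covariates are truncated-normal at physiologic bounds; SEX is
    Bernoulli on the female fraction (0 = male, 1 = female).  With
    ``recompute_bmi`` BMI is derived from the drawn weight and height instead
    of sampled marginally.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    age = _truncnorm_draw(rng, spec.age_mean, spec.age_sd, *TRUNCATION_BOUNDS["AGE"], n)
    wt = _truncnorm_draw(rng, spec.weight_mean, spec.weight_sd, *TRUNCATION_BOUNDS["WT"], n)
    ht = _truncnorm_draw(rng, spec.height_mean, spec.height_sd, *TRUNCATION_BOUNDS["HT"], n)
    if recompute_bmi:
        bmi = wt / (ht / 100.0) ** 2
    else:
        bmi = _truncnorm_draw(rng, spec.bmi_mean, spec.bmi_sd, *TRUNCATION_BOUNDS["BMI"], n)
    sex = (rng.random(n) < spec.female_fraction).astype(float)
    return pd.DataFrame({"AGE": age, "WT": wt, "HT": ht, "BMI": bmi, "SEX": sex})


def simulate_dataset(
    theta: ThetaVector,
    omega: OmegaMatrix,
    residual: ResidualSpec,
    designs: Sequence[StudyDesign] | Mapping[str, StudyDesign] | StudyDesign,
    demographics: Mapping[str, DemographicsSpec] | None = None,
    lloq: float | None = DEFAULT_LLOQ,
    seed: int | np.random.Generator = 0,
    effects: Sequence[CovariateEffect] = (),
    truncate_at_removal: bool = True,
    recompute_bmi: bool = False,
    add_residual: bool = True,
) -> Dataset:
    """Simulate a full multi-study dataset from a population model.

    Per subject: draw covariates from the study's demographic spec, draw
    eta ~ N(0, Omega), apply any covariate effects multiplicatively, evaluate
    the concentration profile at the design's nominal times, add residual
    error, and censor values below ``lloq`` (and the pre-dose sample) as BLQ.
    ``lloq=None`` disables quantification-limit censoring entirely (every
    post-dose sample is kept, including sub-zero noisy draws), which is the
    right setting for estimator self-consistency experiments where dropping
    low records would itself bias the refit.  Deterministic for a fixed seed.
    """
    if isinstance(designs, StudyDesign):
        designs = [designs]
    elif isinstance(designs, Mapping):
        designs = list(designs.values())
    demographics = demographics if demographics is not None else builtin_demographics()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd_eta = np.sqrt(omega.diagonal())
    subjects: list[Subject] = []
    for design in designs:
        n = design.n_subjects
        demo_spec = demographics.get(design.code) if hasattr(demographics, "get") else None
        if demo_spec is not None:
            cov_table = sample_demographics(demo_spec, n, rng, recompute_bmi=recompute_bmi)
        else:
            cov_table = None
        etas = rng.standard_normal((n, 3)) * sd_eta
        times = np.asarray(design.sampling_times_h, dtype=float)
        dose = design.dose_event()
        for i in range(n):
            covs = (
                {k: float(cov_table[k].iloc[i]) for k in cov_table.columns}
                if cov_table is not None
                else {}
            )
            th_i = apply_effects(theta, effects, covs)
            p = individual_params(th_i, etas[i])
            conc = profile(p, dose, times, truncate_at_removal)
            if add_residual:
                noisy = conc + _residual_draws(rng, residual, conc)
            else:
                noisy = conc.copy()
            obs = []
            for t, c in zip(times, noisy):
                predose = t <= dose.t_apply
                if predose or (lloq is not None and c < lloq):
                    obs.append(Observation(time=float(t), blq=True, nominal_time=float(t)))
                else:
                    obs.append(Observation(time=float(t), conc=float(c), nominal_time=float(t)))
            subjects.append(
                Subject(
                    id=f"{design.code}-{i + 1:03d}",
                    dose=dose,
                    observations=obs,
                    covariates=covs,
                    study=design.code,
                    eta_true=tuple(float(e) for e in etas[i]),
                )
            )
    return Dataset(subjects)


def _residual_draws(rng, residual: ResidualSpec, pred: np.ndarray) -> np.ndarray:
    sd = np.sqrt(residual.variance(pred))
    return rng.standard_normal(pred.shape) * sd


def scenario(name: str, seed: int = 0, **overrides):
    """Named simulation presets used in examples, tests and the CLI.

    ``caucasian``      : the four pooled Caucasian designs, no covariate effects
    ``chinese-design`` : the SP-0102 design simulated from the reference model
    ``weight-on-cl``   : Caucasian designs with a planted power effect of
                         weight on clearance (exponent 0.75)
    ``cl-halved``      : Caucasian model with clearance halved (mis-scaled
                         population for discriminative checks)
    """
    theta, omega, residual = reference_model()
    designs = builtin_designs()
    if name == "caucasian":
        chosen = [designs[c] for c in caucasian_design_codes()]
        effects: tuple[CovariateEffect, ...] = ()
    elif name == "chinese-design":
        chosen = [designs["SP-0102"]]
        effects = ()
    elif name == "weight-on-cl":
        chosen = [designs[c] for c in caucasian_design_codes()]
        effects = (
            CovariateEffect(parameter="CL", covariate="WT", form="power", theta_x=0.75, cov_median=70.0),
        )
    elif name == "cl-halved":
        theta = ThetaVector(theta.tvKa, theta.tvV, theta.tvCL / 2.0)
        chosen = [designs[c] for c in caucasian_design_codes()]
        effects = ()
    else:
        raise ValueError(f"unknown scenario {name!r}")
    kwargs = dict(seed=seed, effects=effects)
    kwargs.update(overrides)
    return simulate_dataset(theta, omega, residual, chosen, **kwargs)
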