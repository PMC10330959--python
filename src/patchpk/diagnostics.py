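"""Model qualification: goodness-of-fit, nonparametric bootstrap, VPC.

The goodness-of-fit table carries population predictions (PRED, eta = 0),
individual predictions (IPRED, eta at the conditional mode) and conditional
weighted residuals (CWRES) which are ~N(0, 1) under a correctly specified
model.  The bootstrap resamples subjects with replacement (stratified by
study by default, preserving the design mix) and refits each replicate.
The visual predictive check simulates full-design replicates from the fitted
model and overlays simulated percentile bands on observed percentiles at the
nominal sampling times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset, Subject
from .estimation import (
    FitResult,
    FitSettings,
    InitialEstimates,
    _as_omega_vector,
    _subject_foce,
    _cwres,
    fit,
)
from .reference import DEFAULT_LLOQ

__all__ = ["GofTable", "BootstrapResult", "VpcResult", "gof", "bootstrap", "vpc"]

logger = logging.getLogger(__name__)


@dataclass
class GofTable:
    """Per-observation diagnostics (non-BLQ rows only)."""

    table: pd.DataFrame  # columns: ID, TIME, DV, PRED, IPRED, CWRES

    def cwres(self) -> np.ndarray:
        return self.table["CWRES"].to_numpy()


def gof(fit_result: FitResult, dataset: Dataset) -> GofTable:
    """Recompute the goodness-of-fit table for a fit on its dataset.

    PRED evaluates the model at eta = 0, IPRED at each subject's conditional
    mode; CWRES standardizes the FOCE-linearized residual by the symmetric
    inverse square root of V = F Omega F' + R.
    """
    model = fit_result.model
    params = dict(fit_result.params)
    om = _as_omega_vector(fit_result.omega, len(model.eta_names))
    rows = []
    for s in dataset:
        if not s.quantifiable:
            continue
        _, _, extras = _subject_foce(
            s, params, om, fit_result.residual, model,
            eta0=fit_result.eta.get(s.id), need_gof=True,
        )
        pred0 = model.predict(s, params, np.zeros(len(model.eta_names)), extras["times"])
        cw = _cwres(extras)
        for t, yv, pr, ip, c in zip(extras["times"], extras["y"], pred0, extras["f"], cw):
            rows.append({"ID": s.id, "TIME": t, "DV": yv, "PRED": pr, "IPRED": ip, "CWRES": c})
    table = pd.DataFrame(rows)
    if not np.all(np.isfinite(table["CWRES"].to_numpy())):
        raise RuntimeError("non-finite CWRES encountered")
    return GofTable(table=table)


@dataclass
class BootstrapResult:
    """Percentile summary of bootstrap refits."""

    estimates: dict[str, float]  # original point estimates
    replicates: pd.DataFrame  # one row per converged replicate
    n_requested: int
    n_converged: int
    seed: int

    def summary(self, level: float = 95.0) -> pd.DataFrame:
        lo, hi = (100 - level) / 2, 100 - (100 - level) / 2
        rows = []
        for name in self.replicates.columns:
            vals = self.replicates[name].to_numpy()
            rows.append(
                {
                    "parameter": name,
                    "estimate": self.estimates.get(name, np.nan),
                    "boot_mean": float(np.mean(vals)),
                    f"p{lo:g}": float(np.percentile(vals, lo)),
                    f"p{hi:g}": float(np.percentile(vals, hi)),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def interval(self, name: str, level: float = 95.0) -> tuple[float, float]:
        vals = self.replicates[name].to_numpy()
        lo, hi = (100 - level) / 2, 100 - (100 - level) / 2
        return float(np.percentile(vals, lo)), float(np.percentile(vals, hi))


def _resample_ids(dataset: Dataset, rng, stratify: bool) -> list[str]:
    if stratify:
        ids: list[str] = []
        studies: dict[str, list[str]] = {}
        for s in dataset:
            studies.setdefault(s.study, []).append(s.id)
        for study in sorted(studies):
            pool = studies[study]
            ids.extend(rng.choice(pool, size=len(pool), replace=True).tolist())
        return ids
    pool = [s.id for s in dataset]
    return rng.choice(pool, size=len(pool), replace=True).tolist()


def bootstrap(
    dataset: Dataset,
    fit_result: FitResult,
    n_boot: int = 1000,
    seed: int = 0,
    stratify: bool = True,
    settings: FitSettings | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap of the population fit.

    Subjects are resampled with replacement (same count per stratum) and each
    replicate is refit starting from the original final estimates.
    Non-converged replicates are logged and excluded; the convergence count
    is reported.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    settings = settings or FitSettings(compute_rse=False, final_gof=False)
    by_id = {s.id: s for s in dataset}
    init = InitialEstimates(
        theta=fit_result.theta,
        omega=fit_result.omega,
        residual=fit_result.residual,
        betas=dict(fit_result.betas),
    )
    rows = []
    n_converged = 0
    for b in range(n_boot):
        ids = _resample_ids(dataset, rng, stratify)
        subjects = []
        for k, sid in enumerate(ids):
            src = by_id[sid]
            subjects.append(
                Subject(
                    id=f"{sid}#r{k}",
                    dose=src.dose,
                    observations=src.observations,
                    covariates=src.covariates,
                    study=src.study,
                )
            )
        replicate = Dataset(subjects)
        try:
            res = fit(replicate, init, settings=settings, model=fit_result.model)
        except Exception as exc:
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            continue
        if not res.converged:
            logger.warning("bootstrap replicate %d did not converge; excluded", b)
            continue
        n_converged += 1
        rows.append(dict(res.params))
    return BootstrapResult(
        estimates=dict(fit_result.params),
        replicates=pd.DataFrame(rows),
        n_requested=n_boot,
        n_converged=n_converged,
        seed=seed,
    )


@dataclass
class VpcResult:
    """Simulated and observed percentile curves at the nominal design times."""

    times: np.ndarray
    sim_p5: np.ndarray
    sim_p50: np.ndarray
    sim_p95: np.ndarray
    obs_p5: np.ndarray
    obs_p50: np.ndarray
    obs_p95: np.ndarray
    n_obs_per_time: np.ndarray
    sparse_times: list[float]  # nominal times with < 3 observations
    n_rep: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "sim_p5": self.sim_p5,
                "sim_p50": self.sim_p50,
                "sim_p95": self.sim_p95,
                "obs_p5": self.obs_p5,
                "obs_p50": self.obs_p50,
                "obs_p95": self.obs_p95,
                "n_obs": self.n_obs_per_time,
            }
        )

    def observed_median_coverage(self) -> float:
        """Fraction of nominal times where the observed median lies inside
        the simulated 5th-95th band."""
        inside = (self.obs_p50 >= self.sim_p5) & (self.obs_p50 <= self.sim_p95)
        ok = np.isfinite(self.obs_p50)
        return float(np.mean(inside[ok]))


def vpc(
    fit_result: FitResult,
    dataset: Dataset,
    n_rep: int = 1000,
    seed: int = 0,
    lloq: float = DEFAULT_LLOQ,
) -> VpcResult:
    """Visual predictive check at the nominal design times (no binning).

    ``n_rep`` full-design replicates are simulated with inter-individual
    variability and residual error at the estimated parameters; simulated
    values below the LLOQ are censored and excluded from the percentiles,
    matching observed-data handling.
    """
    model = fit_result.model
    params = dict(fit_result.params)
    om = _as_omega_vector(fit_result.omega, len(model.eta_names))
    sd_eta = np.sqrt(om)
    rng = np.random.default_rng(seed)
    nominal: dict[float, list] = {}
    observed: dict[float, list] = {}
    for s in dataset:
        post = [o for o in s.observations if o.time > s.dose.t_apply]
        if not post:
            continue
        times = np.array([o.time for o in post])
        nominals = np.array([o.nominal_time for o in post])
        etas = rng.standard_normal((n_rep, len(model.eta_names))) * sd_eta
        sims = np.empty((n_rep, times.size))
        for r in range(n_rep):
            sims[r] = model.predict(s, params, etas[r], times)
        noise = rng.standard_normal(sims.shape) * np.sqrt(
            fit_result.residual.variance(sims)
        )
        sims = sims + noise
        sims[sims < lloq] = np.nan
        for j, tn in enumerate(nominals):
            nominal.setdefault(float(tn), []).append(sims[:, j])
        for o in post:
            if not o.blq:
                observed.setdefault(float(o.nominal_time), []).append(o.conc)
    times_sorted = np.array(sorted(nominal))
    sim_p = {5: [], 50: [], 95: []}
    obs_p = {5: [], 50: [], 95: []}
    n_obs = []
    sparse = []
    for t in times_sorted:
        vals = np.concatenate(nominal[t])
        vals = vals[np.isfinite(vals)]
        for q in (5, 50, 95):
            sim_p[q].append(np.percentile(vals, q) if vals.size else np.nan)
        ov = np.array(observed.get(t, []), dtype=float)
        n_obs.append(ov.size)
        if ov.size < 3:
            sparse.append(float(t))
        for q in (5, 50, 95):
            obs_p[q].append(np.percentile(ov, q) if ov.size else np.nan)
    return VpcResult(
        times=times_sorted,
        sim_p5=np.array(sim_p[5]),
        sim_p50=np.array(sim_p[50]),
        sim_p95=np.array(sim_p[95]),
        obs_p5=np.array(obs_p[5]),
        obs_p50=np.array(obs_p[50]),
        obs_p95=np.array(obs_p[95]),
        n_obs_per_time=np.array(n_obs),
        sparse_times=sparse,
        n_rep=n_rep,
        seed=seed,
    )
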