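"""Noncompartmental exposure metrics for single-profile concentration data.

AUC_last uses the linear trapezoid rule over quantifiable samples up to the
last quantifiable time; BLQ records are skipped, except that a leading
pre-dose BLQ anchors the curve at (0, 0).  Cmax is the maximum quantifiable
concentration with Tmax the earliest time achieving it.  Cavg defaults to
AUC_last / t_last_q; an alternative definition (AUC over the patch wear
interval divided by the wear duration) is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset

__all__ = ["NCAResult", "nca_compute", "nca_table"]


@dataclass(frozen=True)
class NCAResult:
    auc_last: float  # ng*h/mL
    cmax: float  # ng/mL
    tmax: float  # h
    cavg: float  # ng/mL
    t_last_q: float  # h


def nca_compute(
    times: np.ndarray,
    concs: np.ndarray,
    blq: np.ndarray | None = None,
    wear_duration: float | None = None,
    cavg_mode: str = "tlast",
) -> NCAResult:
    """Compute NCA metrics for one profile.

    ``concs`` entries at BLQ positions are ignored (may be NaN).  With
    ``cavg_mode="wear"`` the average concentration is AUC over
    [0, wear_duration] divided by the wear duration (linear interpolation at
    the boundary); the default normalizes AUC_last by the last quantifiable
    time.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if blq is None:
        blq = ~np.isfinite(concs)
    blq = np.asarray(blq, dtype=bool)
    if times.shape != concs.shape or times.shape != blq.shape:
        raise ValueError("times, concs and blq must have matching shapes")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")
    q = ~blq
    tq = times[q]
    cq = concs[q]
    if tq.size == 0:
        raise ValueError("all-BLQ profile: no quantifiable samples")
    # leading pre-dose BLQ contributes a zero anchor at t = 0
    if np.any(blq & (times < tq[0])):
        tq = np.concatenate([[0.0], tq])
        cq = np.concatenate([[0.0], cq])
    if tq.size < 2:
        raise ValueError("need at least 2 points to form a trapezoid")
    auc_last = float(np.trapezoid(cq, tq))
    # Cmax/Tmax over quantifiable samples only (the zero anchor is excluded)
    cq_obs = concs[q]
    tq_obs = times[q]
    imax = int(np.argmax(cq_obs))
    cmax = float(cq_obs[imax])
    tmax = float(tq_obs[np.flatnonzero(cq_obs == cmax)[0]])
    t_last_q = float(tq_obs[-1])
    if cavg_mode == "tlast":
        cavg = auc_last / t_last_q if t_last_q > 0 else float("nan")
    elif cavg_mode == "wear":
        if wear_duration is None or wear_duration <= 0:
            raise ValueError('cavg_mode="wear" requires a positive wear_duration')
        cavg = _auc_to(tq, cq, wear_duration) / wear_duration
    else:
        raise ValueError(f"unknown cavg_mode {cavg_mode!r}")
    return NCAResult(auc_last=auc_last, cmax=cmax, tmax=tmax, cavg=cavg, t_last_q=t_last_q)


def _auc_to(t: np.ndarray, c: np.ndarray, t_end: float) -> float:
    """Trapezoidal AUC from the first point to ``t_end`` with linear
    interpolation at the boundary; no extrapolation past the last point."""
    if t_end >= t[-1]:
        return float(np.trapezoid(c, t))
    c_end = float(np.interp(t_end, t, c))
    keep = t < t_end
    tt = np.concatenate([t[keep], [t_end]])
    cc = np.concatenate([c[keep], [c_end]])
    return float(np.trapezoid(cc, tt))


def nca_table(dataset: Dataset, cavg_mode: str = "tlast") -> pd.DataFrame:
    """Batch NCA over a dataset: one row per subject."""
    rows = []
    for s in dataset:
        times = s.times(include_blq=True)
        concs = np.array(
            [o.conc if not o.blq else np.nan for o in s.observations], dtype=float
        )
        blq = np.array([o.blq for o in s.observations], dtype=bool)
        res = nca_compute(times, concs, blq, wear_duration=s.dose.wear_h, cavg_mode=cavg_mode)
        rows.append(
            {
                "ID": s.id,
                "STUDY": s.study,
                "auc_last": res.auc_last,
                "cmax": res.cmax,
                "tmax": res.tmax,
                "cavg": res.cavg,
                "t_last_q": res.t_last_q,
            }
        )
    return pd.DataFrame(rows)
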