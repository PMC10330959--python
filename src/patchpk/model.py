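"""One-compartment transdermal PK model with patch-depot first-order absorption.

The structural model is the linear ODE system

    dAa/dt = -Ka * Aa                 (depot, charged with the patch load)
    dA1/dt =  Ka * Aa - (CL/V) * A1   (central compartment)
    C      =  A1 / V                  (plasma concentration, ng/mL)

solved in closed form.  Patch removal at ``t_remove`` discards the unabsorbed
depot by default (the reservoir leaves with the patch), after which the
central compartment washes out mono-exponentially; setting
``truncate_at_removal=False`` lets the depot keep draining for the full
record.  A high-accuracy ODE evaluator and a two-compartment alternative are
provided for cross-checking and model discrimination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .data import DoseEvent, IndividualParams, ModelState, ThetaVector

__all__ = [
    "individual_params",
    "concentration",
    "profile",
    "model_state",
    "analytic_peak",
    "TwoCompartmentParams",
    "two_compartment_profile",
    "ode_concentration",
]

# switchover to the ka == ke limit form to avoid catastrophic cancellation
_KA_KE_RTOL = 1e-10


def individual_params(
    theta: ThetaVector, eta: tuple[float, float, float] | np.ndarray
) -> IndividualParams:
    """Realize one subject's parameters as typical value times exp(eta).

    Ka = tvKa * exp(eta_Ka), V = tvV * exp(eta_V), CL = tvCL * exp(eta_CL).
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (3,):
        raise ValueError(f"eta must have three components (Ka, V, CL), got shape {eta.shape}")
    if not np.all(np.isfinite(eta)):
        raise ValueError(f"eta must be finite, got {eta}")
    return IndividualParams(
        Ka=theta.tvKa * math.exp(eta[0]),
        V=theta.tvV * math.exp(eta[1]),
        CL=theta.tvCL * math.exp(eta[2]),
        eta=tuple(float(e) for e in eta),
    )


def _conc_during_wear(ka, ke, V, amount, tp):
    """Closed-form concentration while the patch is on; tp = t - t_apply >= 0."""
    ka = np.asarray(ka, dtype=float)
    ke = np.asarray(ke, dtype=float)
    diff = ka - ke
    near = np.abs(diff) < _KA_KE_RTOL * ka
    safe = np.where(near, 1.0, diff)
    general = amount * ka / (V * safe) * (np.exp(-ke * tp) - np.exp(-ka * tp))
    limit = amount * ka * tp * np.exp(-ka * tp) / V
    return np.where(near, limit, general)


def _conc_arrays(ka, ke, V, amount, t, t_apply, t_remove, truncate):
    """Vectorized concentration; all of ka/ke/V/amount/t broadcast together."""
    tp = t - t_apply
    c_on = _conc_during_wear(ka, ke, V, amount, np.maximum(tp, 0.0))
    if truncate:
        wear = t_remove - t_apply
        c_rem = _conc_during_wear(ka, ke, V, amount, wear)
        c_off = c_rem * np.exp(-ke * np.maximum(t - t_remove, 0.0))
        c = np.where(t > t_remove, c_off, c_on)
    else:
        c = c_on
    return np.where(tp < 0, 0.0, c)


def concentration(
    params: IndividualParams,
    dose: DoseEvent,
    t: float | np.ndarray,
    truncate_at_removal: bool = True,
) -> float | np.ndarray:
    """Plasma concentration (ng/mL) at time ``t`` hours.

    Returns 0 before patch application.  While the patch is worn the standard
    first-order absorption solution applies; when ``|Ka - ke|`` falls below a
    relative threshold the degenerate limit ``D*Ka*t'*exp(-Ka*t')/V`` is used.
    With ``truncate_at_removal`` the depot is discarded at ``t_remove`` and
    the concentration decays mono-exponentially from its removal-time value.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("negative time before any dose")
    out = _conc_arrays(
        params.Ka,
        params.ke,
        params.V,
        dose.amount,
        t_arr,
        dose.t_apply,
        dose.t_remove,
        truncate_at_removal,
    )
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def profile(
    params: IndividualParams,
    dose: DoseEvent,
    times: np.ndarray,
    truncate_at_removal: bool = True,
) -> np.ndarray:
    """Concentration profile over a non-decreasing time grid."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must not be empty")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")
    return np.asarray(
        concentration(params, dose, times, truncate_at_removal), dtype=float
    ).reshape(times.shape)


def model_state(
    params: IndividualParams,
    dose: DoseEvent,
    t: float,
    truncate_at_removal: bool = True,
) -> ModelState:
    """Amounts (ng) in depot, central compartment and eliminated at time ``t``.

    Before removal mass balance holds: Aa + A1 + A0 equals the patch load.
    With truncation, removal discards the remaining depot, so the total drops
    by the unabsorbed amount at ``t_remove``.
    """
    if t < dose.t_apply:
        return ModelState(Aa=dose.amount if t >= dose.t_apply else 0.0, A1=0.0, A0=0.0)
    ka, ke, V = params.Ka, params.ke, params.V
    t_eff = min(t, dose.t_remove) if truncate_at_removal else t
    tp = t_eff - dose.t_apply
    Aa = dose.amount * math.exp(-ka * tp)
    A1 = float(_conc_during_wear(ka, ke, V, dose.amount, np.asarray(tp, dtype=float))) * V
    A0 = dose.amount - Aa - A1
    if truncate_at_removal and t > dose.t_remove:
        dt = t - dose.t_remove
        A1_end = A1 * math.exp(-ke * dt)
        A0 += A1 - A1_end  # depot Aa leaves with the patch
        return ModelState(Aa=0.0, A1=A1_end, A0=A0)
    return ModelState(Aa=Aa, A1=A1, A0=A0)


def analytic_peak(
    params: IndividualParams,
    dose: DoseEvent,
    truncate_at_removal: bool = True,
) -> tuple[float, float]:
    """Time (h, absolute) and value (ng/mL) of the concentration maximum.

    The unconstrained peak of the first-order absorption curve sits at
    ``ln(Ka/ke)/(Ka - ke)`` after application (limit 1/Ka when Ka == ke); if
    the patch comes off earlier and truncation applies, the maximum is at
    removal since washout is monotone thereafter.
    """
    ka, ke = params.Ka, params.ke
    if abs(ka - ke) < _KA_KE_RTOL * ka:
        tp_peak = 1.0 / ka
    else:
        tp_peak = math.log(ka / ke) / (ka - ke)
    tmax = dose.t_apply + tp_peak
    if truncate_at_removal and tmax > dose.t_remove:
        tmax = dose.t_remove
    cmax = float(concentration(params, dose, tmax, truncate_at_removal))
    return tmax, cmax


def ode_concentration(
    params: IndividualParams,
    dose: DoseEvent,
    times: np.ndarray,
    truncate_at_removal: bool = True,
    rtol: float = 1e-11,
    atol: float = 1e-9,
) -> np.ndarray:
    """Concentration profile by adaptive Runge-Kutta integration of the ODEs.

    Slower than the closed form by orders of magnitude; intended as an
    independent numerical route for validation and for structural variants
    without a closed form.
    """
    times = np.asarray(times, dtype=float)
    ka, ke = params.Ka, params.ke

    def rhs(_t, y):
        return [-ka * y[0], ka * y[0] - ke * y[1]]

    out = np.zeros_like(times)
    if truncate_at_removal:
        mask_on = (times >= dose.t_apply) & (times <= dose.t_remove)
    else:
        mask_on = times >= dose.t_apply
    eval_on = times[mask_on]
    if eval_on.size:
        span_end = float(max(eval_on.max(), dose.t_apply + 1e-9))
        sol = solve_ivp(
            rhs,
            (dose.t_apply, span_end),
            [dose.amount, 0.0],
            t_eval=eval_on,
            rtol=rtol,
            atol=atol,
            method="DOP853",
        )
        out[mask_on] = sol.y[1] / params.V
    if truncate_at_removal:
        mask_off = times > dose.t_remove
        if np.any(mask_off):
            end = solve_ivp(
                rhs,
                (dose.t_apply, dose.t_remove),
                [dose.amount, 0.0],
                rtol=rtol,
                atol=atol,
                method="DOP853",
            )
            a1_rem = end.y[1, -1]
            sol_off = solve_ivp(
                lambda _t, y: [-ke * y[0]],
                (dose.t_remove, float(times.max())),
                [a1_rem],
                t_eval=times[mask_off],
                rtol=rtol,
                atol=atol,
                method="DOP853",
            )
            out[mask_off] = sol_off.y[0] / params.V
    return out


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Parameters of the two-compartment alternative (all apparent).

    CL2 is the inter-compartmental clearance and V2 the peripheral volume;
    CL2 -> 0 recovers the one-compartment model.
    """

    Ka: float
    V: float
    CL: float
    V2: float
    CL2: float

    def __post_init__(self) -> None:
        for name in ("Ka", "V", "CL", "V2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not (math.isfinite(self.CL2) and self.CL2 >= 0):
            raise ValueError(f"CL2 must be >= 0, got {self.CL2!r}")


def _two_cpt_matrix(p: TwoCompartmentParams) -> np.ndarray:
    k = p.CL / p.V
    k12 = p.CL2 / p.V
    k21 = p.CL2 / p.V2
    return np.array(
        [
            [-p.Ka, 0.0, 0.0],
            [p.Ka, -(k + k12), k21],
            [0.0, k12, -k21],
        ]
    )


def two_compartment_profile(
    params2: TwoCompartmentParams,
    dose: DoseEvent,
    times: np.ndarray,
    truncate_at_removal: bool = True,
) -> np.ndarray:
    """Tri-exponential first-order-absorption two-compartment profile (ng/mL).

    Evaluated through the eigendecomposition of the linear system (the
    standard tri-exponential solution in stable form).  Post-removal kinetics
    with truncation restart from the removal-time amounts with the depot
    discarded.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("negative time before any dose")
    M = _two_cpt_matrix(params2)
    lam, P = np.linalg.eig(M)
    Pinv = np.linalg.inv(P)
    x0 = np.array([dose.amount, 0.0, 0.0])
    c0 = Pinv @ x0

    def amounts(tp):  # tp relative to application, >= 0
        return np.real((P * np.exp(np.outer(tp, lam))[:, None, :]) @ c0)

    tp = np.maximum(times - dose.t_apply, 0.0)
    out = amounts(np.atleast_1d(tp))[:, 1] / params2.V
    if truncate_at_removal and np.any(times > dose.t_remove):
        wear = dose.t_remove - dose.t_apply
        state_rem = amounts(np.array([wear]))[0]
        # discard depot, evolve the two distribution compartments
        M2 = M[1:, 1:]
        lam2, P2 = np.linalg.eig(M2)
        c2 = np.linalg.solve(P2, state_rem[1:])
        dt = np.maximum(times - dose.t_remove, 0.0)
        a_off = np.real((P2 * np.exp(np.outer(dt, lam2))[:, None, :]) @ c2)
        off = a_off[:, 0] / params2.V
        out = np.where(times > dose.t_remove, off, out)
    out = np.maximum(out, 0.0)  # eigendecomposition roundoff can dip below 0
    return np.where(times <= dose.t_apply, 0.0, out).reshape(times.shape)
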