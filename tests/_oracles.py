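"""Independent numerical oracles used by the tests.

These deliberately avoid the package's closed-form/linearized code paths:
concentrations come from adaptive Runge-Kutta integration of the ODEs, and
marginal likelihoods from adaptive Gauss-Hermite quadrature over the random
effects.
"""

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.integrate import solve_ivp
from scipy.optimize import minimize


def ode_profile(ka, V, cl, amount, t_remove, times, truncate=True,
                rtol=1e-12, atol=1e-8):
    """Concentration profile by DOP853 integration of the depot/central ODEs."""
    ke = cl / V
    times = np.asarray(times, dtype=float)

    def rhs(_t, y):
        return [-ka * y[0], ka * y[0] - ke * y[1]]

    out = np.zeros_like(times)
    on = times <= t_remove if truncate else np.ones_like(times, dtype=bool)
    t_eval = times[on]
    if t_eval.size:
        sol = solve_ivp(rhs, (0.0, max(t_eval.max(), 1e-9)), [amount, 0.0],
                        t_eval=t_eval, rtol=rtol, atol=atol, method="DOP853")
        out[on] = sol.y[1] / V
    if truncate and np.any(~on):
        end = solve_ivp(rhs, (0.0, t_remove), [amount, 0.0],
                        rtol=rtol, atol=atol, method="DOP853")
        a1 = end.y[1, -1]
        dt = times[~on] - t_remove
        out[~on] = a1 * np.exp(-ke * dt) / V
    return out


def ode_profile_two_compartment(ka, V, cl, V2, cl2, amount, t_remove, times,
                                truncate=True, rtol=1e-11, atol=1e-10):
    k = cl / V
    k12 = cl2 / V
    k21 = cl2 / V2
    times = np.asarray(times, dtype=float)

    def rhs(_t, y):
        return [
            -ka * y[0],
            ka * y[0] - (k + k12) * y[1] + k21 * y[2],
            k12 * y[1] - k21 * y[2],
        ]

    out = np.zeros_like(times)
    on = times <= t_remove if truncate else np.ones_like(times, dtype=bool)
    if np.any(on):
        sol = solve_ivp(rhs, (0.0, max(times[on].max(), 1e-9)), [amount, 0.0, 0.0],
                        t_eval=times[on], rtol=rtol, atol=atol, method="DOP853")
        out[on] = sol.y[1] / V
    if truncate and np.any(~on):
        end = solve_ivp(rhs, (0.0, t_remove), [amount, 0.0, 0.0],
                        rtol=rtol, atol=atol, method="DOP853")
        y_rem = [0.0, end.y[1, -1], end.y[2, -1]]  # depot discarded
        sol2 = solve_ivp(rhs, (t_remove, times.max()), y_rem,
                         t_eval=times[~on], rtol=rtol, atol=atol, method="DOP853")
        out[~on] = sol2.y[1] / V
    return out


def gh_subject_m2ll(predict, y, sigma, om_var, n_nodes=64):
    """Adaptive Gauss-Hermite -2 log marginal likelihood for one subject.

    ``predict(eta_vector) -> prediction array``; additive residual sd
    ``sigma``; ``om_var`` is the vector of random-effect variances (zero
    entries are inactive).  Quadrature is centered at the joint mode and
    scaled by the Laplace covariance, so a linear-in-eta model is integrated
    to machine precision.
    """
    om_var = np.atleast_1d(np.asarray(om_var, dtype=float))
    act = om_var > 0
    k = int(act.sum())
    oinv = 1.0 / om_var[act]

    def neglogjoint(e_act):
        e = np.zeros(om_var.size)
        e[act] = e_act
        f = predict(e)
        ll = -0.5 * np.sum((y - f) ** 2 / sigma**2 + np.log(2 * np.pi * sigma**2))
        lp = -0.5 * np.sum(e_act**2 * oinv) - 0.5 * np.sum(np.log(2 * np.pi / oinv))
        return -(ll + lp)

    if k == 0:
        return 2.0 * neglogjoint(np.zeros(0))
    res = minimize(neglogjoint, np.zeros(k), method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
    mode = res.x
    H = _hessian(neglogjoint, mode)
    w_, V_ = np.linalg.eigh(H)
    w_ = np.maximum(w_, 1e-12)
    S = V_ @ np.diag(1.0 / np.sqrt(w_)) @ V_.T  # H^{-1/2}
    x, w = hermgauss(n_nodes)
    grids = np.meshgrid(*([x] * k), indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    wts = np.prod(
        np.stack([w[np.searchsorted(x, pts[:, i])] for i in range(k)], axis=1), axis=1
    )
    logvals = np.array(
        [-neglogjoint(mode + np.sqrt(2.0) * (S @ z)) + np.sum(z**2) for z in pts]
    )
    cmax = logvals.max()
    total = np.sum(wts * np.exp(logvals - cmax))
    logL = (
        cmax
        + np.log(total)
        + 0.5 * k * np.log(2.0)
        + np.log(np.abs(np.linalg.det(S)))
    )
    return -2.0 * logL


def _hessian(fun, x, rel_step=1e-4):
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                H[i, i] = (fun(xp) - 2 * f0 + fun(xm)) / h[i] ** 2
            else:
                xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                H[i, j] = H[j, i] = (
                    fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)
                ) / (4 * h[i] * h[j])
    return H


def analytic_auc_one_compartment(ka, V, cl, amount, t_remove, t_end):
    """Exact AUC of the truncated one-compartment patch profile on [0, t_end]."""
    ke = cl / V
    coef = amount * ka / (V * (ka - ke))

    def auc_on(t):  # integral of the absorption-phase curve from 0 to t
        return coef * ((1 - np.exp(-ke * t)) / ke - (1 - np.exp(-ka * t)) / ka)

    if t_end <= t_remove:
        return auc_on(t_end)
    c_rem = coef * (np.exp(-ke * t_remove) - np.exp(-ka * t_remove))
    tail = c_rem / ke * (1 - np.exp(-ke * (t_end - t_remove)))
    return auc_on(t_remove) + tail
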