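"""Covariate effect forms and the stepwise screening machinery."""

import numpy as np
import pytest

import patchpk as pk
from patchpk.covariates import (
    BACKWARD_THRESHOLD,
    FORWARD_THRESHOLD,
    CovariateEffect,
    backward_step,
    default_candidates,
    forward_step,
    run_stepwise,
)
from conftest import small_design

# shared desk-scale screening setup: IIV on CL only, so candidate fits carry
# few free parameters and many replicates stay affordable
SCREEN_OMEGA = pk.OmegaMatrix(0.0, 0.0, 0.1)
SCREEN_RESID = pk.ResidualSpec(kind="additive", sigma_add=0.3)
SCREEN_FIX = frozenset({"tvKa", "tvV", "omega2_Ka", "omega2_V"})
SCREEN_SETTINGS = pk.FitSettings(
    compute_rse=False, final_gof=False, outer_passes=2, outer_ftol=1e-8,
    max_outer_iter=120, fix=SCREEN_FIX,
)
DEMO = {"TEST": pk.builtin_demographics()["392MD/26/C"]}


def _screen_dataset(seed, n=100, effects=()):
    theta, _, _ = pk.reference_model()
    design = small_design(n_subjects=n, times=(0.0, 12, 48, 96, 144, 192), code="TEST")
    return pk.simulate_dataset(theta, SCREEN_OMEGA, SCREEN_RESID, design,
                               demographics=DEMO, seed=seed, lloq=None, effects=effects)


def _base_fit(ds):
    theta, _, _ = pk.reference_model()
    init = pk.InitialEstimates(theta=theta, omega=pk.OmegaMatrix(1e-12, 1e-12, 0.1),
                               residual=SCREEN_RESID)
    return pk.fit(ds, init, settings=SCREEN_SETTINGS)


class TestApplyEffect:
    def test_median_covariate_leaves_parameter_unchanged(self):
        eff = CovariateEffect("CL", "WT", "power", 0.75, cov_median=70.0)
        assert pk.apply_effect(100.0, eff, {"WT": 70.0}) == pytest.approx(100.0)

    def test_zero_coefficient_is_identity(self):
        eff = CovariateEffect("CL", "WT", "power", 0.0, cov_median=70.0)
        assert pk.apply_effect(100.0, eff, {"WT": 95.0}) == pytest.approx(100.0)
        ind = CovariateEffect("V", "SEX", "indicator", 0.0)
        assert pk.apply_effect(100.0, ind, {"SEX": 1.0}) == pytest.approx(100.0)

    def test_power_form_closed_value(self):
        eff = CovariateEffect("CL", "WT", "power", 0.75, cov_median=70.0)
        assert pk.apply_effect(1.0, eff, {"WT": 140.0}) == pytest.approx(2**0.75, rel=1e-12)

    def test_indicator_form(self):
        eff = CovariateEffect("V", "SEX", "indicator", 0.3)
        assert pk.apply_effect(1.0, eff, {"SEX": 1.0}) == pytest.approx(np.exp(0.3))
        assert pk.apply_effect(1.0, eff, {"SEX": 0.0}) == pytest.approx(1.0)

    def test_missing_covariate_raises(self):
        eff = CovariateEffect("CL", "WT", "power", 0.5, cov_median=70.0)
        with pytest.raises(KeyError):
            pk.apply_effect(1.0, eff, {"AGE": 40.0})

    def test_power_form_requires_median(self):
        with pytest.raises(ValueError):
            CovariateEffect("CL", "WT", "power", 0.5)


def test_default_candidate_grid_spans_five_covariates_by_three_parameters():
    ds = _screen_dataset(0, n=10)
    grid = default_candidates(ds)
    assert len(grid) == 15
    forms = {(e.covariate, e.form) for e in grid}
    assert ("SEX", "indicator") in forms
    assert all(f == "power" for c, f in forms if c != "SEX")
    wt = next(e for e in grid if e.covariate == "WT")
    assert wt.cov_median == pytest.approx(ds.covariate_median("WT"))


def test_effect_add_remove_round_trip_is_exact():
    base = (CovariateEffect("CL", "WT", "power", 0.2, cov_median=70.0),)
    added = base + (CovariateEffect("V", "AGE", "power", 0.1, cov_median=40.0),)
    removed = tuple(e for e in added if (e.parameter, e.covariate) != ("V", "AGE"))
    assert removed == base


def test_forward_step_with_no_candidates_adds_nothing(ref_model):
    ds = _screen_dataset(1, n=20)
    base = _base_fit(ds)
    best, entries = forward_step(base, ds, [], settings=SCREEN_SETTINGS)
    assert best is None and entries == []


def test_backward_step_on_empty_model_is_noop():
    ds = _screen_dataset(2, n=20)
    base = _base_fit(ds)
    nxt, entries = backward_step(base, ds, settings=SCREEN_SETTINGS)
    assert nxt is None and entries == []


def test_planted_weight_effect_is_selected_and_retained():
    """A strong planted weight-on-clearance effect (exponent 0.75, n = 100)
    must win the forward step in >= 90% of seeded replicates and survive
    backward elimination."""
    truth = CovariateEffect("CL", "WT", "power", 0.75, cov_median=68.0)
    wins = 0
    n_rep = 20
    for rep in range(n_rep):
        ds = _screen_dataset(100 + rep, effects=(truth,))
        base = _base_fit(ds)
        cands = [
            CovariateEffect("CL", "WT", "power", 0.0, cov_median=ds.covariate_median("WT")),
            CovariateEffect("CL", "AGE", "power", 0.0, cov_median=ds.covariate_median("AGE")),
        ]
        best, entries = forward_step(base, ds, cands, settings=SCREEN_SETTINGS)
        if best is not None and best.model.effects[-1].covariate == "WT":
            wins += 1
    assert wins >= 0.9 * n_rep


def test_stepwise_trace_for_single_planted_effect():
    """Stepwise on one strong planted effect: the trace adds exactly that
    effect forward and keeps it through the backward phase."""
    truth = CovariateEffect("CL", "WT", "power", 0.75, cov_median=68.0)
    ds = _screen_dataset(55, effects=(truth,))
    base = _base_fit(ds)
    cands = [
        CovariateEffect("CL", "WT", "power", 0.0, cov_median=ds.covariate_median("WT")),
        CovariateEffect("CL", "AGE", "power", 0.0, cov_median=ds.covariate_median("AGE")),
    ]
    trace = run_stepwise(ds, base, cands, settings=SCREEN_SETTINGS)
    added = [e for e in trace.entries if e.decision == "added"]
    removed = [e for e in trace.entries if e.decision == "removed"]
    assert len(added) == 1 and added[0].effect.covariate == "WT"
    assert not removed
    assert len(trace.final_effects) == 1
    assert trace.final_effects[0].theta_x == pytest.approx(0.75, abs=0.35)
    # forward additions in the trace always clear the threshold
    assert all(e.delta_ofv > FORWARD_THRESHOLD for e in added)


def test_stepwise_with_empty_grid_returns_base():
    ds = _screen_dataset(9, n=20)
    base = _base_fit(ds)
    trace = run_stepwise(ds, base, [], settings=SCREEN_SETTINGS)
    assert trace.entries == [] and trace.final_effects == ()
    assert trace.final_fit.ofv == base.ofv


def test_null_data_usually_yields_empty_final_model():
    """With no generating covariate effects the screen should end empty in
    most replicates (the nominal false-inclusion rate is ~5% per candidate)."""
    empty = 0
    n_rep = 5
    for rep in range(n_rep):
        ds = _screen_dataset(200 + rep, n=40)
        base = _base_fit(ds)
        cands = [
            CovariateEffect("CL", "WT", "power", 0.0, cov_median=ds.covariate_median("WT")),
            CovariateEffect("CL", "AGE", "power", 0.0, cov_median=ds.covariate_median("AGE")),
            CovariateEffect("CL", "SEX", "indicator", 0.0),
        ]
        trace = run_stepwise(ds, base, cands, settings=SCREEN_SETTINGS)
        empty += not trace.final_effects
    assert empty >= 3


def test_backward_step_removes_force_included_null_effect():
    """A null effect pushed into the model raises the OFV by far less than
    the backward threshold on deletion, so backward elimination drops it."""
    from patchpk.covariates import _refit_with_effects

    ds = _screen_dataset(33, n=30)
    base = _base_fit(ds)
    null_eff = CovariateEffect("CL", "AGE", "power", 0.0,
                               cov_median=ds.covariate_median("AGE"))
    with_null = _refit_with_effects(ds, base, (null_eff,), SCREEN_SETTINGS)
    reduced, entries = backward_step(with_null, ds, settings=SCREEN_SETTINGS)
    assert reduced is not None
    assert reduced.model.effects == ()
    assert any(e.decision == "removed" for e in entries)


def test_nested_model_aic_prefers_smaller_on_null_data():
    """Fitting an extra null covariate coefficient rarely buys more than 2
    OFV units, so AIC prefers the smaller model in the majority of
    replicates."""
    from patchpk.covariates import _refit_with_effects

    prefer_small = 0
    n_rep = 8
    for rep in range(n_rep):
        ds = _screen_dataset(400 + rep, n=20)
        base = _base_fit(ds)
        null_eff = CovariateEffect("CL", "WT", "power", 0.0,
                                   cov_median=ds.covariate_median("WT"))
        bigger = _refit_with_effects(ds, base, (null_eff,), SCREEN_SETTINGS)
        cmp = pk.compare_models(base, bigger)
        prefer_small += cmp.preferred_by_aic == "A"
    assert prefer_small > n_rep / 2


def test_trace_serialization_columns():
    truth = CovariateEffect("CL", "WT", "power", 0.75, cov_median=68.0)
    ds = _screen_dataset(77, n=40, effects=(truth,))
    base = _base_fit(ds)
    cands = [CovariateEffect("CL", "WT", "power", 0.0, cov_median=ds.covariate_median("WT"))]
    trace = run_stepwise(ds, base, cands, settings=SCREEN_SETTINGS)
    frame = trace.to_frame()
    assert list(frame.columns) == [
        "step", "phase", "effect", "ofv_before", "ofv_after", "delta_ofv", "decision",
    ]
    assert (frame["delta_ofv"] == frame["ofv_before"] - frame["ofv_after"]).all()
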