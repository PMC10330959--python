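"""Goodness-of-fit (CWRES), bootstrap, and visual predictive check."""

import numpy as np
import pandas as pd
import pytest

import patchpk as pk
from patchpk.estimation import OneCompartmentPk
from conftest import small_design


def _manual_fit_result(theta, omega, residual, dataset, model=None):
    """Assemble a FitResult at known parameters without running the optimizer
    (conditional modes computed per subject)."""
    model = model or OneCompartmentPk()
    etas = {
        s.id: pk.map_eta(s, theta, omega, residual, model=model)
        for s in dataset
        if s.quantifiable
    }
    params = theta.as_dict() | {
        f"omega2_{e}": v for e, v in zip(model.eta_names, omega.diagonal())
    }
    return pk.FitResult(
        theta=theta, omega=omega, residual=residual, betas={}, params=params,
        ofv=0.0, aic=0.0, bic=0.0, n_obs=dataset.n_obs, n_params=0,
        rse_percent=None, eta=etas, diagnostics=pd.DataFrame(), converged=True,
        n_outer_evals=0, message="manual", model=model,
        data_signature=dataset.signature(),
    )


class TestGof:
    def test_cwres_zero_for_noiseless_zero_iiv_data(self, ref_model):
        theta, _, _ = ref_model
        resid = pk.ResidualSpec(kind="additive", sigma_add=0.5)
        ds = pk.simulate_dataset(theta, pk.OmegaMatrix(0, 0, 0), resid,
                                 small_design(n_subjects=4), seed=0, lloq=None,
                                 add_residual=False)
        fr = _manual_fit_result(theta, pk.OmegaMatrix(1e-12, 1e-12, 1e-12), resid, ds)
        table = pk.gof(fr, ds)
        assert np.max(np.abs(table.cwres())) < 1e-5
        np.testing.assert_allclose(table.table["PRED"], table.table["IPRED"], rtol=1e-6)

    def test_cwres_distribution_under_true_model(self, ref_model):
        """CWRES from well-specified data: mean ~ 0, variance ~ 1, and at
        least 99% of values inside +/-4."""
        theta, omega, resid = ref_model
        design = small_design(n_subjects=50,
                              times=(0.0, 6, 12, 24, 48, 72, 96, 120, 144, 168, 192, 216, 240))
        ds = pk.simulate_dataset(theta, omega, resid, design, seed=42, lloq=None)
        fr = _manual_fit_result(theta, omega, resid, ds)
        cw = pk.gof(fr, ds).cwres()
        assert cw.size >= 500
        assert abs(np.mean(cw)) < 0.15
        assert 0.7 < np.var(cw) < 1.3
        assert np.mean(np.abs(cw) < 4) >= 0.99

    def test_pred_equals_ipred_when_no_random_effects(self, ref_model):
        theta, _, resid = ref_model
        ds = pk.simulate_dataset(theta, pk.OmegaMatrix(0, 0, 0), resid,
                                 small_design(n_subjects=3), seed=5, lloq=None)
        fr = _manual_fit_result(theta, pk.OmegaMatrix(0, 0, 0), resid, ds)
        table = pk.gof(fr, ds).table
        np.testing.assert_array_equal(table["PRED"], table["IPRED"])


def _tiny_fit(ds, resid, free_sigma=True):
    """Cheap fit used by bootstrap tests: only tvCL/omega2_CL (+sigma) free."""
    theta, _, _ = pk.reference_model()
    fix = {"tvKa", "tvV", "omega2_Ka", "omega2_V"}
    if not free_sigma:
        fix.add("sigma_add")
    settings = pk.FitSettings(compute_rse=False, outer_passes=1, outer_ftol=1e-8,
                              max_outer_iter=60, fix=frozenset(fix))
    init = pk.InitialEstimates(theta=theta, omega=pk.OmegaMatrix(1e-12, 1e-12, 0.1),
                               residual=resid)
    return pk.fit(ds, init, settings=settings), settings


class TestBootstrap:
    def _dataset(self, seed=0, n=8):
        theta, _, _ = pk.reference_model()
        omega = pk.OmegaMatrix(0.0, 0.0, 0.15)
        resid = pk.ResidualSpec(kind="additive", sigma_add=0.3)
        design = small_design(n_subjects=n, times=(0.0, 12, 48, 96, 144))
        return pk.simulate_dataset(theta, omega, resid, design, seed=seed, lloq=None), resid

    def test_single_resample_is_reproducible(self):
        ds, resid = self._dataset()
        fit_res, settings = _tiny_fit(ds, resid)
        b1 = pk.bootstrap(ds, fit_res, n_boot=1, seed=11, settings=settings)
        b2 = pk.bootstrap(ds, fit_res, n_boot=1, seed=11, settings=settings)
        pd.testing.assert_frame_equal(b1.replicates, b2.replicates)
        assert b1.n_requested == 1

    def test_degenerate_one_subject_strata_have_zero_width(self):
        theta, _, _ = pk.reference_model()
        resid = pk.ResidualSpec(kind="additive", sigma_add=0.3)
        subjects = []
        for k, code in enumerate(["A", "B"]):
            d = small_design(n_subjects=1, times=(0.0, 12, 48, 96, 144), code=code)
            sub = pk.simulate_dataset(theta, pk.OmegaMatrix(0, 0, 0.15), resid, d,
                                      seed=k, lloq=None).subjects[0]
            subjects.append(sub)
        ds = pk.Dataset(subjects)
        fit_res, settings = _tiny_fit(ds, resid)
        boot = pk.bootstrap(ds, fit_res, n_boot=8, seed=3, settings=settings)
        lo, hi = boot.interval("tvCL")
        # every stratified resample is the identical dataset
        assert hi - lo == pytest.approx(0.0, abs=1e-6 * hi)

    def test_interval_nesting_by_level(self):
        ds, resid = self._dataset(seed=2, n=10)
        fit_res, settings = _tiny_fit(ds, resid)
        boot = pk.bootstrap(ds, fit_res, n_boot=30, seed=5, settings=settings)
        lo90, hi90 = boot.interval("tvCL", level=90.0)
        lo95, hi95 = boot.interval("tvCL", level=95.0)
        assert lo95 <= lo90 <= hi90 <= hi95
        assert boot.n_converged <= boot.n_requested


class TestVpc:
    def test_degenerate_model_bands_collapse_to_typical_profile(self, ref_model):
        theta, _, _ = ref_model
        resid = pk.ResidualSpec(kind="additive", sigma_add=1e-9)
        design = small_design(n_subjects=6)
        ds = pk.simulate_dataset(theta, pk.OmegaMatrix(0, 0, 0), resid, design,
                                 seed=1, lloq=None, add_residual=False)
        fr = _manual_fit_result(theta, pk.OmegaMatrix(0, 0, 0), resid, ds)
        v = pk.vpc(fr, ds, n_rep=40, seed=2, lloq=0.0)
        params = pk.individual_params(theta, (0, 0, 0))
        typical = pk.profile(params, design.dose_event(), v.times)
        np.testing.assert_allclose(v.sim_p5, typical, rtol=1e-5)
        np.testing.assert_allclose(v.sim_p50, typical, rtol=1e-5)
        np.testing.assert_allclose(v.sim_p95, typical, rtol=1e-5)

    def test_percentile_ordering(self, ref_model):
        theta, omega, resid = ref_model
        design = small_design(n_subjects=10)
        ds = pk.simulate_dataset(theta, omega, resid, design, seed=3)
        fr = _manual_fit_result(theta, omega, resid, ds)
        v = pk.vpc(fr, ds, n_rep=60, seed=4)
        assert np.all(v.sim_p5 <= v.sim_p50) and np.all(v.sim_p50 <= v.sim_p95)

    def test_observed_median_mostly_inside_band_for_well_specified_model(self, ref_model):
        theta, omega, resid = ref_model
        design = small_design(n_subjects=24,
                              times=(0.0, 6, 12, 24, 48, 72, 96, 120, 144, 168, 192))
        ds = pk.simulate_dataset(theta, omega, resid, design, seed=9)
        fr = _manual_fit_result(theta, omega, resid, ds)
        v = pk.vpc(fr, ds, n_rep=300, seed=10)
        assert v.observed_median_coverage() >= 0.9

    def test_sparse_times_flagged(self, ref_model):
        theta, omega, resid = ref_model
        design = small_design(n_subjects=4, times=(0.0, 12, 96))
        # censor heavily so some times carry < 3 observations
        ds = pk.simulate_dataset(theta, omega, resid, design, seed=5, lloq=2.0)
        kept = [s for s in ds if s.quantifiable]
        if len(kept) >= 2:
            ds = pk.Dataset(kept)
            fr = _manual_fit_result(theta, omega, resid, ds)
            v = pk.vpc(fr, ds, n_rep=20, seed=6)
            counts = dict(zip(v.times.tolist(), v.n_obs_per_time.tolist()))
            for t, n in counts.items():
                if n < 3:
                    assert t in v.sparse_times
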