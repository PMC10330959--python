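"""Bootstrap and visual predictive check of a fitted population model.

Fits a small simulated study, then (1) resamples subjects with replacement
and refits to get percentile confidence intervals, and (2) simulates
replicate datasets from the fitted model and compares percentile bands with
the observed percentiles at each nominal sampling time.  A well-specified
model keeps the observed median inside the simulated 5th-95th band.
"""

import patchpk as pk
from patchpk.plots import vpc_plot

theta, _, _ = pk.reference_model()
omega = pk.OmegaMatrix(0.0, 0.0, 0.15)
residual = pk.ResidualSpec(kind="additive", sigma_add=0.3)
design = pk.StudyDesign("VAL", 16, pk.PATCH_DOSE_NG, 144.0,
                        (0.0, 12, 48, 96, 144))

dataset = pk.simulate_dataset(theta, omega, residual, design, seed=11, lloq=None)
settings = pk.FitSettings(
    compute_rse=False, outer_passes=1, outer_ftol=1e-8,
    fix=frozenset({"tvKa", "tvV", "omega2_Ka", "omega2_V"}),
)
init = pk.InitialEstimates(theta=theta, omega=pk.OmegaMatrix(1e-12, 1e-12, 0.1),
                           residual=residual)
fit = pk.fit(dataset, init, settings=settings)

boot = pk.bootstrap(dataset, fit, n_boot=60, seed=1, settings=settings)
print(f"bootstrap: {boot.n_converged}/{boot.n_requested} replicates converged")
print(boot.summary().round(4).to_string())

vpc = pk.vpc(fit, dataset, n_rep=400, seed=2)
inside = 100 * vpc.observed_median_coverage()
print(f"\nVPC: observed median inside the simulated 5th-95th band at "
      f"{inside:.0f}% of the nominal times")
vpc_plot(vpc, "vpc_demo.svg")
print("band plot written to vpc_demo.svg")
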