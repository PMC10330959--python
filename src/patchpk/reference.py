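"""Published final population estimates for the granisetron transdermal system.

These are the reported final-model estimates for the 34.3 mg / 52 cm^2
granisetron patch in healthy Caucasian adults: a one-compartment model with
first-order absorption, first-order elimination, exponential (lognormal)
inter-individual variability on Ka, V and CL, and an additive residual error.
They serve as the generating truth for the synthetic-data module and as the
input model for trial simulation.
"""

from __future__ import annotations

from .data import OmegaMatrix, ResidualSpec, ThetaVector

__all__ = [
    "REFERENCE_THETA",
    "REFERENCE_OMEGA",
    "REFERENCE_RESIDUAL",
    "reference_model",
    "PATCH_DOSE_NG",
    "DEFAULT_LLOQ",
]

#: Patch load: 34.3 mg expressed in ng.
PATCH_DOSE_NG = 3.43e7

#: Default lower limit of quantification, ng/mL (assay LLOQ not published).
DEFAULT_LLOQ = 0.1

REFERENCE_THETA = ThetaVector(tvKa=0.0179879, tvV=6_299_030.0, tvCL=31_316.3)

#: Random-effect variances (omega^2) on the log scale; the Ka variance was
#: reported at ~5e-11, i.e. effectively no inter-individual variability in Ka.
REFERENCE_OMEGA = OmegaMatrix(
    omega2_Ka=4.74078e-11,
    omega2_V=1.5462161,
    omega2_CL=0.25423392,
)

REFERENCE_RESIDUAL = ResidualSpec(kind="additive", sigma_add=1.18094)


def reference_model() -> tuple[ThetaVector, OmegaMatrix, ResidualSpec]:
    """The published final population model as (theta, omega, residual)."""
    return REFERENCE_THETA, REFERENCE_OMEGA, REFERENCE_RESIDUAL
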