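"""Elastic property assignment for labelled femur images.

Region labels map to isotropic linear-elastic constants. Cortical bone and the
titanium-alloy stem use fixed moduli; cancellous bone (including marrow, which
is carried as very low-density cancellous material) takes its Young's modulus
from a two-branch power law in relative density rho:

    E(rho) = 0.30442 * rho**1.49 * E0   for rho <= 0.84
    E(rho) = 0.19082 * rho**2.39 * E0   for rho >  0.84

with reference modulus E0 = 15 GPa. As printed the law is discontinuous at the
branch point and gives E(1) = 2.8623 GPa, which disagrees with the tabulated
statement that cancellous bone reaches 15 GPa at rho = 1. Both readings are
available through ``law_variant``: the default ``"as_printed"`` evaluates the
coefficients literally, while ``"normalized"`` rescales both branches by
1/0.19082 so that E(1) = E0. No smoothing is applied at the branch point in
either variant.

Units: lengths are mm and forces N throughout the package, so all moduli are
stored in MPa and stresses emerge in MPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LABEL_BACKGROUND = 0
LABEL_CORTICAL = 1
LABEL_CANCELLOUS = 2
LABEL_STEM = 3

#: Relative density assigned to marrow-filled regions.
MARROW_DENSITY = 0.01


@dataclass(frozen=True)
class MaterialModel:
    """Material constants for the three meshed regions (moduli in MPa)."""

    E0: float = 15000.0
    cortical_E: float = 22500.0
    cortical_nu: float = 0.30
    cancellous_nu: float = 0.30
    stem_E: float = 114000.0
    stem_nu: float = 0.32
    low_coeff: float = 0.30442
    low_exp: float = 1.49
    high_coeff: float = 0.19082
    high_exp: float = 2.39
    rho_break: float = 0.84
    law_variant: str = "as_printed"  # or "normalized"

    def __post_init__(self) -> None:
        for name in ("E0", "cortical_E", "stem_E"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cortical_nu", "cancellous_nu", "stem_nu"):
            nu = getattr(self, name)
            if not 0.0 < nu < 0.5:
                raise ValueError(f"{name} must lie in (0, 0.5)")
        if self.law_variant not in ("as_printed", "normalized"):
            raise ValueError(f"unknown law_variant {self.law_variant!r}")


DEFAULT_MATERIALS = MaterialModel()


def modulus_from_density(rho, model: MaterialModel = DEFAULT_MATERIALS):
    """Young's modulus (MPa) of cancellous bone at relative density ``rho``.

    Accepts a scalar or array with every entry in (0, 1]. Strictly increasing
    within each branch of the power law; the printed discontinuity at
    ``rho_break`` is preserved.
    """
    arr = np.asarray(rho, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise ValueError("relative density must lie in (0, 1]")
    scale = 1.0
    if model.law_variant == "normalized":
        # rescale so the upper branch reaches E0 at rho = 1
        scale = 1.0 / model.high_coeff
    low = model.low_coeff * arr**model.low_exp
    high = model.high_coeff * arr**model.high_exp
    e = np.where(arr <= model.rho_break, low, high) * model.E0 * scale
    if np.isscalar(rho):
        return float(e)
    return e


def material_for_element(label: int, rho: float, model: MaterialModel = DEFAULT_MATERIALS):
    """(E, nu) in (MPa, -) for a single element given its label and density."""
    if label == LABEL_CORTICAL:
        return model.cortical_E, model.cortical_nu
    if label == LABEL_CANCELLOUS:
        return modulus_from_density(rho, model), model.cancellous_nu
    if label == LABEL_STEM:
        return model.stem_E, model.stem_nu
    if label == LABEL_BACKGROUND:
        raise RuntimeError("background pixels must never be meshed")
    raise ValueError(f"unknown region label {label}")


def elastic_arrays(labels, rho, model: MaterialModel = DEFAULT_MATERIALS):
    """Vectorized (E, nu) arrays for per-element label/density arrays."""
    labels = np.asarray(labels)
    rho = np.asarray(rho, dtype=float)
    if np.any(labels == LABEL_BACKGROUND):
        raise RuntimeError("background pixels must never be meshed")
    if not np.all(np.isin(labels, (LABEL_CORTICAL, LABEL_CANCELLOUS, LABEL_STEM))):
        raise ValueError("labels must be in {1, 2, 3}")
    E = np.empty(labels.shape, dtype=float)
    nu = np.empty(labels.shape, dtype=float)
    cort = labels == LABEL_CORTICAL
    canc = labels == LABEL_CANCELLOUS
    stem = labels == LABEL_STEM
    E[cort] = model.cortical_E
    nu[cort] = model.cortical_nu
    if np.any(canc):
        E[canc] = modulus_from_density(rho[canc], model)
    nu[canc] = model.cancellous_nu
    E[stem] = model.stem_E
    nu[stem] = model.stem_nu
    return E, nu
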