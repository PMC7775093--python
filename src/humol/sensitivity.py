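"""Sensitivity of the HU -> density conversion to composition errors, and
first-order uncertainty propagation for ground-truth phantom measurements.

The conversion needs the voxel's molecular composition, which in practice
is assumed (nominal organ values) rather than measured. The central
question is therefore: if the assumed composition is wrong, how wrong are
the recovered mass and electron densities? Because HU_rho and rho_e/rho
are affine in the mass fractions, the answer has closed form and can be
tabulated molecule pair by molecule pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import MOLECULE_NAMES, MolecularComposition
from .model import (
    ModelParams,
    electron_ratio_from_molecular,
    hu_rho_from_molecular,
    rho_from_hu,
    simulate_hu,
)

__all__ = [
    "SensitivityResult",
    "composition_error",
    "sensitivity_grid",
    "beta_per_percent_sensitivity",
    "propagate_ground_truth_uncertainty",
]


@dataclass(frozen=True)
class SensitivityResult:
    """Percent errors in rho and rho_e from a composition mismatch.

    Sign convention: error = 100 * (estimated - true) / estimated, the
    direction in which a clinical user would experience the bias of an
    assumed composition (equivalently 100*(true - estimated)/true with the
    roles of the two compositions read the other way around).
    """

    assumed: MolecularComposition
    true: MolecularComposition
    rho_error_pct: float
    rho_e_error_pct: float


def composition_error(
    assumed: MolecularComposition,
    true: MolecularComposition,
    params: ModelParams,
) -> SensitivityResult:
    """Simulate imaging the TRUE material, convert with the ASSUMED one.

    The true material is taken at unit mass density; the resulting percent
    errors are provably independent of that choice, because both the
    simulated HU + 1000 and the estimated densities scale linearly with
    the true density.
    """
    hu = simulate_hu(1.0, true, params)
    rho_true = 1.0
    rho_e_true = rho_true * electron_ratio_from_molecular(true, params)
    rho_est = rho_from_hu(hu, hu_rho_from_molecular(assumed, params))
    rho_e_est = rho_est * electron_ratio_from_molecular(assumed, params)
    return SensitivityResult(
        assumed=assumed,
        true=true,
        rho_error_pct=100.0 * (rho_est - rho_true) / rho_est,
        rho_e_error_pct=100.0 * (rho_e_est - rho_e_true) / rho_e_est,
    )


def sensitivity_grid(
    params: ModelParams, contamination: float = 0.10
) -> pd.DataFrame:
    """The full pure-composition sensitivity table.

    For every ordered pair of distinct molecule types, assume a pure
    composition of the first while the material actually contains
    ``contamination`` (default 10%) of the second; tabulate the percent
    errors in rho and rho_e. Rows follow the molecule order water, lipid,
    protein, mineral.
    """
    rows = []
    for assumed_name in MOLECULE_NAMES:
        for error_name in MOLECULE_NAMES:
            if error_name == assumed_name:
                continue
            assumed = MolecularComposition.pure(assumed_name)
            true = MolecularComposition(
                **{
                    assumed_name: 1.0 - contamination,
                    error_name: contamination,
                },
                name=f"{assumed_name}+{error_name}",
            )
            result = composition_error(assumed, true, params)
            rows.append(
                {
                    "assumed": assumed_name,
                    "simulated_error": error_name,
                    "rho_error_pct": result.rho_error_pct,
                    "rho_e_error_pct": result.rho_e_error_pct,
                }
            )
    return pd.DataFrame(rows)


def beta_per_percent_sensitivity(params: ModelParams) -> dict[str, float]:
    """Absolute rho_e/rho error per one percentage point of composition.

    Linearity of the electron-ratio model makes this exact: |beta_i| / 100
    for each non-water molecule.
    """
    return {name: abs(params.beta[name]) * 0.01 for name in ("lipid", "protein", "mineral")}


def propagate_ground_truth_uncertainty(
    mass_g: float,
    sigma_mass_g: float,
    volume_cc: float,
    sigma_volume_cc: float,
    z_over_a_fractions: np.ndarray | None = None,
    sigma_fractions: np.ndarray | None = None,
    electron_ratio: float = 1.0,
    z_over_a_water: float | None = None,
) -> tuple[float, float]:
    """First-order (delta-method) uncertainties for measured rho and rho_e.

    rho = m/V gives the standard quadrature relative error

        sigma_rho / rho = sqrt((sigma_m/m)^2 + (sigma_V/V)^2),

    and rho_e = rho * sum_i(omega_i Z_i/A_i) / (Z/A)_water adds the
    independent elemental-fraction contributions

        sigma_rho_e^2 = (ratio * sigma_rho)^2
                      + (rho / (Z/A)_water)^2 * sum_i (Z_i/A_i * sigma_omega_i)^2.

    ``z_over_a_fractions`` and ``sigma_fractions`` are aligned per-element
    arrays of Z/A values and mass-fraction standard deviations; omit both
    for an exactly known composition. ``electron_ratio`` is the nominal
    rho_e/rho about which the propagation is taken (1 for water-like
    materials). Returns (sigma_rho, sigma_rho_e) in absolute units (g/cc
    and water-relative).
    """
    if mass_g <= 0 or volume_cc <= 0:
        raise ValueError("mass and volume must be positive")
    if sigma_mass_g < 0 or sigma_volume_cc < 0:
        raise ValueError("uncertainties must be non-negative")
    from .composition import z_over_a_water as _zaw

    rho = mass_g / volume_cc
    rel_rho = np.hypot(sigma_mass_g / mass_g, sigma_volume_cc / volume_cc)
    sigma_rho = rho * rel_rho

    zaw = _zaw() if z_over_a_water is None else z_over_a_water
    if z_over_a_fractions is None or sigma_fractions is None:
        ratio_var = 0.0
    else:
        za = np.asarray(z_over_a_fractions, dtype=float)
        sig = np.asarray(sigma_fractions, dtype=float)
        if np.any(sig < 0):
            raise ValueError("fraction uncertainties must be non-negative")
        ratio_var = float(np.sum((za * sig) ** 2)) / zaw**2
    sigma_rho_e = np.sqrt((electron_ratio * sigma_rho) ** 2 + rho**2 * ratio_var)
    return float(sigma_rho), float(sigma_rho_e)
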