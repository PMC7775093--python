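"""Closed-form relations among HU, HU_rho, mass density, and electron density.

The central object is the mass-density-normalized Hounsfield unit

    HU_rho = 1000 * (mu/rho_x - mu/rho_water) / (mu/rho_water),

an intrinsic property of a material's composition and the imaging beam:
unlike HU it does not depend on how densely the material is packed. The two
scalar identities

    HU_rho = (HU + 1000) / rho - 1000          (HU_rho from a measured HU)
    rho    = (HU + 1000) / (HU_rho + 1000)     (mass density from HU)

convert between the three quantities. In the four-component tissue model
HU_rho and the electron ratio rho_e/rho are both affine in the molecular
mass fractions,

    HU_rho     = w_lipid*a1 + w_protein*a2 + w_mineral*a3
    rho_e/rho  = 1 + w_lipid*b1 + w_protein*b2 + w_mineral*b3,

with water the zero reference; the alpha coefficients depend on the beam
spectrum, the beta coefficients only on Z/A chemistry. Combining the three
gives electron density directly from HU and composition:

    rho_e = (HU + 1000) * (1 + sum w_i b_i) / (sum w_i a_i + 1000).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Mapping

import numpy as np

from .composition import ElementalComposition, MolecularComposition, z_over_a_water

__all__ = [
    "ModelParams",
    "DensityResult",
    "round_half_away",
    "hu_rho_from_hu",
    "rho_from_hu",
    "hu_rho_from_molecular",
    "electron_ratio_from_molecular",
    "rho_e_from_hu",
    "electron_ratio_from_elemental",
    "rho_e_from_elemental",
    "simulate_hu",
]

_COEF_KEYS = ("lipid", "protein", "mineral")


@dataclass(frozen=True)
class ModelParams:
    """Empirical model coefficients.

    ``alpha`` (HU_rho units) is beam-specific and tagged with the beam label
    it was calibrated for; ``beta`` (dimensionless) depends only on
    elemental Z/A and is beam-independent. Each maps exactly the keys
    lipid/protein/mineral; water's coefficient is identically zero by
    construction and never stored.
    """

    alpha: Mapping[str, float]
    beta: Mapping[str, float] = field(default_factory=dict)
    beam: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", dict(self.alpha))
        object.__setattr__(self, "beta", dict(self.beta))
        if set(self.alpha) != set(_COEF_KEYS):
            raise ValueError(f"alpha must have keys {_COEF_KEYS}, got {set(self.alpha)}")
        if self.beta and set(self.beta) != set(_COEF_KEYS):
            raise ValueError(f"beta must have keys {_COEF_KEYS}, got {set(self.beta)}")

    def alpha_vector(self) -> np.ndarray:
        return np.array([self.alpha[k] for k in _COEF_KEYS])

    def beta_vector(self) -> np.ndarray:
        if not self.beta:
            raise ValueError("beta coefficients not set on these parameters")
        return np.array([self.beta[k] for k in _COEF_KEYS])

    def to_json(self, fh: IO[str] | None = None) -> str:
        payload = {"beam": self.beam, "alpha": self.alpha, "beta": self.beta}
        text = json.dumps(payload, indent=2)
        if fh is not None:
            fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_fh) -> "ModelParams":
        text = text_or_fh.read() if hasattr(text_or_fh, "read") else text_or_fh
        payload = json.loads(text)
        return cls(
            alpha=payload["alpha"],
            beta=payload.get("beta") or {},
            beam=payload.get("beam", ""),
        )


@dataclass(frozen=True)
class DensityResult:
    """A converted voxel or material: mass density, electron density, HU_rho."""

    rho: float
    rho_e: float
    hu_rho: float

    def __post_init__(self) -> None:
        if self.rho < 0 or self.rho_e < 0:
            raise ValueError("densities must be non-negative")


def round_half_away(value, decimals: int = 0):
    """Round half away from zero, the convention of printed physics tables.

    numpy/python banker's rounding maps 0.5 to 0; printed CT tables do not.
    """
    factor = 10.0**decimals
    scaled = np.asarray(value) * factor
    out = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5) / factor
    if np.ndim(value) == 0:
        scalar = float(out)
        return int(scalar) if decimals == 0 else scalar
    return out if decimals else out.astype(int)


def hu_rho_from_hu(hu, rho):
    """Mass-density-normalized HU from a measured HU and known density.

    Scalar or array; ``rho`` must be strictly positive. The result is
    unrounded — use :func:`round_half_away` to compare with printed tables.
    """
    hu = np.asarray(hu, dtype=float)
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr <= 0):
        raise ValueError("mass density must be strictly positive")
    out = (hu + 1000.0) / rho_arr - 1000.0
    return float(out) if out.ndim == 0 else out


def rho_from_hu(hu, hu_rho):
    """Mass density from measured HU and the material's intrinsic HU_rho.

    Exact inverse of :func:`hu_rho_from_hu`. ``hu_rho`` must exceed -1000
    (the vacuum limit of the mass-attenuation ratio).
    """
    hu = np.asarray(hu, dtype=float)
    hu_rho_arr = np.asarray(hu_rho, dtype=float)
    if np.any(hu_rho_arr <= -1000.0):
        raise ValueError("HU_rho must be greater than -1000")
    if np.any(hu < -1000.0):
        raise ValueError(
            "HU below -1000 implies negative density; mask air voxels first "
            "(bulk conversion in humol.volume maps them to zero)"
        )
    out = (hu + 1000.0) / (hu_rho_arr + 1000.0)
    return float(out) if out.ndim == 0 else out


def hu_rho_from_molecular(comp: MolecularComposition, params: ModelParams) -> float:
    """HU_rho predicted from molecular mass fractions (affine, water = 0)."""
    lipid, protein, mineral = comp.nonwater()
    a = params.alpha
    return lipid * a["lipid"] + protein * a["protein"] + mineral * a["mineral"]


def electron_ratio_from_molecular(comp: MolecularComposition, params: ModelParams) -> float:
    """rho_e/rho predicted from molecular mass fractions (pure water = 1)."""
    lipid, protein, mineral = comp.nonwater()
    b = params.beta
    if not b:
        raise ValueError("beta coefficients not set on these parameters")
    return 1.0 + lipid * b["lipid"] + protein * b["protein"] + mineral * b["mineral"]


def rho_e_from_hu(hu, comp: MolecularComposition, params: ModelParams):
    """Electron density directly from HU and molecular composition.

    Identically equal to ``rho_from_hu(hu, HU_rho(comp)) * (rho_e/rho)(comp)``
    — the factorization through mass density is exact, not approximate.
    """
    denominator = hu_rho_from_molecular(comp, params) + 1000.0
    if denominator <= 0:
        raise ValueError("degenerate composition: sum(omega*alpha) + 1000 <= 0")
    ratio = electron_ratio_from_molecular(comp, params)
    hu = np.asarray(hu, dtype=float)
    out = (hu + 1000.0) * ratio / denominator
    return float(out) if out.ndim == 0 else out


def electron_ratio_from_elemental(elem: ElementalComposition) -> float:
    """rho_e/rho from elemental composition: (sum w_i Z_i/A_i) / (Z/A)_water."""
    return elem.z_over_a() / z_over_a_water()


def rho_e_from_elemental(rho: float, elem: ElementalComposition) -> float:
    """Electron density relative to water from mass density and elements."""
    if rho <= 0:
        raise ValueError("mass density must be strictly positive")
    return rho * electron_ratio_from_elemental(elem)


def simulate_hu(rho, comp: MolecularComposition, params: ModelParams):
    """The HU a material would image at, given density, composition, and
    calibrated alpha coefficients — the forward model used by the synthetic
    phantom generator. Inverting it through :func:`hu_rho_from_hu` recovers
    the affine molecular HU_rho exactly.
    """
    rho_arr = np.asarray(rho, dtype=float)
    out = rho_arr * (1000.0 + hu_rho_from_molecular(comp, params)) - 1000.0
    return float(out) if out.ndim == 0 else out


def convert(hu: float, comp: MolecularComposition, params: ModelParams) -> DensityResult:
    """Full scalar conversion of one HU measurement to densities."""
    hu_rho = hu_rho_from_molecular(comp, params)
    rho = rho_from_hu(hu, hu_rho)
    rho_e = rho * electron_ratio_from_molecular(comp, params)
    return DensityResult(rho=rho, rho_e=rho_e, hu_rho=hu_rho)
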