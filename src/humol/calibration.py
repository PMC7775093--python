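"""Empirical calibration: phantom-based alpha fits, tissue-based beta
regression, the clinical piecewise-linear baseline, and material QC.

The phantom route (method 2) to the alpha coefficients needs no knowledge
of the x-ray spectrum: scan a phantom of materials with known mass density,
convert each measured HU to HU_rho via (HU+1000)/rho - 1000, and regress
HU_rho on the (lipid, protein, mineral) mass fractions with no intercept —
pure water is the zero reference, so the model is forced through the
origin. The beta coefficients are likewise a no-intercept regression of
rho_e/rho - 1, computed from elemental Z/A sums, on the same fractions.

Both fits are unweighted ordinary least squares; the published coefficients
are reproduced from the rounded printed phantom data without weighting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .composition import ElementalComposition, MolecularComposition
from .model import ModelParams, electron_ratio_from_elemental, hu_rho_from_hu

__all__ = [
    "CalibrationMaterial",
    "FitResult",
    "fit_alpha_from_phantom",
    "fit_beta_from_tissues",
    "PiecewiseLUT",
    "build_piecewise_lut",
    "qc_flag_materials",
]

logger = logging.getLogger(__name__)

#: Chlorine mass fraction at or above which a surrogate is flagged as
#: non-biological (inclusive threshold).
CHLORINE_THRESHOLD = 0.01


@dataclass
class CalibrationMaterial:
    """One phantom insert: composition(s), density, measured HU per beam."""

    name: str
    molecular: MolecularComposition | None = None
    elemental: ElementalComposition | None = None
    rho: float = 0.0
    hu: dict[str, float] = field(default_factory=dict)
    rho_e: float | None = None
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"{self.name}: mass density must be positive")
        if self.molecular is None and self.elemental is None:
            raise ValueError(f"{self.name}: need molecular or elemental composition")

    def hu_rho(self, beam: str) -> float:
        """Unrounded HU_rho for one beam from measured HU and known rho."""
        if beam not in self.hu:
            raise KeyError(f"{self.name}: no HU measured for beam {beam!r}")
        return hu_rho_from_hu(self.hu[beam], self.rho)


@dataclass(frozen=True)
class FitResult:
    """A no-intercept least-squares fit with its diagnostics."""

    params: ModelParams
    residuals: np.ndarray
    r_squared: float
    rmse: float
    names: tuple[str, ...]

    def residual_for(self, name: str) -> float:
        return float(self.residuals[self.names.index(name)])


def _no_intercept_ols(design: np.ndarray, response: np.ndarray, names) -> tuple:
    """OLS through the origin with rank checking and plain diagnostics."""
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "rank-deficient design matrix (rank "
            f"{rank} < {design.shape[1]}): the materials do not span "
            "independent lipid/protein/mineral variation"
        )
    coef, *_ = np.linalg.lstsq(design, response, rcond=None)
    predicted = design @ coef
    residuals = response - predicted
    ss_res = float(residuals @ residuals)
    centered = response - response.mean()
    ss_tot = float(centered @ centered)
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(ss_res / response.size))
    return coef, residuals, r_squared, rmse


def fit_alpha_from_phantom(
    materials: Sequence[CalibrationMaterial],
    beam: str,
    exclude_flagged: bool = False,
) -> FitResult:
    """Method-2 calibration of the beam-specific alpha coefficients.

    Needs at least three materials whose lipid/protein/mineral fractions
    are not collinear. Materials carrying QC flags are included unless
    ``exclude_flagged``; either way the fit logs exactly which materials
    entered.
    """
    used = [
        m
        for m in materials
        if m.molecular is not None and not (exclude_flagged and m.qc_flags)
    ]
    if len(used) < 3:
        raise ValueError("need at least three materials with molecular compositions")
    logger.info(
        "alpha fit (%s): materials %s", beam, ", ".join(m.name for m in used)
    )
    design = np.array([m.molecular.nonwater() for m in used])
    response = np.array([m.hu_rho(beam) for m in used])
    coef, residuals, r2, rmse = _no_intercept_ols(design, response, None)
    params = ModelParams(
        alpha={"lipid": coef[0], "protein": coef[1], "mineral": coef[2]}, beam=beam
    )
    return FitResult(params, residuals, r2, rmse, tuple(m.name for m in used))


def fit_beta_from_tissues(
    tissues: Sequence[tuple[MolecularComposition, ElementalComposition]],
) -> FitResult:
    """Regress elemental-route rho_e/rho on molecular fractions.

    The response is rho_e/rho - 1 (fixed intercept 1: pure water maps to
    exactly 1), the regressors the lipid/protein/mineral mass fractions.
    """
    if len(tissues) < 3:
        raise ValueError("need at least three tissues")
    design = np.array([mol.nonwater() for mol, _ in tissues])
    response = np.array(
        [electron_ratio_from_elemental(elem) - 1.0 for _, elem in tissues]
    )
    coef, residuals, r2, rmse = _no_intercept_ols(design, response, None)
    params = ModelParams(
        alpha={"lipid": 0.0, "protein": 0.0, "mineral": 0.0},
        beta={"lipid": coef[0], "protein": coef[1], "mineral": coef[2]},
    )
    names = tuple(mol.name or f"tissue{i}" for i, (mol, _) in enumerate(tissues))
    return FitResult(params, residuals, r2, rmse, names)


class PiecewiseLUT:
    """The clinical baseline: piecewise-linear interpolation of HU.

    Breakpoints are (HU, target) pairs sorted by HU; queries interpolate
    linearly between breakpoints and continue the terminal segments
    linearly outside, with a warning beyond 10% past the calibrated HU
    range. Duplicate HU breakpoints with conflicting targets are averaged
    (logged).
    """

    def __init__(self, hu: Sequence[float], values: Sequence[float], target: str = ""):
        hu = np.asarray(hu, dtype=float)
        values = np.asarray(values, dtype=float)
        if hu.size < 2:
            raise ValueError("need at least two breakpoints")
        order = np.argsort(hu, kind="stable")
        hu, values = hu[order], values[order]
        unique_hu, inverse = np.unique(hu, return_inverse=True)
        if unique_hu.size < hu.size:
            merged = np.array(
                [values[inverse == i].mean() for i in range(unique_hu.size)]
            )
            logger.info(
                "piecewise LUT: averaged %d duplicate HU breakpoint(s)",
                hu.size - unique_hu.size,
            )
            hu, values = unique_hu, merged
        if hu.size < 2:
            raise ValueError("need at least two distinct HU breakpoints")
        self.hu = hu
        self.values = values
        self.target = target

    def __call__(self, hu_query) -> np.ndarray | float:
        query = np.asarray(hu_query, dtype=float)
        span = self.hu[-1] - self.hu[0]
        low, high = self.hu[0] - 0.1 * span, self.hu[-1] + 0.1 * span
        if np.any(query < low) or np.any(query > high):
            warnings.warn(
                "query more than 10% beyond the calibrated HU range "
                f"[{self.hu[0]:g}, {self.hu[-1]:g}]; extrapolating linearly",
                stacklevel=2,
            )
        slopes_lo = (self.values[1] - self.values[0]) / (self.hu[1] - self.hu[0])
        slopes_hi = (self.values[-1] - self.values[-2]) / (self.hu[-1] - self.hu[-2])
        out = np.interp(query, self.hu, self.values)
        out = np.where(
            query < self.hu[0], self.values[0] + slopes_lo * (query - self.hu[0]), out
        )
        out = np.where(
            query > self.hu[-1], self.values[-1] + slopes_hi * (query - self.hu[-1]), out
        )
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "hu": self.hu.tolist(),
            "values": self.values.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PiecewiseLUT":
        return cls(payload["hu"], payload["values"], target=payload.get("target", ""))


def build_piecewise_lut(
    materials: Sequence[CalibrationMaterial],
    beam: str,
    target: str = "rho_e",
    exclude_flagged: bool = False,
) -> PiecewiseLUT:
    """Build the clinical HU -> rho or rho_e lookup from phantom inserts.

    ``target`` selects the calibrated quantity: ``"rho"`` uses each
    material's known mass density, ``"rho_e"`` its reference electron
    density (which for commercial phantoms is a manufacturer-provided
    fixture value).
    """
    used = [m for m in materials if not (exclude_flagged and m.qc_flags)]
    hu = [m.hu[beam] for m in used]
    if target == "rho":
        values = [m.rho for m in used]
    elif target == "rho_e":
        if any(m.rho_e is None for m in used):
            missing = [m.name for m in used if m.rho_e is None]
            raise ValueError(f"materials without reference rho_e: {missing}")
        values = [m.rho_e for m in used]
    else:
        raise ValueError(f"unknown LUT target {target!r}")
    return PiecewiseLUT(hu, values, target=target)


def qc_flag_materials(
    materials: Iterable[CalibrationMaterial],
    chlorine_threshold: float = CHLORINE_THRESHOLD,
) -> dict[str, list[str]]:
    """Flag surrogates whose chemistry is not biologically plausible.

    Currently one rule: a chlorine mass fraction at or above the threshold
    (default 1%) marks the material for exclusion from model fits, since
    chlorine at that level does not occur in human tissues and distorts
    the photoelectric component at kV energies. Flags are recorded on the
    materials; exclusion itself stays under the caller's control.
    """
    flags: dict[str, list[str]] = {}
    for material in materials:
        material_flags = []
        if material.elemental is not None:
            cl = material.elemental["Cl"]
            if cl >= chlorine_threshold:
                material_flags.append(
                    f"chlorine mass fraction {cl:.3f} >= {chlorine_threshold:.3f}"
                )
        for flag in material_flags:
            if flag not in material.qc_flags:
                material.qc_flags.append(flag)
        flags[material.name] = material_flags
        if material_flags:
            logger.info("QC flag %s: %s", material.name, "; ".join(material_flags))
    return flags
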