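"""Voxelwise conversion of HU volumes to density maps, and report tables.

Scanner exports may carry float or integer HU; nothing is rounded on
input. Voxels labeled air, or whose HU falls at or below -1000, convert to
rho = rho_e = 0 (their count is logged) instead of raising as the scalar
API does — real volumes always contain air.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import CalibrationMaterial, PiecewiseLUT
from .composition import MolecularComposition
from .model import (
    ModelParams,
    electron_ratio_from_molecular,
    hu_rho_from_molecular,
)

__all__ = ["convert_volume", "run_report"]

logger = logging.getLogger(__name__)

AIR_LABEL = 0


def convert_volume(
    hu: np.ndarray,
    labels: np.ndarray,
    materials: Mapping[int, MolecularComposition],
    params: ModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert an HU volume to mass-density and electron-density volumes.

    ``materials`` maps label values to molecular compositions; label 0 is
    reserved for air and needs no entry. Unlabeled voxel values (labels
    present in the map key set of neither air nor ``materials``) raise,
    listing the offending labels.
    """
    hu = np.asarray(hu, dtype=float)
    labels = np.asarray(labels)
    if hu.shape != labels.shape:
        raise ValueError("HU volume and label map must have the same shape")
    present = set(np.unique(labels).tolist()) - {AIR_LABEL}
    missing = sorted(present - set(materials))
    if missing:
        raise ValueError(f"label values without material definitions: {missing}")

    rho = np.zeros_like(hu)
    rho_e = np.zeros_like(hu)
    for label in sorted(present):
        comp = materials[label]
        mask = labels == label
        hu_rho = hu_rho_from_molecular(comp, params)
        ratio = electron_ratio_from_molecular(comp, params)
        rho[mask] = (hu[mask] + 1000.0) / (hu_rho + 1000.0)
        rho_e[mask] = rho[mask] * ratio

    degenerate = (hu <= -1000.0) & (labels != AIR_LABEL)
    n_air = int(np.count_nonzero(labels == AIR_LABEL))
    n_degenerate = int(np.count_nonzero(degenerate))
    if n_degenerate:
        rho[degenerate] = 0.0
        rho_e[degenerate] = 0.0
    logger.info(
        "convert_volume: %d air voxels, %d labeled voxels at HU <= -1000 set to zero",
        n_air,
        n_degenerate,
    )
    return rho, rho_e


def run_report(
    materials: list[CalibrationMaterial],
    params: ModelParams,
    hu: Mapping[str, float] | None = None,
    lut_rho: PiecewiseLUT | None = None,
    lut_rho_e: PiecewiseLUT | None = None,
) -> pd.DataFrame:
    """Compare ground truth against imaging-derived densities per material.

    For each material with a measured HU (taken from ``hu`` by name, or
    from the material's own record for the params' beam), reports rho and
    rho_e by the molecular-composition method and, when LUTs are given, by
    the clinical piecewise-linear baseline, with percent errors against
    the material's ground truth.
    """
    rows = []
    for material in materials:
        if hu is not None and material.name in hu:
            hu_value = hu[material.name]
        elif params.beam in material.hu:
            hu_value = material.hu[params.beam]
        else:
            raise ValueError(f"no HU measurement for material {material.name!r}")
        hu_rho = hu_rho_from_molecular(material.molecular, params)
        rho_mol = (hu_value + 1000.0) / (hu_rho + 1000.0)
        rho_e_mol = rho_mol * electron_ratio_from_molecular(material.molecular, params)
        row = {
            "name": material.name,
            "hu": hu_value,
            "rho_true": material.rho,
            "rho_e_true": material.rho_e,
            "rho_molecular": rho_mol,
            "rho_e_molecular": rho_e_mol,
            "rho_molecular_err_pct": 100.0 * (rho_mol - material.rho) / material.rho,
        }
        if material.rho_e is not None:
            row["rho_e_molecular_err_pct"] = (
                100.0 * (rho_e_mol - material.rho_e) / material.rho_e
            )
        if lut_rho is not None:
            rho_lut = lut_rho(hu_value)
            row["rho_piecewise"] = rho_lut
            row["rho_piecewise_err_pct"] = 100.0 * (rho_lut - material.rho) / material.rho
        if lut_rho_e is not None and material.rho_e is not None:
            rho_e_lut = lut_rho_e(hu_value)
            row["rho_e_piecewise"] = rho_e_lut
            row["rho_e_piecewise_err_pct"] = (
                100.0 * (rho_e_lut - material.rho_e) / material.rho_e
            )
        rows.append(row)
    return pd.DataFrame(rows)
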