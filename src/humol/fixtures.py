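"""Bundled reference data: phantom tables, molecule library, reference
tissues, attenuation grid, and example beam spectra.

Everything the calibration and validation pipeline needs ships with the
package as plain text, so every stage runs without downloads:

* ``table1`` — the CIRS commercial calibration phantom (assumed molecular
  compositions, manufacturer densities, measured kV/MV HU).
* ``table2`` — an in-house tissue-mimicking phantom with measured
  ground-truth densities and imaging-derived estimates.
* ``molecules`` — elemental compositions for the four model molecules.
* ``tissues`` — reference human tissues with both elemental and molecular
  compositions, for the beta regression and spectrum cross-checks.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .calibration import CalibrationMaterial
from .composition import ElementalComposition, MolecularComposition
from .model import ModelParams
from .spectrum import AttenuationTable, BeamModel, gamma_spectrum

__all__ = [
    "load_fixture",
    "molecule_library",
    "model_molecules",
    "reference_tissues",
    "table1_materials",
    "table2_materials",
    "kv_spectrum",
    "mv_spectrum",
    "attenuation_table",
    "published_params",
    "materials_from_frame",
]

_FIXTURE_FILES = {
    "table1": "table1_cirs.csv",
    "table2": "table2_inhouse.csv",
    "tissues": "tissues_icru44.csv",
}

_ELEMENT_COLUMNS = ["H", "C", "N", "O", "Na", "Mg", "P", "S", "Cl", "K", "Ca", "Fe"]


def load_fixture(name: str) -> pd.DataFrame | dict:
    """Return a bundled fixture verbatim (``table1``/``table2``/``tissues``
    as DataFrames, ``molecules`` as a dict)."""
    if name == "molecules":
        with resources.files("humol.data").joinpath("molecules.json").open() as fh:
            payload = json.load(fh)
        payload.pop("_comment", None)
        return payload
    try:
        filename = _FIXTURE_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; expected one of "
            f"{sorted(_FIXTURE_FILES) + ['molecules']}"
        ) from None
    with resources.files("humol.data").joinpath(filename).open() as fh:
        return pd.read_csv(fh, comment="#")


def molecule_library() -> dict[str, ElementalComposition]:
    """Elemental compositions of the four reference molecules."""
    library = {}
    for name, entry in load_fixture("molecules").items():
        if "formula" in entry:
            library[name] = ElementalComposition.from_formula(entry["formula"], name=name)
        else:
            library[name] = ElementalComposition(entry["mass_fractions"], name=name)
    return library


def model_molecules() -> dict[str, ElementalComposition]:
    """The molecule library keyed by model axis (mineral = hydroxyapatite),
    the mapping :func:`humol.alpha_from_spectrum` expects."""
    library = molecule_library()
    return {
        "water": library["water"],
        "lipid": library["lipid"],
        "protein": library["protein"],
        "mineral": library["hydroxyapatite"],
    }


def _molecular_from_row(row: pd.Series) -> MolecularComposition:
    return MolecularComposition(
        water=row["omega_water"],
        lipid=row["omega_lipid"],
        protein=row["omega_protein"],
        mineral=row["omega_mineral"],
        name=str(row["name"]),
    )


def materials_from_frame(frame: pd.DataFrame) -> list[CalibrationMaterial]:
    """Build calibration materials from the standard material-table schema
    (columns name, omega_*, rho, hu_<beam>..., optional rho_e)."""
    hu_columns = {
        column[3:]: column for column in frame.columns if column.startswith("hu_")
        and not column.startswith("hu_rho")
    }
    materials = []
    for _, row in frame.iterrows():
        materials.append(
            CalibrationMaterial(
                name=str(row["name"]),
                molecular=_molecular_from_row(row),
                rho=float(row["rho"]),
                rho_e=float(row["rho_e"]) if "rho_e" in frame.columns else None,
                hu={beam: float(row[col]) for beam, col in hu_columns.items()},
            )
        )
    return materials


def table1_materials() -> list[CalibrationMaterial]:
    """The CIRS calibration phantom as calibration materials."""
    return materials_from_frame(load_fixture("table1"))


def table2_materials() -> list[CalibrationMaterial]:
    """The in-house tissue-mimicking phantom (ground truth densities)."""
    frame = load_fixture("table2")
    materials = []
    for _, row in frame.iterrows():
        materials.append(
            CalibrationMaterial(
                name=str(row["name"]),
                molecular=_molecular_from_row(row),
                rho=float(row["rho"]),
                rho_e=float(row["rho_e"]),
                hu={},
            )
        )
    return materials


def reference_tissues() -> list[tuple[MolecularComposition, ElementalComposition]]:
    """Reference tissues as (molecular, elemental) composition pairs."""
    frame = load_fixture("tissues")
    pairs = []
    for _, row in frame.iterrows():
        molecular = _molecular_from_row(row)
        elemental = ElementalComposition(
            {el: float(row[el]) for el in _ELEMENT_COLUMNS if float(row[el]) > 0},
            name=str(row["name"]),
        )
        pairs.append((molecular, elemental))
    return pairs


def attenuation_table() -> AttenuationTable:
    """The bundled XCOM-style elemental mass-attenuation grid."""
    return AttenuationTable.bundled()


def kv_spectrum() -> BeamModel:
    """The bundled example kVCT spectrum (heavily filtered 120 kVp)."""
    with resources.files("humol.data").joinpath("spectrum_kv120.csv").open() as fh:
        return BeamModel.from_csv(fh, label="kV120")


def mv_spectrum() -> BeamModel:
    """The default MVCT beam model (gamma PDF, 0.86 MeV mean energy)."""
    return gamma_spectrum(label="MV3.5")


def published_params(beam: str = "kv") -> ModelParams:
    """The published phantom-calibrated (method 2) model coefficients.

    These are the printed empirical values — alpha from the CIRS phantom
    fit for the requested beam, beta from the reference-tissue regression —
    carried as fixture inputs for sensitivity tables and worked examples.
    Refitting them from the bundled tables reproduces them to the printed
    precision.
    """
    alphas = {
        "kv": {"lipid": -50.8, "protein": -58.1, "mineral": 604.8},
        "mv": {"lipid": 4.5, "protein": -54.7, "mineral": -77.5},
    }
    if beam not in alphas:
        raise KeyError(f"unknown beam {beam!r}; expected 'kv' or 'mv'")
    beta = {"lipid": 0.00499, "protein": -0.0419, "mineral": -0.113}
    return ModelParams(alpha=alphas[beam], beta=beta, beam=beam)
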