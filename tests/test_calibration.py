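import numpy as np
import pytest

from humol import (
    CalibrationMaterial,
    MolecularComposition,
    build_piecewise_lut,
    fit_alpha_from_phantom,
    fit_beta_from_tissues,
    hu_rho_from_hu,
    qc_flag_materials,
    simulate_hu,
)
from humol import fixtures
from humol.composition import ElementalComposition, water_elemental


def normal_equations_oracle(design, response):
    """Brute-force no-intercept OLS: solve X'X b = X'y directly."""
    return np.linalg.solve(design.T @ design, design.T @ response)


class TestAlphaFit:
    def test_phantom_kv_reproduces_published_coefficients(self, table1):
        fit = fit_alpha_from_phantom(table1, "kv")
        assert fit.params.alpha["lipid"] == pytest.approx(-50.8, abs=1.0)
        assert fit.params.alpha["protein"] == pytest.approx(-58.1, abs=1.0)
        assert fit.params.alpha["mineral"] == pytest.approx(604.8, abs=1.0)

    def test_phantom_mv_reproduces_published_coefficients(self, table1):
        fit = fit_alpha_from_phantom(table1, "mv")
        assert fit.params.alpha["lipid"] == pytest.approx(4.5, abs=1.0)
        assert fit.params.alpha["protein"] == pytest.approx(-54.7, abs=1.0)
        assert fit.params.alpha["mineral"] == pytest.approx(-77.5, abs=1.0)

    def test_matches_normal_equations_oracle(self, table1):
        design = np.array([m.molecular.nonwater() for m in table1])
        response = np.array([hu_rho_from_hu(m.hu["kv"], m.rho) for m in table1])
        oracle = normal_equations_oracle(design, response)
        fit = fit_alpha_from_phantom(table1, "kv")
        assert fit.params.alpha_vector() == pytest.approx(oracle, rel=1e-10)

    def test_water_material_residual_is_its_own_hu_rho(self, table1):
        # water rows have zero regressors, so prediction = 0 and the
        # residual equals the material's HU_rho (Solid Water: about -14)
        fit = fit_alpha_from_phantom(table1, "kv")
        solid_water = next(m for m in table1 if m.name == "Solid Water")
        assert fit.residual_for("Solid Water") == pytest.approx(
            solid_water.hu_rho("kv"), rel=1e-12
        )
        assert fit.residual_for("Solid Water") == pytest.approx(-13.78, abs=0.01)

    def test_noiseless_synthetic_recovery_to_machine_precision(self, kv_params):
        comps = [
            MolecularComposition(water=0.3, lipid=0.55, protein=0.15),
            MolecularComposition(water=0.75, lipid=0.05, protein=0.20),
            MolecularComposition(water=0.1, lipid=0.4, protein=0.3, mineral=0.2),
            MolecularComposition(water=0.05, lipid=0.2, protein=0.35, mineral=0.4),
        ]
        rhos = [0.958, 1.067, 1.164, 1.613]
        materials = [
            CalibrationMaterial(
                name=f"m{i}",
                molecular=comp,
                rho=rho,
                hu={"kv": simulate_hu(rho, comp, kv_params)},
            )
            for i, (comp, rho) in enumerate(zip(comps, rhos))
        ]
        fit = fit_alpha_from_phantom(materials, "kv")
        for key in ("lipid", "protein", "mineral"):
            assert fit.params.alpha[key] == pytest.approx(
                kv_params.alpha[key], rel=1e-9
            )

    def test_rank_deficient_design_rejected(self):
        water = MolecularComposition.pure("water")
        materials = [
            CalibrationMaterial(name=f"w{i}", molecular=water, rho=1.0, hu={"kv": 0.0})
            for i in range(4)
        ]
        with pytest.raises(ValueError, match="rank"):
            fit_alpha_from_phantom(materials, "kv")

    def test_requires_three_materials(self, table1):
        with pytest.raises(ValueError, match="three"):
            fit_alpha_from_phantom(table1[:2], "kv")


class TestBetaFit:
    def test_bundled_tissues_near_published_coefficients(self):
        fit = fit_beta_from_tissues(fixtures.reference_tissues())
        assert fit.r_squared >= 0.99
        assert fit.params.beta["lipid"] == pytest.approx(0.00499, rel=0.15)
        assert fit.params.beta["protein"] == pytest.approx(-0.0419, rel=0.15)
        assert fit.params.beta["mineral"] == pytest.approx(-0.113, rel=0.15)
        assert fit.rmse < 0.001

    def test_noiseless_recovery_from_constructed_tissues(self):
        beta = {"lipid": 0.005, "protein": -0.04, "mineral": -0.1}
        # build elemental stand-ins whose Z/A produce exactly the chosen betas
        from humol.composition import z_over_a_water

        def elem_with_ratio(ratio):
            # binary H/C mixture tuned to the requested Z/A ratio
            za_h, za_c = 1 / 1.008, 6 / 12.011
            target = ratio * z_over_a_water()
            w_h = (target - za_c) / (za_h - za_c)
            return ElementalComposition({"H": w_h, "C": 1 - w_h})

        tissues = []
        for fracs in [(0.6, 0.3, 0.1, 0.0), (0.2, 0.1, 0.4, 0.3), (0.1, 0.5, 0.2, 0.2),
                      (0.25, 0.25, 0.25, 0.25)]:
            mol = MolecularComposition(
                water=fracs[0], lipid=fracs[1], protein=fracs[2], mineral=fracs[3]
            )
            ratio = 1 + sum(
                f * beta[k] for f, k in zip(fracs[1:], ("lipid", "protein", "mineral"))
            )
            tissues.append((mol, elem_with_ratio(ratio)))
        fit = fit_beta_from_tissues(tissues)
        for key, value in beta.items():
            assert fit.params.beta[key] == pytest.approx(value, rel=1e-9)

    def test_all_water_set_is_degenerate(self):
        water = MolecularComposition.pure("water")
        tissues = [(water, water_elemental()) for _ in range(4)]
        with pytest.raises(ValueError, match="rank"):
            fit_beta_from_tissues(tissues)


class TestPiecewiseLUT:
    def test_breakpoints_reproduce_exactly(self, table1):
        lut = build_piecewise_lut(table1, "kv", target="rho_e")
        muscle = next(m for m in table1 if m.name == "Muscle")
        assert lut(muscle.hu["kv"]) == pytest.approx(1.047)

    def test_midpoint_query_averages_neighbours(self):
        materials = [
            CalibrationMaterial(name="a", molecular=MolecularComposition.pure("water"),
                                rho=1.0, rho_e=1.0, hu={"kv": 0.0}),
            CalibrationMaterial(name="b", molecular=MolecularComposition.pure("water"),
                                rho=1.2, rho_e=1.1, hu={"kv": 100.0}),
        ]
        lut = build_piecewise_lut(materials, "kv", target="rho_e")
        assert lut(50.0) == pytest.approx(1.05)

    def test_monotone_where_targets_monotone(self, table1):
        lut = build_piecewise_lut(table1, "kv", target="rho")
        queries = np.linspace(min(lut.hu), max(lut.hu), 200)
        values = lut(queries)
        assert np.all(np.diff(values) >= -1e-12)

    def test_extrapolation_continues_terminal_segment_with_warning(self):
        materials = [
            CalibrationMaterial(name="a", molecular=MolecularComposition.pure("water"),
                                rho=1.0, hu={"kv": 0.0}),
            CalibrationMaterial(name="b", molecular=MolecularComposition.pure("water"),
                                rho=2.0, hu={"kv": 1000.0}),
        ]
        lut = build_piecewise_lut(materials, "kv", target="rho")
        with pytest.warns(UserWarning, match="extrapolating"):
            assert lut(1500.0) == pytest.approx(2.5)

    def test_duplicate_hu_breakpoints_averaged(self):
        from humol.calibration import PiecewiseLUT

        lut = PiecewiseLUT([0.0, 0.0, 100.0], [1.0, 1.2, 2.0])
        assert lut(0.0) == pytest.approx(1.1)


class TestQC:
    def _material(self, name, cl):
        rest = (1 - cl) / 2
        elem = ElementalComposition({"H": rest, "O": rest, "Cl": cl} if cl else
                                    {"H": rest, "O": rest})
        return CalibrationMaterial(
            name=name, elemental=elem, rho=1.0, hu={"kv": 0.0}
        )

    def test_chlorinated_surrogate_flagged(self):
        material = self._material("lung", 0.02)
        flags = qc_flag_materials([material])
        assert flags["lung"] and material.qc_flags

    def test_water_not_flagged(self):
        material = CalibrationMaterial(
            name="water", elemental=water_elemental(), rho=1.0, hu={"kv": 0.0}
        )
        assert qc_flag_materials([material])["water"] == []

    def test_threshold_is_inclusive(self):
        material = self._material("edge", 0.01)
        assert qc_flag_materials([material])["edge"]

    def test_flagged_materials_retained_but_excludable(self, kv_params):
        flagged = self._material("lung", 0.05)
        flagged.molecular = MolecularComposition(water=0.9, protein=0.1)
        flagged.hu = {"kv": 500.0}  # wildly off-model
        clean = [
            CalibrationMaterial(
                name=f"m{i}", molecular=comp, rho=rho,
                hu={"kv": simulate_hu(rho, comp, kv_params)},
            )
            for i, (comp, rho) in enumerate([
                (MolecularComposition(water=0.3, lipid=0.55, protein=0.15), 0.96),
                (MolecularComposition(water=0.75, lipid=0.05, protein=0.2), 1.07),
                (MolecularComposition(water=0.1, lipid=0.4, protein=0.3, mineral=0.2), 1.16),
            ])
        ]
        qc_flag_materials([flagged] + clean)
        fit = fit_alpha_from_phantom([flagged] + clean, "kv", exclude_flagged=True)
        assert "lung" not in fit.names
        for key in ("lipid", "protein", "mineral"):
            assert fit.params.alpha[key] == pytest.approx(kv_params.alpha[key], rel=1e-9)
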