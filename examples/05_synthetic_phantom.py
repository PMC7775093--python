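"""End-to-end check on a synthetic voxel phantom.

Generate an HU volume from known materials (forward model + Gaussian HU
noise), re-calibrate alpha from the phantom's ROI means, then convert the
volume back to density maps and compare with ground truth.
"""

import numpy as np

from humol import (
    CalibrationMaterial,
    MolecularComposition,
    PhantomRegion,
    SyntheticPhantomSpec,
    convert_volume,
    fit_alpha_from_phantom,
    fixtures,
    generate_phantom,
)

params = fixtures.published_params("kv")
comps = {
    "adipose": (MolecularComposition(water=0.30, lipid=0.55, protein=0.15), 0.958),
    "muscle": (MolecularComposition(water=0.75, lipid=0.05, protein=0.20), 1.067),
    "trab bone": (MolecularComposition(water=0.10, lipid=0.40, protein=0.30,
                                       mineral=0.20), 1.164),
    "dense bone": (MolecularComposition(water=0.05, lipid=0.20, protein=0.35,
                                        mineral=0.40), 1.613),
}
regions = [
    PhantomRegion(name, comp, rho, (0, 8 * i, 0), (16, 8 * i + 8, 8))
    for i, (name, (comp, rho)) in enumerate(comps.items())
]
spec = SyntheticPhantomSpec(shape=(16, 32, 8), regions=regions, noise_sd=10.0, seed=7)
volume = generate_phantom(spec, params)

materials = []
for label, (name, (comp, rho)) in enumerate(comps.items(), start=1):
    roi_mean = float(volume.hu[volume.labels == label].mean())
    materials.append(CalibrationMaterial(name=name, molecular=comp, rho=rho,
                                         hu={"kv": roi_mean}))
fit = fit_alpha_from_phantom(materials, "kv")
print("recovered alpha:", {k: round(float(v), 1) for k, v in fit.params.alpha.items()})
print("generating alpha:", params.alpha)

rho_map, rho_e_map = convert_volume(
    volume.hu, volume.labels,
    {i + 1: comp for i, (comp, _) in enumerate(comps.values())}, params,
)
truth = volume.ground_truth.set_index("material")
for name in comps:
    roi = rho_map[volume.labels == truth.loc[name, "label"]]
    err = 100 * (roi.mean() - truth.loc[name, "rho"]) / truth.loc[name, "rho"]
    print(f"{name:<11} rho error over ROI: {err:+.2f}%  "
          f"(voxel SD {np.std(roi):.4f} g/cc from HU noise)")

# With 10 HU of noise over ~1000-voxel ROIs the recovered alpha sit within
# a few HU_rho of the generating values and ROI-mean densities within a
# small fraction of a percent — the pipeline is exact up to image noise.
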