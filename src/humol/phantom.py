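"""Synthetic voxel phantoms and composition sampling.

The generator builds an HU volume from first principles of the model: each
labeled region gets the noiseless HU its material would image at
(``simulate_hu``), plus optional additive Gaussian HU noise with a fixed
seed. Because the forward model is the exact inverse of the conversion
chain, generated phantoms provide machine-precision ground truth for
end-to-end tests of calibration and voxelwise conversion — they emulate CT
number statistics only, not reconstruction artifacts, beam hardening, or
partial-volume mixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import MOLECULE_NAMES, MolecularComposition
from .model import ModelParams, electron_ratio_from_molecular, simulate_hu

__all__ = [
    "PhantomRegion",
    "SyntheticPhantomSpec",
    "PhantomVolume",
    "generate_phantom",
    "sample_tissue_compositions",
]


@dataclass(frozen=True)
class PhantomRegion:
    """A box-shaped region of one material in voxel coordinates."""

    material: str
    composition: MolecularComposition
    rho: float
    start: tuple[int, int, int]
    stop: tuple[int, int, int]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))


@dataclass
class SyntheticPhantomSpec:
    """Geometry and noise model for a synthetic phantom scan."""

    shape: tuple[int, int, int]
    regions: list[PhantomRegion] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0
    background_hu: float = -1000.0  # air

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise standard deviation must be non-negative")
        for region in self.regions:
            for start, stop, size in zip(region.start, region.stop, self.shape):
                if not (0 <= start < stop <= size):
                    raise ValueError(
                        f"region {region.material!r} extends outside the grid"
                    )


@dataclass(frozen=True)
class PhantomVolume:
    """A generated phantom: HU volume, integer label map, ground truth."""

    hu: np.ndarray
    labels: np.ndarray
    ground_truth: pd.DataFrame
    label_names: dict[int, str]


def generate_phantom(spec: SyntheticPhantomSpec, params: ModelParams) -> PhantomVolume:
    """Generate an HU volume with label map and per-material ground truth.

    Region label 0 is air background. Same spec + params + seed gives a
    bit-identical volume. Overlapping regions are an error rather than a
    silent overwrite.
    """
    hu = np.full(spec.shape, spec.background_hu, dtype=float)
    labels = np.zeros(spec.shape, dtype=np.int32)
    rows = []
    label_names = {0: "air"}
    for index, region in enumerate(spec.regions, start=1):
        sl = region.slices()
        if np.any(labels[sl] != 0):
            raise ValueError(f"region {region.material!r} overlaps an earlier region")
        noiseless = simulate_hu(region.rho, region.composition, params)
        hu[sl] = noiseless
        labels[sl] = index
        rows.append(
            {
                "label": index,
                "material": region.material,
                "rho": region.rho,
                "rho_e": region.rho
                * electron_ratio_from_molecular(region.composition, params),
                "hu_noiseless": noiseless,
                **{f"omega_{m}": getattr(region.composition, m) for m in MOLECULE_NAMES},
            }
        )
        label_names[index] = region.material
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return PhantomVolume(
        hu=hu,
        labels=labels,
        ground_truth=pd.DataFrame(rows),
        label_names=label_names,
    )


def sample_tissue_compositions(
    base: MolecularComposition,
    variation: float,
    n: int,
    seed: int = 0,
) -> list[MolecularComposition]:
    """Dirichlet-style perturbations of a base composition.

    Each nonzero component is drawn from a gamma distribution with mean
    equal to its base fraction and coefficient of variation ``variation``
    (so ``variation=0.10`` emulates the ~10% relative spread reported for
    soft-tissue composition), then the draw is renormalized to unit sum.
    ``variation=0`` returns ``n`` exact copies.
    """
    if not 0.0 <= variation < 1.0:
        raise ValueError("variation must be in [0, 1)")
    if variation == 0.0:
        return [base] * n
    rng = np.random.default_rng(seed)
    names = [m for m in MOLECULE_NAMES if getattr(base, m) > 0]
    means = np.array([getattr(base, m) for m in names])
    shape = 1.0 / variation**2
    draws = rng.gamma(shape, means[None, :] / shape, size=(n, len(names)))
    draws /= draws.sum(axis=1, keepdims=True)
    return [
        MolecularComposition(**dict(zip(names, row)), name=base.name)
        for row in draws
    ]
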