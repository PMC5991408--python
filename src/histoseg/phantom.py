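"""Seeded synthetic multi-contrast brain phantoms with ground-truth labels.

The refinement methods operate purely in histogram space, so the phantom's
job is to reproduce the *statistics* the histograms separate rather than
anatomy: distinct per-tissue intensity clusters across contrasts, thin
bright vessel/dura structures producing very high gradient magnitudes at
medium-to-high intensities, one smooth multiplicative bias field shared by
all contrasts, and additive Gaussian noise.

Geometry is concentric spherical shells (WM core, GM shell, CSF shell) with
radial vessel tubes laid in the CSF shell touching the GM surface and a
dura-like cap shell outside CSF.  Default tissue means are fixture
constants whose contrast-wise orderings mimic sub-millimeter 7T anatomy
(vessels/dura bright in the T1-weighted contrast, CSF dark in T1w but
bright in PDw/T2*w); they are not claims about MR physics.  Noise presets
scale the per-contrast sigma to 0%, 16% and 32% of that contrast's GM mean,
matching the relative noise tiers used to probe histogram degradation.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .volume_io import (BACKGROUND, CSF, DEFAULT_VOCABULARY, DURA, GM, VESSEL,
                        WM, LabelVolume, MultiContrastStack, ScalarVolume)

__all__ = ["PhantomSpec", "generate_phantom", "corrupt_segmentation",
           "default_specs", "DEFAULT_TISSUE_MEANS"]

CONTRAST_NAMES = ("t1w", "pdw", "t2sw")

#: mean intensity per tissue (rows) and contrast (t1w, pdw, t2sw), arbitrary units
DEFAULT_TISSUE_MEANS: Mapping[int, tuple[float, float, float]] = {
    BACKGROUND: (2.0, 2.0, 2.0),
    WM: (100.0, 60.0, 45.0),
    GM: (70.0, 75.0, 60.0),
    CSF: (32.0, 95.0, 85.0),
    VESSEL: (160.0, 85.0, 20.0),
    DURA: (150.0, 65.0, 25.0),
}


@dataclasses.dataclass
class PhantomSpec:
    """All knobs of the synthetic phantom; reproducible per seed."""

    grid_size: tuple[int, int, int] = (64, 64, 64)
    radii: tuple[float, float, float] = (14.0, 20.0, 26.0)  # WM, GM, CSF (voxels)
    tissue_means: Mapping[int, tuple[float, float, float]] = None  # type: ignore[assignment]
    vessel_count: int = 6
    vessel_radius: float = 1.2
    dura_thickness: float = 1.5
    noise_sigma: tuple[float, float, float] = (0.0, 0.0, 0.0)  # per contrast
    bias_amplitude: float = 1.3  # peak-to-trough ratio of the bias field
    common_bias: bool = True  # one shared field, or one per contrast
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue_means is None:
            self.tissue_means = dict(DEFAULT_TISSUE_MEANS)
        r = np.asarray(self.radii, dtype=float)
        if not np.all(np.diff(r) > 0):
            raise ValueError(f"shell radii must be strictly increasing, got {self.radii}")
        if any(m <= 0 for means in self.tissue_means.values() for m in means):
            raise ValueError("tissue means must be positive")
        if any(s < 0 for s in self.noise_sigma):
            raise ValueError("noise sigma must be >= 0")
        if self.bias_amplitude < 1:
            raise ValueError("bias amplitude must be >= 1")
        half = min(self.grid_size) / 2.0
        if r[-1] + self.dura_thickness >= half:
            raise ValueError(
                f"outer radius {r[-1]} + dura {self.dura_thickness} does not fit a "
                f"{self.grid_size} grid"
            )


def _radial_vessels(labels: np.ndarray, r: np.ndarray, spec: PhantomSpec,
                    rng: np.random.Generator) -> None:
    """Lay vessel tubes radially through the CSF shell, touching GM."""
    shape = np.asarray(spec.grid_size, dtype=float)
    center = (shape - 1) / 2.0
    r_wm, r_gm, r_csf = spec.radii
    # seeded random directions on the sphere
    dirs = rng.normal(size=(spec.vessel_count, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in spec.grid_size],
                                  indexing="ij"), axis=-1) - center
    in_shell = (labels == CSF)
    for d in dirs:
        t = coords @ d                       # projection on the tube axis
        perp = coords - t[..., None] * d
        dist = np.linalg.norm(perp, axis=-1)
        tube = (dist <= spec.vessel_radius) & (t >= r_gm - 1.0) & (t <= r_csf)
        labels[tube & in_shell] = VESSEL


def generate_phantom(spec: PhantomSpec) -> tuple[MultiContrastStack, LabelVolume, LabelVolume]:
    """Generate (contrast stack, truth labels, brain mask) for a spec.

    Truth labels are noise free; all contrasts share one smooth positive
    multiplicative bias field; outputs are bit-reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_size
    center = (np.asarray(shape, dtype=float) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))

    r_wm, r_gm, r_csf = spec.radii
    labels = np.full(shape, BACKGROUND, dtype=np.int32)
    labels[r <= r_csf] = CSF
    labels[r <= r_gm] = GM
    labels[r <= r_wm] = WM
    # dura: a thin cap shell just outside CSF, oriented along an oblique
    # axis so the sheet's normal is never aligned with a grid axis over a
    # large patch (an axis-aligned flat sheet is a degenerate geometry whose
    # mid-line would defeat any central-difference derivative)
    axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
    proj = sum((g - c) * a for g, c, a in zip(grids, center, axis))
    dura = (r > r_csf) & (r <= r_csf + spec.dura_thickness) & (proj > 0.3 * r_csf)
    labels[dura] = DURA
    _radial_vessels(labels, r, spec, rng)

    # smooth positive bias field(s): exp(log(A) * (bump - 1/2)) with an
    # off-center Gaussian bump normalized to [0, 1]; per-contrast fields
    # (distinct bump centers) exercise the case where inhomogeneities
    # differ across modalities and closure can no longer cancel them
    def bias_field(offset):
        sigma_b = 0.6 * max(shape)
        bump_c = center + np.asarray(offset) * np.asarray(shape)
        bump = np.exp(-sum((g - c) ** 2 for g, c in zip(grids, bump_c))
                      / (2 * sigma_b ** 2))
        bump = (bump - bump.min()) / (bump.max() - bump.min())
        return np.exp(np.log(spec.bias_amplitude) * (bump - 0.5))

    if spec.common_bias:
        biases = [bias_field((0.25, 0.25, 0.25))] * 3
    else:
        biases = [bias_field(off) for off in
                  ((0.25, 0.25, 0.25), (-0.25, 0.2, 0.1), (0.1, -0.3, 0.25))]

    affine = np.eye(4)
    vols = []
    means = spec.tissue_means
    for ci, cname in enumerate(CONTRAST_NAMES):
        lut = np.zeros(max(means) + 1)
        for lab, m in means.items():
            lut[lab] = m[ci]
        img = lut[labels]
        if spec.noise_sigma[ci] > 0:
            img = img + rng.normal(0.0, spec.noise_sigma[ci], size=shape)
        img = img * biases[ci]
        vols.append(ScalarVolume(img, np.ones(3), affine, name=cname))

    truth = LabelVolume(labels, DEFAULT_VOCABULARY, np.ones(3), affine, name="truth")
    mask = LabelVolume((labels != BACKGROUND).astype(np.int32),
                       {0: "background", 1: "brain"}, np.ones(3), affine, name="brain_mask")
    return MultiContrastStack(vols), truth, mask


def corrupt_segmentation(truth: LabelVolume, include: Sequence[int]) -> LabelVolume:
    """Over-inclusive initial segmentation: GM plus the named labels.

    Emulates automatic segmentations in which vessels and dura are falsely
    labeled as GM; everything else is copied from the truth.
    """
    unknown = [lab for lab in include if lab not in truth.vocabulary]
    if unknown:
        raise ValueError(f"labels {unknown} not in vocabulary {sorted(truth.vocabulary)}")
    out = truth.labels.copy()
    for lab in include:
        out[truth.labels == lab] = GM
    return truth.like(out, name="corrupted")


def default_specs(seed: int = 0) -> dict[str, PhantomSpec]:
    """Named presets with noise at 0%, 16% and 32% of the GM mean."""
    gm = DEFAULT_TISSUE_MEANS[GM]
    specs = {}
    for name, rel in (("clean", 0.0), ("moderate_noise", 0.16), ("high_noise", 0.32)):
        specs[name] = PhantomSpec(noise_sigma=tuple(rel * m for m in gm), seed=seed)
    return specs
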