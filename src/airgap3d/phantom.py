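"""Synthetic FFPE-lung phantoms with injectable air artifacts.

Real phase-contrast micro-CT scans of paraffin-embedded lung show a two-phase
medium — tissue and paraffin at mid-gray intensities with no saturated
voxels — while trapped air bubbles appear as near-black voids wrapped in
near-white rims (an edge artifact of single-distance phase retrieval tuned to
the tissue/paraffin interface).  The generator here reproduces exactly that
intensity signature so every downstream stage (mask extraction, training-pair
transplantation, GAN training, pore morphometrics) can be exercised with a
known ground truth and no external data.

Tissue structure is emulated by thresholding a smoothed Gaussian random
field: white noise blurred at the pore correlation length and cut at the
quantile that yields the requested porosity, giving connected airway-like
pore networks rather than isolated spheres.  Air artifacts are perturbed
spheres whose interior is forced to ``void_value`` (default 0) and whose
surrounding shell — an isotropic Euclidean-distance band — is forced to
``rim_value`` (default 255).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .pair_factory import AirMask
from .volume_io import Volume3D

__all__ = [
    "PhantomSpec",
    "ArtifactSpec",
    "generate_lung_phantom",
    "inject_air_artifacts",
]

# clean phantoms never touch the saturated bins; artifact voxels do
_CLIP_LO, _CLIP_HI = 5, 250


@dataclass
class PhantomSpec:
    """Parameters of the clean (artifact-free) tissue phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    target_porosity: float = 0.45
    pore_correlation_length_vox: float = 3.0
    tissue_mean: float = 180.0
    paraffin_mean: float = 90.0
    noise_sd: float = 6.0
    blur_sigma_vox: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_porosity < 1.0:
            raise ValueError("target_porosity must lie in (0, 1)")
        if not 0.0 < self.paraffin_mean < self.tissue_mean < 255.0:
            raise ValueError("need 0 < paraffin_mean < tissue_mean < 255")
        if self.noise_sd < 0 or self.blur_sigma_vox < 0:
            raise ValueError("noise_sd and blur_sigma_vox must be >= 0")
        if self.pore_correlation_length_vox <= 0:
            raise ValueError("pore_correlation_length_vox must be > 0")


@dataclass
class ArtifactSpec:
    """Parameters of the injected air-bubble artifacts."""

    n_bubbles: int = 3
    radius_range_vox: tuple[float, float] = (3.0, 6.0)
    rim_thickness_vox: int = 2
    void_value: int = 0
    rim_value: int = 255
    shape_irregularity: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.radius_range_vox
        if lo > hi or lo <= 0:
            raise ValueError("radius_range_vox must satisfy 0 < min <= max")
        if self.rim_thickness_vox < 1:
            raise ValueError("rim_thickness_vox must be >= 1")
        if self.n_bubbles < 0:
            raise ValueError("n_bubbles must be >= 0")
        if self.shape_irregularity < 0:
            raise ValueError("shape_irregularity must be >= 0")


def generate_lung_phantom(spec: PhantomSpec) -> Volume3D:
    """Generate a two-phase FFPE-lung-like volume (deterministic per seed).

    The pore (paraffin-filled airway) phase is the sub-quantile set of a
    Gaussian-smoothed random field, so the measured pore fraction matches
    ``target_porosity`` before noise and blur, and stays within a few
    percentage points after.
    """
    shape = tuple(int(s) for s in spec.shape)
    if min(shape) < 4 * spec.pore_correlation_length_vox:
        raise ValueError(
            f"shape {shape} too small for correlation length "
            f"{spec.pore_correlation_length_vox} (need >= 4x per axis)"
        )
    rng = np.random.default_rng(spec.seed)
    fld = ndimage.gaussian_filter(rng.standard_normal(shape),
                                  spec.pore_correlation_length_vox)
    thr = np.quantile(fld, spec.target_porosity)
    pore = fld <= thr
    img = np.where(pore, spec.paraffin_mean, spec.tissue_mean).astype(np.float64)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, shape)
    if spec.blur_sigma_vox > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_vox)
    img = np.clip(np.floor(img + 0.5), _CLIP_LO, _CLIP_HI).astype(np.uint8)
    return Volume3D(img, voxel_size_um=2.0)


def _bubble_void(shape: tuple[int, ...], center: np.ndarray, radius: float,
                 irregularity: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean void for one bubble: a sphere with a smooth low-order radial
    perturbation ``r(direction) = r0 * (1 + irregularity * p(direction))``.

    ``p`` is a random quadratic form on the unit sphere, zero-mean by
    construction-ish and bounded, so irregularity 0 gives an exact sphere
    (analytically checkable) and small values give realistic blobby bubbles.
    """
    r_max = radius * (1.0 + 2.0 * irregularity) + 1.0
    lo = np.maximum(np.floor(center - r_max).astype(int), 0)
    hi = np.minimum(np.ceil(center + r_max).astype(int) + 1, shape)
    grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    d = np.stack([g - c for g, c in zip(grids, center)], axis=-1).astype(np.float64)
    dist = np.sqrt((d ** 2).sum(axis=-1))
    if irregularity > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(dist[..., None] > 0, d / np.maximum(dist[..., None], 1e-12), 0.0)
        A = rng.standard_normal((3, 3))
        A = 0.5 * (A + A.T)
        A -= np.trace(A) / 3.0 * np.eye(3)  # trace-free => zero spherical mean
        quad = np.einsum("...i,ij,...j->...", u, A, u)
        r_local = radius * (1.0 + irregularity * quad)
    else:
        r_local = radius
    void = dist <= r_local
    full = np.zeros(shape, dtype=bool)
    full[tuple(slice(l, h) for l, h in zip(lo, hi))] = void
    return full


def inject_air_artifacts(vol: Volume3D, spec: ArtifactSpec) -> tuple[Volume3D, AirMask]:
    """Inject air-bubble artifacts; return (volume, ground-truth mask).

    The mask is the union of void and rim voxels.  Voxels outside the mask
    are bit-identical to the input.  Rim voxels are the non-void voxels
    within ``rim_thickness_vox`` (Euclidean distance) of the void surface.
    """
    shape = vol.shape
    out = vol.data.copy()
    if spec.n_bubbles == 0:
        empty = AirMask(np.zeros(shape, dtype=bool), vol.origin)
        return Volume3D(out, vol.voxel_size_um, vol.origin), empty

    rng = np.random.default_rng(spec.seed)
    r_lo, r_hi = spec.radius_range_vox
    margin = r_hi * (1.0 + 2.0 * spec.shape_irregularity) + spec.rim_thickness_vox + 1
    if any(s - 2 * margin <= 0 for s in shape):
        raise ValueError(
            f"volume shape {shape} too small for bubbles with margin {margin:.1f}"
        )
    void = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_bubbles):
        center = np.array([rng.uniform(margin, s - margin) for s in shape])
        radius = rng.uniform(r_lo, r_hi)
        void |= _bubble_void(shape, center, radius, spec.shape_irregularity, rng)

    dist_out = ndimage.distance_transform_edt(~void)
    rim = (dist_out <= spec.rim_thickness_vox) & ~void
    out[void] = np.uint8(spec.void_value)
    out[rim] = np.uint8(spec.rim_value)
    mask = AirMask(void | rim, vol.origin)
    return Volume3D(out, vol.voxel_size_um, vol.origin), mask
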