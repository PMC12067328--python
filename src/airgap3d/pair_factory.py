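"""Training-pair construction by air-artifact transplantation.

Paired source/target cubes for supervised artifact suppression cannot be
acquired physically — the same specimen cannot be scanned both with and
without its trapped air bubbles.  Pairs are therefore manufactured: artifact
voxels are segmented out of a cube that has bubbles (two-sided intensity
thresholding at the saturated bins, morphological opening, small-component
removal, dilation to capture the bright rims) and copied verbatim into a
clean cube.  The clean cube is the target ("Real B"); the clean cube with
transplanted artifact voxels is the source ("Real A").

The mask recipe and the artifact-cube classifier share one parameter set
(:class:`MaskParams`) so that training-time and inference-time artifact
detection stay consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .volume_io import Volume3D

__all__ = [
    "AirMask",
    "MaskParams",
    "TrainingPair",
    "extract_cubes",
    "classify_artifact_cube",
    "make_air_mask",
    "transplant_artifacts",
    "build_training_set",
]


@dataclass
class AirMask:
    """Binary 3D mask of artifact voxels (void + rim)."""

    data: np.ndarray
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        self.origin = tuple(int(o) for o in self.origin)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class MaskParams:
    """Thresholds and morphology radii of the air-artifact mask recipe.

    ``low_thr``/``high_thr`` bracket the saturated artifact bins (voids near
    0, rims near 255) with tolerance for noise; the two-sided threshold is
    merged into one binary image before morphology.  ``min_component_vox``
    discards speckle components, standing in for the human judgement of a
    manual artifact/no-artifact sort.
    """

    low_thr: int = 10
    high_thr: int = 245
    opening_radius_vox: int = 1
    dilation_radius_vox: int = 2
    min_component_vox: int = 50

    def __post_init__(self) -> None:
        if not self.low_thr < self.high_thr:
            raise ValueError("low_thr must be < high_thr")
        if self.opening_radius_vox < 0 or self.dilation_radius_vox < 1:
            raise ValueError("opening_radius_vox >= 0 and dilation_radius_vox >= 1 required")
        if self.min_component_vox < 0:
            raise ValueError("min_component_vox must be >= 0")


@dataclass
class TrainingPair:
    """One supervised pair: artifact-bearing source and clean target cube."""

    source: Volume3D  # "Real A": recipient with transplanted artifact voxels
    target: Volume3D  # "Real B": untouched recipient
    mask: AirMask     # the transplanted region
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.source.shape == self.target.shape == self.mask.shape):
            raise ValueError("source, target and mask must share one shape")


def extract_cubes(vol: Volume3D, edge: int, stride: int) -> list[tuple[Volume3D, tuple[int, int, int]]]:
    """Extract cubic sub-volumes on a stride lattice, fully inside ``vol``.

    With ``stride == edge`` the cubes are non-overlapping and tile the
    largest covered sub-volume.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if any(edge > s for s in vol.shape):
        raise ValueError(f"edge {edge} exceeds volume shape {vol.shape}")
    out = []
    for oz, oy, ox in product(*(range(0, s - edge + 1, stride) for s in vol.shape)):
        cube = Volume3D(
            vol.data[oz:oz + edge, oy:oy + edge, ox:ox + edge].copy(),
            vol.voxel_size_um,
            (vol.origin[0] + oz, vol.origin[1] + oy, vol.origin[2] + ox),
        )
        out.append((cube, cube.origin))
    return out


def _extreme_voxels(data: np.ndarray, params: MaskParams) -> np.ndarray:
    return (data <= params.low_thr) | (data >= params.high_thr)


def _drop_small_components(binary: np.ndarray, min_vox: int) -> np.ndarray:
    if min_vox <= 0 or not binary.any():
        return binary
    labels, n = ndimage.label(binary)
    if n == 0:
        return binary
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_vox
    keep[0] = False
    return keep[labels]


def classify_artifact_cube(cube: Volume3D, params: MaskParams = MaskParams(),
                           min_extreme_fraction: float = 0.001) -> tuple[bool, float]:
    """Decide whether a cube contains air artifacts.

    The score is the fraction of saturated-bin voxels after removing
    connected components smaller than ``min_component_vox``; a cube is
    flagged when the score reaches ``min_extreme_fraction``.
    """
    extremes = _drop_small_components(_extreme_voxels(cube.data, params),
                                      params.min_component_vox)
    score = float(extremes.sum()) / extremes.size
    return score >= min_extreme_fraction, score


def make_air_mask(cube: Volume3D, params: MaskParams = MaskParams()) -> AirMask:
    """Segment the air-artifact voxels of a cube.

    Pipeline: two-sided threshold at the saturated bins -> morphological
    opening (ball structuring element) -> remove components smaller than
    ``min_component_vox`` -> dilate (ball) to capture the bright-rim edges.
    """
    binary = _extreme_voxels(cube.data, params)
    if params.opening_radius_vox > 0 and binary.any():
        binary = ndimage.binary_opening(binary, structure=ball(params.opening_radius_vox))
    binary = _drop_small_components(binary, params.min_component_vox)
    if binary.any():
        binary = ndimage.binary_dilation(binary, structure=ball(params.dilation_radius_vox))
    return AirMask(binary, cube.origin)


def transplant_artifacts(donor: Volume3D, recipient: Volume3D, mask: AirMask) -> TrainingPair:
    """Copy the masked voxels of ``donor`` into ``recipient``.

    Returns a pair whose source equals the recipient outside the mask and
    the donor inside it; the target is the recipient unchanged.
    """
    if not (donor.shape == recipient.shape == mask.shape):
        raise ValueError(
            f"shape mismatch: donor {donor.shape}, recipient {recipient.shape}, "
            f"mask {mask.shape}"
        )
    source = recipient.data.copy()
    source[mask.data] = donor.data[mask.data]
    return TrainingPair(
        source=Volume3D(source, recipient.voxel_size_um, recipient.origin),
        target=recipient.copy(),
        mask=mask,
        provenance={"donor_origin": donor.origin, "recipient_origin": recipient.origin},
    )


def build_training_set(clean_cubes: list[Volume3D], artifact_cubes: list[Volume3D],
                       params: MaskParams = MaskParams(), pairing_seed: int = 0,
                       n_pairs: int | None = None) -> list[TrainingPair]:
    """Build supervised pairs from classified clean and artifact cubes.

    Donor/recipient combinations are drawn in a seeded shuffled order over
    the full (artifact x clean) product, so up to ``len(artifact) *
    len(clean)`` pairs have distinct provenance; beyond that, combinations
    repeat (sampled with replacement).
    """
    if not clean_cubes or not artifact_cubes:
        raise ValueError("clean_cubes and artifact_cubes must both be non-empty")
    rng = np.random.default_rng(pairing_seed)
    combos = list(product(range(len(artifact_cubes)), range(len(clean_cubes))))
    order = rng.permutation(len(combos))
    if n_pairs is None:
        n_pairs = len(artifact_cubes)
    pairs: list[TrainingPair] = []
    for i in range(n_pairs):
        if i < len(combos):
            ai, ci = combos[order[i]]
        else:
            ai = int(rng.integers(len(artifact_cubes)))
            ci = int(rng.integers(len(clean_cubes)))
        donor, recipient = artifact_cubes[ai], clean_cubes[ci]
        mask = make_air_mask(donor, params)
        pair = transplant_artifacts(donor, recipient, mask)
        pair.provenance.update({"donor_index": ai, "recipient_index": ci, "pair_id": i})
        pairs.append(pair)
    return pairs
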