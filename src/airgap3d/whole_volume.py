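"""Whole-scan artifact suppression by tiled generator inference.

The trained generator accepts cubes of one fixed edge, so a full scan is
split into non-overlapping cubes on that lattice, each cube is screened for
air artifacts with the same classifier (and parameters) used when building
the training set, flagged cubes are replaced by the generator output, and
everything is reassembled at the original coordinates.  Artifact-free cubes
are copied bit-exactly — the operation is idempotent on clean volumes.

Dimensions that are not multiples of the cube edge are handled by either
``crop`` (process only full cubes, leave the margins untouched — the
faithful default) or ``pad_reflect`` (mirror-pad up to the next multiple,
trim afterwards).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .cgan3d import GeneratorModel, generate
from .pair_factory import MaskParams, classify_artifact_cube
from .volume_io import Volume3D

__all__ = ["TilePlan", "plan_tiles", "suppress_air_artifacts"]


@dataclass
class TilePlan:
    """Non-overlapping tiling of a volume plus per-tile artifact flags."""

    cube_edge: int
    origins: list[tuple[int, int, int]]
    flags: list[bool] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    coverage: tuple[int, int, int] = (0, 0, 0)
    margins: tuple[int, int, int] = (0, 0, 0)
    padding: tuple[int, int, int] = (0, 0, 0)
    remainder_policy: str = "crop"

    def to_dict(self) -> dict:
        return {
            "cube_edge": self.cube_edge,
            "origins": [list(o) for o in self.origins],
            "flags": list(map(bool, self.flags)),
            "scores": list(map(float, self.scores)),
            "coverage": list(self.coverage),
            "margins": list(self.margins),
            "padding": list(self.padding),
            "remainder_policy": self.remainder_policy,
        }


def plan_tiles(vol: Volume3D, edge: int, remainder_policy: str = "crop") -> TilePlan:
    """Lay out the non-overlapping cube lattice over a volume."""
    if remainder_policy not in ("crop", "pad_reflect"):
        raise ValueError(f"unknown remainder policy {remainder_policy!r}")
    shape = vol.shape
    if remainder_policy == "crop":
        if any(s < edge for s in shape):
            raise ValueError(
                f"volume shape {shape} smaller than cube edge {edge}; "
                "use remainder_policy='pad_reflect'"
            )
        counts = tuple(s // edge for s in shape)
        padding = (0, 0, 0)
    else:
        counts = tuple(-(-s // edge) for s in shape)
        padding = tuple(c * edge - s for c, s in zip(counts, shape))
    coverage = tuple(c * edge for c in counts)
    margins = tuple(s - min(cov, s) for s, cov in zip(shape, coverage))
    origins = [
        (z * edge, y * edge, x * edge)
        for z, y, x in product(*(range(c) for c in counts))
    ]
    return TilePlan(cube_edge=edge, origins=origins, coverage=coverage,
                    margins=margins, padding=padding,
                    remainder_policy=remainder_policy)


def suppress_air_artifacts(vol: Volume3D, model: GeneratorModel,
                           mask_params: MaskParams = MaskParams(),
                           min_extreme_fraction: float = 0.001,
                           remainder_policy: str = "crop") -> tuple[Volume3D, TilePlan]:
    """Suppress air artifacts across a whole volume.

    Cubes flagged artifact-free are copied bit-exactly; flagged cubes are
    replaced by the generator output.  Returns the suppressed volume (same
    shape and voxel size as the input) and the tile plan with per-tile
    flags and scores for audit.
    """
    edge = model.spec.cube_edge
    plan = plan_tiles(vol, edge, remainder_policy)

    data = vol.data
    if plan.remainder_policy == "pad_reflect" and any(plan.padding):
        data = np.pad(data, [(0, p) for p in plan.padding], mode="reflect")
    out = data.copy()

    for origin in plan.origins:
        sl = tuple(slice(o, o + edge) for o in origin)
        cube = Volume3D(data[sl], vol.voxel_size_um, origin)
        is_artifact, score = classify_artifact_cube(cube, mask_params,
                                                    min_extreme_fraction)
        plan.flags.append(is_artifact)
        plan.scores.append(score)
        if is_artifact:
            out[sl] = generate(model, cube).data

    out = out[tuple(slice(0, s) for s in vol.shape)]
    return Volume3D(out, vol.voxel_size_um, vol.origin), plan
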