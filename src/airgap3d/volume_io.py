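"""Reading, writing and normalisation of 3D grayscale volumes.

Every other module consumes the in-memory :class:`Volume3D` produced here.
The axis convention is ``(z, y, x)`` with ``z`` the slice axis, matching
stacked-slice storage (one 2D image per z slice).  All processing happens on
8-bit data; floating-point inputs are windowed once, at ingest, with
:func:`to_uint8`.

Supported on-disk formats:

* TIFF stack — a directory of 2D TIFF images, one per leading-axis slice,
  with zero-padded numeric file names (``slice_0000.tif`` ...).
* NIfTI — ``.nii`` / ``.nii.gz``; the isotropic voxel size is stored in the
  header spacing fields.
* raw — a flat binary array next to a plain-text sidecar (``<name>.meta``)
  with ``key=value`` lines: ``shape``, ``dtype``, ``voxel_size_um``,
  ``byte_order``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

_FORMATS = ("tiff-stack", "nifti", "raw")


class VolumeIOError(IOError):
    """Unreadable or unwritable volume file."""


class VolumeFormatError(ValueError):
    """Structurally inconsistent volume data on disk."""


@dataclass
class Volume3D:
    """Dense 3D grid of voxel intensities with isotropic voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel intensities ``I(j, k, l)``; uint8 in [0, 255] after
        normalisation.
    voxel_size_um : float
        Isotropic voxel edge length in micrometres (e.g. 2.0 for the rat-lung
        acquisition geometry this package targets).
    origin : tuple of int
        Voxel offset of this volume/cube within a parent volume.
    """

    data: np.ndarray
    voxel_size_um: float = 1.0
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a non-empty 3D array, got shape {self.data.shape}")
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        self.origin = tuple(int(o) for o in self.origin)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.voxel_size_um, self.origin)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Volume3D):
            return NotImplemented
        return (
            self.data.shape == other.data.shape
            and bool(np.array_equal(self.data, other.data))
            and self.voxel_size_um == other.voxel_size_um
            and self.origin == other.origin
        )


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (deterministic across platforms)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def to_uint8(vol: Volume3D, mode: str = "minmax", lo: float | None = None,
             hi: float | None = None) -> Volume3D:
    """Map arbitrary numeric intensities onto 8-bit [0, 255].

    ``minmax`` maps the observed minimum to 0 and maximum to 255; a constant
    volume maps to all zeros (documented convention — flat sub-blocks occur
    legitimately in phantoms).  ``fixed_window`` maps ``[lo, hi]`` linearly
    onto [0, 255] and clips outside the window.  Rounding is
    half-away-from-zero, then clip.  The mapping is monotone non-decreasing
    in the input intensity.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    if mode == "minmax":
        vmin, vmax = float(data.min()), float(data.max())
        if vmax == vmin:
            out = np.zeros_like(data)
        else:
            out = (data - vmin) / (vmax - vmin) * 255.0
    elif mode == "fixed_window":
        if lo is None or hi is None or not lo < hi:
            raise ValueError("fixed_window requires lo < hi")
        out = (data - lo) / (hi - lo) * 255.0
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'minmax' or 'fixed_window'")
    out = np.clip(_round_half_away(out), 0, 255).astype(np.uint8)
    return Volume3D(out, vol.voxel_size_um, vol.origin)


# ---------------------------------------------------------------------------
# readers / writers


def _read_tiff_stack(path: Path) -> tuple[np.ndarray, float]:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
    if not files:
        raise VolumeIOError(f"no TIFF slices found in {path}")
    slices = []
    for f in files:
        try:
            slices.append(tifffile.imread(f))
        except Exception as exc:  # pragma: no cover - delegated error text
            raise VolumeIOError(f"cannot read TIFF slice {f}: {exc}") from exc
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise VolumeFormatError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
    return np.stack(slices, axis=0), 1.0


def _write_tiff_stack(vol: Volume3D, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(vol.shape[0] - 1)))
    for i in range(vol.shape[0]):
        tifffile.imwrite(path / f"slice_{i:0{width}d}.tif", vol.data[i])


def _read_nifti(path: Path) -> tuple[np.ndarray, float]:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise VolumeIOError(f"cannot read NIfTI file {path}: {exc}") from exc
    # stored as (x, y, z); transpose back to (z, y, x)
    data = np.asarray(img.dataobj).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    return data, float(zooms[0]) if zooms else 1.0


def _write_nifti(vol: Volume3D, path: Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(vol.data).transpose(2, 1, 0), affine=np.eye(4))
    img.header.set_zooms((vol.voxel_size_um,) * 3)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


_META_KEYS = ("shape", "dtype", "voxel_size_um", "byte_order")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta")


def _read_raw(path: Path) -> tuple[np.ndarray, float]:
    meta_path = _sidecar_path(path)
    if not meta_path.exists():
        raise VolumeIOError(f"missing sidecar metadata file {meta_path}")
    meta: dict[str, str] = {}
    for line in meta_path.read_text().splitlines():
        line = line.strip()
        if line and "=" in line:
            k, v = line.split("=", 1)
            meta[k.strip()] = v.strip()
    try:
        shape = tuple(int(s) for s in re.split(r"[,x\s]+", meta["shape"]) if s)
        dtype = np.dtype(meta["dtype"])
    except KeyError as exc:
        raise VolumeFormatError(f"sidecar {meta_path} lacks key {exc}") from exc
    if meta.get("byte_order", "little") == "big":
        dtype = dtype.newbyteorder(">")
    raw = np.fromfile(path, dtype=dtype)
    expected = int(np.prod(shape))
    if raw.size != expected:
        raise VolumeFormatError(
            f"{path}: byte count implies {raw.size} voxels, sidecar shape {shape} "
            f"implies {expected}"
        )
    return raw.reshape(shape), float(meta.get("voxel_size_um", 1.0))


def _write_raw(vol: Volume3D, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(vol.data)
    data.tofile(path)
    meta = (
        f"shape={','.join(map(str, data.shape))}\n"
        f"dtype={data.dtype.name}\n"
        f"voxel_size_um={vol.voxel_size_um}\n"
        f"byte_order=little\n"
    )
    _sidecar_path(path).write_text(meta)


def read_volume(path: str | Path, format: str, voxel_size_um: float | None = None) -> Volume3D:
    """Read a volume from disk.

    If the format carries no voxel size (TIFF stack) and none is given,
    1.0 µm is assumed and a warning logged.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise VolumeIOError(f"no such file or directory: {path}")
    if format == "tiff-stack":
        data, vs = _read_tiff_stack(path)
    elif format == "nifti":
        data, vs = _read_nifti(path)
    else:
        data, vs = _read_raw(path)
    if voxel_size_um is not None:
        vs = voxel_size_um
    elif format == "tiff-stack":
        logger.warning("no voxel size metadata for %s; assuming 1.0 um", path)
    return Volume3D(data, vs)


def write_volume(vol: Volume3D, path: str | Path, format: str) -> None:
    """Write a volume to disk; ``read_volume`` inverts it bit-exactly for 8-bit data."""
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    try:
        if format == "tiff-stack":
            _write_tiff_stack(vol, path)
        elif format == "nifti":
            _write_nifti(vol, path)
        else:
            _write_raw(vol, path)
    except OSError as exc:
        raise VolumeIOError(f"cannot write {format} volume to {path}: {exc}") from exc
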