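"""Image, transform and resampling primitives shared by every pipeline stage.

Conventions
-----------
* Voxel indices are 0-based; the image ``affine`` maps index -> world mm
  (NIfTI convention, as returned by nibabel).
* All spatial transforms act world-to-world in mm, stored as 4x4 homogeneous
  matrices.
* Resampling is pull-based: each output voxel is looked up at the
  inverse-mapped world position in the moving image, with zero fill outside
  the moving image's support.  Zero fill is deliberate: a template volume
  that does not cover the whole head then produces a visible blank slab in
  the deformed mu-map rather than extrapolated tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

MODALITIES = ("emission", "ct", "mu", "label")


@dataclass
class VoxelImage:
    """A 3D scalar grid with voxel spacing and voxel-index -> world-mm affine.

    ``data`` holds activity (arbitrary units), Hounsfield units, linear
    attenuation coefficients in 1/cm, or integer region labels depending on
    ``modality``.
    """

    data: np.ndarray
    affine: np.ndarray
    modality: str = "emission"
    spacing: np.ndarray = field(default=None)  # derived in __post_init__

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"non-3D volume: got {self.data.ndim} dimensions")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.allclose(self.affine[3], [0, 0, 0, 1]):
            raise ValueError("affine last row must be (0, 0, 0, 1)")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.spacing is None:
            self.spacing = np.linalg.norm(self.affine[:3, :3], axis=0)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        if self.modality == "label":
            if not np.issubdtype(self.data.dtype, np.integer):
                raise ValueError("label images must have integer dtype")
            if self.data.min() < 0:
                raise ValueError("label images must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def world_coords(self) -> np.ndarray:
        """World (mm) coordinates of every voxel center, shape (3, *shape)."""
        idx = np.indices(self.shape, dtype=float)
        pts = np.tensordot(self.affine[:3, :3], idx, axes=(1, 0))
        return pts + self.affine[:3, 3].reshape(3, 1, 1, 1)

    def like(self, data: np.ndarray, modality: str | None = None) -> "VoxelImage":
        """New image on the same grid with different voxel values."""
        return VoxelImage(data=data, affine=self.affine.copy(),
                          modality=modality or self.modality)


@dataclass
class AffineTransform:
    """4x4 homogeneous world-to-world map in mm; rigid or full affine."""

    matrix: np.ndarray
    kind: str = "affine"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-9):
            raise ValueError("transform last row must be (0, 0, 0, 1)")
        if self.kind not in ("rigid", "affine"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "rigid":
            R = self.matrix[:3, :3]
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or not np.isclose(
                np.linalg.det(R), 1.0, atol=1e-6
            ):
                raise ValueError("rigid transform requires orthogonal 3x3 part with det +1")

    @classmethod
    def identity(cls, kind: str = "rigid") -> "AffineTransform":
        return cls(np.eye(4), kind=kind)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), kind=self.kind)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self o other: apply ``other`` first, then ``self``."""
        kind = "rigid" if self.kind == other.kind == "rigid" else "affine"
        return AffineTransform(self.matrix @ other.matrix, kind=kind)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) world points through the transform."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]


def read_image(path) -> VoxelImage:
    """Load a 3D NIfTI-1 volume.

    The modality tag is inferred from the NIfTI ``descrip`` field when the
    file was written by :func:`write_image`; otherwise it defaults to
    ``emission`` (``label`` for integer dtypes).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # malformed header
        raise ValueError(f"malformed NIfTI file {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise ValueError(f"non-3D volume: {path} has shape {img.shape}")
    data = np.asanyarray(img.dataobj)
    descrip = ""
    try:
        descrip = img.header["descrip"].tobytes().decode("ascii", "ignore").rstrip("\x00")
    except Exception:
        pass
    modality = None
    for tag in MODALITIES:
        if descrip == f"temac:{tag}":
            modality = tag
    if modality is None:
        modality = "label" if np.issubdtype(data.dtype, np.integer) else "emission"
    return VoxelImage(data=data, affine=img.affine, modality=modality)


def write_image(img: VoxelImage, path) -> None:
    """Write a :class:`VoxelImage` as NIfTI-1.  Mu values stay in 1/cm."""
    path = Path(path)
    nii = nib.Nifti1Image(img.data, img.affine)
    nii.header["descrip"] = f"temac:{img.modality}".encode("ascii")
    try:
        nib.save(nii, str(path))
    except Exception as exc:
        raise OSError(f"cannot write image to {path}: {exc}") from exc


def read_transform(path) -> AffineTransform:
    """Read a plain-text 4x4 row-major transform matrix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such transform file: {path}")
    try:
        mat = np.loadtxt(str(path))
    except ValueError as exc:
        raise ValueError(f"non-numeric token in transform file {path}") from exc
    if mat.shape != (4, 4):
        raise ValueError(f"transform file {path} must hold a 4x4 matrix, got {mat.shape}")
    R = mat[:3, :3]
    kind = "rigid" if (
        np.allclose(R @ R.T, np.eye(3), atol=1e-6) and np.isclose(np.linalg.det(R), 1.0, atol=1e-6)
    ) else "affine"
    return AffineTransform(mat, kind=kind)


def write_transform(t: AffineTransform, path) -> None:
    np.savetxt(str(path), t.matrix, fmt="%.17g")


def resample(
    moving: VoxelImage,
    t: AffineTransform,
    target: VoxelImage,
    interp: str = "trilinear",
) -> VoxelImage:
    """Resample ``moving`` onto ``target``'s grid through world transform ``t``.

    ``t`` maps moving-world onto target-world, so each output voxel pulls its
    value from the moving image at ``A_m^-1 T^-1 A_t i``.  Positions outside
    the moving volume are filled with 0.
    """
    if interp not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    if moving.modality == "label" and interp != "nearest":
        raise ValueError("label images must be resampled with nearest interpolation")
    try:
        t_inv = np.linalg.inv(t.matrix)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular transform cannot be inverted") from exc
    # Composite map: target index -> moving index.
    m = np.linalg.inv(moving.affine) @ t_inv @ target.affine
    idx = np.indices(target.shape, dtype=float).reshape(3, -1)
    src = m[:3, :3] @ idx + m[:3, 3:4]
    # Snap coordinates that are integer up to matrix-inversion roundoff, so
    # identity transforms and exact voxel-pitch shifts reproduce voxel values
    # exactly instead of leaking ~1e-14 interpolation error.
    near = np.round(src)
    snap = np.abs(src - near) < 1e-6
    src[snap] = near[snap]
    order = 1 if interp == "trilinear" else 0
    out = ndimage.map_coordinates(
        moving.data.astype(float) if order else moving.data,
        src, order=order, mode="constant", cval=0.0, prefilter=False,
    ).reshape(target.shape)
    if moving.modality == "label":
        out = out.astype(moving.data.dtype)
    return VoxelImage(data=out, affine=target.affine.copy(), modality=moving.modality)
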