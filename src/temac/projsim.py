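"""Scanner geometry, projectors, attenuation factors and noisy acquisition.

The scanner is modelled as a multi-slice 2D parallel-beam system: every
sinogram slice collects line integrals within one transaxial image plane,
with angles uniform over [0, pi).  The projector is realized as a sparse
system matrix built from bilinear ray sampling at half-voxel steps, so the
back projector (its transpose) is the exact adjoint of the forward
projector — a property the EM reconstruction relies on.

Line integrals carry mm units; attenuation coefficients are stored in 1/cm
and converted inside the integral.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter1d

from .io_core import VoxelImage
from .synthdata import HeadPhantom

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
SCATTER_FWHM_MM = 40.0  # radial width of the smooth scatter background


@dataclass(frozen=True)
class ScannerGeometry:
    """Multi-slice parallel-beam ring: angles x radial bins per slice."""

    n_angles: int = 96
    n_bins: int = 96
    bin_spacing: float = 2.0  # mm
    n_slices: int = 40
    slice_spacing: float = 3.0  # mm
    fov_radius: float = 96.0  # mm

    def __post_init__(self):
        if self.n_angles < 4 or self.n_bins < 4:
            raise ValueError("need at least 4 angles and 4 radial bins")
        if self.bin_spacing <= 0 or self.slice_spacing <= 0:
            raise ValueError("spacings must be positive")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.bin_spacing


@dataclass
class Sinogram:
    """Projection data, shape (slice, angle, radial bin)."""

    data: np.ndarray
    geometry: ScannerGeometry
    kind: str = "expectation"  # counts | expectation | acf | additive

    def __post_init__(self):
        self.data = np.asarray(self.data)
        expected = (self.geometry.n_slices, self.geometry.n_angles, self.geometry.n_bins)
        if self.data.shape != expected:
            raise ValueError(f"sinogram shape {self.data.shape} != geometry {expected}")
        if self.kind not in ("counts", "expectation", "acf", "additive"):
            raise ValueError(f"unknown sinogram kind {self.kind!r}")
        if self.kind == "counts":
            if np.any(self.data < 0) or not np.allclose(self.data, np.round(self.data)):
                raise ValueError("counts sinogram must hold non-negative integers")
        if self.kind == "acf":
            if np.any(self.data <= 0) or np.any(self.data > 1 + 1e-12):
                raise ValueError("attenuation factors must lie in (0, 1]")

    def like(self, data: np.ndarray, kind: str | None = None) -> "Sinogram":
        return Sinogram(data=data, geometry=self.geometry, kind=kind or self.kind)


_MATRIX_CACHE: dict = {}


def _grid_key(img: VoxelImage, g: ScannerGeometry):
    return (img.shape, img.affine.tobytes(), g)


def _check_grid(img: VoxelImage, g: ScannerGeometry) -> None:
    lin = img.affine[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin))):
        raise ValueError("projector requires an axis-aligned image grid")
    if img.shape[2] != g.n_slices:
        raise ValueError(
            f"image has {img.shape[2]} planes but geometry expects {g.n_slices} slices"
        )
    if not np.isclose(img.spacing[2], g.slice_spacing):
        raise ValueError("image plane spacing does not match geometry slice spacing")


def system_matrix(img: VoxelImage, g: ScannerGeometry) -> sparse.csr_array:
    """In-plane system matrix, shape (n_angles*n_bins, nx*ny).

    Entry (row, voxel) is the bilinear sampling weight times the step length
    in mm, so ``A @ plane`` approximates every line integral of the plane.
    Matrices are cached per (grid, geometry) because building dominates cost.
    """
    _check_grid(img, g)
    key = _grid_key(img, g)
    if key in _MATRIX_CACHE:
        return _MATRIX_CACHE[key]
    nx, ny = img.shape[:2]
    sx, sy = img.spacing[:2]
    ox, oy = img.affine[0, 3], img.affine[1, 3]
    step = 0.5 * min(sx, sy)
    half_len = g.fov_radius * 1.05
    ts = np.arange(-half_len, half_len + step / 2, step)
    bins = g.bin_centers

    rows_all, cols_all, vals_all = [], [], []
    for a, theta in enumerate(g.angles):
        ct, st = np.cos(theta), np.sin(theta)
        # world positions of all samples for this angle: (n_bins, n_t)
        x = bins[:, None] * ct - ts[None, :] * st
        y = bins[:, None] * st + ts[None, :] * ct
        fx = (x - ox) / sx
        fy = (y - oy) / sy
        ix0 = np.floor(fx).astype(np.int64)
        iy0 = np.floor(fy).astype(np.int64)
        wx = fx - ix0
        wy = fy - iy0
        valid = (ix0 >= 0) & (ix0 < nx - 1) & (iy0 >= 0) & (iy0 < ny - 1)
        row = np.broadcast_to((a * g.n_bins + np.arange(g.n_bins))[:, None], fx.shape)
        for dx, dy in ((0, 0), (1, 0), (0, 1), (1, 1)):
            w = (wx if dx else 1 - wx) * (wy if dy else 1 - wy) * step
            m = valid & (w > 0)
            rows_all.append(row[m])
            cols_all.append((ix0[m] + dx) * ny + (iy0[m] + dy))
            vals_all.append(w[m])
    A = sparse.csr_array(
        (
            np.concatenate(vals_all),
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        ),
        shape=(g.n_angles * g.n_bins, nx * ny),
    )
    A.sum_duplicates()
    _MATRIX_CACHE[key] = A
    return A


def forward_project(img: VoxelImage, g: ScannerGeometry) -> Sinogram:
    """Line integrals of ``img`` along every line of response, in value*mm."""
    A = system_matrix(img, g)
    nx, ny, nz = img.shape
    planes = img.data.reshape(nx * ny, nz).astype(float)
    sino = (A @ planes).T.reshape(nz, g.n_angles, g.n_bins)
    return Sinogram(np.ascontiguousarray(sino), g, kind="expectation")


def back_project(s: Sinogram, g: ScannerGeometry, grid: VoxelImage) -> VoxelImage:
    """Adjoint of :func:`forward_project` onto ``grid``."""
    if s.geometry != g:
        raise ValueError("sinogram geometry does not match")
    A = system_matrix(grid, g)
    nx, ny, nz = grid.shape
    planes = A.T @ s.data.reshape(nz, -1).T.astype(float)
    return grid.like(planes.reshape(nx, ny, nz), modality="emission")


def attenuation_factors(mu: VoxelImage, g: ScannerGeometry) -> Sinogram:
    """Photon survival factors exp(-integral of mu) per line of response.

    ``mu`` is in 1/cm; the projector integrates in mm, hence the /10.
    """
    if np.any(mu.data < 0):
        raise ValueError("attenuation coefficients must be non-negative")
    line = forward_project(mu, g)
    return Sinogram(np.exp(-line.data / 10.0), g, kind="acf")


def simulate_acquisition(
    ph: HeadPhantom,
    g: ScannerGeometry,
    total_counts: int = 5_000_000,
    scatter_fraction: float = 0.2,
    randoms_fraction: float = 0.1,
    seed: int = 0,
):
    """Simulate one noisy scan of a phantom.

    The expectation is trues*ACF + scatter + randoms: trues are attenuated
    line integrals of the activity, scatter is a radially Gaussian-smoothed
    copy of the attenuated trues scaled to the requested fraction, randoms
    are uniform.  The total expectation is scaled to ``total_counts`` and
    counts are drawn Poisson per bin.

    Returns the counts sinogram and a ground-truth record holding the exact
    scatter and randoms expectations, the true (blurred-free) mu-map and the
    trues expectation.
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    if scatter_fraction < 0 or randoms_fraction < 0 or scatter_fraction + randoms_fraction >= 1:
        raise ValueError("scatter and randoms fractions must be in [0, 1) and sum below 1")
    from .mumap import hu_to_mu  # local import to avoid a cycle

    mu = hu_to_mu(ph.hu)
    trues = forward_project(ph.activity, g)
    acf = attenuation_factors(mu, g)
    t_att = trues.data * acf.data

    tsum = t_att.sum()
    if tsum <= 0:
        raise ValueError("phantom produces no counts inside the field of view")
    trues_frac = 1.0 - scatter_fraction - randoms_fraction
    t_att = t_att * (trues_frac * total_counts / tsum)

    if scatter_fraction > 0:
        sigma_bins = SCATTER_FWHM_MM * FWHM_TO_SIGMA / g.bin_spacing
        sc = gaussian_filter1d(t_att, sigma_bins, axis=2, mode="constant")
        sc *= scatter_fraction * total_counts / sc.sum()
    else:
        sc = np.zeros_like(t_att)
    rnd = np.full_like(t_att, randoms_fraction * total_counts / t_att.size)

    expectation = t_att + sc + rnd
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expectation).astype(np.int64)

    ground_truth = {
        "trues": Sinogram(t_att, g, kind="expectation"),
        "scatter": Sinogram(sc, g, kind="additive"),
        "randoms": Sinogram(rnd, g, kind="additive"),
        "acf": acf,
        "mu": mu,
        "expectation": Sinogram(expectation, g, kind="expectation"),
    }
    return Sinogram(counts, g, kind="counts"), ground_truth


# --- sinogram file format: flat binary payload + JSON text header ----------

def write_sinogram(s: Sinogram, path) -> None:
    """Write ``<path>`` as raw little-endian binary plus ``<path>.json`` header."""
    path = Path(path)
    dtype = "<i8" if s.kind == "counts" else "<f8"
    s.data.astype(dtype).tofile(path)
    g = s.geometry
    header = {
        "shape": list(s.data.shape),
        "dtype": dtype,
        "kind": s.kind,
        "geometry": {
            "n_angles": g.n_angles, "n_bins": g.n_bins, "bin_spacing": g.bin_spacing,
            "n_slices": g.n_slices, "slice_spacing": g.slice_spacing,
            "fov_radius": g.fov_radius,
        },
    }
    Path(str(path) + ".json").write_text(json.dumps(header, indent=1))


def read_sinogram(path) -> Sinogram:
    path = Path(path)
    header = json.loads(Path(str(path) + ".json").read_text())
    g = ScannerGeometry(**header["geometry"])
    data = np.fromfile(path, dtype=header["dtype"]).reshape(header["shape"])
    return Sinogram(data, g, kind=header["kind"])
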