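"""Rigid and affine registration by coarse-to-fine block matching.

A multi-resolution pyramid is built over both images.  At every level the
fixed image is partitioned into small cubic blocks; the highest-variance
blocks are matched against the (currently resampled) moving image by
normalized cross-correlation over a voxel-quantized displacement search, and
a global transform is fitted to the resulting displacement field with
iterated trimming — the least-trimmed-squares strategy that makes block
matching robust to locally wrong matches.

Normalized cross-correlation is invariant to local affine intensity scaling,
which is exactly the robustness needed to register an attenuation-corrected
template PET onto an uncorrected emission reconstruction: the corrections
change intensity levels, not the location of structural features.

The returned transform maps moving-world onto fixed-world, so
``resample(moving, t, fixed)`` aligns the moving image with the fixed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import AffineTransform, VoxelImage, resample


PEAK_CURVATURE_MIN = 1e-4  # minimum |NCC curvature| for sub-voxel refinement


class RegistrationError(RuntimeError):
    """Raised when too few block matches survive to constrain the fit."""

    def __init__(self, message: str, score: float | None = None):
        super().__init__(message)
        self.score = score


@dataclass
class RegistrationConfig:
    levels: int = 3
    block_voxels: int = 4
    variance_keep: float = 0.5
    search_mm: tuple = (12.0, 6.0, 3.0)  # per level, coarsest -> finest
    trim_fraction: float = 0.5
    max_iter_per_level: int = 8
    mode: str = "affine"
    # Parabolic refinement of the NCC peak per block.  Off by default: the
    # vertex offsets of asymmetric peaks carry a systematic radial pattern
    # that an affine fit absorbs as spurious scale.  Rigid fits are
    # insensitive to it, and rigid cross-modality alignment benefits from
    # the averaging (see prepare_template).
    subvoxel: bool = False
    # When the finest level fails to converge within its iteration budget,
    # average this many trailing iterates (plus grant the level the same
    # number of extra iterations) instead of returning the last one.
    average_last: int = 10
    relaxation: float = 0.5  # damping of the per-iteration update

    def __post_init__(self):
        if not (0 < self.variance_keep <= 1 and 0 < self.trim_fraction <= 1):
            raise ValueError("variance_keep and trim_fraction must be in (0, 1]")
        if self.levels < 1:
            raise ValueError("need at least one pyramid level")
        if self.mode not in ("rigid", "affine"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def search_at(self, level: int) -> float:
        s = np.atleast_1d(self.search_mm).astype(float)
        return float(s[min(level, len(s) - 1)])


def _downsample(img: VoxelImage, factor: int) -> VoxelImage:
    """Block-mean downsampling with a consistently shifted affine."""
    if factor == 1:
        return VoxelImage(img.data.astype(float), img.affine.copy(), modality=img.modality)
    shape = np.asarray(img.shape)
    crop = (shape // factor) * factor
    d = img.data[: crop[0], : crop[1], : crop[2]].astype(float)
    d = d.reshape(crop[0] // factor, factor, crop[1] // factor, factor,
                  crop[2] // factor, factor).mean(axis=(1, 3, 5))
    affine = img.affine.copy()
    affine[:3, 3] = affine[:3, 3] + affine[:3, :3] @ (np.full(3, (factor - 1) / 2.0))
    affine[:3, :3] = affine[:3, :3] * factor
    return VoxelImage(d, affine, modality=img.modality)


def _center_of_mass_world(img: VoxelImage) -> np.ndarray:
    w = np.clip(img.data.astype(float), 0, None)
    total = w.sum()
    if total <= 0:
        raise RegistrationError("image has no positive mass for initialization")
    idx = np.indices(img.shape, dtype=float)
    com_idx = np.array([(idx[k] * w).sum() / total for k in range(3)])
    return img.affine[:3, :3] @ com_idx + img.affine[:3, 3]


def _block_sums(arr: np.ndarray, b: int) -> np.ndarray:
    B = np.asarray(arr.shape) // b
    v = arr[: B[0] * b, : B[1] * b, : B[2] * b]
    return v.reshape(B[0], b, B[1], b, B[2], b).sum(axis=(1, 3, 5))


def _match_blocks(fixed: VoxelImage, moving_res: np.ndarray, cfg: RegistrationConfig,
                  search_vox: int):
    """Best NCC displacement per retained block.

    Returns world block centers, world displacements and best scores.
    Ties in NCC resolve to the smallest displacement, then lexicographic,
    by evaluating candidates in that order with strict improvement.
    """
    b = cfg.block_voxels
    f = fixed.data.astype(float)
    nvox = b**3
    Sf = _block_sums(f, b)
    Sf2 = _block_sums(f * f, b)
    var_f = Sf2 - Sf**2 / nvox
    nblocks = var_f.size

    keep_n = max(int(np.ceil(cfg.variance_keep * nblocks)), 1)
    thresh = np.sort(var_f.ravel())[::-1][keep_n - 1]
    keep = (var_f >= thresh) & (var_f > 1e-12)

    pad = search_vox
    mpad = np.pad(moving_res, pad, mode="constant")
    X, Y, Z = f.shape

    n_off = 2 * search_vox + 1
    offsets = [
        (dx, dy, dz)
        for dx in range(-search_vox, search_vox + 1)
        for dy in range(-search_vox, search_vox + 1)
        for dz in range(-search_vox, search_vox + 1)
    ]
    offsets.sort(key=lambda d: (d[0] ** 2 + d[1] ** 2 + d[2] ** 2, d))

    best_ncc = np.full(var_f.shape, -np.inf)
    best_d = np.zeros(var_f.shape + (3,))
    ncc_cube = np.full((n_off, n_off, n_off) + var_f.shape, -np.inf)
    eps = 1e-12
    for dx, dy, dz in offsets:
        m = mpad[pad + dx: pad + dx + X, pad + dy: pad + dy + Y, pad + dz: pad + dz + Z]
        Sm = _block_sums(m, b)
        Sm2 = _block_sums(m * m, b)
        Sfm = _block_sums(f * m, b)
        var_m = Sm2 - Sm**2 / nvox
        cov = Sfm - Sf * Sm / nvox
        with np.errstate(invalid="ignore", divide="ignore"):
            ncc = cov / np.sqrt(np.maximum(var_f * var_m, eps))
        ncc = np.where(var_m > 1e-12, ncc, -np.inf)
        ncc_cube[dx + search_vox, dy + search_vox, dz + search_vox] = ncc
        better = ncc > best_ncc
        best_ncc = np.where(better, ncc, best_ncc)
        best_d[better] = (dx, dy, dz)

    if cfg.subvoxel:
        # Parabolic refinement of the NCC peak along each axis; skipped at
        # the search boundary.  Counters the half-voxel bias of the
        # quantized search that trimming alone cannot average away.
        bidx = (best_d + search_vox).astype(int)
        grids = np.indices(var_f.shape)
        for axis in range(3):
            c = bidx[..., axis]
            interior = (c > 0) & (c < n_off - 1)
            lo = np.clip(c - 1, 0, n_off - 1)
            hi = np.clip(c + 1, 0, n_off - 1)
            sel = [bidx[..., 0], bidx[..., 1], bidx[..., 2]]
            sel_lo = list(sel)
            sel_lo[axis] = lo
            sel_hi = list(sel)
            sel_hi[axis] = hi
            n0 = ncc_cube[sel[0], sel[1], sel[2], grids[0], grids[1], grids[2]]
            nl = ncc_cube[sel_lo[0], sel_lo[1], sel_lo[2], grids[0], grids[1], grids[2]]
            nh = ncc_cube[sel_hi[0], sel_hi[1], sel_hi[2], grids[0], grids[1], grids[2]]
            with np.errstate(invalid="ignore", divide="ignore"):
                denom = nl - 2 * n0 + nh
                delta = 0.5 * (nl - nh) / denom
            # require real curvature at the peak: on a near-flat correlation
            # surface (e.g. self-registration) the quotient is numerical
            # noise clipped to +-0.5 voxel, which the fit turns into
            # spurious scale/rotation
            ok = interior & np.isfinite(delta) & (denom < -PEAK_CURVATURE_MIN)
            best_d[..., axis] += np.where(ok, np.clip(delta, -0.5, 0.5), 0.0)

    valid = keep & np.isfinite(best_ncc)
    bi = np.argwhere(valid)
    if bi.size == 0:
        return np.empty((0, 3)), np.empty((0, 3)), np.empty(0)
    centers_idx = bi * b + (b - 1) / 2.0
    lin, off = fixed.affine[:3, :3], fixed.affine[:3, 3]
    p = centers_idx @ lin.T + off
    d_world = best_d[valid] @ lin.T
    return p, d_world, best_ncc[valid]


def _fit_rigid(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = t
    return M


def _fit_affine(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    Ph = np.hstack([P, np.ones((len(P), 1))])
    X, *_ = np.linalg.lstsq(Ph, Q, rcond=None)
    M = np.eye(4)
    M[:3, :3] = X[:3].T
    M[:3, 3] = X[3]
    return M


def _trimmed_fit(P, Q, mode: str, trim_fraction: float, min_matches: int) -> np.ndarray:
    fit = _fit_rigid if mode == "rigid" else _fit_affine
    inliers = np.arange(len(P))
    M = None
    for _ in range(4):
        if len(inliers) < min_matches:
            raise RegistrationError(
                f"only {len(inliers)} block matches survive trimming "
                f"(need {min_matches} for {mode} fit)"
            )
        M = fit(P[inliers], Q[inliers])
        res = np.linalg.norm(P @ M[:3, :3].T + M[:3, 3] - Q, axis=1)
        keep_n = max(int(np.ceil(trim_fraction * len(P))), min_matches)
        new_inliers = np.argsort(res, kind="stable")[:keep_n]
        if len(new_inliers) == len(inliers) and np.array_equal(np.sort(new_inliers), np.sort(inliers)):
            break
        inliers = new_inliers
    return M


def _delta_magnitude(M: np.ndarray) -> tuple[float, float]:
    """Translation norm (mm) and rotation-equivalent angle (deg) of an update."""
    t = float(np.linalg.norm(M[:3, 3]))
    A = M[:3, :3]
    cosang = (np.trace(A) - 1.0) / 2.0
    ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    return t, ang


def register(moving: VoxelImage, fixed: VoxelImage, cfg: RegistrationConfig | None = None) -> AffineTransform:
    """Estimate the world transform mapping ``moving`` onto ``fixed``."""
    cfg = cfg or RegistrationConfig()
    for img, name in ((moving, "moving"), (fixed, "fixed")):
        if np.ptp(img.data) == 0:
            raise RegistrationError(f"{name} image is constant")

    # Center-of-mass initialization.
    T = np.eye(4)
    T[:3, 3] = _center_of_mass_world(fixed) - _center_of_mass_world(moving)

    min_matches = {"rigid": 6, "affine": 12}
    for level in range(cfg.levels):
        factor = 2 ** (cfg.levels - 1 - level)
        f_lvl = _downsample(fixed, factor)
        m_lvl = _downsample(moving, factor)
        voxel = float(np.min(f_lvl.spacing))
        search_vox = max(int(np.ceil(cfg.search_at(level) / voxel)), 1)
        # Affine mode still solves the coarsest level rigidly for stability.
        stage = "rigid" if (cfg.mode == "rigid" or level == 0) else "affine"
        finest = level == cfg.levels - 1
        iters = cfg.max_iter_per_level + (cfg.average_last if finest else 0)
        converged = False
        history = []
        for _ in range(iters):
            m_res = resample(m_lvl, AffineTransform(T), f_lvl, interp="trilinear")
            P, D, _scores = _match_blocks(f_lvl, m_res.data, cfg, search_vox)
            if len(P) < min_matches[stage]:
                raise RegistrationError(
                    f"{len(P)} usable block matches at level {level} "
                    f"(need {min_matches[stage]})"
                )
            dS = _trimmed_fit(P, P + D, stage, cfg.trim_fraction, min_matches[stage])
            # Damped update: the quantized search overestimates sub-voxel
            # residuals, which makes undamped iterations oscillate.
            dS = np.eye(4) + cfg.relaxation * (dS - np.eye(4))
            T = np.linalg.inv(dS) @ T
            history.append(T.copy())
            dt, dang = _delta_magnitude(dS)
            if dt < 0.01 and dang < 0.01:
                converged = True
                break
        if finest and not converged and cfg.average_last > 1:
            # Noisy matching (cross-modality or low counts) leaves the
            # fixed-point iteration wandering in a small basin instead of
            # converging; averaging the trailing iterates gives a stable,
            # reproducible estimate at its center.
            T = np.mean(history[-cfg.average_last:], axis=0)

    if cfg.mode == "rigid":
        # Numerical cleanup: project the linear part back onto SO(3).
        U, _, Vt = np.linalg.svd(T[:3, :3])
        R = U @ np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))]) @ Vt
        T = T.copy()
        T[:3, :3] = R
        return AffineTransform(T, kind="rigid")
    return AffineTransform(T, kind="affine")
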