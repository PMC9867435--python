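"""Digital head phantoms for end-to-end testing of the correction pipeline.

Each phantom is a set of nested ellipsoids on a common grid: scalp (soft
tissue), skull shell (bone), cortical gray matter over a white-matter core,
air-filled paranasal sinuses, and a neck stub.  Three co-registered volumes
are produced: an emission activity map, a CT image in Hounsfield units, and
an integer label atlas that partitions the brain into contiguous volumes of
interest (VOIs).

The generator exposes the three axes of anatomical variation the template
study design needs: head tilt about the left-right axis, loss of inferior
coverage (an all-air slab replacing the bottom of the scan, the failure mode
that punches a blank gap into a deformed mu-map), and paranasal sinus size.
Regional uptake varies across VOIs through seeded multiplicative factors so
relative VOI intensities have realistic spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.segmentation import watershed

from .io_core import VoxelImage

# Tissue constants: conventional HU values and arbitrary-unit FDG-like activity.
HU_AIR = -1000.0
HU_SOFT = 0.0
HU_WHITE = 25.0
HU_GRAY = 40.0
HU_SKULL = 800.0
ACT_GRAY = 3.0
ACT_SOFT = 0.3


@dataclass
class PhantomParams:
    seed: int
    tilt_deg: float
    crop_mm: float
    sinus_scale: float
    gray_white_ratio: float
    n_vois: int


@dataclass
class HeadPhantom:
    """Paired activity / HU / VOI-label volumes on one grid."""

    activity: VoxelImage
    hu: VoxelImage
    vois: VoxelImage
    params: PhantomParams

    @property
    def brain_mask(self) -> np.ndarray:
        return self.vois.data > 0


def centered_affine(shape, spacing) -> np.ndarray:
    """Index->world affine placing the volume center at the world origin."""
    shape = np.asarray(shape)
    spacing = np.asarray(spacing, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = -(shape - 1) / 2.0 * spacing
    return affine


def _ellipsoid(coords, center, semi):
    x, y, z = coords
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def make_head_phantom(
    shape=(64, 64, 40),
    spacing=(3.0, 3.0, 3.0),
    seed: int = 0,
    tilt_deg: float = 0.0,
    crop_mm: float = 0.0,
    sinus_scale: float = 1.0,
    n_vois: int = 16,
    gray_white_ratio: float = 3.0,
    voi_uptake_sigma: float = 0.15,
) -> HeadPhantom:
    """Build one head phantom.

    Parameters
    ----------
    shape, spacing
        Grid size (>= (32, 32, 16)) and voxel size in mm.
    seed
        Drives anatomical jitter (+-8% on ellipsoid semi-axes), VOI seed
        placement and per-VOI uptake factors.  Same seed, same phantom.
    tilt_deg
        Head tilt about the left-right (x) axis, degrees.
    crop_mm
        Thickness of the inferior slab replaced by air, emulating a scan
        that missed the bottom of the head.
    sinus_scale
        Volume multiplier for the paranasal air sinuses (1 = nominal).
    n_vois
        Number of contiguous brain VOIs in the label atlas.
    voi_uptake_sigma
        Log-normal sigma of the per-VOI regional uptake factors; 0 gives
        anatomically uniform gray/white uptake.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < m for s, m in zip(shape, (32, 32, 16))):
        raise ValueError("phantom grid must be at least (32, 32, 16)")
    if n_vois < 2:
        raise ValueError("need at least 2 VOIs")
    spacing = np.asarray(spacing, dtype=float)
    rng = np.random.default_rng(seed)
    affine = centered_affine(shape, spacing)

    extent = np.asarray(shape) * spacing  # mm
    idx = np.indices(shape, dtype=float)
    world = np.tensordot(affine[:3, :3], idx, axes=(1, 0)) + affine[:3, 3].reshape(3, 1, 1, 1)

    # Head geometry in mm, jittered per seed.
    jit = 1.0 + 0.08 * rng.uniform(-1, 1, size=3)
    head_c = np.array([0.0, 0.0, extent[2] * 0.08])
    scalp_semi = np.array([extent[0] * 0.34, extent[1] * 0.40, extent[2] * 0.42]) * jit
    skull_outer = scalp_semi - 5.0
    skull_inner = skull_outer - 6.0
    brain_semi = skull_inner - 2.0
    white_semi = brain_semi * 0.62

    # Evaluate shapes in the head frame, tilted about x through the head center.
    th = np.deg2rad(tilt_deg)
    rel = world - head_c.reshape(3, 1, 1, 1)
    y = np.cos(th) * rel[1] + np.sin(th) * rel[2]
    z = -np.sin(th) * rel[1] + np.cos(th) * rel[2]
    coords = (rel[0], y, z)
    origin = np.zeros(3)

    scalp = _ellipsoid(coords, origin, scalp_semi)
    skull = _ellipsoid(coords, origin, skull_outer) & ~_ellipsoid(coords, origin, skull_inner)
    brain = _ellipsoid(coords, origin, brain_semi)
    white = _ellipsoid(coords, origin, white_semi)

    # Paranasal sinuses: paired air pockets in the anterior-inferior face,
    # between brain and scalp; semi-axes scale with sinus_scale ** (1/3).
    s = max(float(sinus_scale), 0.0) ** (1.0 / 3.0)
    sinus_semi = np.array([9.0, 11.0, 11.0]) * s
    sinus_c = np.array([0.0, -scalp_semi[1] * 0.62, -scalp_semi[2] * 0.52])
    sinus = np.zeros(shape, dtype=bool)
    if s > 0:
        for dx in (-11.0, 11.0):
            sinus |= _ellipsoid(coords, sinus_c + [dx, 0, 0], sinus_semi)
    sinus &= ~brain  # sinuses never replace brain tissue

    # Neck stub: soft-tissue cylinder from below the head to the volume floor.
    neck_top = -scalp_semi[2] * 0.55
    neck = (coords[0] ** 2 + (y - scalp_semi[1] * 0.15) ** 2 <= 32.0**2) & (z < neck_top)

    hu = np.full(shape, HU_AIR)
    act = np.zeros(shape)
    for mask, h, a in (
        (neck, HU_SOFT, ACT_SOFT),
        (scalp, HU_SOFT, ACT_SOFT),
        (skull, HU_SKULL, 0.0),
        (brain, HU_GRAY, ACT_GRAY),
        (white, HU_WHITE, ACT_GRAY / gray_white_ratio),
        (sinus, HU_AIR, 0.0),
    ):
        hu[mask] = h
        act[mask] = a

    # Inferior coverage loss: bottom crop_mm of the volume replaced by air.
    if crop_mm > 0:
        head_bottom = head_c[2] - scalp_semi[2]
        zmin = float(world[2].min())
        if zmin + crop_mm > head_c[2]:
            raise ValueError("crop_mm exceeds the head extent")
        cropped = world[2] < zmin + crop_mm
        hu[cropped] = HU_AIR
        act[cropped] = 0.0
        del head_bottom
    else:
        cropped = np.zeros(shape, dtype=bool)

    brain_mask = (brain | white) & ~cropped & ~sinus
    n_brain = int(brain_mask.sum())
    if n_brain < n_vois:
        raise ValueError(f"n_vois={n_vois} exceeds brain voxel count {n_brain}")

    # Contiguous VOI partition: nearest-seed flooding inside the brain mask.
    flat = np.flatnonzero(brain_mask)
    seeds = rng.choice(flat, size=n_vois, replace=False)
    markers = np.zeros(shape, dtype=np.int32)
    markers.flat[seeds] = np.arange(1, n_vois + 1)
    labels = watershed(np.zeros(shape), markers=markers, mask=brain_mask).astype(np.int32)

    # Seeded regional uptake variation across VOIs.
    if voi_uptake_sigma > 0:
        factors = rng.lognormal(mean=0.0, sigma=voi_uptake_sigma, size=n_vois)
        for lab in range(1, n_vois + 1):
            act[labels == lab] *= factors[lab - 1]

    params = PhantomParams(seed=seed, tilt_deg=float(tilt_deg), crop_mm=float(crop_mm),
                           sinus_scale=float(sinus_scale),
                           gray_white_ratio=float(gray_white_ratio), n_vois=int(n_vois))
    return HeadPhantom(
        activity=VoxelImage(act, affine, modality="emission"),
        hu=VoxelImage(hu, affine, modality="ct"),
        vois=VoxelImage(labels, affine, modality="label"),
        params=params,
    )


def make_template_set(n_templates: int, seed: int = 100, **phantom_kwargs) -> list[HeadPhantom]:
    """Phantoms with systematically varied tilt, coverage and sinus size.

    The set always contains at least one member with inferior coverage loss
    (crop_mm > 0) and one with enlarged paranasal sinuses (sinus_scale > 1),
    mirroring the anatomical variation a pool of scanned template subjects
    would show.
    """
    if n_templates < 1:
        raise ValueError("need at least one template")
    base = [
        dict(tilt_deg=0.0, crop_mm=0.0, sinus_scale=1.0),   # well-covered baseline
        dict(tilt_deg=3.0, crop_mm=0.0, sinus_scale=1.8),   # pronounced sinuses
        dict(tilt_deg=5.0, crop_mm=38.0, sinus_scale=1.0),  # insufficient coverage
        dict(tilt_deg=8.0, crop_mm=0.0, sinus_scale=1.2),
    ]
    variations = [dict(base[i % len(base)]) for i in range(n_templates)]
    if not any(v["crop_mm"] > 0 for v in variations):
        variations[-1]["crop_mm"] = 38.0
    if not any(v["sinus_scale"] > 1 for v in variations):
        variations[0]["sinus_scale"] = 1.8
    out = []
    for i, var in enumerate(variations):
        out.append(make_head_phantom(seed=seed + 7919 * (i + 1), **var, **phantom_kwargs))
    return out
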