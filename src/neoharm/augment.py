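"""Training-time data augmentation for image/label pairs.

Transforms and parameter ranges follow common neonatal-MRI training
practice: random affine (rotations up to +/-10 degrees, scaling 0.8-1.2),
random motion ghosting (rotations +/-2 degrees, translations +/-2 mm),
random k-space spike artifacts, and random multiplicative bias fields.
Spatial transforms are applied identically to the image (trilinear) and the
label map (nearest neighbour); intensity-only artifacts touch the image
alone.  Everything is deterministic given the seed.

Motion is emulated by averaging the image with a small number of rigidly
displaced copies (ghosting), and spikes by injecting a high-intensity point
into the image's k-space; both are lightweight stand-ins for full k-space
simulation that reproduce the characteristic artifact appearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import TissueLabelMap, Volume3D

__all__ = ["AugmentPlan", "sample_affine", "augment_pair"]


@dataclass(frozen=True)
class AugmentPlan:
    """Ranges and per-transform application probabilities."""

    rot_deg: float = 10.0
    scale_range: tuple[float, float] = (0.8, 1.2)
    motion_rot_deg: float = 2.0
    motion_trans_mm: float = 2.0
    spike_intensity: tuple[float, float] = (0.05, 0.15)
    bias_amplitude: float = 0.2
    p_affine: float = 0.5
    p_motion: float = 0.5
    p_spike: float = 0.5
    p_bias: float = 0.5
    affine_only: bool = False  # parcellation training uses affine alone

    def __post_init__(self):
        if self.scale_range[0] > self.scale_range[1]:
            raise ValueError("scale_range must be ordered")
        for p in (self.p_affine, self.p_motion, self.p_spike, self.p_bias):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.rot_deg < 0 or self.motion_rot_deg < 0 or self.motion_trans_mm < 0:
            raise ValueError("ranges must be non-negative")


def _rotation_matrix(angles_rad: np.ndarray) -> np.ndarray:
    ax, ay, az = angles_rad
    rx = np.array([[1, 0, 0],
                   [0, np.cos(ax), -np.sin(ax)],
                   [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)],
                   [0, 1, 0],
                   [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0],
                   [np.sin(az), np.cos(az), 0],
                   [0, 0, 1]])
    return rz @ ry @ rx


def sample_affine(plan: AugmentPlan, seed: int,
                  shape: tuple[int, int, int] = (1, 1, 1)) -> np.ndarray:
    """Draw a random 4x4 voxel-space affine composed about the volume centre.

    Rotation angles per axis are uniform in +/-rot_deg; a single isotropic
    scale factor is uniform in scale_range.  The 3x3 block's determinant is
    therefore the cubed scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ang = np.deg2rad(rng.uniform(-plan.rot_deg, plan.rot_deg, size=3))
    s = rng.uniform(*plan.scale_range)
    m = _rotation_matrix(ang) * s
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    out = np.eye(4)
    out[:3, :3] = m
    out[:3, 3] = center - m @ center
    return out


def _apply_affine(data: np.ndarray, mat: np.ndarray, order: int) -> np.ndarray:
    # ndimage maps output coords through matrix to input coords: use inverse
    inv = np.linalg.inv(mat)
    return ndimage.affine_transform(data, inv[:3, :3], offset=inv[:3, 3],
                                    order=order, mode="nearest")


def _motion_ghost(img: np.ndarray, plan: AugmentPlan, spacing: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    out = img.astype(float).copy()
    weight = 1.0
    n_ghost = 2
    for _ in range(n_ghost):
        ang = np.deg2rad(rng.uniform(-plan.motion_rot_deg, plan.motion_rot_deg, 3))
        trans_vox = rng.uniform(-plan.motion_trans_mm, plan.motion_trans_mm, 3) / spacing
        m = np.eye(4)
        m[:3, :3] = _rotation_matrix(ang)
        center = (np.asarray(img.shape, dtype=float) - 1.0) / 2.0
        m[:3, 3] = center - m[:3, :3] @ center + trans_vox
        w = rng.uniform(0.1, 0.3)
        out = out + w * _apply_affine(img.astype(float), m, order=1)
        weight += w
    return out / weight


def _spike(img: np.ndarray, plan: AugmentPlan, rng: np.random.Generator) -> np.ndarray:
    k = np.fft.fftn(img)
    shape = np.asarray(img.shape)
    # a spike away from the k-space centre produces a stripe pattern
    pos = tuple((rng.integers(2, max(3, s // 4)) for s in shape))
    amp = rng.uniform(*plan.spike_intensity) * np.abs(k.ravel()[0])
    phase = rng.uniform(0, 2 * np.pi)
    k[pos] += amp * np.exp(1j * phase)
    return np.real(np.fft.ifftn(k))


def _bias(img: np.ndarray, plan: AugmentPlan, rng: np.random.Generator) -> np.ndarray:
    coarse = rng.standard_normal((3, 3, 3))
    f = ndimage.zoom(coarse, [s / 3 for s in img.shape], order=3)
    f = f[: img.shape[0], : img.shape[1], : img.shape[2]]
    pad = [(0, img.shape[i] - f.shape[i]) for i in range(3)]
    f = np.pad(f, pad, mode="edge")
    f = f / (np.abs(f).max() + 1e-12)
    return img * (1.0 + plan.bias_amplitude * f)


def augment_pair(image: Volume3D, labels: TissueLabelMap, plan: AugmentPlan,
                 seed: int) -> tuple[Volume3D, TissueLabelMap]:
    """Apply one random augmentation draw to an image/label pair.

    Order: affine -> motion -> spike -> bias.  The affine acts on both
    members (image trilinear, labels nearest-neighbour); the remaining
    transforms are intensity-only.  Grid shape and spacing never change, and
    no new label values are introduced.
    """
    if image.data.shape != labels.labels.shape:
        raise ValueError("image and label grids differ")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    img = image.data.astype(np.float32)
    lab = labels.labels
    spacing = np.asarray(image.spacing_mm)

    if rng.random() < plan.p_affine:
        mat = sample_affine(plan, seed=int(rng.integers(2**31)), shape=img.shape)
        img = _apply_affine(img.astype(float), mat, order=1).astype(np.float32)
        lab = _apply_affine(lab.astype(np.float32), mat, order=0).astype(lab.dtype)
    if not plan.affine_only:
        if rng.random() < plan.p_motion:
            img = _motion_ghost(img, plan, spacing, rng).astype(np.float32)
        if rng.random() < plan.p_spike:
            img = _spike(img, plan, rng).astype(np.float32)
        if rng.random() < plan.p_bias:
            img = _bias(img, plan, rng).astype(np.float32)
    from dataclasses import replace

    return Volume3D(np.clip(img, -1.0, 1.0), image.spacing_mm), \
        replace(labels, labels=lab)
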