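"""Data augmentation: matched spatial transforms plus image-only noise.

Spatial transforms (flip, rotation, scale, translation) are composed into a
single affine map applied once to the image (bilinear, reflective edge
padding) and exactly to the keypoints, so drawn confidence-map targets stay
aligned with the warped image.  Under a horizontal or vertical flip the
keypoint labels are permuted by the skeleton's bilateral swap relation
(left/right body parts exchange names).  Keypoints carried outside the frame
become invisible rather than being clipped.

Noise transforms (additive noise, pixel dropout, blur/sharpen, contrast)
act on the image only and leave keypoints untouched.

The default sampling distributions follow common practice for overhead
single-animal imagery: per-axis Bernoulli(0.5) flips, rotation uniform on
[-180, 180) degrees, scale uniform on [90%, 110%], and per-axis translation
uniform on [-5%, +5%] of the image size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .skeleton import KeypointSet, Skeleton

__all__ = [
    "AugmentConfig",
    "SpatialParams",
    "NoiseParams",
    "sample_params",
    "spatial_transform",
    "noise_transform",
    "affine_matrix",
    "transform_points",
    "warp_image",
]


@dataclass(frozen=True)
class SpatialParams:
    """One concrete draw of the spatial transform parameters."""

    flip_h: bool = False
    flip_v: bool = False
    theta_deg: float = 0.0
    scale: float = 1.0
    tx: float = 0.0  # translation, fraction of image width
    ty: float = 0.0  # translation, fraction of image height


@dataclass(frozen=True)
class NoiseParams:
    """One concrete draw of the image-noise parameters.

    All-zero strengths give the identity.  ``contrast_factor`` of 1 is
    neutral; dropout sets a ``dropout_fraction`` of pixels to
    ``dropout_fill``.
    """

    additive_amplitude: float = 0.0
    dropout_fraction: float = 0.0
    dropout_fill: float = 0.0
    blur_sigma: float = 0.0
    sharpen_amount: float = 0.0
    contrast_factor: float = 1.0


@dataclass(frozen=True)
class AugmentConfig:
    """Sampling distributions for augmentation parameters.

    ``flip_p`` applies independently per axis; rotation is uniform on
    ``[-rotation_range, +rotation_range)`` degrees; ``scale_range`` and
    ``translate_range`` are uniform intervals (translation as a fraction of
    image size).  Noise strengths are drawn uniformly on ``[0, max]``; the
    contrast factor uniformly on ``contrast_range``.
    """

    flip_p: float = 0.5
    rotation_range: float = 180.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_range: tuple[float, float] = (-0.05, 0.05)
    additive_amplitude_max: float = 10.0
    dropout_fraction_max: float = 0.05
    blur_sigma_max: float = 1.0
    sharpen_amount_max: float = 0.5
    contrast_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_p <= 1.0:
            raise ValueError("flip_p must be in [0, 1]")
        for name in ("scale_range", "translate_range", "contrast_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be well ordered")


def sample_params(
    config: AugmentConfig, rng: np.random.Generator
) -> tuple[SpatialParams, NoiseParams]:
    """Draw one set of spatial and noise parameters from ``config``."""
    spatial = SpatialParams(
        flip_h=bool(rng.random() < config.flip_p),
        flip_v=bool(rng.random() < config.flip_p),
        theta_deg=float(
            rng.uniform(-config.rotation_range, config.rotation_range)
        ),
        scale=float(rng.uniform(*config.scale_range)),
        tx=float(rng.uniform(*config.translate_range)),
        ty=float(rng.uniform(*config.translate_range)),
    )
    noise = NoiseParams(
        additive_amplitude=float(rng.uniform(0, config.additive_amplitude_max)),
        dropout_fraction=float(rng.uniform(0, config.dropout_fraction_max)),
        dropout_fill=0.0,
        blur_sigma=float(rng.uniform(0, config.blur_sigma_max)),
        sharpen_amount=float(rng.uniform(0, config.sharpen_amount_max)),
        contrast_factor=float(rng.uniform(*config.contrast_range)),
    )
    return spatial, noise


def affine_matrix(params: SpatialParams, shape: tuple[int, int]) -> np.ndarray:
    """Homogeneous 3x3 forward map for (x, y) points.

    Composition: flip about the image centre, then rotation/scale about the
    centre ``c = ((W-1)/2, (H-1)/2)`` with the rotation matrix
    ``[[cos, -sin], [sin, cos]]`` in (x, y-down) coordinates, then
    translation by ``(tx * W, ty * H)``.
    """
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0

    flip = np.eye(3)
    if params.flip_h:
        flip = np.array([[-1, 0, w - 1.0], [0, 1, 0], [0, 0, 1]]) @ flip
    if params.flip_v:
        flip = np.array([[1, 0, 0], [0, -1, h - 1.0], [0, 0, 1]]) @ flip

    th = np.deg2rad(params.theta_deg)
    s = params.scale
    rot = np.array(
        [
            [s * np.cos(th), -s * np.sin(th), 0],
            [s * np.sin(th), s * np.cos(th), 0],
            [0, 0, 1],
        ]
    )
    to_c = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    from_c = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
    trans = np.array(
        [[1, 0, params.tx * w], [0, 1, params.ty * h], [0, 0, 1.0]]
    )
    return trans @ from_c @ rot @ to_c @ flip


def transform_points(matrix: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Apply a homogeneous 3x3 map to an ``(K, 2)`` array of (x, y) points."""
    pts = np.asarray(pts, dtype=np.float64)
    homo = np.column_stack([pts, np.ones(len(pts))])
    out = homo @ matrix.T
    return out[:, :2]


def warp_image(image: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Warp an (H, W, C) image by the forward map ``matrix`` (one bilinear pass).

    Edge padding is by reflection.  Integer inputs are warped in float and
    clipped back to their range.
    """
    inv = np.linalg.inv(matrix)
    # scipy maps output (row, col) -> input (row, col): reorder the (x, y) map
    mat_rc = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
    off_rc = np.array([inv[1, 2], inv[0, 2]])
    out = np.empty_like(image, dtype=np.float64)
    for c in range(image.shape[2]):
        out[..., c] = ndimage.affine_transform(
            image[..., c].astype(np.float64),
            mat_rc,
            offset=off_rc,
            order=1,
            mode="reflect",
        )
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    return out


def spatial_transform(
    image: np.ndarray,
    kp: KeypointSet,
    skel: Skeleton,
    params: SpatialParams,
) -> tuple[np.ndarray, KeypointSet]:
    """Apply one spatial augmentation to an image and its keypoints.

    The image and the keypoints receive the same affine map; flips also
    permute keypoint labels by the skeleton's swap involution (once per
    flipped axis).  Keypoints mapped outside ``[0, W-1] x [0, H-1]`` are
    marked invisible.
    """
    if kp.n_keypoints != skel.n_keypoints:
        raise ValueError("keypoint count does not match skeleton")
    h, w = image.shape[:2]
    matrix = affine_matrix(params, (h, w))
    coords = transform_points(matrix, kp.coords)
    visible = kp.visible.copy()

    n_flips = int(params.flip_h) + int(params.flip_v)
    if n_flips % 2 == 1:
        coords = coords[skel.swap]
        visible = visible[skel.swap]

    with np.errstate(invalid="ignore"):
        inside = (
            (coords[:, 0] >= 0)
            & (coords[:, 0] <= w - 1)
            & (coords[:, 1] >= 0)
            & (coords[:, 1] <= h - 1)
        )
    visible = visible & inside
    return warp_image(image, matrix), KeypointSet(coords, visible)


def noise_transform(
    image: np.ndarray, params: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    """Apply image-only noise; keypoints are untouched by construction.

    Output stays in the input's valid intensity range; all-zero strengths
    (and a contrast factor of 1) return the image unchanged.
    """
    if np.issubdtype(image.dtype, np.integer):
        lo, hi = np.iinfo(image.dtype).min, np.iinfo(image.dtype).max
    else:
        lo, hi = 0.0, 1.0
    out = image.astype(np.float64)

    if params.blur_sigma > 0:
        for c in range(out.shape[2]):
            out[..., c] = ndimage.gaussian_filter(out[..., c], params.blur_sigma)
    if params.sharpen_amount > 0:
        for c in range(out.shape[2]):
            blurred = ndimage.gaussian_filter(out[..., c], 1.0)
            out[..., c] = out[..., c] + params.sharpen_amount * (
                out[..., c] - blurred
            )
    if params.contrast_factor != 1.0:
        mean = out.mean()
        out = mean + params.contrast_factor * (out - mean)
    if params.additive_amplitude > 0:
        out = out + rng.uniform(
            -params.additive_amplitude, params.additive_amplitude, out.shape
        )
    if params.dropout_fraction > 0:
        mask = rng.random(out.shape[:2]) < params.dropout_fraction
        out[mask] = params.dropout_fill

    out = np.clip(out, lo, hi)
    if np.issubdtype(image.dtype, np.integer):
        return np.rint(out).astype(image.dtype)
    return out


def augment_example(
    image: np.ndarray,
    kp: KeypointSet,
    skel: Skeleton,
    config: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, KeypointSet]:
    """Sample parameters and apply spatial then noise augmentation."""
    spatial, noise = sample_params(config, rng)
    image2, kp2 = spatial_transform(image, kp, skel, spatial)
    return noise_transform(image2, noise, rng), kp2


def no_noise(config: AugmentConfig) -> AugmentConfig:
    """Copy of ``config`` with every noise strength zeroed (spatial only)."""
    return replace(
        config,
        additive_amplitude_max=0.0,
        dropout_fraction_max=0.0,
        blur_sigma_max=0.0,
        sharpen_amount_max=0.0,
        contrast_range=(1.0, 1.0),
    )
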