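"""Synthetic articulated-animal datasets for testing every pipeline stage.

A :class:`CreatureSpec` defines a tree-structured creature: per-keypoint
segment lengths and rest angles plus angular jitter.  Poses are sampled by
forward kinematics from the root (placed at the image centre, emulating an
egocentrically aligned single individual), and images are rendered as
anti-aliased bright limbs on a dark background with additive Gaussian noise
— the structure of overhead single-animal footage, without photorealism.

Presets mirror the shape of three reference datasets: ``fly192``
(192x192, 32 keypoints), ``locust160`` (160x160, 35), ``zebra160``
(160x160, 9), all grayscale with bilaterally symmetric skeletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .skeleton import AnnotationSet, KeypointSet, Skeleton

__all__ = [
    "CreatureSpec",
    "sample_pose",
    "render",
    "make_dataset",
    "make_creature",
    "toy_creature",
    "PRESETS",
]


@dataclass(frozen=True)
class CreatureSpec:
    """Articulated-creature description used by the fixture generator.

    ``lengths[i]`` is the segment length (px) from keypoint ``i`` to its
    parent (root: 0); ``rest_angles[i]`` is the segment's rest direction in
    degrees, with 0 pointing up (-y) and positive angles clockwise;
    ``jitter_std[i]`` is the standard deviation (degrees) of Gaussian joint
    jitter, accumulated along the chain from the root so whole limbs swing
    coherently.
    """

    skeleton: Skeleton
    lengths: np.ndarray
    rest_angles: np.ndarray
    jitter_std: np.ndarray
    limb_thickness: float = 3.0
    body_radius: float = 5.0
    noise_level: float = 0.05
    image_size: tuple[int, int] = (160, 160)
    channels: int = 1
    margin: float = 15.0

    def __post_init__(self) -> None:
        k = self.skeleton.n_keypoints
        for name in ("lengths", "rest_angles", "jitter_std"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (k,):
                raise ValueError(f"{name} must have shape ({k},)")
            object.__setattr__(self, name, arr)
        if np.any(self.lengths < 0):
            raise ValueError("segment lengths must be nonnegative")
        rest = rest_pose(self)
        h, w = self.image_size
        lo = rest.coords.min(axis=0)
        hi = rest.coords.max(axis=0)
        if (
            not rest.visible.all()
            or lo[0] < self.margin
            or lo[1] < self.margin
            or hi[0] > w - 1 - self.margin
            or hi[1] > h - 1 - self.margin
        ):
            raise ValueError(
                f"rest pose does not fit image {self.image_size} with "
                f"margin {self.margin}"
            )


def _topological_order(skel: Skeleton) -> list[int]:
    order, placed = [], set()
    pending = list(range(skel.n_keypoints))
    while pending:
        rest = []
        for i in pending:
            p = skel.parent[i]
            if p == -1 or p in placed:
                order.append(i)
                placed.add(i)
            else:
                rest.append(i)
        pending = rest
    return order


def _pose(spec: CreatureSpec, jitter: np.ndarray) -> KeypointSet:
    skel = spec.skeleton
    h, w = spec.image_size
    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    coords = np.zeros((skel.n_keypoints, 2))
    accum = np.zeros(skel.n_keypoints)
    for i in _topological_order(skel):
        p = skel.parent[i]
        if p == -1:
            coords[i] = centre
            accum[i] = jitter[i]
            continue
        accum[i] = accum[p] + jitter[i]
        theta = np.deg2rad(spec.rest_angles[i] + accum[i])
        direction = np.array([np.sin(theta), -np.cos(theta)])
        coords[i] = coords[p] + spec.lengths[i] * direction
    visible = (
        (coords[:, 0] >= 0)
        & (coords[:, 0] <= w - 1)
        & (coords[:, 1] >= 0)
        & (coords[:, 1] <= h - 1)
    )
    return KeypointSet(coords, visible)


def rest_pose(spec: CreatureSpec) -> KeypointSet:
    """Deterministic pose with zero jitter."""
    return _pose(spec, np.zeros(spec.skeleton.n_keypoints))


def sample_pose(spec: CreatureSpec, rng: np.random.Generator) -> KeypointSet:
    """Forward-kinematic pose draw: rest angles plus accumulated jitter.

    The root sits at the image centre; keypoints landing outside the frame
    are marked invisible.
    """
    jitter = rng.normal(0.0, spec.jitter_std)
    return _pose(spec, jitter)


def render(
    spec: CreatureSpec, kp: KeypointSet, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Render a pose: anti-aliased limbs, a body disc, background noise.

    Returns ``(H, W, C)`` uint8.  With zero noise, limb interiors are at
    full intensity and the background at zero.
    """
    h, w = spec.image_size
    jj, ii = np.meshgrid(np.arange(w, dtype=np.float64),
                         np.arange(h, dtype=np.float64))
    canvas = np.zeros((h, w))

    def paint_segment(p0, p1, radius):
        d = p1 - p0
        len2 = float(d @ d)
        dx, dy = jj - p0[0], ii - p0[1]
        if len2 == 0.0:
            dist = np.hypot(dx, dy)
        else:
            t = np.clip((dx * d[0] + dy * d[1]) / len2, 0.0, 1.0)
            dist = np.hypot(dx - t * d[0], dy - t * d[1])
        np.maximum(canvas, np.clip(radius + 0.5 - dist, 0.0, 1.0), out=canvas)

    for child, parent in spec.skeleton.edges:
        if kp.visible[child] and kp.visible[parent]:
            paint_segment(
                kp.coords[child], kp.coords[parent], spec.limb_thickness / 2.0
            )
    root = spec.skeleton.root
    if kp.visible[root]:
        paint_segment(kp.coords[root], kp.coords[root], spec.body_radius)

    image = canvas * 255.0
    if spec.noise_level > 0 and rng is not None:
        image = image + rng.normal(0.0, spec.noise_level * 255.0, image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return np.repeat(image[..., None], spec.channels, axis=-1)


def make_dataset(spec: CreatureSpec, n: int, seed: int = 0) -> AnnotationSet:
    """Generate ``n`` annotated (image, keypoints) pairs, all marked annotated."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    images, coords, visible = [], [], []
    for _ in range(n):
        kp = sample_pose(spec, rng)
        images.append(render(spec, kp, rng))
        coords.append(kp.coords)
        visible.append(kp.visible)
    return AnnotationSet(
        images=np.stack(images),
        keypoints=np.stack(coords),
        visible=np.stack(visible),
        skeleton=spec.skeleton,
        annotated=np.ones(n, dtype=bool),
    )


# ---------------------------------------------------------------------------
# presets


def _creature(
    image_size,
    body,  # list of (name, parent, length, angle)
    limbs,  # list of (base_name, side_names..., ) described below
    jitter=8.0,
    **kwargs,
) -> CreatureSpec:
    """Assemble a bilaterally symmetric creature.

    ``body`` rows are ``(name, parent_name, length, rest_angle)``.  ``limbs``
    rows are ``(prefix, parent_name, n_joints, length, base_angle, bend)``;
    each produces a ``left_*``/``right_*`` chain mirrored through the swap
    relation, with joint ``j`` at angle ``±(base_angle + j * bend)``.
    """
    names, parents, lengths, angles, swaps = [], [], [], [], []

    def add(name, parent, length, angle, swap=""):
        names.append(name)
        parents.append(parent)
        lengths.append(length)
        angles.append(angle)
        swaps.append(swap)

    for name, parent, length, angle in body:
        add(name, parent, length, angle)
    for prefix, parent, n_joints, length, base_angle, bend in limbs:
        for side, sign in (("left", -1), ("right", 1)):
            prev = parent
            for j in range(n_joints):
                name = f"{side}_{prefix}_{j}"
                other = f"{'right' if side == 'left' else 'left'}_{prefix}_{j}"
                add(name, prev, length, sign * (base_angle + j * bend), other)
                prev = name

    lookup = {n: i for i, n in enumerate(names)}
    parent_idx = np.array(
        [lookup[p] if p else -1 for p in parents], dtype=np.int64
    )
    swap_idx = np.array(
        [lookup[s] if s else i for i, s in enumerate(swaps)], dtype=np.int64
    )
    skel = Skeleton(names=names, parent=parent_idx, swap=swap_idx)
    k = len(names)
    return CreatureSpec(
        skeleton=skel,
        lengths=np.array(lengths, dtype=np.float64),
        rest_angles=np.array(angles, dtype=np.float64),
        jitter_std=np.full(k, float(jitter)),
        image_size=image_size,
        **kwargs,
    )


def _zebra160() -> CreatureSpec:
    body = [
        ("spine", "", 0, 0),
        ("shoulder", "spine", 20, 0),
        ("neck", "shoulder", 12, 0),
        ("head", "neck", 12, 0),
        ("snout", "head", 10, 0),
        ("hip", "spine", 20, 180),
        ("tail_base", "hip", 12, 180),
    ]
    limbs = [("ear", "head", 1, 8, 50, 0)]
    return _creature((160, 160), body, limbs, jitter=6.0, body_radius=7.0)


def _fly192() -> CreatureSpec:
    body = [
        ("thorax", "", 0, 0),
        ("head", "thorax", 22, 0),
        ("abdomen_mid", "thorax", 20, 180),
        ("abdomen_tip", "abdomen_mid", 18, 180),
    ]
    limbs = [
        ("antenna", "head", 2, 9, 30, 10),
        ("front_leg", "thorax", 4, 11, 55, 12),
        ("mid_leg", "thorax", 4, 11, 90, 10),
        ("hind_leg", "thorax", 4, 11, 125, 8),
    ]
    return _creature((192, 192), body, limbs, jitter=7.0)


def _locust160() -> CreatureSpec:
    body = [
        ("head", "", 0, 0),
        ("pronotum", "head", 14, 180),
        ("abdomen_base", "pronotum", 14, 180),
        ("abdomen_mid", "abdomen_base", 13, 180),
        ("abdomen_tip", "abdomen_mid", 12, 180),
    ]
    limbs = [
        ("antenna", "head", 3, 8, 25, 8),
        ("front_leg", "pronotum", 4, 8, 60, 12),
        ("mid_leg", "pronotum", 4, 8, 95, 10),
        ("hind_leg", "abdomen_base", 4, 10, 125, 8),
    ]
    return _creature((160, 160), body, limbs, jitter=6.0)


def toy_creature(
    image_size: int = 64, jitter: float = 8.0, noise_level: float = 0.05
) -> CreatureSpec:
    """Small 5-keypoint creature for fast training and decoding tests.

    Geometry scales with ``image_size`` (the default 64 px frame holds a
    creature with 12-14 px segments).
    """
    f = image_size / 64.0
    body = [
        ("body", "", 0, 0),
        ("head", "body", 14 * f, 0),
        ("tail", "body", 12 * f, 180),
    ]
    limbs = [("arm", "body", 1, 12 * f, 80, 0)]
    return _creature(
        (image_size, image_size),
        body,
        limbs,
        jitter=jitter,
        noise_level=noise_level,
        body_radius=max(4.0 * f, 2.0),
        limb_thickness=max(3.0 * f, 1.5),
        margin=15.0 * f,
    )


PRESETS = {
    "fly192": _fly192,
    "locust160": _locust160,
    "zebra160": _zebra160,
}


def make_creature(preset: str) -> CreatureSpec:
    """Build a preset creature: ``fly192``, ``locust160``, or ``zebra160``."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return PRESETS[preset]()


def scaled_creature(preset: str, factor: float) -> CreatureSpec:
    """A preset creature scaled geometrically by ``factor``.

    Segment lengths, limb thickness, body radius, and the image size all
    scale together (the image size is rounded to a multiple of 16 so every
    supported output stride still divides it); the skeleton topology, rest
    angles, and jitter are untouched.  Useful for running the full training
    pipeline quickly at reduced resolution.
    """
    spec = make_creature(preset)
    h, w = spec.image_size
    size = (max(int(round(h * factor / 16)) * 16, 32),
            max(int(round(w * factor / 16)) * 16, 32))
    return CreatureSpec(
        skeleton=spec.skeleton,
        lengths=spec.lengths * factor,
        rest_angles=spec.rest_angles,
        jitter_std=spec.jitter_std,
        limb_thickness=max(spec.limb_thickness * factor, 1.5),
        body_radius=max(spec.body_radius * factor, 2.0),
        noise_level=spec.noise_level,
        image_size=size,
        channels=spec.channels,
        margin=spec.margin * factor,
    )
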