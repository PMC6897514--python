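"""Training-set curation: diverse frame sampling and egocentric alignment.

Frame sampling embeds each image as a downscaled grayscale vector, clusters
the embeddings with k-means (k = 10 by default), and draws frames round-robin
across clusters so the selected set spans distinct postures rather than
consecutive, highly correlated frames.

Egocentric alignment applies the rigid rotation + translation that places
the midpoint of two chosen body-axis keypoints at the image centre with the
axis pointing straight up, standardising orientation before annotation and
training.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize
from sklearn.cluster import KMeans

from .augment import transform_points, warp_image
from .skeleton import KeypointSet

__all__ = ["kmeans_sample", "egocentric_align"]

DEFAULT_K = 10


def _embed(images: np.ndarray, size: int = 32) -> np.ndarray:
    """Flattened ``size x size`` grayscale embedding of each image."""
    n = images.shape[0]
    out = np.empty((n, size * size))
    for i in range(n):
        img = images[i].astype(np.float64)
        gray = img.mean(axis=-1) if img.ndim == 3 else img
        out[i] = resize(
            gray, (size, size), order=1, anti_aliasing=True
        ).ravel()
    return out


def kmeans_sample(
    images: np.ndarray,
    k: int = DEFAULT_K,
    n: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Select ``n`` diverse frame indices by k-means cluster sampling.

    Frames are drawn round-robin across the ``k`` clusters, uniformly at
    random without replacement within each cluster, so every non-empty
    cluster contributes before any contributes twice.  Deterministic given
    ``seed``.
    """
    images = np.asarray(images)
    if images.size == 0:
        raise ValueError("empty image set")
    n_images = images.shape[0]
    n = n_images if n is None else n
    if n > n_images:
        raise ValueError(f"cannot sample {n} of {n_images} frames")
    k = min(k, n_images)

    embedding = _embed(images)
    labels = KMeans(n_clusters=k, n_init=5, random_state=seed).fit_predict(
        embedding
    )
    rng = np.random.default_rng(seed)
    pools = [
        rng.permutation(np.flatnonzero(labels == c)).tolist() for c in range(k)
    ]
    selected: list[int] = []
    while len(selected) < n:
        for pool in pools:
            if pool and len(selected) < n:
                selected.append(int(pool.pop()))
    return np.array(selected[:n])


def egocentric_align(
    image: np.ndarray,
    kp: KeypointSet,
    axis: tuple[int, int],
) -> tuple[np.ndarray, KeypointSet]:
    """Rigidly align an image so the body axis is vertical and centred.

    ``axis = (a, b)`` names two keypoints; the rigid map sends their
    midpoint to the image centre and rotates so the vector a -> b points
    along -y (up).  No scaling is applied.  Keypoints moved out of frame
    become invisible.
    """
    a, b = axis
    if not (kp.visible[a] and kp.visible[b]):
        raise ValueError("axis keypoints must be visible")
    pa, pb = kp.coords[a], kp.coords[b]
    if np.allclose(pa, pb):
        raise ValueError("axis keypoints coincide")
    h, w = image.shape[:2]
    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    mid = (pa + pb) / 2.0

    v = pb - pa
    current = np.arctan2(v[1], v[0])
    target = -np.pi / 2.0  # straight up in y-down coordinates
    th = target - current
    rot = np.array(
        [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
    )
    # p -> centre + R (p - mid)
    matrix = np.eye(3)
    matrix[:2, :2] = rot
    matrix[:2, 2] = centre - rot @ mid

    coords = transform_points(matrix, kp.coords)
    with np.errstate(invalid="ignore"):
        inside = (
            (coords[:, 0] >= 0)
            & (coords[:, 0] <= w - 1)
            & (coords[:, 1] >= 0)
            & (coords[:, 1] <= h - 1)
        )
    visible = kp.visible & inside
    return warp_image(image, matrix), KeypointSet(coords, visible)
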