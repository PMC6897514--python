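"""Skeletons, keypoint sets, and annotated datasets.

A skeleton is a rooted tree of named keypoints.  Each keypoint stores the
index of its parent (the root stores ``-1``) and the index of its bilateral
mirror partner under a left/right body flip (its own index if unpaired).
Edges of the tree — child to parent — form the posture graph used to draw
geometric training targets.

Coordinates are ``(x, y)`` with ``x`` the column and ``y`` the row, 0-based
and continuous, with the origin at the centre of the top-left pixel.
Invisible keypoints carry NaN coordinates mirrored by a boolean flag.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Skeleton",
    "KeypointSet",
    "AnnotationSet",
    "parse_skeleton",
    "skeleton_to_csv",
    "load_annotations",
    "save_annotations",
    "split_train_val",
]


class SkeletonError(ValueError):
    """Raised for malformed skeleton definitions."""


@dataclass(frozen=True)
class Skeleton:
    """Rooted tree of named keypoints with bilateral-swap relations.

    Parameters
    ----------
    names : list of str
        Ordered keypoint labels.
    parent : ndarray of int
        ``parent[i]`` is the index of keypoint ``i``'s parent; the root is
        marked with ``-1``.
    swap : ndarray of int
        ``swap[i]`` is the index of keypoint ``i``'s mirror partner;
        unpaired keypoints map to themselves.
    """

    names: tuple[str, ...]
    parent: np.ndarray
    swap: np.ndarray

    def __post_init__(self) -> None:
        parent = np.asarray(self.parent, dtype=np.int64)
        swap = np.asarray(self.swap, dtype=np.int64)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "swap", swap)
        n = len(self.names)
        if len(set(self.names)) != n:
            raise SkeletonError("duplicate keypoint names")
        if parent.shape != (n,) or swap.shape != (n,):
            raise SkeletonError("parent/swap length mismatch")
        if np.any((parent < -1) | (parent >= n)):
            raise SkeletonError("parent index out of range")
        if np.any((swap < 0) | (swap >= n)):
            raise SkeletonError("swap index out of range")
        roots = np.flatnonzero(parent == -1)
        if len(roots) != 1:
            raise SkeletonError(f"expected exactly one root, found {len(roots)}")
        if not np.array_equal(swap[swap], np.arange(n)):
            raise SkeletonError("swap relation is not an involution")
        # walk to the root from every node; a cycle never reaches it
        for i in range(n):
            seen = set()
            j = i
            while parent[j] != -1:
                if j in seen:
                    raise SkeletonError("cyclic parent relation")
                seen.add(j)
                j = parent[j]

    @property
    def n_keypoints(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def edges(self) -> list[tuple[int, int]]:
        """(child, parent) pairs for every non-root keypoint, in index order."""
        return [(i, int(p)) for i, p in enumerate(self.parent) if p != -1]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def branch_of(self, i: int) -> int:
        """Index of the child-of-root ancestor of keypoint ``i``.

        Keypoints are grouped into limbs by the branch of the root they hang
        from; the root itself maps to ``-1``.
        """
        if i == self.root:
            return -1
        j = i
        while self.parent[j] != self.root:
            j = int(self.parent[j])
        return j


def parse_skeleton(source) -> Skeleton:
    """Parse a skeleton from CSV text with columns ``name,parent,swap``.

    ``parent`` and ``swap`` refer to other rows by name; an empty ``parent``
    marks the root and an empty ``swap`` means the keypoint is its own mirror.
    ``source`` may be a path, an open text stream, or the CSV text itself.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    required = {"name", "parent", "swap"}
    if not required.issubset(df.columns):
        raise SkeletonError(f"skeleton CSV must have columns {sorted(required)}")
    names = [s.strip() for s in df["name"]]
    if len(set(names)) != len(names):
        raise SkeletonError("duplicate keypoint names")
    lookup = {name: i for i, name in enumerate(names)}

    def resolve(value: str, column: str, default: int) -> int:
        value = value.strip()
        if value == "":
            return default
        if value not in lookup:
            raise SkeletonError(f"unknown {column} name: {value!r}")
        return lookup[value]

    # the root may leave its parent empty or name itself
    parent = np.array(
        [
            -1 if (p := resolve(v, "parent", -1)) == i else p
            for i, v in enumerate(df["parent"])
        ],
        dtype=np.int64,
    )
    swap = np.array(
        [resolve(v, "swap", i) for i, v in enumerate(df["swap"])], dtype=np.int64
    )
    return Skeleton(names=names, parent=parent, swap=swap)


def skeleton_to_csv(skel: Skeleton) -> str:
    """Serialize a skeleton back to ``name,parent,swap`` CSV text."""
    rows = []
    for i, name in enumerate(skel.names):
        p = "" if skel.parent[i] == -1 else skel.names[skel.parent[i]]
        s = "" if skel.swap[i] == i else skel.names[skel.swap[i]]
        rows.append(f"{name},{p},{s}")
    return "name,parent,swap\n" + "\n".join(rows) + "\n"


@dataclass
class KeypointSet:
    """2-D keypoint coordinates plus visibility for one image.

    ``coords`` is ``(K, 2)`` float, ``(x, y)`` in input-image pixels;
    invisible keypoints hold NaN and ``visible`` is False there.
    """

    coords: np.ndarray
    visible: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        coords = np.array(self.coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must have shape (K, 2)")
        if self.visible is None:
            visible = ~np.isnan(coords).any(axis=1)
        else:
            visible = np.asarray(self.visible, dtype=bool)
        if visible.shape != (coords.shape[0],):
            raise ValueError("visible must have shape (K,)")
        coords[~visible] = np.nan
        self.coords = coords
        self.visible = visible

    @property
    def n_keypoints(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "KeypointSet":
        return KeypointSet(self.coords.copy(), self.visible.copy())


@dataclass
class AnnotationSet:
    """Images plus keypoint annotations sharing one skeleton.

    ``images`` is ``(N, H, W, C)`` uint8; ``keypoints`` is ``(N, K, 2)``
    float ``(x, y)``; ``visible`` is ``(N, K)`` bool; ``annotated`` marks
    examples whose keypoints are trustworthy ground truth.
    """

    images: np.ndarray
    keypoints: np.ndarray
    visible: np.ndarray
    skeleton: Skeleton
    annotated: np.ndarray = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.uint8)
        self.keypoints = np.asarray(self.keypoints, dtype=np.float64)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.images.ndim != 4:
            raise ValueError("images must have shape (N, H, W, C)")
        n = self.images.shape[0]
        k = self.skeleton.n_keypoints
        if self.keypoints.shape != (n, k, 2):
            raise ValueError(
                f"keypoints shape {self.keypoints.shape} does not match "
                f"N={n}, K={k}"
            )
        if self.visible.shape != (n, k):
            raise ValueError("visible must have shape (N, K)")
        if self.annotated is None:
            self.annotated = np.ones(n, dtype=bool)
        else:
            self.annotated = np.asarray(self.annotated, dtype=bool)
            if self.annotated.shape != (n,):
                raise ValueError("annotated must have shape (N,)")

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return self.images.shape[1:]

    def keypoint_set(self, i: int) -> KeypointSet:
        return KeypointSet(self.keypoints[i].copy(), self.visible[i].copy())

    def subset(self, indices) -> "AnnotationSet":
        indices = np.asarray(indices)
        if indices.dtype != bool:
            indices = indices.astype(np.int64)
        return AnnotationSet(
            images=self.images[indices],
            keypoints=self.keypoints[indices],
            visible=self.visible[indices],
            skeleton=self.skeleton,
            annotated=self.annotated[indices],
        )


def save_annotations(aset: AnnotationSet, path) -> None:
    """Write an :class:`AnnotationSet` to an HDF5 container.

    Layout: ``/images`` (uint8), ``/keypoints`` (float32, x then y),
    ``/visible`` (uint8), ``/annotated`` (uint8), with the skeleton CSV text
    stored verbatim as a root attribute.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=aset.images, dtype=np.uint8)
        f.create_dataset("keypoints", data=aset.keypoints.astype(np.float32))
        f.create_dataset("visible", data=aset.visible.astype(np.uint8))
        f.create_dataset("annotated", data=aset.annotated.astype(np.uint8))
        f.attrs["skeleton"] = skeleton_to_csv(aset.skeleton)


def load_annotations(path) -> AnnotationSet:
    """Read an :class:`AnnotationSet` written by :func:`save_annotations`."""
    with h5py.File(path, "r") as f:
        for key in ("images", "keypoints", "visible", "annotated"):
            if key not in f:
                raise KeyError(f"annotation container missing /{key}")
        if "skeleton" not in f.attrs:
            raise KeyError("annotation container missing skeleton attribute")
        skel = parse_skeleton(str(f.attrs["skeleton"]))
        return AnnotationSet(
            images=f["images"][()],
            keypoints=f["keypoints"][()].astype(np.float64),
            visible=f["visible"][()].astype(bool),
            skeleton=skel,
            annotated=f["annotated"][()].astype(bool),
        )


def validation_size(n: int, val_fraction: float) -> int:
    """Number of validation examples: ``round(N * val_fraction)``, half up."""
    return int(np.floor(n * val_fraction + 0.5))


def split_train_val(
    aset: AnnotationSet, val_fraction: float = 0.1, seed: int = 0
) -> tuple[AnnotationSet, AnnotationSet]:
    """Randomly partition into train and validation sets.

    The validation set holds ``round(N * val_fraction)`` examples; the split
    is disjoint, exhaustive, and deterministic given ``seed``.
    """
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must be in (0, 1)")
    n = len(aset)
    n_val = validation_size(n, val_fraction)
    if n_val < 1 or n - n_val < 1:
        raise ValueError(
            f"cannot split N={n} at val_fraction={val_fraction}: "
            "both splits must be nonempty"
        )
    order = np.random.default_rng(seed).permutation(n)
    val_idx = np.sort(order[:n_val])
    train_idx = np.sort(order[n_val:])
    return aset.subset(train_idx), aset.subset(val_idx)
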