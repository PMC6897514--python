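"""Ground-truth confidence maps for keypoints and the hierarchical posture graph.

Keypoint targets are 2-D Gaussians of amplitude 1 drawn on a grid downsampled
by an integer output stride ``s``; a point at image coordinate ``(x, y)``
maps to map coordinate ``(x/s, y/s)`` (pure division, no half-pixel offset,
so encoding and peak decoding are exact inverses of each other).

Posture-graph targets are Gaussian-profile line segments drawn along skeleton
edges and combined into a four-level hierarchy: individual edges, limbs
(branches of the root), the whole graph, and the whole graph fused with the
keypoint peaks.  Maps are combined with an elementwise maximum so values stay
in [0, 1] at limb junctions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import KeypointSet, Skeleton

__all__ = [
    "ConfidenceMapStack",
    "draw_keypoint_maps",
    "draw_graph_maps",
    "assemble_stack",
]

#: Default Gaussian scale of drawn peaks, in input-image pixels.
DEFAULT_SIGMA = 5.0


@dataclass
class ConfidenceMapStack:
    """A ``(K + G, h, w)`` stack of confidence maps at one output stride.

    The first ``K`` maps are keypoint peaks; the remaining ``G`` are the
    four-level posture graph.  ``level_index`` holds the boundaries of the
    graph levels inside the ``G`` graph maps as offsets
    ``[0, E, E+B, E+B+1, E+B+2]``.
    """

    maps: np.ndarray
    stride: int
    sigma: float
    n_keypoints: int
    level_index: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3:
            raise ValueError("maps must have shape (K+G, h, w)")
        if self.maps.shape[0] < self.n_keypoints:
            raise ValueError("stack shallower than n_keypoints")

    @property
    def n_graph_maps(self) -> int:
        return self.maps.shape[0] - self.n_keypoints

    @property
    def keypoint_maps(self) -> np.ndarray:
        return self.maps[: self.n_keypoints]

    @property
    def graph_maps(self) -> np.ndarray:
        return self.maps[self.n_keypoints :]

    def graph_level(self, level: int) -> np.ndarray:
        """Graph maps of one hierarchy level (1-based, 1..4)."""
        if not 1 <= level <= 4:
            raise ValueError("level must be in 1..4")
        lo, hi = self.level_index[level - 1], self.level_index[level]
        return self.graph_maps[lo:hi]


def _check_grid(shape: tuple[int, int], stride: int, sigma: float) -> tuple[int, int]:
    h_img, w_img = shape
    if stride < 1 or h_img % stride or w_img % stride:
        raise ValueError(f"stride {stride} must divide image shape {shape}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return h_img // stride, w_img // stride


def draw_keypoint_maps(
    kp: KeypointSet,
    shape: tuple[int, int],
    stride: int = 1,
    sigma: float = DEFAULT_SIGMA,
) -> np.ndarray:
    """Render one Gaussian peak map per keypoint.

    For a visible keypoint at image coordinates ``(x, y)`` the map value at
    grid point ``(i, j)`` (row, column) is
    ``exp(-((j - x/s)^2 + (i - y/s)^2) / (2 (sigma/s)^2))``.
    Invisible keypoints yield all-zero maps.

    Returns an array of shape ``(K, H/s, W/s)``.
    """
    h, w = _check_grid(shape, stride, sigma)
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    sig = sigma / stride
    maps = np.zeros((kp.n_keypoints, h, w))
    for k in range(kp.n_keypoints):
        if not kp.visible[k]:
            continue
        x, y = kp.coords[k] / stride
        maps[k] = np.exp(-((jj - x) ** 2 + (ii - y) ** 2) / (2.0 * sig**2))
    return maps


def _segment_distance(
    ii: np.ndarray, jj: np.ndarray, p0: np.ndarray, p1: np.ndarray
) -> np.ndarray:
    """Euclidean distance from each grid point to the segment p0--p1.

    Points are (x, y); ``jj``/``ii`` are the column/row coordinate grids.
    """
    d = p1 - p0
    len2 = float(d @ d)
    dx = jj - p0[0]
    dy = ii - p0[1]
    if len2 == 0.0:  # degenerate segment: distance to the point
        return np.hypot(dx, dy)
    t = np.clip((dx * d[0] + dy * d[1]) / len2, 0.0, 1.0)
    return np.hypot(dx - t * d[0], dy - t * d[1])


def draw_graph_maps(
    kp: KeypointSet,
    skel: Skeleton,
    shape: tuple[int, int],
    stride: int = 1,
    sigma: float = DEFAULT_SIGMA,
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Render the four-level hierarchical posture-graph maps.

    Level 1 — one Gaussian-profile line map per skeleton edge (child-parent),
    the same width as the keypoint peaks.  Level 2 — one map per limb, where
    a limb is the set of edges sharing the same child-of-root ancestor,
    combined by elementwise max.  Level 3 — the whole graph (max over all
    edge maps).  Level 4 — the graph fused with all keypoint peaks.

    Edges with an invisible endpoint contribute a zero map.  Returns
    ``(maps, level_index)`` with ``maps`` of shape ``(E + B + 2, h, w)`` and
    ``level_index = (0, E, E+B, E+B+1, E+B+2)``.
    """
    edges = skel.edges
    if not edges:
        raise ValueError("skeleton has no edges")
    h, w = _check_grid(shape, stride, sigma)
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    sig = sigma / stride

    edge_maps = np.zeros((len(edges), h, w))
    for e, (child, parent) in enumerate(edges):
        if not (kp.visible[child] and kp.visible[parent]):
            continue
        p0 = kp.coords[child] / stride
        p1 = kp.coords[parent] / stride
        dist = _segment_distance(ii, jj, p0, p1)
        edge_maps[e] = np.exp(-(dist**2) / (2.0 * sig**2))

    # limbs: group edges by the branch of the root their child hangs from
    branches = sorted({skel.branch_of(child) for child, _ in edges})
    limb_maps = np.zeros((len(branches), h, w))
    for b, branch in enumerate(branches):
        member = [e for e, (child, _) in enumerate(edges)
                  if skel.branch_of(child) == branch]
        limb_maps[b] = edge_maps[member].max(axis=0)

    whole = edge_maps.max(axis=0)
    kp_maps = draw_keypoint_maps(kp, shape, stride, sigma)
    fused = np.maximum(whole, kp_maps.max(axis=0)) if len(kp_maps) else whole

    maps = np.concatenate([edge_maps, limb_maps, whole[None], fused[None]])
    e_n, b_n = len(edges), len(branches)
    level_index = (0, e_n, e_n + b_n, e_n + b_n + 1, e_n + b_n + 2)
    return maps, level_index


def assemble_stack(
    keypoint_maps: np.ndarray,
    graph_maps: np.ndarray | None,
    stride: int,
    sigma: float,
    level_index: tuple[int, ...] = (),
    include_graph: bool = True,
) -> ConfidenceMapStack:
    """Concatenate keypoint maps (first) and graph maps into one stack.

    With ``include_graph=False`` the graph maps are dropped — the inference
    configuration, where only keypoint peaks are decoded.
    """
    keypoint_maps = np.asarray(keypoint_maps, dtype=np.float64)
    if include_graph and graph_maps is not None and len(graph_maps):
        graph_maps = np.asarray(graph_maps, dtype=np.float64)
        if graph_maps.shape[1:] != keypoint_maps.shape[1:]:
            raise ValueError(
                f"graph map shape {graph_maps.shape[1:]} does not match "
                f"keypoint map shape {keypoint_maps.shape[1:]}"
            )
        maps = np.concatenate([keypoint_maps, graph_maps])
    else:
        maps = keypoint_maps
        level_index = ()
    return ConfidenceMapStack(
        maps=maps,
        stride=stride,
        sigma=sigma,
        n_keypoints=keypoint_maps.shape[0],
        level_index=tuple(level_index),
    )


def render_targets(
    kp: KeypointSet,
    skel: Skeleton,
    shape: tuple[int, int],
    stride: int,
    sigma: float = DEFAULT_SIGMA,
    include_graph: bool = True,
) -> ConfidenceMapStack:
    """Convenience: full training target stack for one annotated example."""
    kp_maps = draw_keypoint_maps(kp, shape, stride, sigma)
    if include_graph:
        graph, level_index = draw_graph_maps(kp, skel, shape, stride, sigma)
    else:
        graph, level_index = None, ()
    return assemble_stack(kp_maps, graph, stride, sigma, level_index, include_graph)
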