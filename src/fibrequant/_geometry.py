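"""Pixel-set geometry: Feret diameters, principal axes, capsule rasterisation.

Conventions used throughout the package: coordinates are 0-based (row, col),
distances are Euclidean between pixel centers, and Feret diameters are
measured on the pixel *extent* (each pixel treated as a unit square), so a
single pixel has a minimum Feret diameter of 1 px.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

__all__ = [
    "feret_diameters",
    "principal_axis_angle",
    "elongation",
    "min_component_distance",
    "capsule_pixels",
]


def _pixel_corners(coords: np.ndarray) -> np.ndarray:
    """Corners of the unit squares covering the footprint pixels, (4n, 2)."""
    coords = np.asarray(coords, dtype=float)
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    corners = (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    # qhull copes with duplicates, but deduplication keeps it fast on big blobs
    return np.unique(corners, axis=0)


def feret_diameters(coords: np.ndarray) -> tuple[float, float]:
    """Maximum and minimum Feret diameter of a pixel footprint, in pixels.

    The maximum Feret diameter is the largest caliper distance across the
    footprint (used as fibre length); the minimum is the smallest caliper
    width over all directions (fibre width). Both are computed on the convex
    hull of the pixel corner points.

    Parameters
    ----------
    coords : (n, 2) int array of pixel (row, col) coordinates.

    Returns
    -------
    (feret_max, feret_min) in pixel units.
    """
    coords = np.atleast_2d(np.asarray(coords))
    if coords.shape[0] == 0:
        raise ValueError("empty footprint")
    pts = _pixel_corners(coords)
    hull = ConvexHull(pts)
    verts = pts[hull.vertices]  # counter-clockwise

    # max Feret: diameter of the hull vertex set (small hulls: O(h^2) is fine)
    diff = verts[:, None, :] - verts[None, :, :]
    feret_max = float(np.sqrt((diff ** 2).sum(-1)).max())

    # min Feret: the width of the hull is attained perpendicular to some edge
    edges = np.roll(verts, -1, axis=0) - verts
    lengths = np.sqrt((edges ** 2).sum(1))
    keep = lengths > 0
    normals = np.stack([-edges[keep][:, 1], edges[keep][:, 0]], axis=1)
    normals /= lengths[keep][:, None]
    proj = verts @ normals.T  # (h, e) projections onto each edge normal
    widths = proj.max(0) - proj.min(0)
    feret_min = float(widths.min())
    return feret_max, feret_min


def _coord_cov(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    c = coords - coords.mean(0)
    cov = c.T @ c / len(coords)
    # each pixel is a unit square; its own second moment regularises
    # degenerate (collinear) footprints
    return cov + np.eye(2) / 12.0


def principal_axis_angle(coords: np.ndarray) -> float:
    """Orientation of the footprint's principal axis, radians in [0, pi)."""
    cov = _coord_cov(coords)
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, np.argmax(vals)]
    ang = float(np.arctan2(v[1], v[0]))
    return ang % np.pi


def elongation(coords: np.ndarray) -> float:
    """Ratio sqrt(lambda_max / lambda_min) of the footprint's inertia axes (>= 1)."""
    vals = np.linalg.eigvalsh(_coord_cov(coords))
    return float(np.sqrt(vals[1] / vals[0]))


def axis_angle_between(a1: float, a2: float) -> float:
    """Acute angle (radians) between two undirected axes."""
    d = abs(a1 - a2) % np.pi
    return min(d, np.pi - d)


def min_component_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum pixel-center distance between two footprints, in pixels."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if len(a) > len(b):
        a, b = b, a
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return float(np.min(d))


def capsule_pixels(
    center: tuple[float, float],
    angle: float,
    length_px: float,
    width_px: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Rasterise a capsule (rectangle with semicircular caps) onto the grid.

    ``length_px`` is the end-to-end extent including the caps and must be
    >= ``width_px``. Returns (n, 2) int coordinates of pixels whose centers
    lie inside the capsule and inside the image; may be empty.
    """
    if length_px < width_px:
        raise ValueError("capsule length must be >= width")
    half_seg = (length_px - width_px) / 2.0
    radius = width_px / 2.0
    u = np.array([np.cos(angle), np.sin(angle)])
    c = np.asarray(center, dtype=float)

    half_extent = length_px / 2.0 + 1.0
    r0 = max(int(np.floor(c[0] - half_extent)), 0)
    r1 = min(int(np.ceil(c[0] + half_extent)), shape[0] - 1)
    c0 = max(int(np.floor(c[1] - half_extent)), 0)
    c1 = min(int(np.ceil(c[1] + half_extent)), shape[1] - 1)
    if r1 < r0 or c1 < c0:
        return np.empty((0, 2), dtype=np.intp)

    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    rel = pts - c
    t = rel @ u  # signed position along the axis
    t_clamped = np.clip(t, -half_seg, half_seg)
    closest = c + t_clamped[:, None] * u
    dist = np.sqrt(((pts - closest) ** 2).sum(1))
    inside = dist <= radius
    return np.stack([rr.ravel()[inside], cc.ravel()[inside]], axis=1).astype(np.intp)
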