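"""Arena geometry.

The experimental tank is an octagonal arena; the narrowest (flat-to-flat)
width is the physically meaningful scale, so the default constructor takes
that width and builds a regular octagon centred on the origin with flats
facing the coordinate axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ArenaSpec", "regular_octagon"]


def _support_width(vertices: np.ndarray, direction: np.ndarray) -> float:
    proj = vertices @ direction
    return float(proj.max() - proj.min())


@dataclass(frozen=True)
class ArenaSpec:
    """Convex polygonal arena in cm, origin at the centroid.

    ``vertices`` is an (m, 2) array in counter-clockwise order (not closed);
    ``narrowest_width`` is the minimum support width over the edge normals,
    i.e. the flat-to-flat width for a regular even-sided polygon.
    """

    vertices: np.ndarray
    narrowest_width: float
    _normals: np.ndarray = field(init=False, repr=False, compare=False)
    _offsets: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("vertices must be an (m, 2) array with m >= 3")
        object.__setattr__(self, "vertices", v)
        edges = np.roll(v, -1, axis=0) - v
        cross = edges[:, 0] * np.roll(edges, -1, axis=0)[:, 1] - edges[:, 1] * np.roll(edges, -1, axis=0)[:, 0]
        if np.any(cross <= 0):
            raise ValueError("arena polygon must be convex and counter-clockwise")
        # outward normals and signed offsets of each edge line (n.x = c)
        normals = np.stack([edges[:, 1], -edges[:, 0]], axis=1)
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        offsets = np.einsum("ij,ij->i", normals, v)
        object.__setattr__(self, "_normals", normals)
        object.__setattr__(self, "_offsets", offsets)
        width = min(_support_width(v, n) for n in normals)
        if abs(width - self.narrowest_width) > 1e-6:
            raise ValueError(
                f"stored narrowest_width {self.narrowest_width} does not match "
                f"polygon width {width:.8f}"
            )

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Vectorised inside test; NaN positions count as inside (missing)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        proj = p @ self._normals.T - self._offsets
        inside = np.all(proj <= tol, axis=1)
        inside |= np.isnan(p).any(axis=1)
        return inside if np.asarray(points).ndim > 1 else inside[0]

    def wall_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance to the nearest wall (positive inside)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        proj = self._offsets - p @ self._normals.T
        d = proj.min(axis=1)
        return d if np.asarray(points).ndim > 1 else d[0]


def regular_octagon(narrowest_width: float = 105.0) -> ArenaSpec:
    """Regular octagon with the given flat-to-flat width (cm), flats on axes."""
    if narrowest_width <= 0:
        raise ValueError("narrowest_width must be positive")
    apothem = narrowest_width / 2.0
    circum_r = apothem / np.cos(np.pi / 8.0)
    angles = np.pi / 8.0 + np.arange(8) * np.pi / 4.0
    verts = circum_r * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    return ArenaSpec(vertices=verts, narrowest_width=narrowest_width)
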