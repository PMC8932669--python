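"""Closed 2D outlines: the basic geometric object of the pipeline.

An :class:`Outline` is an ordered ring of vertices describing a lateral jaw
silhouette (or any simple closed curve).  The first vertex is *not* repeated
at the end; the closing edge is implicit.  Vertices are stored
counterclockwise so that the signed polygon area is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

__all__ = [
    "Outline",
    "resample_outline",
    "detect_self_intersection",
    "standardize_area",
    "read_outline_csv",
    "write_outline_csv",
]


@dataclass(frozen=True)
class Outline:
    """Ordered closed polygon; first vertex not repeated.

    Parameters
    ----------
    vertices : (n, 2) float array
        Vertex coordinates in arbitrary length units, ordered along the
        boundary.  ``n >= 3`` is required.
    """

    vertices: np.ndarray = field()

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("outline needs an (n, 2) array with n >= 3")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return self.vertices.shape[0]

    # -- basic geometry ----------------------------------------------------
    @property
    def signed_area(self) -> float:
        """Shoelace area; positive for counterclockwise orientation."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area(self) -> float:
        return abs(self.signed_area)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    @property
    def centroid(self) -> np.ndarray:
        """Area centroid of the enclosed polygon."""
        v = self.vertices
        w = np.vstack([v, v[:1]])
        cross = w[:-1, 0] * w[1:, 1] - w[1:, 0] * w[:-1, 1]
        a = cross.sum() / 2.0
        cx = np.sum((w[:-1, 0] + w[1:, 0]) * cross) / (6.0 * a)
        cy = np.sum((w[:-1, 1] + w[1:, 1]) * cross) / (6.0 * a)
        return np.array([cx, cy])

    def reversed(self) -> "Outline":
        return Outline(self.vertices[::-1].copy())

    def ensure_ccw(self) -> "Outline":
        return self if self.signed_area > 0 else self.reversed()

    def to_shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)


def resample_outline(outline: Outline, n_points: int) -> Outline:
    """Resample to ``n_points`` vertices at equal arc-length spacing.

    The new start vertex coincides with the original start vertex and the
    traversal direction is preserved.  Resampling walks the original
    polygonal boundary, so new vertices lie exactly on the input edges.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    v = outline.vertices
    closed = np.vstack([v, v[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    perim = seglen.sum()
    if perim <= 0:
        raise ValueError("degenerate outline: zero perimeter")
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = np.linspace(0.0, perim, n_points, endpoint=False)
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seglen) - 1)
    frac = (targets - cum[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0)
    pts = closed[idx] + frac[:, None] * seg[idx]
    return Outline(pts)


def detect_self_intersection(outline: Outline) -> bool:
    """True iff two non-adjacent edges of the closed polygon intersect.

    Shared endpoints of consecutive edges do not count.  Backed by the
    GEOS simplicity test on the closed ring.
    """
    v = outline.vertices
    ring = shapely.LineString(np.vstack([v, v[:1]]))
    return not ring.is_simple


def standardize_area(outline: Outline, target_area: float = 1.0) -> Outline:
    """Isotropically rescale about the area centroid to ``target_area``."""
    a = outline.area
    if a <= 0:
        raise ValueError("outline has zero or negative area")
    if target_area <= 0:
        raise ValueError("target_area must be positive")
    c = outline.centroid
    s = np.sqrt(target_area / a)
    return Outline(c + s * (outline.vertices - c))


def write_outline_csv(outline: Outline, path) -> None:
    pd.DataFrame(outline.vertices, columns=["x", "y"]).to_csv(path, index=False)


def read_outline_csv(path) -> Outline:
    df = pd.read_csv(path)
    return Outline(df[["x", "y"]].to_numpy(dtype=float))
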