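"""Elliptic Fourier analysis (EFA) of closed outlines.

A closed outline is decomposed into ``H`` harmonic ellipses following the
classical closed-polygon formulation of Kuhl & Giardina (1982).  Each
harmonic ``n`` contributes four coefficients ``(a_n, b_n, c_n, d_n)``::

    x(t) = A0 + sum_n  a_n cos(n t) + b_n sin(n t)
    y(t) = C0 + sum_n  c_n cos(n t) + d_n sin(n t),   t in [0, 2*pi)

Size and rotation are removed by the standard first-harmonic normalization
(rotate the parameter to the first-ellipse semi-major phase, rotate space to
align the semi-major axis with +x, divide by the semi-major length).  A
normalized decomposition at ``H`` harmonics has ``a1 = 1, b1 = c1 = 0``
and therefore ``4 H - 3`` free parameters (45 at the default ``H = 12``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .outline import Outline, resample_outline

__all__ = [
    "EFACoefficients",
    "efa_decompose",
    "normalize_efa",
    "efa_reconstruct",
    "canonical_orientation",
    "coefficients_to_frame",
    "frame_to_coefficients",
]

DEFAULT_HARMONICS = 12


@dataclass(frozen=True)
class EFACoefficients:
    """Per-harmonic elliptic Fourier descriptors.

    ``harmonics`` is an ``(H, 4)`` array with rows ``(a_n, b_n, c_n, d_n)``
    for ``n = 1..H``; ``dc_offset`` is ``(A0, C0)``.
    """

    harmonics: np.ndarray = field()
    dc_offset: tuple[float, float] = (0.0, 0.0)
    normalized: bool = False

    def __post_init__(self) -> None:
        h = np.asarray(self.harmonics, dtype=float)
        if h.ndim != 2 or h.shape[1] != 4 or h.shape[0] < 1:
            raise ValueError("harmonics must be an (H, 4) array")
        object.__setattr__(self, "harmonics", h)
        object.__setattr__(self, "dc_offset", (float(self.dc_offset[0]), float(self.dc_offset[1])))

    @property
    def n_harmonics(self) -> int:
        return self.harmonics.shape[0]

    # -- 45-vector packing -------------------------------------------------
    def flatten(self) -> np.ndarray:
        """Free-parameter vector of a normalized decomposition.

        Order: ``(d1, a2, b2, c2, d2, ..., aH, bH, cH, dH)`` — the fixed
        ``a1 = 1, b1 = c1 = 0`` entries are suppressed, leaving ``4H - 3``
        values (45 at ``H = 12``).
        """
        if not self.normalized:
            raise ValueError("flatten() is defined for normalized coefficients")
        return np.concatenate([[self.harmonics[0, 3]], self.harmonics[1:].ravel()])

    @classmethod
    def from_flat(cls, vec: np.ndarray) -> "EFACoefficients":
        vec = np.asarray(vec, dtype=float).ravel()
        if (vec.size - 1) % 4 != 0:
            raise ValueError("flat vector length must be 4*H - 3")
        h = 1 + (vec.size - 1) // 4
        harm = np.empty((h, 4))
        harm[0] = [1.0, 0.0, 0.0, vec[0]]
        harm[1:] = vec[1:].reshape(h - 1, 4)
        return cls(harm, (0.0, 0.0), normalized=True)


def efa_decompose(outline: Outline, n_harmonics: int = DEFAULT_HARMONICS) -> EFACoefficients:
    """Kuhl–Giardina elliptic Fourier coefficients of a closed polygon."""
    v = outline.vertices
    if len(v) < 2 * n_harmonics + 1:
        raise ValueError("need at least 2*n_harmonics + 1 vertices")
    closed = np.vstack([v, v[:1]])
    dxy = np.diff(closed, axis=0)
    dt = np.hypot(dxy[:, 0], dxy[:, 1])
    if np.any(dt == 0):
        keep = dt > 0
        dxy, dt = dxy[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = (2.0 * np.pi) * t / T

    n = np.arange(1, n_harmonics + 1)[:, None]
    const = T / (2.0 * n**2 * np.pi**2)
    cos_d = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    sin_d = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    vx, vy = dxy[:, 0] / dt, dxy[:, 1] / dt
    a = const[:, 0] * (cos_d @ vx)
    b = const[:, 0] * (sin_d @ vx)
    c = const[:, 0] * (cos_d @ vy)
    d = const[:, 0] * (sin_d @ vy)

    # DC component (curve mean), Kuhl & Giardina eq. for A0/C0
    xi = np.cumsum(dxy[:, 0]) - (dxy[:, 0] / dt) * t[1:]
    A0 = (1.0 / T) * np.sum((dxy[:, 0] / (2 * dt)) * np.diff(t**2) + xi * dt)
    delta = np.cumsum(dxy[:, 1]) - (dxy[:, 1] / dt) * t[1:]
    C0 = (1.0 / T) * np.sum((dxy[:, 1] / (2 * dt)) * np.diff(t**2) + delta * dt)

    harm = np.stack([a, b, c, d], axis=1)
    return EFACoefficients(harm, (closed[0, 0] + A0, closed[0, 1] + C0), normalized=False)


def normalize_efa(coeffs: EFACoefficients) -> EFACoefficients:
    """Remove size, rotation and starting-point phase (first-ellipse rule).

    After normalization ``a1 = 1`` and ``b1 = c1 = 0``; ``|d1|`` is the
    aspect ratio of the first harmonic ellipse.  The DC offset is discarded.
    Reflection is *not* removed (apply :func:`canonical_orientation` to the
    outline before decomposition if a consistent anatomical frame is needed).
    Idempotent: normalizing twice is a no-op.
    """
    harm = coeffs.harmonics.copy()
    a1, b1, c1, d1 = harm[0]
    # parameter-phase rotation to the first-ellipse semi-major vertex
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), a1**2 - b1**2 + c1**2 - d1**2)
    # theta is defined up to pi/2; pick the branch that lands on the major axis
    for cand in (theta, theta + np.pi / 2.0):
        ct, st = np.cos(cand), np.sin(cand)
        a1r = a1 * ct + b1 * st
        c1r = c1 * ct + d1 * st
        b1r = -a1 * st + b1 * ct
        d1r = -c1 * st + d1 * ct
        if a1r**2 + c1r**2 >= b1r**2 + d1r**2:
            theta = cand
            break
    n = np.arange(1, coeffs.n_harmonics + 1)
    ct, st = np.cos(n * theta), np.sin(n * theta)
    a, b, c, d = harm.T.copy()
    harm[:, 0] = a * ct + b * st
    harm[:, 1] = -a * st + b * ct
    harm[:, 2] = c * ct + d * st
    harm[:, 3] = -c * st + d * ct

    # spatial rotation aligning the semi-major axis with +x, then unit scale
    psi = np.arctan2(harm[0, 2], harm[0, 0])
    scale = np.hypot(harm[0, 0], harm[0, 2])
    if scale <= 0:
        raise ValueError("degenerate first harmonic: zero semi-major axis")
    cp, sp = np.cos(psi), np.sin(psi)
    rot = np.array([[cp, sp], [-sp, cp]])
    out = np.empty_like(harm)
    for i in range(harm.shape[0]):
        m = rot @ harm[i].reshape(2, 2)
        out[i] = m.ravel()
    out /= scale
    # snap the enforced zeros so that normalization is exactly idempotent
    out[0, 0] = 1.0
    out[0, 1] = 0.0
    out[0, 2] = 0.0
    return EFACoefficients(out, (0.0, 0.0), normalized=True)


def efa_reconstruct(coeffs: EFACoefficients, n_points: int = 600) -> Outline:
    """Trace the truncated Fourier series at equally spaced parameter values."""
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    n = np.arange(1, coeffs.n_harmonics + 1)[:, None]
    cos_nt, sin_nt = np.cos(n * t), np.sin(n * t)
    a, b, c, d = coeffs.harmonics.T
    x = coeffs.dc_offset[0] + a @ cos_nt + b @ sin_nt
    y = coeffs.dc_offset[1] + c @ cos_nt + d @ sin_nt
    return Outline(np.column_stack([x, y]))


def canonical_orientation(outline: Outline, n_probe: int = 400) -> Outline:
    """Rotate/flip an outline into the anatomical frame assumed downstream.

    Convention: long (anteroposterior) axis along x, anterior (tapered end)
    toward +x, dorsal margin toward +y.  The major axis comes from the
    principal axis of the densely resampled boundary; the dorsal side is
    identified by the sign of the vertical skewness of boundary points (a
    jaw has a long sub-straight dorsal margin and a ventrally bulging body,
    so boundary mass concentrates dorsally); the anterior end is the end
    with the smaller vertical extent.  Output is counterclockwise.
    """
    probe = resample_outline(outline, n_probe)
    pts = probe.vertices - probe.centroid
    cov = pts.T @ pts / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    rot = np.array([[major[0], major[1]], [-major[1], major[0]]])
    pts = pts @ rot.T
    y = pts[:, 1]
    flip_y = np.mean((y - y.mean()) ** 3) > 0  # boundary mass should sit dorsally
    if flip_y:
        pts[:, 1] *= -1.0
    x = pts[:, 0]
    right = x - x.min() > 0.75 * (x.max() - x.min())
    left = x - x.min() < 0.25 * (x.max() - x.min())
    flip_x = np.ptp(pts[right, 1]) > np.ptp(pts[left, 1])  # tapered end to +x
    v = outline.vertices - outline.centroid
    v = v @ rot.T
    if flip_y:
        v[:, 1] *= -1.0
    if flip_x:
        v[:, 0] *= -1.0
    return Outline(v).ensure_ccw()


def coefficients_to_frame(items: dict[str, EFACoefficients]) -> pd.DataFrame:
    """Tabulate normalized coefficient vectors, one row per specimen."""
    rows = {}
    for taxon, co in items.items():
        rows[taxon] = co.flatten()
    any_vec = next(iter(rows.values()))
    h = 1 + (any_vec.size - 1) // 4
    cols = ["d1"] + [f"{ch}{n}" for n in range(2, h + 1) for ch in "abcd"]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "taxon_id"
    return df


def frame_to_coefficients(df: pd.DataFrame) -> dict[str, EFACoefficients]:
    return {str(ix): EFACoefficients.from_flat(row.to_numpy()) for ix, row in df.iterrows()}
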