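"""Analytic geometry of the perturbed-ellipse cell model.

A cell boundary is an ellipse with a sinusoidal radial perturbation:

    r(theta) = r_ellipse(theta) * (1 + eps * sin(lobes * theta + phase))

where ``r_ellipse(theta) = a*b / sqrt((b cos)^2 + (a sin)^2)`` for
semi-axes ``a >= b``. ``eps`` (the irregularity amplitude) pushes
solidity below 1 in a controlled way once ``lobes >= 3``.

All descriptor "truth" values are computed from a dense polygonal
sampling of this boundary, so the generator and the pixel-based
measurements share one geometric definition.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull

#: canonical descriptor order used across the package
DESCRIPTOR_COLUMNS = [
    "area_um2",
    "major_um",
    "minor_um",
    "circularity",
    "aspect_ratio",
    "roundness",
    "solidity",
]


def boundary_radius(
    theta: np.ndarray,
    a: float | np.ndarray,
    b: float | np.ndarray,
    eps: float | np.ndarray = 0.0,
    lobes: int | np.ndarray = 5,
    phase: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Radius of the perturbed ellipse at polar angle(s) theta (cell frame)."""
    r_e = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    return r_e * (1.0 + eps * np.sin(lobes * theta + phase))


def boundary_polygon(
    a, b, eps=0.0, lobes=5, phase=0.0, n_vertices: int = 360
) -> tuple[np.ndarray, np.ndarray]:
    """Vertex arrays (x, y) of the boundary polygon, centered at the origin.

    Parameters broadcast: scalars give one polygon of shape
    ``(n_vertices,)``, 1-d arrays of length n give ``(n, n_vertices)``.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    a, b, eps, lobes, phase = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(v, dtype=float)) for v in (a, b, eps, lobes, phase))
    )
    r = boundary_radius(theta[None, :], a[:, None], b[:, None], eps[:, None], lobes[:, None], phase[:, None])
    x = r * np.cos(theta)[None, :]
    y = r * np.sin(theta)[None, :]
    return x, y


def _polygon_area_signed(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    x1 = np.roll(x, -1, axis=-1)
    y1 = np.roll(y, -1, axis=-1)
    return 0.5 * np.sum(x * y1 - x1 * y, axis=-1)


def _polygon_perimeter(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    dx = np.roll(x, -1, axis=-1) - x
    dy = np.roll(y, -1, axis=-1) - y
    return np.sum(np.hypot(dx, dy), axis=-1)


def _polygon_second_moments(x, y, area):
    """Central second moments (cov_xx, cov_yy, cov_xy) of the polygon region.

    Green's-theorem closed forms; vertices counter-clockwise. Returns the
    covariance matrix entries of the uniform density over the region.
    """
    x1 = np.roll(x, -1, axis=-1)
    y1 = np.roll(y, -1, axis=-1)
    c = x * y1 - x1 * y
    cx = np.sum((x + x1) * c, axis=-1) / (6.0 * area)
    cy = np.sum((y + y1) * c, axis=-1) / (6.0 * area)
    ixx = np.sum((y * y + y * y1 + y1 * y1) * c, axis=-1) / 12.0
    iyy = np.sum((x * x + x * x1 + x1 * x1) * c, axis=-1) / 12.0
    ixy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * c, axis=-1) / 24.0
    cov_xx = iyy / area - cx**2
    cov_yy = ixx / area - cy**2
    cov_xy = ixy / area - cx * cy
    return cov_xx, cov_yy, cov_xy


def equivalent_ellipse_axes(cov_xx, cov_yy, cov_xy):
    """Major/minor axis lengths of the moment-equivalent ellipse.

    Matches the ImageJ / regionprops "fit ellipse" convention: axes are
    ``4 * sqrt(eigenvalue)`` of the region covariance.
    """
    tr = cov_xx + cov_yy
    det_term = np.sqrt(np.maximum((cov_xx - cov_yy) ** 2 + 4.0 * cov_xy**2, 0.0))
    lam1 = 0.5 * (tr + det_term)
    lam2 = 0.5 * (tr - det_term)
    return 4.0 * np.sqrt(np.maximum(lam1, 0.0)), 4.0 * np.sqrt(np.maximum(lam2, 0.0))


def _hull_areas(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    out = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        pts = np.column_stack([x[i], y[i]])
        out[i] = ConvexHull(pts).volume  # 2-d: volume is the area
    return out


def polygon_descriptors(
    a, b, eps=0.0, lobes=5, phase=0.0, n_vertices: int = 360
) -> dict[str, np.ndarray]:
    """Seven-descriptor panel of perturbed-ellipse cells, from geometry.

    Inputs are in physical units (µm for semi-axes); the returned
    ``area_um2`` / ``major_um`` / ``minor_um`` carry those units, the
    remaining four descriptors are dimensionless. Circularity is clamped
    to <= 1.
    """
    x, y = boundary_polygon(a, b, eps=eps, lobes=lobes, phase=phase, n_vertices=n_vertices)
    area = _polygon_area_signed(x, y)
    perim = _polygon_perimeter(x, y)
    cov_xx, cov_yy, cov_xy = _polygon_second_moments(x, y, area)
    major, minor = equivalent_ellipse_axes(cov_xx, cov_yy, cov_xy)
    hull = _hull_areas(x, y)
    circ = np.minimum(4.0 * np.pi * area / perim**2, 1.0)
    return {
        "area_um2": area,
        "major_um": major,
        "minor_um": minor,
        "circularity": circ,
        "aspect_ratio": major / minor,
        "roundness": 4.0 * area / (np.pi * major**2),
        "solidity": np.minimum(area / hull, 1.0),
        "perimeter_um": perim,
    }
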