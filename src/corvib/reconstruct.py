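"""Rotational 3-D reconstruction of the deformed corneal contour.

A single cross-sectional contour is swept about a vertical symmetry axis
(by default the maximum-deformation column): each contour point at lateral
distance ``r`` from the axis traces the arc ``(r cos(theta), r sin(theta))``
for ``theta`` in [-pi/2, pi/2], carrying its row value along; the swept
points are then linearly interpolated onto a regular (n, w) grid.  Points on
the left of the axis fill the ``x <= axis`` part of the surface, points on
the right the other, so an asymmetric contour yields an asymmetric surface.
The ``w = 0`` slice reproduces the measured contour exactly and the surface
is mirror-symmetric in ``w`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import Calibration


@dataclass
class Surface3D:
    """Gridded swept surface in physical units (mm).

    ``z_mm`` has shape (len(w_mm), len(x_mm)); NaN marks grid nodes outside
    the swept support (beyond the lateral extent of the contour).
    """

    x_mm: np.ndarray
    w_mm: np.ndarray
    z_mm: np.ndarray
    axis_column: int
    sweep_count: int


def reconstruct_3d(
    contour: np.ndarray,
    calibration: Calibration,
    axis_column: int,
    sweep_count: int = 181,
    full_rotation: bool = False,
) -> Surface3D:
    """Sweep one contour about ``axis_column``.

    ``sweep_count`` sets the number of interpolated slices (rows of the w
    grid).  ``full_rotation`` extends the w range symmetrically — the swept
    surface itself is already mirror-symmetric, so this only doubles the
    sampled slice count for viewers expecting a full turn.
    """
    contour = np.asarray(contour, dtype=float)
    N = contour.size
    if not 0 <= axis_column <= N - 1:
        raise ValueError(f"invalid axis: column {axis_column} outside [0, {N - 1}]")
    pw = calibration.pixel_width_mm
    ph = calibration.pixel_height_um / 1000.0
    x_cols = np.arange(N) * pw
    axis_x = axis_column * pw
    z = contour * ph

    r_left = axis_x - x_cols[0]
    r_right = x_cols[-1] - axis_x
    r_max = max(r_left, r_right)
    n_w = sweep_count * 2 - 1 if full_rotation else sweep_count
    if n_w % 2 == 0:
        n_w += 1  # keep the exact w = 0 slice
    w_mm = np.linspace(-r_max, r_max, n_w)
    w_mm[n_w // 2] = 0.0  # exact central slice

    X, W = np.meshgrid(x_cols, w_mm)
    rho = np.hypot(X - axis_x, W)
    side = np.where(X >= axis_x, 1.0, -1.0)
    sample_x = axis_x + side * rho
    z_mm = np.interp(sample_x.ravel(), x_cols, z).reshape(X.shape)
    # nodes whose swept radius exceeds the contour extent on that side
    reach = np.where(side > 0, r_right, r_left)
    z_mm[rho > reach + 1e-12] = np.nan
    # w = 0 slice: exact input values (interp at the nodes is exact anyway)
    z_mm[n_w // 2, :] = z
    return Surface3D(
        x_mm=x_cols, w_mm=w_mm, z_mm=z_mm,
        axis_column=axis_column, sweep_count=sweep_count,
    )


def export_surface_csv(surface: Surface3D, path: str | Path) -> None:
    """Write the gridded surface as long-form CSV (x_mm, w_mm, z_mm)."""
    X, W = np.meshgrid(surface.x_mm, surface.w_mm)
    ok = np.isfinite(surface.z_mm)
    arr = np.column_stack([X[ok], W[ok], surface.z_mm[ok]])
    header = "x_mm,w_mm,z_mm"
    np.savetxt(path, arr, delimiter=",", header=header, comments="", fmt="%.6f")


def export_surface_obj(surface: Surface3D, path: str | Path) -> None:
    """Write a simple OBJ mesh (quads split into triangles, NaN cells skipped)."""
    z = surface.z_mm
    n_w, n_x = z.shape
    idx = np.full(z.shape, -1, dtype=int)
    lines = []
    count = 0
    for j in range(n_w):
        for k in range(n_x):
            if np.isfinite(z[j, k]):
                count += 1
                idx[j, k] = count
                lines.append(
                    f"v {surface.x_mm[k]:.6f} {surface.w_mm[j]:.6f} {z[j, k]:.6f}"
                )
    for j in range(n_w - 1):
        for k in range(n_x - 1):
            q = idx[j, k], idx[j, k + 1], idx[j + 1, k + 1], idx[j + 1, k]
            if min(q) > 0:
                lines.append(f"f {q[0]} {q[1]} {q[2]}")
                lines.append(f"f {q[0]} {q[2]} {q[3]}")
    Path(path).write_text("\n".join(lines) + "\n")
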