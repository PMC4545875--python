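"""Hub-location statistics and interpolated head maps.

The hub-location statistic is the "center of mass" of the betweenness-
centrality distribution over the scalp: the BC-weighted mean of the 2-D
electrode coordinates,

    (x, y) = sum_i bc_i * (x_i, y_i) / sum_i bc_i.

The normalization by the total BC makes the statement "equal BC on all
nodes puts the center exactly in the middle (Cz)" hold for any layout;
an unnormalized dot product would only do so if the coordinates summed
to zero.  The y component (front-to-back, y > 0 anterior) is the primary
statistic; larger y with increasing disease severity means the hubs
shift forward, away from the posterior regions.

Head maps use biharmonic (thin-plate) spline interpolation with Green's
function g(r) = r^2 (ln r - 1) plus an affine term, so the surface
passes exactly through the channel values and reproduces constant and
linear fields exactly.  Rendering is a side effect for inspection only;
no statistic is ever read off the interpolated surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import Montage
from .mst import CentralityVector

__all__ = ["MassCenter", "center_of_mass", "headmap", "render_headmap", "hub_shift_table"]


@dataclass(frozen=True)
class MassCenter:
    """BC-weighted mean electrode position, head units, y > 0 anterior."""

    x: float
    y: float


def center_of_mass(bc, montage: Montage) -> MassCenter:
    """Weighted mean of channel coordinates; weights must not all be 0."""
    weights = np.asarray(getattr(bc, "bc", bc), dtype=float)
    if len(weights) != montage.n_channels:
        raise ValueError(
            f"{len(weights)} weights for {montage.n_channels} channels"
        )
    total = weights.sum()
    if total <= 0:
        raise ValueError("center of mass undefined: all weights are zero")
    xy = montage.coord_array()
    cx, cy = (weights @ xy) / total
    return MassCenter(x=float(cx), y=float(cy))


def _greens(r: np.ndarray) -> np.ndarray:
    """Biharmonic Green's function g(r) = r^2 (ln r - 1), g(0) = 0."""
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * (np.log(r[nz]) - 1.0)
    return out


def _fit_spline(coords: np.ndarray, values: np.ndarray):
    n = coords.shape[0]
    r = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    G = _greens(r)
    P = np.column_stack([np.ones(n), coords])  # affine part: 1, x, y
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = G
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.concatenate([values, np.zeros(3)])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular biharmonic spline system (duplicate electrode "
            "coordinates?)"
        ) from exc
    return sol[:n], sol[n:]


def headmap(
    values_per_channel,
    montage: Montage,
    grid_resolution: int = 128,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate channel values over the unit-disc head.

    Returns ``(xs, ys, field)`` where ``field`` is a
    (grid_resolution, grid_resolution) array, NaN outside the unit disc.
    """
    values = np.asarray(values_per_channel, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("channel values must be finite")
    if montage.n_channels < 3:
        raise ValueError("head map interpolation needs at least 3 channels")
    coords = montage.coord_array()
    w, abc = _fit_spline(coords, values)
    xs = np.linspace(-1.0, 1.0, grid_resolution)
    ys = np.linspace(-1.0, 1.0, grid_resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    r = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=-1)
    field = _greens(r) @ w + abc[0] + pts @ abc[1:]
    field = field.reshape(grid_resolution, grid_resolution)
    field[gx**2 + gy**2 > 1.0] = np.nan
    return xs, ys, field


def evaluate_spline(values_per_channel, montage: Montage, points) -> np.ndarray:
    """Evaluate the interpolant at arbitrary (x, y) points."""
    values = np.asarray(values_per_channel, dtype=float)
    coords = montage.coord_array()
    w, abc = _fit_spline(coords, values)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=-1)
    return _greens(r) @ w + abc[0] + pts @ abc[1:]


def render_headmap(
    values_per_channel,
    montage: Montage,
    path,
    mass_center: MassCenter | None = None,
    grid_resolution: int = 128,
    title: str | None = None,
) -> None:
    """Render the interpolated head map to an image file."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    xs, ys, field = headmap(values_per_channel, montage, grid_resolution)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.pcolormesh(xs, ys, field, shading="auto", cmap="viridis")
    circle = plt.Circle((0, 0), 1.0, fill=False, color="k", lw=1.5)
    ax.add_patch(circle)
    coords = montage.coord_array()
    ax.plot(coords[:, 0], coords[:, 1], "k.", ms=3)
    if mass_center is not None:
        ax.plot(mass_center.x, mass_center.y, "r+", ms=12, mew=2)
    ax.set_aspect("equal")
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.75)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def hub_shift_table(
    cohort_bc: dict[str, dict[str, CentralityVector]],
    montage: Montage,
) -> pd.DataFrame:
    """Tidy per-subject, per-band center-of-mass table.

    ``cohort_bc`` maps subject id -> band name -> centrality vector.
    Returns columns (subject, band, x, y); y is the primary statistic.
    """
    if not cohort_bc:
        raise ValueError("empty cohort")
    rows = []
    for subject, per_band in cohort_bc.items():
        for band, cv in per_band.items():
            com = center_of_mass(cv, montage)
            rows.append((subject, band, com.x, com.y))
    return pd.DataFrame(rows, columns=["subject", "band", "x", "y"])
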