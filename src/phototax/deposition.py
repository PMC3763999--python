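"""Seeded synthetic initial conditions.

Runs start from a random cell deposition over a strip at the bottom of the
domain (away from the light source): each grid element in the strip draws an
independent concentration with mean ``cbar``, mimicking cells spotted on an
agarose surface.  Pre-laid EPS trails support merge/trail-following demos
and tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core_model import ConfigError, GridSpec

#: Per-element distributions: name -> draw(rng, cbar, size) with mean cbar.
DISTRIBUTIONS: dict[str, Callable] = {
    "uniform": lambda rng, cbar, size: rng.uniform(0.0, 2.0 * cbar, size),
    "exponential": lambda rng, cbar, size: rng.exponential(cbar, size),
}


@dataclass(frozen=True)
class DepositionSpec:
    """Random deposition over the bottom ``region_fraction`` of the domain.

    ``cbar`` is the target mean concentration over the deposition region
    (not the whole domain).  The default per-element law is uniform on
    [0, 2*cbar], which has mean cbar and stays nonnegative.
    """

    cbar: float
    region_fraction: float = 0.2
    distribution: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.region_fraction <= 1:
            raise ConfigError(f"region_fraction must be in (0, 1], got {self.region_fraction}")
        if not self.cbar > 0:
            raise ConfigError(f"cbar must be positive, got {self.cbar}")
        if self.distribution not in DISTRIBUTIONS:
            raise ConfigError(
                f"unknown distribution {self.distribution!r}; "
                f"known: {sorted(DISTRIBUTIONS)}"
            )


def region_rows(grid: GridSpec, region_fraction: float) -> int:
    """Number of rows in the deposition strip (bottom of the domain)."""
    return int(round(region_fraction * grid.ny))


def make_deposition(grid: GridSpec, spec: DepositionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw the initial cell field and its boolean deposition mask.

    Returns ``(C0, mask)`` where ``C0`` is zero outside the bottom strip and
    i.i.d. with mean ``spec.cbar`` inside it.  Reproducible from
    ``spec.seed``.
    """
    n_rows = region_rows(grid, spec.region_fraction)
    if n_rows < 2:
        raise ConfigError(
            f"deposition region of {n_rows} row(s) is too thin; "
            f"need at least 2 rows (ny={grid.ny}, fraction={spec.region_fraction})"
        )
    rng = np.random.default_rng(spec.seed)
    C0 = np.zeros(grid.shape)
    C0[:n_rows, :] = DISTRIBUTIONS[spec.distribution](rng, spec.cbar, (n_rows, grid.nx))
    mask = np.zeros(grid.shape, dtype=bool)
    mask[:n_rows, :] = True
    return C0, mask


def make_eps_trail(
    grid: GridSpec,
    geometry: tuple[float, float, float, float] | Sequence[tuple[float, float]],
    depth: float,
    width: float | None = None,
) -> np.ndarray:
    """Pre-laid EPS field: ``depth`` inside the geometry, zero outside.

    ``geometry`` is either an axis-aligned rectangle ``(x0, y0, x1, y1)`` in
    natural length units, or a polyline (list of >= 2 points) buffered to
    ``width`` (also natural units).  Geometry must lie within the domain.
    """
    if depth < 0:
        raise ConfigError(f"trail depth must be nonnegative, got {depth}")
    S0 = np.zeros(grid.shape)
    extent_x, extent_y = grid.nx * grid.dx, grid.ny * grid.dx
    if len(geometry) == 4 and np.isscalar(geometry[0]):
        x0, y0, x1, y1 = geometry
        if not (0 <= x0 <= x1 <= extent_x and 0 <= y0 <= y1 <= extent_y):
            raise ConfigError(f"rectangle {geometry} outside domain {extent_x}x{extent_y}")
        i0, i1 = int(np.floor(x0 / grid.dx)), int(np.ceil(x1 / grid.dx))
        j0, j1 = int(np.floor(y0 / grid.dx)), int(np.ceil(y1 / grid.dx))
        S0[j0:j1, i0:i1] = depth
        return S0
    points = np.asarray(geometry, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2 or points.shape[1] != 2:
        raise ConfigError("polyline geometry needs >= 2 (x, y) points")
    if width is None or not width > 0:
        raise ConfigError("polyline geometry requires a positive width")
    if np.any(points < 0) or np.any(points[:, 0] > extent_x) or np.any(points[:, 1] > extent_y):
        raise ConfigError("polyline outside domain")
    jj, ii = np.mgrid[0 : grid.ny, 0 : grid.nx]
    centers = np.stack([(ii + 0.5) * grid.dx, (jj + 0.5) * grid.dx], axis=-1)
    half = width / 2.0
    inside = np.zeros(grid.shape, dtype=bool)
    for a, b in zip(points[:-1], points[1:]):
        ab = b - a
        denom = float(ab @ ab)
        rel = centers - a
        s = np.clip((rel @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
        closest = a + np.multiply.outer(s, ab) if denom > 0 else np.broadcast_to(a, centers.shape)
        dist = np.linalg.norm(centers - closest, axis=-1)
        inside |= dist <= half
    S0[inside] = depth
    return S0
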