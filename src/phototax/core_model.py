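"""Dimensionless reaction-diffusion model of EPS-mediated phototaxis.

Two scalar fields live on a regular 2D grid: the cell concentration ``C``
and the concentration ``S`` of secreted extracellular polymeric substance
(EPS).  Both are measured as the height the material would occupy if spread
locally with uniform thickness, normalized by the mobility saturation depth
sigma.  Cells secrete EPS at a constant rate, and their effective diffusion
coefficient (mobility) is a saturating function of the local EPS level,

    M(S) = S / (1 + S),            0 <= M < 1.

A constant force of magnitude ``beta`` pointing toward the light source
biases the random walk, giving the cell flux

    J = -M grad(C) + beta * M * C * b_hat,

so the fields evolve by

    dS/dt = C - S/tau          (tau -> infinity when decay is disabled)
    dC/dt = -div(J)

in natural units: length lambda = sqrt(m0/ks), time T = 1/ks, density sigma,
where m0 is the maximum mobility and ks the EPS production rate.  The only
free parameters are the mean initial cell concentration ``cbar``, the bias
strength ``beta``, and optionally the EPS decay constant ``tau``.

Discretization: finite-volume on a square grid.  The diffusive flux is
evaluated on cell faces with the face mobility taken as the arithmetic mean
of the two adjacent mobilities; the advective flux uses first-order upwind
along the current bias direction.  Boundary faces carry zero total flux, so
total cell mass is conserved to rounding.  Time stepping is forward Euler.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

#: Version string recorded in run provenance.
CODE_VERSION = "0.1.0"

#: Undershoots of C or S no deeper than this are clipped to zero and charged
#: to the mass-error account; anything deeper aborts the run as an
#: instability.  Distinguishes float rounding from a genuinely unstable dt.
CLIP_TOLERANCE = 1e-12

#: Safety factor applied to the linear stability estimate.
STABILITY_SAFETY = 0.5


class DomainError(ValueError):
    """A field violates a physical-domain requirement (e.g. negativity)."""


class ConfigError(ValueError):
    """Invalid model or run configuration."""


class StabilityError(RuntimeError):
    """The forward-Euler step produced negativity or non-finite values."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Regular 2D grid.

    Rows (axis 0, ``ny``) run along the light axis; the light source sits at
    the top (increasing row index).  Columns (axis 1, ``nx``) are
    perpendicular to the light.  ``dx`` is the spacing in natural length
    units; the physical extent is ``(nx*dx, ny*dx)``.
    """

    nx: int = 360
    ny: int = 720
    dx: float = 0.25

    def __post_init__(self) -> None:
        if self.nx < 4 or self.ny < 4:
            raise ConfigError(f"grid must be at least 4x4, got {self.nx}x{self.ny}")
        if not self.dx > 0:
            raise ConfigError(f"grid spacing must be positive, got {self.dx}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def cell_area(self) -> float:
        return self.dx * self.dx


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless control parameters.

    ``cbar``  mean initial cell concentration over the deposition region,
              in units of the saturation depth sigma.
    ``beta``  bias-force magnitude in natural units.
    ``tau``   EPS decay constant; ``None`` means no decay (tau -> infinity).
    """

    cbar: float
    beta: float
    tau: float | None = None

    def __post_init__(self) -> None:
        if not self.cbar > 0:
            raise ConfigError(f"cbar must be positive, got {self.cbar}")
        if self.beta < 0:
            raise ConfigError(f"beta must be nonnegative, got {self.beta}")
        if self.tau is not None and not self.tau > 0:
            raise ConfigError(f"tau must be positive (or None for no decay), got {self.tau}")

    @property
    def tau_effective(self) -> float:
        """Decay constant with the no-decay sentinel mapped to +inf."""
        return math.inf if self.tau is None else self.tau


@dataclass(frozen=True)
class BiasSchedule:
    """Piecewise-constant bias direction.

    ``entries`` is an ordered list of ``(start_time, (ux, uy))`` with unit
    direction vectors in the grid plane; the magnitude comes from
    ``ModelParams.beta``.  The first entry must start at t=0.  The default
    schedule points toward the light at the top of the domain for all time.
    """

    entries: tuple[tuple[float, tuple[float, float]], ...] = ((0.0, (0.0, 1.0)),)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigError("bias schedule must have at least one entry")
        times = [t for t, _ in self.entries]
        if times[0] != 0.0:
            raise ConfigError("first bias-schedule entry must start at t=0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigError("bias-schedule start times must be strictly increasing")
        for t, (ux, uy) in self.entries:
            norm = math.hypot(ux, uy)
            if abs(norm - 1.0) > 1e-9:
                raise ConfigError(
                    f"bias direction at t={t} must be a unit vector, |({ux},{uy})|={norm}"
                )

    def direction_at(self, t: float) -> tuple[float, float]:
        """Unit bias direction in effect at time ``t``."""
        current = self.entries[0][1]
        for start, direction in self.entries:
            if start <= t + 1e-12:
                current = direction
            else:
                break
        return current

    @property
    def switch_times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.entries[1:])


@dataclass
class FieldState:
    """The pair of fields (C, S) at dimensionless time ``t``."""

    C: np.ndarray
    S: np.ndarray
    t: float

    def __post_init__(self) -> None:
        if self.C.shape != self.S.shape:
            raise ConfigError(f"C and S shapes differ: {self.C.shape} vs {self.S.shape}")

    def copy(self) -> "FieldState":
        return FieldState(self.C.copy(), self.S.copy(), self.t)


@dataclass
class SimulationResult:
    """Snapshots of a run plus everything needed to reproduce it."""

    snapshots: list[FieldState]
    params: ModelParams
    grid: GridSpec
    schedule: BiasSchedule
    deposition_mask: np.ndarray | None
    seed: int | None
    dt: float
    t_end: float
    early_stopped: bool = False
    mass_clip_error: float = 0.0
    code_version: str = CODE_VERSION

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])

    @property
    def final(self) -> FieldState:
        return self.snapshots[-1]

    @property
    def initial(self) -> FieldState:
        return self.snapshots[0]


@dataclass(frozen=True)
class PhysicalScales:
    """Dimensional parameters mapping natural units to physical ones.

    ``m0``    maximum mobility (area/time, e.g. um^2/s)
    ``ks``    EPS production rate (1/time)
    ``sigma`` saturation depth (length, e.g. um)

    Derived: length scale lambda = sqrt(m0/ks), time scale T = 1/ks, density
    scale sigma.  The reference convention T = 2000 s makes 300 natural
    time units equal one 600,000 s experiment.
    """

    m0: float
    ks: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.m0 > 0 and self.ks > 0 and self.sigma > 0):
            raise ConfigError("all physical scales must be strictly positive")

    @property
    def length(self) -> float:
        return math.sqrt(self.m0 / self.ks)

    @property
    def time(self) -> float:
        return 1.0 / self.ks

    @property
    def concentration(self) -> float:
        return self.sigma

    @property
    def speed(self) -> float:
        return self.length / self.time


# ---------------------------------------------------------------------------
# Elementary rates (numpy reference path)
# ---------------------------------------------------------------------------

def mobility(S: np.ndarray | float) -> np.ndarray | float:
    """Dimensionless mobility M = S/(1+S), saturating at 1."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise DomainError("EPS concentration must be nonnegative")
    out = S / (1.0 + S)
    return out if out.ndim else float(out)


def eps_rate(C: np.ndarray, S: np.ndarray, tau: float | None = None) -> np.ndarray:
    """dS/dt = C (production) minus S/tau when decay is enabled."""
    C = np.asarray(C, dtype=float)
    S = np.asarray(S, dtype=float)
    if C.shape != S.shape:
        raise ConfigError(f"C and S shapes differ: {C.shape} vs {S.shape}")
    if np.any(C < 0) or np.any(S < 0):
        raise DomainError("concentration fields must be nonnegative")
    if tau is None:
        return C.copy()
    if not tau > 0:
        raise ConfigError(f"tau must be positive, got {tau}")
    return C - S / tau


def _face_fluxes(
    C: np.ndarray, M: np.ndarray, bx: float, by: float, dx: float
) -> tuple[np.ndarray, np.ndarray]:
    """Total (diffusive + advective) fluxes on interior x- and y-faces.

    ``Fx[j, i]`` is the flux in +x through the face between columns i, i+1;
    ``Fy[j, i]`` the flux in +y between rows j, j+1.  Boundary faces are
    zero-flux and are not represented.
    """
    # diffusive part: face mobility is the arithmetic mean of neighbors
    Fx = -0.5 * (M[:, :-1] + M[:, 1:]) * (C[:, 1:] - C[:, :-1]) / dx
    Fy = -0.5 * (M[:-1, :] + M[1:, :]) * (C[1:, :] - C[:-1, :]) / dx
    # advective part: first-order upwind of the carried quantity M*C
    MC = M * C
    if bx > 0:
        Fx += bx * MC[:, :-1]
    elif bx < 0:
        Fx += bx * MC[:, 1:]
    if by > 0:
        Fy += by * MC[:-1, :]
    elif by < 0:
        Fy += by * MC[1:, :]
    return Fx, Fy


def cell_rate(
    C: np.ndarray,
    S: np.ndarray,
    beta_vec: Sequence[float],
    grid: GridSpec,
) -> np.ndarray:
    """dC/dt = -div J with J = -M grad(C) + beta * M * C * b_hat.

    Conservative: fluxes are defined on cell faces with zero flux through
    the boundary, so the domain sum of rate * dx^2 vanishes to rounding.
    """
    C = np.asarray(C, dtype=float)
    S = np.asarray(S, dtype=float)
    if C.shape != grid.shape or S.shape != grid.shape:
        raise ConfigError(f"fields must have grid shape {grid.shape}")
    if not (np.all(np.isfinite(C)) and np.all(np.isfinite(S))):
        raise StabilityError("non-finite values entering cell_rate")
    M = mobility(S)
    bx, by = float(beta_vec[0]), float(beta_vec[1])
    Fx, Fy = _face_fluxes(C, M, bx, by, grid.dx)
    div = np.zeros_like(C)
    div[:, :-1] += Fx
    div[:, 1:] -= Fx
    div[:-1, :] += Fy
    div[1:, :] -= Fy
    return -div / grid.dx


def total_mass(C: np.ndarray, grid: GridSpec) -> float:
    """Total cell mass: sum of C over the domain times the cell area."""
    C = np.asarray(C, dtype=float)
    if not np.all(np.isfinite(C)):
        raise DomainError("C must be finite")
    return float(C.sum()) * grid.cell_area


def stability_limit(params: ModelParams, grid: GridSpec) -> float:
    """Recommended maximum forward-Euler dt.

    Half the linear estimate min(dx^2/4, dx/beta) at the saturated mobility
    M=1 (the advective bound is inactive at beta=0).
    """
    diffusive = grid.dx * grid.dx / 4.0
    advective = math.inf if params.beta == 0 else grid.dx / params.beta
    return STABILITY_SAFETY * min(diffusive, advective)


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

def step(
    state: FieldState,
    params: ModelParams,
    grid: GridSpec,
    schedule: BiasSchedule | None = None,
    dt: float = 0.01,
) -> FieldState:
    """One forward-Euler step of the coupled system (reference path).

    Both rates are evaluated at the incoming state.  Undershoots within
    ``CLIP_TOLERANCE`` are clipped to zero; deeper ones raise
    :class:`StabilityError`.
    """
    if not dt > 0:
        raise ConfigError(f"dt must be positive, got {dt}")
    schedule = schedule or BiasSchedule()
    ux, uy = schedule.direction_at(state.t)
    bvec = (params.beta * ux, params.beta * uy)
    dC = cell_rate(state.C, state.S, bvec, grid)
    tau = params.tau_effective
    dS = state.C - state.S / tau  # S/inf == 0 exactly: no-decay production C
    C_new = state.C + dt * dC
    S_new = state.S + dt * dS
    for name, f in (("C", C_new), ("S", S_new)):
        if not np.all(np.isfinite(f)):
            raise StabilityError(
                f"non-finite {name} at t={state.t + dt:.4f}; reduce dt "
                f"(recommended <= {stability_limit(params, grid):.3g})"
            )
        lo = f.min()
        if lo < -CLIP_TOLERANCE:
            raise StabilityError(
                f"{name} undershoot {lo:.3e} at t={state.t + dt:.4f} exceeds the "
                f"clip tolerance; reduce dt (recommended <= "
                f"{stability_limit(params, grid):.3g})"
            )
        np.clip(f, 0.0, None, out=f)
    return FieldState(C_new, S_new, state.t + dt)


@njit(cache=True)
def _advance_kernel(C, S, n_steps, dt, dx, bx, by, tau, clip_tol):  # pragma: no cover
    """Advance (C, S) in place by ``n_steps`` forward-Euler steps.

    Identical arithmetic to the numpy reference path (cell_rate/step), fused
    into one pass.  Returns (status, clip_mass_error): status 0 on success,
    1 on an undershoot beyond tolerance, 2 on non-finite values.
    """
    ny, nx = C.shape
    M = np.empty((ny, nx))
    Fx = np.empty((ny, nx - 1))
    Fy = np.empty((ny - 1, nx))
    dCdt = np.empty((ny, nx))
    clip_err = 0.0
    for _ in range(n_steps):
        for j in range(ny):
            for i in range(nx):
                M[j, i] = S[j, i] / (1.0 + S[j, i])
        for j in range(ny):
            for i in range(nx - 1):
                f = -0.5 * (M[j, i] + M[j, i + 1]) * (C[j, i + 1] - C[j, i]) / dx
                if bx > 0.0:
                    f += bx * (M[j, i] * C[j, i])
                elif bx < 0.0:
                    f += bx * (M[j, i + 1] * C[j, i + 1])
                Fx[j, i] = f
        for j in range(ny - 1):
            for i in range(nx):
                f = -0.5 * (M[j, i] + M[j + 1, i]) * (C[j + 1, i] - C[j, i]) / dx
                if by > 0.0:
                    f += by * (M[j, i] * C[j, i])
                elif by < 0.0:
                    f += by * (M[j + 1, i] * C[j + 1, i])
                Fy[j, i] = f
        for j in range(ny):
            for i in range(nx):
                div = 0.0
                if i < nx - 1:
                    div += Fx[j, i]
                if i > 0:
                    div -= Fx[j, i - 1]
                if j < ny - 1:
                    div += Fy[j, i]
                if j > 0:
                    div -= Fy[j - 1, i]
                dCdt[j, i] = -div / dx
        for j in range(ny):
            for i in range(nx):
                s_new = S[j, i] + dt * (C[j, i] - S[j, i] / tau)
                c_new = C[j, i] + dt * dCdt[j, i]
                if not (np.isfinite(c_new) and np.isfinite(s_new)):
                    return 2, clip_err
                if c_new < 0.0:
                    if c_new < -clip_tol:
                        return 1, clip_err
                    clip_err -= c_new
                    c_new = 0.0
                if s_new < 0.0:
                    if s_new < -clip_tol:
                        return 1, clip_err
                    s_new = 0.0
                C[j, i] = c_new
                S[j, i] = s_new
    return 0, clip_err


def _segment_boundaries(n_total: int, n_stride: int, switch_steps: Sequence[int]) -> list[int]:
    """Step counts at which the integrator pauses: snapshots, bias switches."""
    marks = set(range(n_stride, n_total, n_stride))
    marks.update(s for s in switch_steps if 0 < s < n_total)
    marks.add(n_total)
    return sorted(marks)


def simulate(
    params: ModelParams,
    grid: GridSpec,
    C0: np.ndarray,
    schedule: BiasSchedule | None = None,
    t_end: float = 300.0,
    dt: float = 0.01,
    stride: float = 1.0,
    S0: np.ndarray | None = None,
    deposition_mask: np.ndarray | None = None,
    seed: int | None = None,
    early_stop: bool = True,
    snapshot_dtype: np.dtype | type = np.float64,
) -> SimulationResult:
    """Integrate the model from ``C0`` (and EPS ``S0``, default zero).

    Snapshots are recorded every ``stride`` time units, the first being the
    initial condition.  With ``early_stop`` the run ends once any column's
    cell front (adaptive-threshold rule of the morphology module) reaches
    row ny-2, i.e. motile groups have crossed the domain.  The result is
    fully reproducible from (params, grid, C0/seed, schedule, dt).
    """
    from . import morphology  # deferred: morphology imports our types

    if not t_end > 0:
        raise ConfigError(f"t_end must be positive, got {t_end}")
    if not dt > 0:
        raise ConfigError(f"dt must be positive, got {dt}")
    if params.tau is not None and dt >= params.tau:
        raise ConfigError(f"dt={dt} must be smaller than the decay constant tau={params.tau}")
    C = np.array(C0, dtype=np.float64, order="C", copy=True)
    if C.shape != grid.shape:
        raise ConfigError(f"C0 must have grid shape {grid.shape}")
    if np.any(C < 0):
        raise DomainError("C0 must be nonnegative")
    if S0 is None:
        S = np.zeros(grid.shape)
    else:
        S = np.array(S0, dtype=np.float64, order="C", copy=True)
        if S.shape != grid.shape or np.any(S < 0):
            raise DomainError("S0 must be nonnegative with grid shape")
    schedule = schedule or BiasSchedule()
    tau = params.tau_effective

    def snap(t: float) -> FieldState:
        return FieldState(C.astype(snapshot_dtype), S.astype(snapshot_dtype), t)

    snapshots = [snap(0.0)]
    result = SimulationResult(
        snapshots, params, grid, schedule,
        None if deposition_mask is None else np.asarray(deposition_mask, bool),
        seed, dt, t_end,
    )
    thr_floor = 1e-3 * params.cbar
    # all scheduling lives on the integer step lattice: t = n * dt
    n_total = int(round(t_end / dt))
    if n_total < 1:
        raise ConfigError(f"t_end={t_end} shorter than one step dt={dt}")
    n_stride = max(1, int(round(stride / dt)))
    switch_steps = [int(round(t / dt)) for t in schedule.switch_times]
    n_done = 0
    early = False
    clip_total = 0.0
    log_every = max(1, int(round(10.0 / dt)))
    next_log = log_every
    for n_target in _segment_boundaries(n_total, n_stride, switch_steps):
        ux, uy = schedule.direction_at(n_done * dt)
        status, clip = _advance_kernel(
            C, S, n_target - n_done, dt, grid.dx,
            params.beta * ux, params.beta * uy, tau, CLIP_TOLERANCE,
        )
        clip_total += clip
        n_done = n_target
        t_now = n_done * dt
        if status != 0:
            kind = "negativity beyond tolerance" if status == 1 else "non-finite values"
            raise StabilityError(
                f"{kind} before t={t_now:.4f}; reduce dt (recommended <= "
                f"{stability_limit(params, grid):.3g})"
            )
        if n_done % n_stride == 0 or n_done == n_total:
            snapshots.append(snap(t_now))
            if early_stop:
                front = morphology.front_positions(C, floor=thr_floor)
                if np.any(front >= grid.ny - 2):
                    early = True
                    break
        if n_done >= next_log:
            next_log += log_every
            logger.info(
                "t=%.1f mass=%.6g maxC=%.3g maxS=%.3g", t_now,
                total_mass(C, grid), C.max(), S.max(),
            )
    result.early_stopped = early
    result.mass_clip_error = clip_total * grid.cell_area
    return result


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------

_SCALE_KINDS = ("length", "time", "concentration", "speed")


def _scale_factor(kind: str, scales: PhysicalScales) -> float:
    if kind not in _SCALE_KINDS:
        raise ConfigError(f"unknown kind {kind!r}; expected one of {_SCALE_KINDS}")
    return getattr(scales, kind)


def to_physical(value, kind: str, scales: PhysicalScales):
    """Convert a natural-unit value to physical units (length*lambda, ...)."""
    return np.asarray(value, dtype=float) * _scale_factor(kind, scales)


def from_physical(value, kind: str, scales: PhysicalScales):
    """Inverse of :func:`to_physical`."""
    return np.asarray(value, dtype=float) / _scale_factor(kind, scales)
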