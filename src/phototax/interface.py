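"""Run configuration, snapshot I/O, canned demonstrations, and rendering.

The YAML run configuration is a flat key-value mapping; grid and numerics
default to the reference setup (360x720 grid, dx=0.25, dt=0.01, t_end=300,
deposition over the bottom 20%).  Snapshot sequences round-trip through an
HDF5 container.  The merge demo reproduces the plate-rotation experiment:
fingers form under an upward bias, the bias is rotated 90 degrees, and a
finger crossing a neighbor's EPS trail speeds up and spreads out.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import morphology
from .core_model import (
    BiasSchedule,
    ConfigError,
    FieldState,
    GridSpec,
    ModelParams,
    SimulationResult,
    simulate,
    stability_limit,
)
from .deposition import DepositionSpec, make_deposition

logger = logging.getLogger(__name__)

#: Reference regime parameters, calibrated on the reproduced phase diagram:
#: the fingering point sits mid-band (~9 distinct groups on the full grid);
#: the uniform-front point is 32x denser; the non-motile point is far enough
#: down the concentration axis (at minimal bias) that the deposition strip
#: cannot move half its mass into fresh territory within t=300.
FINGERING_PARAMS = ModelParams(cbar=0.0625, beta=2.0**1.5)
UNIFORM_FRONT_PARAMS = ModelParams(cbar=2.0, beta=2.0**1.5)
NON_MOTILE_PARAMS = ModelParams(cbar=2.0**-12, beta=1.0)

REFERENCE_PARAMS = {
    "fingering": FINGERING_PARAMS,
    "uniform_front": UNIFORM_FRONT_PARAMS,
    "non_motile": NON_MOTILE_PARAMS,
}


@dataclass
class RunConfig:
    """Everything needed to reproduce a single simulation."""

    cbar: float
    beta: float
    tau: float | None = None
    nx: int = 360
    ny: int = 720
    dx: float = 0.25
    dt: float = 0.01
    t_end: float = 300.0
    stride: float = 1.0
    seed: int = 0
    region_fraction: float = 0.2
    bias_schedule: list = field(default_factory=lambda: [[0.0, 0.0, 1.0]])
    out_dir: str | None = None

    @property
    def params(self) -> ModelParams:
        return ModelParams(self.cbar, self.beta, self.tau)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.nx, self.ny, self.dx)

    @property
    def schedule(self) -> BiasSchedule:
        return BiasSchedule(tuple((t, (ux, uy)) for t, ux, uy in self.bias_schedule))

    @property
    def deposition(self) -> DepositionSpec:
        return DepositionSpec(cbar=self.cbar, region_fraction=self.region_fraction, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["tau"] is None:
            del d["tau"]
        if d["out_dir"] is None:
            del d["out_dir"]
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing keys take the reference defaults; unknown keys are rejected;
    cbar and beta are required.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for req in ("cbar", "beta"):
        if req not in raw:
            raise ConfigError(f"required config key missing: {req!r}")
    cfg = RunConfig(**raw)
    # touch the validating constructors now so errors name the field
    cfg.params, cfg.grid, cfg.schedule, cfg.deposition
    return cfg


def run_config(cfg: RunConfig, early_stop: bool = True,
               snapshot_dtype=np.float64) -> SimulationResult:
    """Execute a configured simulation."""
    limit = stability_limit(cfg.params, cfg.grid)
    if cfg.dt > limit * 2:  # the safety factor is advisory; 2x limit is not
        logger.warning("dt=%g exceeds the stability estimate %g", cfg.dt, limit)
    C0, mask = make_deposition(cfg.grid, cfg.deposition)
    return simulate(
        cfg.params, cfg.grid, C0, cfg.schedule, t_end=cfg.t_end, dt=cfg.dt,
        stride=cfg.stride, deposition_mask=mask, seed=cfg.seed,
        early_stop=early_stop, snapshot_dtype=snapshot_dtype,
    )


def reference_config(regime: str, grid: str = "full", seed: int = 0) -> RunConfig:
    """One of the three shipped regime configs (fingering/uniform/non-motile)."""
    if regime not in REFERENCE_PARAMS:
        raise ConfigError(f"unknown regime {regime!r}; known: {sorted(REFERENCE_PARAMS)}")
    p = REFERENCE_PARAMS[regime]
    if grid == "full":
        g = GridSpec()
        dt = 0.01
    elif grid == "reduced":
        # full height (fronts need the whole course), 2/3 the reference width
        g = GridSpec(nx=240, ny=720, dx=0.25)
        dt = 0.0078125
    else:
        raise ConfigError(f"grid must be 'full' or 'reduced', got {grid!r}")
    return RunConfig(
        cbar=p.cbar, beta=p.beta, tau=p.tau,
        nx=g.nx, ny=g.ny, dx=g.dx, dt=dt, seed=seed,
    )


# ---------------------------------------------------------------------------
# HDF5 snapshot container
# ---------------------------------------------------------------------------

def save_result(result: SimulationResult, path: str | Path) -> None:
    """Write a snapshot sequence to an HDF5 container.

    Datasets: /C and /S (T x ny x nx), /t (T), /deposition_mask; run
    metadata (params, grid, seed, numerics, schedule) as root attributes.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("C", data=np.stack([s.C for s in result.snapshots]))
        f.create_dataset("S", data=np.stack([s.S for s in result.snapshots]))
        f.create_dataset("t", data=result.times)
        if result.deposition_mask is not None:
            f.create_dataset("deposition_mask", data=result.deposition_mask)
        f.attrs["cbar"] = result.params.cbar
        f.attrs["beta"] = result.params.beta
        f.attrs["tau"] = result.params.tau_effective
        f.attrs["nx"] = result.grid.nx
        f.attrs["ny"] = result.grid.ny
        f.attrs["dx"] = result.grid.dx
        f.attrs["seed"] = -1 if result.seed is None else result.seed
        f.attrs["dt"] = result.dt
        f.attrs["t_end"] = result.t_end
        f.attrs["early_stopped"] = result.early_stopped
        f.attrs["mass_clip_error"] = result.mass_clip_error
        f.attrs["code_version"] = result.code_version
        f.attrs["schedule"] = json.dumps(
            [[t, d[0], d[1]] for t, d in result.schedule.entries]
        )


def load_result(path: str | Path) -> SimulationResult:
    """Read a snapshot container written by :func:`save_result`."""
    with h5py.File(path, "r") as f:
        C = f["C"][...]
        S = f["S"][...]
        t = f["t"][...]
        mask = f["deposition_mask"][...].astype(bool) if "deposition_mask" in f else None
        a = dict(f.attrs)
    tau = None if math.isinf(float(a["tau"])) else float(a["tau"])
    schedule = BiasSchedule(
        tuple((float(e[0]), (float(e[1]), float(e[2]))) for e in json.loads(a["schedule"]))
    )
    snaps = [FieldState(C[i], S[i], float(t[i])) for i in range(len(t))]
    seed = int(a["seed"])
    result = SimulationResult(
        snaps,
        ModelParams(float(a["cbar"]), float(a["beta"]), tau),
        GridSpec(int(a["nx"]), int(a["ny"]), float(a["dx"])),
        schedule,
        mask,
        None if seed < 0 else seed,
        float(a["dt"]),
        float(a["t_end"]),
        early_stopped=bool(a["early_stopped"]),
        mass_clip_error=float(a.get("mass_clip_error", 0.0)),
        code_version=str(a["code_version"]),
    )
    return result


# ---------------------------------------------------------------------------
# Merge demo
# ---------------------------------------------------------------------------

#: Radius (natural length units) of the moving observation window used by
#: the merge demo; large enough to hold a finger plus its dispersal halo.
DEMO_WINDOW_RADIUS = 5.0


def _window_metrics(
    snap: FieldState, center: tuple[float, float], radius: float,
    beta: float, schedule: BiasSchedule, grid: GridSpec,
) -> tuple[float, float, tuple[float, float]]:
    """Group kinematics inside a fixed circular window around ``center``.

    Returns (mean cell speed, spread, mean velocity vector), all mass-
    weighted over the window.  Speed is the continuum analog of averaging
    single-cell velocities: |J|/C with J = -M grad C + beta M C b_hat.
    Spread is the radius of the mass-effective area
    (sum C)^2/(sum C^2) * dx^2 (inverse participation ratio): dispersing
    the same mass over more elements grows it, with no dependence on a
    segmentation threshold.
    """
    C = np.asarray(snap.C, dtype=float)
    S = np.asarray(snap.S, dtype=float)
    ny, nx = C.shape
    jj, ii = np.mgrid[0:ny, 0:nx]
    x = (ii + 0.5) * grid.dx
    y = (jj + 0.5) * grid.dx
    inside = (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2
    M = S / (1.0 + S)
    grady, gradx = np.gradient(C, grid.dx)
    ux, uy = schedule.direction_at(snap.t)
    Jx = -M * gradx + beta * ux * M * C
    Jy = -M * grady + beta * uy * M * C
    w = C[inside]
    wtot = float(w.sum())
    if wtot <= 0:
        return math.nan, math.nan, (0.0, 0.0)
    speed = float(np.hypot(Jx, Jy)[inside].sum()) / wtot
    vx = float(Jx[inside].sum()) / wtot
    vy = float(Jy[inside].sum()) / wtot
    area_eff = wtot**2 / float((w**2).sum()) * grid.cell_area
    return speed, math.sqrt(area_eff / math.pi), (vx, vy)


@dataclass(frozen=True)
class MergeDemoReport:
    """Outcome of the bias-rotation merge demonstration."""

    event_detected: bool
    event_time: float = math.nan
    pre_speed: float = math.nan
    post_speed: float = math.nan
    pre_spread: float = math.nan
    post_spread: float = math.nan
    n_events: int = 0


def merge_demo(
    params: ModelParams = FINGERING_PARAMS,
    grid: GridSpec | None = None,
    rotate_at: float = 80.0,
    t_end: float = 160.0,
    dt: float = 0.0078125,
    seed: int = 0,
    S0: np.ndarray | None = None,
) -> tuple[MergeDemoReport, SimulationResult]:
    """Form fingers, rotate the bias 90 degrees, and look for a trail crossing.

    Runs a fingering-regime simulation with the bias pointing at the light
    until ``rotate_at``, then switches it to the +x direction so motile
    groups sweep across their neighbors' EPS trails.  Reports the first
    trail-crossing event's pre/post group speed and spatial spread (mass-
    weighted RMS radius); "no merge" is a valid, non-fatal outcome.
    """
    if grid is None:
        grid = GridSpec(nx=240, ny=720, dx=0.25)
    if not 0 < rotate_at < t_end:
        raise ConfigError("rotate_at must lie inside (0, t_end)")
    schedule = BiasSchedule(((0.0, (0.0, 1.0)), (rotate_at, (1.0, 0.0))))
    C0, mask = make_deposition(grid, DepositionSpec(cbar=params.cbar, seed=seed))
    result = simulate(
        params, grid, C0, schedule, t_end=t_end, dt=dt, S0=S0,
        deposition_mask=mask, seed=seed, early_stop=False,
        snapshot_dtype=np.float32,
    )
    tracks = morphology.track_groups(result)
    events = [
        e for e in morphology.detect_merges(result, tracks) if e.time > rotate_at
    ]
    if not events:
        return MergeDemoReport(False), result
    # the demonstration follows the first substantive crossing, not a graze
    strong = [e for e in events if e.overlap >= morphology.MIN_GROUP_SIZE]
    first = min(strong or events, key=lambda e: e.time)
    tr = next(t for t in tracks if t.track_id == first.track_id)
    local = tr.times.index(first.time)
    i_e = tr.start_index + local
    window = morphology.RAMP_WINDOW
    # pre: a fixed observation window on the formed finger just before
    # contact, then advected with the group's mean velocity so that the
    # post measurement sees the same material even after it disperses
    # below the segmentation threshold
    R = DEMO_WINDOW_RADIUS
    center = tr.centroids[max(0, local - 1)]
    pre_snap = result.snapshots[i_e - 1] if i_e > 0 else result.snapshots[i_e]
    pre_speed, pre_spread, v_vec = _window_metrics(
        pre_snap, center, R, params.beta, schedule, grid
    )
    n_post = min(window, len(result.snapshots) - 1 - i_e)
    for k in range(n_post):
        snap_k = result.snapshots[i_e + k]
        dt_snap = result.snapshots[i_e + k + 1].t - snap_k.t
        _, _, v_vec = _window_metrics(snap_k, center, R, params.beta, schedule, grid)
        center = (center[0] + v_vec[0] * dt_snap, center[1] + v_vec[1] * dt_snap)
    post_snap = result.snapshots[i_e + n_post]
    post_speed, post_spread, _ = _window_metrics(
        post_snap, center, R, params.beta, schedule, grid
    )
    return (
        MergeDemoReport(
            True, first.time, pre_speed, post_speed,
            pre_spread, post_spread, len(events),
        ),
        result,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _to_rgb(C: np.ndarray, S: np.ndarray, c_scale: float, s_scale: float) -> np.ndarray:
    """Cells green, EPS red, co-localization orange; origin at the bottom."""
    g = np.clip(np.asarray(C, float) / c_scale, 0.0, 1.0)
    r = np.clip(np.asarray(S, float) / s_scale, 0.0, 1.0)
    rgb = np.zeros(C.shape + (3,))
    rgb[..., 0] = r
    rgb[..., 1] = g
    return rgb[::-1, :, :]  # flip so the light source is at the image top


def render(
    result: SimulationResult,
    out_dir: str | Path,
    indices: list[int] | None = None,
    prefix: str = "snapshot",
) -> list[Path]:
    """Write PNG renders of snapshots (purely presentational)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if indices is None:
        n = len(result.snapshots)
        indices = sorted({0, n // 2, n - 1})
    c_scale = max(2.0 * result.params.cbar, 1e-12)
    s_scale = 1.0  # the mobility half-saturation level
    paths = []
    for i in indices:
        snap = result.snapshots[i]
        fig, ax = plt.subplots(figsize=(4, 4 * result.grid.ny / result.grid.nx))
        ax.imshow(_to_rgb(snap.C, snap.S, c_scale, s_scale), interpolation="nearest")
        ax.set_axis_off()
        ax.set_title(f"t = {snap.t:g}")
        p = out / f"{prefix}_{i:04d}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths


_CLASS_COLORS = {
    morphology.FINGERING: "tab:red",
    morphology.UNIFORM_FRONT: "tab:gray",
    morphology.NON_MOTILE: "black",
}


def render_phase_diagram(diagram, path: str | Path) -> Path:
    """Scatter plot of a phase diagram with one color per class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for pt in diagram.points:
        y = pt.params.beta if diagram.mode == "bias" else pt.params.tau_effective
        ax.scatter(
            pt.params.cbar, y,
            c=_CLASS_COLORS.get(pt.consensus_label, "tab:blue"), s=30,
        )
    ax.set_xscale("log", base=2)
    ax.set_yscale("log", base=2)
    ax.set_xlabel("mean cell concentration  $\\bar{C}$")
    ax.set_ylabel("bias $\\beta$" if diagram.mode == "bias" else "EPS decay $\\tau$")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
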