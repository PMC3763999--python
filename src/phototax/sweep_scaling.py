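"""Phase-diagram sweeps and power-law scaling fits.

Sweeps cover the (cbar, beta) plane (bias mode) or the (cbar, tau) plane at
fixed beta (decay mode), with axis values log2-spaced and several seeded
replicates per point, reproducing the three-class phase structure
(non-motile / uniform front / fingering).  Within the fingering region the
module fits the empirical scaling laws: group biomass N ~ cbar, steady
speed v_ss ~ cbar^(1/3), ramp time ~ cbar^(-1/2), and v_ss ~ N^(1/3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import morphology
from .core_model import (
    BiasSchedule,
    ConfigError,
    GridSpec,
    ModelParams,
    SimulationResult,
    simulate,
)
from .deposition import DepositionSpec, make_deposition

logger = logging.getLogger(__name__)

#: Default replicate count per phase point.
DEFAULT_SEEDS = 3

#: Seed offset between phase points (replicate r of point p gets
#: master + POINT_SEED_STRIDE * p + r).
POINT_SEED_STRIDE = 8191

#: Default bias-sweep axes: cbar over 2^-12 .. 2^-3 in half-powers of two
#: (19 values, 3.3 decades), beta over 2^0 .. 2^3 (10 values, one decade).
#: The cbar range brackets the reproduced phase structure: below ~2^-11 at
#: weak bias the strip cannot build enough EPS to move half its mass out
#: within t=300 (non-motile); near the top of the range fronts advance
#: uniformly.
BIAS_CBAR_VALUES = tuple(2.0 ** (0.5 * k) for k in range(-24, -5))
BIAS_BETA_VALUES = tuple(2.0 ** e for e in np.linspace(0.0, 3.0, 10))

#: Default decay-sweep axes: cbar over 2^-8 .. 2^-2.5 (12 values), tau over
#: 2^0 .. 2^6.5 in half-powers (14 values), at a fixed fingering-band beta.
#: Short decay constants starve low-concentration strips of EPS
#: (non-motile); long ones recover the decay-free morphology.
DECAY_CBAR_VALUES = tuple(2.0 ** (0.5 * k) for k in range(-16, -4))
DECAY_TAU_VALUES = tuple(2.0 ** (0.5 * k) for k in range(0, 14))

#: Fixed bias for the decay sweep: midpoint (in log2) of the swept beta
#: decade, inside the fingering band of the reproduced phase diagram.
DECAY_SWEEP_BETA = 4.0

#: Default sweep grid: full domain height (fronts must travel the full
#: 144 natural-length course for finger kinetics to reach steady state)
#: at 2/3 the reference width.  The full reference grid is 360x720.
SWEEP_GRID = GridSpec(nx=240, ny=720, dx=0.25)

#: Scaling-sweep defaults: one fingering-band bias, cbar in whole powers
#: of four spanning three decades, two seeds per point.
SCALING_BETA = 4.0
SCALING_CBAR_VALUES = tuple(2.0 ** k for k in range(-10, 1, 2))
SCALING_SEEDS = 2

#: Tracks whose final centroid advance is within this fraction of the
#: leader's advance count as "leading groups" for scaling statistics.
LEADING_FRACTION = 0.8


@dataclass
class RunSummary:
    """Flattened morphology metrics of one simulation."""

    cbar: float
    beta: float
    tau: float | None
    seed: int
    label: str
    fresh_fraction: float
    instability: float
    n_groups: int
    mean_N: float = math.nan
    mean_v_ss: float = math.nan
    mean_ramp: float = math.nan
    n_tracks_used: int = 0
    merge_events: int = 0


@dataclass
class PhasePoint:
    """One parameter point of a phase diagram with its replicates."""

    params: ModelParams
    replicates: list[RunSummary] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.replicates]

    @property
    def consensus_label(self) -> str:
        labs = self.labels
        return max(set(labs), key=labs.count)


@dataclass
class PhaseDiagram:
    """Grid of classified phase points over (cbar, second axis)."""

    mode: str  # "bias" or "decay"
    cbar_values: tuple[float, ...]
    second_axis_values: tuple[float, ...]  # beta (bias mode) or tau (decay mode)
    points: list[PhasePoint] = field(default_factory=list)
    fixed_beta: float | None = None  # decay mode only

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pt in self.points:
            for rep in pt.replicates:
                rows.append(vars(rep).copy())
        return pd.DataFrame(rows)

    def select(self, label: str | None = None, **param_filters) -> list[RunSummary]:
        out = []
        for pt in self.points:
            ok = all(
                math.isclose(getattr(pt.params, k) or math.inf, v or math.inf)
                for k, v in param_filters.items()
            )
            if not ok:
                continue
            for rep in pt.replicates:
                if label is None or rep.label == label:
                    out.append(rep)
        return out


@dataclass(frozen=True)
class ScalingFit:
    """Least-squares power-law fit y = exp(intercept) * x^exponent."""

    exponent: float
    intercept: float
    exponent_se: float
    r_squared: float
    n_points: int


def fit_power_law(x, y) -> ScalingFit:
    """Fit a power law by ordinary least squares on (ln x, ln y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("x and y must be 1D arrays of equal length")
    if x.size < 4:
        raise ConfigError(f"power-law fit needs >= 4 points, got {x.size}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ConfigError("power-law fit requires strictly positive values")
    res = stats.linregress(np.log(x), np.log(y))
    return ScalingFit(
        exponent=float(res.slope),
        intercept=float(res.intercept),
        exponent_se=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n_points=int(x.size),
    )


# ---------------------------------------------------------------------------
# Per-run metric extraction
# ---------------------------------------------------------------------------

def leading_tracks(result: SimulationResult) -> list[morphology.GroupTrack]:
    """Tracks alive at the end whose advance is close to the leader's.

    Advance is the final centroid position minus the deposition edge along
    the light axis; tracks within ``LEADING_FRACTION`` of the leader and
    spanning at least the minimum snapshot count qualify.
    """
    tracks = [
        tr
        for tr in morphology.track_groups(result)
        if tr.alive_at_end and tr.n_snapshots >= morphology.MIN_TRACK_SNAPSHOTS
    ]
    if not tracks:
        return []
    if result.deposition_mask is not None and result.deposition_mask.any():
        edge = (result.deposition_mask.any(axis=1).sum()) * result.grid.dx
    else:
        edge = 0.0
    advances = [tr.centroids[-1][1] - edge for tr in tracks]
    best = max(advances)
    if best <= 0:
        return tracks
    return [tr for tr, adv in zip(tracks, advances) if adv >= LEADING_FRACTION * best]


def summarize_run(result: SimulationResult, count_merges: bool = False) -> RunSummary:
    """Classify one run and average kinetics over its leading groups."""
    label = morphology.classify(result)
    p = result.params
    out = RunSummary(
        p.cbar, p.beta, p.tau, result.seed if result.seed is not None else -1,
        label.label, label.fresh_fraction, label.instability, label.n_groups,
    )
    if label.label != morphology.NON_MOTILE:
        lead = leading_tracks(result)
        if lead:
            kin = [morphology.group_kinetics(tr) for tr in lead]
            out.mean_N = float(np.mean([k[0] for k in kin]))
            out.mean_v_ss = float(np.mean([k[1] for k in kin]))
            out.mean_ramp = float(np.mean([k[2] for k in kin]))
            out.n_tracks_used = len(lead)
        if count_merges:
            out.merge_events = len(morphology.detect_merges(result))
    return out


def run_point(
    params: ModelParams,
    grid: GridSpec,
    seed: int,
    dt: float = 0.01,
    t_end: float = 300.0,
    stride: float = 1.0,
    count_merges: bool = False,
) -> RunSummary:
    """Run one seeded simulation at a phase point and summarize it."""
    C0, mask = make_deposition(grid, DepositionSpec(cbar=params.cbar, seed=seed))
    result = simulate(
        params, grid, C0, BiasSchedule(), t_end=t_end, dt=dt, stride=stride,
        deposition_mask=mask, seed=seed, snapshot_dtype=np.float32,
    )
    return summarize_run(result, count_merges=count_merges)


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def run_sweep(
    mode: str = "bias",
    cbar_values=None,
    second_axis_values=None,
    n_seeds: int = DEFAULT_SEEDS,
    grid: GridSpec = SWEEP_GRID,
    dt: float = 0.0078125,
    t_end: float = 300.0,
    master_seed: int = 0,
    fixed_beta: float = DECAY_SWEEP_BETA,
    manifest_path: str | Path | None = None,
    count_merges: bool = False,
) -> PhaseDiagram:
    """Classify every (cbar, second-axis) pair with seeded replicates.

    ``mode='bias'`` sweeps beta with no EPS decay; ``mode='decay'`` sweeps
    tau at the fixed fingering-band beta.  Replicate r of point p is seeded
    ``master_seed + POINT_SEED_STRIDE*p + r``.  When ``manifest_path`` is
    given, per-run rows are appended as they complete and already-recorded
    runs are skipped on resume; individual run failures are logged per
    point, not fatal to the sweep.
    """
    if mode not in ("bias", "decay"):
        raise ConfigError(f"unknown sweep mode {mode!r}")
    if n_seeds < 1:
        raise ConfigError("n_seeds must be >= 1")
    if cbar_values is None:
        cbar_values = BIAS_CBAR_VALUES if mode == "bias" else DECAY_CBAR_VALUES
    if second_axis_values is None:
        second_axis_values = BIAS_BETA_VALUES if mode == "bias" else DECAY_TAU_VALUES
    diagram = PhaseDiagram(
        mode, tuple(cbar_values), tuple(second_axis_values),
        fixed_beta=fixed_beta if mode == "decay" else None,
    )
    done: set[tuple[float, float, float, int]] = set()
    manifest = Path(manifest_path) if manifest_path is not None else None
    if manifest is not None and manifest.exists():
        prev = pd.read_csv(manifest)
        done = {
            (round(r.cbar, 12), round(r.beta, 12), round(r.tau, 12), int(r.seed))
            for r in prev.itertuples()
        }
    p_idx = 0
    for second in second_axis_values:
        for cbar in cbar_values:
            if mode == "bias":
                params = ModelParams(cbar=cbar, beta=second, tau=None)
            else:
                params = ModelParams(cbar=cbar, beta=fixed_beta, tau=second)
            point = PhasePoint(params)
            for r in range(n_seeds):
                seed = master_seed + POINT_SEED_STRIDE * p_idx + r
                key = (
                    round(params.cbar, 12), round(params.beta, 12),
                    round(params.tau_effective, 12), seed,
                )
                if key in done:
                    row = prev[
                        np.isclose(prev.cbar, params.cbar)
                        & np.isclose(prev.beta, params.beta)
                        & (prev.seed == seed)
                    ].iloc[0]
                    point.replicates.append(
                        RunSummary(**{k: row[k] for k in RunSummary.__dataclass_fields__ if k in row})
                    )
                    continue
                try:
                    summary = run_point(
                        params, grid, seed, dt=dt, t_end=t_end, count_merges=count_merges
                    )
                except Exception as exc:  # recorded per point, sweep continues
                    logger.error("run failed at %s seed=%d: %s", params, seed, exc)
                    continue
                point.replicates.append(summary)
                if manifest is not None:
                    row = vars(summary).copy()
                    row["tau"] = params.tau_effective
                    pd.DataFrame([row]).to_csv(
                        manifest, mode="a", header=not manifest.exists(), index=False
                    )
            diagram.points.append(point)
            p_idx += 1
    return diagram


# ---------------------------------------------------------------------------
# Scaling summaries and replicate consistency
# ---------------------------------------------------------------------------

#: The four fitted relationships: (name, x metric, y metric).
SCALING_RELATIONSHIPS = (
    ("N_vs_cbar", "cbar", "mean_N"),
    ("v_vs_cbar", "cbar", "mean_v_ss"),
    ("ramp_vs_cbar", "cbar", "mean_ramp"),
    ("v_vs_N", "mean_N", "mean_v_ss"),
)


def scaling_summary(diagram: PhaseDiagram, min_points: int = 4) -> pd.DataFrame:
    """Power-law fits over the fingering region, one set per beta value.

    Per phase point, metrics are replicate means over the leading groups;
    fits needing fewer than ``min_points`` usable points are omitted with
    a reason row.
    """
    betas = (
        [diagram.fixed_beta]
        if diagram.mode == "decay"
        else sorted({pt.params.beta for pt in diagram.points})
    )
    rows = []
    for beta in betas:
        pts = []
        for pt in diagram.points:
            if not math.isclose(pt.params.beta, beta):
                continue
            reps = [r for r in pt.replicates if r.label == morphology.FINGERING]
            if not reps:
                continue
            rec = {"cbar": pt.params.cbar}
            for metric in ("mean_N", "mean_v_ss", "mean_ramp"):
                vals = [getattr(r, metric) for r in reps if math.isfinite(getattr(r, metric))]
                rec[metric] = float(np.mean(vals)) if vals else math.nan
            pts.append(rec)
        frame = pd.DataFrame(pts)
        for name, xcol, ycol in SCALING_RELATIONSHIPS:
            base = {"relationship": name, "beta": beta}
            if frame.empty:
                rows.append(base | {"omitted": "no fingering points"})
                continue
            sub = frame[[xcol, ycol]].dropna()
            sub = sub[(sub[xcol] > 0) & (sub[ycol] > 0)]
            if len(sub) < min_points:
                rows.append(base | {"omitted": f"only {len(sub)} usable points"})
                continue
            fit = fit_power_law(sub[xcol].to_numpy(), sub[ycol].to_numpy())
            rows.append(
                base
                | {
                    "exponent": fit.exponent,
                    "intercept": fit.intercept,
                    "exponent_se": fit.exponent_se,
                    "r_squared": fit.r_squared,
                    "n_points": fit.n_points,
                    "omitted": "",
                }
            )
    return pd.DataFrame(rows)


def _relative_spread(values) -> float:
    """max |x_i - mean| / mean; 0 for identical values."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0:
        return 0.0 if np.all(v == 0) else math.inf
    return float(np.max(np.abs(v - m)) / abs(m))


def replicate_consistency(diagram: PhaseDiagram) -> pd.DataFrame:
    """Per-point class agreement and metric spread across replicates.

    Reports, for every phase point with >= 2 replicates, whether all
    replicates received the same class, and the relative spread
    (max |x - mean| / mean) of mean finger speed and ramp time.
    """
    rows = []
    for pt in diagram.points:
        if len(pt.replicates) < 2:
            continue
        labels = pt.labels
        speeds = [r.mean_v_ss for r in pt.replicates if math.isfinite(r.mean_v_ss)]
        ramps = [r.mean_ramp for r in pt.replicates if math.isfinite(r.mean_ramp)]
        rows.append(
            {
                "cbar": pt.params.cbar,
                "beta": pt.params.beta,
                "tau": pt.params.tau_effective,
                "n_replicates": len(pt.replicates),
                "class_agreement": len(set(labels)) == 1,
                "consensus_class": pt.consensus_label,
                "speed_spread": _relative_spread(speeds) if len(speeds) >= 2 else math.nan,
                "ramp_spread": _relative_spread(ramps) if len(ramps) >= 2 else math.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Canned scaling sweep
# ---------------------------------------------------------------------------

def run_scaling_sweep(
    master_seed: int = 0,
    cbar_values=SCALING_CBAR_VALUES,
    beta: float = SCALING_BETA,
    n_seeds: int = SCALING_SEEDS,
    grid: GridSpec = SWEEP_GRID,
    dt: float = 0.0078125,
) -> tuple[PhaseDiagram, pd.DataFrame]:
    """Decay-free scaling sweep along the fingering band.

    Runs ``n_seeds`` replicates at each cbar value at one fingering-band
    bias and fits the four power-law relationships over the points that
    classify as fingering.  Returns the phase diagram and the fit table.
    """
    diagram = run_sweep(
        mode="bias",
        cbar_values=tuple(cbar_values),
        second_axis_values=(beta,),
        n_seeds=n_seeds,
        grid=grid,
        dt=dt,
        master_seed=master_seed,
    )
    return diagram, scaling_summary(diagram)
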