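"""Quantification of simulated community morphologies.

Mirrors the analysis applied to the cell-concentration movies: a run is
classed as non-motile if less than half of the cell mass reaches fresh
territory; motile runs are split into uniform-front vs fingering by the
growth of the front instability (standard deviation of per-column front
positions over mean front advance, with 0.01 as the cut).  Distinct motile
groups (fingers) are segmented as connected components above an adaptive
threshold, linked over time by mask overlap, and characterized by biomass,
center-of-mass speed, and ramp time; EPS trail-crossing events between
groups are detected from the S field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_model import ConfigError, GridSpec, SimulationResult

#: Fraction of the mass-weighted 95th percentile of C used as the adaptive
#: front/segmentation threshold; scale-free across the concentration sweep.
THRESHOLD_FRACTION = 0.1

#: Mass quantile defining the reference concentration of the threshold.
THRESHOLD_MASS_QUANTILE = 0.95

#: Floor on the adaptive threshold, as a fraction of cbar.
THRESHOLD_FLOOR_FRACTION = 1e-3

#: Fresh-mass fraction below which a run is non-motile.
FRESH_MASS_CUT = 0.5

#: Front-instability value separating uniform fronts from fingering.
INSTABILITY_CUT = 0.01

#: Minimum connected-component size (grid elements) for a motile group.
MIN_GROUP_SIZE = 10

#: EPS level above which the field counts as a trail for merge detection.
TRAIL_THRESHOLD = 0.05

#: 8-connectivity structuring element for component labelling.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)

NON_MOTILE = "non_motile"
UNIFORM_FRONT = "uniform_front"
FINGERING = "fingering"


# ---------------------------------------------------------------------------
# Thresholds and front tracing
# ---------------------------------------------------------------------------

def adaptive_threshold(C: np.ndarray, floor: float = 0.0) -> float:
    """Scale-free segmentation threshold for a concentration snapshot.

    A fixed fraction of the mass-weighted 95th percentile of C (the
    concentration below which 95% of the cell mass sits), floored at
    ``floor`` (typically 1e-3 * cbar).  Weighting by mass keeps the
    threshold pinned to the dense motile groups; an unweighted percentile
    would be dominated by the vast low-level halo/trail pixels and trace a
    spurious diffusive skin instead of the cell front.  An all-zero field
    gets +inf so that nothing is ever above threshold.
    """
    pos = np.sort(C[C > 0].ravel())
    if pos.size == 0:
        return math.inf
    cum = np.cumsum(pos)
    ref = float(pos[np.searchsorted(cum, THRESHOLD_MASS_QUANTILE * cum[-1])])
    return max(THRESHOLD_FRACTION * ref, floor)


def front_positions(C: np.ndarray, threshold: float | None = None, floor: float = 0.0) -> np.ndarray:
    """Per-column front row index (toward the light); -1 where absent."""
    thr = adaptive_threshold(C, floor) if threshold is None else threshold
    above = C > thr
    any_above = above.any(axis=0)
    ny = C.shape[0]
    rows = ny - 1 - np.argmax(above[::-1, :], axis=0)
    return np.where(any_above, rows, -1)


@dataclass(frozen=True)
class FrontTrace:
    """Per-column position of the advancing cell front at one time.

    ``rows`` holds the largest row index above threshold per column, -1
    where the column has no cells; ``dx`` converts rows to natural units.
    """

    rows: np.ndarray
    dx: float
    threshold: float
    t: float = 0.0

    @property
    def present(self) -> np.ndarray:
        return self.rows >= 0

    @property
    def positions(self) -> np.ndarray:
        """Front positions in natural length units; NaN where absent."""
        return np.where(self.present, self.rows * self.dx, np.nan)


def front_trace(
    C: np.ndarray,
    grid: GridSpec | None = None,
    dx: float = 1.0,
    floor: float = 0.0,
    threshold: float | None = None,
    t: float = 0.0,
) -> FrontTrace:
    """Trace the moving cell front with the adaptive threshold rule."""
    if np.any(np.asarray(C) < 0):
        raise ConfigError("C must be nonnegative")
    if grid is not None:
        dx = grid.dx
    thr = adaptive_threshold(C, floor) if threshold is None else threshold
    return FrontTrace(front_positions(C, threshold=thr), dx, thr, t)


def instability_metric(trace_t: FrontTrace, trace_0: FrontTrace) -> float:
    """Front-instability growth metric.

    Standard deviation of the front positions, normalized by the mean
    distance the front has advanced: 0 for a perfectly flat advancing
    front, near 1 for strongly fingered fronts.  NaN (flagged undefined)
    when the mean advance is not positive or no columns are shared.
    """
    if trace_t.rows.shape != trace_0.rows.shape:
        raise ConfigError("traces must share columns")
    both = trace_t.present & trace_0.present
    if not both.any():
        return math.nan
    pt = trace_t.positions[both]
    p0 = trace_0.positions[both]
    advance = float(np.mean(pt - p0))
    if advance <= 0:
        return math.nan
    return float(np.std(pt)) / advance


def fresh_mass_fraction(result: SimulationResult) -> float:
    """Fraction of final cell mass outside the initial deposition region."""
    if result.deposition_mask is None:
        raise ConfigError("result has no deposition mask")
    if len(result.snapshots) < 2:
        raise ConfigError("need at least two snapshots")
    C = np.asarray(result.final.C, dtype=float)
    total = float(C.sum())
    if total == 0:
        return 0.0
    return float(C[~result.deposition_mask].sum()) / total


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassLabel:
    """Morphology class with its supporting metrics."""

    label: str
    fresh_fraction: float
    instability: float
    n_groups: int = 0


def classify(result: SimulationResult) -> ClassLabel:
    """Three-way morphology classification of a completed run.

    non_motile if less than half the mass reached fresh territory;
    otherwise uniform_front or fingering according to whether the front
    instability at the final snapshot exceeds 0.01.
    """
    floor = THRESHOLD_FLOOR_FRACTION * result.params.cbar
    fresh = fresh_mass_fraction(result)
    t0 = front_trace(result.initial.C, grid=result.grid, floor=floor, t=result.initial.t)
    t1 = front_trace(result.final.C, grid=result.grid, floor=floor, t=result.final.t)
    inst = instability_metric(t1, t0)
    groups = segment_groups(result.final.C, dx=result.grid.dx, S=result.final.S, floor=floor)
    if fresh < FRESH_MASS_CUT or math.isnan(inst):
        return ClassLabel(NON_MOTILE, fresh, inst, len(groups))
    label = UNIFORM_FRONT if inst <= INSTABILITY_CUT else FINGERING
    return ClassLabel(label, fresh, inst, len(groups))


# ---------------------------------------------------------------------------
# Group segmentation
# ---------------------------------------------------------------------------

@dataclass
class MotileGroup:
    """A segmented finger: one 8-connected component above threshold."""

    id: int
    pixels: np.ndarray  # flat indices into the field
    shape: tuple[int, int]
    biomass: float  # integral of C over the component, in mass units
    centroid: tuple[float, float]  # (x, y) in natural length units
    trail_depth: float = math.nan  # mean S in a band just behind the group

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m.flat[self.pixels] = True
        return m

    @property
    def size(self) -> int:
        return self.pixels.size


def segment_groups(
    C: np.ndarray,
    dx: float = 1.0,
    S: np.ndarray | None = None,
    threshold: float | None = None,
    floor: float = 0.0,
    min_size: int = MIN_GROUP_SIZE,
) -> list[MotileGroup]:
    """Segment distinct motile groups in a concentration snapshot.

    8-connected components of {C > threshold}; components smaller than
    ``min_size`` grid elements are discarded as threshold speckle.  Biomass
    is the integral of C over the component; trail depth is the mean S in
    the 4 rows immediately behind (below) the component's trailing edge.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ConfigError("C must be nonnegative")
    thr = adaptive_threshold(C, floor) if threshold is None else threshold
    labels, n = ndimage.label(C > thr, structure=_STRUCTURE_8)
    if n == 0:
        return []
    groups: list[MotileGroup] = []
    ny, nx = C.shape
    for lab in range(1, n + 1):
        pix = np.flatnonzero(labels == lab)
        if pix.size < min_size:
            continue
        jj, ii = np.unravel_index(pix, C.shape)
        w = C.flat[pix]
        wtot = float(w.sum())
        cx = float((w * (ii + 0.5)).sum()) / wtot * dx
        cy = float((w * (jj + 0.5)).sum()) / wtot * dx
        depth = math.nan
        if S is not None:
            j_trail_hi = int(jj.min())
            j_trail_lo = max(0, j_trail_hi - 4)
            if j_trail_hi > j_trail_lo:
                band = np.asarray(S)[j_trail_lo:j_trail_hi, ii.min() : ii.max() + 1]
                depth = float(band.mean())
        groups.append(
            MotileGroup(len(groups), pix, (ny, nx), wtot * dx * dx, (cx, cy), depth)
        )
    return groups


def count_groups(result: SimulationResult) -> int:
    """Number of distinct motile groups at the final snapshot."""
    floor = THRESHOLD_FLOOR_FRACTION * result.params.cbar
    return len(segment_groups(result.final.C, dx=result.grid.dx, floor=floor))


# ---------------------------------------------------------------------------
# Tracking
# ---------------------------------------------------------------------------

@dataclass
class GroupTrack:
    """A motile group linked across snapshots by maximal mask overlap."""

    track_id: int
    start_index: int  # snapshot index of the first appearance
    times: list[float] = field(default_factory=list)
    pixel_history: list[np.ndarray] = field(default_factory=list)
    biomasses: list[float] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    trail_depths: list[float] = field(default_factory=list)
    alive_at_end: bool = False
    merged_into: int | None = None  # surviving track if this one was absorbed
    absorbed: list[tuple[float, int]] = field(default_factory=list)  # (t, track)
    parent_id: int | None = None  # track this one split from, if any
    # speed history of the ancestor lineage before this track's birth; a
    # finger that splits off an already-motile front has already ramped
    lineage_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    lineage_speeds: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    @property
    def centroid_array(self) -> np.ndarray:
        return np.asarray(self.centroids, dtype=float)

    @property
    def speeds(self) -> np.ndarray:
        """Center-of-mass speed series, central differences over time."""
        c = self.centroid_array
        t = np.asarray(self.times)
        n = len(t)
        v = np.empty(n)
        if n == 1:
            return np.zeros(1)
        disp = c[1:] - c[:-1]
        step_speed = np.hypot(disp[:, 0], disp[:, 1]) / (t[1:] - t[:-1])
        v[0] = step_speed[0]
        v[-1] = step_speed[-1]
        if n > 2:
            central = c[2:] - c[:-2]
            v[1:-1] = np.hypot(central[:, 0], central[:, 1]) / (t[2:] - t[:-2])
        return v

    def spread(self, index: int, C: np.ndarray, dx: float) -> float:
        """Mass-weighted RMS radius of the group mask at a local index."""
        pix = self.pixel_history[index]
        jj, ii = np.unravel_index(pix, C.shape)
        w = np.asarray(C).flat[pix]
        wtot = w.sum()
        cx = (w * ii).sum() / wtot
        cy = (w * jj).sum() / wtot
        r2 = (ii - cx) ** 2 + (jj - cy) ** 2
        return float(math.sqrt((w * r2).sum() / wtot)) * dx


def track_groups(
    result: SimulationResult,
    min_size: int = MIN_GROUP_SIZE,
) -> list[GroupTrack]:
    """Link segmented groups across snapshots into tracks.

    Each group inherits the track of the previous-snapshot group it
    overlaps most (in pixels); groups with no overlap start new tracks
    (births and splits).  When several groups claim one track, the largest
    overlap wins and the rest start new tracks.  A track whose mask is
    taken over by a group assigned to a different track is closed with a
    merge event recorded on the survivor.
    """
    snaps = result.snapshots
    if len(snaps) < 3:
        raise ConfigError("tracking needs at least 3 snapshots")
    floor = THRESHOLD_FLOOR_FRACTION * result.params.cbar
    dx = result.grid.dx
    shape = result.grid.shape
    tracks: list[GroupTrack] = []
    prev_img = np.full(shape, -1, dtype=np.int32).ravel()
    active: set[int] = set()
    for i, snap in enumerate(snaps):
        groups = segment_groups(snap.C, dx=dx, S=snap.S, floor=floor, min_size=min_size)
        # candidate track per group: maximal pixel overlap with previous ids
        candidates: list[dict[int, int]] = []
        for g in groups:
            ids = prev_img[g.pixels]
            ids = ids[ids >= 0]
            if ids.size:
                vals, counts = np.unique(ids, return_counts=True)
                candidates.append(dict(zip(vals.tolist(), counts.tolist())))
            else:
                candidates.append({})
        # greedy one-to-one matching by decreasing overlap (label-free)
        pairs = sorted(
            ((ov, g_idx, tid) for g_idx, cand in enumerate(candidates) for tid, ov in cand.items()),
            key=lambda p: (-p[0], p[1], p[2]),
        )
        assignment: dict[int, int] = {}  # group idx -> track id
        claimed: set[int] = set()
        for ov, g_idx, tid in pairs:
            if g_idx in assignment or tid in claimed:
                continue
            assignment[g_idx] = tid
            claimed.add(tid)
        new_active: set[int] = set()
        cur_img = np.full(len(prev_img), -1, dtype=np.int32)
        for g_idx, g in enumerate(groups):
            tid = assignment.get(g_idx)
            if tid is None:
                tid = len(tracks)
                parent = (
                    max(candidates[g_idx], key=candidates[g_idx].get)
                    if candidates[g_idx]
                    else None
                )
                tracks.append(GroupTrack(tid, i, parent_id=parent))
            tr = tracks[tid]
            tr.times.append(snap.t)
            tr.pixel_history.append(g.pixels)
            tr.biomasses.append(g.biomass)
            tr.centroids.append(g.centroid)
            tr.trail_depths.append(g.trail_depth)
            cur_img[g.pixels] = tid
            new_active.add(tid)
        # tracks that lost their mask: merged into whoever took it, else ended
        for tid in active - new_active:
            lost = tracks[tid]
            ids = cur_img[lost.pixel_history[-1]]
            ids = ids[ids >= 0]
            if ids.size == 0:
                # the fading fragment may sit just beside its absorber
                m = np.zeros(shape, dtype=bool)
                m.ravel()[lost.pixel_history[-1]] = True
                m = ndimage.binary_dilation(m, structure=_STRUCTURE_8, iterations=3)
                ids = cur_img[m.ravel()]
                ids = ids[ids >= 0]
            if ids.size:
                vals, counts = np.unique(ids, return_counts=True)
                survivor = int(vals[np.argmax(counts)])
                lost.merged_into = survivor
                tracks[survivor].absorbed.append((snap.t, tid))
        prev_img = cur_img
        active = new_active
    for tid in active:
        tracks[tid].alive_at_end = True
    for tr in tracks:
        _materialize_lineage(tr, tracks)
    return tracks


def _materialize_lineage(track: GroupTrack, tracks: list[GroupTrack]) -> None:
    """Collect ancestor speed history from before the track's birth."""
    t_pre: list[np.ndarray] = []
    v_pre: list[np.ndarray] = []
    cutoff = track.times[0] if track.times else 0.0
    node = track
    seen = {track.track_id}
    while node.parent_id is not None and node.parent_id not in seen:
        node = tracks[node.parent_id]
        seen.add(node.track_id)
        t = np.asarray(node.times)
        keep = t < cutoff
        if keep.any():
            t_pre.append(t[keep])
            v_pre.append(node.speeds[keep])
            cutoff = float(t[keep][0])
    if t_pre:
        track.lineage_times = np.concatenate(t_pre[::-1])
        track.lineage_speeds = np.concatenate(v_pre[::-1])


# ---------------------------------------------------------------------------
# Per-group kinetics
# ---------------------------------------------------------------------------

#: Fraction of the track tail used for steady-state averages.
TAIL_FRACTION = 0.25

#: Moving-average window (snapshots) for the ramp-time criterion.
RAMP_WINDOW = 5

#: Speed fraction of v_ss defining the end of the ramp.
RAMP_LEVEL = 0.9

#: Minimum track length (snapshots) for kinetics / scaling fits.
MIN_TRACK_SNAPSHOTS = 10


def group_kinetics(track: GroupTrack) -> tuple[float, float, float]:
    """Biomass N, steady-state speed v_ss, and ramp time of a track.

    v_ss and N are means over the final quarter of the track; the ramp
    time is the earliest snapshot time at which the 5-snapshot moving
    average of the speed first reaches 0.9 * v_ss (windows shrink at the
    series edges, so a constant-speed track ramps at its first snapshot).
    The ramp search runs over the track's ancestor lineage as well: a
    finger that split off an already-motile front inherits the parent's
    acceleration history instead of being floored at its own birth time.
    """
    n = track.n_snapshots
    if n < MIN_TRACK_SNAPSHOTS:
        raise ConfigError(
            f"track {track.track_id} spans {n} < {MIN_TRACK_SNAPSHOTS} snapshots"
        )
    k = max(1, int(math.ceil(TAIL_FRACTION * n)))
    v = track.speeds
    v_ss = float(np.mean(v[-k:]))
    N = float(np.mean(np.asarray(track.biomasses)[-k:]))
    t_ext = np.concatenate([track.lineage_times, np.asarray(track.times)])
    v_ext = np.concatenate([track.lineage_speeds, v])
    half = RAMP_WINDOW // 2
    ramp_time = t_ext[-1]
    for i in range(len(v_ext)):
        lo, hi = max(0, i - half), min(len(v_ext), i + half + 1)
        if np.mean(v_ext[lo:hi]) >= RAMP_LEVEL * v_ss:
            ramp_time = t_ext[i]
            break
    return N, v_ss, float(ramp_time)


# ---------------------------------------------------------------------------
# Merge / trail-crossing detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergeEvent:
    """First contact of a track with another track's EPS trail."""

    time: float
    track_id: int
    source_track_id: int
    pre_speed: float
    post_speed: float
    pre_spread: float
    post_spread: float
    overlap: int = 0  # crossing area in grid elements


def _follow_merges(
    tracks: list[GroupTrack], track: GroupTrack, snap_idx: int
) -> tuple[GroupTrack, int] | None:
    """Track segment covering absolute snapshot ``snap_idx``, following the
    merge-survivor chain forward when the track has ended."""
    node = track
    while snap_idx >= node.start_index + node.n_snapshots:
        if node.merged_into is None:
            return None
        node = tracks[node.merged_into]
    local = snap_idx - node.start_index
    return (node, local) if local >= 0 else None


def detect_merges(
    result: SimulationResult,
    tracks: list[GroupTrack] | None = None,
    trail_threshold: float = TRAIL_THRESHOLD,
    window: int = RAMP_WINDOW,
) -> list[MergeEvent]:
    """Detect trail-crossing events between tracked groups.

    An event fires the first time a track's mask overlaps EPS above
    ``trail_threshold`` lying in another track's historical footprint (and
    not its own), outside the initial deposition region.  Pre/post speeds
    and spatial spreads are measured ``window`` snapshots before/after.
    """
    if tracks is None:
        tracks = track_groups(result)
    snaps = result.snapshots
    npix = int(np.prod(result.grid.shape))
    dep = (
        result.deposition_mask.ravel()
        if result.deposition_mask is not None
        else np.zeros(npix, dtype=bool)
    )
    footprints = {tr.track_id: np.zeros(npix, dtype=bool) for tr in tracks}
    count = np.zeros(npix, dtype=np.int16)
    events: list[MergeEvent] = []
    fired: set[int] = set()
    by_start: dict[int, list[GroupTrack]] = {}
    for tr in tracks:
        for local in range(tr.n_snapshots):
            by_start.setdefault(tr.start_index + local, []).append(tr)
    for i, snap in enumerate(snaps):
        here = by_start.get(i, [])
        trail = (np.asarray(snap.S).ravel() > trail_threshold) & ~dep
        for tr in here:
            local = i - tr.start_index
            if tr.track_id in fired or local < window:
                continue
            px = tr.pixel_history[local]
            own = footprints[tr.track_id]
            cand = px[trail[px] & (count[px] - own[px].astype(np.int16) >= 1)]
            if cand.size == 0:
                continue
            source, best = -1, 0
            for other in tracks:
                if other.track_id == tr.track_id:
                    continue
                ov = int(footprints[other.track_id][cand].sum())
                if ov > best:
                    source, best = other.track_id, ov
            if source < 0:
                continue
            # pre metrics from the track itself; post metrics follow the
            # merge-survivor chain (a merging finger is absorbed into the
            # combined, faster, more dispersed group)
            v = tr.speeds
            pre_lo = max(0, local - window)
            pre_speed = float(np.mean(v[pre_lo:local])) if local > pre_lo else float(v[local])
            pre_idx = max(0, local - 1)  # the formed finger just before contact
            pre_spread = tr.spread(pre_idx, snaps[tr.start_index + pre_idx].C, result.grid.dx)
            post_speeds: list[float] = []
            post_entry: tuple[GroupTrack, int, int] | None = None
            for k in range(1, window + 1):
                found = _follow_merges(tracks, tr, i + k)
                if found is None:
                    break
                node, lk = found
                post_speeds.append(float(node.speeds[lk]))
                post_entry = (node, lk, i + k)
            post_speed = float(np.mean(post_speeds)) if post_speeds else float(v[local])
            if post_entry is not None:
                node, lk, abs_idx = post_entry
                post_spread = node.spread(lk, snaps[abs_idx].C, result.grid.dx)
            else:
                post_spread = tr.spread(local, snap.C, result.grid.dx)
            events.append(
                MergeEvent(snap.t, tr.track_id, source, pre_speed, post_speed,
                           pre_spread, post_spread, overlap=int(cand.size))
            )
            fired.add(tr.track_id)
        for tr in here:
            px = tr.pixel_history[i - tr.start_index]
            fp = footprints[tr.track_id]
            fresh = px[~fp[px]]
            count[fresh] += 1
            fp[px] = True
    return events


# ---------------------------------------------------------------------------
# Run summary
# ---------------------------------------------------------------------------

def morphology_summary(result: SimulationResult, run_id: str = "run") -> pd.DataFrame:
    """Per-run morphology summary table (one row per track).

    Run-level columns (class, fresh fraction, instability, group count) are
    repeated on every row; a run without usable tracks yields a single row
    with empty track fields.
    """
    label = classify(result)
    base = {
        "run_id": run_id,
        "cbar": result.params.cbar,
        "beta": result.params.beta,
        "tau": result.params.tau if result.params.tau is not None else math.inf,
        "seed": result.seed,
        "class": label.label,
        "fresh_fraction": label.fresh_fraction,
        "instability": label.instability,
        "n_groups": label.n_groups,
    }
    rows = []
    try:
        tracks = track_groups(result)
    except ConfigError:
        tracks = []
    for tr in tracks:
        if tr.n_snapshots < MIN_TRACK_SNAPSHOTS:
            continue
        N, v_ss, ramp = group_kinetics(tr)
        rows.append(
            base
            | {
                "track_id": tr.track_id,
                "N": N,
                "v_ss": v_ss,
                "ramp_time": ramp,
                "merged_with": tr.merged_into if tr.merged_into is not None else -1,
                "alive_at_end": tr.alive_at_end,
            }
        )
    if not rows:
        rows.append(
            base
            | {"track_id": -1, "N": math.nan, "v_ss": math.nan, "ramp_time": math.nan,
               "merged_with": -1, "alive_at_end": False}
        )
    return pd.DataFrame(rows)
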