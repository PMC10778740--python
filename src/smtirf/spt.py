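"""Single-particle tracking: linking, MSD, diffusion, motion classification.

Per-frame detections are linked into trajectories by global minimum-cost
assignment (max displacement 7 px) with a gap-closing pass (max distance
7 px over at most 2 missed frames).  Each track's 2-D mean square
displacement is

    MSD(n*dt) = 1/(N-1-n) * sum_{i=1}^{N-1-n} [x((i+n)dt)-x(i*dt)]^2
                                             + [y((i+n)dt)-y(i*dt)]^2

for lags n = 1..5; the diffusion coefficient follows from an ordinary
least-squares line through the first four MSD points via MSD = 4*D*dt.
Whole tracks are classified free / confined / immobile from the
moment-scaling-spectrum slope plus a near-zero-D floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Trajectory",
    "MSDProfile",
    "DiffusionEstimate",
    "LinkingParams",
    "ClassifierParams",
    "link_trajectories",
    "compute_msd",
    "estimate_D",
    "mss_slope",
    "classify_motion",
    "diffusion_report",
]


# --------------------------------------------------------------------------
# containers and parameters
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-ordered subpixel positions of one particle, in micrometres."""

    particle_id: int
    frames: np.ndarray            # strictly increasing frame indices
    positions: np.ndarray         # (N, 2) [x, y] um
    dt: float                     # frame interval, s
    cell: str | int = 0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, int)
        self.positions = np.asarray(self.positions, float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def filled_positions(self) -> np.ndarray:
        """Positions on a gapless frame grid; gap-closed frames are linearly
        interpolated (the particle was undetected there, not absent)."""
        full = np.arange(self.frames[0], self.frames[-1] + 1)
        if len(full) == len(self.frames):
            return self.positions
        x = np.interp(full, self.frames, self.positions[:, 0])
        y = np.interp(full, self.frames, self.positions[:, 1])
        return np.column_stack([x, y])


@dataclass
class MSDProfile:
    """MSD at lags 1..n_max with the number of displacement pairs per lag."""

    lags: np.ndarray              # lag index n
    msd_values: np.ndarray        # um^2
    counts: np.ndarray
    dt: float

    @property
    def lag_times(self) -> np.ndarray:
        return self.lags * self.dt


@dataclass
class DiffusionEstimate:
    """D from the leading MSD points; negative slopes floored at 0."""

    D: float                      # um^2/s
    intercept: float              # um^2
    fit_lags: int
    floored: bool = False
    mode: str | None = None


@dataclass(frozen=True)
class LinkingParams:
    """Frame-to-frame linking and gap-closing bounds (pixels / frames)."""

    max_distance: float = 7.0
    gap_max_distance: float = 7.0
    gap_max_frames: int = 2
    min_track_length: int = 7

    def __post_init__(self):
        if min(self.max_distance, self.gap_max_distance) <= 0 or self.gap_max_frames < 0:
            raise ValueError("linking distances must be positive and gap frames >= 0")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")


@dataclass(frozen=True)
class ClassifierParams:
    """Whole-track motion classifier settings.

    A track is immobile when its fitted D falls below D_imm_max (um^2/s, the
    level reached by pure localization jitter), confined when the
    moment-scaling-spectrum slope falls below S_conf (0.5 for free Brownian
    motion, ~0 for fully confined), free otherwise.
    """

    D_imm_max: float = 0.005
    S_conf: float = 0.4
    min_length: int = 20
    mss_lags: int = 5
    mss_orders: tuple[int, ...] = (1, 2, 3, 4, 5, 6)


# --------------------------------------------------------------------------
# linking
# --------------------------------------------------------------------------

def _assign(pos_a: np.ndarray, pos_b: np.ndarray, max_dist: float):
    """Global minimum-cost one-to-one assignment within max_dist.

    Returns pairs (i, j) with ||a_i - b_j|| <= max_dist; unmatched points on
    either side stay unmatched.
    """
    if len(pos_a) == 0 or len(pos_b) == 0:
        return []
    d = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=2)
    big = max_dist * 1e6
    cost = np.where(d <= max_dist, d, big)
    rows, cols = linear_sum_assignment(cost)
    return [(i, j) for i, j in zip(rows, cols) if d[i, j] <= max_dist]


def link_trajectories(detections_by_frame: dict[int, np.ndarray],
                      params: LinkingParams = LinkingParams(),
                      pixel_size: float = 0.16,
                      frame_interval: float = 0.1) -> list[Trajectory]:
    """Link per-frame detections into trajectories.

    ``detections_by_frame`` maps frame index to an (n, 2) array of [x, y]
    positions in pixels (SpotDetection lists are also accepted).  Linking is
    a global minimum-total-displacement assignment per consecutive frame
    pair, followed by a gap-closing assignment joining track ends to track
    starts across at most ``gap_max_frames`` missing frames within
    ``gap_max_distance`` pixels.  Positions are returned in micrometres.
    """
    frames = sorted(detections_by_frame)
    pos = {}
    for f in frames:
        dets = detections_by_frame[f]
        if len(dets) and not isinstance(dets, np.ndarray):
            dets = np.array([[d.x, d.y] for d in dets])
        pos[f] = np.asarray(dets, float).reshape(-1, 2)

    # phase 1: frame-to-frame assignment
    tracks: list[dict] = []       # {'frames': [..], 'idx': [(f, i)..]}
    open_by_idx: dict[int, dict] = {}   # detection index in previous frame -> track
    prev_f = None
    for f in frames:
        cur = pos[f]
        new_open: dict[int, dict] = {}
        if prev_f is not None and f == prev_f + 1 and open_by_idx:
            prev_idx = list(open_by_idx)
            prev_pos = pos[prev_f][prev_idx]
            pairs = _assign(prev_pos, cur, params.max_distance)
            matched_b = set()
            for a, b in pairs:
                tr = open_by_idx[prev_idx[a]]
                tr["frames"].append(f)
                tr["idx"].append((f, b))
                new_open[b] = tr
                matched_b.add(b)
            for b in range(len(cur)):
                if b not in matched_b:
                    tr = {"frames": [f], "idx": [(f, b)]}
                    tracks.append(tr)
                    new_open[b] = tr
        else:
            for b in range(len(cur)):
                tr = {"frames": [f], "idx": [(f, b)]}
                tracks.append(tr)
                new_open[b] = tr
        open_by_idx = new_open
        prev_f = f

    # phase 2: gap closing on track ends vs starts
    if params.gap_max_frames > 0 and len(tracks) > 1:
        merged = True
        while merged:
            merged = False
            ends = [(t, t["frames"][-1], pos[t["idx"][-1][0]][t["idx"][-1][1]])
                    for t in tracks]
            starts = [(t, t["frames"][0], pos[t["idx"][0][0]][t["idx"][0][1]])
                      for t in tracks]
            cand = []
            for ei, (te, fe, pe) in enumerate(ends):
                for si, (ts, fs, ps) in enumerate(starts):
                    if ts is te:
                        continue
                    gap = fs - fe - 1
                    if 1 <= gap <= params.gap_max_frames:
                        dist = float(np.linalg.norm(pe - ps))
                        if dist <= params.gap_max_distance:
                            cand.append((dist, ei, si))
            used_e, used_s = set(), set()
            for dist, ei, si in sorted(cand):
                if ei in used_e or si in used_s:
                    continue
                te, ts = ends[ei][0], starts[si][0]
                if te is ts or ts not in tracks:
                    continue
                te["frames"].extend(ts["frames"])
                te["idx"].extend(ts["idx"])
                tracks.remove(ts)
                used_e.add(ei)
                used_s.add(si)
                merged = True

    out = []
    pid = 0
    for t in tracks:
        if len(t["frames"]) < params.min_track_length:
            continue
        p_px = np.array([pos[f][i] for f, i in t["idx"]])
        out.append(Trajectory(particle_id=pid, frames=np.asarray(t["frames"]),
                              positions=p_px * pixel_size, dt=frame_interval))
        pid += 1
    return out


# --------------------------------------------------------------------------
# MSD and diffusion
# --------------------------------------------------------------------------

def compute_msd(traj, n_max: int = 5, dt: float | None = None) -> MSDProfile:
    """Time-averaged 2-D MSD for lags n = 1..n_max.

    Implements MSD(n*dt) = (1/(N-1-n)) * sum_{i=1}^{N-1-n} of the squared
    displacement between positions i and i+n (0-based); the sum starts at
    i = 1, so the very first position pair is not included.  Requires an
    unbroken track of at least n_max + 2 frames.
    """
    if isinstance(traj, Trajectory):
        p = traj.filled_positions()
        dt = traj.dt
    else:
        p = np.asarray(traj, float)
        if dt is None:
            raise ValueError("dt required for a bare position array")
    N = len(p)
    if N < n_max + 2:
        raise ValueError(f"track of {N} frames is too short; "
                         f"need at least n_max + 2 = {n_max + 2}")
    lags = np.arange(1, n_max + 1)
    msd = np.empty(n_max)
    counts = np.empty(n_max, dtype=int)
    for n in lags:
        disp = p[1 + n:N] - p[1:N - n]          # i = 1 .. N-1-n
        sq = np.einsum("ij,ij->i", disp, disp)
        counts[n - 1] = N - 1 - n
        msd[n - 1] = sq.sum() / (N - 1 - n)
    return MSDProfile(lags=lags, msd_values=msd, counts=counts, dt=dt)


def estimate_D(msd: MSDProfile, fit_lags: int = 4,
               through_origin: bool = False) -> DiffusionEstimate:
    """D from an OLS line through the first ``fit_lags`` MSD points.

    MSD(dt') = 4*D*dt' + b with a free intercept b absorbing static
    localization error (set through_origin=True to force b = 0).  A negative
    slope is floored at D = 0 and flagged.
    """
    if len(msd.lags) < fit_lags:
        raise ValueError(f"need at least {fit_lags} MSD points")
    t = msd.lag_times[:fit_lags]
    y = msd.msd_values[:fit_lags]
    if np.ptp(t) == 0:
        raise ValueError("degenerate lag times")
    if through_origin:
        slope = float(np.dot(t, y) / np.dot(t, t))
        intercept = 0.0
    else:
        slope, intercept = np.polyfit(t, y, 1)
    D = slope / 4.0
    floored = D < 0
    return DiffusionEstimate(D=max(D, 0.0), intercept=float(intercept),
                             fit_lags=fit_lags, floored=bool(floored))


# --------------------------------------------------------------------------
# motion classification
# --------------------------------------------------------------------------

def mss_slope(positions: np.ndarray, dt: float, n_lags: int = 5,
              orders=(1, 2, 3, 4, 5, 6)) -> float:
    """Moment-scaling-spectrum slope of one track.

    For each displacement-moment order p, the scaling exponent nu_p is the
    log-log slope of E|r(t+n*dt) - r(t)|^p against lag time; the MSS slope
    is d(nu_p)/dp.  Free Brownian motion gives 0.5; confined or stalled
    motion pushes it toward 0.
    """
    p = np.asarray(positions, float)
    lags = np.arange(1, n_lags + 1)
    log_t = np.log(lags * dt)
    nus = []
    for q in orders:
        mom = np.empty(n_lags)
        for n in lags:
            disp = p[n:] - p[:-n]
            r = np.hypot(disp[:, 0], disp[:, 1])
            mom[n - 1] = np.mean(r ** q)
        if np.any(mom <= 0):
            return 0.0
        nus.append(np.polyfit(log_t, np.log(mom), 1)[0])
    return float(np.polyfit(np.asarray(orders, float), nus, 1)[0])


def classify_motion(traj, params: ClassifierParams = ClassifierParams(),
                    dt: float | None = None) -> str:
    """Label a whole track 'free', 'confined', 'immobile' or 'unclassified'.

    Immobile: fitted D below the localization-noise floor D_imm_max.
    Confined: MSS slope below S_conf.  Free otherwise.  Tracks shorter than
    ``min_length`` frames are 'unclassified'.
    """
    if isinstance(traj, Trajectory):
        p, dt = traj.filled_positions(), traj.dt
    else:
        p = np.asarray(traj, float)
        if dt is None:
            raise ValueError("dt required for a bare position array")
    if len(p) < params.min_length:
        return "unclassified"
    est = estimate_D(compute_msd(p, n_max=params.mss_lags, dt=dt))
    if est.D <= params.D_imm_max:
        return "immobile"
    if mss_slope(p, dt, params.mss_lags, params.mss_orders) < params.S_conf:
        return "confined"
    return "free"


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------

def diffusion_report(tracks: list[Trajectory],
                     classifier: ClassifierParams = ClassifierParams(),
                     fit_lags: int = 4) -> dict:
    """Per-mode fractions and per-mode D summaries, pooled and per cell.

    Emits both pooling conventions: D statistics over all molecules pooled,
    and the mean of per-cell means.
    """
    if not tracks:
        raise ValueError("no tracks to report")
    rows = []
    for tr in tracks:
        mode = classify_motion(tr, classifier)
        try:
            est = estimate_D(compute_msd(tr, n_max=classifier.mss_lags), fit_lags)
            D = est.D
        except ValueError:
            D = np.nan
        rows.append({"particle": tr.particle_id, "cell": tr.cell,
                     "n_frames": tr.n_frames, "mode": mode, "D": D})
    table = pd.DataFrame(rows)
    classified = table[table["mode"] != "unclassified"]
    report = {"n_tracks": int(len(table)),
              "n_unclassified": int((table["mode"] == "unclassified").sum()),
              "fractions": {}, "D_pooled": {}, "D_per_cell_mean": {}}
    n_cls = max(len(classified), 1)
    for mode in ("free", "confined", "immobile"):
        sub = classified[classified["mode"] == mode]
        report["fractions"][mode] = float(len(sub) / n_cls)
        if len(sub):
            report["D_pooled"][mode] = {"mean": float(sub["D"].mean()),
                                        "sd": float(sub["D"].std(ddof=1)) if len(sub) > 1 else 0.0,
                                        "n": int(len(sub))}
            cell_means = sub.groupby("cell")["D"].mean()
            report["D_per_cell_mean"][mode] = {"mean": float(cell_means.mean()),
                                               "sd": float(cell_means.std(ddof=1)) if len(cell_means) > 1 else 0.0,
                                               "n_cells": int(len(cell_means))}
    report["_table"] = table
    return report


def tracks_to_table(tracks: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        rows.append(pd.DataFrame({"track": tr.particle_id, "frame": tr.frames,
                                  "x_um": tr.positions[:, 0],
                                  "y_um": tr.positions[:, 1]}))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["track", "frame", "x_um", "y_um"])
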