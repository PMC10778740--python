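"""Synthetic TIRF movie and trace generation with ground truth.

Emulates the acquisition regime of single-molecule TIRF imaging of
fluorescent-protein-tagged membrane receptors: 160 nm pixels, diffraction-
limited spots (~5x5 px Gaussian PSF), 400-frame fixed-cell movies at
100 ms/frame for photobleaching-step stoichiometry, and 300-frame live-cell
movies at 10 Hz for single-particle tracking.  Every generated movie is
paired with a ground-truth record (true oligomer sizes, bleach frames,
positions, motion modes, diffusion coefficients) so each downstream
analysis stage can be validated by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "AcquisitionGeometry",
    "StoichiometryModel",
    "MotionModel",
    "NoiseModel",
    "ParticleTruth",
    "GroundTruth",
    "Movie",
    "sample_bleach_times",
    "sample_trajectory",
    "sample_trajectories",
    "render_movie",
    "simulate_photobleaching_experiment",
    "simulate_tracking_experiment",
    "make_step_trace",
    "make_bleach_trace",
    "BLEACH_GEOMETRY",
    "TRACKING_GEOMETRY",
]

MODES = ("free", "confined", "immobile")


def _as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence or a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# parameter blocks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionGeometry:
    """Camera/optics geometry of one acquisition.

    pixel_size is the object-plane pixel pitch in micrometres, psf_sigma the
    Gaussian PSF width in pixels (1.0 px so a spot spans ~5x5 px at 160 nm
    pixels).
    """

    pixel_size: float = 0.16          # um / pixel
    frame_interval: float = 0.1       # s
    n_frames: int = 400
    image_shape: tuple[int, int] = (256, 256)   # (rows, cols)
    psf_sigma: float = 1.0            # pixels

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")

    @property
    def field_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in micrometres."""
        rows, cols = self.image_shape
        return cols * self.pixel_size, rows * self.pixel_size

    @property
    def area_um2(self) -> float:
        w, h = self.field_um
        return w * h

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


#: 400-frame fixed-cell photobleaching acquisition, 100 ms/frame, 160 nm px.
BLEACH_GEOMETRY = AcquisitionGeometry(n_frames=400, frame_interval=0.1)

#: 300-frame live-cell tracking acquisition at 10 Hz.
TRACKING_GEOMETRY = AcquisitionGeometry(n_frames=300, frame_interval=0.1)


@dataclass(frozen=True)
class StoichiometryModel:
    """Oligomer-size mixture and per-fluorophore photophysics.

    ``fractions[k-1]`` is the probability that a spot is a k-mer (k = 1..K,
    K = 4 by default).  Each fluorophore bleaches independently with a
    memoryless per-frame hazard ``bleach_rate``; no blinking by default.
    """

    fractions: tuple[float, ...] = (0.4016, 0.2891, 0.2042, 0.1051)
    unit_intensity: float = 200.0     # peak amplitude per fluorophore (counts)
    bleach_rate: float = 0.015        # per-frame hazard

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if f.ndim != 1 or f.size < 1:
            raise ValueError("fractions must be a 1-D probability vector")
        if np.any(f < 0):
            raise ValueError("fractions must be >= 0")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 within 1e-9")
        if not (0.0 < self.bleach_rate < 1.0):
            raise ValueError("bleach_rate must be in (0, 1)")

    @property
    def max_size(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class MotionModel:
    """Lateral motion of one particle class.

    mode 'free': 2-D Brownian motion with diffusion coefficient D (um^2/s);
    'confined': Brownian motion reflected at a circular boundary of radius
    confinement_radius around the start; 'immobile': stationary up to i.i.d.
    localization jitter.  localization_noise_sd (um) is added as i.i.d.
    positional noise in every mode.
    """

    mode: str = "free"
    D: float = 0.1                    # um^2/s
    confinement_radius: float | None = None   # um
    localization_noise_sd: float = 0.0        # um

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown motion mode {self.mode!r}; expected one of {MODES}")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.mode == "confined" and (self.confinement_radius is None or self.confinement_radius <= 0):
            raise ValueError("confined mode requires confinement_radius > 0")
        if self.localization_noise_sd < 0:
            raise ValueError("localization_noise_sd must be >= 0")

    @property
    def effective_D(self) -> float:
        return 0.0 if self.mode == "immobile" else self.D


@dataclass(frozen=True)
class NoiseModel:
    """EMCCD-style camera noise.

    Shot noise is Poisson on signal+background; EM multiplication is
    approximated by inflating the Poisson variance by ``em_gain_factor``
    (2 by default, the standard EMCCD excess-noise approximation).  Gaussian
    read noise is added on top.
    """

    background_level: float = 200.0   # counts / pixel
    read_noise_sd: float = 0.0        # counts
    shot_noise: bool = True
    em_gain_factor: float = 2.0

    def __post_init__(self):
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.em_gain_factor < 1:
            raise ValueError("em_gain_factor must be >= 1")

    @classmethod
    def off(cls, background_level: float = 0.0) -> "NoiseModel":
        """Noise-free rendering (for photometric fixtures)."""
        return cls(background_level=background_level, read_noise_sd=0.0,
                   shot_noise=False, em_gain_factor=1.0)

    @classmethod
    def for_snr(cls, snr: float, amplitude: float, em_gain_factor: float = 2.0) -> "NoiseModel":
        """Background level giving a per-pixel background noise sd of
        amplitude/snr, so a single fluorophore of that peak amplitude images
        at the requested signal-to-noise ratio."""
        if snr <= 0:
            raise ValueError("snr must be > 0")
        sd = amplitude / snr
        return cls(background_level=sd * sd / em_gain_factor,
                   read_noise_sd=0.0, shot_noise=True,
                   em_gain_factor=em_gain_factor)

    @property
    def background_noise_sd(self) -> float:
        var = self.read_noise_sd ** 2
        if self.shot_noise:
            var += self.em_gain_factor * self.background_level
        return math.sqrt(var)

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = image + self.background_level
        if self.shot_noise:
            g = self.em_gain_factor
            # Poisson(mean/g)*g has the right mean and g-fold inflated variance
            out = rng.poisson(np.maximum(out, 0.0) / g).astype(np.float64) * g
        if self.read_noise_sd > 0:
            out = out + rng.normal(0.0, self.read_noise_sd, size=out.shape)
        return np.maximum(out, 0.0)


# --------------------------------------------------------------------------
# ground truth containers
# --------------------------------------------------------------------------

@dataclass
class ParticleTruth:
    """Ground-truth record of one simulated particle."""

    particle_id: int
    oligomer_size: int
    bleach_frames: np.ndarray         # one entry per fluorophore, frame index
    positions: np.ndarray             # (n_frames, 2) [x, y] in um
    mode: str
    D: float

    @property
    def n_visible_steps(self) -> int:
        """Number of distinct downward intensity steps inside the movie.

        Fluorophores bleaching in the same frame merge into one step;
        a bleach frame >= n_frames never drops within the movie.
        """
        n_frames = self.positions.shape[0]
        t = np.asarray(self.bleach_frames)
        return int(np.unique(t[t < n_frames]).size)


@dataclass
class GroundTruth:
    """All ground-truth particles of one simulated experiment."""

    particles: list[ParticleTruth]
    geometry: AcquisitionGeometry

    def __len__(self):
        return len(self.particles)

    def sizes(self) -> np.ndarray:
        return np.array([p.oligomer_size for p in self.particles], dtype=int)

    def modes(self) -> list[str]:
        return [p.mode for p in self.particles]

    def to_frame_table(self) -> pd.DataFrame:
        """One row per particle per frame: positions and static truth."""
        rows = []
        for p in self.particles:
            n = p.positions.shape[0]
            rows.append(pd.DataFrame({
                "particle": p.particle_id,
                "frame": np.arange(n),
                "x_um": p.positions[:, 0],
                "y_um": p.positions[:, 1],
                "oligomer_size": p.oligomer_size,
                "mode": p.mode,
                "true_D": p.D,
            }))
        if not rows:
            return pd.DataFrame(columns=["particle", "frame", "x_um", "y_um",
                                         "oligomer_size", "mode", "true_D"])
        return pd.concat(rows, ignore_index=True)

    def to_particle_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "particle": [p.particle_id for p in self.particles],
            "oligomer_size": self.sizes(),
            "n_visible_steps": [p.n_visible_steps for p in self.particles],
            "mode": self.modes(),
            "true_D": [p.D for p in self.particles],
            "x0_um": [p.positions[0, 0] for p in self.particles],
            "y0_um": [p.positions[0, 1] for p in self.particles],
        })


@dataclass
class Movie:
    """A multi-frame single-channel movie with physical calibration."""

    data: np.ndarray                  # (n_frames, rows, cols), float
    pixel_size: float                 # um / px
    frame_interval: float             # s

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def write_tiff(self, path) -> None:
        """Write as 16-bit multi-page TIFF with calibration in metadata."""
        arr = np.clip(np.rint(self.data), 0, 65535).astype(np.uint16)
        tifffile.imwrite(
            path, arr,
            metadata={"pixel_size_um": self.pixel_size,
                      "frame_interval_s": self.frame_interval},
        )

    @classmethod
    def read_tiff(cls, path, pixel_size: float | None = None,
                  frame_interval: float | None = None) -> "Movie":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray().astype(np.float64)
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if data.ndim == 2:
            data = data[None]
        return cls(
            data=data,
            pixel_size=pixel_size if pixel_size is not None else float(meta.get("pixel_size_um", 0.16)),
            frame_interval=frame_interval if frame_interval is not None else float(meta.get("frame_interval_s", 0.1)),
        )


# --------------------------------------------------------------------------
# sampling primitives
# --------------------------------------------------------------------------

def sample_bleach_times(k: int, bleach_rate: float, n_frames: int, seed) -> np.ndarray:
    """Frame indices at which each of k fluorophores goes dark.

    Each time is an independent geometric variate with per-frame hazard
    ``bleach_rate`` (support 1, 2, ...), truncated at ``n_frames``; a value of
    ``n_frames`` means the fluorophore survives the whole movie.  A
    fluorophore with bleach time T is emitting in frames f < T.  Returned
    sorted ascending.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0.0 < bleach_rate < 1.0):
        raise ValueError("bleach_rate must be in (0, 1)")
    rng = _as_rng(seed)
    t = rng.geometric(bleach_rate, size=k)
    return np.sort(np.minimum(t, n_frames))


def sample_trajectories(motion: MotionModel, geometry: AcquisitionGeometry,
                        starts: np.ndarray, seed) -> np.ndarray:
    """Vectorised trajectory sampling: (n_particles, n_frames, 2) in um."""
    rng = _as_rng(seed)
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    n, _ = starts.shape
    T = geometry.n_frames
    dt = geometry.frame_interval

    if motion.mode == "immobile":
        path = np.repeat(starts[:, None, :], T, axis=1)
    elif motion.mode == "free":
        steps = rng.normal(0.0, math.sqrt(2.0 * motion.D * dt), size=(n, T - 1, 2))
        path = np.concatenate([np.zeros((n, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
        path += starts[:, None, :]
    elif motion.mode == "confined":
        R = motion.confinement_radius
        # subdivide each frame so the sub-step sd stays << R; radial
        # reflection is only accurate for small steps
        n_sub = max(1, int(math.ceil(50.0 * motion.D * dt / (R * R))))
        sd = math.sqrt(2.0 * motion.D * dt / n_sub)
        rel = np.zeros((n, 2))
        path = np.empty((n, T, 2))
        path[:, 0] = starts
        for f in range(1, T):
            for _ in range(n_sub):
                rel = rel + rng.normal(0.0, sd, size=(n, 2))
                # radial reflection at the circular boundary
                r = np.hypot(rel[:, 0], rel[:, 1])
                while np.any(r > R):
                    over = r > R
                    rel[over] *= (np.abs(2.0 * R - r[over]) / r[over])[:, None]
                    r = np.hypot(rel[:, 0], rel[:, 1])
            path[:, f] = starts + rel
    else:  # pragma: no cover - guarded by MotionModel
        raise ValueError(f"unknown motion mode {motion.mode!r}")

    if motion.localization_noise_sd > 0:
        path = path + rng.normal(0.0, motion.localization_noise_sd, size=path.shape)
    return path


def sample_trajectory(motion: MotionModel, geometry: AcquisitionGeometry,
                      start, seed) -> np.ndarray:
    """One trajectory, (n_frames, 2) [x, y] in um."""
    return sample_trajectories(motion, geometry, np.asarray(start, float)[None, :], seed)[0]


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _stamp_gaussian(image: np.ndarray, x_px: float, y_px: float,
                    amplitude: float, sigma: float) -> None:
    """Add an isotropic 2-D Gaussian evaluated at pixel centres, in place."""
    h, w = image.shape
    half = int(math.ceil(4.0 * sigma))
    c0 = max(int(math.floor(x_px)) - half, 0)
    c1 = min(int(math.floor(x_px)) + half + 1, w)
    r0 = max(int(math.floor(y_px)) - half, 0)
    r1 = min(int(math.floor(y_px)) + half + 1, h)
    if c0 >= c1 or r0 >= r1:
        return
    cc = np.arange(c0, c1) - x_px
    rr = np.arange(r0, r1) - y_px
    g = np.exp(-(rr[:, None] ** 2 + cc[None, :] ** 2) / (2.0 * sigma ** 2))
    image[r0:r1, c0:c1] += amplitude * g


def um_to_px(pos_um: np.ndarray, pixel_size: float) -> np.ndarray:
    """Continuous um coordinates -> pixel-index coordinates.

    A spot centred on pixel (i, j) has continuous coordinate
    ((j+0.5)*pixel, (i+0.5)*pixel), so x_px = x_um/pixel - 0.5.
    """
    return np.asarray(pos_um, float) / pixel_size - 0.5


def px_to_um(pos_px: np.ndarray, pixel_size: float) -> np.ndarray:
    return (np.asarray(pos_px, float) + 0.5) * pixel_size


def render_movie(particles: list[ParticleTruth], geometry: AcquisitionGeometry,
                 noise: NoiseModel, seed, unit_intensity: float = 200.0) -> tuple[Movie, GroundTruth]:
    """Render particles into a noisy movie.

    Each unbleached fluorophore contributes a 2-D Gaussian of width
    ``psf_sigma`` and peak ``unit_intensity`` at the particle's position;
    background and camera noise are applied per the NoiseModel.
    """
    rng = _as_rng(seed)
    T = geometry.n_frames
    h, w = geometry.image_shape
    sigma = geometry.psf_sigma
    clean = np.zeros((T, h, w))

    for p in particles:
        pos_px = um_to_px(p.positions, geometry.pixel_size)
        bleach = np.asarray(p.bleach_frames)
        n_on = (bleach[None, :] > np.arange(T)[:, None]).sum(axis=1)
        static = bool(np.all(pos_px == pos_px[0]))
        if static:
            stamp = np.zeros((h, w))
            _stamp_gaussian(stamp, pos_px[0, 0], pos_px[0, 1], unit_intensity, sigma)
            changes = np.flatnonzero(np.diff(n_on, prepend=-1))
            for f0, f1 in zip(changes, list(changes[1:]) + [T]):
                if n_on[f0] > 0:
                    clean[f0:f1] += n_on[f0] * stamp
        else:
            for f in range(T):
                if n_on[f] > 0:
                    _stamp_gaussian(clean[f], pos_px[f, 0], pos_px[f, 1],
                                    n_on[f] * unit_intensity, sigma)

    for f in range(T):
        clean[f] = noise.apply(clean[f], rng)

    movie = Movie(clean, geometry.pixel_size, geometry.frame_interval)
    return movie, GroundTruth(list(particles), geometry)


def _scatter_positions(n: int, geometry: AcquisitionGeometry, rng,
                       margin_um: float = 0.8,
                       min_separation_um: float = 0.64) -> np.ndarray:
    """Scatter spots over the field with a hard-core minimum separation.

    Single-molecule fields are selected for well-dispersed spots; the
    default 0.64 um (4 px at 160 nm) core matches the proximity scale below
    which two emitters are unresolvable anyway.  Set min_separation_um=0 for
    pure Poisson placement.
    """
    w, h = geometry.field_um
    if min_separation_um <= 0:
        x = rng.uniform(margin_um, w - margin_um, size=n)
        y = rng.uniform(margin_um, h - margin_um, size=n)
        return np.column_stack([x, y])
    pts = np.empty((n, 2))
    d2 = min_separation_um ** 2
    k = 0
    attempts = 0
    while k < n:
        if attempts > 200 * max(n, 1):
            raise ValueError("cannot place spots at the requested density "
                             "with the minimum separation")
        cand = np.array([rng.uniform(margin_um, w - margin_um),
                         rng.uniform(margin_um, h - margin_um)])
        attempts += 1
        if k == 0 or np.min(np.sum((pts[:k] - cand) ** 2, axis=1)) >= d2:
            pts[k] = cand
            k += 1
    return pts


def _n_particles_for_density(density: float, geometry: AcquisitionGeometry,
                             rng, poisson: bool = True) -> int:
    # ~5x5 px footprint at 160 nm/px is ~0.64 um^2; above ~0.6/um^2 spots
    # can no longer be placed without ubiquitous overlap
    if density > 0.6:
        raise ValueError("requested spot density is not physically packable")
    mean = density * geometry.area_um2
    return int(rng.poisson(mean)) if poisson else int(round(mean))


def simulate_photobleaching_experiment(stoich: StoichiometryModel,
                                       geometry: AcquisitionGeometry = BLEACH_GEOMETRY,
                                       noise: NoiseModel | None = None,
                                       seed=0,
                                       density: float = 0.2,
                                       n_particles: int | None = None) -> tuple[Movie, GroundTruth]:
    """Fixed-cell photobleaching movie: immobile oligomers bleaching stepwise.

    Spot density defaults to 0.2/um^2, below the 0.25/um^2 ceiling used for
    selecting well-dispersed single-molecule fields.
    """
    rng = _as_rng(seed)
    if noise is None:
        noise = NoiseModel()
    if n_particles is None:
        n_particles = _n_particles_for_density(density, geometry, rng)
    sizes = rng.choice(np.arange(1, stoich.max_size + 1), size=n_particles,
                       p=np.asarray(stoich.fractions))
    starts = _scatter_positions(n_particles, geometry, rng)
    particles = []
    for i in range(n_particles):
        bleach = sample_bleach_times(int(sizes[i]), stoich.bleach_rate,
                                     geometry.n_frames, rng)
        positions = np.repeat(starts[i][None, :], geometry.n_frames, axis=0)
        particles.append(ParticleTruth(i, int(sizes[i]), bleach, positions,
                                       "immobile", 0.0))
    return render_movie(particles, geometry, noise, rng,
                        unit_intensity=stoich.unit_intensity)


def simulate_tracking_experiment(mode_fractions,
                                 D_by_mode,
                                 geometry: AcquisitionGeometry = TRACKING_GEOMETRY,
                                 noise: NoiseModel | None = None,
                                 seed=0,
                                 density: float = 0.05,
                                 n_particles: int | None = None,
                                 confinement_radius: float = 0.2,
                                 localization_noise_sd: float = 0.02,
                                 unit_intensity: float = 200.0,
                                 bleach_rate: float | None = None) -> tuple[Movie, GroundTruth]:
    """Live-cell tracking movie: moving monomeric spots, 300 frames at 10 Hz.

    mode_fractions is a probability vector over (free, confined, immobile);
    D_by_mode gives the matching diffusion coefficients in um^2/s (ignored
    for immobile).  Photobleaching during tracking is off by default.
    """
    rng = _as_rng(seed)
    frac = np.asarray(mode_fractions, float)
    if frac.ndim != 1 or frac.size != 3 or np.any(frac < 0) or abs(frac.sum() - 1) > 1e-9:
        raise ValueError("mode_fractions must be a probability 3-vector (free, confined, immobile)")
    D_by_mode = np.asarray(D_by_mode, float)
    if noise is None:
        noise = NoiseModel()
    if n_particles is None:
        n_particles = _n_particles_for_density(density, geometry, rng)
    which = rng.choice(3, size=n_particles, p=frac)
    starts = _scatter_positions(n_particles, geometry, rng)
    particles = []
    for i in range(n_particles):
        mode = MODES[which[i]]
        D = 0.0 if mode == "immobile" else float(D_by_mode[which[i]])
        motion = MotionModel(mode=mode, D=D,
                             confinement_radius=confinement_radius if mode == "confined" else None,
                             localization_noise_sd=localization_noise_sd)
        positions = sample_trajectory(motion, geometry, starts[i], rng)
        if bleach_rate is not None:
            bleach = sample_bleach_times(1, bleach_rate, geometry.n_frames, rng)
        else:
            bleach = np.array([geometry.n_frames])
        particles.append(ParticleTruth(i, 1, bleach, positions, mode, D))
    return render_movie(particles, geometry, noise, rng,
                        unit_intensity=unit_intensity)


# --------------------------------------------------------------------------
# bare traces (no rendering) for counter calibration and recovery studies
# --------------------------------------------------------------------------

def make_step_trace(n_steps: int, n_frames: int, step_size: float,
                    noise_sd: float, seed, min_separation: int = 10,
                    pedestal: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """A piecewise-constant downward staircase with Gaussian noise.

    Step frames are drawn uniformly with at least ``min_separation`` frames
    between consecutive steps and from the trace ends.  Returns
    (trace, step_frames).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    rng = _as_rng(seed)
    if n_steps > 0:
        span = n_frames - (n_steps + 1) * min_separation
        if span < 0:
            raise ValueError("trace too short for requested steps/separation")
        offsets = np.sort(rng.uniform(0, span, size=n_steps))
        frames = (offsets + min_separation * (1 + np.arange(n_steps))).astype(int)
    else:
        frames = np.empty(0, dtype=int)
    level = pedestal + step_size * n_steps
    trace = np.full(n_frames, level, dtype=float)
    for j, f in enumerate(frames):
        trace[f:] = pedestal + step_size * (n_steps - j - 1)
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=n_frames)
    return trace, frames


def make_bleach_trace(oligomer_size: int, stoich: StoichiometryModel,
                      n_frames: int, noise_sd: float, seed) -> tuple[np.ndarray, np.ndarray]:
    """Intensity trace of one k-mer under geometric bleaching.

    Intensity at frame f is unit_intensity times the number of fluorophores
    with bleach time > f, plus Gaussian noise.  Returns (trace, bleach_frames).
    """
    rng = _as_rng(seed)
    bleach = sample_bleach_times(oligomer_size, stoich.bleach_rate, n_frames, rng)
    n_on = (bleach[None, :] > np.arange(n_frames)[:, None]).sum(axis=1)
    trace = stoich.unit_intensity * n_on.astype(float)
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=n_frames)
    return trace, bleach


# --------------------------------------------------------------------------
# run artefacts
# --------------------------------------------------------------------------

def write_experiment(out_dir, movie: Movie, truth: GroundTruth,
                     params: dict, seed: int) -> None:
    """Write movie TIFF, ground-truth table and a JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    movie.write_tiff(out / "movie.tif")
    truth.to_frame_table().to_csv(out / "ground_truth.csv", index=False)
    manifest = {"seed": int(seed), "parameters": _jsonable(params)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
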