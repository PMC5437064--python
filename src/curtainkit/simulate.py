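"""Synthetic single-molecule data generators.

Produces the observables the analysis modules consume: binding-position
samples from site/background mixtures, 1D Brownian trajectories on a
tethered DNA molecule (with reflecting tether ends and optional
reflecting/trapping site encounters), right-censored exponential dwell
times, rendered TIFF frame stacks with a pixel-integrated Gaussian PSF
and Poisson/read noise, and deterministic encounter-behavior fixtures
with exact category counts.

All generators take an integer seed (or a ``numpy.random.Generator``) and
are bit-reproducible for a given preset + seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .presets import ExperimentPreset

__all__ = [
    "Trajectory",
    "DwellSample",
    "simulate_binding_positions",
    "simulate_trajectory",
    "simulate_dwell_times",
    "render_frames",
    "make_behavior_fixtures",
    "trajectories_to_frame",
    "trajectories_from_frame",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered positions of one particle at a fixed frame interval.

    ``y_um`` is the coordinate along the DNA axis (um from the barrier
    anchor).  Image-space pixel coordinates are optional and filled in by
    the renderer/tracker.  ``censored_start``/``censored_end`` flag
    records that touch the first/last movie frame.
    """

    particle_id: int
    dt_s: float
    y_um: np.ndarray
    x_px: np.ndarray | None = None
    y_px: np.ndarray | None = None
    frames: np.ndarray | None = None
    censored_start: bool = False
    censored_end: bool = False

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("frame interval must be positive")
        object.__setattr__(self, "y_um", np.asarray(self.y_um, dtype=float))

    @property
    def n_frames(self) -> int:
        return len(self.y_um)

    def y_kb(self, um_per_kb: float) -> np.ndarray:
        return self.y_um / um_per_kb


@dataclass(frozen=True)
class DwellSample:
    """Dwell times with right-censoring flags (True = censored at t_obs)."""

    times_s: np.ndarray
    censored: np.ndarray
    t_obs_s: float = math.inf

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_s", np.asarray(self.times_s, dtype=float))
        object.__setattr__(self, "censored", np.asarray(self.censored, dtype=bool))
        if self.times_s.shape != self.censored.shape:
            raise ValueError("times and censoring flags must align")

    @property
    def n_events(self) -> int:
        return int((~self.censored).sum())


def simulate_binding_positions(
    preset: ExperimentPreset, n: int, seed
) -> np.ndarray:
    """Draw ``n`` i.i.d. binding positions (kb from cosL) from the preset
    mixture.

    Site components are Gaussians (optionally broadened by uniform
    tether-anchor jitter); the background is uniform over the substrate.
    Draws falling outside ``[0, genome_kb]`` are redrawn.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    weights = [s.weight for s in preset.sites] + [preset.background_weight]
    total = float(sum(weights))
    if total <= 0:
        raise ValueError(f"preset {preset.name!r}: all mixture weights are zero")
    probs = np.asarray(weights) / total
    rng = _rng(seed)
    genome_kb = preset.geometry.genome_kb
    comp = rng.choice(len(probs), size=n, p=probs)
    out = np.empty(n)
    for k in range(len(probs)):
        idx = np.flatnonzero(comp == k)
        if idx.size == 0:
            continue
        if k == len(preset.sites):  # uniform background
            out[idx] = rng.uniform(0.0, genome_kb, idx.size)
            continue
        site = preset.sites[k]
        draws = site.center_kb + rng.normal(0.0, site.sd_kb or 0.0, idx.size)
        if site.jitter_kb > 0:
            draws += rng.uniform(-site.jitter_kb / 2, site.jitter_kb / 2, idx.size)
        bad = (draws < 0) | (draws > genome_kb)
        while bad.any():
            redraw = site.center_kb + rng.normal(0.0, site.sd_kb or 0.0, int(bad.sum()))
            if site.jitter_kb > 0:
                redraw += rng.uniform(-site.jitter_kb / 2, site.jitter_kb / 2, redraw.size)
            draws[bad] = redraw
            bad = (draws < 0) | (draws > genome_kb)
        out[idx] = draws
    return out


def _reflect(z: np.ndarray, length: float) -> np.ndarray:
    """Fold an unbounded coordinate into [0, length] (method of images)."""
    return length - np.abs(np.mod(z, 2.0 * length) - length)


def simulate_trajectory(
    preset: ExperimentPreset,
    d_um2_s: float,
    n_frames: int,
    start_um: float,
    seed,
    particle_id: int = 0,
    localization_noise: bool = True,
) -> Trajectory:
    """Discrete 1D Brownian walk along a tethered DNA molecule.

    Per-step displacements are Normal(0, 2 D dt); tether ends reflect.
    A site interaction from the preset is applied at
    ``interaction_site_kb``: ``reflecting`` rejects (mirrors) steps across
    the site coordinate, ``trapping`` pins the particle at the site once
    reached.  Gaussian localization noise (``optics.loc_sigma_um``) is
    added on top of the physical positions.
    """
    if d_um2_s < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    geom = preset.geometry
    if not 0 <= start_um <= geom.tether_um:
        raise ValueError("start position outside the tether")
    rng = _rng(seed)
    dt = preset.optics.frame_interval_s
    step_sd = math.sqrt(2.0 * d_um2_s * dt)
    steps = rng.normal(0.0, step_sd, n_frames - 1) if n_frames > 1 else np.empty(0)

    interaction = preset.site_interaction
    site_um = None
    if preset.interaction_site_kb is not None and interaction != "none":
        site_um = preset.interaction_site_kb * geom.um_per_kb

    if site_um is None:
        y = _reflect(start_um + np.concatenate(([0.0], np.cumsum(steps))), geom.tether_um)
    else:
        y = np.empty(n_frames)
        y[0] = start_um
        trapped = interaction == "trapping" and abs(start_um - site_um) < 1e-9
        for i, s in enumerate(steps):
            cur = y[i]
            if trapped:
                y[i + 1] = site_um
                continue
            nxt = cur + s
            # reflect at tether ends
            nxt = float(_reflect(np.asarray(nxt), geom.tether_um))
            if interaction == "reflecting":
                if (cur - site_um) * (nxt - site_um) < 0:
                    nxt = 2.0 * site_um - nxt  # mirror the crossing step
            elif interaction == "trapping":
                if (cur - site_um) * (nxt - site_um) <= 0:
                    nxt = site_um
                    trapped = True
            y[i + 1] = nxt

    if localization_noise and preset.optics.loc_sigma_um > 0:
        y = y + rng.normal(0.0, preset.optics.loc_sigma_um, n_frames)
        y = np.clip(y, 0.0, geom.tether_um)
    return Trajectory(particle_id=particle_id, dt_s=dt, y_um=y)


def simulate_dwell_times(
    t_half_s: float, n: int, t_obs_s: float, seed
) -> DwellSample:
    """Exponential dwell times with right-censoring at the observation
    window.

    Draws are Exponential with mean ``t_half / ln 2``; values exceeding
    ``t_obs`` are returned as ``t_obs`` with the censoring flag set.
    """
    if t_half_s <= 0:
        raise ValueError("half-life must be positive")
    if not t_obs_s > 0:
        raise ValueError("observation window must be positive (may be inf)")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    mean = t_half_s / math.log(2.0)
    times = rng.exponential(mean, n)
    censored = times > t_obs_s
    times = np.where(censored, t_obs_s, times)
    return DwellSample(times, censored, t_obs_s)


def _psf_pixel_integral(xc, yc, sigma, nx, ny):
    """Photon fraction of a 2D Gaussian PSF integrated over each pixel.

    Pixel centers sit at integer coordinates: pixel (i, j) covers
    [j - 0.5, j + 0.5) x [i - 0.5, i + 0.5); the emitter sits at
    (xc, yc) in the same units.
    """
    xs = np.arange(nx + 1) - 0.5
    ys = np.arange(ny + 1) - 0.5
    s = sigma * math.sqrt(2.0)
    fx = 0.5 * (erf((xs[1:] - xc) / s) - erf((xs[:-1] - xc) / s))
    fy = 0.5 * (erf((ys[1:] - yc) / s) - erf((ys[:-1] - yc) / s))
    return np.outer(fy, fx)


def render_frames(
    trajectories: list[Trajectory],
    preset: ExperimentPreset,
    seed,
    shape: tuple[int, int] = (32, 128),
    rows_px: list[float] | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Render trajectories into a 16-bit grayscale frame stack.

    The DNA axis maps to the image x axis (``x_px = y_um / pixel_um``);
    each particle occupies a fixed transverse row.  Each emitter is a
    pixel-integrated symmetric Gaussian PSF scaled to the preset photon
    rate; with ``noise=True`` the expected image (signal + constant
    background) is Poisson-sampled and Gaussian read noise is added.
    Returns an array of shape ``(n_frames, ny, nx)``, dtype uint16.
    """
    if preset.optics.photons_per_frame <= 0:
        raise ValueError("photon rate must be positive")
    ny, nx = shape
    n_frames = max((t.n_frames for t in trajectories), default=0)
    if n_frames == 0:
        raise ValueError("no frames to render")
    if rows_px is None:
        rows_px = [
            (i + 1) * ny / (len(trajectories) + 1) for i in range(len(trajectories))
        ]
    rng = _rng(seed)
    opt = preset.optics
    stack = np.empty((n_frames, ny, nx), dtype=np.uint16)
    for f in range(n_frames):
        expected = np.full((ny, nx), float(opt.background) if noise else 0.0)
        for traj, row in zip(trajectories, rows_px):
            if f >= traj.n_frames:
                continue
            xc = traj.y_um[f] / opt.pixel_um
            if not (-3 * opt.psf_sigma_px <= xc <= nx + 3 * opt.psf_sigma_px):
                raise ValueError(
                    f"particle {traj.particle_id} at {xc:.1f} px is outside "
                    f"the {nx}-px field of view"
                )
            expected += opt.photons_per_frame * _psf_pixel_integral(
                xc, row, opt.psf_sigma_px, nx, ny
            )
        if noise:
            frame = rng.poisson(expected).astype(float)
            if opt.read_noise > 0:
                frame += rng.normal(0.0, opt.read_noise, frame.shape)
        else:
            frame = expected
        stack[f] = np.clip(np.round(frame), 0, 65535).astype(np.uint16)
    return stack


def _triangle(n: int, lo: float, hi: float) -> np.ndarray:
    """Deterministic approach-and-return path lo -> hi -> lo over n frames."""
    half = n // 2
    up = np.linspace(lo, hi, half)
    down = np.linspace(hi, lo, n - half)
    return np.concatenate([up, down])


def make_behavior_fixtures(
    preset: ExperimentPreset, n_frames: int = 200
) -> list[tuple[Trajectory, str]]:
    """Deterministic trajectories (kb units) realizing the preset's exact
    encounter-behavior category counts.

    Paths are parametric (linear crossings, triangular approach-reverse,
    small-ripple stationary records) rather than stochastic so that
    classification percentages are exact.  Positions are stored in the
    ``y_um`` slot in kb units (the classifier consumes kb directly).
    Returns ``(trajectory, true_label)`` pairs.
    """
    site = preset.interaction_site_kb
    if site is None:
        raise ValueError("behavior fixtures require an interaction site")
    dt = preset.optics.frame_interval_s
    out: list[tuple[Trajectory, str]] = []
    pid = 0
    t = np.arange(n_frames)
    for label, count in sorted(preset.behavior_counts.items()):
        for i in range(count):
            # small deterministic per-molecule variation
            amp = 4.0 + 0.05 * i
            ripple = 0.05 * np.sin(2 * math.pi * t / (20 + i % 7))
            if label == "bypass":
                side = 1 if i % 2 == 0 else -1
                y = site - side * amp + side * np.linspace(0, 2 * amp, n_frames)
            elif label == "blocked":
                side = 1 if i % 2 == 0 else -1
                y = site - side * _triangle(n_frames, amp, 0.5 - 0.01 * (i % 10))
            elif label == "captured":
                y = np.full(n_frames, site + 0.1 * (i % 3 - 1))
            elif label == "no_encounter":
                y = np.full(n_frames, site - 10.0 - 0.1 * i)
            else:
                raise ValueError(f"unknown behavior label {label!r}")
            y = y + ripple
            out.append(
                (Trajectory(particle_id=pid, dt_s=dt, y_um=y), label)
            )
            pid += 1
    return out


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Long-format table (particle, frame, t_s, y_um, x_px, y_px)."""
    rows = []
    for traj in trajectories:
        frames = (
            traj.frames if traj.frames is not None else np.arange(traj.n_frames)
        )
        for j, f in enumerate(frames):
            rows.append(
                {
                    "particle": traj.particle_id,
                    "frame": int(f),
                    "t_s": float(f) * traj.dt_s,
                    "y_um": traj.y_um[j],
                    "x_px": traj.x_px[j] if traj.x_px is not None else np.nan,
                    "y_px": traj.y_px[j] if traj.y_px is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def trajectories_from_frame(df: pd.DataFrame, dt_s: float) -> list[Trajectory]:
    """Inverse of :func:`trajectories_to_frame`."""
    out = []
    for pid, grp in df.groupby("particle"):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                particle_id=int(pid),
                dt_s=dt_s,
                y_um=grp["y_um"].to_numpy(),
                x_px=grp["x_px"].to_numpy() if "x_px" in grp else None,
                y_px=grp["y_px"].to_numpy() if "y_px" in grp else None,
                frames=grp["frame"].to_numpy(),
            )
        )
    return out
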