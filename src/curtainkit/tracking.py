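"""Particle detection, sub-pixel 2D Gaussian localization, greedy
nearest-neighbor trajectory linking, and kymograph extraction.

Detection thresholds on the robust background level (median + k * MAD)
and non-maximum-suppresses candidates within one PSF radius.  Each
candidate is refined by least-squares fitting of a symmetric 2D Gaussian
plus constant offset inside a square ROI, giving sub-pixel positions.
Localizations are linked frame-to-frame by greedy nearest-neighbor
assignment with a displacement gate and optional gap closing; gaps are
recorded, never interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .simulate import Trajectory

__all__ = [
    "Localization",
    "Kymograph",
    "detect_spots",
    "fit_gaussian_2d",
    "link_trajectories",
    "extract_kymograph",
    "track_stack",
]


@dataclass(frozen=True)
class Localization:
    """One fitted emitter in one frame (pixel units, sub-pixel centers)."""

    frame: int
    x_px: float
    y_px: float
    amplitude: float
    sigma_px: float
    offset: float
    residual: float
    ok: bool = True
    error: str | None = None


@dataclass(frozen=True)
class Kymograph:
    """Space-time image: intensity profile along the DNA axis per frame.

    ``data`` has shape (n_positions, n_frames).
    """

    data: np.ndarray
    pixel_um: float
    dt_s: float


def detect_spots(
    frame: np.ndarray, threshold_k: float = 6.0, psf_sigma_px: float = 1.2
) -> list[tuple[int, int]]:
    """Candidate emitter pixels: local maxima above a robust threshold.

    The threshold is the background median plus ``threshold_k`` times the
    MAD-based robust sigma (1.4826 * MAD), so k = 6 means six background
    standard deviations.  Non-maximum suppression keeps only the
    brightest candidate within one PSF radius (3 sigma).  Returns
    (row, col) integer peak positions sorted by decreasing intensity.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0 or min(frame.shape) < 3:
        raise ValueError("detection requires a 2D image of at least 3x3 pixels")
    med = np.median(frame)
    mad = np.median(np.abs(frame - med))
    threshold = med + threshold_k * 1.4826 * mad
    radius = max(1, int(round(3.0 * psf_sigma_px)))
    footprint = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    is_max = frame == ndimage.maximum_filter(frame, footprint=footprint, mode="nearest")
    rows, cols = np.nonzero(is_max & (frame > threshold))
    order = np.argsort(frame[rows, cols])[::-1]
    peaks: list[tuple[int, int]] = []
    for k in order:
        r, c = int(rows[k]), int(cols[k])
        if all((r - pr) ** 2 + (c - pc) ** 2 > radius**2 for pr, pc in peaks):
            peaks.append((r, c))
    return peaks


def _gauss2d(coords, amp, xc, yc, sigma, offset):
    x, y = coords
    return amp * np.exp(-((x - xc) ** 2 + (y - yc) ** 2) / (2.0 * sigma**2)) + offset


def fit_gaussian_2d(
    frame: np.ndarray,
    candidate: tuple[int, int],
    roi_half: int = 5,
    frame_index: int = 0,
) -> Localization:
    """Least-squares symmetric 2D Gaussian + offset fit around a candidate.

    The ROI must lie fully inside the frame.  Non-convergent or degenerate
    fits (vanishing amplitude, center outside the ROI) are returned as
    flagged localizations with an error code, never silently dropped.
    """
    frame = np.asarray(frame, dtype=float)
    r0, c0 = candidate
    if not (
        roi_half <= r0 < frame.shape[0] - roi_half
        and roi_half <= c0 < frame.shape[1] - roi_half
    ):
        raise ValueError("ROI extends outside the frame")
    roi = frame[r0 - roi_half : r0 + roi_half + 1, c0 - roi_half : c0 + roi_half + 1]
    yy, xx = np.mgrid[0 : roi.shape[0], 0 : roi.shape[1]]
    offset0 = float(np.median(roi))
    amp0 = float(roi.max() - offset0)

    def _fail(code: str) -> Localization:
        return Localization(
            frame_index, float(c0), float(r0), 0.0, 0.0, offset0, math.inf,
            ok=False, error=code,
        )

    if amp0 <= 0:
        return _fail("no_signal")
    p0 = (amp0, float(roi_half), float(roi_half), 1.5, offset0)
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (xx.ravel(), yy.ravel()),
            roi.ravel(),
            p0=p0,
            maxfev=2000,
        )
    except RuntimeError:
        return _fail("no_convergence")
    amp, xc, yc, sigma, offset = popt
    sigma = abs(sigma)
    if amp <= 0 or sigma <= 0:
        return _fail("degenerate_fit")
    if not (0 <= xc <= 2 * roi_half and 0 <= yc <= 2 * roi_half):
        return _fail("center_outside_roi")
    resid = roi - _gauss2d((xx, yy), *popt)
    return Localization(
        frame=frame_index,
        x_px=c0 - roi_half + float(xc),
        y_px=r0 - roi_half + float(yc),
        amplitude=float(amp),
        sigma_px=float(sigma),
        offset=float(offset),
        residual=float(np.sqrt(np.mean(resid**2))),
    )


@dataclass
class _Track:
    pid: int
    frames: list[int]
    xs: list[float]
    ys: list[float]


def link_trajectories(
    localizations: list[list[Localization]],
    max_disp_px: float = 5.0,
    max_gap: int = 1,
    dt_s: float = 0.05,
    pixel_um: float = 0.2667,
) -> list[Trajectory]:
    """Greedy nearest-neighbor linking of per-frame localizations.

    Candidate (track, detection) pairs within ``max_disp_px`` of the
    track's last position (and at most ``max_gap`` missed frames) are
    assigned in order of increasing displacement, ties broken by lower
    track id.  Unmatched detections start new tracks; each detection
    joins at most one track.  Missing frames are recorded as gaps in the
    trajectory's frame index array.  Failed localizations are ignored.
    """
    active: list[_Track] = []
    done: list[_Track] = []
    next_pid = 0
    for f, locs in enumerate(localizations):
        locs = [l for l in locs if l.ok]
        # retire stale tracks
        still = []
        for tr in active:
            (still if f - tr.frames[-1] <= max_gap + 1 else done).append(tr)
        active = still
        pairs = []
        for ti, tr in enumerate(active):
            for di, det in enumerate(locs):
                d = math.hypot(det.x_px - tr.xs[-1], det.y_px - tr.ys[-1])
                if d <= max_disp_px:
                    pairs.append((d, tr.pid, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for _, _, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            tr = active[ti]
            det = locs[di]
            tr.frames.append(f)
            tr.xs.append(det.x_px)
            tr.ys.append(det.y_px)
        for di, det in enumerate(locs):
            if di not in used_d:
                active.append(_Track(next_pid, [f], [det.x_px], [det.y_px]))
                next_pid += 1
    done.extend(active)
    done.sort(key=lambda tr: tr.pid)
    n_frames_total = len(localizations)
    out = []
    for tr in done:
        x = np.asarray(tr.xs)
        out.append(
            Trajectory(
                particle_id=tr.pid,
                dt_s=dt_s,
                y_um=x * pixel_um,  # DNA axis is the image x axis
                x_px=x,
                y_px=np.asarray(tr.ys),
                frames=np.asarray(tr.frames),
                censored_start=tr.frames[0] == 0,
                censored_end=tr.frames[-1] == n_frames_total - 1,
            )
        )
    return out


def extract_kymograph(
    stack: np.ndarray,
    row_px: int,
    halfwidth_px: int = 2,
    pixel_um: float = 0.2667,
    dt_s: float = 0.05,
) -> Kymograph:
    """Average a band of rows around the DNA axis in every frame.

    Returns a (n_positions, n_frames) space-time image.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a (frames, ny, nx) stack")
    lo = row_px - halfwidth_px
    hi = row_px + halfwidth_px + 1
    if lo < 0 or hi > stack.shape[1]:
        raise ValueError("kymograph line outside image bounds")
    profile = stack[:, lo:hi, :].mean(axis=1)  # (frames, nx)
    return Kymograph(profile.T.copy(), pixel_um, dt_s)


def track_stack(
    stack: np.ndarray,
    threshold_k: float = 6.0,
    psf_sigma_px: float = 1.2,
    roi_half: int = 5,
    max_disp_px: float = 5.0,
    max_gap: int = 1,
    dt_s: float = 0.05,
    pixel_um: float = 0.2667,
) -> list[Trajectory]:
    """Full detect -> fit -> link pipeline over a frame stack."""
    per_frame: list[list[Localization]] = []
    for f, frame in enumerate(np.asarray(stack, dtype=float)):
        locs = []
        for r, c in detect_spots(frame, threshold_k, psf_sigma_px):
            r = int(np.clip(r, roi_half, frame.shape[0] - roi_half - 1))
            c = int(np.clip(c, roi_half, frame.shape[1] - roi_half - 1))
            locs.append(fit_gaussian_2d(frame, (r, c), roi_half, frame_index=f))
        per_frame.append(locs)
    return link_trajectories(per_frame, max_disp_px, max_gap, dt_s, pixel_um)
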