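"""Normalized cross-correlation template tracking.

Re-implements the feature-window / candidate-window tracker popularised
by kinematic analysis tools: a small template (feature window) extracted
around the target is matched against a larger search region (candidate
window) in each subsequent frame by the zero-normalized cross-correlation
coefficient, with optional sub-pixel peak refinement, template update,
confidence gating and manual re-seeding.

Coordinates are 0-based pixel indices with the origin at the top-left and
y increasing downward; reported positions refer to the template centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .phantom import FrameStack

__all__ = [
    "TrackerConfig",
    "Trajectory",
    "STATUS_TRACKED",
    "STATUS_LOW_CONFIDENCE",
    "STATUS_RESEEDED",
    "STATUS_LOST",
    "ncc_map",
    "locate_peak",
    "track_sequence",
    "reseed",
]

STATUS_TRACKED = "tracked"
STATUS_LOW_CONFIDENCE = "low_confidence"
STATUS_RESEEDED = "reseeded"
STATUS_LOST = "lost"

_TEMPLATE_UPDATE = ("never", "always", "on_accept")


@dataclass(frozen=True)
class TrackerConfig:
    """Tracker tuning parameters.

    The defaults cover inter-frame displacements up to ~18 px — a 40 mm
    peak-to-peak sinusoid at a 2 s period, sampled at 15 frames/s under a
    1.27x magnification, peaks near 16 px/frame — with margin.
    """

    feature_window_px: int = 25
    search_window_px: int = 61
    ncc_accept_threshold: float = 0.5
    template_update: str = "on_accept"
    subpixel: bool = True
    lost_after: int = 5  # consecutive low-confidence frames before giving up

    def __post_init__(self) -> None:
        if self.feature_window_px % 2 == 0 or self.search_window_px % 2 == 0:
            raise ValueError("window sizes must be odd")
        if self.search_window_px <= self.feature_window_px:
            raise ValueError("search window must be larger than the feature window")
        if not 0 <= self.ncc_accept_threshold <= 1:
            raise ValueError("ncc_accept_threshold must lie in [0, 1]")
        if self.template_update not in _TEMPLATE_UPDATE:
            raise ValueError(f"template_update must be one of {_TEMPLATE_UPDATE}")
        if self.lost_after < 1:
            raise ValueError("lost_after must be >= 1")


@dataclass
class Trajectory:
    """Per-frame target positions with matching confidence and status."""

    frame_index: np.ndarray
    time_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    ncc_score: np.ndarray
    status: np.ndarray  # array of status strings

    def __post_init__(self) -> None:
        n = len(self.frame_index)
        for name in ("time_ms", "x_px", "y_px", "ncc_score", "status"):
            if len(getattr(self, name)) != n:
                raise ValueError("all trajectory columns must share one length")

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def lost_mask(self) -> np.ndarray:
        return self.status == STATUS_LOST


# ---------------------------------------------------------------------------
# Correlation map
# ---------------------------------------------------------------------------

def ncc_map(template: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Zero-normalized cross-correlation of ``template`` over ``region``.

    At each valid offset the Pearson correlation coefficient between the
    template and the co-located region patch is computed (both windows
    mean-subtracted, divided by the product of their standard
    deviations); the result is clamped to [-1, 1].  Region patches with
    zero variance yield a coefficient of 0.

    Raises
    ------
    ValueError
        If the template has zero intensity variance (the coefficient is
        undefined) or the region is not strictly larger than the template.
    """
    template = np.asarray(template, dtype=np.float64)
    region = np.asarray(region, dtype=np.float64)
    th, tw = template.shape
    rh, rw = region.shape
    if rh <= th or rw <= tw:
        raise ValueError("region must be strictly larger than the template")
    t = template - template.mean()
    t_norm = np.sqrt((t * t).sum())
    if t_norm == 0:
        raise ValueError("template has zero intensity variance; NCC undefined")

    windows = sliding_window_view(region, (th, tw))  # (rh-th+1, rw-tw+1, th, tw)
    n = th * tw
    win_sum = windows.sum(axis=(2, 3))
    win_sq = (windows * windows).sum(axis=(2, 3))
    cross = np.einsum("ijkl,kl->ij", windows, t)
    win_var = win_sq - win_sum * win_sum / n
    denom = t_norm * np.sqrt(np.clip(win_var, 0.0, None))
    out = np.zeros_like(cross)
    ok = denom > 0
    out[ok] = cross[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0)


def locate_peak(ncc: np.ndarray, subpixel: bool = True) -> tuple[float, float, float]:
    """Locate the correlation peak as ``(dx, dy, peak_value)`` offsets.

    The integer argmax is found first (ties broken toward the smallest
    (row, column) offset); with ``subpixel`` each axis is refined
    independently by fitting a quadratic through the peak and its two
    axial neighbours, with the correction bounded to +/-0.5 px.
    """
    ncc = np.asarray(ncc, dtype=np.float64)
    if ncc.size == 0:
        raise ValueError("empty correlation map")
    iy, ix = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
    peak = float(ncc[iy, ix])
    dy, dx = float(iy), float(ix)
    if subpixel:
        dx += _quadratic_offset(ncc[iy, :], ix)
        dy += _quadratic_offset(ncc[:, ix], iy)
    return dx, dy, peak


def _quadratic_offset(line: np.ndarray, i: int) -> float:
    """Vertex offset of the parabola through samples (i-1, i, i+1)."""
    if i <= 0 or i >= len(line) - 1:
        return 0.0
    a, b, c = float(line[i - 1]), float(line[i]), float(line[i + 1])
    denom = a - 2.0 * b + c
    if denom == 0:
        return 0.0
    off = 0.5 * (a - c) / denom
    return float(np.clip(off, -0.5, 0.5))


# ---------------------------------------------------------------------------
# Sequence tracking
# ---------------------------------------------------------------------------

def _extract_patch(frame: np.ndarray, cx: int, cy: int, size: int) -> np.ndarray:
    half = size // 2
    return frame[cy - half:cy + half + 1, cx - half:cx + half + 1]


def _clamped_origin(c: int, half: int, size: int, limit: int) -> tuple[int, bool]:
    """Top-left of a window of ``size`` centred near ``c``; True if clamped."""
    o = c - half
    clamped = False
    if o < 0:
        o, clamped = 0, True
    elif o + size > limit:
        o, clamped = limit - size, True
    return o, clamped


def track_sequence(
    frames: FrameStack,
    seed_point: tuple[float, float],
    seed_frame: int = 0,
    config: TrackerConfig | None = None,
) -> Trajectory:
    """Track a target through a frame stack from a manual seed point.

    The feature window is initialized around ``seed_point`` in
    ``seed_frame``.  For each subsequent frame the search window is
    centred on the last accepted position and the template matched by
    NCC; the new position is the matched template centre (plus the
    sub-pixel anchor offset recorded when the template was captured, so
    template refreshes do not re-quantize the trajectory).  Frames whose
    peak NCC falls below the acceptance threshold are flagged
    ``low_confidence`` with the template frozen; after ``lost_after``
    consecutive low-confidence frames the target is declared ``lost``.
    Frames before ``seed_frame`` are marked lost (track forward only; use
    a seed in the first frame for full coverage).
    """
    if config is None:
        config = TrackerConfig()
    n_frames = len(frames)
    if not 0 <= seed_frame < n_frames:
        raise ValueError(f"seed_frame {seed_frame} out of range [0, {n_frames})")
    rows, cols = frames.shape
    f_half = config.feature_window_px // 2
    s_size = config.search_window_px
    s_half = s_size // 2
    sx, sy = float(seed_point[0]), float(seed_point[1])
    ix, iy = int(round(sx)), int(round(sy))
    if not (f_half <= ix < cols - f_half and f_half <= iy < rows - f_half):
        raise ValueError("seed point too close to the image border for the feature window")

    x = np.full(n_frames, np.nan)
    y = np.full(n_frames, np.nan)
    score = np.full(n_frames, np.nan)
    status = np.full(n_frames, STATUS_LOST, dtype=object)

    template = np.asarray(_extract_patch(frames.frames[seed_frame], ix, iy, config.feature_window_px), float)
    # sub-pixel anchor: where the tracked point sits relative to the
    # template's integer centre at capture time
    anchor = (sx - ix, sy - iy)
    x[seed_frame], y[seed_frame] = sx, sy
    score[seed_frame] = 1.0
    status[seed_frame] = STATUS_TRACKED
    _run_forward(frames, seed_frame + 1, template, anchor, (sx, sy), config,
                 x, y, score, status)
    time_ms = np.arange(n_frames) / frames.frame_rate_hz * 1000.0
    return Trajectory(frame_index=np.arange(n_frames), time_ms=time_ms,
                      x_px=x, y_px=y, ncc_score=score,
                      status=np.asarray(status, dtype=object))


def _run_forward(frames, start, template, anchor, last_accept, config,
                 x, y, score, status):
    """Forward tracking loop writing into the trajectory arrays in place."""
    rows, cols = frames.shape
    s_size = config.search_window_px
    s_half = s_size // 2
    f_half = config.feature_window_px // 2
    low_run = 0
    ax, ay = anchor
    px, py = last_accept
    for k in range(start, len(frames)):
        frame = np.asarray(frames.frames[k], float)
        cx, cy = int(round(px - ax)), int(round(py - ay))
        ox, clx = _clamped_origin(cx, s_half, s_size, cols)
        oy, cly = _clamped_origin(cy, s_half, s_size, rows)
        region = frame[oy:oy + s_size, ox:ox + s_size]
        ncc = ncc_map(template, region)
        dx, dy, peak = locate_peak(ncc, config.subpixel)
        mx = ox + dx + f_half  # matched template-centre position
        my = oy + dy + f_half
        x[k] = mx + ax
        y[k] = my + ay
        score[k] = peak
        accepted = peak >= config.ncc_accept_threshold and not (clx or cly)
        if accepted:
            status[k] = STATUS_TRACKED
            low_run = 0
            px, py = x[k], y[k]
            if config.template_update in ("always", "on_accept"):
                nix, niy = int(round(mx)), int(round(my))
                if f_half <= nix < cols - f_half and f_half <= niy < rows - f_half:
                    template = _extract_patch(frame, nix, niy, config.feature_window_px)
                    ax, ay = x[k] - nix, y[k] - niy
        else:
            status[k] = STATUS_LOW_CONFIDENCE
            low_run += 1
            if config.template_update == "always":
                # 'always' refreshes regardless of confidence
                nix, niy = int(round(mx)), int(round(my))
                if f_half <= nix < cols - f_half and f_half <= niy < rows - f_half:
                    template = _extract_patch(frame, nix, niy, config.feature_window_px)
                    ax, ay = x[k] - nix, y[k] - niy
            if low_run >= config.lost_after:
                for j in range(k + 1, len(frames)):
                    status[j] = STATUS_LOST
                return


def reseed(
    traj: Trajectory,
    frames: FrameStack,
    frame: int,
    point: tuple[float, float],
    config: TrackerConfig | None = None,
) -> Trajectory:
    """Manually correct the track at ``frame`` and re-run forward.

    The position at ``frame`` is replaced by ``point`` (status
    ``reseeded``), a fresh template is captured there, and tracking
    resumes forward.  Frames before ``frame`` are untouched.
    """
    if config is None:
        config = TrackerConfig()
    n_frames = len(frames)
    if not 0 <= frame < len(traj):
        raise ValueError(f"frame {frame} outside trajectory range")
    rows, cols = frames.shape
    f_half = config.feature_window_px // 2
    px, py = float(point[0]), float(point[1])
    ix, iy = int(round(px)), int(round(py))
    if not (f_half <= ix < cols - f_half and f_half <= iy < rows - f_half):
        raise ValueError("reseed point too close to the image border")

    out = Trajectory(
        frame_index=traj.frame_index.copy(), time_ms=traj.time_ms.copy(),
        x_px=traj.x_px.copy(), y_px=traj.y_px.copy(),
        ncc_score=traj.ncc_score.copy(), status=traj.status.copy(),
    )
    out.x_px[frame], out.y_px[frame] = px, py
    out.ncc_score[frame] = 1.0
    out.status[frame] = STATUS_RESEEDED
    template = np.asarray(_extract_patch(frames.frames[frame], ix, iy, config.feature_window_px), float)
    _run_forward(frames, frame + 1, template, (px - ix, py - iy), (px, py),
                 config, out.x_px, out.y_px, out.ncc_score, out.status)
    return out
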