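"""Synthetic motion-phantom video generation.

Emulates a programmable respiratory motion platform carrying a small
high-attenuation sphere in front of a flat-panel detector, so that every
downstream stage (tracking, amplitude analysis) can be validated against
known ground truth without any acquisition hardware.

The acquisition model is pulsed radiography: ``frame_rate_hz`` pulses per
second over ``duration_s`` seconds onto a square 16-bit detector with a
fixed pixel pitch.  Object-plane motion is magnified geometrically by a
factor M before it reaches the detector, so a displacement of ``d`` mm at
the object appears as ``d * M / pixel_pitch_mm`` pixels in the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "MotionPattern",
    "AcquisitionGeometry",
    "GroundTruthTrajectory",
    "FrameStack",
    "BreathingTrace",
    "object_position",
    "project_and_sample",
    "render_video",
    "generate_breathing_video",
    "validation_suite",
]

_ORBITS = ("linear", "parallelogram")


@dataclass(frozen=True)
class MotionPattern:
    """Parametric platform motion.

    Parameters
    ----------
    amplitude_mm
        Peak-to-peak amplitude along the platform's motion axis
        (object plane, mm).  For a ``parallelogram`` orbit this field is
        unused for the waveform itself; the per-axis component amplitudes
        are configured directly.
    period_s
        Sinusoid period in seconds.
    rotation_deg
        Platform rotation measured from the vertical axis: 0 deg is pure
        vertical motion, 90 deg pure horizontal.
    orbit
        ``"linear"`` (straight line at ``rotation_deg``) or
        ``"parallelogram"`` (vertical sinusoid plus a horizontal offset
        whose sign follows the vertical velocity direction).
    parallelogram_h_mm, parallelogram_v_mm
        Component peak-to-peak amplitudes when ``orbit="parallelogram"``.
    phantom_platform_distance_mm
        Offset of the sphere above the platform surface; bookkeeping only,
        used to select the corresponding ``magnification``.
    magnification
        Geometric magnification M (>= 1) of the object in the image.
    axis_swap
        If True, swap the horizontal/vertical component assignment.  The
        platform's mounted orientation determines which detector axis the
        cosine component of a diagonal motion falls on; both conventions
        are reproducible via this flag.
    phase_deg
        Initial motion phase; 0 places the object at mid-position moving
        toward positive displacement at t = 0.
    """

    amplitude_mm: float = 20.0
    period_s: float = 4.0
    rotation_deg: float = 0.0
    orbit: str = "linear"
    parallelogram_h_mm: float = 0.0
    parallelogram_v_mm: float = 0.0
    phantom_platform_distance_mm: float = 100.0
    magnification: float = 1.20
    axis_swap: bool = False
    phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.orbit not in _ORBITS:
            raise ValueError(f"unknown orbit {self.orbit!r}; expected one of {_ORBITS}")
        if self.orbit == "linear" and self.amplitude_mm <= 0:
            raise ValueError("amplitude_mm must be > 0")
        if self.period_s <= 0:
            raise ValueError("period_s must be > 0")
        if self.magnification < 1:
            raise ValueError("magnification must be >= 1")
        if not 0 <= self.rotation_deg <= 90:
            raise ValueError("rotation_deg must lie in [0, 90]")
        if self.orbit == "parallelogram" and (
            self.parallelogram_h_mm <= 0 or self.parallelogram_v_mm <= 0
        ):
            raise ValueError("parallelogram orbits need both component amplitudes > 0")


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Detector and timing parameters of one acquisition.

    Defaults reproduce the native acquisition: 15 pulses per second for
    20 s (300 frames) on a 1062 x 1062 detector with 0.4 mm pixels at a
    source-to-detector distance of 120 cm.
    """

    frame_rate_hz: float = 15.0
    duration_s: float = 20.0
    matrix_px: int = 1062
    pixel_pitch_mm: float = 0.4
    sdd_mm: float = 1200.0

    def __post_init__(self) -> None:
        for name in ("frame_rate_hz", "duration_s", "matrix_px", "pixel_pitch_mm", "sdd_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_frames(self) -> int:
        return round(self.frame_rate_hz * self.duration_s)

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class GroundTruthTrajectory:
    """True object-plane and detector-plane positions per frame."""

    times_s: np.ndarray
    x_mm: np.ndarray  # horizontal object-plane displacement
    y_mm: np.ndarray  # vertical object-plane displacement (positive = down)
    x_px: np.ndarray  # detector-plane column position
    y_px: np.ndarray  # detector-plane row position
    magnification: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.times_s)
        for name in ("x_mm", "y_mm", "x_px", "y_px"):
            if len(getattr(self, name)) != n:
                raise ValueError("all trajectory series must share one length")

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass
class FrameStack:
    """Ordered grayscale frames plus the metadata needed to calibrate them."""

    frames: np.ndarray  # (n, rows, cols)
    pixel_pitch_mm: float
    frame_rate_hz: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) array")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


# ---------------------------------------------------------------------------
# Motion waveforms
# ---------------------------------------------------------------------------

def object_position(pattern: MotionPattern, t):
    """Object-plane displacement (h_mm, v_mm) at time(s) ``t`` seconds.

    Linear orbit: sinusoidal displacement of peak-to-peak ``amplitude_mm``
    along a line at ``rotation_deg`` from vertical.  Parallelogram orbit:
    vertical sinusoid of peak-to-peak ``parallelogram_v_mm`` plus a
    horizontal offset of half ``parallelogram_h_mm`` whose sign follows
    the vertical velocity, tracing a closed two-branch loop.  In both
    cases the per-axis peak-to-peak over one full period equals the
    configured component amplitude exactly.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    phase = 2 * math.pi * t / pattern.period_s + math.radians(pattern.phase_deg)
    if pattern.orbit == "linear":
        d = 0.5 * pattern.amplitude_mm * np.sin(phase)
        theta = math.radians(pattern.rotation_deg)
        h = d * math.sin(theta)
        v = d * math.cos(theta)
    else:  # parallelogram
        v = 0.5 * pattern.parallelogram_v_mm * np.sin(phase)
        # horizontal branch selected by the vertical velocity sign
        h = 0.5 * pattern.parallelogram_h_mm * np.where(np.cos(phase) >= 0, 1.0, -1.0)
    if pattern.axis_swap:
        h, v = v, h
    return h, v


def project_and_sample(
    pattern: MotionPattern,
    geom: AcquisitionGeometry,
    center_px: tuple[float, float] | None = None,
) -> GroundTruthTrajectory:
    """Sample the pattern at the frame rate and project onto the detector.

    ``center_px`` is the (x, y) detector position of the motion midpoint;
    defaults to the image center.  Detector displacement is object
    displacement times the magnification; image y increases downward and
    carries the vertical motion component.
    """
    if center_px is None:
        c = (geom.matrix_px - 1) / 2.0
        center_px = (c, c)
    t = geom.times_s()
    h, v = object_position(pattern, t)
    scale = pattern.magnification / geom.pixel_pitch_mm
    x_px = center_px[0] + h * scale
    y_px = center_px[1] + v * scale
    bad = (x_px < 0) | (x_px > geom.matrix_px - 1) | (y_px < 0) | (y_px > geom.matrix_px - 1)
    if np.any(bad):
        first = int(np.argmax(bad))
        raise ValueError(
            f"trajectory leaves the {geom.matrix_px}x{geom.matrix_px} image "
            f"at frame {first} (x={x_px[first]:.1f}, y={y_px[first]:.1f})"
        )
    return GroundTruthTrajectory(
        times_s=t, x_mm=np.asarray(h) + np.zeros_like(t), y_mm=np.asarray(v) + np.zeros_like(t),
        x_px=x_px, y_px=y_px, magnification=pattern.magnification,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_SUPERSAMPLE = 4  # sub-pixel rendering: 4x oversampling then box-averaging


def _background(shape: tuple[int, int], level: float, texture_amp: float) -> np.ndarray:
    """Smooth low-frequency cosine-mixture background (deterministic)."""
    rows, cols = shape
    y = np.arange(rows)[:, None]
    x = np.arange(cols)[None, :]
    bg = np.full((rows, cols), level, dtype=float)
    if texture_amp > 0:
        bg += texture_amp * (
            0.5 * np.cos(2 * np.pi * x / 211.0 + 0.7)
            + 0.5 * np.cos(2 * np.pi * y / 173.0 + 1.9)
            + 0.35 * np.cos(2 * np.pi * (x + y) / 307.0 + 0.3)
            + 0.25 * np.cos(2 * np.pi * (x - 2 * y) / 401.0 + 2.2)
        )
    return bg


def _disk_deficit_patch(
    radius_px: float, frac_x: float, frac_y: float, contrast: float, psf_sigma_px: float
) -> tuple[np.ndarray, int]:
    """Attenuation patch of a sphere centred at (frac_x, frac_y) within a pixel.

    Returns the patch and its half-size; the patch covers
    ``[-half, half]`` pixels around the containing pixel.  The deficit
    follows the projected chord length of a sphere, peak-normalized to
    ``contrast``, blurred by a Gaussian system PSF.
    """
    half = int(math.ceil(radius_px + 3.0 * psf_sigma_px + 2.0))
    n = 2 * half + 1
    s = _SUPERSAMPLE
    # supersampled cell-centre coordinates relative to the patch centre pixel
    coords = (np.arange(n * s) + 0.5) / s - 0.5 - half
    dx = coords[None, :] - frac_x
    dy = coords[:, None] - frac_y
    r2 = (dx * dx + dy * dy) / (radius_px * radius_px)
    chord = np.sqrt(np.clip(1.0 - r2, 0.0, None))
    patch = chord.reshape(n, s, n, s).mean(axis=(1, 3)) * contrast
    if psf_sigma_px > 0:
        patch = gaussian_filter(patch, psf_sigma_px, mode="constant")
    return patch, half


def render_video(
    traj: GroundTruthTrajectory,
    geom: AcquisitionGeometry,
    sphere_diameter_mm: float = 2.0,
    noise_sd: float = 240.0,
    seed: int = 0,
    *,
    background_level: float = 30000.0,
    texture_amp: float = 500.0,
    contrast: float = 12000.0,
    psf_sigma_px: float = 0.8,
) -> FrameStack:
    """Render a 16-bit frame stack of a dark sphere following ``traj``.

    Each frame is a smooth background texture plus seeded additive
    Gaussian noise, minus an attenuation disk whose profile is the
    projected chord length of a sphere of diameter
    ``sphere_diameter_mm * magnification``, blurred by a Gaussian system
    PSF and rendered with sub-pixel accuracy.  Bit-identical for a fixed
    seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n_px = geom.matrix_px
    radius_px = 0.5 * sphere_diameter_mm * traj.magnification / geom.pixel_pitch_mm
    margin = radius_px + 1
    if (
        np.min(traj.x_px) < margin or np.max(traj.x_px) > n_px - 1 - margin
        or np.min(traj.y_px) < margin or np.max(traj.y_px) > n_px - 1 - margin
    ):
        raise ValueError("sphere does not fit in the frame along the whole trajectory")

    bg = _background((n_px, n_px), background_level, texture_amp)
    rng = np.random.default_rng(seed)
    n_frames = len(traj)
    frames = np.empty((n_frames, n_px, n_px), dtype=np.uint16)
    for k in range(n_frames):
        img = bg.copy()
        cx, cy = float(traj.x_px[k]), float(traj.y_px[k])
        ix, iy = int(round(cx)), int(round(cy))
        patch, half = _disk_deficit_patch(radius_px, cx - ix, cy - iy, contrast, psf_sigma_px)
        y0, y1 = iy - half, iy + half + 1
        x0, x1 = ix - half, ix + half + 1
        py0, px0 = max(0, -y0), max(0, -x0)
        y0, x0 = max(0, y0), max(0, x0)
        y1, x1 = min(n_px, y1), min(n_px, x1)
        img[y0:y1, x0:x1] -= patch[py0:py0 + (y1 - y0), px0:px0 + (x1 - x0)]
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, size=img.shape)
        np.clip(img, 0, 65535, out=img)
        frames[k] = np.round(img).astype(np.uint16)
    return FrameStack(frames=frames, pixel_pitch_mm=geom.pixel_pitch_mm,
                      frame_rate_hz=geom.frame_rate_hz, bit_depth=16)


# ---------------------------------------------------------------------------
# Validation suite
# ---------------------------------------------------------------------------

# platform-surface offsets (mm) and the calibrated magnification each selects
PLATFORM_MAGNIFICATION = {0.0: 1.09, 50.0: 1.15, 100.0: 1.20, 150.0: 1.27}


def validation_suite() -> list[tuple[str, MotionPattern, dict[str, float]]]:
    """The full programmable-platform validation suite.

    Returns ``(name, pattern, predetermined)`` triples covering every
    unique platform setting: peak-to-peak amplitudes 10/20/30/40 mm at a
    4 s period, periods 2/4/6 s at 20 mm, diagonal motion at 30 and 45
    degrees, two parallelogram orbits (3/17 and 6/14 mm), and platform
    offsets 0/50/100/150 mm (magnifications 1.09/1.15/1.20/1.27).
    ``predetermined`` maps measured axes (``"h"``/``"v"``) to the true
    object-plane component peak-to-peak amplitudes in mm; vertical-only
    patterns are evaluated on the vertical axis alone.
    """

    def lin(amp, period=4.0, rot=0.0, dist=100.0):
        return MotionPattern(
            amplitude_mm=amp, period_s=period, rotation_deg=rot,
            phantom_platform_distance_mm=dist,
            magnification=PLATFORM_MAGNIFICATION[dist],
        )

    suite: list[tuple[str, MotionPattern, dict[str, float]]] = []
    for amp in (10.0, 20.0, 30.0, 40.0):
        suite.append((f"amp{amp:g}_T4_V_M1.20", lin(amp), {"v": amp}))
    for period in (2.0, 6.0):
        suite.append((f"amp20_T{period:g}_V_M1.20", lin(20.0, period), {"v": 20.0}))
    for rot in (30.0, 45.0):
        h = 20.0 * math.sin(math.radians(rot))
        v = 20.0 * math.cos(math.radians(rot))
        suite.append((f"amp20_T4_diag{rot:g}_M1.20", lin(20.0, rot=rot), {"h": h, "v": v}))
    for h, v in ((3.0, 17.0), (6.0, 14.0)):
        pattern = MotionPattern(
            orbit="parallelogram", parallelogram_h_mm=h, parallelogram_v_mm=v,
            period_s=4.0, phantom_platform_distance_mm=100.0,
            magnification=PLATFORM_MAGNIFICATION[100.0],
        )
        suite.append((f"para_h{h:g}_v{v:g}_M1.20", pattern, {"h": h, "v": v}))
    for dist in (0.0, 50.0, 150.0):
        mag = PLATFORM_MAGNIFICATION[dist]
        suite.append((f"amp20_T4_V_M{mag:.2f}", lin(20.0, dist=dist), {"v": 20.0}))
    return suite


# ---------------------------------------------------------------------------
# Irregular breathing
# ---------------------------------------------------------------------------

@dataclass
class BreathingTrace:
    """Per-cycle description of an irregular breathing pattern.

    The vertical (superior-inferior) waveform is a concatenation of
    half-sine cycles, one per (period, amplitude) pair, with an optional
    superposed cardiac-frequency ripple.  A horizontal component is a
    scaled copy delayed by ``hysteresis_phase_deg``, producing the open
    hysteresis loop seen in some tumor trajectories.
    """

    cycle_periods_s: list[float] = field(default_factory=lambda: [4.0])
    cycle_amplitudes_mm: list[float] = field(default_factory=lambda: [20.0])
    cardiac_ripple_mm: float = 0.0
    cardiac_freq_hz: float = 1.2
    hysteresis_phase_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cycle_periods_s) != len(self.cycle_amplitudes_mm):
            raise ValueError("periods and amplitudes must pair up one-to-one")
        if len(self.cycle_periods_s) == 0:
            raise ValueError("at least one breathing cycle is required")
        if any(p <= 0 for p in self.cycle_periods_s) or any(
            a < 0 for a in self.cycle_amplitudes_mm
        ):
            raise ValueError("periods must be > 0 and amplitudes >= 0")

    @classmethod
    def irregular(
        cls,
        n_cycles: int = 6,
        seed: int = 0,
        period_range_s: tuple[float, float] = (1.6, 4.2),
        amplitude_range_mm: tuple[float, float] = (5.0, 17.6),
        cardiac_ripple_mm: float = 0.3,
        cardiac_freq_hz: float = 1.2,
        hysteresis_phase_deg: float = 30.0,
    ) -> "BreathingTrace":
        """Draw a reproducible irregular trace.

        Default per-cycle period and amplitude ranges follow the spread
        observed across breathing cycles of a free-breathing patient
        (periods 1.6-4.2 s; amplitudes up to 17.6 mm).
        """
        rng = np.random.default_rng(seed)
        periods = rng.uniform(*period_range_s, size=n_cycles)
        amps = rng.uniform(*amplitude_range_mm, size=n_cycles)
        return cls(
            cycle_periods_s=periods.tolist(),
            cycle_amplitudes_mm=amps.tolist(),
            cardiac_ripple_mm=cardiac_ripple_mm,
            cardiac_freq_hz=cardiac_freq_hz,
            hysteresis_phase_deg=hysteresis_phase_deg,
            seed=seed,
        )

    def vertical_mm(self, t) -> np.ndarray:
        """Respiratory waveform (without ripple) at time(s) ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        starts = np.concatenate([[0.0], np.cumsum(self.cycle_periods_s)])
        out = np.zeros_like(t)
        for i, (period, amp) in enumerate(
            zip(self.cycle_periods_s, self.cycle_amplitudes_mm)
        ):
            mask = (t >= starts[i]) & (t < starts[i + 1])
            out[mask] = amp * np.sin(np.pi * (t[mask] - starts[i]) / period)
        return out

    def signal_mm(self, t) -> np.ndarray:
        """Respiratory waveform plus cardiac ripple."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = self.vertical_mm(t)
        if self.cardiac_ripple_mm > 0:
            out = out + 0.5 * self.cardiac_ripple_mm * np.sin(
                2 * np.pi * self.cardiac_freq_hz * t
            )
        return out


def generate_breathing_video(
    trace: BreathingTrace,
    geom: AcquisitionGeometry,
    center_px: tuple[float, float] | None = None,
    magnification: float = 1.0,
    h_ratio: float = 0.2,
    **render_kwargs,
) -> tuple[FrameStack, GroundTruthTrajectory]:
    """Render an irregular-breathing video with known ground truth.

    Vertical position follows the trace's concatenated half-sine cycles
    plus cardiac ripple; horizontal position is ``h_ratio`` times the
    vertical waveform delayed by the trace's hysteresis phase (computed
    against the mean cycle period), producing an open loop when the phase
    is nonzero.  Rendering parameters are forwarded to
    :func:`render_video`.
    """
    if trace.cycle_periods_s[0] > geom.duration_s:
        raise ValueError("not even one breathing cycle fits in the acquisition")
    if center_px is None:
        c = (geom.matrix_px - 1) / 2.0
        center_px = (c, c)
    t = geom.times_s()
    v_mm = trace.signal_mm(t)
    mean_period = float(np.mean(trace.cycle_periods_s))
    delay = trace.hysteresis_phase_deg / 360.0 * mean_period
    h_mm = h_ratio * trace.signal_mm(np.clip(t - delay, 0.0, None))
    scale = magnification / geom.pixel_pitch_mm
    traj = GroundTruthTrajectory(
        times_s=t, x_mm=h_mm, y_mm=v_mm,
        x_px=center_px[0] + h_mm * scale,
        y_px=center_px[1] + v_mm * scale,
        magnification=magnification,
    )
    stack = render_video(traj, geom, seed=trace.seed, **render_kwargs)
    return stack, traj
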