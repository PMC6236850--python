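"""Digital motion phantom: 2-D attenuation slices under respiratory motion.

The phantom emulates a programmable motion platform: objects of varied
size and contrast embedded in a lung-mimicking (near-air) slab, translated
along the superior-inferior (S-I) or anterior-posterior (A-P) axis by a
programmable respiratory waveform.  Slices are 2-D axial grids; S-I motion
is represented as in-plane translation of slice content, which is the
natural reduction for a per-slice 2-D reconstruction model — blur is
measured along the motion axis exactly as on the physical platform.

Conventions
-----------
* Image grids are square, ``n x n`` pixels over ``fov_mm`` millimetres,
  pixel (row, col) = (n//2, n//2) at the isocenter; +x is columns (A-P
  analog), +y is rows (S-I analog).
* Waveform ``displacement`` is in mm, peak-to-peak equal to ``amplitude``;
  the unitless ``surrogate`` (the breathing-belt analog) is the same trace
  normalized to [-1, 1] and phase-locked to the displacement.
* Phase 0 of a phase sort corresponds to end-inhale = surrogate maxima.

Objects are composed additively: an object's ``attenuation`` is the
contrast it adds on top of whatever lies beneath it (so a 0.018/mm disk on
a 0.001/mm slab reads 0.019/mm, soft tissue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "PhantomObject",
    "MotionWaveform",
    "SuiteSpec",
    "generate_waveform",
    "rasterize",
    "phantom_at_time",
    "standard_phantom_suite",
]

SAWTOOTH_RESET_FRACTION = 0.1
"""Fraction of the cycle spent on the rapid reset stroke of the sawtooth."""


@dataclass(frozen=True)
class GridSpec:
    """Square reconstruction/rasterization grid: ``n`` pixels over ``fov_mm``."""

    n: int = 256
    fov_mm: float = 500.0

    def __post_init__(self) -> None:
        if self.n < 8:
            raise ValueError("grid must be at least 8 pixels")
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be > 0")

    @property
    def px(self) -> float:
        """Pixel spacing [mm]."""
        return self.fov_mm / self.n

    @property
    def center_index(self) -> int:
        return self.n // 2

    def coords(self) -> np.ndarray:
        """Physical coordinate [mm] of each pixel center along one axis."""
        return (np.arange(self.n) - self.center_index) * self.px


@dataclass(frozen=True)
class PhantomObject:
    """One embedded object.

    ``size`` is the diameter for disks, or the (x, y) edge lengths for
    rectangles (a scalar means a square).  ``excursion`` is the object's
    peak-to-peak travel [mm] along ``motion_axis`` ('SI', 'AP' or 'none');
    the waveform sets the time course, the excursion its scale.
    """

    shape: str
    center: tuple[float, float]
    size: float | tuple[float, float]
    attenuation: float
    motion_axis: str = "none"
    excursion: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "rectangle"):
            raise ValueError("shape must be 'disk' or 'rectangle'")
        if self.motion_axis not in ("SI", "AP", "none"):
            raise ValueError("motion_axis must be 'SI', 'AP' or 'none'")
        sizes = np.atleast_1d(np.asarray(self.size, dtype=float))
        if np.any(sizes <= 0):
            raise ValueError("size must be > 0")
        if self.excursion < 0:
            raise ValueError("excursion must be >= 0")


@dataclass(frozen=True)
class MotionWaveform:
    """A sampled respiratory trace: the clock for motion and phase sorting."""

    kind: str
    breathing_period: float
    amplitude: float
    sample_times: np.ndarray
    surrogate: np.ndarray
    displacement: np.ndarray
    seed: int = 0
    irregularity: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.sample_times) == len(self.surrogate) == len(self.displacement)):
            raise ValueError("sample_times, surrogate and displacement must align")

    @property
    def duration(self) -> float:
        return float(self.sample_times[-1])

    def displacement_at(self, t) -> np.ndarray:
        """Displacement [mm] at arbitrary times, linearly interpolated."""
        return np.interp(t, self.sample_times, self.displacement)

    def surrogate_at(self, t) -> np.ndarray:
        return np.interp(t, self.sample_times, self.surrogate)


def generate_waveform(
    kind: str,
    breathing_rate_bpm: float,
    amplitude: float,
    duration: float,
    sample_rate: float = 200.0,
    irregularity: float = 0.0,
    seed: int = 0,
) -> MotionWaveform:
    """Generate a respiratory waveform.

    Parameters
    ----------
    kind : {'sinusoidal', 'sawtooth', 'irregular'}
        Sinusoid (S-I platform analog), sawtooth with a rapid 10%% reset
        stroke (A-P analog), or a sinusoid whose per-cycle period and
        exhale depth are jittered by ``irregularity``.
    breathing_rate_bpm : float
        Breaths per minute; the period is ``BP = 60 / bpm`` seconds.
    amplitude : float
        Peak-to-peak displacement [mm].
    duration : float
        Trace length [s]; must cover at least two cycles, otherwise the
        trace cannot be phase sorted.
    irregularity : float
        Fractional per-cycle jitter (irregular kind only): each cycle's
        period and depth are scaled by ``1 + irregularity * u`` with
        ``u ~ U[-1, 1]`` from the seeded generator.

    The trace is deterministic given ``seed``.
    """
    if breathing_rate_bpm <= 0:
        raise ValueError("breathing_rate_bpm must be > 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    bp = 60.0 / breathing_rate_bpm
    if amplitude > 0 and duration < 2 * bp:
        raise ValueError(
            f"insufficient cycles for phase sorting: duration {duration:g} s "
            f"< 2 breathing periods ({2 * bp:g} s)"
        )
    t = np.arange(0.0, duration, 1.0 / sample_rate)

    if kind == "sinusoidal":
        disp = (amplitude / 2.0) * np.sin(2.0 * np.pi * t / bp)
    elif kind == "sawtooth":
        rho = SAWTOOTH_RESET_FRACTION
        f = np.mod(t / bp, 1.0)
        ramp = amplitude / 2.0 - amplitude * f / (1.0 - rho)
        reset = -amplitude / 2.0 + amplitude * (f - (1.0 - rho)) / rho
        disp = np.where(f <= 1.0 - rho, ramp, reset)
    elif kind == "irregular":
        rng = np.random.default_rng(seed)
        n_cycles = int(np.ceil(duration / bp * (1.0 + irregularity))) + 2
        periods = bp * (1.0 + irregularity * rng.uniform(-1.0, 1.0, n_cycles))
        depths = amplitude * (1.0 + irregularity * rng.uniform(-1.0, 1.0, n_cycles))
        starts = np.concatenate([[0.0], np.cumsum(periods)])
        cyc = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, n_cycles - 1)
        phase = (t - starts[cyc]) / periods[cyc]
        # all peaks pinned at +amplitude/2 so cycle boundaries stay continuous;
        # exhale depth varies per cycle
        disp = amplitude / 2.0 - depths[cyc] / 2.0 * (1.0 - np.cos(2.0 * np.pi * phase))
    else:
        raise ValueError("kind must be 'sinusoidal', 'sawtooth' or 'irregular'")

    if amplitude > 0:
        surrogate = 2.0 * disp / amplitude
    else:
        surrogate = np.zeros_like(disp)
    return MotionWaveform(
        kind=kind,
        breathing_period=bp,
        amplitude=float(amplitude),
        sample_times=t,
        surrogate=surrogate,
        displacement=disp,
        seed=seed,
        irregularity=irregularity,
    )


def _object_coverage(obj: PhantomObject, grid: GridSpec, cx: float, cy: float) -> np.ndarray:
    """Pixel coverage (0..1) of one object centered at (cx, cy) [mm]."""
    xs = grid.coords()
    ys = grid.coords()
    px = grid.px
    if obj.shape == "disk":
        r = float(np.atleast_1d(obj.size)[0]) / 2.0
        X, Y = np.meshgrid(xs - cx, ys - cy)
        d = np.hypot(X, Y)
        cov = np.zeros_like(d)
        cov[d <= r - 0.75 * px] = 1.0
        # area-weighted anti-aliasing on the boundary ring: fraction of a
        # 16x16 sub-pixel grid falling inside the disk
        ring = (d > r - 0.75 * px) & (d < r + 0.75 * px)
        if np.any(ring):
            sub = (np.arange(16) + 0.5) / 16.0 - 0.5
            sx, sy = np.meshgrid(sub * px, sub * px)
            rx = X[ring][:, None] + sx.ravel()[None, :]
            ry = Y[ring][:, None] + sy.ravel()[None, :]
            cov[ring] = np.mean(rx**2 + ry**2 <= r**2, axis=1)
    else:
        sizes = np.atleast_1d(np.asarray(obj.size, dtype=float))
        w, h = (sizes[0], sizes[0]) if sizes.size == 1 else (sizes[0], sizes[1])
        # exact per-axis pixel overlap (separable area weighting)
        covx = np.clip(
            (np.minimum(xs + px / 2, cx + w / 2) - np.maximum(xs - px / 2, cx - w / 2)) / px,
            0.0,
            1.0,
        )
        covy = np.clip(
            (np.minimum(ys + px / 2, cy + h / 2) - np.maximum(ys - px / 2, cy - h / 2)) / px,
            0.0,
            1.0,
        )
        cov = np.outer(covy, covx)
    return cov


def _extent(obj: PhantomObject) -> tuple[float, float]:
    sizes = np.atleast_1d(np.asarray(obj.size, dtype=float))
    if obj.shape == "disk" or sizes.size == 1:
        return float(sizes[0]) / 2.0, float(sizes[0]) / 2.0
    return float(sizes[0]) / 2.0, float(sizes[1]) / 2.0


def rasterize(
    objects: Sequence[PhantomObject],
    grid: GridSpec,
    shifts: dict[str, float] | None = None,
) -> np.ndarray:
    """Rasterize objects onto the grid, with optional per-axis shifts [mm].

    ``shifts`` maps motion axis ('SI' -> +y, 'AP' -> +x) to the current
    waveform displacement; each moving object is displaced by that value
    scaled by its own excursion (see :func:`phantom_at_time`).  Objects
    (partially) outside the grid are clipped with a warning.
    """
    shifts = shifts or {}
    img = np.zeros((grid.n, grid.n), dtype=float)
    half_fov = grid.fov_mm / 2.0
    for obj in objects:
        dx = dy = 0.0
        if obj.motion_axis == "SI":
            dy = shifts.get("SI", 0.0)
        elif obj.motion_axis == "AP":
            dx = shifts.get("AP", 0.0)
        cx, cy = obj.center[0] + dx, obj.center[1] + dy
        ex, ey = _extent(obj)
        if abs(cx) + ex > half_fov or abs(cy) + ey > half_fov:
            warnings.warn(
                f"object {obj.label or obj.shape} extends outside the grid; clipping",
                stacklevel=2,
            )
        img += obj.attenuation * _object_coverage(obj, grid, cx, cy)
    return img


def phantom_at_time(
    objects: Sequence[PhantomObject],
    waveform: MotionWaveform,
    t: float,
    grid: GridSpec,
) -> np.ndarray:
    """Attenuation image [1/mm] of the phantom at time ``t``.

    Each moving object is displaced along its axis by the waveform
    displacement scaled by ``excursion / amplitude`` (so objects with
    different excursions share one clock); static objects stay put.
    """
    disp = float(waveform.displacement_at(t))
    img = np.zeros((grid.n, grid.n), dtype=float)
    for obj in objects:
        if obj.motion_axis == "none" or obj.excursion == 0 or waveform.amplitude == 0:
            scale = 0.0
        else:
            scale = obj.excursion / waveform.amplitude
        img += obj.attenuation * _object_coverage(
            obj,
            grid,
            obj.center[0] + (disp * scale if obj.motion_axis == "AP" else 0.0),
            obj.center[1] + (disp * scale if obj.motion_axis == "SI" else 0.0),
        )
    return img


@dataclass(frozen=True)
class SuiteSpec:
    """One factorial phantom study: objects + waveform kind + (bpm, pitch) grid."""

    name: str
    objects: tuple[PhantomObject, ...]
    waveform_kind: str
    breathing_rates_bpm: tuple[float, ...]
    pitches: tuple[float, ...]
    amplitude: float = 30.0

    @property
    def configs(self) -> list[dict]:
        """Full factorial (bpm x pitch) list of run configurations."""
        return [
            {"kind": self.waveform_kind, "bpm": b, "pitch": p, "amplitude": self.amplitude}
            for b in self.breathing_rates_bpm
            for p in self.pitches
        ]


def _suite_objects(axis: str) -> tuple[PhantomObject, ...]:
    slab = PhantomObject(
        shape="rectangle",
        center=(0.0, 0.0),
        size=(300.0, 200.0),
        attenuation=0.001,
        label="slab",
    )
    if axis == "SI":
        movers = (
            PhantomObject("disk", (-60.0, 0.0), 20.0, 0.018, "SI", 30.0, label="disk20"),
            PhantomObject("disk", (60.0, 0.0), 30.0, 0.018, "SI", 30.0, label="disk30"),
        )
    else:
        movers = (
            PhantomObject("disk", (0.0, 40.0), 20.0, 0.018, "AP", 30.0, label="disk20"),
        )
    return (slab,) + movers


def standard_phantom_suite(name: str) -> SuiteSpec:
    """Canonical factorial studies of the virtual motion-platform protocol.

    ``si_sinusoid_grid``
        Objects translated S-I under a sinusoid; breathing rates 10, 12,
        15 and 20 bpm at pitches 0.06, 0.08 and 0.10 (12 configurations).
    ``ap_sawtooth_grid``
        An object translated A-P under a sawtooth; 8, 10 and 12 bpm at the
        same three pitches (9 configurations).
    ``static_truth``
        The same objects held stationary (zero-amplitude waveform); the
        ground truth that residual blur is measured against.
    """
    if name == "si_sinusoid_grid":
        return SuiteSpec(
            name=name,
            objects=_suite_objects("SI"),
            waveform_kind="sinusoidal",
            breathing_rates_bpm=(10.0, 12.0, 15.0, 20.0),
            pitches=(0.06, 0.08, 0.10),
        )
    if name == "ap_sawtooth_grid":
        return SuiteSpec(
            name=name,
            objects=_suite_objects("AP"),
            waveform_kind="sawtooth",
            breathing_rates_bpm=(8.0, 10.0, 12.0),
            pitches=(0.06, 0.08, 0.10),
        )
    if name == "static_truth":
        return SuiteSpec(
            name=name,
            objects=_suite_objects("SI"),
            waveform_kind="sinusoidal",
            breathing_rates_bpm=(12.0,),
            pitches=(0.10,),
            amplitude=0.0,
        )
    raise ValueError(
        "unknown suite; one of 'si_sinusoid_grid', 'ap_sawtooth_grid', 'static_truth'"
    )
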