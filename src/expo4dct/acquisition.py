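"""Time-stamped projection acquisition of the moving phantom.

The forward model is 2-D parallel beam: the gantry angle advances
continuously with time (``theta_k = 2 pi t_k / RT``), one projection every
``RT / projections_per_rotation`` seconds, and each projection is the set
of line integrals of the phantom *as it stands at that instant*.  Couch
motion is not geometrically simulated — pitch enters only through the
temporal gating budget (:mod:`expo4dct.geometry`); this is the central
desk-scale simplification and makes the weighting, which acts purely on
the temporal axis, geometry-agnostic.  Parallel geometry also gives the
exact half-rotation (pi) data-completeness minimum the gating logic
assumes.

Projections of moving content are assembled from per-group reference
sinograms via the shift theorem of the parallel-beam transform: a rigid
translation ``d`` of the content shifts the projection along the detector
by ``d . u`` (``u`` the detector axis), evaluated with linear detector
interpolation.  Static content is assembled without interpolation, so a
static phantom's sinogram is exactly the discrete forward projection of
its rasterized image.

Detector convention: ``n`` samples at the grid's pixel spacing, sample
``n//2`` on the isocenter ray.  Line integrals are in attenuation times mm
(unitless for mu in 1/mm).  Optional zero-mean Gaussian noise is added to
the line integrals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks

from .geometry import ScannerGeometry
from .phantom import GridSpec, MotionWaveform, PhantomObject, rasterize

__all__ = [
    "DynamicSinogram",
    "project_image",
    "acquire",
    "peak_detect",
    "assign_phases",
]


def project_image(image: np.ndarray, angles, px: float) -> np.ndarray:
    """Discrete parallel-beam forward projection of a 2-D image.

    For each angle ``theta`` the image is sampled on the rotated grid
    ``point = s*u + t*v`` (``u = (cos, sin)`` detector axis, ``v`` the ray
    direction), with bilinear interpolation and zero outside, and summed
    along the ray; detector and ray step both equal the pixel spacing.

    Returns an ``(n_angles, n)`` array of line integrals [mu * mm].
    """
    image = np.asarray(image, dtype=float)
    n = image.shape[0]
    if image.shape != (n, n):
        raise ValueError("image must be square")
    c = n // 2
    s = np.arange(n) - c
    t = np.arange(n) - c
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    out = np.empty((len(angles), n), dtype=float)
    for k, theta in enumerate(angles):
        ct, st = np.cos(theta), np.sin(theta)
        X = s[:, None] * ct - t[None, :] * st
        Y = s[:, None] * st + t[None, :] * ct
        vals = map_coordinates(image, [Y + c, X + c], order=1, cval=0.0)
        out[k] = vals.sum(axis=1) * px
    return out


@dataclass(frozen=True)
class DynamicSinogram:
    """Time-stamped projections of a moving phantom, plus phase tags.

    ``data[k]`` is the detector line of the k-th projection, acquired at
    ``times[k]`` with gantry angle index ``angle_indices[k]`` (angle =
    ``2 pi a / projections_per_rotation``).  Phase arrays are filled by
    :func:`assign_phases`.
    """

    data: np.ndarray
    times: np.ndarray
    angle_indices: np.ndarray
    geometry: ScannerGeometry
    grid: GridSpec
    waveform: MotionWaveform
    noise_sigma: float = 0.0
    seed: int = 0
    n_phases: int | None = None
    phase_fraction: np.ndarray | None = None
    phase_bin: np.ndarray | None = None
    cycle_index: np.ndarray | None = None
    peak_times: np.ndarray | None = None

    @property
    def n_projections(self) -> int:
        return self.data.shape[0]

    @property
    def n_detectors(self) -> int:
        return self.data.shape[1]

    @property
    def detector_coords(self) -> np.ndarray:
        """Detector sample positions [mm]."""
        return self.grid.coords()

    @property
    def angles(self) -> np.ndarray:
        """Gantry angle [rad] of each projection."""
        p = self.geometry.projections_per_rotation
        return 2.0 * np.pi * self.angle_indices / p


def acquire(
    objects: Sequence[PhantomObject],
    waveform: MotionWaveform,
    geom: ScannerGeometry,
    grid: GridSpec,
    duration: float | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DynamicSinogram:
    """Simulate a continuous low-pitch acquisition over the moving phantom.

    ``duration`` defaults to the waveform duration and must cover at least
    two breathing cycles (otherwise retrospective sorting is impossible).
    Gaussian noise of ``noise_sigma`` (line-integral units) is added with
    the seeded generator; the run is bit-reproducible given the seed.
    """
    if duration is None:
        duration = waveform.duration
    if waveform.amplitude > 0 and duration < 2 * waveform.breathing_period:
        raise ValueError("duration must cover at least two breathing cycles")
    if duration > waveform.duration + 1e-9:
        raise ValueError("duration exceeds the waveform support")
    p = geom.projections_per_rotation
    if p % 2:
        raise ValueError("projections_per_rotation must be even (conjugate folding)")
    rate = p / geom.rotation_time
    n_proj = int(np.floor(duration * rate))
    times = np.arange(n_proj) / rate
    angle_indices = np.arange(n_proj) % p
    all_angles = 2.0 * np.pi * np.arange(p) / p

    # group objects by (axis, excursion scale); one reference sinogram each
    groups: dict[tuple[str, float], list[PhantomObject]] = {}
    for obj in objects:
        moving = (
            obj.motion_axis != "none" and obj.excursion > 0 and waveform.amplitude > 0
        )
        key = (obj.motion_axis, obj.excursion / waveform.amplitude) if moving else ("none", 0.0)
        groups.setdefault(key, []).append(obj)

    px = grid.px
    s_mm = grid.coords()
    data = np.zeros((n_proj, grid.n), dtype=float)
    disp = waveform.displacement_at(times)
    cos_a = np.cos(all_angles)
    sin_a = np.sin(all_angles)
    for (axis, scale), objs in groups.items():
        base = project_image(rasterize(objs, grid), all_angles, px)
        if axis == "none" or scale == 0.0:
            data += base[angle_indices]
            continue
        # detector shift of a translation d along x is d*cos(theta), along y d*sin(theta)
        trig = cos_a if axis == "AP" else sin_a
        delta = disp * scale * trig[angle_indices]
        for k in range(n_proj):
            data[k] += np.interp(
                s_mm - delta[k], s_mm, base[angle_indices[k]], left=0.0, right=0.0
            )

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sigma, data.shape)

    return DynamicSinogram(
        data=data,
        times=times,
        angle_indices=angle_indices,
        geometry=geom,
        grid=grid,
        waveform=waveform,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def peak_detect(times: np.ndarray, samples: np.ndarray) -> np.ndarray:
    """End-inhale (surrogate maximum) times of a sampled breathing trace.

    Local maxima above the trace mean with prominence at least a quarter
    of the trace range, refined to sub-sample precision by a quadratic fit
    through the peak and its neighbours.  Invariant to adding a constant
    to the trace; deterministic.
    """
    times = np.asarray(times, dtype=float)
    samples = np.asarray(samples, dtype=float)
    rng = samples.max() - samples.min()
    if rng == 0:
        return np.empty(0)
    idx, _ = find_peaks(samples, height=samples.mean(), prominence=0.25 * rng)
    if len(idx) == 0:
        return np.empty(0)
    dt = np.diff(times).mean()
    refined = []
    for i in idx:
        if 0 < i < len(samples) - 1:
            y0, y1, y2 = samples[i - 1], samples[i], samples[i + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            refined.append(times[i] + np.clip(shift, -1, 1) * dt)
        else:
            refined.append(times[i])
    return np.asarray(refined)


def assign_phases(sino: DynamicSinogram, n_phases: int = 10) -> DynamicSinogram:
    """Tag every projection with its respiratory phase.

    Surrogate peaks mark end-inhale; a projection's ``phase_fraction`` is
    its elapsed fraction of the local peak-to-peak interval (extrapolated
    with the edge intervals outside the first/last peak), and its bin is
    ``round(fraction * n_phases) mod n_phases`` — bins are centered, bin 0
    on end-inhale and bin ``n_phases/2`` on end-exhale for symmetric
    waveforms.  Returns a new tagged sinogram.
    """
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    peaks = peak_detect(sino.waveform.sample_times, sino.waveform.surrogate)
    if len(peaks) < 2:
        raise ValueError("cannot phase-sort: fewer than two surrogate peaks")
    t = sino.times
    pos = np.interp(t, peaks, np.arange(len(peaks), dtype=float))
    before = t < peaks[0]
    after = t > peaks[-1]
    pos[before] = (t[before] - peaks[0]) / (peaks[1] - peaks[0])
    pos[after] = (len(peaks) - 1) + (t[after] - peaks[-1]) / (peaks[-1] - peaks[-2])
    frac = np.mod(pos, 1.0)
    cycle = np.floor(pos).astype(int)
    bins = np.mod(np.round(frac * n_phases).astype(int), n_phases)
    return replace(
        sino,
        n_phases=n_phases,
        phase_fraction=frac,
        phase_bin=bins,
        cycle_index=cycle,
        peak_times=peaks,
    )
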