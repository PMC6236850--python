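"""Phase-resolved, temporally weighted filtered backprojection.

For each phase bin the gate is a contiguous run of projections centered on
the *phase point*: the projection whose phase tag lies nearest the bin
center.  Its length is the temporal budget's projection count — the
half-rotation minimum when the breathing-period condition holds, wider
otherwise.  Raw cosine-squared or EXPO weights are laid over the gate,
normalized within ray-redundancy groups (gantry angles folded to [0, pi):
theta and theta + pi measure the same line with the detector flipped), and
applied to ramp-filtered projections before backprojection.  When the gate
sits at the pi minimum no weighting is employed (every ray appears once),
so the two schemes coincide exactly.

The reconstruction grid equals the phantom grid; pixel values are linear
attenuation [1/mm], convertible to HU with :func:`to_hu`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import DynamicSinogram
from .geometry import GatingBudget, gating_budget
from .phantom import GridSpec
from .weighting import (
    DEFAULT_STEEPNESS,
    WeightCurve,
    build_weight_curve,
    normalize_weights,
)

__all__ = [
    "PhaseImage",
    "DerivativeImages",
    "ramp_filter",
    "select_window",
    "reconstruct_phase",
    "reconstruct_4dct",
    "reconstruct_static",
    "derivative_images",
    "to_hu",
]

MU_WATER = 0.019
"""Default linear attenuation of water [1/mm] for the HU scale."""


@dataclass(frozen=True)
class PhaseImage:
    """One reconstructed phase: attenuation grid plus its gate description."""

    pixels: np.ndarray
    phase_bin: int
    scheme: str
    window: tuple[int, int]
    phase_point_index: int
    weight_curve: WeightCurve
    grid: GridSpec


@dataclass(frozen=True)
class DerivativeImages:
    """Voxelwise max / min / mean over the phase stack (MIP, minIP, AVG-CT)."""

    mip: np.ndarray
    minip: np.ndarray
    avg: np.ndarray


def ramp_filter(n: int) -> np.ndarray:
    """Frequency response of the band-limited ramp filter, length ``n``.

    Built as the DFT of the exact spatial-domain ramp kernel
    (h[0] = 1/4, h[odd] = -1/(pi k)^2, h[even] = 0) rather than |f|
    directly, which avoids the DC bias of the naive discretization.
    """
    kern = np.zeros(n)
    kern[0] = 0.25
    odd = np.arange(1, n // 2 + 1, 2)
    kern[odd] = -1.0 / (np.pi * odd) ** 2
    kern[-odd] = -1.0 / (np.pi * odd) ** 2
    return 2.0 * np.real(np.fft.fft(kern))


def _filter_rows(rows: np.ndarray) -> np.ndarray:
    """Ramp-filter detector lines (rows), unit sample spacing."""
    n = rows.shape[-1]
    size = max(64, int(2 ** np.ceil(np.log2(2 * n))))
    resp = ramp_filter(size)
    padded = np.zeros(rows.shape[:-1] + (size,))
    padded[..., :n] = rows
    return np.real(np.fft.ifft(np.fft.fft(padded, axis=-1) * resp, axis=-1))[..., :n]


def select_window(
    sino: DynamicSinogram, phase_bin: int, budget: GatingBudget | None = None
) -> tuple[int, int, int]:
    """Choose the contiguous projection gate for one phase bin.

    Returns ``(start, stop, phase_point)``: the window ``[start, stop)`` of
    the budget's projection count, centered on the projection whose phase
    fraction is nearest the bin center among those the window fits around
    (earliest on ties).

    Raises
    ------
    ValueError
        If the sinogram is not phase-tagged, or no placement of the window
        fits inside the acquisition ("insufficient acquisition duration").
    """
    if sino.phase_fraction is None or sino.n_phases is None:
        raise ValueError("sinogram is not phase-tagged; run assign_phases first")
    if budget is None:
        budget = gating_budget(sino.geometry, sino.waveform.breathing_period)
    it = budget.window_projection_count
    n = sino.n_projections
    if it > n:
        raise ValueError(
            f"insufficient acquisition duration: window needs {it} projections, "
            f"acquisition has {n}"
        )
    center_frac = phase_bin / sino.n_phases
    dist = np.abs(sino.phase_fraction - center_frac)
    dist = np.minimum(dist, 1.0 - dist)  # circular
    half = it // 2
    fits = (np.arange(n) >= half) & (np.arange(n) - half + it <= n)
    if not np.any(fits):
        raise ValueError("insufficient acquisition duration: window never fits")
    masked = np.where(fits, dist, np.inf)
    center = int(np.argmin(masked))  # argmin takes the earliest on ties
    start = center - half
    return start, start + it, center


def _weighted_fbp(
    sino: DynamicSinogram,
    start: int,
    stop: int,
    weights_norm: np.ndarray,
) -> np.ndarray:
    """Backbone: normalized per-projection weights -> attenuation image."""
    geom, grid = sino.geometry, sino.grid
    p = geom.projections_per_rotation
    n_half = p // 2
    n_det = sino.n_detectors

    # fold weighted projections into per-angle rows (backprojection is linear)
    rows = np.zeros((p, n_det))
    aidx = sino.angle_indices[start:stop]
    np.add.at(rows, aidx, weights_norm[:, None] * sino.data[start:stop])
    active = np.flatnonzero(np.abs(rows).max(axis=1) > 0)

    q = _filter_rows(rows[active] / grid.px)  # unit-spacing filtering

    c = grid.n // 2
    xy = np.arange(grid.n) - c
    X, Y = np.meshgrid(xy, xy)  # pixel units; X = cols (x), Y = rows (y)
    det = np.arange(n_det) - c
    image = np.zeros((grid.n, grid.n))
    angles = 2.0 * np.pi * active / p
    for row, theta in zip(q, angles):
        s = X * np.cos(theta) + Y * np.sin(theta)
        image += np.interp(s, det, row, left=0.0, right=0.0)
    return image * (np.pi / (2.0 * n_half))


def reconstruct_phase(
    sino: DynamicSinogram,
    phase_bin: int,
    scheme: str = "expo",
    steepness: float = DEFAULT_STEEPNESS,
    budget: GatingBudget | None = None,
    exp_center: int | None = None,
) -> PhaseImage:
    """Weighted FBP of one phase bin.

    ``scheme`` is 'cosine_squared', 'expo' or 'uniform'; whenever the gate
    equals the half-rotation minimum the curve degrades to uniform (no
    weighting is employed at the pi minimum), making the schemes
    bit-identical there.
    """
    if budget is None:
        budget = gating_budget(sino.geometry, sino.waveform.breathing_period)
    start, stop, center = select_window(sino, phase_bin, budget)
    it = stop - start
    eff_scheme = scheme if it > budget.minimum_projection_count else "uniform"
    curve = build_weight_curve(it, eff_scheme, steepness, exp_center)
    labels = sino.angle_indices[start:stop] % (sino.geometry.projections_per_rotation // 2)
    w_norm = normalize_weights(curve.weights, labels)
    pixels = _weighted_fbp(sino, start, stop, w_norm)
    return PhaseImage(
        pixels=pixels,
        phase_bin=phase_bin,
        scheme=scheme,
        window=(start, stop),
        phase_point_index=center,
        weight_curve=curve,
        grid=sino.grid,
    )


def reconstruct_4dct(
    sino: DynamicSinogram,
    n_phases: int | None = None,
    scheme: str = "expo",
    steepness: float = DEFAULT_STEEPNESS,
    budget: GatingBudget | None = None,
) -> list[PhaseImage]:
    """Map :func:`reconstruct_phase` over all phase bins (deterministic)."""
    if n_phases is None:
        if sino.n_phases is None:
            raise ValueError("n_phases not given and sinogram is untagged")
        n_phases = sino.n_phases
    elif sino.n_phases != n_phases:
        from .acquisition import assign_phases

        sino = assign_phases(sino, n_phases)
    return [
        reconstruct_phase(sino, b, scheme, steepness, budget) for b in range(n_phases)
    ]


def reconstruct_static(sino: DynamicSinogram) -> np.ndarray:
    """Plain FBP from the first half rotation (the static ground truth).

    Bypasses phase sorting — a stationary phantom has no surrogate peaks —
    and reconstructs from the minimum pi gate with uniform weights, so the
    static image carries the same reconstruction point-spread function as
    the phase images it is compared against.
    """
    m = sino.geometry.projections_per_rotation // 2
    if sino.n_projections < m:
        raise ValueError("acquisition shorter than a half rotation")
    return _weighted_fbp(sino, 0, m, np.ones(m))


def derivative_images(phases: list[PhaseImage] | list[np.ndarray]) -> DerivativeImages:
    """MIP / minIP / AVG-CT: voxelwise max, min and mean over the phases."""
    if len(phases) == 0:
        raise ValueError("need at least one phase image")
    arrs = [p.pixels if isinstance(p, PhaseImage) else np.asarray(p) for p in phases]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("phase images must share one grid")
    stack = np.stack(arrs)
    return DerivativeImages(
        mip=stack.max(axis=0), minip=stack.min(axis=0), avg=stack.mean(axis=0)
    )


def to_hu(image: np.ndarray, mu_water: float = MU_WATER) -> np.ndarray:
    """Hounsfield scale: ``HU = 1000 (mu - mu_water) / mu_water``."""
    if mu_water <= 0:
        raise ValueError("mu_water must be > 0")
    return 1000.0 * (np.asarray(image, dtype=float) - mu_water) / mu_water
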