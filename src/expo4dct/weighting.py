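"""Temporal weighting of the gating window: cosine-squared and EXPO.

When the gating window is wider than the half-rotation minimum, the extra
(temporally redundant) projections degrade temporal resolution.  The
conventional remedy is a cosine-squared taper across the window,

    W(i) = cos^2( pi * (i - I_m) / I_t ),

where ``I_t`` is the window length in projections and ``I_m`` the
mid-phase (reconstruction phase point) index.  The EXPO weight multiplies
this taper by a decaying exponential,

    EXPO(i) = cos^2( pi * (i - I_m) / I_t ) * exp( -|i - I_h| * E_f / I_t ),

whose steepness ``E_f`` (clinical default 2.0) further suppresses
projections far from the phase point, trading residual motion blur for a
modest noise increase.  ``I_h`` defaults to ``I_m`` so the exponential
peaks at the phase point.

Weights are raw, in [0, 1]; :func:`normalize_weights` rescales them within
ray-redundancy groups (projections measuring the same line) so each ray is
reconstructed from unit total weight.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SCHEMES",
    "WeightCurve",
    "cosine_squared_weight",
    "exponential_term",
    "expo_weight",
    "build_weight_curve",
    "normalize_weights",
    "effective_temporal_width",
]

SCHEMES = ("cosine_squared", "expo", "uniform")

DEFAULT_STEEPNESS = 2.0
"""Clinical default E_f; fixed in clinical mode, exposed for research."""


def cosine_squared_weight(i, mid_phase, total):
    """Raw cosine-squared weight of projection ``i`` in a window of ``total``.

    1 at the mid-phase point, 0 at the window edges (offset ``total/2``);
    indices outside the window get weight 0 (the projection is not used).
    Accepts scalars or arrays.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    offset = np.asarray(i, dtype=float) - mid_phase
    w = np.cos(np.pi * offset / total) ** 2
    w = np.where(np.abs(offset) <= total / 2.0, w, 0.0)
    return w if w.ndim else float(w)


def exponential_term(i, center, total, steepness):
    """Exponential factor ``exp(-|i - center| * E_f / total)``.

    1 at the center, strictly decreasing with distance for ``E_f > 0``;
    ``E_f = 0`` degenerates to 1 everywhere (EXPO -> cosine-squared).
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if steepness < 0:
        raise ValueError("steepness must be >= 0")
    term = np.exp(-np.abs(np.asarray(i, dtype=float) - center) * steepness / total)
    return term if term.ndim else float(term)


def expo_weight(i, mid_phase, exp_center, total, steepness=DEFAULT_STEEPNESS):
    """EXPO weight: cosine-squared taper times the exponential factor.

    Pointwise <= the cosine-squared weight whenever ``steepness >= 0``.
    """
    return cosine_squared_weight(i, mid_phase, total) * exponential_term(
        i, exp_center, total, steepness
    )


@dataclass(frozen=True)
class WeightCurve:
    """A per-projection weight curve over one gating window.

    ``weights[i]`` is the raw weight of the window's i-th projection,
    ``mid_phase_index`` the phase point (``I_m``), ``exp_center_index`` the
    exponential center (``I_h``, = ``I_m`` by default), ``steepness`` the
    EXPO ``E_f``.
    """

    total_projections: int
    mid_phase_index: int
    exp_center_index: int
    steepness: float
    weights: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; one of {SCHEMES}")
        if len(self.weights) != self.total_projections:
            raise ValueError("weights length must equal total_projections")

    def with_weights(self, weights: np.ndarray) -> "WeightCurve":
        return replace(self, weights=np.asarray(weights, dtype=float))


def build_weight_curve(
    total: int,
    scheme: str = "expo",
    steepness: float = DEFAULT_STEEPNESS,
    exp_center: int | None = None,
) -> WeightCurve:
    """Build the raw weight curve for a window of ``total`` projections.

    The mid-phase index is ``total // 2`` (the projection the window is
    centered on).  ``scheme='uniform'`` gives all-ones — the no-weighting
    case used when the window sits at its half-rotation minimum.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; one of {SCHEMES}")
    mid = total // 2
    center = mid if exp_center is None else int(exp_center)
    idx = np.arange(total)
    if scheme == "uniform":
        w = np.ones(total, dtype=float)
    elif scheme == "cosine_squared":
        w = cosine_squared_weight(idx, mid, total)
    else:
        w = expo_weight(idx, mid, center, total, steepness)
    return WeightCurve(
        total_projections=total,
        mid_phase_index=mid,
        exp_center_index=center,
        steepness=float(steepness),
        weights=w,
        scheme=scheme,
    )


def normalize_weights(weights: np.ndarray, group_labels: np.ndarray) -> np.ndarray:
    """Rescale weights so each ray-redundancy group sums to one.

    ``group_labels[i]`` identifies the ray (e.g. the gantry angle folded to
    [0, pi)) measured by window projection ``i``; projections sharing a
    label are redundant measurements of the same line integral and their
    normalized weights must sum to 1 so every ray carries unit total weight
    into the backprojection.  Relative ordering within a group is preserved.

    Raises
    ------
    ValueError
        If some group's raw weights sum to zero (no usable data for that
        ray).
    """
    w = np.asarray(weights, dtype=float)
    labels = np.asarray(group_labels)
    if w.shape != labels.shape:
        raise ValueError("weights and group_labels must have the same shape")
    uniq, inverse = np.unique(labels, return_inverse=True)
    sums = np.bincount(inverse, weights=w, minlength=len(uniq))
    if np.any(sums <= 0):
        bad = uniq[sums <= 0]
        raise ValueError(f"insufficient data for ray group(s) {bad!r}: zero total weight")
    return w / sums[inverse]


def effective_temporal_width(curve: WeightCurve | np.ndarray) -> float:
    """Full width at half maximum of a weight curve, in projections.

    Crossings of half the curve maximum are located by linear interpolation
    between indices.  Where the curve never falls below half maximum on a
    side (e.g. the uniform curve), the support edge (+-0.5 beyond the last
    index) is used, so a uniform curve of length n has width n.
    """
    w = curve.weights if isinstance(curve, WeightCurve) else np.asarray(curve, float)
    n = len(w)
    if n == 0 or np.all(w == 0):
        raise ValueError("degenerate weight curve")
    half = w.max() / 2.0
    peak = int(np.argmax(w))

    left = -0.5
    for j in range(peak, 0, -1):
        if w[j - 1] < half <= w[j]:
            left = (j - 1) + (half - w[j - 1]) / (w[j] - w[j - 1])
            break
    right = n - 0.5
    for j in range(peak, n - 1):
        if w[j + 1] < half <= w[j]:
            right = j + (w[j] - half) / (w[j] - w[j + 1])
            break
    return float(right - left)
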