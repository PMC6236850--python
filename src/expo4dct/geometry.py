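"""Helical-acquisition temporal budget for respiration-gated CT.

In low-pitch helical 4DCT every longitudinal (z) position must remain
inside the collimated beam for at least one full breathing period so that
each respiratory phase can be reconstructed everywhere in the field of
view.  The worst-off voxels sit at the edge of the FOV, where the beam
footprint projected from the source is narrowest.  This module computes
that budget: the visible length ``Z_m`` along z at the FOV edge, the couch
velocity ``V``, the transit time ``TT = Z_m / V``, the resulting upper
bounds on breathing period (at fixed pitch) and pitch (at fixed breathing
period), and — when the bound is violated — how many extra seconds of
projection data (``T_w``) the reconstruction gate must absorb and how many
projections that corresponds to.

All lengths are millimetres, all times seconds, pitch is unitless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ScannerGeometry",
    "GatingBudget",
    "StaticCouchError",
    "visibility_length",
    "couch_velocity",
    "transit_time",
    "max_breathing_period",
    "max_pitch",
    "window_widening",
    "minimum_projection_count",
    "window_projection_count",
    "gating_budget",
]


class StaticCouchError(ValueError):
    """Couch velocity is zero: transit time is unbounded."""


@dataclass(frozen=True)
class ScannerGeometry:
    """Scanner/acquisition geometry.

    Parameters
    ----------
    source_isocenter_distance : float
        Source to isocenter distance ``R_S`` [mm].
    fov : float
        Reconstruction field of view diameter [mm]; must be < 2*R_S.
    collimation : float
        Longitudinal beam width at isocenter ``COLL`` [mm].
    rotation_time : float
        Gantry rotation time ``RT`` [s].
    pitch : float
        Unitless pitch factor ``PF`` (couch travel per rotation / COLL).
    projections_per_rotation : int
        Angular sampling; projections acquired per full gantry rotation.
    """

    source_isocenter_distance: float = 570.0
    fov: float = 500.0
    collimation: float = 24.0
    rotation_time: float = 0.5
    pitch: float = 0.1
    projections_per_rotation: int = 720

    def __post_init__(self) -> None:
        if self.source_isocenter_distance <= 0:
            raise ValueError("source_isocenter_distance must be > 0")
        if self.fov <= 0:
            raise ValueError("fov must be > 0")
        if self.fov >= 2 * self.source_isocenter_distance:
            raise ValueError(
                "fov must be smaller than twice the source-isocenter distance "
                "(otherwise the FOV edge is never illuminated)"
            )
        if self.collimation <= 0:
            raise ValueError("collimation must be > 0")
        if self.rotation_time <= 0:
            raise ValueError("rotation_time must be > 0")
        if self.pitch < 0:
            raise ValueError("pitch must be >= 0")
        if self.projections_per_rotation < 2:
            raise ValueError("projections_per_rotation must be >= 2")


@dataclass(frozen=True)
class GatingBudget:
    """Everything the gate-selection step needs, for one breathing period.

    ``window_widening`` is zero exactly when the breathing-period condition
    holds, in which case ``window_projection_count`` equals the half-rotation
    minimum.
    """

    visibility_length: float
    couch_velocity: float
    transit_time: float
    max_breathing_period: float
    window_widening: float
    window_projection_count: int
    minimum_projection_count: int

    @property
    def condition_satisfied(self) -> bool:
        """True when the breathing period fits inside the transit time."""
        return self.window_widening == 0.0


def visibility_length(geom: ScannerGeometry) -> float:
    """Visible length ``Z_m`` [mm] along z at the edge of the FOV.

    ``Z_m = (R_S - FOV/2) * COLL / R_S``: the collimated beam, projected
    from the source, narrows towards the FOV edge by the similar-triangle
    factor ``(R_S - FOV/2)/R_S``.
    """
    rs = geom.source_isocenter_distance
    return (rs - geom.fov / 2.0) * geom.collimation / rs


def couch_velocity(geom: ScannerGeometry) -> float:
    """Couch velocity ``V = PF * COLL / RT`` [mm/s]."""
    return geom.pitch * geom.collimation / geom.rotation_time


def transit_time(geom: ScannerGeometry) -> float:
    """Time ``TT = Z_m / V`` [s] a FOV-edge voxel stays inside the beam.

    Raises
    ------
    StaticCouchError
        If the couch velocity is zero (pitch 0): the voxel never leaves
        the beam and the transit time is unbounded.
    """
    v = couch_velocity(geom)
    if v == 0.0:
        raise StaticCouchError("static couch: transit time is unbounded")
    return visibility_length(geom) / v


def max_breathing_period(geom: ScannerGeometry) -> float:
    """Largest breathing period [s] fully illuminated at the FOV edge.

    ``BP <= (R_S - FOV/2)/R_S * RT/PF``.  Algebraically identical to the
    transit time; a breathing waveform satisfies the full-illumination
    condition iff its period does not exceed the returned bound.
    """
    if geom.pitch == 0.0:
        raise StaticCouchError(
            "pitch is zero: any breathing period is fully illuminated"
        )
    rs = geom.source_isocenter_distance
    return (rs - geom.fov / 2.0) / rs * geom.rotation_time / geom.pitch


def max_pitch(geom: ScannerGeometry, breathing_period: float) -> float:
    """Largest pitch satisfying full illumination for ``breathing_period``.

    ``PF <= (1 - FOV/(2 R_S)) * RT / BP``.  Round-trips with
    :func:`max_breathing_period`: plugging the bound back reproduces BP.
    """
    if breathing_period <= 0:
        raise ValueError("breathing_period must be > 0")
    rs = geom.source_isocenter_distance
    return (1.0 - geom.fov / (2.0 * rs)) * geom.rotation_time / breathing_period


def window_widening(geom: ScannerGeometry, breathing_period: float) -> float:
    """Extra gate duration ``T_w`` [s] needed when the BP bound is violated.

    ``T_w = BP - RT/PF * (1 - FOV/(2 R_S))``, clamped at zero when the
    condition is satisfied (a negative widening is unphysical; at or below
    the bound the gate stays at its half-rotation minimum).
    """
    if breathing_period <= 0:
        raise ValueError("breathing_period must be > 0")
    tw = breathing_period - max_breathing_period(geom)
    return max(0.0, tw)


def minimum_projection_count(geom: ScannerGeometry) -> int:
    """Half-rotation (pi) projection minimum for a parallel-beam image."""
    return math.ceil(geom.projections_per_rotation / 2)


def window_projection_count(geom: ScannerGeometry, breathing_period: float) -> int:
    """Projections in the temporal gate for one phase reconstruction.

    The half-rotation minimum plus the widening ``T_w`` converted to
    projections at the scanner's uniform sampling rate
    ``projections_per_rotation / RT`` (the vendor's discretization is not
    public; a linear mapping is assumed), rounded up.
    """
    tw = window_widening(geom, breathing_period)
    rate = geom.projections_per_rotation / geom.rotation_time
    count = math.ceil(geom.projections_per_rotation / 2 + tw * rate)
    return max(count, minimum_projection_count(geom))


def gating_budget(geom: ScannerGeometry, breathing_period: float) -> GatingBudget:
    """Bundle the full temporal budget for one geometry + breathing period."""
    return GatingBudget(
        visibility_length=visibility_length(geom),
        couch_velocity=couch_velocity(geom),
        transit_time=transit_time(geom),
        max_breathing_period=max_breathing_period(geom),
        window_widening=window_widening(geom, breathing_period),
        window_projection_count=window_projection_count(geom, breathing_period),
        minimum_projection_count=minimum_projection_count(geom),
    )
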