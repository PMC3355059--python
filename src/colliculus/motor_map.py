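"""Log-polar coordinate transforms of the superior-colliculus motor map.

The deeper SC layers hold a retinotopically organized map of saccade
vectors: rostral sites encode small saccades, caudal sites large ones,
and direction is laid out along the medial-lateral axis.  Following
Ottes, Van Gisbergen & Eggermont (1986), a saccade vector with amplitude
``R`` (deg) and direction ``Phi`` (deg CCW from rightward horizontal)
maps onto Cartesian map coordinates ``(u, v)`` (mm) through a complex
logarithm::

    u = B_u * ln( sqrt(R^2 + 2*A*R*cos(Phi) + A^2) / A )
    v = B_v * atan2( R*sin(Phi), R*cos(Phi) + A )

with ``A`` = 3.0 deg, ``B_u`` = 1.4 mm and ``B_v`` = 1.8 mm/rad for the
monkey SC.  The efferent (inverse) map follows from
``R * exp(i*Phi) = A * (exp(u/B_u + i*v/B_v) - 1)``.

Angles are degrees at every public interface; conversion to radians
happens only inside the formulas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SaccadeVector",
    "MapPoint",
    "MapParams",
    "DEFAULT_MAP",
    "afferent_map",
    "efferent_map",
    "rotate_to_horizontal",
    "map_distance",
]


def _normalize_degrees(phi: float) -> float:
    """Wrap an angle into (-180, 180]."""
    phi = math.fmod(phi, 360.0)
    if phi <= -180.0:
        phi += 360.0
    elif phi > 180.0:
        phi -= 360.0
    return phi


@dataclass(frozen=True)
class SaccadeVector:
    """A saccade displacement in polar visual coordinates.

    Attributes
    ----------
    R : float
        Amplitude in degrees of visual angle; must be >= 0.
    Phi : float
        Direction in degrees CCW from the rightward horizontal meridian,
        normalized to (-180, 180].
    """

    R: float
    Phi: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.R) or not np.isfinite(self.Phi):
            raise ValueError("saccade vector components must be finite")
        if self.R < 0:
            raise ValueError(f"amplitude R must be >= 0, got {self.R}")
        object.__setattr__(self, "Phi", _normalize_degrees(float(self.Phi)))

    @property
    def xy(self) -> tuple[float, float]:
        phi = math.radians(self.Phi)
        return (self.R * math.cos(phi), self.R * math.sin(phi))


@dataclass(frozen=True)
class MapPoint:
    """Cartesian motor-map coordinates: u rostral-caudal, v medial-lateral (mm)."""

    u: float
    v: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u) and np.isfinite(self.v)):
            raise ValueError("map coordinates must be finite")


@dataclass(frozen=True)
class MapParams:
    """Geometry of the log-polar motor map.

    A (deg) sets the foveal magnification rolloff, B_u (mm) the
    rostral-caudal scale and B_v (mm/rad) the medial-lateral scale.
    """

    A: float = 3.0
    B_u: float = 1.4
    B_v: float = 1.8

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.B_u > 0 and self.B_v > 0):
            raise ValueError("map parameters must all be positive")


DEFAULT_MAP = MapParams()


def afferent_map(vec: SaccadeVector, p: MapParams = DEFAULT_MAP) -> MapPoint:
    """Map a saccade vector from visual space onto the motor map.

    Continuous and injective on the open contralateral hemifield.
    Directions beyond +-170 deg approach the map's branch cut; a warning
    is issued there because the represented hemifield ends.
    """
    if abs(vec.Phi) > 170.0 and vec.R > 1.0:
        warnings.warn(
            f"direction {vec.Phi:.1f} deg lies outside the reliably "
            "represented contralateral hemifield",
            stacklevel=2,
        )
    phi = math.radians(vec.Phi)
    x = vec.R * math.cos(phi) + p.A
    y = vec.R * math.sin(phi)
    u = p.B_u * math.log(math.hypot(x, y) / p.A)
    v = p.B_v * math.atan2(y, x)
    return MapPoint(u, v)


def efferent_map(pt: MapPoint, p: MapParams = DEFAULT_MAP) -> SaccadeVector:
    """Map a motor-map site back to its saccade vector (inverse of afferent_map)."""
    z = p.A * (np.exp(pt.u / p.B_u + 1j * pt.v / p.B_v) - 1.0)
    R = abs(z)
    Phi = math.degrees(np.angle(z)) if R > 0 else 0.0
    return SaccadeVector(R, Phi)


def rotate_to_horizontal(vec: SaccadeVector, phi_pref: float) -> SaccadeVector:
    """Rotate a saccade vector clockwise by a cell's preferred direction.

    Used when pooling across cells: each cell's preferred vector is
    rotated onto the rightward horizontal meridian, and every saccade of
    that cell is rotated by the same amount.  Amplitude is unchanged.
    """
    return SaccadeVector(vec.R, vec.Phi - phi_pref)


def map_distance(a: MapPoint, b: MapPoint) -> float:
    """Euclidean distance between two motor-map sites, in mm."""
    return math.hypot(a.u - b.u, a.v - b.v)
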