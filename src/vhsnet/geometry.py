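"""Pure geometry of vertebral heart scale (VHS) scoring.

The VHS index expresses cardiac size in vertebral-length units.  Six
anatomical landmarks define it on a lateral thoracic radiograph:

* ``A``, ``B`` — endpoints of the heart's long axis (carina to apex),
* ``C``, ``D`` — endpoints of the short axis, drawn perpendicular to the
  long axis at the widest point of the cardiac silhouette,
* ``E``, ``F`` — the vertebral reference segment, from the cranial aspect
  of the fourth thoracic vertebra (T4) to the caudal end of the ninth,
  i.e. six vertebral lengths.

Then ``VHS = 6 * (|AB| + |CD|) / |EF|``.  Hearts with VHS below 8.2 are
small, between 8.2 and 10 (inclusive) normal, and above 10 enlarged
(cardiomegaly).

Coordinates are pixels in the source image: x grows rightward, y grows
downward, origin at the top-left corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateGeometryError, DomainError, FormatError

#: Number of vertebral lengths spanned by the reference segment E–F.
VERTEBRAL_SPAN = 6.0

#: Below this y-difference between A and B (pixels) the slope rule for the
#: short axis is undefined and the symmetric x-replacement rule is used.
SLOPE_EPS = 1e-6


@dataclass(frozen=True)
class Point:
    """A 2-D image point in pixel coordinates (y grows downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise DomainError(f"point coordinates must be finite, got ({self.x}, {self.y})")


@dataclass(frozen=True)
class KeyPointSet:
    """The six VHS landmarks A–F (see module docstring for anatomy)."""

    A: Point
    B: Point
    C: Point
    D: Point
    E: Point
    F: Point

    def translated(self, dx: float, dy: float) -> "KeyPointSet":
        return KeyPointSet(*(Point(p.x + dx, p.y + dy) for p in self))

    def __iter__(self):
        return iter((self.A, self.B, self.C, self.D, self.E, self.F))


@dataclass(frozen=True)
class VhsThresholds:
    """Class boundaries on the VHS scale (small < low <= normal <= high < large)."""

    low: float = 8.2
    high: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise DomainError(f"thresholds must satisfy 0 < low < high, got {self.low}, {self.high}")


DEFAULT_THRESHOLDS = VhsThresholds()

CLASS_NAMES = ("small", "normal", "large")


def segment_length(p: Point, q: Point) -> float:
    """Euclidean length of the segment from ``p`` to ``q`` in pixels."""
    return math.hypot(p.x - q.x, p.y - q.y)


def vhs_score(kps: KeyPointSet, *, span: float = VERTEBRAL_SPAN, ef_tol: float = 1e-9) -> float:
    """Vertebral heart scale ``span * (|AB| + |CD|) / |EF|``.

    The score is dimensionless, hence invariant under rotation, translation
    and uniform scaling of all six points.

    Raises
    ------
    DegenerateGeometryError
        If the vertebral segment E–F is shorter than ``ef_tol`` pixels.
    """
    ef = segment_length(kps.E, kps.F)
    if ef <= ef_tol:
        raise DegenerateGeometryError(f"vertebral segment EF has length {ef!r}; VHS is undefined")
    return span * (segment_length(kps.A, kps.B) + segment_length(kps.C, kps.D)) / ef


def orthogonalize(kps: KeyPointSet, *, eps: float = SLOPE_EPS) -> KeyPointSet:
    """Project the short axis so that CD is exactly perpendicular to AB.

    Only ``D`` changes.  With ``(x1,y1),(x2,y2),(x3,y3),(x4,y4)`` the
    coordinates of A, B, C, D, the slope of the corrected short axis is
    ``s = -(x1-x2)/(y1-y2)`` and D's ordinate is replaced by
    ``y4_hat = s*(x4-x3) + y3``.

    When AB is horizontal (``|y1-y2| < eps``) that slope is undefined; the
    symmetric rule is applied instead — D's abscissa is replaced by C's —
    which likewise makes CD (now vertical) perpendicular to AB.

    The map is an exact fixed point on its own output (idempotent).
    """
    x1, y1 = kps.A.x, kps.A.y
    x2, y2 = kps.B.x, kps.B.y
    x3, y3 = kps.C.x, kps.C.y
    x4, y4 = kps.D.x, kps.D.y
    if abs(y1 - y2) < eps:
        return replace(kps, D=Point(x3, y4))
    s = -(x1 - x2) / (y1 - y2)
    return replace(kps, D=Point(x4, s * (x4 - x3) + y3))


def classify_vhs(vhs: float, thresholds: VhsThresholds = DEFAULT_THRESHOLDS) -> int:
    """Three-way cardiac size class from a VHS value.

    Returns 0 (small) for ``vhs < low``, 1 (normal) for
    ``low <= vhs <= high`` — both boundaries inclusive — and 2 (large)
    otherwise.  Monotonically non-decreasing in ``vhs``.
    """
    if not math.isfinite(vhs) or vhs <= 0.0:
        raise DomainError(f"VHS must be a positive finite number, got {vhs!r}")
    if vhs < thresholds.low:
        return 0
    if vhs <= thresholds.high:
        return 1
    return 2


def classify_vhs_array(vhs, thresholds: VhsThresholds = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Vectorized :func:`classify_vhs` (no positivity check; clips nothing)."""
    v = np.asarray(vhs, dtype=float)
    return (v >= thresholds.low).astype(np.int64) + (v > thresholds.high).astype(np.int64)


#: Flattening order of the 12-vector representation.
FLAT_ORDER = ("Ax", "Ay", "Bx", "By", "Cx", "Cy", "Dx", "Dy", "Ex", "Ey", "Fx", "Fy")


def flatten(kps: KeyPointSet) -> np.ndarray:
    """KeyPointSet -> 12-vector ``(Ax, Ay, Bx, By, ..., Fx, Fy)``."""
    return np.array([c for p in kps for c in (p.x, p.y)], dtype=float)


def unflatten(vec) -> KeyPointSet:
    """12-vector -> KeyPointSet; inverse of :func:`flatten`."""
    v = np.asarray(vec, dtype=float).ravel()
    if v.shape != (12,):
        raise FormatError(f"expected a 12-element coordinate vector, got shape {np.asarray(vec).shape}")
    pts = [Point(float(v[i]), float(v[i + 1])) for i in range(0, 12, 2)]
    return KeyPointSet(*pts)
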