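"""Planar geometry turning labeled knee landmarks into positioning QC criteria.

Knee radiograph positioning is judged here by three quantities derived from
nine anatomical landmarks (labels ``A``–``I``):

* **AP overlap ratio** — on an anteroposterior view, the fraction of the
  fibular head's transverse extent (measured perpendicular to the fibular
  shaft axis ``L1``, the line through ``A`` and ``B``) that is covered by the
  tibia.  ``C`` is the head point closest to the tibia, ``D`` the furthest,
  and ``E`` the point where the tibial edge crosses the head.
* **LAT overlap ratio** — the same construction on a lateral view.
* **LAT flexion angle** — on a lateral view, the angle between the femoral
  shaft axis ``L2`` (through ``F`` and ``G``) and the tibial shaft axis
  ``L3`` (through ``H`` and ``I``); a fully extended limb reads 180 degrees.

Coordinates are 0-based pixel centers with ``x`` the image column and ``y``
the image row; this convention is shared by every reader and writer in the
package.

Distances to ``L1`` are signed, with the side containing ``C`` taken as
positive.  The overlap ratio is then the single expression
``(Sc - Se) / (Sc - Sd)`` regardless of which side of the shaft axis ``E``
falls on: when ``E`` lies opposite ``C`` its signed distance is negative and
the ratio grows past the midpoint, exactly as the two printed same-side /
opposite-side branches require.  The ratio is clamped to [0, 1] (its stated
range); clamping is reported so callers can flag it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "AP_LABELS",
    "LAT_ONLY_LABELS",
    "LABELS",
    "View",
    "Point2D",
    "Keypoint",
    "KeypointSet",
    "Line2D",
    "QCResult",
    "GeometryError",
    "CoincidentPointsError",
    "DegenerateGeometryError",
    "fit_line",
    "signed_distance",
    "overlap_ratio",
    "flexion_angle",
    "compute_qc",
]

#: Landmarks present on both views (fibular shaft A/B, fibular head C/D/E).
AP_LABELS: tuple[str, ...] = ("A", "B", "C", "D", "E")
#: Landmarks only annotated on lateral views (femoral shaft F/G, tibial shaft H/I).
LAT_ONLY_LABELS: tuple[str, ...] = ("F", "G", "H", "I")
#: Full landmark alphabet, in canonical (heatmap-channel) order.
LABELS: tuple[str, ...] = AP_LABELS + LAT_ONLY_LABELS

#: Two points closer than this (pixels) are considered coincident.  Far below
#: annotation precision.
COINCIDENT_TOL = 1e-9

#: Width of the flexion-angle range used for normalization (degrees).
FLEXION_RANGE_DEG = 180.0


class View(str, Enum):
    """Radiographic projection: anteroposterior or lateral."""

    AP = "AP"
    LAT = "LAT"


class GeometryError(ValueError):
    """Base class for geometric precondition violations."""


class CoincidentPointsError(GeometryError):
    """Two points meant to define a line are (numerically) identical."""


class DegenerateGeometryError(GeometryError):
    """The keypoint configuration admits no well-defined criterion."""


@dataclass(frozen=True)
class Point2D:
    """A 2-D image point; ``x`` is the column, ``y`` the row (0-based)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite point ({self.x}, {self.y})")

    def __sub__(self, other: "Point2D") -> tuple[float, float]:
        return (self.x - other.x, self.y - other.y)

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class Keypoint:
    """A labeled landmark.  An invisible keypoint carries no trusted position."""

    label: str
    position: Point2D
    visible: bool = True

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise GeometryError(f"unknown keypoint label {self.label!r}")


@dataclass
class KeypointSet:
    """All landmarks of one image, tied to its projection view.

    AP sets carry visible ``A``–``E`` with ``F``–``I`` absent or invisible;
    LAT sets carry all nine visible.  ``validate()`` enforces this; the
    constructor does not, so partially detected sets can be represented.
    """

    view: View
    keypoints: dict[str, Keypoint] = field(default_factory=dict)

    def __getitem__(self, label: str) -> Keypoint:
        return self.keypoints[label]

    def __contains__(self, label: str) -> bool:
        return label in self.keypoints

    def position(self, label: str) -> Point2D:
        kp = self.keypoints.get(label)
        if kp is None or not kp.visible:
            raise GeometryError(f"keypoint {label} is absent or invisible")
        return kp.position

    def visible_labels(self) -> tuple[str, ...]:
        return tuple(
            lab for lab in LABELS if lab in self.keypoints and self.keypoints[lab].visible
        )

    def validate(self) -> None:
        """Raise :class:`GeometryError` if the view invariant is violated."""
        vis = set(self.visible_labels())
        if self.view is View.AP:
            missing = set(AP_LABELS) - vis
            if missing:
                raise GeometryError(f"AP set missing visible keypoints {sorted(missing)}")
            extra = vis & set(LAT_ONLY_LABELS)
            if extra:
                raise GeometryError(f"AP set has visible LAT-only keypoints {sorted(extra)}")
        else:
            missing = set(LABELS) - vis
            if missing:
                raise GeometryError(f"LAT set missing visible keypoints {sorted(missing)}")

    @classmethod
    def from_points(
        cls,
        view: View | str,
        points: Mapping[str, tuple[float, float]] | Iterable[tuple[str, float, float]],
    ) -> "KeypointSet":
        """Build a set from ``{label: (x, y)}`` or ``(label, x, y)`` records."""
        if isinstance(points, Mapping):
            items = [(lab, xy[0], xy[1]) for lab, xy in points.items()]
        else:
            items = list(points)
        kps = {
            lab: Keypoint(lab, Point2D(float(x), float(y)), visible=True)
            for lab, x, y in items
        }
        return cls(view=View(view), keypoints=kps)


@dataclass(frozen=True)
class Line2D:
    """An infinite line given by an anchor point and a unit direction."""

    anchor: Point2D
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        nrm = math.hypot(*self.direction)
        if not math.isclose(nrm, 1.0, rel_tol=0, abs_tol=1e-12):
            raise GeometryError(f"direction {self.direction} is not unit-norm")

    @property
    def normal(self) -> tuple[float, float]:
        dx, dy = self.direction
        return (-dy, dx)


@dataclass(frozen=True)
class QCResult:
    """The positioning criteria of one image.

    ``flexion_angle_deg`` and ``normalized_flexion`` are ``None`` on AP views.
    ``ratio_clamped`` records whether the raw overlap ratio fell outside
    [0, 1] and was clamped.
    """

    view: View
    overlap_ratio: float
    flexion_angle_deg: float | None = None
    normalized_flexion: float | None = None
    ratio_clamped: bool = False


def fit_line(p: Point2D, q: Point2D) -> Line2D:
    """Line through two distinct points, direction normalized p→q."""
    dx, dy = q.x - p.x, q.y - p.y
    nrm = math.hypot(dx, dy)
    if nrm <= COINCIDENT_TOL:
        raise CoincidentPointsError(f"cannot fit a line through coincident points {p} and {q}")
    return Line2D(anchor=p, direction=(dx / nrm, dy / nrm))


def signed_distance(p: Point2D, line: Line2D, reference: Point2D) -> float:
    """Perpendicular distance from ``p`` to ``line``, positive on ``reference``'s side.

    ``reference`` must not lie on the line; it fixes which half-plane is
    positive.  The magnitude is the usual point-to-line Euclidean distance.
    """
    nx, ny = line.normal
    s_ref = (reference.x - line.anchor.x) * nx + (reference.y - line.anchor.y) * ny
    if abs(s_ref) <= COINCIDENT_TOL:
        raise GeometryError("reference point lies on the line; positive side undefined")
    s = (p.x - line.anchor.x) * nx + (p.y - line.anchor.y) * ny
    return s if s_ref > 0 else -s


def _overlap_ratio_raw(kps: KeypointSet) -> float:
    a, b = kps.position("A"), kps.position("B")
    c, d, e = kps.position("C"), kps.position("D"), kps.position("E")
    l1 = fit_line(a, b)
    sc = signed_distance(c, l1, c)  # positive by construction
    sd = signed_distance(d, l1, c)
    se = signed_distance(e, l1, c)
    width = sc - sd
    if abs(width) < COINCIDENT_TOL:
        raise DegenerateGeometryError(
            "fibular head has no transverse width relative to the shaft axis (Sc == Sd)"
        )
    return (sc - se) / width


def overlap_ratio(kps: KeypointSet) -> float:
    """Fibular-head/tibia overlap ratio in [0, 1] from keypoints A–E.

    Computes signed distances Sc, Sd, Se of the head extremes C, D and the
    tibial-edge crossing E to the fibular shaft axis ``L1`` (C's side
    positive) and returns ``(Sc - Se) / (Sc - Sd)`` clamped to [0, 1].
    """
    return min(1.0, max(0.0, _overlap_ratio_raw(kps)))


def flexion_angle(kps: KeypointSet) -> float:
    """Angle (degrees, in [0, 180]) between femoral and tibial shaft vectors.

    Uses the directed vectors ``F - G`` (femur, distal→proximal) and
    ``I - H`` (tibia, proximal→distal), so a fully extended, collinear limb
    reads 180.
    """
    f, g = kps.position("F"), kps.position("G")
    h, i = kps.position("H"), kps.position("I")
    ux, uy = f.x - g.x, f.y - g.y
    vx, vy = i.x - h.x, i.y - h.y
    if math.hypot(ux, uy) <= COINCIDENT_TOL:
        raise CoincidentPointsError("femoral shaft points F and G coincide")
    if math.hypot(vx, vy) <= COINCIDENT_TOL:
        raise CoincidentPointsError("tibial shaft points H and I coincide")
    dot = ux * vx + uy * vy
    cross = ux * vy - uy * vx
    return math.degrees(math.atan2(abs(cross), dot))


def compute_qc(kps: KeypointSet) -> QCResult:
    """All QC criteria the view supports.

    AP views yield the overlap ratio only; LAT views additionally yield the
    flexion angle and its range-normalized value (angle / 180).
    """
    kps.validate()
    raw = _overlap_ratio_raw(kps)
    ratio = min(1.0, max(0.0, raw))
    clamped = not (0.0 <= raw <= 1.0)
    if kps.view is View.AP:
        return QCResult(view=View.AP, overlap_ratio=ratio, ratio_clamped=clamped)
    angle = flexion_angle(kps)
    return QCResult(
        view=View.LAT,
        overlap_ratio=ratio,
        flexion_angle_deg=angle,
        normalized_flexion=angle / FLEXION_RANGE_DEG,
        ratio_clamped=clamped,
    )
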