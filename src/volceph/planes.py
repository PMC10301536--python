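"""The six anatomical cutting planes, built from named landmarks.

The protocol: the Frankfort Horizontal (FH) plane and a posterior coronal
plane through both porions delimit the lower two-thirds of the face; the
bispinal (palatal), occlusal, mental-foramina and mandibular-base (gonion-
menton) planes then partition it into the malar, maxillary, mandibular and
chin slabs.

Orientation conventions: FH, palatal, occlusal, foramina and mandibular-base
normals point superior; the coronal normal points anterior.  A small head
coordinate frame (origin at the mid-porion point, up = FH normal, anterior
toward ANS) makes the conventions explicit; all orderings are validated
rather than assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegeneratePlaneError, LandmarkError
from .geometry import Plane, plane_fit, plane_from_points
from .landmarks import LandmarkSet

log = logging.getLogger(__name__)

__all__ = [
    "HeadFrame",
    "PlaneStack",
    "StackDiagnostics",
    "build_head_frame",
    "frankfort_plane",
    "coronal_porion_plane",
    "palatal_plane",
    "occlusal_plane",
    "mandibular_base_plane",
    "mental_foramina_plane",
    "build_plane_stack",
    "validate_plane_stack",
]


@dataclass(frozen=True)
class HeadFrame:
    """Right-handed orthonormal head frame.

    origin: mid-porion point; up: FH normal toward the cranium; anterior:
    in-FH direction toward ANS, perpendicular to the porion axis; left
    completes the right-handed triad (anterior x up).
    """

    origin: np.ndarray
    up: np.ndarray
    anterior: np.ndarray
    left: np.ndarray

    def __post_init__(self):
        for name in ("up", "anterior", "left"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v / np.linalg.norm(v))
        G = np.stack([self.left, self.anterior, self.up])
        if not np.allclose(G @ G.T, np.eye(3), atol=1e-9):
            raise DegeneratePlaneError("head frame triad is not orthonormal")
        if np.linalg.det(G) < 0:
            raise DegeneratePlaneError("head frame triad is not right-handed")


def frankfort_plane(lm: LandmarkSet) -> Plane:
    """FH plane: both porions + left orbitale (exact), or a least-squares fit
    through all four points when ``orbitale_r`` is present.  The normal is
    oriented superior (ANS gets a negative signed distance)."""
    pts = [lm["porion_l"], lm["porion_r"], lm["orbitale_l"]]
    if "orbitale_r" in lm:
        plane = plane_fit(pts + [lm["orbitale_r"]])
    else:
        plane = plane_from_points(*pts)
    if plane.signed_distance(lm["ans"]) > 0:
        plane = plane.flipped()
    return plane


def build_head_frame(lm: LandmarkSet) -> HeadFrame:
    """Construct the canonical head frame from porions, orbitale and ANS."""
    fh = frankfort_plane(lm)
    up = fh.normal
    origin = 0.5 * (lm["porion_l"] + lm["porion_r"])
    axis = lm["porion_l"] - lm["porion_r"]
    axis_in_plane = axis - (axis @ up) * up
    if np.linalg.norm(axis_in_plane) < 1e-9:
        raise LandmarkError("porion axis is degenerate (coincident porions?)")
    axis_in_plane /= np.linalg.norm(axis_in_plane)
    anterior = np.cross(up, axis_in_plane)
    if anterior @ (lm["ans"] - origin) < 0:
        anterior = -anterior
    left = np.cross(anterior, up)
    if (lm["ans"] - lm["pns"]) @ anterior <= 0:
        raise LandmarkError("ANS is not anterior of PNS in the head frame")
    return HeadFrame(origin=origin, up=up, anterior=anterior, left=left)


def coronal_porion_plane(lm: LandmarkSet, frame: HeadFrame) -> Plane:
    """Posterior coronal plane through both porions, parallel to the up axis;
    normal = frame.anterior (ANS strictly on the positive side)."""
    plane = Plane(frame.anterior, float(frame.anterior @ frame.origin))
    if plane.signed_distance(lm["ans"]) <= 0:
        raise LandmarkError(
            "ANS lies behind the bi-porion coronal plane; landmark orientation "
            "is inconsistent"
        )
    return plane


def palatal_plane(lm: LandmarkSet, frame: HeadFrame) -> Plane:
    """Bispinal plane: contains ANS and PNS, completed with the lateral axis
    (transversely level); normal oriented superior."""
    direction = lm["pns"] - lm["ans"]
    n = np.cross(direction, frame.left)
    if np.linalg.norm(n) < 1e-9 * max(np.linalg.norm(direction), 1.0):
        raise DegeneratePlaneError("ANS->PNS direction is parallel to the lateral axis")
    n = n / np.linalg.norm(n)
    plane = Plane(n, float(n @ lm["ans"]))
    if plane.normal @ frame.up < 0:
        plane = plane.flipped()
    return plane


def occlusal_plane(lm: LandmarkSet, frame: HeadFrame) -> Plane:
    """Functional occlusal plane through the anterior and both molar occlusal
    landmarks; normal oriented superior."""
    plane = plane_from_points(
        lm["occlusal_anterior"], lm["occlusal_molar_l"], lm["occlusal_molar_r"]
    )
    if plane.normal @ frame.up < 0:
        plane = plane.flipped()
    return plane


def mandibular_base_plane(lm: LandmarkSet, frame: HeadFrame) -> Plane:
    """Mandibular base (gonion-gonion-menton) plane separating face from
    neck; normal oriented superior (face side positive)."""
    plane = plane_from_points(lm["gonion_l"], lm["gonion_r"], lm["menton"])
    if plane.normal @ frame.up < 0:
        plane = plane.flipped()
    return plane


def mental_foramina_plane(lm: LandmarkSet, frame: HeadFrame) -> Plane:
    """FH-parallel plane through the midpoint of the mental foramina.

    When the two foramina sit at different heights no FH-parallel plane can
    contain both; the midpoint rule is symmetric and deterministic, and each
    foramen's residual distance is logged.
    """
    mid = 0.5 * (lm["mental_foramen_l"] + lm["mental_foramen_r"])
    plane = Plane(frame.up, float(frame.up @ mid))
    for side in ("mental_foramen_l", "mental_foramen_r"):
        res = plane.signed_distance(lm[side])
        if abs(res) > 1e-9:
            log.info("mental foramina plane: %s is %.3f mm off-plane", side, res)
    return plane


@dataclass(frozen=True)
class PlaneStack:
    """The six oriented cutting planes of the protocol."""

    fh: Plane
    coronal_porion: Plane
    palatal: Plane
    occlusal: Plane
    foramina: Plane
    mandibular_base: Plane


def build_plane_stack(lm: LandmarkSet) -> PlaneStack:
    frame = build_head_frame(lm)
    return PlaneStack(
        fh=frankfort_plane(lm),
        coronal_porion=coronal_porion_plane(lm, frame),
        palatal=palatal_plane(lm, frame),
        occlusal=occlusal_plane(lm, frame),
        foramina=mental_foramina_plane(lm, frame),
        mandibular_base=mandibular_base_plane(lm, frame),
    )


@dataclass
class StackDiagnostics:
    """Pass/fail per stack constraint with the measured gap in mm.

    ``checks`` maps a constraint name to ``(passed, gap_mm)``; positive gaps
    satisfy the constraint with margin.
    """

    checks: dict[str, tuple[bool, float]]

    @property
    def ok(self) -> bool:
        return all(passed for passed, _ in self.checks.values())

    def failures(self) -> list[str]:
        return [
            f"{name} (gap {gap:.3f} mm)"
            for name, (passed, gap) in self.checks.items()
            if not passed
        ]


def validate_plane_stack(stack: PlaneStack, lm: LandmarkSet) -> StackDiagnostics:
    """Check the superior-to-inferior ordering of the plane stack.

    Plane heights are compared along the vertical (up) line through ANS;
    additional constraints: ANS below FH and anterior of the coronal plane,
    menton on/below the foramina plane, the anterior occlusal point above the
    mandibular base.  Diagnostics only -- segmentation refuses on failure
    unless forced by configuration.
    """
    up = stack.fh.normal
    ans = lm["ans"]

    def height(plane: Plane) -> float:
        denom = plane.normal @ up
        if abs(denom) < 1e-6:
            return float("nan")
        return float((plane.offset - plane.normal @ ans) / denom)

    h = {
        "fh": height(stack.fh),
        "palatal": height(stack.palatal),
        "occlusal": height(stack.occlusal),
        "foramina": height(stack.foramina),
    }
    checks: dict[str, tuple[bool, float]] = {}
    order = ["fh", "palatal", "occlusal", "foramina"]
    for hi, lo in zip(order, order[1:]):
        gap = h[hi] - h[lo]
        checks[f"{hi}_above_{lo}"] = (bool(gap >= 0) and np.isfinite(gap), gap)
    gap = -stack.foramina.signed_distance(lm["menton"])
    checks["menton_on_or_below_foramina"] = (gap >= -1e-9, float(gap))
    gap = -stack.fh.signed_distance(ans)
    checks["ans_below_fh"] = (gap > 0, float(gap))
    gap = stack.coronal_porion.signed_distance(ans)
    checks["ans_anterior_of_coronal"] = (gap > 0, float(gap))
    gap = stack.mandibular_base.signed_distance(lm["occlusal_anterior"])
    checks["occlusal_above_mandibular_base"] = (gap > 0, float(gap))
    return StackDiagnostics(checks=checks)
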