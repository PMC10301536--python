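"""Slab segmentation of the lower two-thirds of the face.

The lower two-thirds is the region below the Frankfort Horizontal plane,
anterior of the bi-porion coronal plane and above the mandibular base plane.
It is partitioned into four contiguous slabs by a fixed cut tree -- palatal
plane first (above = malar), then occlusal (above = maxillary), then the
mental-foramina plane (above = mandibular, below = chin) -- so the partition
is exact by construction: the four slab volumes sum to the lower-two-thirds
volume to machine precision.

Soft tissue is measured as the full solid enclosed by the skin surface within
each slab; internal cavities or bone are not subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import trimesh

from .cohort import VolumeProfile
from .errors import MeshIntegrityError, PlaneStackError
from .geometry import cut_mesh, mesh_volume
from .landmarks import LandmarkSet
from .planes import PlaneStack, validate_plane_stack

log = logging.getLogger(__name__)

__all__ = ["SlabSet", "extract_lower_two_thirds", "partition_slabs",
           "slab_volumes", "export_slabs"]


@dataclass
class SlabSet:
    """The four watertight slab meshes plus the lower-two-thirds they tile.

    A slab a plane does not reach is ``None``; such empty slabs are permitted
    but flagged in ``empty``.
    """

    malar: trimesh.Trimesh | None
    maxillary: trimesh.Trimesh | None
    mandibular: trimesh.Trimesh | None
    chin: trimesh.Trimesh | None
    lower_two_thirds: trimesh.Trimesh
    provenance: dict = field(default_factory=dict)

    @property
    def empty(self) -> list[str]:
        return [
            name
            for name in ("malar", "maxillary", "mandibular", "chin")
            if getattr(self, name) is None
        ]

    def volumes(self) -> dict[str, float]:
        return {
            name: (mesh_volume(m) if m is not None else 0.0)
            for name in ("malar", "maxillary", "mandibular", "chin")
            for m in [getattr(self, name)]
        }


def _require_side(piece, stage: str):
    if piece is None:
        raise MeshIntegrityError(
            f"{stage} produced an empty region; landmarks are inconsistent "
            "with the mesh"
        )
    return piece


def extract_lower_two_thirds(
    mesh: trimesh.Trimesh, stack: PlaneStack
) -> trimesh.Trimesh:
    """Keep the region below FH, anterior of the coronal plane and above the
    mandibular base: three successive capped cuts."""
    _, below_fh = cut_mesh(mesh, stack.fh)
    below_fh = _require_side(below_fh, "FH cut")
    anterior, _ = cut_mesh(below_fh, stack.coronal_porion)
    anterior = _require_side(anterior, "bi-porion coronal cut")
    above_base, _ = cut_mesh(anterior, stack.mandibular_base)
    return _require_side(above_base, "mandibular base cut")


def partition_slabs(
    lower: trimesh.Trimesh,
    stack: PlaneStack,
    lm: LandmarkSet | None = None,
    force: bool = False,
    provenance: dict | None = None,
) -> SlabSet:
    """Partition the lower two-thirds into the four contiguous slabs.

    If a landmark set is supplied the plane stack is validated first and a
    failed ordering refuses to segment unless ``force`` is set.
    """
    if lm is not None:
        diag = validate_plane_stack(stack, lm)
        if not diag.ok:
            msg = "plane stack validation failed: " + "; ".join(diag.failures())
            if not force:
                raise PlaneStackError(msg)
            log.warning("%s (forced, continuing)", msg)

    malar, rest = cut_mesh(lower, stack.palatal)
    maxillary, rest2 = cut_mesh(rest, stack.occlusal) if rest is not None else (None, None)
    mandibular, chin = (
        cut_mesh(rest2, stack.foramina) if rest2 is not None else (None, None)
    )
    slabs = SlabSet(
        malar=malar,
        maxillary=maxillary,
        mandibular=mandibular,
        chin=chin,
        lower_two_thirds=lower,
        provenance=provenance or {},
    )
    if slabs.empty:
        log.warning("empty slabs: %s", ", ".join(slabs.empty))
    return slabs


def slab_volumes(slabs: SlabSet) -> VolumeProfile:
    """Measure the four slab volumes (mm³) as a :class:`VolumeProfile`."""
    v = slabs.volumes()
    return VolumeProfile(v["malar"], v["maxillary"], v["mandibular"], v["chin"])


def export_slabs(slabs: SlabSet, stem: str | Path) -> list[Path]:
    """Write each non-empty slab as ``<stem>_<region>.stl`` for inspection."""
    stem = Path(stem)
    written = []
    for name in ("malar", "maxillary", "mandibular", "chin"):
        mesh = getattr(slabs, name)
        if mesh is None:
            continue
        path = stem.parent / f"{stem.name}_{name}.stl"
        mesh.export(path)
        written.append(path)
    return written
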