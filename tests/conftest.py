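"""Shared fixtures: analytic meshes, canonical landmark sets, synthetic heads.

All fixtures are generated programmatically; expensive ones (calibrated
heads) are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from volceph.landmarks import LandmarkSet
from volceph.planes import build_plane_stack
from volceph.slabs import extract_lower_two_thirds, partition_slabs, slab_volumes
from volceph.synthetic import HeadSpec, calibrate_to_distribution, generate_head

FEMALE_VOLUMES = (283005.0, 212433.0, 202279.0, 34340.0)
MALE_VOLUMES = (300436.0, 230526.0, 242905.0, 49444.0)
FEMALE_SHARES = (38.7, 29.0, 27.6, 4.7)


@pytest.fixture(scope="session")
def unit_cube() -> trimesh.Trimesh:
    """Axis-aligned unit cube spanning [0, 1]^3 (12 triangles)."""
    cube = trimesh.creation.box(extents=(1, 1, 1))
    cube.apply_translation([0.5, 0.5, 0.5])
    return trimesh.Trimesh(vertices=cube.vertices, faces=cube.faces, process=False)


@pytest.fixture(scope="session")
def icosphere() -> trimesh.Trimesh:
    """Icosphere of radius 10 mm, 4 subdivisions."""
    s = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return trimesh.Trimesh(vertices=s.vertices, faces=s.faces, process=False)


def make_landmarks(
    z_palatal=-20.0,
    z_occlusal=-35.0,
    z_foramina=-62.0,
    include_orbitale_r=False,
) -> LandmarkSet:
    """Canonical axis-aligned landmark set (FH = z=0, coronal = y=0)."""
    pts = {
        "porion_l": [60, 0, 0],
        "porion_r": [-60, 0, 0],
        "orbitale_l": [-30, 70, 0],
        "ans": [0, 90, z_palatal],
        "pns": [0, 40, z_palatal],
        "occlusal_anterior": [0, 85, z_occlusal],
        "occlusal_molar_l": [25, 45, z_occlusal],
        "occlusal_molar_r": [-25, 45, z_occlusal],
        "gonion_l": [50, 10, -60],
        "gonion_r": [-50, 10, -60],
        "menton": [0, 85, -75],
        "mental_foramen_l": [25, 75, z_foramina],
        "mental_foramen_r": [-25, 75, z_foramina],
    }
    if include_orbitale_r:
        pts["orbitale_r"] = [30, 70, 0]
    return LandmarkSet({k: np.asarray(v, float) for k, v in pts.items()})


@pytest.fixture
def canonical_landmarks() -> LandmarkSet:
    return make_landmarks()


def make_box_head():
    """200 x 200 x 240 mm box head with horizontal cutting planes.

    Plane heights: FH z=0, coronal y=0, palatal -40, occlusal -80,
    foramina -120, base -160; each anterior-half slab is 200*100*40 mm³.
    """
    box = trimesh.creation.box(extents=(200, 200, 240))
    box.apply_translation([0, 0, -40])  # z in [-160, 80]
    mesh = trimesh.Trimesh(vertices=box.vertices, faces=box.faces, process=False)
    lm = LandmarkSet(
        {
            "porion_l": [60, 0, 0],
            "porion_r": [-60, 0, 0],
            "orbitale_l": [-30, 70, 0],
            "ans": [0, 90, -40.0],
            "pns": [0, 40, -40.0],
            "occlusal_anterior": [0, 85, -80.0],
            "occlusal_molar_l": [25, 45, -80.0],
            "occlusal_molar_r": [-25, 45, -80.0],
            "mental_foramen_l": [25, 75, -120.0],
            "mental_foramen_r": [-25, 75, -120.0],
            "gonion_l": [50, 10, -160.0],
            "gonion_r": [-50, 10, -160.0],
            "menton": [0, 85, -160.0],
        }
    )
    return mesh, lm


@pytest.fixture(scope="session")
def box_head():
    return make_box_head()


#: reduced loft resolution for fast unit tests
FAST_RES = {"n_theta": 36, "n_rings": 28}


@pytest.fixture(scope="session")
def default_head():
    """One default synthetic head with landmarks, stack and slab profile."""
    mesh, lm = generate_head(HeadSpec(**FAST_RES))
    stack = build_plane_stack(lm)
    lower = extract_lower_two_thirds(mesh, stack)
    slabs = partition_slabs(lower, stack, lm=lm)
    return {
        "mesh": mesh,
        "landmarks": lm,
        "stack": stack,
        "lower": lower,
        "slabs": slabs,
        "profile": slab_volumes(slabs),
    }


@pytest.fixture(scope="session")
def female_calibrated():
    """A head calibrated to the female normative share distribution."""
    spec = calibrate_to_distribution(HeadSpec(**FAST_RES), FEMALE_SHARES)
    mesh, lm = generate_head(spec)
    stack = build_plane_stack(lm)
    lower = extract_lower_two_thirds(mesh, stack)
    slabs = partition_slabs(lower, stack, lm=lm)
    return {
        "spec": spec,
        "mesh": mesh,
        "landmarks": lm,
        "stack": stack,
        "lower": lower,
        "profile": slab_volumes(slabs),
    }


def random_rigid_transform(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random rotation + bounded translation as a 4x4 matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    M = trimesh.transformations.quaternion_matrix(q)
    M[:3, 3] = rng.uniform(-50, 50, size=3)
    return M
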