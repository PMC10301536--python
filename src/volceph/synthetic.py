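"""Synthetic watertight head meshes, cohorts and jury-score tables.

Real clinical inputs (CBCT-derived STL surfaces of a normative cohort) are
not publicly available, so this module generates stand-ins: a deliberately simple
lofted-superellipse head whose landmarks are placed analytically and whose
slab-volume distribution is tunable.  Realism is not the goal -- plane-stack
validity and a controllable, measurable volume distribution are.

The closed loop is the module's contract: a head calibrated to target shares,
when pushed through the *real* measurement pipeline (plane stack ->
lower-two-thirds -> slab partition -> volumes), reproduces those shares
within 0.5 percentage points.

Cohorts draw per-region volumes from independent normal distributions around
a gender preset (truncated at 3 sigma and at zero), calibrate one head per
subject, and record the drawn volumes as ground truth.  Jury scores follow a
latent-attractiveness model: score = clip(round-to-half(latent + judge bias +
session noise), 1, 10), with the session-noise variance chosen analytically
so the expected test-retest Pearson r matches the requested target.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy.optimize import brentq

from .cohort import (
    REGIONS,
    JuryScores,
    load_references,
    percentage_distribution,
    reference_mean_volumes,
)
from .errors import CalibrationError, VolcephError
from .geometry import Plane, cut_mesh, ensure_outward, mesh_volume
from .landmarks import LandmarkSet, write_landmarks
from .planes import build_plane_stack
from .slabs import extract_lower_two_thirds, partition_slabs, slab_volumes

log = logging.getLogger(__name__)

__all__ = [
    "HeadSpec",
    "CohortSpec",
    "SyntheticSubject",
    "generate_head",
    "calibrate_to_distribution",
    "draw_subject_volumes",
    "generate_cohort",
    "generate_jury_scores",
    "simulate_study",
    "gender_preset_shares",
]


@dataclass(frozen=True)
class HeadSpec:
    """Parameters of one synthetic head (all lengths in mm at scale 1).

    The four plane heights are z-levels below the Frankfort plane (z = 0);
    they must be strictly ordered 0 > palatal > occlusal > foramina > base.
    """

    scale: float = 1.0
    gender: str = "female"
    z_palatal: float = -20.0
    z_occlusal: float = -45.0
    z_foramina: float = -62.0
    z_base: float = -80.0
    half_width: float = 70.0        # lateral superellipse semi-axis at widest
    depth_front: float = 85.0       # anterior semi-axis
    depth_back: float = 60.0        # posterior semi-axis
    exponent: float = 2.5           # cross-section superellipse exponent
    v_exponent: float = 2.2         # vertical profile exponent
    chin_prominence: float = 8.0    # anterior bump near the chin (mm)
    menton_drop: float = 0.0        # menton below the gonion level (tilts base)
    z_top: float = 60.0             # cranial apex above FH
    bottom_margin: float = 15.0     # mesh extends this far below the base
    n_theta: int = 48               # vertices per cross-section ring
    n_rings: int = 40               # lofted rings between the poles
    seed: int = 0

    def __post_init__(self):
        zs = (0.0, self.z_palatal, self.z_occlusal, self.z_foramina, self.z_base)
        if not all(a > b for a, b in zip(zs, zs[1:])):
            raise VolcephError(
                "plane heights must satisfy 0 > palatal > occlusal > foramina "
                f"> base, got {zs[1:]}"
            )
        if min(self.half_width, self.depth_front, self.depth_back) <= 0:
            raise VolcephError("head semi-axes must be positive")
        if self.scale <= 0:
            raise VolcephError("scale must be positive")
        if self.n_theta < 12 or self.n_rings < 8:
            raise VolcephError("resolution too low for a watertight loft")


def _vertical_profile(spec: HeadSpec):
    """Return (z_bottom, z_center, half_height, w(z)) of the loft envelope."""
    z_bot = spec.z_base - spec.bottom_margin
    zc = 0.5 * (spec.z_top + z_bot)
    H = 0.5 * (spec.z_top - z_bot)
    q = spec.v_exponent

    def w(z):
        u = min(abs((z - zc) / H), 1.0)
        return (1.0 - u**q) ** (1.0 / q)

    return z_bot, zc, H, w


def _chin_bump(spec: HeadSpec, z: float) -> float:
    # centred relative to the (never-calibrated) base level so the mesh shape
    # is independent of the tunable inner plane heights
    zc_chin = 0.85 * spec.z_base
    return spec.chin_prominence * np.exp(-(((z - zc_chin) / 12.0) ** 2))


def _section_point(spec: HeadSpec, z: float, theta: float, w) -> tuple[float, float]:
    p = spec.exponent
    a = spec.half_width * w(z)
    b = (spec.depth_front * w(z) + _chin_bump(spec, z)) if np.sin(theta) >= 0 \
        else spec.depth_back * w(z)
    c, s = np.cos(theta), np.sin(theta)
    # kill trig round-off at the axes so meridian vertices are exactly lateral
    if abs(c) < 1e-12:
        c = 0.0
    if abs(s) < 1e-12:
        s = 0.0
    x = a * np.sign(c) * abs(c) ** (2.0 / p)
    y = b * np.sign(s) * abs(s) ** (2.0 / p)
    return x, y


def generate_head(spec: HeadSpec) -> tuple[trimesh.Trimesh, LandmarkSet]:
    """Build a watertight lofted head mesh and its consistent landmark set.

    Deterministic: the same spec always yields byte-identical vertex arrays.
    """
    z_bot, zc, H, w = _vertical_profile(spec)
    m, nt = spec.n_rings, spec.n_theta
    # cosine ring spacing keeps the poles round
    ring_z = zc + H * np.cos(np.pi * np.arange(1, m + 1) / (m + 1))
    thetas = 2.0 * np.pi * np.arange(nt) / nt

    verts = [np.array([0.0, 0.0, spec.z_top])]  # top pole = index 0
    for z in ring_z:
        for th in thetas:
            x, y = _section_point(spec, z, th, w)
            verts.append(np.array([x, y, z]))
    verts.append(np.array([0.0, 0.0, z_bot]))  # bottom pole
    V = np.asarray(verts) * spec.scale
    bottom = len(V) - 1

    faces = []
    ring0 = 1
    for i in range(nt):  # top fan
        faces.append([0, ring0 + i, ring0 + (i + 1) % nt])
    for j in range(m - 1):  # quad strips
        r0 = ring0 + j * nt
        r1 = r0 + nt
        for i in range(nt):
            i2 = (i + 1) % nt
            faces.append([r0 + i, r1 + i, r1 + i2])
            faces.append([r0 + i, r1 + i2, r0 + i2])
    rl = ring0 + (m - 1) * nt
    for i in range(nt):  # bottom fan
        faces.append([bottom, rl + (i + 1) % nt, rl + i])

    mesh = trimesh.Trimesh(vertices=V, faces=np.asarray(faces), process=False)
    mesh = ensure_outward(mesh)
    if not mesh.is_watertight:
        raise VolcephError("generated loft is not watertight (invalid spec?)")

    s = spec.scale
    a0 = spec.half_width * w(0.0)
    bf = lambda z: spec.depth_front * w(z) + _chin_bump(spec, z)  # noqa: E731
    lm = LandmarkSet(
        {
            "porion_l": np.array([a0, 0.0, 0.0]) * s,
            "porion_r": np.array([-a0, 0.0, 0.0]) * s,
            "orbitale_l": np.array([30.0, 0.6 * bf(0.0), 0.0]) * s,
            "orbitale_r": np.array([-30.0, 0.6 * bf(0.0), 0.0]) * s,
            "ans": np.array([0.0, bf(spec.z_palatal), spec.z_palatal]) * s,
            "pns": np.array(
                [0.0, bf(spec.z_palatal) - 50.0, spec.z_palatal]
            ) * s,
            "occlusal_anterior": np.array(
                [0.0, 0.9 * bf(spec.z_occlusal), spec.z_occlusal]
            ) * s,
            "occlusal_molar_l": np.array([25.0, 25.0, spec.z_occlusal]) * s,
            "occlusal_molar_r": np.array([-25.0, 25.0, spec.z_occlusal]) * s,
            "mental_foramen_l": np.array(
                [25.0, 0.8 * bf(spec.z_foramina), spec.z_foramina]
            ) * s,
            "mental_foramen_r": np.array(
                [-25.0, 0.8 * bf(spec.z_foramina), spec.z_foramina]
            ) * s,
            "gonion_l": np.array(
                [0.8 * spec.half_width * w(spec.z_base), 0.0, spec.z_base]
            ) * s,
            "gonion_r": np.array(
                [-0.8 * spec.half_width * w(spec.z_base), 0.0, spec.z_base]
            ) * s,
            "menton": np.array(
                [0.0, 0.9 * bf(spec.z_base), spec.z_base - spec.menton_drop]
            ) * s,
        }
    )
    return mesh, lm


def gender_preset_shares(gender: str) -> tuple[float, float, float, float]:
    """Target shares for a gender preset.

    The female preset is the reported female distribution.  The male preset
    uses the shares derived from the reported male mean volumes (the male
    share line as printed is not consistent with its own volumes).
    """
    if gender == "female":
        ref = load_references()["female"]
        return tuple(ref.shares[r] for r in REGIONS)
    if gender == "male":
        vols = reference_mean_volumes()["male"]
        return percentage_distribution([vols[r] for r in REGIONS], decimals=None)
    raise VolcephError(f"unknown gender preset {gender!r}")


def calibrate_to_distribution(
    spec: HeadSpec,
    target_shares,
    tol_pp: float = 0.5,
    max_iter: int = 50,
) -> HeadSpec:
    """Adjust the three inner plane heights so the measured distribution of
    the generated head matches ``target_shares`` (percent, summing to ~100).

    Each height is solved by bracketed root finding on the cumulative share
    above a horizontal plane, computed with the real cutting pipeline on the
    head's lower two-thirds; the result is verified with a full slab
    partition.
    """
    t = np.asarray(target_shares, float)
    if t.shape != (4,) or np.any(t <= 0):
        raise CalibrationError(f"invalid target shares {target_shares}")
    if abs(t.sum() - 100.0) > 0.5:
        raise CalibrationError(f"target shares sum to {t.sum():.2f}, not 100")
    t = t / t.sum() * 100.0

    mesh, lm = generate_head(spec)
    stack = build_plane_stack(lm)
    lower = extract_lower_two_thirds(mesh, stack)
    total = mesh_volume(lower)
    up = np.array([0.0, 0.0, 1.0])

    def share_above(z: float) -> float:
        above, _ = cut_mesh(lower, Plane(up, z))
        return 100.0 * (mesh_volume(above) if above is not None else 0.0) / total

    z_lo = spec.z_base * spec.scale + 0.5
    z_hi = -0.5
    cum = np.cumsum(t)[:3]
    solved = []
    for c in cum:
        f = lambda z: share_above(z) - c  # noqa: E731
        try:
            z = brentq(f, z_lo, z_hi, xtol=0.01, maxiter=max_iter)
        except ValueError as exc:
            raise CalibrationError(
                f"cannot bracket cumulative share {c:.2f}% in "
                f"[{z_lo:.1f}, {z_hi:.1f}] mm: {exc}"
            ) from None
        solved.append(z)
    z_pal, z_occ, z_for = (z / spec.scale for z in solved)
    if not (0 > z_pal > z_occ > z_for > spec.z_base):
        raise CalibrationError(f"solved plane heights unordered: {solved}")
    new_spec = dataclasses.replace(
        spec, z_palatal=z_pal, z_occlusal=z_occ, z_foramina=z_for
    )

    mesh2, lm2 = generate_head(new_spec)
    stack2 = build_plane_stack(lm2)
    lower2 = extract_lower_two_thirds(mesh2, stack2)
    measured = slab_volumes(partition_slabs(lower2, stack2, lm=lm2)).shares
    residuals = np.asarray(measured) - t
    if np.max(np.abs(residuals)) > tol_pp:
        raise CalibrationError(
            f"calibration residuals {np.round(residuals, 3).tolist()} pp "
            f"exceed {tol_pp} pp"
        )
    return new_spec


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the normative cohort design: 26 females and 20 males in
    the aesthetic subsample, 6 judges scoring twice.  ``volume_cv`` is the per-region
    coefficient of variation of the normally distributed subject volumes.
    """

    n_female: int = 26
    n_male: int = 20
    volume_cv: float = 0.08
    n_judges: int = 6
    n_sessions: int = 2
    test_retest_r: float = 0.85
    score_mean: float = 8.0
    score_sd: float = 1.0
    judge_bias_sd: float = 0.3
    seed: int = 0
    resolution: tuple[int, int] = (48, 40)  # (n_theta, n_rings)

    def __post_init__(self):
        if self.n_female < 0 or self.n_male < 0:
            raise VolcephError("cohort sizes must be >= 0")
        if self.volume_cv < 0:
            raise VolcephError("volume_cv must be >= 0")
        if not (-1.0 <= self.test_retest_r <= 1.0):
            raise VolcephError("test_retest_r must lie in [-1, 1]")


@dataclass
class SyntheticSubject:
    subject_id: str
    gender: str
    spec: HeadSpec
    mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    true_volumes: dict[str, float]  # the drawn per-region targets (mm³)


def _base_total(gender: str, resolution: tuple[int, int]) -> float:
    spec = HeadSpec(gender=gender, n_theta=resolution[0], n_rings=resolution[1])
    mesh, lm = generate_head(spec)
    stack = build_plane_stack(lm)
    return mesh_volume(extract_lower_two_thirds(mesh, stack))


def draw_subject_volumes(
    rng: np.random.Generator, mean_volumes: np.ndarray, cv: float
) -> np.ndarray:
    """One subject's per-region volume draw: independent normals with the
    given coefficient of variation, truncated at 3 sigma and at zero."""
    mean_volumes = np.asarray(mean_volumes, float)
    sd = cv * mean_volumes
    draw = rng.normal(mean_volumes, sd)
    return np.clip(
        draw, np.maximum(mean_volumes - 3 * sd, 1.0), mean_volumes + 3 * sd
    )


def generate_cohort(cspec: CohortSpec) -> list[SyntheticSubject]:
    """Generate per-subject heads whose slab volumes scatter normally around
    the gender presets.  Deterministic under ``cspec.seed``."""
    rng = np.random.default_rng(cspec.seed)
    ref_volumes = reference_mean_volumes()
    subjects: list[SyntheticSubject] = []
    base_totals = {
        g: _base_total(g, cspec.resolution)
        for g, n in (("female", cspec.n_female), ("male", cspec.n_male))
        if n > 0
    }
    counters = {"female": 0, "male": 0}
    for gender, n in (("female", cspec.n_female), ("male", cspec.n_male)):
        preset = np.array([ref_volumes[gender][r] for r in REGIONS])
        for _ in range(n):
            counters[gender] += 1
            sid = f"{gender[0]}{counters[gender]:03d}"
            draw = draw_subject_volumes(rng, preset, cspec.volume_cv)
            shares = 100.0 * draw / draw.sum()
            scale = float((draw.sum() / base_totals[gender]) ** (1.0 / 3.0))
            spec = HeadSpec(
                gender=gender,
                scale=scale,
                n_theta=cspec.resolution[0],
                n_rings=cspec.resolution[1],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            try:
                spec = calibrate_to_distribution(spec, shares)
            except CalibrationError as exc:
                raise CalibrationError(f"subject {sid}: {exc}") from exc
            mesh, lm = generate_head(spec)
            subjects.append(
                SyntheticSubject(
                    subject_id=sid,
                    gender=gender,
                    spec=spec,
                    mesh=mesh,
                    landmarks=lm,
                    true_volumes=dict(zip(REGIONS, draw.tolist())),
                )
            )
    return subjects


def generate_jury_scores(cspec: CohortSpec, subject_ids) -> JuryScores:
    """Latent-attractiveness jury scores with a controlled test-retest r.

    For judge j, subject s, session t:
    ``score = clip(round_to_half(latent_s + bias_j + eps_jst), 1, 10)`` with
    ``sd(eps) = score_sd * sqrt((1 - r) / r)`` so the expected within-judge
    across-subject correlation of the two sessions is the target r (before
    rounding/clipping).  ``r = 1`` uses zero noise: session 2 duplicates
    session 1 exactly.
    """
    r = cspec.test_retest_r
    if r <= 0.0:
        raise VolcephError(
            "test_retest_r must be positive for the noise-variance construction"
        )
    rng = np.random.default_rng([cspec.seed, 7919])
    ids = list(subject_ids)
    latent = rng.normal(cspec.score_mean, cspec.score_sd, size=len(ids))
    bias = rng.normal(0.0, cspec.judge_bias_sd, size=cspec.n_judges)
    sd_eps = cspec.score_sd * np.sqrt((1.0 - r) / r)
    rows = []
    for j in range(cspec.n_judges):
        for t in range(1, cspec.n_sessions + 1):
            eps = (
                rng.normal(0.0, sd_eps, size=len(ids))
                if sd_eps > 0
                else np.zeros(len(ids))
            )
            raw = latent + bias[j] + eps
            score = np.clip(np.round(raw * 2.0) / 2.0, 1.0, 10.0)
            for sid, sc in zip(ids, score):
                rows.append(
                    {
                        "judge_id": f"judge{j + 1}",
                        "session": t,
                        "subject_id": sid,
                        "score": float(sc),
                    }
                )
    return JuryScores(pd.DataFrame(rows))


def simulate_study(cspec: CohortSpec, out_dir: str | Path) -> dict:
    """Write a full synthetic study to ``out_dir``: per-subject STL + landmark
    JSON, a cohort manifest CSV, a jury-score CSV and a provenance record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = generate_cohort(cspec)
    manifest_rows = []
    truth_rows = []
    for s in subjects:
        mesh_path = out / f"{s.subject_id}.stl"
        lm_path = out / f"{s.subject_id}_landmarks.json"
        s.mesh.export(mesh_path)
        write_landmarks(s.landmarks, lm_path)
        manifest_rows.append(
            {
                "subject_id": s.subject_id,
                "gender": s.gender,
                "mesh_path": mesh_path.name,
                "landmarks_path": lm_path.name,
            }
        )
        truth_rows.append(
            {"subject_id": s.subject_id, "gender": s.gender,
             **{f"v_{r}": s.true_volumes[r] for r in REGIONS}}
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    pd.DataFrame(truth_rows).to_csv(out / "true_volumes.csv", index=False)
    scores = generate_jury_scores(cspec, [s.subject_id for s in subjects])
    scores.to_csv(out / "scores.csv")
    provenance = {
        "cohort_spec": dataclasses.asdict(cspec),
        "n_subjects": len(subjects),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1)
    log.info("simulated %d subjects into %s", len(subjects), out)
    return {
        "manifest": manifest,
        "scores": out / "scores.csv",
        "truth": out / "true_volumes.csv",
        "n_subjects": len(subjects),
    }
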