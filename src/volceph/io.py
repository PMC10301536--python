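"""File I/O, run configuration and the end-to-end pipelines.

STL is the only mesh format (binary or ASCII; STL stores a triangle soup, so
the reader merges duplicate vertices to restore connectivity).  Landmarks are
JSON objects or ``name,x,y,z`` CSV.  Reports are JSON plus flat CSV, each
carrying the package version and a hash of the configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import __version__
from .cohort import (
    REGIONS,
    CohortTable,
    JuryScores,
    VolumeProfile,
    cohort_summary,
    compare_to_reference,
    judge_repeatability,
    load_references,
    normality_check,
    select_attractive,
)
from .errors import MeshIntegrityError, PlaneStackError
from .geometry import boundary_edge_count, ensure_outward, mesh_volume
from .landmarks import LandmarkSet, read_landmarks, write_landmarks  # noqa: F401
from .planes import build_plane_stack, validate_plane_stack
from .slabs import extract_lower_two_thirds, partition_slabs, slab_volumes

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_mesh",
    "read_landmarks",
    "write_landmarks",
    "run_measure",
    "run_cohort",
]


@dataclass(frozen=True)
class RunConfig:
    """Knobs of a measurement run (defaults match the reporting conventions)."""

    decimals: int = 1               # share rounding (ratios use 2)
    plane_snap_mm: float = 1e-9     # on-plane vertex tolerance for cuts
    voxel_mm: float = 0.5           # voxel oracle resolution, when used
    cutoff: float = 8.5             # inclusive jury-score selection threshold
    reference: str | None = None    # normative reference id ("female"/"male")
    force_segmentation: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.plane_snap_mm <= 0 or self.voxel_mm <= 0:
            raise ValueError("tolerances must be positive")
        if not (1.0 <= self.cutoff <= 10.0):
            raise ValueError("cutoff must lie in [1, 10]")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Read an STL file (binary or ASCII) into a validated watertight mesh.

    Duplicate vertices are merged (STL stores per-triangle vertices), the
    orientation is repaired with a warning if the surface is inward-facing,
    and a surface that is not watertight raises with its boundary-edge count.
    """
    mesh = trimesh.load(str(path), force="mesh", process=False)
    mesh = trimesh.Trimesh(
        vertices=mesh.vertices.copy(), faces=mesh.faces.copy(), process=False
    )
    mesh.merge_vertices(digits_vertex=6)  # 1e-6 mm grid
    mesh.remove_unreferenced_vertices()
    if not mesh.is_watertight:
        raise MeshIntegrityError(
            f"{path}: mesh is not watertight",
            boundary_edges=boundary_edge_count(mesh),
        )
    if not mesh.is_winding_consistent:
        raise MeshIntegrityError(f"{path}: inconsistent face winding")
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        mesh = ensure_outward(mesh)
    return mesh


def _profile_payload(profile: VolumeProfile, decimals: int) -> dict:
    return profile.as_dict(decimals)


def run_measure(
    mesh_path: str | Path,
    landmarks_path: str | Path,
    config: RunConfig = RunConfig(),
    out: str | Path | None = None,
) -> dict:
    """Measure one subject: plane stack -> validation -> lower two-thirds ->
    slab partition -> volume profile (-> optional reference comparison).

    Returns the report dict; with ``out`` set, writes ``<out>.json`` and
    ``<out>.csv``.  Stack-validation failure raises unless
    ``config.force_segmentation`` is set.
    """
    mesh = read_mesh(mesh_path)
    lm = read_landmarks(landmarks_path)
    stack = build_plane_stack(lm)
    diag = validate_plane_stack(stack, lm)
    if not diag.ok and not config.force_segmentation:
        raise PlaneStackError(
            "plane stack validation failed: " + "; ".join(diag.failures())
        )
    lower = extract_lower_two_thirds(mesh, stack)
    slabs = partition_slabs(
        lower, stack, lm=lm, force=config.force_segmentation,
        provenance={"mesh": str(mesh_path), "landmarks": str(landmarks_path)},
    )
    profile = slab_volumes(slabs)
    report = {
        "tool": "volceph",
        "version": __version__,
        "config_hash": config.hash(),
        "inputs": {"mesh": str(mesh_path), "landmarks": str(landmarks_path)},
        "head_volume_mm3": mesh_volume(mesh),
        "lower_two_thirds_mm3": mesh_volume(lower),
        "profile": _profile_payload(profile, config.decimals),
        "empty_slabs": slabs.empty,
        "stack_diagnostics": {
            k: {"passed": bool(p), "gap_mm": float(g)}
            for k, (p, g) in diag.checks.items()
        },
    }
    if config.reference is not None:
        refs = load_references()
        if config.reference not in refs:
            raise KeyError(
                f"unknown reference {config.reference!r}; have {sorted(refs)}"
            )
        cmp_df = compare_to_reference(profile, refs[config.reference])
        report["reference_comparison"] = {
            "reference": config.reference,
            "flags": list(refs[config.reference].flags),
            "deviations_pp": {
                r: float(cmp_df.loc[r, "deviation_pp"]) for r in REGIONS
            },
            "equalizing_volume_mm3": {
                r: float(cmp_df.loc[r, "equalizing_volume_mm3"]) for r in REGIONS
            },
        }
    if out is not None:
        _write_report(report, out)
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_report(report: dict, out: str | Path) -> None:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out.with_suffix(".json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    flat = {}

    def _flatten(prefix, obj):
        if isinstance(obj, dict):
            for k, v in obj.items():
                _flatten(f"{prefix}{k}.", v)
        elif isinstance(obj, (list, tuple)):
            flat[prefix[:-1]] = ";".join(map(str, obj))
        else:
            flat[prefix[:-1]] = obj

    _flatten("", report)
    pd.DataFrame([flat]).to_csv(out.with_suffix(".csv"), index=False)


def run_cohort(
    manifest_path: str | Path,
    scores_path: str | Path,
    config: RunConfig = RunConfig(),
    out: str | Path | None = None,
) -> dict:
    """Cohort pipeline: per-subject measurement, jury selection, judge
    repeatability, per-region normality, gender summary, normative deviations.

    Per-subject failures are logged and excluded; the summary reports how
    many subjects failed.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    needed = {"subject_id", "gender", "mesh_path", "landmarks_path"}
    if not needed.issubset(manifest.columns):
        raise ValueError(f"manifest needs columns {sorted(needed)}")
    scores = JuryScores.from_csv(scores_path)
    mean_scores = scores.mean_per_subject()
    selected = set(select_attractive(scores, cutoff=config.cutoff))
    if not selected:
        warnings.warn(
            f"no subject reaches the cutoff {config.cutoff}; summary still emitted",
            stacklevel=2,
        )

    rows, failures = [], []
    root = manifest_path.parent
    for _, entry in manifest.iterrows():
        sid = entry["subject_id"]
        try:
            rep = run_measure(
                root / entry["mesh_path"], root / entry["landmarks_path"], config
            )
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            log.error("subject %s failed: %s", sid, exc)
            failures.append({"subject_id": sid, "error": str(exc)})
            continue
        prof = rep["profile"]
        rows.append(
            {
                "subject_id": sid,
                "gender": entry["gender"],
                **{f"v_{r}": prof[f"v_{r}"] for r in REGIONS},
                "mean_score": float(mean_scores.get(sid, np.nan)),
                "selected": sid in selected,
            }
        )
    if not rows:
        raise RuntimeError("no subject could be measured")
    cohort = CohortTable(pd.DataFrame(rows))

    repeat = judge_repeatability(scores)
    normality = {}
    refs = load_references()
    for gender in sorted(set(cohort.table.gender)):
        sub = cohort.table[cohort.table.gender == gender]
        per_region = {}
        for r in REGIONS:
            try:
                w, p = normality_check(sub[f"v_{r}"].to_numpy())
                per_region[r] = {"W": w, "p": p}
            except Exception as exc:  # small stratum or zero variance
                per_region[r] = {"error": str(exc)}
        normality[gender] = per_region

    summary = cohort_summary(cohort, decimals=config.decimals)
    deviations = {}
    for gender, stratum in summary.items():
        profile = VolumeProfile(
            *(stratum["mean_volumes_mm3"][r] for r in REGIONS)
        )
        cmp_df = compare_to_reference(profile, refs[gender])
        deviations[gender] = {
            r: float(cmp_df.loc[r, "deviation_pp"]) for r in REGIONS
        }

    result = {
        "tool": "volceph",
        "version": __version__,
        "config_hash": config.hash(),
        "n_subjects": int(len(rows)),
        "n_failed": int(len(failures)),
        "failures": failures,
        "cutoff": config.cutoff,
        "n_selected": int(len(selected)),
        "selected": sorted(selected),
        "judge_repeatability": {
            j: {"r": float(repeat.loc[j, "r"]), "p": float(repeat.loc[j, "p"]),
                "n_paired": int(repeat.loc[j, "n_paired"])}
            for j in repeat.index
        },
        "mean_judge_r": repeat.attrs["mean_r"],
        "normality": normality,
        "summary": summary,
        "deviation_from_reference_pp": deviations,
    }
    if out is not None:
        _write_report(result, out)
        cohort.table.to_csv(Path(out).with_suffix(".subjects.csv"), index=False)
    return result
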