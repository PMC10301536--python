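"""Named cephalometric landmarks and their file formats.

A landmark set maps anatomical point names to 3D coordinates in mm.  The
required names cover everything the six cutting planes need: both porions,
the left orbitale (right optional), ANS/PNS, an anterior + two molar occlusal
points, both gonions, menton, and both mental foramina.

File formats: a JSON object ``{"name": [x, y, z], ...}`` or a CSV with
columns ``name,x,y,z``.  Unknown names are preserved but ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import LandmarkError

__all__ = ["REQUIRED_LANDMARKS", "OPTIONAL_LANDMARKS", "LandmarkSet",
           "read_landmarks", "write_landmarks"]

REQUIRED_LANDMARKS = (
    "porion_l",
    "porion_r",
    "orbitale_l",
    "ans",
    "pns",
    "occlusal_anterior",
    "occlusal_molar_l",
    "occlusal_molar_r",
    "gonion_l",
    "gonion_r",
    "menton",
    "mental_foramen_l",
    "mental_foramen_r",
)
OPTIONAL_LANDMARKS = ("orbitale_r",)

#: left/right pairs that must be laterally separated
_PAIRS = (
    ("porion_l", "porion_r"),
    ("occlusal_molar_l", "occlusal_molar_r"),
    ("gonion_l", "gonion_r"),
    ("mental_foramen_l", "mental_foramen_r"),
)
_MIN_PAIR_SEPARATION_MM = 10.0


@dataclass
class LandmarkSet:
    """Validated mapping from landmark name to a 3-vector in mm."""

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        clean: dict[str, np.ndarray] = {}
        problems: list[str] = []
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=float).reshape(-1)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                problems.append(f"landmark {name!r} has invalid coordinates {p!r}")
                continue
            clean[name] = arr
        missing = [n for n in REQUIRED_LANDMARKS if n not in clean]
        if missing:
            problems.append("missing required landmarks: " + ", ".join(missing))
        for left, right in _PAIRS:
            if left in clean and right in clean:
                sep = float(np.linalg.norm(clean[left] - clean[right]))
                if sep < _MIN_PAIR_SEPARATION_MM:
                    problems.append(
                        f"{left}/{right} separated by only {sep:.2f} mm "
                        f"(< {_MIN_PAIR_SEPARATION_MM} mm)"
                    )
        if problems:
            raise LandmarkError("; ".join(problems))
        self.points = clean

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise LandmarkError(f"landmark {name!r} not present") from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def names(self) -> list[str]:
        return list(self.points)

    def transformed(self, matrix: np.ndarray) -> "LandmarkSet":
        """Apply a 4x4 homogeneous transform to every landmark."""
        M = np.asarray(matrix, dtype=float)
        out = {
            n: (M[:3, :3] @ p + M[:3, 3]) for n, p in self.points.items()
        }
        return LandmarkSet(out)


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark file (JSON object or ``name,x,y,z`` CSV)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        if not isinstance(raw, dict):
            raise LandmarkError(f"{path}: landmark JSON must be an object")
        return LandmarkSet({str(k): np.asarray(v, float) for k, v in raw.items()})
    df = pd.read_csv(path)
    needed = {"name", "x", "y", "z"}
    if not needed.issubset(df.columns):
        raise LandmarkError(
            f"{path}: landmark CSV needs columns name,x,y,z (got {list(df.columns)})"
        )
    dups = df["name"][df["name"].duplicated()].tolist()
    if dups:
        raise LandmarkError(f"{path}: duplicate landmark names: {dups}")
    return LandmarkSet(
        {
            str(r["name"]): np.array([r["x"], r["y"], r["z"]], dtype=float)
            for _, r in df.iterrows()
        }
    )


def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    """Write landmarks as JSON (or CSV if the suffix is .csv)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        pd.DataFrame(
            [{"name": n, "x": p[0], "y": p[1], "z": p[2]}
             for n, p in lm.points.items()]
        ).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            json.dump({n: p.tolist() for n, p in lm.points.items()}, fh, indent=1)
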