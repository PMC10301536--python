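"""Cohort-level statistics: volume distributions, jury selection, reliability.

The core statistic is the percentage distribution of soft-tissue volume over
the four slabs of the lower two-thirds (malar, maxillary, mandibular, chin)
and the maxilla/mandible volume ratio.  Around it sit the study-design
stages: inclusive-cutoff selection of the most attractive subjects from a
6-judge x 2-session aesthetic score table, per-judge test-retest Pearson
repeatability, Shapiro-Wilk normality of the volumes, gender-stratified
summaries, and comparison of an individual profile to a gender-specific
normative reference.

Reported shares use half-away-from-zero rounding at 1 decimal (ratios at 2
decimals), matching clinical reporting precision.  Gender-stratum shares are
computed from the mean volumes, not as means of per-subject shares.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources as importlib_resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CohortError

__all__ = [
    "VolumeProfile",
    "JuryScores",
    "NormativeReference",
    "CohortTable",
    "REGIONS",
    "round_half_away",
    "percentage_distribution",
    "maxillomandibular_ratio",
    "select_attractive",
    "pearson_repeatability",
    "judge_repeatability",
    "normality_check",
    "cohort_summary",
    "compare_to_reference",
    "load_references",
]

REGIONS = ("malar", "maxillary", "mandibular", "chin")

GENDERS = ("female", "male")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (2.25 -> 2.3, -2.25 -> -2.3 at 1 decimal)."""
    f = 10.0**decimals
    return math.copysign(math.floor(abs(x) * f + 0.5) / f, x)


@dataclass(frozen=True)
class VolumeProfile:
    """Four slab volumes (mm³) with total, percentage shares and the
    maxilla/mandible ratio.  Shares are stored unrounded and sum to 100."""

    v_malar: float
    v_maxillary: float
    v_mandibular: float
    v_chin: float

    @property
    def volumes(self) -> tuple[float, float, float, float]:
        return (self.v_malar, self.v_maxillary, self.v_mandibular, self.v_chin)

    @property
    def total(self) -> float:
        return float(sum(self.volumes))

    @property
    def shares(self) -> tuple[float, float, float, float]:
        t = self.total
        if t <= 0:
            raise CohortError("total volume must be positive to compute shares")
        return tuple(100.0 * v / t for v in self.volumes)

    @property
    def mm_ratio(self) -> float:
        return maxillomandibular_ratio(
            self.v_maxillary, self.v_mandibular, decimals=None
        )

    def __post_init__(self):
        if any((not np.isfinite(v)) or v < 0 for v in self.volumes):
            raise CohortError(f"volumes must be finite and >= 0, got {self.volumes}")

    def rounded_shares(self, decimals: int = 1) -> tuple[float, ...]:
        return tuple(round_half_away(s, decimals) for s in self.shares)

    def as_dict(self, decimals: int = 1) -> dict:
        shares = self.rounded_shares(decimals)
        return {
            **{f"v_{r}": v for r, v in zip(REGIONS, self.volumes)},
            "total": self.total,
            **{f"share_{r}": s for r, s in zip(REGIONS, shares)},
            "mm_ratio": round_half_away(self.mm_ratio, 2),
        }


def percentage_distribution(volumes, decimals: int | None = 1):
    """Shares (percent of the total) of four region volumes.

    ``decimals=None`` returns unrounded shares; otherwise half-away-from-zero
    rounding at the given number of decimals.
    """
    v = [float(x) for x in volumes]
    if len(v) != 4:
        raise CohortError(f"expected 4 region volumes, got {len(v)}")
    total = sum(v)
    if total <= 0:
        raise CohortError("total volume must be > 0")
    shares = [100.0 * x / total for x in v]
    if decimals is None:
        return tuple(shares)
    return tuple(round_half_away(s, decimals) for s in shares)


def maxillomandibular_ratio(
    v_maxillary: float, v_mandibular: float, decimals: int | None = 2
) -> float:
    """Maxillary / mandibular volume ratio (> 1: maxillary prevalence)."""
    if v_mandibular <= 0:
        raise CohortError("mandibular volume must be > 0 for the ratio")
    r = float(v_maxillary) / float(v_mandibular)
    return r if decimals is None else round_half_away(r, decimals)


# ---------------------------------------------------------------------------
# jury scores
# ---------------------------------------------------------------------------

@dataclass
class JuryScores:
    """Long-format aesthetic score table (judge x session x subject).

    Scores are on the 1-10 attractiveness scale.  Every subject must be
    scored by every judge in session 1; session 2 (the repeat after a washout
    interval) may be partial.
    """

    table: pd.DataFrame

    REQUIRED_COLUMNS = ("judge_id", "session", "subject_id", "score")

    def __post_init__(self):
        df = self.table.copy()
        missing = [c for c in self.REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise CohortError(f"score table missing columns: {missing}")
        df["score"] = df["score"].astype(float)
        df["session"] = df["session"].astype(int)
        if ((df["score"] < 1) | (df["score"] > 10)).any():
            bad = df.loc[(df["score"] < 1) | (df["score"] > 10)]
            raise CohortError(
                f"scores outside [1, 10] for subjects {sorted(set(bad.subject_id))}"
            )
        s1 = df[df.session == 1]
        judges = sorted(set(df.judge_id))
        for j in judges:
            scored = set(s1[s1.judge_id == j].subject_id)
            everyone = set(df.subject_id)
            if scored != everyone:
                raise CohortError(
                    f"judge {j!r} did not score subjects "
                    f"{sorted(everyone - scored)} in session 1"
                )
        self.table = df

    @classmethod
    def from_csv(cls, path) -> "JuryScores":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def mean_per_subject(self) -> pd.Series:
        """Mean over all (judge, session) scores, pooled equally."""
        return self.table.groupby("subject_id")["score"].mean()


def select_attractive(scores: JuryScores, cutoff: float = 8.5, subjects=None):
    """Subjects whose mean score over all judges and sessions is >= cutoff.

    The threshold is inclusive.  ``subjects`` optionally names the full roster;
    any of them with no scores raises an error naming the subject.
    """
    means = scores.mean_per_subject()
    if subjects is not None:
        missing = [s for s in subjects if s not in means.index]
        if missing:
            raise CohortError(f"subjects with no scores: {missing}")
    selected = means[means >= cutoff].index.tolist()
    return sorted(selected)


def pearson_repeatability(session1, session2) -> tuple[float, float]:
    """Pearson r and two-sided p for one judge's paired session scores."""
    a = np.asarray(session1, float)
    b = np.asarray(session2, float)
    if len(a) != len(b) or len(a) < 3:
        raise CohortError("need >= 3 paired scores per judge")
    if np.std(a) == 0 or np.std(b) == 0:
        raise CohortError("zero variance in a session; r undefined")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)


def judge_repeatability(scores: JuryScores) -> pd.DataFrame:
    """Per-judge test-retest Pearson correlation between sessions 1 and 2.

    Returns a DataFrame indexed by judge with columns r, p, n_paired; judges
    with undefined r (zero variance) get NaN and are excluded from the
    ``mean_r`` attribute with a warning.
    """
    wide = scores.table.pivot_table(
        index="subject_id", columns=["judge_id", "session"], values="score"
    )
    rows = []
    for judge in sorted(set(scores.table.judge_id)):
        try:
            sub = wide[judge][[1, 2]].dropna()
        except KeyError:
            continue  # judge missing a session entirely
        try:
            r, p = pearson_repeatability(sub[1], sub[2])
        except CohortError as exc:
            warnings.warn(f"judge {judge!r}: {exc}; excluded from mean r",
                          stacklevel=2)
            r, p = float("nan"), float("nan")
        rows.append({"judge_id": judge, "r": r, "p": p, "n_paired": len(sub)})
    out = pd.DataFrame(rows).set_index("judge_id")
    out.attrs["mean_r"] = float(np.nanmean(out["r"])) if len(out) else float("nan")
    return out


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston AS R94, via scipy)."""
    v = np.asarray(values, float)
    if len(v) < 3:
        raise CohortError("Shapiro-Wilk needs n >= 3")
    if len(v) > 5000:
        raise CohortError("Shapiro-Wilk limited to n <= 5000")
    if np.ptp(v) == 0:
        raise CohortError("zero variance; Shapiro-Wilk undefined")
    w, p = sps.shapiro(v)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# cohort table and summaries
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Per-subject volume profiles with gender, mean score and selection flag.

    Backed by a DataFrame with columns subject_id, gender, v_malar,
    v_maxillary, v_mandibular, v_chin and optional mean_score, selected.
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table.copy()
        needed = ["subject_id", "gender"] + [f"v_{r}" for r in REGIONS]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise CohortError(f"cohort table missing columns: {missing}")
        if df["subject_id"].duplicated().any():
            dups = df["subject_id"][df["subject_id"].duplicated()].tolist()
            raise CohortError(f"duplicate subject ids: {dups}")
        bad = sorted(set(df["gender"]) - set(GENDERS))
        if bad:
            raise CohortError(
                f"unknown gender labels {bad}; expected one of {GENDERS}"
            )
        self.table = df

    def profiles(self) -> dict[str, VolumeProfile]:
        return {
            row["subject_id"]: VolumeProfile(
                *(row[f"v_{r}"] for r in REGIONS)
            )
            for _, row in self.table.iterrows()
        }


def cohort_summary(cohort: CohortTable, decimals: int = 1) -> dict:
    """Gender-stratified summary: mean volumes, shares from those means,
    maxilla/mandible ratio from the mean volumes, and subject counts.

    Shares are computed FROM the mean volumes (not by averaging per-subject
    shares), so a stratum's printed shares are exactly the distribution of
    its printed mean volumes.
    """
    out: dict[str, dict] = {}
    for gender in GENDERS:
        sub = cohort.table[cohort.table.gender == gender]
        if len(sub) == 0:
            warnings.warn(f"no subjects in stratum {gender!r}; omitted",
                          stacklevel=2)
            continue
        means = [float(sub[f"v_{r}"].mean()) for r in REGIONS]
        profile = VolumeProfile(*means)
        out[gender] = {
            "n": int(len(sub)),
            "mean_volumes_mm3": dict(zip(REGIONS, means)),
            "shares_percent": dict(
                zip(REGIONS, profile.rounded_shares(decimals))
            ),
            "shares_percent_unrounded": dict(zip(REGIONS, profile.shares)),
            "mm_ratio": round_half_away(profile.mm_ratio, 2),
        }
    if not out:
        raise CohortError("cohort has no subjects in any known stratum")
    return out


# ---------------------------------------------------------------------------
# normative references
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormativeReference:
    """Gender-specific target shares (percent) of the four regions."""

    gender: str
    shares: dict[str, float]
    source: str = "embedded"
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        missing = [r for r in REGIONS if r not in self.shares]
        if missing:
            raise CohortError(f"reference missing regions: {missing}")
        total = sum(self.shares.values())
        if not (95.0 <= total <= 105.0):
            raise CohortError(f"reference shares sum to {total}, far from 100")


def load_references() -> dict[str, NormativeReference]:
    """The embedded normative reference distributions, stored verbatim as
    reported (the male set sums to 99% and carries inconsistency flags)."""
    with importlib_resources.files("volceph.resources").joinpath(
        "normative_references.json"
    ).open() as fh:
        raw = json.load(fh)
    refs = {}
    for gender, entry in raw["references"].items():
        refs[gender] = NormativeReference(
            gender=gender,
            shares={r: float(entry["shares"][r]) for r in REGIONS},
            source=raw.get("source", "embedded"),
            flags=tuple(entry.get("flags", [])),
        )
    return refs


def reference_mean_volumes() -> dict[str, dict[str, float]]:
    """The reported gender mean volumes (mm³) backing the references."""
    with importlib_resources.files("volceph.resources").joinpath(
        "normative_references.json"
    ).open() as fh:
        raw = json.load(fh)
    return {
        g: {r: float(e["mean_volumes_mm3"][r]) for r in REGIONS}
        for g, e in raw["references"].items()
    }


def compare_to_reference(
    profile: VolumeProfile, ref: NormativeReference
) -> pd.DataFrame:
    """Signed deviation of a subject's shares from a normative reference.

    For each region: ``deviation_pp`` = subject share - reference share (in
    percentage points) and ``equalizing_volume_mm3`` = the volume change that
    would bring that region's share to the reference at constant total
    (positive = tissue to add).  The equalizing changes are per-region,
    holding the total fixed; applying one changes the other shares, so they
    are a first-order guide, not a simultaneous solution.
    """
    shares = dict(zip(REGIONS, profile.shares))
    total = profile.total
    rows = []
    for r in REGIONS:
        dev = shares[r] - ref.shares[r]
        rows.append(
            {
                "region": r,
                "subject_share": shares[r],
                "reference_share": ref.shares[r],
                "deviation_pp": dev,
                "equalizing_volume_mm3": -dev / 100.0 * total,
            }
        )
    out = pd.DataFrame(rows).set_index("region")
    out.attrs["reference_gender"] = ref.gender
    out.attrs["reference_flags"] = list(ref.flags)
    return out
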