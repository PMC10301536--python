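"""Percentage distributions, jury selection, reliability and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from volceph.cohort import (
    REGIONS,
    CohortTable,
    JuryScores,
    VolumeProfile,
    cohort_summary,
    compare_to_reference,
    judge_repeatability,
    load_references,
    maxillomandibular_ratio,
    normality_check,
    pearson_repeatability,
    percentage_distribution,
    round_half_away,
    select_attractive,
)
from volceph.errors import CohortError

from conftest import FEMALE_VOLUMES, MALE_VOLUMES


class TestPercentageDistribution:
    def test_female_mean_volumes(self):
        assert percentage_distribution(FEMALE_VOLUMES) == (38.7, 29.0, 27.6, 4.7)

    def test_symmetry(self):
        assert percentage_distribution((1, 1, 1, 1)) == (25.0, 25.0, 25.0, 25.0)

    def test_male_mean_volumes_one_decimal(self):
        assert percentage_distribution(MALE_VOLUMES) == (36.5, 28.0, 29.5, 6.0)

    def test_zero_total_rejected(self):
        with pytest.raises(CohortError):
            percentage_distribution((0, 0, 0, 0))

    def test_rounding_half_away(self):
        assert round_half_away(2.25, 1) == 2.3
        assert round_half_away(-2.25, 1) == -2.3
        assert round_half_away(29.5035, 0) == 30.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=1e-3, max_value=1e7), min_size=4,
                    max_size=4))
    def test_unrounded_shares_sum_to_100(self, volumes):
        shares = percentage_distribution(volumes, decimals=None)
        assert sum(shares) == pytest.approx(100.0, abs=1e-9)


class TestRatio:
    def test_female_printed_ratio(self):
        assert maxillomandibular_ratio(212433, 202279) == 1.05

    def test_equal_volumes(self):
        assert maxillomandibular_ratio(5.0, 5.0) == 1.0

    def test_male_volume_derived_ratio(self):
        # from the male mean volumes; differs from the printed 0.87, which
        # traces to the internally inconsistent male share line
        assert maxillomandibular_ratio(230526, 242905) == 0.95

    def test_zero_mandible_rejected(self):
        with pytest.raises(CohortError):
            maxillomandibular_ratio(1.0, 0.0)


def _scores_from_means(means: dict[str, float]) -> JuryScores:
    rows = [
        {"judge_id": "j1", "session": 1, "subject_id": sid, "score": m}
        for sid, m in means.items()
    ]
    return JuryScores(pd.DataFrame(rows))


class TestSelection:
    def test_inclusive_threshold(self):
        scores = _scores_from_means({"s1": 8.7, "s2": 8.4, "s3": 8.5})
        assert select_attractive(scores, cutoff=8.5) == ["s1", "s3"]

    def test_empty_cohort(self):
        scores = _scores_from_means({"s1": 9.0})
        assert select_attractive(scores, cutoff=9.5) == []

    def test_boundary_full_jury(self):
        rows = [
            {"judge_id": f"j{j}", "session": t, "subject_id": "solo",
             "score": 8.5}
            for j in range(1, 7)
            for t in (1, 2)
        ]
        scores = JuryScores(pd.DataFrame(rows))
        assert select_attractive(scores, cutoff=8.5) == ["solo"]

    def test_monotone_in_cutoff(self):
        scores = _scores_from_means(
            {f"s{i}": 6.0 + 0.5 * i for i in range(8)}
        )
        prev = None
        for cutoff in (6.0, 7.0, 8.0, 9.0):
            sel = set(select_attractive(scores, cutoff=cutoff))
            if prev is not None:
                assert sel.issubset(prev)
            prev = sel

    def test_missing_subject_named(self):
        scores = _scores_from_means({"s1": 9.0})
        with pytest.raises(CohortError, match="s2"):
            select_attractive(scores, subjects=["s1", "s2"])


class TestRepeatability:
    def test_identical_sessions(self):
        r, _ = pearson_repeatability([8, 9, 7, 6], [8, 9, 7, 6])
        assert r == pytest.approx(1.0)

    def test_reversed_sessions(self):
        s1 = [8.0, 9.0, 7.0, 6.0]
        r, _ = pearson_repeatability(s1, [11 - x for x in s1])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 4.0, var1 = 5.0, var2 = 3.5 -> r = 4 / sqrt(17.5)
        r, _ = pearson_repeatability([8, 9, 7, 6], [7.5, 9, 7, 6.5])
        assert r == pytest.approx(4.0 / np.sqrt(17.5), abs=1e-12)
        assert r == pytest.approx(0.9562, abs=1e-3)

    def test_symmetric_and_affine_invariant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(7, 1, 10)
        b = a + rng.normal(0, 0.5, 10)
        r_ab, _ = pearson_repeatability(a, b)
        r_ba, _ = pearson_repeatability(b, a)
        r_scaled, _ = pearson_repeatability(2.0 * a + 1.0, 0.5 * b - 3.0)
        assert r_ab == pytest.approx(r_ba, abs=1e-12)
        assert r_ab == pytest.approx(r_scaled, abs=1e-10)

    def test_zero_variance_judge_excluded_with_warning(self):
        rows = []
        for sid, (x, y) in {"a": (8, 8), "b": (9, 8), "c": (7, 8)}.items():
            rows.append({"judge_id": "flat", "session": 1, "subject_id": sid,
                         "score": y})
            rows.append({"judge_id": "flat", "session": 2, "subject_id": sid,
                         "score": y})
            rows.append({"judge_id": "ok", "session": 1, "subject_id": sid,
                         "score": x})
            rows.append({"judge_id": "ok", "session": 2, "subject_id": sid,
                         "score": x})
        scores = JuryScores(pd.DataFrame(rows))
        with pytest.warns(UserWarning, match="flat"):
            table = judge_repeatability(scores)
        assert np.isnan(table.loc["flat", "r"])
        assert table.attrs["mean_r"] == pytest.approx(table.loc["ok", "r"])


class TestNormality:
    def test_against_reference_implementation(self):
        """Frozen oracle from R's shapiro.test on the same sample:
        W = 0.90805, p = 0.2679."""
        w, p = normality_check([148, 154, 158, 160, 161, 162, 166, 170, 182, 195])
        assert w == pytest.approx(0.90805, abs=1e-3)
        assert p == pytest.approx(0.2679, abs=1e-3)

    def test_normal_draws_usually_pass(self):
        rng = np.random.default_rng(2024)
        passes = sum(
            normality_check(rng.normal(7e5, 5e4, 26))[1] > 0.05
            for _ in range(100)
        )
        assert passes >= 90

    def test_zero_variance_flagged(self):
        with pytest.raises(CohortError):
            normality_check([1.0] * 10)

    def test_too_small_sample(self):
        with pytest.raises(CohortError):
            normality_check([1.0, 2.0])


def _cohort_of(rows) -> CohortTable:
    return CohortTable(pd.DataFrame(rows))


class TestCohortSummary:
    def test_single_subject_reproduces_reported_female_distribution(self):
        cohort = _cohort_of(
            [{"subject_id": "f1", "gender": "female",
              **{f"v_{r}": v for r, v in zip(REGIONS, FEMALE_VOLUMES)}}]
        )
        with pytest.warns(UserWarning):  # empty male stratum
            summary = cohort_summary(cohort)
        shares = summary["female"]["shares_percent"]
        assert tuple(shares[r] for r in REGIONS) == (38.7, 29.0, 27.6, 4.7)
        assert summary["female"]["mm_ratio"] == 1.05
        assert summary["female"]["n"] == 1

    def test_duplicated_subject_idempotent(self):
        rows = [
            {"subject_id": f"f{i}", "gender": "female",
             **{f"v_{r}": v for r, v in zip(REGIONS, FEMALE_VOLUMES)}}
            for i in (1, 2)
        ]
        with pytest.warns(UserWarning):
            two = cohort_summary(_cohort_of(rows))
        with pytest.warns(UserWarning):
            one = cohort_summary(_cohort_of(rows[:1]))
        assert two["female"]["shares_percent"] == one["female"]["shares_percent"]
        assert two["female"]["n"] == 2

    def test_unknown_gender_rejected(self):
        with pytest.raises(CohortError, match="gender"):
            _cohort_of(
                [{"subject_id": "x", "gender": "other",
                  **{f"v_{r}": 1.0 for r in REGIONS}}]
            )

    def test_duplicate_ids_rejected(self):
        rows = [
            {"subject_id": "dup", "gender": "female",
             **{f"v_{r}": 1.0 for r in REGIONS}}
        ] * 2
        with pytest.raises(CohortError, match="dup"):
            _cohort_of(rows)


class TestReferences:
    def test_embedded_values(self):
        refs = load_references()
        female = refs["female"]
        assert tuple(female.shares[r] for r in REGIONS) == (38.7, 29.0, 27.6, 4.7)
        male = refs["male"]
        assert tuple(male.shares[r] for r in REGIONS) == (37.0, 26.0, 30.0, 6.0)
        # male shares are stored verbatim (sum 99) and flagged
        assert sum(male.shares.values()) == pytest.approx(99.0)
        assert male.flags and not female.flags

    def test_identity_comparison(self):
        ref = load_references()["female"]
        profile = VolumeProfile(38.7, 29.0, 27.6, 4.7)  # shares-as-volumes
        df = compare_to_reference(profile, ref)
        assert np.allclose(df["deviation_pp"], 0.0, atol=1e-9)

    def test_deviation_and_equalizing_volume(self):
        total = 732057.0
        shares = np.array([36.7, 29.0, 29.6, 4.7]) / 100.0 * total
        profile = VolumeProfile(*shares)
        df = compare_to_reference(profile, load_references()["female"])
        assert df.loc["malar", "deviation_pp"] == pytest.approx(-2.0, abs=1e-9)
        assert df.loc["mandibular", "deviation_pp"] == pytest.approx(2.0, abs=1e-9)
        assert df.loc["maxillary", "deviation_pp"] == pytest.approx(0.0, abs=1e-9)
        assert df.loc["malar", "equalizing_volume_mm3"] == pytest.approx(
            0.02 * total, rel=1e-9
        )
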