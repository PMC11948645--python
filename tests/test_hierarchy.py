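"""Hierarchy score, trajectories, group comparisons and behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gradnorm.atlas import NETWORKS, make_atlas
from gradnorm.hierarchy import (age_bin_analysis, behavior_correlation,
                                compare_centiles, fit_score_trajectory,
                                hierarchy_score, score_cohort,
                                sigma_age_effect)
from gradnorm.normative import NormativeConfig


class TestHierarchyScore:
    def test_analytic_cases(self):
        g = np.array([1.0, 2.0, -1.0])
        assert hierarchy_score(g, g) == pytest.approx(1.0)
        assert hierarchy_score(2 * g, g) == pytest.approx(1.0)
        assert hierarchy_score(-g, g) == pytest.approx(-1.0)
        assert hierarchy_score([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="zero"):
            hierarchy_score([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="mismatch"):
            hierarchy_score([1.0, 2.0], [1.0, 2.0, 3.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 100), st.integers(0, 2**31 - 1))
    def test_scale_invariance_and_antisymmetry(self, c, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(12), rng.standard_normal(12)
        s = hierarchy_score(a, b)
        assert hierarchy_score(c * a, b) == pytest.approx(s, abs=1e-10)
        assert hierarchy_score(-a, b) == pytest.approx(-s, abs=1e-10)
        assert -1 - 1e-12 <= s <= 1 + 1e-12


def _scores_cohort(rng, n=400, group="TD", trend=0.01, noise=0.05,
                   peak=None):
    age = rng.uniform(5, 22, n)
    if peak is None:
        mu = trend * age
    else:
        mu = -0.002 * (age - peak) ** 2
    score = mu + rng.normal(0, noise, n)
    cohort = pd.DataFrame({
        "subject_id": [f"{group.lower()}-{i}" for i in range(n)],
        "age": age,
        "sex": rng.choice(["male", "female"], n),
        "group": group,
    })
    scores = pd.DataFrame({"score": score},
                          index=pd.Index(cohort["subject_id"],
                                         name="subject_id"))
    return scores, cohort


class TestTrajectory:
    def test_linear_trend_slope_recovered(self):
        rng = np.random.default_rng(0)
        scores, cohort = _scores_cohort(rng, trend=0.01)
        fit = fit_score_trajectory(scores, cohort, "TD", NormativeConfig())
        for sex in ("male", "female"):
            assert fit.slope_per_year[sex] == pytest.approx(0.01, abs=0.003)

    def test_monotone_curve_has_no_interior_peak(self):
        rng = np.random.default_rng(1)
        scores, cohort = _scores_cohort(rng, trend=0.02, noise=0.02)
        fit = fit_score_trajectory(scores, cohort, "TD",
                                   NormativeConfig(select_smoothing=True))
        assert fit.peak_age["male"] is None
        assert fit.peak_age["female"] is None

    def test_inverted_u_peak_recovered(self):
        rng = np.random.default_rng(2)
        scores, cohort = _scores_cohort(rng, peak=15.0, noise=0.03)
        fit = fit_score_trajectory(scores, cohort, "TD",
                                   NormativeConfig(select_smoothing=True))
        for sex in ("male", "female"):
            assert fit.peak_age[sex] == pytest.approx(15.0, abs=1.5)

    def test_bands_bracket_median(self):
        rng = np.random.default_rng(3)
        scores, cohort = _scores_cohort(rng)
        fit = fit_score_trajectory(scores, cohort, "TD", NormativeConfig())
        for sex in ("male", "female"):
            assert (fit.band_low[sex] <= fit.median[sex]).all()
            assert (fit.median[sex] <= fit.band_high[sex]).all()

    def test_absent_group_rejected(self):
        rng = np.random.default_rng(4)
        scores, cohort = _scores_cohort(rng)
        with pytest.raises(ValueError):
            fit_score_trajectory(scores, cohort, "ASD", NormativeConfig())

    def test_sigma_narrowing_detected(self):
        rng = np.random.default_rng(5)
        n = 500
        age = rng.uniform(5, 22, n)
        score = rng.normal(0, 0.2 * np.exp(-0.06 * age))
        cohort = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)],
                               "age": age,
                               "sex": rng.choice(["male", "female"], n),
                               "group": "TD"})
        scores = pd.DataFrame({"score": score},
                              index=pd.Index(cohort["subject_id"],
                                             name="subject_id"))
        res = sigma_age_effect(scores, cohort, "TD",
                               NormativeConfig(mu_terms=("age",)))
        assert res.p < 0.05 and res.sign == -1


class TestScoreCohort:
    def test_subject_matching_median_curve_scores_one(self, tiny_atlas):
        rng = np.random.default_rng(6)
        from gradnorm.normative import fit_normative

        n = 200
        age = rng.uniform(5, 22, n)
        sex = rng.choice(["male", "female"], n)
        models = {}
        target = {}
        for j, parcel in enumerate(tiny_atlas.parcel_ids):
            base = np.sin(j) + 0.01 * j * age / 22
            y = base + rng.normal(0, 0.05, n)
            models[parcel] = fit_normative(y, age, sex,
                                           NormativeConfig(mu_terms=("age",)))
            target[parcel] = models[parcel].median(age, sex)
        cohort = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)],
                               "age": age, "sex": sex, "group": "TD"})
        gradients = pd.DataFrame(target,
                                 index=pd.Index(cohort["subject_id"],
                                                name="subject_id"))
        scores = score_cohort(gradients, models, cohort)
        np.testing.assert_allclose(scores["score"], 1.0, atol=1e-10)

    def test_missing_model_rejected(self, tiny_atlas):
        cohort = pd.DataFrame({"subject_id": ["a"], "age": [9.0],
                               "sex": ["male"], "group": ["TD"]})
        gradients = pd.DataFrame({"p1": [0.3]}, index=["a"])
        with pytest.raises(ValueError, match="model"):
            score_cohort(gradients, {}, cohort)


class TestGroupComparisons:
    def _centiles(self, rng, n_per=60, shift=None):
        atlas = make_atlas(21, network_sizes={k: 3 for k in NETWORKS})
        cohort = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(2 * n_per)],
            "age": rng.uniform(5, 22, 2 * n_per),
            "sex": rng.choice(["male", "female"], 2 * n_per),
            "group": ["ASD"] * n_per + ["TD"] * n_per,
        })
        cent = pd.DataFrame(
            rng.uniform(0.2, 0.8, (2 * n_per, atlas.n_parcels)),
            index=pd.Index(cohort["subject_id"], name="subject_id"),
            columns=list(atlas.parcel_ids))
        if shift:
            asd = cohort["group"] == "ASD"
            for net, delta in shift.items():
                cols = np.asarray(cent.columns)[atlas.labels() == net]
                cent.loc[asd.to_numpy(), cols] += delta
        return atlas, cohort, cent

    def test_identical_groups_give_null_table(self):
        rng = np.random.default_rng(7)
        atlas, cohort, cent = self._centiles(rng)
        half = cent.iloc[:60].to_numpy()
        cent.iloc[60:] = half  # identical distributions subject-for-subject
        out = compare_centiles(cent, cohort, atlas, level="network")
        np.testing.assert_allclose(out["t"], 0.0, atol=1e-10)
        np.testing.assert_allclose(out["q"], 1.0)

    def test_planted_network_shift_signs(self):
        rng = np.random.default_rng(8)
        atlas, cohort, cent = self._centiles(
            rng, shift={"DMN": -0.15, "DorsalAttention": 0.15})
        out = compare_centiles(cent, cohort, atlas, level="network")
        out = out.set_index("feature")
        assert out.loc["DMN", "t"] < 0 and out.loc["DMN", "q"] < 0.05
        assert out.loc["DorsalAttention", "t"] > 0
        assert out.loc["DorsalAttention", "q"] < 0.05

    def test_age_bins_follow_half_open_convention(self):
        rng = np.random.default_rng(9)
        atlas, cohort, cent = self._centiles(rng)
        cohort["age"] = 12.0  # boundary age belongs to the middle bin
        out = age_bin_analysis(cent, cohort, atlas)
        assert out.loc[out["bin"] == "5-12", "flagged"].all()
        assert not out.loc[out["bin"] == "12-15", "flagged"].any()

    def test_single_age_cohort_populates_one_bin(self):
        rng = np.random.default_rng(10)
        atlas, cohort, cent = self._centiles(rng)
        cohort["age"] = 8.0
        out = age_bin_analysis(cent, cohort, atlas)
        assert not out.loc[out["bin"] == "5-12", "flagged"].any()
        assert out.loc[out["bin"] != "5-12", "flagged"].all()


class TestBehavior:
    def test_exact_anticorrelation(self):
        rng = np.random.default_rng(11)
        n = 40
        cohort = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)],
                               "age": rng.uniform(5, 22, n),
                               "sex": "male", "group": "ASD"})
        scores = pd.DataFrame({"score": rng.standard_normal(n)},
                              index=pd.Index(cohort["subject_id"],
                                             name="subject_id"))
        cohort["srs_total"] = -scores["score"].to_numpy()
        out = behavior_correlation(scores, cohort)
        assert out.loc[out["scale"] == "srs_total", "r"].iloc[0] == \
            pytest.approx(-1.0)

    def test_missing_columns_rejected(self):
        cohort = pd.DataFrame({"subject_id": ["a"], "age": [9.0],
                               "sex": ["male"], "group": ["TD"]})
        scores = pd.DataFrame({"score": [0.5]}, index=["a"])
        with pytest.raises(ValueError):
            behavior_correlation(scores, cohort)
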