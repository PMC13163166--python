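"""Mixed-model comparisons, effect sizes, transforms and BH correction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from sleepfrag.stats import (
    ModelResult,
    benjamini_hochberg,
    compare_transition_probabilities,
    fit_group_comparison,
    maybe_log_transform,
    split_night_model,
)


def bh_oracle(p: list[float], q: float) -> list[bool]:
    """Exhaustive step-up oracle: largest k with p_(k) <= k q / m rejects
    every hypothesis of rank <= k."""
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    rejected = [False] * m
    for k in range(k_star):
        rejected[order[k]] = True
    return rejected


def simulate_family_cohort(
    n_families: int,
    effect: float,
    rng: np.random.Generator,
    family_sd: float = 0.5,
) -> pd.DataFrame:
    """Patient/sibling pairs with a shared family intercept and unit noise."""
    rows = []
    for f in range(n_families):
        fam_eff = rng.normal(0, family_sd)
        for grp in ("patient", "sibling"):
            rows.append(
                {
                    "subject_id": f"{grp[0]}{f}",
                    "family_id": f"F{f}",
                    "group": grp,
                    "age_years": rng.uniform(10, 60),
                    "sex": "M" if rng.random() < 0.5 else "F",
                    "y": fam_eff
                    + (effect if grp == "patient" else 0.0)
                    + rng.normal(),
                }
            )
    return pd.DataFrame(rows)


class TestBenjaminiHochberg:
    def test_all_ones(self):
        rejected, adjusted = benjamini_hochberg([1.0] * 5)
        assert not rejected.any()
        assert np.all(adjusted == 1.0)

    def test_single_p(self):
        rejected, _ = benjamini_hochberg([0.04], q=0.05)
        assert rejected[0]

    def test_reference_list(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212,
             0.216]
        rejected, adjusted = benjamini_hochberg(p, q=0.05)
        assert rejected.tolist() == bh_oracle(p, 0.05)
        # k* = 2: p_(2) = 0.008 <= 2q/m = 0.01, p_(3) = 0.039 > 0.015
        assert rejected.sum() == 2
        # adjusted p monotone in rank
        order = np.argsort(p)
        assert np.all(np.diff(adjusted[order]) >= -1e-12)

    def test_matches_oracle_on_random_lists(self, rng):
        """1,000 random lists of <= 20 p-values agree with the exhaustive
        step-up oracle."""
        for _ in range(1000):
            m = int(rng.integers(1, 21))
            p = rng.random(m).tolist()
            q = float(rng.choice([0.01, 0.05, 0.1, 0.25]))
            rejected, adjusted = benjamini_hochberg(p, q=q)
            assert rejected.tolist() == bh_oracle(p, q)
            order = np.argsort(p)
            assert np.all(np.diff(adjusted[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.2, 1.4])
        with pytest.raises(ValueError):
            benjamini_hochberg([-0.1])


class TestMaybeLogTransform:
    def test_policy_never(self, rng):
        vals = rng.random(50)
        out, flag = maybe_log_transform(vals, policy="never")
        assert not flag and np.array_equal(out, vals)

    def test_lognormal_triggers_auto(self, rng):
        vals = rng.lognormal(0.0, 1.0, 500)
        assert scipy.stats.skew(vals, bias=False) > 1  # oracle premise
        out, flag = maybe_log_transform(vals, policy="auto")
        assert flag and np.allclose(out, np.log(vals))

    def test_normal_left_alone(self, rng):
        vals = rng.normal(10, 1, 500)
        _, flag = maybe_log_transform(vals, policy="auto")
        assert not flag

    def test_always_requires_positive(self):
        with pytest.raises(ValueError, match="positive"):
            maybe_log_transform(np.array([1.0, 0.0]), policy="always")

    def test_auto_falls_back_on_nonpositive(self, rng):
        vals = np.concatenate([rng.lognormal(0, 1.5, 300), [0.0]])
        out, flag = maybe_log_transform(vals, policy="auto")
        assert not flag and np.array_equal(out, vals)


class TestFitGroupComparison:
    def test_constant_outcome_is_an_error(self, rng):
        df = simulate_family_cohort(20, 0.0, rng)
        df["y"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_group_comparison(df, outcome="y")

    def test_collinear_design_named(self, rng):
        df = simulate_family_cohort(20, 0.0, rng)
        df["age_copy"] = df["age_years"]
        with pytest.raises(ValueError, match="age_copy"):
            fit_group_comparison(
                df, outcome="y",
                fixed_covariates=("age_years", "age_copy", "sex"),
            )

    def test_cohens_d_identity(self, rng):
        df = simulate_family_cohort(50, 0.8, rng)
        res = fit_group_comparison(df, outcome="y", transform_policy="never")
        assert res.cohens_d == pytest.approx(res.coefficient / res.residual_sd)
        assert res.ci95_low <= res.coefficient <= res.ci95_high

    def test_effect_recovery_sign(self, rng):
        """Injected standardized effect d = 1 at n = 100 recovers a positive
        Cohen's d in >= 95% of 200 replicates."""
        hits = 0
        for _ in range(200):
            df = simulate_family_cohort(50, 1.0, rng)
            res = fit_group_comparison(df, outcome="y",
                                       transform_policy="never")
            hits += res.cohens_d > 0
        assert hits / 200 >= 0.95

    def test_null_type_one_error_calibrated(self, rng):
        """Zero true group effect, n = 200, 200 replicates: empirical
        type-I error at alpha = .05 within [0.02, 0.08]."""
        false_pos = 0
        for _ in range(200):
            df = simulate_family_cohort(100, 0.0, rng)
            res = fit_group_comparison(df, outcome="y",
                                       transform_policy="never")
            false_pos += res.p_value < 0.05
        assert 0.02 <= false_pos / 200 <= 0.08

    def test_ols_when_no_random_term(self, rng):
        df = simulate_family_cohort(40, 0.5, rng)
        res = fit_group_comparison(df, outcome="y", random_term=None,
                                   transform_policy="never")
        assert res.model_descriptor.startswith("ols")

    def test_degenerate_random_effect_degrades_to_ols(self, rng):
        """With zero family variance the model falls back gracefully."""
        df = simulate_family_cohort(60, 0.5, rng, family_sd=0.0)
        res = fit_group_comparison(df, outcome="y", transform_policy="never")
        assert np.isfinite(res.p_value)
        assert res.model_descriptor.split(":")[0] in (
            "lme", "ols-degenerate-re", "ols-fallback"
        )

    def test_auto_log_transform_fires_on_skewed_outcome(self, rng):
        df = simulate_family_cohort(100, 0.0, rng, family_sd=0.0)
        df["y"] = np.exp(2.0 * rng.normal(size=len(df)))
        res = fit_group_comparison(df, outcome="y", transform_policy="auto")
        assert res.transformed_flag


class TestSplitNightModel:
    @staticmethod
    def _long_table(n_subjects, rng, patient_second_shift=0.0):
        rows, cov = [], []
        for i in range(n_subjects):
            grp = "patient" if i % 2 == 0 else "sibling"
            sid, fam = f"S{i}", f"F{i // 2}"
            cov.append(
                {"subject_id": sid, "family_id": fam, "group": grp,
                 "age_years": rng.uniform(10, 60),
                 "sex": "M" if rng.random() < 0.5 else "F"}
            )
            subj_eff = rng.normal(0, 0.5)
            for half in ("first", "second"):
                shift = (
                    patient_second_shift
                    if grp == "patient" and half == "second"
                    else 0.0
                )
                rows.append(
                    {"subject_id": sid, "half": half, "metric": "m",
                     "value": subj_eff + shift + rng.normal()}
                )
        return pd.DataFrame(rows), pd.DataFrame(cov)

    def test_duplicated_half_rows_rejected(self, rng):
        long, cov = self._long_table(10, rng)
        dup = pd.concat([long, long.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicated"):
            split_night_model(dup, cov, "m")

    def test_patient_specific_second_half_increase(self, rng):
        """A patient-only second-half shift yields a positive patient
        night-half contrast and a larger second-half group contrast."""
        long, cov = self._long_table(400, rng, patient_second_shift=1.0)
        out = split_night_model(long, cov, "m", transform_policy="never")
        assert set(out) == {
            "interaction", "half_effect_in_siblings",
            "half_effect_in_patients", "group_difference_first_half",
            "group_difference_second_half",
        }
        assert out["half_effect_in_patients"].coefficient > 0
        assert out["half_effect_in_patients"].p_value < 0.05
        assert (
            out["group_difference_second_half"].coefficient
            > out["group_difference_first_half"].coefficient
        )
        assert out["interaction"].coefficient > 0

    def test_null_interaction_p_uniform(self, rng):
        """No half effect in either group: interaction p-values uniform over
        200 replicates (KS at alpha = .01)."""
        pvals = []
        for _ in range(200):
            long, cov = self._long_table(40, rng)
            out = split_night_model(long, cov, "m", transform_policy="never")
            pvals.append(out["interaction"].p_value)
        stat, p = scipy.stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_single_half_subjects_excluded(self, rng):
        long, cov = self._long_table(20, rng)
        long = long.drop(long[(long["subject_id"] == "S0")
                              & (long["half"] == "second")].index)
        out = split_night_model(long, cov, "m", transform_policy="never")
        assert out["interaction"].n_subjects == 19


class TestComparisonGrid:
    def test_fifty_models_and_undefined_row_exclusion(self, small_cohort):
        from sleepfrag.markov import estimate_transition_matrix, matrix_table

        mats = [
            estimate_transition_matrix(h)
            for h in small_cohort.hypnograms_5s + small_cohort.hypnograms_30s
        ]
        long = matrix_table(mats)
        grid = compare_transition_probabilities(
            long, small_cohort.cohort_table, min_subjects=10
        )
        assert grid.n_models == 50
        assert len(grid.cells) + len(grid.unfit) == 50
        # BH flags exist exactly for fitted cells
        assert set(grid.bh_rejected) == set(grid.cells)
        frame = grid.to_frame()
        assert len(frame) == 50

    def test_subject_missing_origin_excluded_from_row_cells_only(self):
        rng = np.random.default_rng(9)
        rows = []
        cov = []
        for i in range(24):
            sid = f"S{i}"
            cov.append(
                {"subject_id": sid, "family_id": f"F{i}",
                 "group": "patient" if i % 2 else "sibling",
                 "age_years": 30.0, "sex": "F"}
            )
            for frm in ("WAKE", "N1", "N2", "N3", "REM"):
                for to in ("WAKE", "N1", "N2", "N3", "REM"):
                    prob = np.nan if (sid == "S0" and frm == "N3") else rng.random()
                    rows.append(
                        {"subject_id": sid, "resolution": "epoch30",
                         "from_stage": frm, "to_stage": to, "prob": prob}
                    )
        long = pd.DataFrame(rows)
        grid = compare_transition_probabilities(
            long, pd.DataFrame(cov), min_subjects=5
        )
        for (res, frm, to), model in grid.cells.items():
            expected = 23 if frm == "N3" else 24
            assert model.n_observations == expected
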