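"""Eligibility, variance screening, residualization and moment stacking."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from panelgvar.preprocess import (
    compute_moments,
    filter_eligibility,
    filter_near_zero_variance,
    preprocess_panel,
    residualize,
)
from panelgvar.simulate import PanelData, apply_missingness, generate_population

from conftest import make_config


def _panel_with_wave_counts(counts, T=6, p=2, seed=0):
    """One individual per requested observed-wave count."""
    rng = np.random.default_rng(seed)
    rows = []
    for ind, k in enumerate(counts):
        observed = np.zeros(T, dtype=int)
        observed[rng.choice(T, size=k, replace=False)] = 1
        for t in range(T):
            feats = rng.random(p) if observed[t] else [np.nan] * p
            rows.append(
                {"id": ind, "wave": t + 1, "observed": observed[t],
                 "age": 40.0, "gender": "female", "ethnicity": "white",
                 "med_antidepressant": 0, "med_moodstab": 0,
                 "med_anxiolytic": 0, "med_antipsychotic": 0,
                 "ehr_entries": 3 * observed[t], "ehr_words": 100 * observed[t],
                 **{f"f_{j + 1:02d}": feats[j] for j in range(p)}}
            )
    return PanelData(pd.DataFrame(rows), [f"f_{j + 1:02d}" for j in range(p)], T)


class TestEligibility:
    def test_full_observation_retained_four_waves_excluded(self):
        panel = _panel_with_wave_counts([6, 5, 4, 3])
        kept, n_excluded = filter_eligibility(panel)
        assert sorted(kept.individuals) == [0, 1]
        assert n_excluded == 2

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 7, size=60)
        panel = _panel_with_wave_counts(counts.tolist())
        kept, _ = filter_eligibility(panel)
        assert kept.n_individuals == int((counts >= 5).sum())

    def test_idempotent(self):
        panel = _panel_with_wave_counts([6, 5, 4, 6, 2])
        once, _ = filter_eligibility(panel)
        twice, n2 = filter_eligibility(once)
        assert n2 == 0
        assert once.df.equals(twice.df)

    def test_all_excluded_raises(self):
        panel = _panel_with_wave_counts([1, 2])
        with pytest.raises(ValueError, match="eligibility"):
            filter_eligibility(panel)


class TestNearZeroVariance:
    def _binary_panel(self, prevalences, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        p = len(prevalences)
        rows = {"id": np.repeat(np.arange(n), 1), "wave": 1,
                "observed": 1}
        df = pd.DataFrame(rows)
        for k, prev in enumerate(prevalences):
            df[f"f_{k + 1:02d}"] = rng.binomial(1, prev, n)
        return PanelData(df, [f"f_{k + 1:02d}" for k in range(p)], 1)

    def test_constant_feature_excluded(self):
        panel = self._binary_panel([0.0, 0.5], seed=1)
        kept, log = filter_near_zero_variance(panel)
        assert kept.features == ["f_02"]
        assert "zero variance" in log["f_01"][0]

    def test_planted_prevalences_split(self):
        prevalences = [0.001] * 5 + [0.2] * 5
        panel = self._binary_panel(prevalences, n=20_000, seed=2)
        kept, log = filter_near_zero_variance(panel)
        assert len(log) == 5
        assert len(kept.features) == 5
        assert set(kept.features) == {f"f_{k:02d}" for k in range(6, 11)}

    def test_all_excluded_raises(self):
        panel = self._binary_panel([0.0, 0.0])
        with pytest.raises(ValueError, match="every feature"):
            filter_near_zero_variance(panel)

    def test_idempotent(self):
        panel = self._binary_panel([0.01, 0.3, 0.5], n=20_000, seed=3)
        once, _ = filter_near_zero_variance(panel)
        twice, log2 = filter_near_zero_variance(once)
        assert once.features == twice.features
        assert not log2


class TestResidualize:
    def test_covariate_free_design_mean_centers(self):
        # with no covariates in the design (exactly orthogonal case) the
        # regression keeps only the intercept, so residuals are the
        # per-wave mean-centered values
        panel = _panel_with_wave_counts([6] * 50, p=2, seed=8)
        res = residualize(panel, covariate_names=[])
        for wave in (1, 4):
            sub = res.panel.df[res.panel.df["wave"] == wave]
            orig = panel.df[panel.df["wave"] == wave]
            centered = orig[panel.features] - orig[panel.features].mean()
            assert np.allclose(
                sub[panel.features].to_numpy(), centered.to_numpy(), atol=1e-12
            )

    def test_exact_linear_feature_zeroed(self):
        panel = _panel_with_wave_counts([6] * 30, p=1, seed=9)
        df = panel.df.copy()
        df["age"] = np.repeat(np.linspace(20, 60, 30), 6)
        df["f_01"] = 2.0 + 0.5 * df["age"]
        panel = PanelData(df, ["f_01"], 6)
        res = residualize(panel, covariate_names=["age"])
        assert np.abs(res.panel.df["f_01"].to_numpy()).max() < 1e-9

    def test_matches_normal_equations_oracle(self):
        # 5 observations, one wave: solve X'X b = X'y by hand-coded
        # Gaussian elimination and compare residuals
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 2.5, 3.1, 4.8, 4.9])
        df = pd.DataFrame({
            "id": np.arange(5), "wave": 1, "observed": 1, "age": x,
            "gender": "female", "ethnicity": "white",
            "med_antidepressant": 0, "med_moodstab": 0, "med_anxiolytic": 0,
            "med_antipsychotic": 0, "ehr_entries": 1, "ehr_words": 10,
            "f_01": y,
        })
        panel = PanelData(df, ["f_01"], 1)
        res = residualize(panel, covariate_names=["age"])

        X = np.column_stack([np.ones(5), x])
        A = X.T @ X
        b = X.T @ y
        # 2x2 elimination
        m = A[1, 0] / A[0, 0]
        A1 = A[1, 1] - m * A[0, 1]
        b1 = b[1] - m * b[0]
        beta1 = b1 / A1
        beta0 = (b[0] - A[0, 1] * beta1) / A[0, 0]
        expected = y - (beta0 + beta1 * x)
        assert np.allclose(
            res.panel.df["f_01"].to_numpy(), expected, atol=1e-10
        )

    def test_unobserved_waves_stay_missing(self):
        panel = _panel_with_wave_counts([6, 5, 5, 6], p=2, seed=10)
        res = residualize(panel)
        miss = res.panel.df[res.panel.df["observed"] == 0]
        assert miss[panel.features].isna().all().all()


class TestMoments:
    def test_two_identical_individuals_zero_covariance(self):
        panel = _panel_with_wave_counts([6], p=2, seed=11)
        df2 = panel.df.copy()
        df2["id"] = 1
        df3 = panel.df.copy()
        df3["id"] = 2
        trip = PanelData(
            pd.concat([panel.df, df2, df3], ignore_index=True),
            panel.features, 6,
        )
        m = compute_moments(trip)
        assert np.allclose(m.cov, 0.0)

    def test_toy_table_matches_direct_formula(self):
        # 3 individuals x 2 features x 2 waves: compare to the covariance
        # computed entry-by-entry from the definition
        data = np.array(
            [
                [[1.0, 2.0], [0.0, 1.0]],
                [[2.0, 0.0], [1.0, 3.0]],
                [[0.0, 1.0], [2.0, 2.0]],
            ]
        )  # (3, T=2, p=2)
        rows = []
        for ind in range(3):
            for t in range(2):
                rows.append(
                    {"id": ind, "wave": t + 1, "observed": 1,
                     "f_01": data[ind, t, 0], "f_02": data[ind, t, 1]}
                )
        panel = PanelData(pd.DataFrame(rows), ["f_01", "f_02"], 2)
        m = compute_moments(panel)
        stacked = data.reshape(3, 4)
        mean = stacked.mean(axis=0)
        expected = np.zeros((4, 4))
        for a in range(4):
            for b in range(4):
                expected[a, b] = np.sum(
                    (stacked[:, a] - mean[a]) * (stacked[:, b] - mean[b])
                ) / 2.0
        assert np.allclose(m.cov, expected)
        assert np.allclose(m.mean, mean)

    def test_complete_data_pairwise_equals_impute(self):
        panel = _panel_with_wave_counts([6] * 20, p=2, seed=12)
        res = residualize(panel)
        a = compute_moments(res, missing_policy="pairwise")
        b = compute_moments(res, missing_policy="impute")
        assert np.allclose(a.cov, b.cov)
        assert np.allclose(a.mean, b.mean)

    def test_covariate_shift_leaves_moments_unchanged(self):
        cfg = make_config(p=3, n=400, seed=15,
                          covariate_effects={"age": np.array([0.2, 0.1, 0.0])})
        panel = generate_population(cfg)
        m1, _, _ = preprocess_panel(panel, skip_variance_filter=True)
        shifted = panel.copy()
        shifted.df["age"] = shifted.df["age"] + 100.0
        m2, _, _ = preprocess_panel(shifted, skip_variance_filter=True)
        assert np.allclose(m1.cov, m2.cov, atol=1e-8)
        assert np.allclose(m1.mean, m2.mean, atol=1e-8)

    def test_missing_data_pairwise_runs(self):
        cfg = make_config(p=3, n=600, seed=16)
        panel = apply_missingness(generate_population(cfg), 0.1, seed=5)
        m, _, _ = preprocess_panel(panel, skip_variance_filter=True)
        assert np.all(np.isfinite(m.cov))
        w = np.linalg.eigvalsh(m.cov)
        assert w.min() > -1e-10
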