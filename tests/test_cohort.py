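"""Synthetic cohort generator: moments, demographics, MAR missingness."""

import numpy as np
import pandas as pd
import pytest

from fusionern.config import ConfigError, GeneratorConfig
from fusionern.cohort import (apply_missingness, generate_cohort,
                              generate_incremental_cohort,
                              generate_path_cohort, generate_roi_scores,
                              incremental_blocks)
from fusionern.incremental import ols_hierarchical_r2


class TestGenerateCohort:
    def test_female_count_matches_binomial_expectation(self, config):
        counts = [generate_cohort(config, seed=s)[0]["sex"].sum()
                  for s in range(40)]
        mean = np.mean(counts)
        se = np.sqrt(0.523 * 0.477 * 176 / 40)
        assert abs(mean - 0.523 * 176) < 3 * se  # expected 92 females

    def test_noise_free_parent_equals_clipped_latent(self):
        cfg = GeneratorConfig()
        cfg.indicators.parent_resid_var = 0.0
        cfg.indicators.child_resid_var = 0.0
        cfg.indicators.child_loading = 1.0
        cfg.indicators.child_intercept = 0.0
        cohort, truth = generate_cohort(cfg, seed=3)
        expected = np.clip(np.round(truth["eta13"]), 0, 82)
        assert np.array_equal(cohort["scared_parent_13"], expected)
        assert np.array_equal(cohort["scared_child_13"], expected)

    def test_large_n_latent_change_moments_within_one_percent(self):
        cfg = GeneratorConfig(n_subjects=50_000)
        _, truth = generate_cohort(cfg, seed=9)
        assert truth["delta"].mean() == pytest.approx(
            cfg.anxiety.mean_delta, abs=0.01 * abs(cfg.anxiety.mean_delta)
            + 3 * np.sqrt(cfg.anxiety.var_delta / 50_000))
        assert truth["delta"].var() == pytest.approx(
            cfg.anxiety.var_delta, rel=0.03)
        assert np.cov(truth["eta13"], truth["delta"])[0, 1] == pytest.approx(
            cfg.anxiety.cov_eta13_delta, abs=0.6)

    def test_scared_range_and_binary_dx(self, config):
        cohort, _ = generate_cohort(config, seed=5)
        for col in ("scared_parent_13", "scared_child_15"):
            assert cohort[col].between(0, 82).all()
        assert set(cohort["dx_13"].unique()) <= {0.0, 1.0}

    def test_non_psd_anxiety_covariance_rejected(self):
        cfg = GeneratorConfig()
        cfg.anxiety.cov_eta13_delta = 1e3  # breaks PSD
        with pytest.raises(ConfigError, match="positive semidefinite"):
            generate_cohort(cfg, seed=0)

    def test_determinism_byte_identical(self, config):
        a1, t1 = generate_cohort(config, seed=11)
        a2, t2 = generate_cohort(config, seed=11)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_neural_truth_moments(self):
        cfg = GeneratorConfig(n_subjects=30_000)
        _, truth = generate_cohort(cfg, seed=21)
        p = cfg.neural[("fusion", "dacc")]
        assert truth["fusion_dacc_change"].mean() == pytest.approx(
            p.mean_change, abs=3 * np.sqrt(p.var_change / 30_000))
        assert truth["fusion_dacc_change"].var() == pytest.approx(
            p.var_change, rel=0.05)


class TestMissingness:
    def test_zero_rates_are_a_no_op(self, config):
        cohort, truth = generate_cohort(config, seed=2)
        scores = generate_roi_scores(truth, config, seed=3)
        cfg = GeneratorConfig()
        cfg.missing.rate = 0.0
        cfg.missing.anxiety_rate = 0.0
        c2, s2 = apply_missingness(cohort, scores, cfg, seed=4)
        pd.testing.assert_frame_equal(cohort, c2)
        pd.testing.assert_frame_equal(scores, s2)

    def test_realized_rate_matches_configured(self):
        cfg = GeneratorConfig(n_subjects=10_000)
        cfg.missing.rate = 0.3
        cohort, truth = generate_cohort(cfg, seed=6)
        scores = generate_roi_scores(truth, cfg, seed=7)
        _, s2 = apply_missingness(cohort, scores, cfg, seed=8)
        rate = np.mean([s2[f"{m}_dacc_{w}"].isna().mean()
                        for m in ("eeg", "fmri") for w in ("13", "15")])
        assert 0.29 <= rate <= 0.31

    def test_minority_participants_miss_more(self):
        cfg = GeneratorConfig(n_subjects=5_000)
        cfg.missing.minority_logodds = 0.7
        cohort, truth = generate_cohort(cfg, seed=12)
        scores = generate_roi_scores(truth, cfg, seed=13)
        _, s2 = apply_missingness(cohort, scores, cfg, seed=14)
        miss = s2["fmri_dacc_13"].isna()
        rate_min = miss[cohort["minority"] == 1].mean()
        rate_maj = miss[cohort["minority"] == 0].mean()
        assert rate_min > rate_maj

    def test_fusion_missing_when_either_modality_missing(self, config):
        cohort, truth = generate_cohort(config, seed=15)
        scores = generate_roi_scores(truth, config, seed=16)
        _, s2 = apply_missingness(cohort, scores, config, seed=17)
        either = s2["eeg_dacc_13"].isna() | s2["fmri_dacc_13"].isna()
        assert (s2["fusion_dacc_13"].isna() == either).all()

    def test_invalid_rate_rejected(self):
        cfg = GeneratorConfig()
        cfg.missing.rate = 1.2
        with pytest.raises(ConfigError, match="outside"):
            cfg.validate()


class TestBlockStructuredGenerators:
    def test_population_block_contributions_recovered_large_n(self):
        cfg = GeneratorConfig(n_subjects=50_000)
        frame, truth = generate_incremental_cohort(cfg, seed=5,
                                                   with_missing=False)
        df = frame.copy()
        df["eta13"] = truth["eta13"]
        df["delta"] = truth["delta"]
        _, dr2 = ols_hierarchical_r2(df, incremental_blocks(), "delta")
        assert np.allclose(dr2, cfg.incremental.delta_r2, atol=0.01)

    def test_invalid_block_contributions_rejected(self):
        cfg = GeneratorConfig()
        cfg.incremental.delta_r2 = (0.6, 0.3, 0.2, 0.2)  # sums beyond 1
        with pytest.raises(ConfigError, match="sum"):
            generate_incremental_cohort(cfg, seed=0)

    def test_path_generator_matches_configured_coefficients(self):
        cfg = GeneratorConfig(n_subjects=60_000)
        frame, truth = generate_path_cohort(cfg, seed=8, with_missing=False)
        df = frame.copy()
        df["eta13"] = truth["eta13"]
        df["delta"] = truth["delta"]
        preds = ["sex", "minority", "bi", "eta13", "fusion_dacc_13",
                 "fusion_pcc_13", "fusion_dacc_change", "fusion_pcc_change",
                 "fusion_dacc_13_x_bi", "fusion_pcc_13_x_bi",
                 "fusion_dacc_change_x_bi", "fusion_pcc_change_x_bi"]
        x = np.column_stack([np.ones(len(df)), df[preds].to_numpy()])
        coef, *_ = np.linalg.lstsq(x, df["delta"].to_numpy(), rcond=None)
        pp = cfg.path
        expected = [pp.sex, pp.minority, pp.bi, pp.anxiety13, pp.dacc_13,
                    pp.pcc_13, pp.dacc_change, pp.pcc_change,
                    pp.bi_x_dacc_13, pp.bi_x_pcc_13, pp.bi_x_dacc_change,
                    pp.bi_x_pcc_change]
        assert np.allclose(coef[1:], expected, atol=0.12)

    def test_change_predictor_missing_when_any_wave_missing(self, config):
        frame, _ = generate_incremental_cohort(config, seed=3)
        base_obs = frame["eeg_dacc_13"].notna()
        chg_obs = frame["eeg_dacc_change"].notna()
        # a subject with an observed change predictor must have wave 13
        assert (chg_obs <= base_obs).all()
        # products mirror their scores
        assert (frame["eeg_dacc_13_x_bi"].isna()
                == frame["eeg_dacc_13"].isna()).all()
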