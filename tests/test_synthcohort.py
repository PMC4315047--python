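"""Synthetic cohort generator: determinism, realized correlations,
band-limiting, hub planting, motion bounds, and clinical coupling."""

import numpy as np
import pytest
from scipy import stats

from tremornet.synthcohort import (
    ScoreCoupling,
    SyntheticConfig,
    default_score_couplings,
    generate_clinical,
    generate_cohort,
    generate_motion_traces,
    generate_truth,
    slope_for_correlation,
)


def _roi_mean_corr(run, labels, n_regions):
    series = np.vstack([run.data[labels == k].mean(axis=0) for k in range(n_regions)])
    return np.corrcoef(series)


class TestConfigValidation:
    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="band"):
            SyntheticConfig(band=(0.01, 0.3), tr=2.0)

    def test_non_psd_base_cov_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            SyntheticConfig(base_cov=np.array([[1.0, 2.0], [2.0, 1.0]]), effect_delta=np.zeros((2, 2)))

    def test_non_psd_after_effect_rejected(self):
        cfg = SyntheticConfig(
            n_group_a=1,
            n_group_b=1,
            base_cov=np.array([[1.0, 0.9], [0.9, 1.0]]),
            effect_delta=np.array([[0.0, 0.5], [0.5, 0.0]]),
            latent_sd=0.0,
            seed=0,
        )
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_truth(cfg)

    def test_hub_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="hub"):
            SyntheticConfig(grid_shape=(4, 4, 4), hub_voxels=((5, 0, 0),))


class TestCohortGeneration:
    def test_same_seed_bit_identical(self, tiny_config):
        runs_a, truth_a = generate_cohort(tiny_config)
        runs_b, truth_b = generate_cohort(tiny_config)
        assert all(np.array_equal(x.data, y.data) for x, y in zip(runs_a, runs_b))
        assert np.array_equal(truth_a.true_scores_latent, truth_b.true_scores_latent)

    def test_group_partition_sizes(self, tiny_config):
        truth = generate_truth(tiny_config)
        assert (truth.group_labels == 0).sum() == tiny_config.n_group_a
        assert (truth.group_labels == 1).sum() == tiny_config.n_group_b

    def test_zero_effect_gives_equal_group_correlations(self):
        cfg = SyntheticConfig(
            n_group_a=12,
            n_group_b=12,
            grid_shape=(6, 6, 4),
            n_volumes=180,
            n_regions=2,
            base_cov=np.array([[1.0, 0.4], [0.4, 1.0]]),
            effect_delta=np.zeros((2, 2)),
            hub_voxels=(),
            seed=11,
        )
        runs, truth = generate_cohort(cfg)
        rs = np.array(
            [_roi_mean_corr(r, truth.region_labels, 2)[0, 1] for r in runs]
        )
        diff = rs[truth.group_labels == 1].mean() - rs[truth.group_labels == 0].mean()
        assert abs(diff) < 0.1

    def test_realized_correlation_matches_nominal(self):
        # Monte-Carlo oracle: pooled empirical ROI correlation over 200
        # subjects should sit within +/-0.05 of the planted r = 0.6
        cfg = SyntheticConfig(
            n_group_a=200,
            n_group_b=0,
            grid_shape=(6, 6, 2),
            n_volumes=180,
            n_regions=2,
            base_cov=np.array([[1.0, 0.6], [0.6, 1.0]]),
            effect_delta=np.zeros((2, 2)),
            hub_voxels=(),
            seed=21,
        )
        runs, truth = generate_cohort(cfg)
        pooled = np.mean([_roi_mean_corr(r, truth.region_labels, 2)[0, 1] for r in runs])
        assert pooled == pytest.approx(0.6, abs=0.05)

    def test_power_concentrated_in_band(self, tiny_config):
        runs, _ = generate_cohort(tiny_config)
        x = runs[0].masked_series()
        spec = np.abs(np.fft.rfft(x - x.mean(axis=1, keepdims=True), axis=1)) ** 2
        freqs = np.fft.rfftfreq(tiny_config.n_volumes, d=tiny_config.tr)
        inband = (freqs >= 0.01) & (freqs <= 0.1)
        assert spec[:, inband].sum() / spec.sum() >= 0.8

    def test_patient_group_has_higher_roi_correlation(self, tiny_config):
        runs, truth = generate_cohort(tiny_config)
        rs = np.array([_roi_mean_corr(r, truth.region_labels, 2)[0, 1] for r in runs])
        assert rs[truth.group_labels == 1].mean() > rs[truth.group_labels == 0].mean()

    def test_hub_has_highest_mean_wdc(self):
        # over several cohorts the planted hub ranks first in mean
        # correlation-sum centrality
        from tremornet.centrality import compute_wdc_map

        wins = 0
        for s in range(5):
            cfg = SyntheticConfig(
                n_group_a=4, n_group_b=4, grid_shape=(6, 6, 6), n_volumes=120, seed=500 + s
            )
            runs, _ = generate_cohort(cfg)
            mean_map = np.mean([compute_wdc_map(r).values for r in runs], axis=0)
            wins += np.unravel_index(mean_map.argmax(), cfg.grid_shape) == cfg.hub_voxels[0]
        assert wins >= 4


class TestMotionTraces:
    def test_zero_amplitude_all_zero(self, tiny_config):
        traces = generate_motion_traces(tiny_config, step_sd_mm=0.0, step_sd_rad=0.0)
        assert all((t == 0).all() for t in traces)

    def test_defaults_stay_below_exclusion_bounds(self):
        cfg = SyntheticConfig(n_group_a=10, n_group_b=10, seed=3)
        for t in generate_motion_traces(cfg):
            assert np.abs(t[:, :3]).max() < 3.0  # mm
            assert np.abs(t[:, 3:]).max() < np.deg2rad(3.0)

    def test_deterministic(self, tiny_config):
        a = generate_motion_traces(tiny_config)
        b = generate_motion_traces(tiny_config)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_row_count_matches_volumes(self, tiny_config):
        assert generate_motion_traces(tiny_config)[0].shape == (tiny_config.n_volumes, 6)


class TestClinical:
    def test_noiseless_positive_slope_perfect_spearman(self, tiny_config):
        tiny_config.score_coupling = dict(
            default_score_couplings(),
            tremor=ScoreCoupling(slope=1.0, noise_sd=0.0, baseline=0.0),
        )
        truth = generate_truth(tiny_config)
        table = generate_clinical(truth)
        pat = table["group"] == "patient"
        rho, _ = stats.spearmanr(table.loc[pat, "tremor"], truth.true_scores_latent[truth.group_labels == 1])
        assert rho == pytest.approx(1.0)

    def test_controls_scores_missing(self, tiny_config):
        truth = generate_truth(tiny_config)
        table = generate_clinical(truth)
        ctrl = table["group"] == "control"
        assert table.loc[ctrl, ["duration", "tremor", "hy", "updrs"]].isna().all().all()
        assert table.loc[~ctrl, "tremor"].between(1, 4).all()

    def test_zero_slope_uncorrelated(self):
        rhos = []
        for s in range(40):
            cfg = SyntheticConfig(n_group_a=0, n_group_b=16, grid_shape=(2, 2, 2), seed=s)
            cfg.score_coupling = dict(
                default_score_couplings(), tremor=ScoreCoupling(slope=0.0, noise_sd=1.0, lo=-10, hi=10)
            )
            truth = generate_truth(cfg)
            table = generate_clinical(truth)
            rhos.append(stats.spearmanr(table["tremor"], truth.true_scores_latent).statistic)
        assert abs(np.mean(rhos)) < 0.1

    def test_missing_coupling_named_in_error(self, tiny_config):
        truth = generate_truth(tiny_config)
        with pytest.raises(KeyError, match="tremor"):
            generate_clinical(truth, couplings={"duration": ScoreCoupling(1.0, 0.1)})

    def test_target_spearman_recovered_over_cohorts(self):
        # simulation oracle: the same latent/score model sampled directly
        # must agree with the package's generated tables on the mean
        # Spearman correlation at n = 16 over 500 cohorts
        rho_target, latent_sd, noise_sd = 0.6, 0.2, 1.0
        slope = slope_for_correlation(rho_target, latent_sd, noise_sd)
        couplings = dict(
            default_score_couplings(),
            tremor=ScoreCoupling(slope=slope, noise_sd=noise_sd, lo=-np.inf, hi=np.inf),
        )
        got = []
        for s in range(500):
            cfg = SyntheticConfig(n_group_a=0, n_group_b=16, grid_shape=(2, 2, 2), seed=7000 + s)
            truth = generate_truth(cfg)
            table = generate_clinical(truth, couplings=couplings)
            got.append(stats.spearmanr(table["tremor"], truth.true_scores_latent).statistic)
        oracle_rng = np.random.default_rng(99)
        oracle = []
        for _ in range(500):
            lat = np.abs(oracle_rng.normal(1.0, latent_sd, 16))
            score = slope * lat + oracle_rng.normal(0, noise_sd, 16)
            oracle.append(stats.spearmanr(score, lat).statistic)
        se = np.sqrt(np.var(got) / 500 + np.var(oracle) / 500)
        assert abs(np.mean(got) - np.mean(oracle)) < 3 * se + 1e-9
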