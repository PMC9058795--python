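"""Generator tests: moment recovery, degenerate limits, reproducibility."""

import numpy as np
import pandas as pd
import pytest

import songnorms as sn
from songnorms.synthetic import RANDOM_EFFECTS


def _zero_g_params(repeat_noise_sd=0.0):
    params = sn.default_true_parameters()
    zero = {c: np.zeros((6, 6)) for c in sn.CONTEXTS}
    return sn.TrueParameters(traits=params.traits, beta=params.beta, G=zero,
                             V_year=np.zeros((2, 2)), R_resid=np.zeros((2, 2)),
                             repeat_noise_sd=repeat_noise_sd)


def test_zero_covariance_gives_zero_deviations():
    cfg = sn.SimulationConfig(n_individuals=50, seed=1)
    _, truth = sn.simulate_individuals(cfg, _zero_g_params())
    assert (truth["deviation"] == 0).all()


def test_degenerate_context_probs_assign_single_context():
    cfg = sn.SimulationConfig(n_individuals=80, context_probs=(1.0, 0.0, 0.0),
                              prop_repeated=0.0, seed=2)
    individuals, _ = sn.simulate_individuals(cfg, sn.default_true_parameters())
    assert (individuals["context"] == "male").all()


def test_non_psd_covariance_rejected_with_context_name():
    params = sn.default_true_parameters()
    bad = params.G["female"].copy()
    bad[0, 0] = -1.0
    with pytest.raises(ValueError, match="female"):
        sn.TrueParameters(traits=params.traits, beta=params.beta,
                          G={**params.G, "female": bad},
                          V_year=params.V_year, R_resid=params.R_resid)


def test_moment_recovery_against_true_covariance():
    """Sample covariance of drawn deviations matches G element-wise at n=10,000."""
    base = sn.default_true_parameters()
    params = sn.TrueParameters(traits=base.traits, beta=base.beta, G=base.G,
                               V_year=base.V_year, R_resid=base.R_resid,
                               repeat_noise_sd=0.0)
    cfg = sn.SimulationConfig(n_individuals=10_000, context_probs=(1.0, 0, 0),
                              prop_repeated=0.0, seed=3)
    _, truth = sn.simulate_individuals(cfg, params)
    dev = truth.pivot_table(index="individual_id", columns=["effect", "trait"],
                            values="deviation")
    cols = [(e, t) for e in RANDOM_EFFECTS for t in params.traits]
    dev = dev[cols].to_numpy()
    emp = np.cov(dev, rowvar=False)
    g = params.G["male"]
    n = dev.shape[0]
    # SE of a sample covariance between jointly normal coordinates; the
    # threshold is Bonferroni-adjusted for the 36 simultaneous comparisons
    # (3.9 ~ two-sided z at alpha = 0.005/36)
    se = np.sqrt((np.outer(np.diag(g), np.diag(g)) + g ** 2) / n)
    assert (np.abs(emp - g) <= 3.9 * se + 1e-12).all()


def test_order_slope_sample_variance_within_3se():
    base = sn.default_true_parameters()
    params = sn.TrueParameters(traits=base.traits, beta=base.beta, G=base.G,
                               V_year=base.V_year, R_resid=base.R_resid,
                               repeat_noise_sd=0.0)
    cfg = sn.SimulationConfig(n_individuals=10_000, context_probs=(1.0, 0, 0),
                              prop_repeated=0.0, seed=4)
    _, truth = sn.simulate_individuals(cfg, params)
    slopes = truth[(truth["effect"] == "order") & (truth["trait"] == "SL")][
        "deviation"].to_numpy()
    true_var = params.G["male"][2, 2]
    se = true_var * np.sqrt(2 / (len(slopes) - 1))
    assert abs(slopes.var(ddof=1) - true_var) <= 3 * se


def test_conditional_mean_matches_recorded_linear_predictor():
    """Regressing a trait on its recorded linear predictor gives slope ~1."""
    cfg = sn.SimulationConfig(n_individuals=150, songs_per_recording=(10, 30),
                              seed=5)
    songs, *_ = sn.simulate_dataset(cfg)
    for trait in ("SL", "MF"):
        x = songs[f"linpred_{trait}"].to_numpy()
        y = songs[trait].to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        assert abs(slope - 1.0) < 0.05
        assert abs(intercept) < 0.05


def test_values_equal_linear_predictor_when_residual_zero():
    params = _zero_g_params()
    cfg = sn.SimulationConfig(n_individuals=20, songs_per_recording=(5, 8), seed=6)
    songs, *_ = sn.simulate_dataset(cfg, params)
    np.testing.assert_allclose(songs["SL"], songs["linpred_SL"], atol=1e-12)


def test_intercept_only_truth_gives_constant_trait():
    params = _zero_g_params()
    beta = np.zeros_like(params.beta)
    beta[:, 0] = 1.0
    params = sn.TrueParameters(traits=params.traits, beta=beta, G=params.G,
                               V_year=params.V_year, R_resid=params.R_resid)
    cfg = sn.SimulationConfig(n_individuals=15, songs_per_recording=(4, 6), seed=7)
    songs, *_ = sn.simulate_dataset(cfg, params)
    assert np.allclose(songs["SL"], 1.0) and np.allclose(songs["MF"], 1.0)


def test_interaction_beta_recovered_by_ols_refit():
    """OLS slope of SL on z(order) among female-context songs recovers
    beta[order] + beta[order x female] = 0.044 + 0.285."""
    params = _zero_g_params()
    params = sn.TrueParameters(traits=params.traits,
                               beta=sn.default_true_parameters().beta,
                               G=params.G, V_year=np.zeros((2, 2)),
                               R_resid=0.3 * np.eye(2))
    cfg = sn.SimulationConfig(n_individuals=2_000, songs_per_recording=(10, 20),
                              context_probs=(0.0, 1.0, 0.0), prop_repeated=0.0,
                              seed=8)
    songs, *_ = sn.simulate_dataset(cfg, params)
    z_order = ((songs["song_order"] - songs["song_order"].mean())
               / songs["song_order"].std(ddof=1))
    slope = np.polyfit(z_order, songs["SL"], 1)[0]
    assert abs(slope - (0.044 + 0.285)) < 0.02


def test_reproducibility_identical_seed_identical_tables():
    cfg = sn.SimulationConfig(n_individuals=25, seed=99)
    a = sn.simulate_dataset(cfg)[0].to_csv(index=False)
    b = sn.simulate_dataset(cfg)[0].to_csv(index=False)
    assert a == b


def test_missing_position_fraction_within_binomial_bounds():
    cfg = sn.SimulationConfig(n_individuals=100, songs_per_recording=(20, 40),
                              missing_position_prob=0.15, seed=10)
    songs, *_ = sn.simulate_dataset(cfg)
    n = len(songs)
    frac = songs["position"].isna().mean()
    se = np.sqrt(0.15 * 0.85 / n)
    assert abs(frac - 0.15) <= 2.576 * se  # 99% binomial bounds


def test_repeated_recordings_share_intercepts_and_drift_slopes():
    params = sn.default_true_parameters()
    cfg = sn.SimulationConfig(n_individuals=60, prop_repeated=1.0,
                              repeat_same_context_prob=1.0, seed=11)
    _, truth = sn.simulate_individuals(cfg, params)
    wide = truth.pivot_table(index=["individual_id", "effect", "trait"],
                             columns="recording_order", values="deviation")
    ints = wide.xs("intercept", level="effect")
    np.testing.assert_allclose(ints[1], ints[2])
    slopes = wide.xs("order", level="effect")
    assert not np.allclose(slopes[1], slopes[2])
    # both recordings deviate i.i.d., so the between-recording difference
    # has SD sqrt(2) * repeat_noise_sd
    drift = (slopes[2] - slopes[1]).to_numpy()
    assert abs(drift.std(ddof=1) - np.sqrt(2) * params.repeat_noise_sd) < 0.1


# ---------------------------------------------------------------------------
# syllables


def test_syllable_count_matches_complexity_target():
    # raw complexity = 0.55 + 0.12 * z; z chosen so the target is 0.75
    songs = pd.DataFrame({"recording_id": ["r1"], "song_order": [1],
                          "SL": [0.0], "complexity": [(0.75 - 0.55) / 0.12]})
    syl = sn.simulate_syllables(songs, K_true=8, seed=1,
                                syllables_per_song=(4, 4))
    assert len(syl) == 4
    assert syl["true_type"].nunique() == 3  # round(0.75 * 4)


def test_infeasible_complexity_target_rejected():
    songs = pd.DataFrame({"recording_id": ["r1"], "song_order": [1],
                          "SL": [0.0], "complexity": [0.0]})
    with pytest.raises(ValueError, match="infeasible"):
        sn.simulate_syllables(songs, K_true=8, seed=1, complexity_mean=1.4)


def test_cluster_spread_zero_collapses_features():
    songs = pd.DataFrame({"recording_id": ["r1", "r1"], "song_order": [1, 2],
                          "SL": [0.0, 0.0], "complexity": [0.0, 0.0]})
    syl = sn.simulate_syllables(songs, K_true=5, cluster_spread=0.0, seed=2,
                                syllables_per_song=(10, 10))
    for _, grp in syl.groupby("true_type"):
        assert grp["min_freq"].std() == pytest.approx(0.0, abs=1e-9)


def test_syllables_tile_song_length():
    songs = pd.DataFrame({"recording_id": ["r1"], "song_order": [1],
                          "SL": [1.0], "complexity": [0.0]})
    syl = sn.simulate_syllables(songs, K_true=5, seed=3, sl_mean_s=4.0,
                                sl_sd_s=0.5)
    span = (syl["onset"] + syl["duration"]).max() - syl["onset"].min()
    assert span == pytest.approx(4.5)  # 4.0 + 0.5 * z with z = 1
    assert (syl["duration"] > 0).all()
    assert (syl["min_freq"] <= syl["mean_freq"]).all()
    assert (syl["mean_freq"] <= syl["max_freq"] + 1e-9).all()
    np.testing.assert_allclose(syl["bandwidth"],
                               syl["max_freq"] - syl["min_freq"])
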