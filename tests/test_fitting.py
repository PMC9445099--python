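"""Parameter-recovery estimators: round-trip identities, error handling,
Monte-Carlo calibration under noise."""
import math

import numpy as np
import pandas as pd
import pytest

from tebbo import (
    BranchingRateModel,
    GrowthParameters,
    MeanFieldModel,
    ObservationNoiseModel,
    ProliferationFeedbackModel,
    TipSpeedModel,
    TipTrack,
    compare_cellcount_prediction,
    fit_branching_rate,
    fit_proliferation_feedback,
    fit_tip_speed,
    generate_feedback_pairs,
)


# --- proliferation feedback -------------------------------------------------


def test_noiseless_feedback_recovers_generators_exactly():
    kd0, w0 = 1.0, 60.0
    widths = np.linspace(5, 55, 20)
    rates = kd0 * (1 - widths / w0)
    fit = fit_proliferation_feedback(list(zip(widths, rates)))
    assert fit.kd0 == pytest.approx(kd0, abs=1e-12)
    assert fit.w0 == pytest.approx(w0, rel=1e-12)
    assert fit.r2 == pytest.approx(1.0)


def test_two_points_give_interpolating_line():
    fit = fit_proliferation_feedback([(10.0, 0.9), (50.0, 0.1)])
    assert fit.slope == pytest.approx(-0.02)
    assert fit.intercept == pytest.approx(1.1)


def test_degenerate_design_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        fit_proliferation_feedback([(10.0, 0.5), (10.0, 0.6), (10.0, 0.7)])


def test_positive_slope_marks_w0_invalid():
    fit = fit_proliferation_feedback([(10.0, 0.1), (30.0, 0.5), (50.0, 0.9)])
    assert not fit.w0_valid
    with pytest.raises(ValueError, match="w0 is undefined"):
        fit.w0
    assert "invalid" in fit.summary()


def test_feedback_bootstrap_is_seeded():
    rng = np.random.default_rng(0)
    widths = rng.uniform(10, 50, 50)
    rates = 1.5 * (1 - widths / 60) + rng.normal(0, 0.05, 50)
    model = ProliferationFeedbackModel(widths, rates)
    a = model.fit(n_boot=200, seed=11)
    b = model.fit(n_boot=200, seed=11)
    assert a.ci95_kd0 == b.ci95_kd0 and a.ci95_w0 == b.ci95_w0
    assert a.ci95_kd0[0] < a.kd0 < a.ci95_kd0[1]
    assert a.ci95_w0[0] < a.w0 < a.ci95_w0[1]
    with pytest.raises(ValueError, match="seed"):
        model.fit(n_boot=10)


def test_feedback_recovery_under_measurement_noise():
    """Monte-Carlo calibration: 85-point scatters at 10% multiplicative noise
    recover kd0 and w0 within 10% in at least 90% of seeded repeats."""
    truth = GrowthParameters(kd0=1.5, w0=60.0)
    hits = 0
    n_rep = 200
    for r in range(n_rep):
        pairs = generate_feedback_pairs(
            truth, ObservationNoiseModel(seed=50_000 + r), n_pairs=85
        )
        fit = ProliferationFeedbackModel.from_dataframe(pairs).fit()
        ok = (
            fit.w0_valid
            and abs(fit.kd0 / truth.kd0 - 1) <= 0.10
            and abs(fit.w0 / truth.w0 - 1) <= 0.10
        )
        hits += ok
    assert hits / n_rep >= 0.90


def test_estimator_consistency_as_noise_shrinks_and_n_grows():
    truth = GrowthParameters(kd0=1.5, w0=60.0)
    max_err = {}
    for cv in (0.2, 0.05, 0.0):
        for n in (40, 160, 640):
            errs = []
            for r in range(10):
                noise = ObservationNoiseModel(
                    width_cv=cv, growth_rate_cv=cv, seed=7_000 + r
                )
                fit = ProliferationFeedbackModel.from_dataframe(
                    generate_feedback_pairs(truth, noise, n_pairs=n)
                ).fit()
                errs.append(max(abs(fit.kd0 / 1.5 - 1), abs(fit.w0 / 60 - 1)))
            max_err[(cv, n)] = float(np.mean(errs))
    assert max_err[(0.0, 640)] < 1e-10          # exact at zero noise
    assert max_err[(0.05, 640)] < max_err[(0.2, 640)]
    assert max_err[(0.2, 640)] < max_err[(0.2, 40)]


# --- branching rate ---------------------------------------------------------


def test_exact_exponential_counts_recover_rate():
    t = np.arange(0.0, 10.0)
    fit = fit_branching_rate(list(zip(t, np.exp(0.55 * t))))
    assert fit.rate == pytest.approx(0.55, abs=1e-12)
    assert fit.rate_pinned == pytest.approx(0.55, abs=1e-12)
    assert fit.log_intercept == pytest.approx(0.0, abs=1e-12)


def test_constant_counts_give_zero_rate():
    fit = fit_branching_rate([(0.0, 4.0), (1.0, 4.0), (2.0, 4.0)])
    assert fit.rate == pytest.approx(0.0, abs=1e-12)


def test_nonpositive_count_names_offending_row():
    with pytest.raises(ValueError, match="row 1"):
        fit_branching_rate([(0.0, 1.0), (1.0, 0.0), (2.0, 3.0)])


def test_too_few_time_points_rejected():
    with pytest.raises(ValueError, match="at least 3"):
        fit_branching_rate([(0.0, 1.0), (1.0, 2.0)])


def test_rate_confidence_interval_covers_estimate():
    t = np.arange(0.0, 10.0)
    counts = np.exp(0.5 * t) * np.exp(np.random.default_rng(3).normal(0, 0.05, 10))
    fit = BranchingRateModel(t, counts).fit()
    lo, hi = fit.ci95_rate
    assert lo < fit.rate < hi


# --- tip speed --------------------------------------------------------------


def test_single_exact_track():
    v0, sd = fit_tip_speed([TipTrack(np.array([0.0, 1.0, 2.0]), np.array([0.0, 80.0, 160.0]))])
    assert v0 == pytest.approx(80.0) and sd == 0.0


def test_stationary_track_gives_zero_speed():
    v0, _ = fit_tip_speed([TipTrack(np.array([0.0, 1.0, 2.0]), np.array([5.0, 5.0, 5.0]))])
    assert v0 == pytest.approx(0.0, abs=1e-12)


def test_short_tracks_skipped_with_warning_then_error():
    good = TipTrack(np.array([0.0, 1.0, 2.0]), np.array([0.0, 80.0, 160.0]))
    short = TipTrack(np.array([0.0, 1.0]), np.array([0.0, 80.0]))
    with pytest.warns(UserWarning, match="skipping"):
        res = TipSpeedModel([good, short]).fit()
    assert res.n_tracks == 1 and res.n_skipped == 1
    with pytest.warns(UserWarning):
        with pytest.raises(ValueError, match="skipped"):
            TipSpeedModel([short]).fit()


def test_track_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        TipTrack(np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 2.0]))


def test_noisy_path_length_tracks_recover_speed_within_one_percent():
    # path length grows at exactly v0 regardless of heading noise; additive
    # jitter on the samples leaves per-track slopes unbiased
    rng = np.random.default_rng(12)
    tracks = []
    for _ in range(20):
        t = np.arange(0.0, 2.01, 0.1)
        tracks.append(TipTrack(t, 80.0 * t + rng.normal(0, 2.0, t.size)))
    v0, _ = fit_tip_speed(tracks)
    assert v0 == pytest.approx(80.0, rel=0.01)


# --- cell-count comparison --------------------------------------------------


def observed_from(traj, times, shift_sd=0.0):
    sub = traj.interp(times)
    mean = sub["Nc [cells]"].to_numpy()
    sd = 0.15 * mean
    return pd.DataFrame(
        {
            "time [day]": times,
            "mean_nc [cells]": mean + shift_sd * sd,
            "sd_nc [cells]": sd,
        }
    )


def test_identical_observation_gives_zero_rmse_full_coverage():
    traj = MeanFieldModel(GrowthParameters()).simulate(9.0, dt=0.01)
    obs = observed_from(traj, np.arange(1.0, 9.1))
    rmse, cov = compare_cellcount_prediction(traj, obs)
    assert rmse == pytest.approx(0.0, abs=1e-12)
    assert cov == 1.0


def test_one_sd_shift_still_counts_as_covered():
    traj = MeanFieldModel(GrowthParameters()).simulate(9.0, dt=0.01)
    obs = observed_from(traj, np.arange(1.0, 9.1), shift_sd=1.0)
    _, cov = compare_cellcount_prediction(traj, obs)
    assert cov == 1.0


def test_disjoint_times_rejected():
    traj = MeanFieldModel(GrowthParameters()).simulate(5.0, dt=0.01)
    obs = observed_from(traj, np.arange(1.0, 5.1))
    obs["time [day]"] += 10.0
    with pytest.raises(ValueError):
        compare_cellcount_prediction(traj, obs)


def test_noisy_ensemble_coverage():
    """Observed means from 55 noisy organoids (CV 15%) stay within ±1 sd of
    the prediction at most time points."""
    p = GrowthParameters()
    traj = MeanFieldModel(p).simulate(9.0, dt=0.01)
    times = np.arange(1.0, 9.1)
    rng = np.random.default_rng(99)
    truth = traj.interp(times)["Nc [cells]"].to_numpy()
    sigma = math.sqrt(math.log(1 + 0.15**2))
    samples = truth[None, :] * rng.lognormal(-sigma**2 / 2, sigma, (55, times.size))
    obs = pd.DataFrame(
        {
            "time [day]": times,
            "mean_nc [cells]": samples.mean(axis=0),
            "sd_nc [cells]": samples.std(axis=0, ddof=1),
        }
    )
    _, cov = compare_cellcount_prediction(traj, obs)
    assert cov >= 0.8
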