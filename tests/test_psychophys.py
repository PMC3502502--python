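import numpy as np
import pandas as pd
import pytest

from morphconnect import (
    MorphSchedule,
    RatingDataset,
    build_age_regressor,
    build_gender_regressor,
    build_run_regressors,
    fit_gender_exponent,
    fit_stevens_exponent,
    make_gender_ratings,
    make_ratings,
    make_run_schedules,
    perceived_gender_level,
    trichotomize_raters,
)
from morphconnect.psychophys import _age_sse, build_task_regressor


# ---------------------------------------------------------------------------
# Stevens exponent fitting
# ---------------------------------------------------------------------------

def test_linear_exponent_noiseless():
    r = make_ratings(n_morphs=40, n_subjects=3, exponent=1.0, noise_sd=0.0, seed=1)
    fit = fit_stevens_exponent(r)
    assert fit.exponent == pytest.approx(1.0, abs=1e-6)
    assert fit.sse == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("p_true", [0.3, 0.5, 1.0, 3.0])
def test_exponent_roundtrip_noiseless(p_true):
    """Fitting the generator's own noiseless output recovers the exponent."""
    r = make_ratings(n_morphs=60, n_subjects=2, exponent=p_true, noise_sd=0.0, seed=2)
    fit = fit_stevens_exponent(r, p_grid=np.linspace(0.1, 4.0, 120))
    assert fit.exponent == pytest.approx(p_true, abs=1e-6)


def test_noisy_fit_matches_bruteforce_oracle():
    """Grid+refine minimum agrees with an exhaustive 10x-refined grid scan."""
    r = make_ratings(n_morphs=121, n_subjects=24, exponent=0.3, seed=3)
    rec = r.records
    start = rec["start_age"].to_numpy()
    target = rec["target_age"].to_numpy()
    rating = rec["rating"].to_numpy()

    coarse = np.linspace(0.1, 1.5, 60)
    sses = [_age_sse(p, start, target, rating)[0] for p in coarse]
    i = int(np.argmin(sses))
    fine = np.linspace(coarse[max(i - 1, 0)], coarse[min(i + 1, 59)], 10 * 60)
    fine_sses = [_age_sse(p, start, target, rating)[0] for p in fine]
    p_oracle = fine[int(np.argmin(fine_sses))]

    fit = fit_stevens_exponent(r, p_grid=coarse)
    assert fit.exponent == pytest.approx(p_oracle, abs=(fine[1] - fine[0]) * 2)


def test_fit_errors():
    rec = pd.DataFrame(
        {
            "morph_id": range(12),
            "subject_id": 0,
            "start_age": 20.0,
            "target_age": 40.0,
            "rating": 0.0,
        }
    )
    with pytest.raises(ValueError, match="degenerate"):
        fit_stevens_exponent(RatingDataset(rec))
    small = make_ratings(n_morphs=3, n_subjects=2, seed=1)
    with pytest.raises(ValueError, match="at least 10"):
        fit_stevens_exponent(small)


def test_gender_exponent_recovery():
    df = make_gender_ratings(noise_sd=0.0, seed=4)
    fit = fit_gender_exponent(df["position"].to_numpy(), df["rating"].to_numpy())
    assert fit.exponent == pytest.approx(3.0, abs=1e-5)


# ---------------------------------------------------------------------------
# regressors
# ---------------------------------------------------------------------------

def test_constant_age_morph_zero_regressor():
    s = MorphSchedule(start_age=30.0, target_age=30.0)
    reg = build_age_regressor(s)
    assert np.all(reg.values == 0.0)


def test_young_morph_stronger_than_old():
    """Equal 16-year changes: the young morph integrates more stimulus."""
    young = build_age_regressor(MorphSchedule(10.0, 26.0), normalize=False)
    old = build_age_regressor(MorphSchedule(64.0, 80.0), normalize=False)
    assert young.values.sum() > old.values.sum()


def test_aging_upweighted_to_initial_period():
    """For p<1 the unsigned derivative decreases along an aging morph."""
    s = MorphSchedule(20.0, 60.0)
    reg = build_age_regressor(s, p=0.3, normalize=False)
    morph_frames = int(s.duration_s * s.fps)
    vals = reg.values[:morph_frames]
    assert np.all(np.diff(vals) < 0)
    # finite-difference oracle: |a(t+dt)^p - a(t)^p| computed directly
    t = np.arange(morph_frames) / s.fps
    a = 20.0 + (t / 6.0) * 40.0
    a_next = 20.0 + (np.minimum(t + 1 / 24, 6.0) / 6.0) * 40.0
    np.testing.assert_allclose(vals, np.abs(a_next**0.3 - a**0.3), rtol=1e-12)


def test_age_out_of_range_rejected():
    with pytest.raises(ValueError, match="outside"):
        MorphSchedule(1.0, 30.0)
    with pytest.raises(ValueError, match="outside"):
        MorphSchedule(30.0, 90.0)


def test_gender_regressor_no_transition_flat():
    reg = build_gender_regressor(MorphSchedule(20.0, 60.0, has_gender_transition=False))
    assert np.all(reg.values == 0.0)


def test_gender_regressor_peaks_mid_morph():
    s = MorphSchedule(20.0, 60.0, has_gender_transition=True)
    reg = build_gender_regressor(s, gamma=3.0)
    morph_frames = int(s.duration_s * s.fps)
    center_pair = morph_frames // 2
    assert abs(int(np.argmax(reg.values)) - center_pair) <= 1
    assert reg.values.max() == 1.0


def test_perceived_gender_above_linear():
    # closed form: P(3/4) = 0.5*(1 + 0.5^(1/3))
    assert perceived_gender_level(0.75, 3.0) == pytest.approx(0.8969, abs=5e-4)
    assert perceived_gender_level(0.75, 3.0) > 0.75
    assert perceived_gender_level(0.5, 3.0) == pytest.approx(0.5)


def test_still_period_contributes_zero():
    s = MorphSchedule(10.0, 70.0, has_gender_transition=True)
    morph_frames = int(s.duration_s * s.fps)
    for reg in (build_age_regressor(s), build_gender_regressor(s)):
        assert np.all(reg.values[morph_frames:] == 0.0)


def test_task_regressor_single_impulse():
    reg = build_task_regressor(MorphSchedule(10.0, 70.0), anticipation_s=5.0)
    assert reg.values.sum() == 1.0
    assert int(np.argmax(reg.values)) == 5 * 24


def test_run_regressors_normalized_and_near_orthogonal():
    """Balanced design: age and gender regressors decorrelate (|r| < 0.2)."""
    schedules = make_run_schedules(120, seed=11)
    regs = build_run_regressors(schedules)
    for reg in regs.values():
        assert reg.values.min() >= 0.0
        assert reg.values.max() == 1.0
    r = np.corrcoef(regs["age"].values, regs["gender"].values)[0, 1]
    assert abs(r) < 0.2


# ---------------------------------------------------------------------------
# rater trichotomization
# ---------------------------------------------------------------------------

def test_trichotomize_quintiles_24():
    errors = {f"s{i:02d}": float(i) for i in range(24)}
    groups = trichotomize_raters(errors)
    assert (len(groups["high"]), len(groups["average"]), len(groups["low"])) == (5, 14, 5)
    assert groups["high"] == [f"s{i:02d}" for i in range(5)]
    assert groups["low"] == [f"s{i:02d}" for i in range(19, 24)]


def test_trichotomize_five_subjects():
    groups = trichotomize_raters([3.0, 1.0, 2.0, 5.0, 4.0])
    assert groups["high"] == [1]
    assert groups["low"] == [3]
    assert sorted(groups["average"]) == [0, 2, 4]


def test_trichotomize_order_invariant(rng):
    errors = list(enumerate(rng.permutation(20).astype(float)))
    shuffled = [errors[i] for i in rng.permutation(len(errors))]
    assert trichotomize_raters(errors) == trichotomize_raters(shuffled)


def test_trichotomize_ties_stable_by_subject_id():
    errors = {"b": 1.0, "a": 1.0, "c": 1.0, "d": 2.0, "e": 3.0}
    groups = trichotomize_raters(errors)
    assert groups["high"] == ["a"]  # tie at the cutoff broken by id


def test_trichotomize_too_few():
    with pytest.raises(ValueError):
        trichotomize_raters([1.0, 2.0, 3.0])
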