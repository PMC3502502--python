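import numpy as np
import pytest
from scipy import stats

from morphconnect import (
    MorphSchedule,
    Regressor,
    VertexGLM,
    cope_to_percent_bold,
    gamma_hrf,
    make_bold,
    make_design,
    make_run_schedules,
    normalize_response_magnitudes,
    build_run_regressors,
)
from morphconnect.firstlevel import dct_highpass_basis, highpass_filter


@pytest.fixture(scope="module")
def small_design():
    """12-morph run (84 s, 35 volumes at TR 2.4 s) with one spike confound."""
    regs = build_run_regressors(make_run_schedules(12, seed=3))
    hrf = gamma_hrf(dt_s=1 / 24)
    return make_design(list(regs.values()), hrf, tr_s=2.4, n_volumes=35, confound_spikes=[5])


# ---------------------------------------------------------------------------
# HRF
# ---------------------------------------------------------------------------

def test_hrf_unit_sum_and_nonnegative():
    hrf = gamma_hrf(dt_s=0.1)
    assert hrf.values.sum() == pytest.approx(1.0)
    assert np.all(hrf.values >= 0)


def test_hrf_peak_at_gamma_mode():
    # gamma(shape k, scale s) mode = (k-1)s; for lag 6, sd 3: k=4, s=1.5 -> 4.5 s
    hrf = gamma_hrf(lag_s=6.0, sd_s=3.0, dt_s=0.01)
    peak_s = np.argmax(hrf.values) * 0.01
    assert peak_s == pytest.approx(hrf.mode_s(), abs=0.02)
    assert hrf.mode_s() == pytest.approx(4.5)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def test_impulse_convolves_to_hrf():
    """Convolution identity: a unit impulse reproduces the kernel."""
    fps = 24
    vals = np.zeros(int(round(35 * 2.4 * fps)))
    vals[0] = 1.0
    reg = Regressor("impulse", vals, fps=fps)
    hrf = gamma_hrf(dt_s=1 / fps)
    design = make_design([reg], hrf, tr_s=2.4, n_volumes=35, highpass_s=None, add_derivatives=False)
    col = design.column("impulse")
    padded = np.concatenate([hrf.values, np.zeros(vals.size)])
    expected = padded[(np.arange(35) * 2.4 * fps).round().astype(int)]
    np.testing.assert_allclose(col, expected, atol=1e-12)


def test_design_columns_and_spikes(small_design):
    d = small_design
    assert d.task_columns == ["age", "gender", "task"]
    assert "age_deriv" in d.derivative_columns
    assert "spike_5" in d.confound_columns and "intercept" in d.confound_columns
    assert len(set(d.frame.columns)) == d.frame.shape[1]


def test_run_length_mismatch_rejected():
    reg = Regressor("age", np.ones(100), fps=24)
    with pytest.raises(ValueError, match="covers"):
        make_design([reg], gamma_hrf(dt_s=1 / 24), tr_s=2.4, n_volumes=35)


def test_highpass_removes_slow_sinusoid():
    """DCT projection at 100 s wipes out a 200-s-period drift (<1% power)."""
    tr = 2.4
    n = 350
    t = np.arange(n) * tr
    slow = np.sin(2 * np.pi * t / 200.0)
    filtered = highpass_filter(slow, tr, 100.0)
    assert np.sum(filtered**2) < 0.01 * np.sum(slow**2)
    # fast signal survives
    fast = np.sin(2 * np.pi * t / 20.0)
    assert np.sum(highpass_filter(fast, tr, 100.0) ** 2) > 0.95 * np.sum(fast**2)


def test_dct_basis_empty_for_short_run():
    assert dct_highpass_basis(5, 2.4, 100.0).shape == (5, 0)


# ---------------------------------------------------------------------------
# GLM fitting
# ---------------------------------------------------------------------------

def test_noiseless_fit_exact(small_design):
    betas = np.array([[1.0, -0.5], [0.3, 0.2], [0.0, 0.1]])
    bold = make_bold(small_design, betas, noise=(0.0, 0.0), spike_frames=(5,), seed=1)
    res = VertexGLM(bold.data, small_design).fit()
    np.testing.assert_allclose(res.copes["age"], betas[0], atol=1e-8)
    np.testing.assert_allclose(res.copes["gender"], betas[1], atol=1e-8)
    assert np.all(res.varcopes["age"] < 1e-12)


def test_beta_recovery_white_noise(small_design):
    """Mean beta-hat over 500 noisy vertices lands within 2 SE of truth."""
    v = 500
    betas = np.vstack([np.full(v, 2.0), np.zeros(v), np.zeros(v)])
    bold = make_bold(small_design, betas, noise=(0.0, 1.0), seed=7)
    res = VertexGLM(bold.data, small_design).fit()
    est = res.copes["age"]
    se = est.std(ddof=1) / np.sqrt(v)
    assert abs(est.mean() - 2.0) < 2 * se


def test_null_t_calibration(small_design):
    """Type-I error of the contrast t-test is 5% +- 1.5% under white noise."""
    v = 2000
    betas = np.zeros((3, v))
    bold = make_bold(small_design, betas, noise=(0.0, 1.0), seed=3)
    res = VertexGLM(bold.data, small_design).fit()
    t = res.tstat("age")
    crit = stats.t.isf(0.025, df=res.dof)
    rate = np.mean(np.abs(t) > crit)
    assert rate == pytest.approx(0.05, abs=0.015)


def test_residuals_orthogonal_to_design(small_design):
    betas = np.array([[1.0], [0.5], [0.0]])
    bold = make_bold(small_design, betas, noise=(0.0, 1.0), seed=4)
    res = VertexGLM(bold.data, small_design).fit()
    proj = small_design.matrix.T @ res.resid
    assert np.abs(proj).max() < 1e-8


def test_rank_deficient_names_column(small_design):
    dup = small_design.frame.copy()
    dup["age_copy"] = dup["age"]
    bad = small_design.__class__(
        frame=dup,
        tr_s=small_design.tr_s,
        task_columns=small_design.task_columns,
        derivative_columns=small_design.derivative_columns,
        confound_columns=small_design.confound_columns,
    )
    with pytest.raises(ValueError, match="age_copy"):
        VertexGLM(np.zeros((35, 2)), bad)


def test_prewhitening_reduces_residual_autocorrelation(small_design):
    betas = np.vstack([np.full(50, 1.0), np.zeros(50), np.zeros(50)])
    bold = make_bold(small_design, betas, noise=(0.6, 1.0), seed=5)
    plain = VertexGLM(bold.data, small_design).fit()
    white = VertexGLM(bold.data, small_design).fit(prewhiten=True)
    # estimated AR coefficient is substantial and beta stays unbiased-ish
    assert white.ar1.mean() > 0.2
    assert abs(white.copes["age"].mean() - 1.0) < 0.5
    assert abs(plain.copes["age"].mean() - 1.0) < 0.5


# ---------------------------------------------------------------------------
# percent BOLD and response normalisation
# ---------------------------------------------------------------------------

def test_percent_bold_basics():
    assert cope_to_percent_bold(1.0, np.array([0.0, 1.0]), 100.0) == pytest.approx(1.0)
    assert cope_to_percent_bold(1.0, np.array([0.0, 1.0]), 200.0) == pytest.approx(0.5)


def test_percent_bold_forward_inverse(small_design):
    """A planted 0.5% modulation is recovered to within 0.05 points."""
    eff = small_design.column("age")
    ptp = np.ptp(eff)
    baseline = 100.0
    beta_true = 0.5 * baseline / (100.0 * ptp)  # yields exactly 0.5% BOLD
    v = 100
    betas = np.vstack([np.full(v, beta_true), np.zeros(v), np.zeros(v)])
    bold = make_bold(small_design, betas, noise=(0.0, 0.02), baseline=baseline, seed=6)
    res = VertexGLM(bold.data, small_design).fit()
    pb = cope_to_percent_bold(res.copes["age"], eff, bold.data.mean(axis=0))
    assert pb.mean() == pytest.approx(0.5, abs=0.05)


def test_normalize_response_magnitudes():
    np.testing.assert_allclose(normalize_response_magnitudes([2.0, 4.0, 6.0]), [1, 2, 3])
    np.testing.assert_allclose(normalize_response_magnitudes([3.0, 3.0]), [1, 1])
    a = np.array([2.0, 5.0, 9.0])
    np.testing.assert_allclose(
        normalize_response_magnitudes(a * 7.3), normalize_response_magnitudes(a)
    )
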