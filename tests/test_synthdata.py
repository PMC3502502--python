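import numpy as np
import pytest

from morphconnect import (
    build_run_regressors,
    fit_stevens_exponent,
    gamma_hrf,
    horn_schunck,
    make_bold,
    make_design,
    make_gender_ratings,
    make_linked_maps,
    make_morph_frames,
    make_orientation_phantom,
    make_ratings,
    make_run_schedules,
)


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def test_generators_bit_identical_for_same_seed():
    a = make_ratings(n_morphs=20, n_subjects=3, seed=9)
    b = make_ratings(n_morphs=20, n_subjects=3, seed=9)
    assert a.records.equals(b.records)

    fa, fla = make_morph_frames("deform", seed=9)
    fb, flb = make_morph_frames("deform", seed=9)
    np.testing.assert_array_equal(fa, fb)
    np.testing.assert_array_equal(fla[0].u, flb[0].u)

    pa = make_orientation_phantom("crossing", seed=9)
    pb = make_orientation_phantom("crossing", seed=9)
    np.testing.assert_array_equal(pa.field.directions, pb.field.directions)

    ga = make_gender_ratings(seed=9)
    gb = make_gender_ratings(seed=9)
    assert ga.equals(gb)


def test_different_seed_differs():
    a = make_ratings(n_morphs=20, n_subjects=3, seed=9)
    b = make_ratings(n_morphs=20, n_subjects=3, seed=10)
    assert not a.records["rating"].equals(b.records["rating"])


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------

def test_zero_gradient_zero_rating():
    r = make_ratings(n_morphs=30, n_subjects=1, noise_sd=0.0, seed=1)
    rec = r.records
    same = rec["start_age"] == rec["target_age"]
    assert np.all(rec.loc[same, "rating"] == 0.0)


def test_linear_exponent_exact_scaling():
    r = make_ratings(n_morphs=30, n_subjects=1, exponent=1.0, scale=0.02, noise_sd=0.0, seed=2)
    rec = r.records
    np.testing.assert_allclose(
        rec["rating"], 0.02 * np.abs(rec["target_age"] - rec["start_age"]), rtol=1e-12
    )


def test_noisy_mean_matches_noiseless():
    """Monte-Carlo mean over many raters sits within 3 SE of the clean value."""
    clean = make_ratings(n_morphs=15, n_subjects=1, noise_sd=0.0, seed=3)
    noisy = make_ratings(n_morphs=15, n_subjects=700, noise_sd=0.3, seed=3)
    clean_vals = clean.records.set_index("morph_id")["rating"]
    grouped = noisy.records.groupby("morph_id")["rating"]
    for morph_id, clean_val in clean_vals.items():
        if clean_val < 1.2:
            continue  # clipping at zero would bias the comparison
        m = grouped.mean()[morph_id]
        se = 0.3 / np.sqrt(700)
        assert abs(m - clean_val) < 3 * se


def test_negative_noise_rejected():
    with pytest.raises(ValueError):
        make_ratings(noise_sd=-0.1)


def test_rating_roundtrip_recovers_exponent():
    r = make_ratings(n_morphs=60, n_subjects=2, exponent=0.3, noise_sd=0.0, seed=4)
    assert fit_stevens_exponent(r).exponent == pytest.approx(0.3, abs=1e-6)


# ---------------------------------------------------------------------------
# morph-surrogate frames
# ---------------------------------------------------------------------------

def test_static_truth_flow_zero():
    _, flows = make_morph_frames("static", n_frames=3, seed=5)
    assert np.all(flows[0].u == 0) and np.all(flows[0].v == 0)


def test_translate_truth_flow_uniform():
    frames, flows = make_morph_frames("translate", n_frames=3, seed=5, speed=1.0)
    assert np.all(flows[0].u == 1.0) and np.all(flows[0].v == 0.0)
    # luminance conserved across frames (within 1%, blobs away from borders)
    sums = frames.sum(axis=(1, 2))
    assert np.ptp(sums) / sums[0] < 0.01


def test_expand_truth_flow_radial():
    frames, flows = make_morph_frames("expand", n_frames=3, size=(32, 32), seed=5)
    f = flows[0]
    yy, xx = np.mgrid[0:32, 0:32].astype(float)
    cx, cy = 15.5, 15.5
    r = np.hypot(xx - cx, yy - cy)
    mag = f.magnitude()
    # magnitude proportional to distance from centre
    inner = (r > 1) & (r < 15)
    np.testing.assert_allclose(mag[inner] / r[inner], mag[inner][0] / r[inner][0], rtol=1e-9)


def test_estimated_flow_correlates_with_truth():
    """Horn-Schunck recovers the planted translation (r > 0.9 on support)."""
    frames, flows = make_morph_frames("translate", n_frames=2, seed=6, speed=1.0)
    est = horn_schunck(frames[0], frames[1], alpha=0.1, n_iter=200)
    support = frames[0] > 0.1
    # uniform truth magnitude: compare the estimate against the truth level
    assert est.u[support].mean() == pytest.approx(1.0, abs=0.25)
    deform_frames, deform_flows = make_morph_frames("deform", n_frames=2, seed=6)
    est2 = horn_schunck(deform_frames[0], deform_frames[1], alpha=0.1, n_iter=200)
    sup2 = deform_frames[0] > 0.1
    r2 = np.corrcoef(est2.u[sup2], deform_flows[0].u[sup2])[0, 1]
    assert r2 > 0.9


def test_unknown_motion_model():
    with pytest.raises(ValueError):
        make_morph_frames("spin")


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def design():
    regs = build_run_regressors(make_run_schedules(12, seed=3))
    return make_design(list(regs.values()), gamma_hrf(dt_s=1 / 24), tr_s=2.4, n_volumes=35)


def test_pure_noise_betas_near_zero(design):
    from morphconnect import VertexGLM

    bold = make_bold(design, np.zeros((3, 400)), noise=(0.0, 1.0), seed=8)
    res = VertexGLM(bold.data, design).fit()
    est = res.copes["age"]
    assert abs(est.mean()) < 3 * est.std(ddof=1) / np.sqrt(400)


def test_ar0_residual_autocorrelation_near_zero(design):
    bold = make_bold(design, np.zeros((3, 200)), noise=(0.0, 1.0), seed=9)
    resid = bold.data - bold.data.mean(axis=0)
    num = np.sum(resid[1:] * resid[:-1], axis=0)
    den = np.sum(resid**2, axis=0)
    assert abs((num / den).mean()) < 0.05


def test_ar_coefficient_reflected_in_series(design):
    bold = make_bold(design, np.zeros((3, 200)), noise=(0.6, 1.0), seed=10)
    resid = bold.data - bold.data.mean(axis=0)
    rho = np.sum(resid[1:] * resid[:-1], axis=0) / np.sum(resid**2, axis=0)
    assert rho.mean() == pytest.approx(0.6, abs=0.1)


def test_spike_offsets_added(design):
    quiet = make_bold(design, np.zeros((3, 5)), noise=(0.0, 0.0), seed=11)
    spiked = make_bold(
        design, np.zeros((3, 5)), noise=(0.0, 0.0), spike_frames=(4,), spike_amplitude=7.0, seed=11
    )
    diff = spiked.data - quiet.data
    assert np.all(diff[4] == 7.0)
    assert np.all(np.delete(diff, 4, axis=0) == 0.0)


# ---------------------------------------------------------------------------
# linked maps
# ---------------------------------------------------------------------------

def test_linked_maps_null_bound(ico2):
    from morphconnect import spatial_crosscorr

    n = ico2.n_vertices
    rhos = [
        spatial_crosscorr(*make_linked_maps(ico2, 0.0, seed=100 + r)).rho for r in range(30)
    ]
    assert abs(np.mean(rhos)) < 3 / np.sqrt(n)


def test_linked_maps_ranges(ico2):
    act, prof = make_linked_maps(ico2, 0.5, seed=12)
    assert np.all(act.values >= 0)
    assert np.all((prof.score > -4.0) & (prof.score < 0.0))
    assert prof.excluded_vertices.size == 0
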