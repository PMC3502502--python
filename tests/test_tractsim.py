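import numpy as np
import pytest
from scipy import ndimage

from morphconnect import (
    TrackConfig,
    connectivity_profile,
    make_orientation_phantom,
    path_distribution_volume,
    track_samples,
)
from morphconnect.tractsim import TrackResult


@pytest.fixture(scope="module")
def bundle():
    return make_orientation_phantom("straight_bundle", dispersion_deg=0.0)


def _track(phantom, n_samples, seed=1, **kw):
    cfg = TrackConfig(n_samples=n_samples, seed=seed, **kw)
    return track_samples(
        phantom.field, phantom.seed_points, cfg, init_directions=phantom.seed_directions
    )


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

def test_bundle_directions_parallel_to_axis(bundle):
    f = bundle.field
    active = f.fractions[..., 0] > 0
    dots = f.directions[active, 0] @ np.array([1.0, 0.0, 0.0])
    np.testing.assert_allclose(dots, 1.0)


def test_crossing_center_orthogonal_fibers():
    ph = make_orientation_phantom("crossing")
    f = ph.field
    both = (f.fractions > 0).all(axis=-1)
    assert both.any()
    d = f.directions[both]
    dots = np.einsum("ij,ij->i", d[:, 0], d[:, 1])
    np.testing.assert_allclose(dots, 0.0, atol=1e-12)
    np.testing.assert_allclose(f.fractions[both], 0.5)


def test_disconnected_gap_is_isotropic():
    ph = make_orientation_phantom("disconnected", gap_voxels=6)
    f = ph.field
    # along the bundle core there is a contiguous isotropic stretch >= 5
    core = f.isotropic[:, 6, 6]
    best = cur = 0
    for val in core:
        cur = cur + 1 if val else 0
        best = max(best, cur)
    assert best >= 5
    # while the connected phantom's core is oriented throughout
    connected = make_orientation_phantom("straight_bundle")
    assert not connected.field.isotropic[2:-2, 6, 6].any()


def test_bad_geometry_rejected():
    with pytest.raises(ValueError):
        make_orientation_phantom("loop")
    with pytest.raises(ValueError):
        make_orientation_phantom("disconnected", gap_voxels=3)


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def test_deterministic_bundle_connects_all(bundle):
    res = _track(bundle, 50)
    assert res.connecting_fraction() == 1.0


def test_disconnected_fraction_negligible():
    ph = make_orientation_phantom("disconnected", dispersion_deg=10.0)
    cfg = TrackConfig(n_samples=500, seed=2)
    res = track_samples(
        ph.field, ph.seed_points[::4], cfg, init_directions=ph.seed_directions[::4]
    )
    assert res.connecting_permille() < 0.1


def test_waypoint_filters_connections():
    """Only samples that traversed every waypoint count as connecting."""
    ph = make_orientation_phantom("straight_bundle", dispersion_deg=5.0)
    on_path = np.zeros(ph.field.shape, dtype=bool)
    on_path[14:16] = True  # slab crossing the bundle mid-way
    off_path = np.zeros(ph.field.shape, dtype=bool)
    off_path[14:16, 0, 0] = True  # corner the bundle never visits
    cfg = TrackConfig(n_samples=300, seed=3)

    def run(wps):
        return track_samples(
            ph.field, ph.seed_points[:8], cfg,
            init_directions=ph.seed_directions[:8], waypoints=wps,
        ).total_connecting

    plain = run(None)
    assert plain > 0
    assert run([on_path]) == plain  # every connecting sample crosses the slab
    assert run([off_path]) == 0
    assert run([on_path, off_path]) == 0


def test_dispersion_monotonically_degrades_connectivity():
    fractions = []
    for disp in (0.0, 10.0, 25.0):
        ph = make_orientation_phantom("straight_bundle", dispersion_deg=disp)
        res = _track(ph, 400, seed=4)
        fractions.append(res.connecting_fraction())
    assert fractions[0] >= fractions[1] >= fractions[2]
    assert fractions[0] == 1.0


def test_monte_carlo_sd_matches_binomial():
    """Connecting-fraction scatter across RNG seeds is ~binomial."""
    ph = make_orientation_phantom("straight_bundle", dispersion_deg=15.0)
    seeds = ph.seed_points[27:28]  # one central seed vertex
    dirs = ph.seed_directions[27:28]
    ns = 1000
    fracs = []
    for rep in range(20):
        cfg = TrackConfig(n_samples=ns, seed=100 + rep)
        res = track_samples(ph.field, seeds, cfg, init_directions=dirs)
        fracs.append(res.connecting_fraction())
    f = np.mean(fracs)
    expected_sd = np.sqrt(f * (1 - f) / ns)
    assert np.std(fracs, ddof=1) == pytest.approx(expected_sd, rel=0.6)


def test_empty_seed_set_rejected(bundle):
    with pytest.raises(ValueError, match="empty"):
        track_samples(bundle.field, np.empty((0, 3)), TrackConfig(n_samples=10))


# ---------------------------------------------------------------------------
# connectivity profiles
# ---------------------------------------------------------------------------

def test_score_log10_values(bundle):
    mesh = bundle.target_mesh
    res = TrackResult(
        seed_points=bundle.seed_points[:1],
        connect_counts=np.array([100]),
        n_samples=10_000,
        visit_counts=np.zeros(bundle.field.shape, dtype=np.int64),
        arrival_points=np.repeat(mesh.vertices[5][None], 100, axis=0),
        arrival_seed_index=np.zeros(100, dtype=int),
    )
    prof = connectivity_profile(res, mesh, fwhm_mm=0.0)
    assert prof.score[5] == pytest.approx(-2.0)  # log10(100/10^4)
    # cs equal to ns at a vertex gives score 0
    res.arrival_points = np.repeat(mesh.vertices[5][None], 10_000, axis=0)
    prof = connectivity_profile(res, mesh, fwhm_mm=0.0)
    assert prof.score[5] == pytest.approx(0.0)


def test_profile_smoothing_conserves_counts(bundle):
    res = _track(bundle, 200, seed=5)
    raw = connectivity_profile(res, bundle.target_mesh, fwhm_mm=0.0)
    smoothed = connectivity_profile(res, bundle.target_mesh, fwhm_mm=2.0)
    assert smoothed.cs.sum() == pytest.approx(raw.cs.sum(), rel=1e-6)


def test_zero_vertices_excluded(bundle):
    res = _track(bundle, 100, seed=6)
    prof = connectivity_profile(res, bundle.target_mesh, fwhm_mm=0.0)
    assert np.all(np.isfinite(prof.score[prof.included_vertices]))
    assert np.all(prof.cs[prof.excluded_vertices] == 0)


# ---------------------------------------------------------------------------
# path-distribution volume
# ---------------------------------------------------------------------------

def test_path_volume_thresholding():
    counts = np.arange(27).reshape(3, 3, 3)
    np.testing.assert_array_equal(path_distribution_volume(counts, 0), counts)
    assert path_distribution_volume(counts, 100).sum() == 0
    out = path_distribution_volume(counts, 20)
    assert np.all(out[out > 0] >= 20)


def test_bundle_path_volume_single_component(bundle):
    res = _track(bundle, 200, seed=7)
    vol = path_distribution_volume(res.visit_counts, threshold=100)
    labeled, n = ndimage.label(vol > 0)
    assert n == 1
    # suprathreshold voxels trace the bundle along x
    xs = np.flatnonzero(vol.any(axis=(1, 2)))
    assert xs.size >= 20
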