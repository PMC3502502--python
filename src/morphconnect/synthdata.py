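"""Synthetic inputs with known ground truth for every pipeline stage.

Emulated here: morph-stimulus rating experiments (Stevens-law responses with
additive noise), short grayscale image sequences with analytically known
motion (blob surrogates for face-morph keyframes), multi-subject vertex-wise
BOLD series with planted effect maps and AR(1) noise, voxel-grid
fiber-orientation phantoms (bundle, crossing, disconnected null) with
seed/target surface patches, and paired activation/connectivity maps with a
controllable monotone (Gaussian-copula) link.  All generators take a seed
and reproduce bit-identical output for identical seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .firstlevel import DesignMatrix
from .inference import VertexStatMap
from .mesh import SurfaceMesh, make_planar_patch, make_surface_mesh
from .opticflow import FlowField
from .psychophys import perceived_gender_level
from .stimuli import AGE_MAX, AGE_MIN, MorphSchedule, RatingDataset
from .tractsim import ConnectivityProfile, OrientationField

__all__ = [
    "DEFAULT_SEED",
    "make_surface_mesh",
    "make_run_schedules",
    "make_ratings",
    "make_gender_ratings",
    "make_morph_frames",
    "BOLDDataset",
    "make_bold",
    "Phantom",
    "make_orientation_phantom",
    "make_linked_maps",
    "make_truth_map",
]

DEFAULT_SEED = 20121120


# ---------------------------------------------------------------------------
# stimulus schedules and ratings
# ---------------------------------------------------------------------------

def make_run_schedules(
    n_morphs: int = 120,
    fps: int = 24,
    seed: int = DEFAULT_SEED,
    gender_fraction: float = 0.5,
) -> list[MorphSchedule]:
    """A run of morph stimuli: ages pseudo-randomised over 10-year steps.

    Half of the morphs (by default) carry a gender transition; age changes
    are drawn identically for transition and non-transition morphs so the
    age and gender regressors decorrelate by design.
    """
    rng = np.random.default_rng(seed)
    n_gender = int(round(n_morphs * gender_fraction))
    has_gender = np.zeros(n_morphs, dtype=bool)
    has_gender[rng.permutation(n_morphs)[:n_gender]] = True
    schedules = []
    for i in range(n_morphs):
        start = float(rng.uniform(AGE_MIN, AGE_MAX))
        # age change quantised to 10-year intervals, direction random
        delta = float(rng.integers(0, 7)) * 10.0 * (1 if rng.random() < 0.5 else -1)
        target = float(np.clip(start + delta, AGE_MIN, AGE_MAX))
        schedules.append(
            MorphSchedule(
                start_age=start,
                target_age=target,
                has_gender_transition=bool(has_gender[i]),
                fps=fps,
            )
        )
    return schedules


def make_ratings(
    n_morphs: int = 121,
    n_subjects: int = 24,
    exponent: float = 0.3,
    scale: float | None = None,
    noise_sd: float | None = None,
    seed: int = DEFAULT_SEED,
    scale_max: float = 3.0,
    age_noise_slope: float = 0.0,
) -> RatingDataset:
    """Synthetic age-difference ratings following Stevens' power law.

    ``rating = scale * |target^p - start^p| + N(0, sd)``, clipped at zero.
    ``scale`` defaults so the largest possible age gradient maps to
    ``scale_max`` (3.0 a.u.); ``noise_sd`` defaults to 10% of the rating
    range.  ``age_noise_slope`` optionally grows the noise SD with the mean
    absolute age of the pair (a.u. per year), mimicking the harder
    estimation of older faces.
    """
    if noise_sd is not None and noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    rng = np.random.default_rng(seed)
    start = rng.uniform(AGE_MIN, AGE_MAX, size=n_morphs)
    target = rng.uniform(AGE_MIN, AGE_MAX, size=n_morphs)
    if scale is None:
        scale = scale_max / (AGE_MAX ** exponent - AGE_MIN ** exponent)
    if noise_sd is None:
        noise_sd = 0.1 * scale_max
    clean = scale * np.abs(target ** exponent - start ** exponent)
    rows = []
    for subj in range(n_subjects):
        sd = noise_sd + age_noise_slope * 0.5 * (start + target)
        noisy = clean + rng.normal(0.0, 1.0, size=n_morphs) * sd
        rows.append(
            pd.DataFrame(
                {
                    "morph_id": np.arange(n_morphs),
                    "subject_id": subj,
                    "start_age": start,
                    "target_age": target,
                    "rating": np.clip(noisy, 0.0, None),
                }
            )
        )
    return RatingDataset(pd.concat(rows, ignore_index=True), scale_max=scale_max)


def make_gender_ratings(
    n_positions: int = 119,
    n_morphs: int = 60,
    gamma: float = 3.0,
    noise_sd: float = 0.1,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Perceived-gender ratings sampled along transition-morph continua.

    Positions are morph coordinates in [0, 1]; ratings follow the perceived
    gender S-curve (per-half exponent ``gamma``) plus Gaussian noise at
    ``noise_sd`` of the unit rating range, clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, 1.0, size=n_positions)
    morph_ids = rng.integers(0, n_morphs, size=n_positions)
    clean = perceived_gender_level(positions, gamma)
    ratings = np.clip(clean + rng.normal(0.0, noise_sd, size=n_positions), 0.0, 1.0)
    return pd.DataFrame({"morph_id": morph_ids, "position": positions, "rating": ratings})


# ---------------------------------------------------------------------------
# morph-surrogate image sequences with analytic ground-truth motion
# ---------------------------------------------------------------------------

def make_morph_frames(
    motion_model: str = "translate",
    n_frames: int = 8,
    size: tuple[int, int] = (64, 64),
    seed: int = DEFAULT_SEED,
    speed: float = 1.0,
    expansion_rate: float = 0.02,
    deform_amplitude: float = 0.5,
    n_blobs: int = 6,
) -> tuple[np.ndarray, list[FlowField]]:
    """Gaussian-blob image sequences with known dense motion.

    Returns ``(frames, truth_flows)``: frames of shape (n_frames, H, W) in
    [0, 1] and one ground-truth :class:`FlowField` per successive frame pair.
    Motion models: ``static`` (zero flow), ``translate`` (uniform
    ``speed`` px/frame along x), ``expand`` (radial flow about the centre,
    magnitude proportional to distance) and ``deform`` (smooth sinusoidal
    displacement field).
    """
    if motion_model not in {"static", "translate", "expand", "deform"}:
        raise ValueError(f"unknown motion model '{motion_model}'")
    h, w = size
    rng = np.random.default_rng(seed)
    cx = rng.uniform(0.25 * w, 0.75 * w, n_blobs)
    cy = rng.uniform(0.25 * h, 0.75 * h, n_blobs)
    amp = rng.uniform(0.4, 1.0, n_blobs)
    width = rng.uniform(0.04 * min(h, w), 0.10 * min(h, w), n_blobs)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    def render(px: np.ndarray, py: np.ndarray) -> np.ndarray:
        img = np.zeros((h, w))
        for k in range(n_blobs):
            img += amp[k] * np.exp(-(((px - cx[k]) ** 2) + ((py - cy[k]) ** 2)) / (2 * width[k] ** 2))
        return img

    peak = render(xx, yy).max()
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])

    frames = []
    flows: list[FlowField] = []
    for t in range(n_frames):
        if motion_model == "static":
            px, py = xx, yy
        elif motion_model == "translate":
            px, py = xx - speed * t, yy
        elif motion_model == "expand":
            s = (1.0 + expansion_rate) ** t
            px = center[0] + (xx - center[0]) / s
            py = center[1] + (yy - center[1]) / s
        else:  # deform
            dx = deform_amplitude * np.sin(2 * np.pi * yy / h)
            dy = deform_amplitude * np.sin(2 * np.pi * xx / w)
            px, py = xx - t * dx, yy - t * dy
        frames.append(0.8 * render(px, py) / peak)

    for t in range(n_frames - 1):
        if motion_model == "static":
            u = np.zeros((h, w))
            v = np.zeros((h, w))
        elif motion_model == "translate":
            u = np.full((h, w), speed)
            v = np.zeros((h, w))
        elif motion_model == "expand":
            u = expansion_rate * (xx - center[0])
            v = expansion_rate * (yy - center[1])
        else:
            u = deform_amplitude * np.sin(2 * np.pi * yy / h)
            v = deform_amplitude * np.sin(2 * np.pi * xx / w)
        flows.append(FlowField(u=u, v=v))

    return np.stack(frames), flows


# ---------------------------------------------------------------------------
# synthetic BOLD data
# ---------------------------------------------------------------------------

@dataclass
class BOLDDataset:
    """Per-subject vertex-wise BOLD series with known ground truth."""

    data: np.ndarray  # (T, V)
    tr_s: float
    truth_betas: np.ndarray  # (n_task_columns, V)
    ar_coef: float
    noise_sd: float
    spike_frames: tuple[int, ...] = ()
    baseline: float = 100.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data must be finite")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]


def make_bold(
    design: DesignMatrix,
    truth_betas: np.ndarray,
    noise: tuple[float, float] = (0.3, 1.0),
    spike_frames: tuple[int, ...] = (),
    spike_amplitude: float = 5.0,
    baseline: float = 100.0,
    seed: int = DEFAULT_SEED,
) -> BOLDDataset:
    """Simulate ``Y = X beta + baseline + AR(1) noise + spikes``.

    ``truth_betas`` has one row per task column of the design (effects are
    zero outside designated active vertices).  ``noise = (ar, sd)`` sets the
    AR(1) coefficient and the marginal noise SD; spikes add a global offset
    at the listed volumes.
    """
    ar, sd = noise
    if sd < 0:
        raise ValueError("noise SD must be nonnegative")
    if not -1 < ar < 1:
        raise ValueError("AR(1) coefficient must lie in (-1, 1)")
    truth_betas = np.atleast_2d(np.asarray(truth_betas, float))
    n_task = len(design.task_columns)
    if truth_betas.shape[0] != n_task:
        raise ValueError(f"truth_betas needs {n_task} rows (one per task column)")
    x_task = np.column_stack([design.column(c) for c in design.task_columns])
    t, v = design.n_volumes, truth_betas.shape[1]
    y = x_task @ truth_betas + baseline
    if sd > 0:
        rng = np.random.default_rng(seed)
        innov = rng.normal(0.0, sd * np.sqrt(max(1.0 - ar ** 2, 1e-12)), size=(t, v))
        noise_ts = signal.lfilter([1.0], [1.0, -ar], innov, axis=0)
        y = y + noise_ts
    for f in spike_frames:
        if not 0 <= f < t:
            raise ValueError(f"spike frame {f} outside run")
        y[f] += spike_amplitude
    return BOLDDataset(
        data=y,
        tr_s=design.tr_s,
        truth_betas=truth_betas,
        ar_coef=ar,
        noise_sd=sd,
        spike_frames=tuple(spike_frames),
        baseline=baseline,
    )


def make_truth_map(
    mesh: SurfaceMesh,
    center_vertices: list[int],
    radius_mm: float,
    amplitude: float = 1.0,
    profile: str = "cosine",
) -> np.ndarray:
    """Per-vertex effect-size map: patches around centre vertices.

    ``cosine`` tapers smoothly from ``amplitude`` at the centre to zero at
    ``radius_mm``; ``flat`` plants a uniform patch.  Effects are exactly
    zero outside the patches.
    """
    beta = np.zeros(mesh.n_vertices)
    d = mesh.geodesic_distances(center_vertices)
    for row in np.atleast_2d(d):
        inside = row <= radius_mm
        if profile == "flat":
            beta[inside] = np.maximum(beta[inside], amplitude)
        else:
            taper = amplitude * 0.5 * (1 + np.cos(np.pi * row[inside] / radius_mm))
            beta[inside] = np.maximum(beta[inside], taper)
    return beta


# ---------------------------------------------------------------------------
# fiber-orientation phantoms
# ---------------------------------------------------------------------------

@dataclass
class Phantom:
    """An orientation field plus seed/target surface patches."""

    field: OrientationField
    seed_points: np.ndarray
    seed_directions: np.ndarray
    seed_mesh: SurfaceMesh
    target_mesh: SurfaceMesh
    geometry: str
    waypoints: list[np.ndarray] = field(default_factory=list)


def make_orientation_phantom(
    geometry: str = "straight_bundle",
    grid_shape: tuple[int, int, int] = (30, 12, 12),
    voxel_size_mm: float = 2.0,
    seed: int = DEFAULT_SEED,
    dispersion_deg: float = 10.0,
    bundle_fraction: float = 0.9,
    tube_radius_vox: float = 2.5,
    gap_voxels: int = 6,
    patch_size: int = 8,
) -> Phantom:
    """Two-fiber voxel phantoms for tractography validation.

    ``straight_bundle``: a tube of voxels along x with a single fiber
    parallel to the bundle axis joining the seed and target patches.
    ``crossing``: the central region additionally carries an orthogonal
    fiber (fractions 0.5/0.5) from a crossing arm along y.
    ``disconnected``: the bundle interrupted by >= 5 isotropic voxels (the
    null-connectivity control).  Voxels outside any bundle are isotropic.
    """
    if geometry not in {"straight_bundle", "crossing", "disconnected"}:
        raise ValueError(f"unknown phantom geometry '{geometry}'")
    if geometry == "disconnected" and gap_voxels < 5:
        raise ValueError("disconnected phantom needs a gap of >= 5 voxels")
    nx, ny, nz = grid_shape
    directions = np.zeros((*grid_shape, 2, 3))
    fractions = np.zeros((*grid_shape, 2))
    isotropic = np.ones(grid_shape, dtype=bool)
    dispersion = np.full(grid_shape, dispersion_deg, dtype=float)

    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    yy, zz = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    tube = (yy - cy) ** 2 + (zz - cz) ** 2 <= tube_radius_vox ** 2

    x0, x1 = 2, nx - 3  # bundle spans voxels [x0, x1]
    bundle = np.zeros(grid_shape, dtype=bool)
    bundle[x0: x1 + 1, tube] = True
    if geometry == "disconnected":
        g0 = (nx - gap_voxels) // 2
        bundle[g0: g0 + gap_voxels] = False

    directions[bundle, 0] = (1.0, 0.0, 0.0)
    fractions[bundle, 0] = bundle_fraction
    isotropic[bundle] = False

    waypoints: list[np.ndarray] = []
    if geometry == "crossing":
        cx_lo, cx_hi = nx // 2 - 2, nx // 2 + 2
        xx2, zz2 = np.meshgrid(np.arange(nx), np.arange(nz), indexing="ij")
        arm_sec = (np.abs(xx2 - (nx - 1) / 2.0) <= 2) & (np.abs(zz2 - cz) <= tube_radius_vox)
        arm = np.zeros(grid_shape, dtype=bool)
        for y in range(ny):
            arm[:, y, :] |= arm_sec
        overlap = arm & bundle
        arm_only = arm & ~bundle
        directions[arm_only, 0] = (0.0, 1.0, 0.0)
        fractions[arm_only, 0] = bundle_fraction
        isotropic[arm_only] = False
        directions[overlap, 0] = (1.0, 0.0, 0.0)
        directions[overlap, 1] = (0.0, 1.0, 0.0)
        fractions[overlap] = (0.5, 0.5)
        wp = np.zeros(grid_shape, dtype=bool)
        wp[cx_lo:cx_hi + 1][:, tube] = True
        waypoints.append(wp)

    seed_mask = np.zeros(grid_shape, dtype=bool)
    seed_mask[x0: x0 + 2, tube] = True
    target_mask = np.zeros(grid_shape, dtype=bool)
    target_mask[x1 - 1: x1 + 1, tube] = True
    stop_mask = np.zeros(grid_shape, dtype=bool)

    fieldvol = OrientationField(
        shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        directions=directions,
        fractions=fractions,
        dispersion_deg=dispersion,
        isotropic=isotropic,
        masks={"seed": seed_mask, "target": target_mask, "stop": stop_mask},
    )

    # seed/target surface patches: planar 1-mm grids across the tube
    # cross-section, with seed points projected 1 mm inward along the bundle
    span = patch_size - 1
    origin_y = (cy + 0.5) * voxel_size_mm - span / 2.0
    origin_z = (cz + 0.5) * voxel_size_mm - span / 2.0
    seed_x = (x0 + 0.5) * voxel_size_mm
    target_x = (x1 + 0.5) * voxel_size_mm
    seed_mesh = make_planar_patch(
        patch_size, patch_size, 1.0, origin=(seed_x - 1.0, origin_y, origin_z)
    )
    target_mesh = make_planar_patch(
        patch_size, patch_size, 1.0, origin=(target_x + 1.0, origin_y, origin_z)
    )
    seed_points = seed_mesh.vertices + np.array([1.0, 0.0, 0.0])
    seed_directions = np.tile(np.array([1.0, 0.0, 0.0]), (seed_points.shape[0], 1))

    return Phantom(
        field=fieldvol,
        seed_points=seed_points,
        seed_directions=seed_directions,
        seed_mesh=seed_mesh,
        target_mesh=target_mesh,
        geometry=geometry,
        waypoints=waypoints,
    )


# ---------------------------------------------------------------------------
# paired activation/connectivity maps (Gaussian copula)
# ---------------------------------------------------------------------------

def make_linked_maps(
    mesh: SurfaceMesh,
    rho_target: float,
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
    ns: int = 10_000,
) -> tuple[VertexStatMap, ConnectivityProfile]:
    """Paired vertex maps with a controllable monotone (rank) link.

    A bivariate Gaussian copula with Pearson correlation
    ``2 sin(pi * rho_target / 6)`` gives a population Spearman correlation
    of exactly ``rho_target``; monotone transforms then map one latent to an
    activation-probability scale (|log10 p|) and the other to a
    connectivity-score scale (log10(cs/ns) in [-4, 0]).  ``noise_sd`` adds
    independent Gaussian jitter to the second latent, degrading the link
    below the nominal target.
    """
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError("rho_target must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    n = mesh.n_vertices
    r = 2.0 * np.sin(np.pi * rho_target / 6.0)
    z1 = rng.standard_normal(n)
    z2 = r * z1 + np.sqrt(max(1.0 - r ** 2, 0.0)) * rng.standard_normal(n)
    if noise_sd > 0:
        z2 = z2 + noise_sd * rng.standard_normal(n)

    # monotone transforms onto the scales used downstream
    neglogp = -np.log10(np.maximum(stats.norm.sf(z1), 1e-300))
    score = 4.0 * stats.norm.cdf(z2) - 4.0
    cs = ns * 10.0 ** score
    activation = VertexStatMap(neglogp, name="neglog10p", mesh=mesh)
    profile = ConnectivityProfile(
        seed_id="synthetic_seed",
        target_id="synthetic_target",
        cs=cs,
        ns=ns,
        score=score,
        excluded_vertices=np.empty(0, dtype=int),
        mesh=mesh,
    )
    return activation, profile
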