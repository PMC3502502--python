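"""Probabilistic streamline tractography on synthetic fiber-orientation fields.

Each voxel carries up to two mean fiber orientations (crossing-fiber model)
with volume fractions and an angular dispersion.  A streamline sample draws
an orientation per voxel per step (fiber chosen proportionally to its
fraction, axis perturbed by a Watson-like axial Gaussian, sign chosen to
minimise turning), advances a fixed step, and terminates on leaving the
grid, entering a stop mask, exceeding the curvature threshold or exhausting
``max_steps``.  A sample connects when it enters the target mask having
visited every waypoint mask.  Per-target-vertex counts of arriving samples
(cs) out of ns sent per seed vertex give the connectivity score
``log10(cs/ns)`` after slight surface smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh
from .inference import smooth_vertex_map

__all__ = [
    "OrientationField",
    "TrackConfig",
    "TrackResult",
    "track_samples",
    "ConnectivityProfile",
    "connectivity_profile",
    "path_distribution_volume",
]

DEFAULT_SEED = 20121120


@dataclass
class OrientationField:
    """Voxel grid of up to two fiber orientations per voxel.

    ``directions``: (nx, ny, nz, 2, 3) unit vectors (zero rows where a fiber
    is absent); ``fractions``: (nx, ny, nz, 2) volume fractions summing to at
    most 1; ``dispersion_deg``: per-voxel angular SD of the orientation
    perturbation; ``isotropic``: voxels with no preferred orientation.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: float
    directions: np.ndarray
    fractions: np.ndarray
    dispersion_deg: np.ndarray
    isotropic: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, float)
        self.fractions = np.asarray(self.fractions, float)
        self.dispersion_deg = np.asarray(self.dispersion_deg, float)
        self.isotropic = np.asarray(self.isotropic, bool)
        if self.directions.shape != (*self.shape, 2, 3):
            raise ValueError("directions must be (nx, ny, nz, 2, 3)")
        if self.fractions.shape != (*self.shape, 2):
            raise ValueError("fractions must be (nx, ny, nz, 2)")
        if np.any(self.fractions < 0) or np.any(self.fractions.sum(axis=-1) > 1 + 1e-9):
            raise ValueError("fractions must be in [0,1] and sum to <= 1 per voxel")
        norms = np.linalg.norm(self.directions, axis=-1)
        active = self.fractions > 0
        if not np.allclose(norms[active], 1.0, atol=1e-6):
            raise ValueError("active fiber directions must be unit vectors")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape, float) * self.voxel_size_mm

    def voxel_of(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest-neighbour voxel indices of points (no interpolation)."""
        return np.floor(np.asarray(points_mm, float) / self.voxel_size_mm).astype(int)


@dataclass
class TrackConfig:
    """Tracking parameters (defaults mirror the study contract)."""

    n_samples: int = 10_000
    step_mm: float = 0.5
    max_steps: int = 1000
    curvature_threshold_deg: float = 80.0
    dispersion_deg: float | None = None  # None -> per-voxel field values
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")


@dataclass
class TrackResult:
    """Raw tracking output: counts, visit volume and arrival geometry."""

    seed_points: np.ndarray
    connect_counts: np.ndarray  # per seed vertex
    n_samples: int
    visit_counts: np.ndarray  # voxel grid, unique visits per sample
    arrival_points: np.ndarray  # (M, 3) target-entry positions, mm
    arrival_seed_index: np.ndarray  # (M,) which seed vertex sent the sample

    @property
    def total_sent(self) -> int:
        return int(self.n_samples * self.seed_points.shape[0])

    @property
    def total_connecting(self) -> int:
        return int(self.connect_counts.sum())

    def connecting_fraction(self) -> float:
        return self.total_connecting / self.total_sent

    def connecting_permille(self) -> float:
        return 1000.0 * self.connecting_fraction()


def _random_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    g = rng.standard_normal((n, 3))
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def track_samples(
    fieldvol: OrientationField,
    seed_points: np.ndarray,
    cfg: TrackConfig | None = None,
    targets: np.ndarray | None = None,
    stops: np.ndarray | None = None,
    waypoints: list[np.ndarray] | None = None,
    init_directions: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> TrackResult:
    """Send ``cfg.n_samples`` probabilistic streamlines from each seed point.

    Parameters
    ----------
    seed_points : (N, 3) array
        Seed positions in mm (surface vertices projected into the volume).
    targets, stops : bool volumes
        Default to the field's ``masks['target']`` / ``masks['stop']``.
    waypoints : list of bool volumes
        A sample connects only after visiting every waypoint.
    init_directions : (N, 3) array, optional
        Initial propagation direction per seed; when omitted the first drawn
        orientation keeps a random sign.
    """
    cfg = cfg or TrackConfig()
    seed_points = np.atleast_2d(np.asarray(seed_points, float))
    if seed_points.size == 0:
        raise ValueError("empty seed set")
    if targets is None:
        targets = fieldvol.masks.get("target")
    if targets is None:
        raise ValueError("no target mask given")
    stops = stops if stops is not None else fieldvol.masks.get("stop")
    waypoints = waypoints or []
    rng = rng or np.random.default_rng(cfg.seed)

    shape = fieldvol.shape
    vs = fieldvol.voxel_size_mm
    cos_thr = np.cos(np.deg2rad(cfg.curvature_threshold_deg))
    visit = np.zeros(shape, dtype=np.int64)
    connect_counts = np.zeros(seed_points.shape[0], dtype=np.int64)
    arrivals: list[np.ndarray] = []
    arrival_seed: list[np.ndarray] = []

    for si, seed in enumerate(seed_points):
        n = cfg.n_samples
        pos = np.repeat(seed[None, :], n, axis=0)
        prev_dir = (
            np.repeat(init_directions[si][None, :] / np.linalg.norm(init_directions[si]), n, axis=0)
            if init_directions is not None
            else None
        )
        alive = np.ones(n, dtype=bool)
        wp_seen = np.ones((n, max(len(waypoints), 1)), dtype=bool)
        if waypoints:
            wp_seen[:] = False
        prev_vox = np.full((n, 3), -1, dtype=int)

        for _ in range(cfg.max_steps):
            if not alive.any():
                break
            ai = np.flatnonzero(alive)
            vox = np.floor(pos[ai] / vs).astype(int)
            inside = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
            alive[ai[~inside]] = False
            ai = ai[inside]
            if ai.size == 0:
                break
            vox = vox[inside]
            vt = tuple(vox.T)

            entered = np.any(vox != prev_vox[ai], axis=1)
            ev = vox[entered]
            if ev.size:
                np.add.at(visit, tuple(ev.T), 1)
            prev_vox[ai] = vox

            if stops is not None:
                hit_stop = stops[vt]
                alive[ai[hit_stop]] = False
                keep = ~hit_stop
                ai, vox, vt = ai[keep], vox[keep], tuple(vox[keep].T)
                if ai.size == 0:
                    continue

            for wi, wp in enumerate(waypoints):
                wp_seen[ai, wi] |= wp[vt]

            hit_target = targets[vt]
            ok = hit_target & np.all(wp_seen[ai], axis=1)
            if ok.any():
                idx = ai[ok]
                connect_counts[si] += idx.size
                arrivals.append(pos[idx].copy())
                arrival_seed.append(np.full(idx.size, si))
            alive[ai[hit_target]] = False
            keep = ~hit_target
            ai, vox, vt = ai[keep], vox[keep], tuple(vox[keep].T)
            if ai.size == 0:
                continue

            # draw an orientation per voxel
            m = ai.size
            iso = fieldvol.isotropic[vt]
            new_dir = np.empty((m, 3))
            if iso.any():
                new_dir[iso] = _random_unit(rng, int(iso.sum()))
            fib = ~iso
            if fib.any():
                fvox = tuple(c[fib] for c in vt)
                fr = fieldvol.fractions[fvox]  # (k, 2)
                tot = fr.sum(axis=1, keepdims=True)
                p0 = np.where(tot[:, 0] > 0, fr[:, 0] / np.maximum(tot[:, 0], 1e-300), 1.0)
                pick = (rng.random(int(fib.sum())) >= p0).astype(int)
                axes = fieldvol.directions[fvox][np.arange(pick.size), pick]
                disp = (
                    np.full(pick.size, cfg.dispersion_deg)
                    if cfg.dispersion_deg is not None
                    else fieldvol.dispersion_deg[fvox]
                )
                sigma = np.deg2rad(disp)[:, None]
                pert = axes + sigma * rng.standard_normal((pick.size, 3))
                pert /= np.linalg.norm(pert, axis=1, keepdims=True)
                new_dir[fib] = pert

            if prev_dir is not None:
                dots = np.einsum("ij,ij->i", new_dir, prev_dir[ai])
                new_dir[dots < 0] *= -1.0
                dots = np.abs(dots)
                too_curved = dots < cos_thr
                alive[ai[too_curved]] = False
                keep = ~too_curved
                ai, new_dir = ai[keep], new_dir[keep]
                if ai.size == 0:
                    continue
            else:
                sign = np.where(rng.random(m) < 0.5, -1.0, 1.0)
                new_dir *= sign[:, None]
                prev_dir = np.zeros((n, 3))

            pos[ai] += cfg.step_mm * new_dir
            prev_dir[ai] = new_dir

    arr = np.concatenate(arrivals) if arrivals else np.empty((0, 3))
    arr_seed = np.concatenate(arrival_seed) if arrival_seed else np.empty(0, dtype=int)
    return TrackResult(
        seed_points=seed_points,
        connect_counts=connect_counts,
        n_samples=cfg.n_samples,
        visit_counts=visit,
        arrival_points=arr,
        arrival_seed_index=arr_seed,
    )


@dataclass
class ConnectivityProfile:
    """Per-target-vertex connectivity: cs arriving samples out of ns sent.

    ``score = log10(cs_smoothed / ns)``; vertices whose smoothed count is
    still zero are excluded (their log score is undefined) and listed.
    """

    seed_id: str
    target_id: str
    cs: np.ndarray
    ns: int
    score: np.ndarray
    excluded_vertices: np.ndarray
    mesh: SurfaceMesh | None = None

    @property
    def included_vertices(self) -> np.ndarray:
        mask = np.ones(self.cs.size, dtype=bool)
        mask[self.excluded_vertices] = False
        return np.flatnonzero(mask)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"vertex_id": np.arange(self.cs.size), "cs": self.cs, "score": self.score}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def connectivity_profile(
    result: TrackResult,
    target_mesh: SurfaceMesh,
    fwhm_mm: float = 2.0,
    seed_id: str = "seed",
    target_id: str = "target",
    pseudo_count: float = 0.0,
) -> ConnectivityProfile:
    """Build the per-vertex connectivity profile on the target patch.

    Arriving samples are assigned to the nearest target vertex, counts are
    surface-smoothed at ``fwhm_mm`` (sum-conserving), divided by the samples
    sent per seed vertex (ns) and log10-transformed.  ``pseudo_count`` > 0
    floors the counts instead of excluding zero vertices.
    """
    cs_raw = np.zeros(target_mesh.n_vertices)
    if result.arrival_points.shape[0]:
        tree = cKDTree(target_mesh.vertices)
        _, nearest = tree.query(result.arrival_points)
        np.add.at(cs_raw, nearest, 1.0)
    cs = smooth_vertex_map(cs_raw, target_mesh, fwhm_mm) if fwhm_mm > 0 else cs_raw
    cs = np.maximum(cs, 0.0)
    if pseudo_count > 0:
        cs = np.maximum(cs, pseudo_count)
    excluded = np.flatnonzero(cs <= 0)
    score = np.full(target_mesh.n_vertices, -np.inf)
    pos = cs > 0
    score[pos] = np.log10(cs[pos] / result.n_samples)
    return ConnectivityProfile(
        seed_id=seed_id,
        target_id=target_id,
        cs=cs,
        ns=result.n_samples,
        score=score,
        excluded_vertices=excluded,
        mesh=target_mesh,
    )


def path_distribution_volume(visit_counts: np.ndarray, threshold: int = 100) -> np.ndarray:
    """Threshold the per-voxel visit counts for path-distribution display.

    Voxels visited by fewer than ``threshold`` samples are zeroed; the rest
    keep their counts (NIfTI-compatible volume).
    """
    v = np.asarray(visit_counts)
    out = np.where(v >= threshold, v, 0)
    return out
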