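"""End-to-end orchestration of the synthetic structure-function pipeline.

Stages (each cacheable, all seeded from one master seed):

1. ``psychofit``  — generate rating experiments, fit Stevens exponents.
2. ``regressors`` — build the run's age/gender/task regressors at 24 fps.
3. ``flow``       — synthesize morph-surrogate keyframes, estimate
                    Horn-Schunck flow, reduce to the 1-fps nuisance series.
4. ``glm``        — simulate multi-subject BOLD on the icosphere with
                    planted effect patches; per-subject vertex GLMs;
                    surface smoothing of COPE/VARCOPE maps.
5. ``infer``      — mixed-effects group maps with permutation cluster-mass
                    FWER (Bonferroni across contrasts).
6. ``tract``      — orientation phantoms (connected bundle + disconnected
                    control); probabilistic tracking both directions;
                    per-vertex connectivity profiles.
7. ``sfc``        — patch-level activation maps and the directed
                    activation-connectivity Spearman cross-correlations.

A JSON manifest records the config hash, seeds and stage outputs; re-running
with an unchanged config resumes from cached stage outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .firstlevel import VertexGLM, gamma_hrf, make_design
from .inference import GroupModel, smooth_vertex_map
from .io import save_volume
from .mesh import make_surface_mesh
from .opticflow import build_flow_regressor
from .psychophys import build_run_regressors, fit_gender_exponent, fit_stevens_exponent
from .stimuli import Regressor
from .structfunc import crosscorr_matrix
from .synthdata import (
    DEFAULT_SEED,
    make_bold,
    make_gender_ratings,
    make_morph_frames,
    make_orientation_phantom,
    make_ratings,
    make_run_schedules,
    make_truth_map,
)
from .tractsim import TrackConfig, connectivity_profile, path_distribution_volume, track_samples

__all__ = ["ConfigError", "DependencyError", "PipelineConfig", "run_pipeline", "demo_config"]

STAGES = ["psychofit", "regressors", "flow", "glm", "infer", "tract", "sfc"]

DEFAULTS: dict = {
    "seed": DEFAULT_SEED,
    "stages": {s: True for s in STAGES},
    "fps": 24,
    "tr_s": 2.4,
    "n_morphs": 36,
    "n_subjects": 8,
    "n_raters": 24,
    "n_rating_morphs": 121,
    "highpass_s": 100.0,
    "hrf": {"lag_s": 6.0, "sd_s": 3.0},
    "prewhiten": False,
    "mesh_subdivisions": 2,
    "smoothing_fwhm_mm": 5.0,
    "conn_smoothing_fwhm_mm": 2.0,
    "noise": {"ar": 0.3, "sd": 1.0},
    "effect_amplitude": 6.0,
    "patch_radius_mm": 18.0,
    "n_perm": 200,
    "cluster_forming_p": 0.01,
    "n_samples": 2000,
    "path_threshold": 100,
    "dispersion_deg": 10.0,
    "tube_radius_vox": 1.75,
    "flow_alpha": 1.0,
    "flow_iters": 30,
    "flow_image_px": 32,
    "anticipation_s": 5.0,
}


class ConfigError(ValueError):
    """The pipeline configuration violates the schema."""


class DependencyError(RuntimeError):
    """A stage needs outputs of an upstream stage that has not run."""


class PipelineConfig(dict):
    """Validated pipeline configuration (defaults merged in)."""

    @classmethod
    def from_dict(cls, overrides: dict | None = None) -> "PipelineConfig":
        cfg = copy.deepcopy(DEFAULTS)
        for key, val in (overrides or {}).items():
            if key not in DEFAULTS:
                raise ConfigError(f"unknown config key '{key}'")
            if isinstance(DEFAULTS[key], dict):
                if not isinstance(val, dict):
                    raise ConfigError(f"'{key}' must be a mapping")
                bad = set(val) - set(DEFAULTS[key])
                if bad:
                    raise ConfigError(f"unknown keys under '{key}': {sorted(bad)}")
                cfg[key].update(val)
            else:
                cfg[key] = val
        out = cls(cfg)
        out.validate()
        return out

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def validate(self) -> None:
        c = self
        checks = [
            (c["fps"] > 0, "fps must be positive"),
            (c["tr_s"] > 0, "tr_s must be positive"),
            (c["n_morphs"] >= 2, "need at least 2 morphs"),
            (c["n_subjects"] >= 2, "need at least 2 subjects"),
            (c["n_perm"] >= 100, "n_perm must be >= 100"),
            (0 < c["cluster_forming_p"] < 1, "cluster_forming_p must be in (0,1)"),
            (c["n_samples"] >= 1, "n_samples must be >= 1"),
            (c["smoothing_fwhm_mm"] >= 0, "smoothing_fwhm_mm must be >= 0"),
            (0 <= c["noise"]["ar"] < 1, "AR coefficient must be in [0,1)"),
            (c["noise"]["sd"] >= 0, "noise sd must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        run_s = self.run_seconds
        vols = run_s / c["tr_s"]
        if abs(vols - round(vols)) > 1e-9:
            raise ConfigError(
                f"run of {run_s:g} s is not a whole number of {c['tr_s']:g}-s volumes"
            )

    @property
    def run_seconds(self) -> float:
        return self["n_morphs"] * 7.0  # 6-s morph + 1-s still

    @property
    def n_volumes(self) -> int:
        return int(round(self.run_seconds / self["tr_s"]))

    def sha(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(dict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def demo_config(**overrides) -> PipelineConfig:
    """Reduced-size configuration that completes end-to-end in minutes."""
    return PipelineConfig.from_dict(overrides)


# ---------------------------------------------------------------------------
# manifest / caching helpers
# ---------------------------------------------------------------------------

def _load_manifest(rundir: Path) -> dict:
    path = rundir / "manifest.json"
    if path.exists():
        return json.loads(path.read_text())
    return {}


def _write_manifest(rundir: Path, manifest: dict) -> None:
    (rundir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _stage_cached(manifest: dict, rundir: Path, stage: str, sha: str) -> bool:
    info = manifest.get("stages", {}).get(stage)
    if not info or info.get("config_sha") != sha:
        return False
    return all((rundir / f).exists() for f in info["outputs"])


def _require(manifest: dict, rundir: Path, stage: str, needed: str) -> None:
    info = manifest.get("stages", {}).get(needed)
    if not info or not all((rundir / f).exists() for f in info["outputs"]):
        raise DependencyError(f"stage '{stage}' requires outputs of stage '{needed}'")


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_psychofit(cfg: PipelineConfig, rundir: Path) -> list[str]:
    seed = cfg["seed"]
    age = make_ratings(
        n_morphs=cfg["n_rating_morphs"], n_subjects=cfg["n_raters"], exponent=0.3, seed=seed
    )
    fit_age = fit_stevens_exponent(age, p_grid=np.linspace(0.1, 1.5, 60))
    gender = make_gender_ratings(seed=seed + 1)
    fit_gender = fit_gender_exponent(
        gender["position"].to_numpy(), gender["rating"].to_numpy(), np.linspace(1.0, 5.0, 60)
    )
    age.to_csv(rundir / "age_ratings.csv")
    gender.to_csv(rundir / "gender_ratings.csv", index=False)
    out = {
        "age_exponent": fit_age.exponent,
        "age_scale": fit_age.scale,
        "age_sse": fit_age.sse,
        "gender_exponent": fit_gender.exponent,
        "gender_sse": fit_gender.sse,
    }
    (rundir / "psychofit.json").write_text(json.dumps(out, indent=2, sort_keys=True))
    return ["psychofit.json", "age_ratings.csv", "gender_ratings.csv"]


def _stage_regressors(cfg: PipelineConfig, rundir: Path) -> list[str]:
    fits = json.loads((rundir / "psychofit.json").read_text())
    schedules = make_run_schedules(cfg["n_morphs"], fps=cfg["fps"], seed=cfg["seed"] + 2)
    regs = build_run_regressors(
        schedules,
        p_age=fits["age_exponent"],
        gamma=fits["gender_exponent"],
        anticipation_s=cfg["anticipation_s"],
    )
    files = []
    for name, reg in regs.items():
        fname = f"regressor_{name}.csv"
        reg.to_csv(rundir / fname)
        files.append(fname)
    return files


def _stage_flow(cfg: PipelineConfig, rundir: Path) -> list[str]:
    rng = np.random.default_rng(cfg["seed"] + 3)
    models = ["translate", "expand", "deform"]
    values = []
    px = cfg["flow_image_px"]
    for m in range(cfg["n_morphs"]):
        model = models[m % len(models)]
        frames, _ = make_morph_frames(
            model,
            n_frames=7,  # 1-fps keyframes over the 6-s morph
            size=(px, px),
            seed=int(rng.integers(0, 2**31)),
            speed=float(rng.uniform(0.5, 1.5)),
        )
        reg = build_flow_regressor(
            frames, fps=1.0, fps_bin=1.0, alpha=cfg["flow_alpha"],
            n_iter=cfg["flow_iters"], normalize=False,
        )
        values.extend(reg.values.tolist())
        values.append(0.0)  # the 1-s still
    reg = Regressor("flow", np.asarray(values), fps=1.0).normalize()
    reg.to_csv(rundir / "regressor_flow.csv")
    return ["regressor_flow.csv"]


def _load_regressor(rundir: Path, name: str) -> Regressor:
    return Regressor.from_csv(rundir / f"regressor_{name}.csv", name=name)


def _pick_patch_centers(mesh) -> dict[str, int]:
    d0 = mesh.geodesic_distances(0)[0]
    far = int(np.argmax(d0))
    dfar = mesh.geodesic_distances(far)[0]
    mid = int(np.argmax(np.minimum(d0, dfar)))
    return {"age_a": 0, "age_b": far, "gender": mid}


def _stage_glm(cfg: PipelineConfig, rundir: Path) -> list[str]:
    regs = [_load_regressor(rundir, n) for n in ("age", "gender", "task")]
    regs.append(_load_regressor(rundir, "flow"))
    hrf = gamma_hrf(cfg["hrf"]["lag_s"], cfg["hrf"]["sd_s"], dt_s=1.0 / cfg["fps"])
    rng = np.random.default_rng(cfg["seed"] + 4)
    spikes = sorted(rng.choice(cfg.n_volumes, size=2, replace=False).tolist())
    design = make_design(
        regs, hrf, tr_s=cfg["tr_s"], n_volumes=cfg.n_volumes,
        highpass_s=cfg["highpass_s"], confound_spikes=spikes,
    )
    design.to_tsv(rundir / "design.tsv")

    mesh = make_surface_mesh(cfg["mesh_subdivisions"])
    centers = _pick_patch_centers(mesh)
    amp = cfg["effect_amplitude"]
    truth = {
        "age": make_truth_map(
            mesh, [centers["age_a"], centers["age_b"]], cfg["patch_radius_mm"], amp, profile="flat"
        ),
        "gender": make_truth_map(mesh, [centers["gender"]], cfg["patch_radius_mm"], amp, profile="flat"),
        "task": np.zeros(mesh.n_vertices),
        "flow": np.zeros(mesh.n_vertices),
    }
    betas = np.vstack([truth[r.name] for r in regs])
    files = ["design.tsv"]
    pd.DataFrame(centers, index=[0]).to_csv(rundir / "patch_centers.csv", index=False)
    files.append("patch_centers.csv")

    contrasts = ["age", "gender"]
    copes = {c: [] for c in contrasts}
    varcopes = {c: [] for c in contrasts}
    for s in range(cfg["n_subjects"]):
        bold = make_bold(
            design, betas, noise=(cfg["noise"]["ar"], cfg["noise"]["sd"]),
            spike_frames=tuple(spikes), seed=cfg["seed"] + 100 + s,
        )
        res = VertexGLM(bold.data, design).fit(prewhiten=cfg["prewhiten"])
        for c in contrasts:
            copes[c].append(smooth_vertex_map(res.copes[c], mesh, cfg["smoothing_fwhm_mm"]))
            varcopes[c].append(smooth_vertex_map(res.varcopes[c], mesh, cfg["smoothing_fwhm_mm"]))
    for c in contrasts:
        pd.DataFrame(np.array(copes[c])).to_csv(rundir / f"copes_{c}.csv", index=False)
        pd.DataFrame(np.array(varcopes[c])).to_csv(rundir / f"varcopes_{c}.csv", index=False)
        files += [f"copes_{c}.csv", f"varcopes_{c}.csv"]
    return files


def _stage_infer(cfg: PipelineConfig, rundir: Path) -> list[str]:
    mesh = make_surface_mesh(cfg["mesh_subdivisions"])
    files = []
    contrasts = ["age", "gender"]
    for i, c in enumerate(contrasts):
        copes = pd.read_csv(rundir / f"copes_{c}.csv").to_numpy()
        varcopes = pd.read_csv(rundir / f"varcopes_{c}.csv").to_numpy()
        res = GroupModel(copes, varcopes, mesh).fit(
            n_perm=cfg["n_perm"],
            cluster_forming_p=cfg["cluster_forming_p"],
            n_contrasts=len(contrasts),
            seed=cfg["seed"] + 5 + i,
        )
        res.cluster_table().to_csv(rundir / f"clusters_{c}.csv", index=False)
        res.stat_map().to_csv(rundir / f"neglog10p_{c}.csv")
        files += [f"clusters_{c}.csv", f"neglog10p_{c}.csv"]
    return files


def _track_pair(phantom, cfg: PipelineConfig, reverse: bool, seed: int):
    f = phantom.field
    if not reverse:
        seeds, dirs = phantom.seed_points, phantom.seed_directions
        targets, target_mesh = f.masks["target"], phantom.target_mesh
    else:
        seeds = phantom.target_mesh.vertices - np.array([1.0, 0.0, 0.0])
        dirs = -phantom.seed_directions
        targets, target_mesh = f.masks["seed"], phantom.seed_mesh
    tc = TrackConfig(n_samples=cfg["n_samples"], seed=seed)
    result = track_samples(
        f, seeds, tc, targets=targets, stops=f.masks.get("stop"), init_directions=dirs
    )
    profile = connectivity_profile(
        result, target_mesh, fwhm_mm=cfg["conn_smoothing_fwhm_mm"]
    )
    return result, profile


def _stage_tract(cfg: PipelineConfig, rundir: Path) -> list[str]:
    files = []
    fractions = {}
    for geometry, tag in (("straight_bundle", "bundle"), ("disconnected", "null")):
        phantom = make_orientation_phantom(
            geometry, seed=cfg["seed"] + 6, dispersion_deg=cfg["dispersion_deg"],
            tube_radius_vox=cfg["tube_radius_vox"],
        )
        for reverse, dirtag in ((False, "fwd"), (True, "rev")):
            result, profile = _track_pair(
                phantom, cfg, reverse, seed=cfg["seed"] + 7 + int(reverse)
            )
            name = f"profile_{tag}_{dirtag}.csv"
            profile.to_csv(rundir / name)
            files.append(name)
            fractions[f"{tag}_{dirtag}"] = result.connecting_permille()
            if tag == "bundle" and not reverse:
                vol = path_distribution_volume(result.visit_counts, cfg["path_threshold"])
                save_volume(vol, rundir / "paths_bundle.nii.gz", phantom.field.voxel_size_mm)
                files.append("paths_bundle.nii.gz")
    (rundir / "connect_permille.json").write_text(json.dumps(fractions, indent=2, sort_keys=True))
    files.append("connect_permille.json")
    return files


def _patch_activation(cfg: PipelineConfig, rundir: Path, patch_mesh, seed: int) -> np.ndarray:
    """Group -log10 p on a cortical patch whose effect tracks the bundle core."""
    from .inference import group_stat

    regs = [_load_regressor(rundir, n) for n in ("age", "gender", "task")]
    regs.append(_load_regressor(rundir, "flow"))
    hrf = gamma_hrf(cfg["hrf"]["lag_s"], cfg["hrf"]["sd_s"], dt_s=1.0 / cfg["fps"])
    design = make_design(
        regs, hrf, tr_s=cfg["tr_s"], n_volumes=cfg.n_volumes, highpass_s=cfg["highpass_s"]
    )
    center = patch_mesh.vertices.mean(axis=0)
    d = np.linalg.norm(patch_mesh.vertices - center, axis=1)
    w = np.exp(-(d ** 2) / (2 * 3.0 ** 2))
    truth = np.vstack(
        [cfg["effect_amplitude"] * w]
        + [np.zeros(patch_mesh.n_vertices) for _ in range(len(regs) - 1)]
    )
    copes, varcopes = [], []
    for s in range(cfg["n_subjects"]):
        bold = make_bold(
            design, truth, noise=(cfg["noise"]["ar"], cfg["noise"]["sd"]), seed=seed + s
        )
        res = VertexGLM(bold.data, design).fit()
        copes.append(res.copes["age"])
        varcopes.append(res.varcopes["age"])
    _, neglog = group_stat(np.array(copes), np.array(varcopes))
    return neglog


def _stage_sfc(cfg: PipelineConfig, rundir: Path) -> list[str]:
    from .tractsim import ConnectivityProfile

    profiles = {}
    meshes = {}
    for geometry, tag, names in (
        ("straight_bundle", "bundle", ("A", "B")),
        ("disconnected", "null", ("C", "D")),
    ):
        phantom = make_orientation_phantom(
            geometry, seed=cfg["seed"] + 6, dispersion_deg=cfg["dispersion_deg"],
            tube_radius_vox=cfg["tube_radius_vox"],
        )
        meshes[names[0]] = phantom.seed_mesh
        meshes[names[1]] = phantom.target_mesh
        for reverse, pair in ((False, (names[0], names[1])), (True, (names[1], names[0]))):
            df = pd.read_csv(rundir / f"profile_{tag}_{'rev' if reverse else 'fwd'}.csv")
            cs = df["cs"].to_numpy()
            target_mesh = meshes[pair[1]]
            excluded = np.flatnonzero(cs <= 0)
            profiles[pair] = ConnectivityProfile(
                seed_id=pair[0], target_id=pair[1], cs=cs, ns=cfg["n_samples"],
                score=df["score"].to_numpy(), excluded_vertices=excluded, mesh=target_mesh,
            )
    activations = {
        name: _patch_activation(cfg, rundir, mesh, seed=cfg["seed"] + 200 + 50 * i)
        for i, (name, mesh) in enumerate(sorted(meshes.items()))
    }
    table = crosscorr_matrix(activations, profiles)
    table.to_csv(rundir / "crosscorr.csv", index=False)
    return ["crosscorr.csv"]


_STAGE_FUNCS = {
    "psychofit": (_stage_psychofit, []),
    "regressors": (_stage_regressors, ["psychofit"]),
    "flow": (_stage_flow, []),
    "glm": (_stage_glm, ["regressors", "flow"]),
    "infer": (_stage_infer, ["glm"]),
    "tract": (_stage_tract, []),
    "sfc": (_stage_sfc, ["regressors", "flow", "tract"]),
}


def run_pipeline(config: PipelineConfig | dict | None = None, out_dir="run") -> Path:
    """Run all enabled stages into ``out_dir``; returns the run directory.

    Deterministic given the config's seeds.  A stage whose outputs already
    exist under an identical config hash is skipped; a stage whose upstream
    dependency is neither enabled nor cached raises :class:`DependencyError`.
    """
    if config is None:
        config = PipelineConfig.from_dict()
    elif not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(config)
    rundir = Path(out_dir)
    rundir.mkdir(parents=True, exist_ok=True)
    sha = config.sha()
    manifest = _load_manifest(rundir)
    if manifest.get("config_sha") not in (None, sha):
        manifest = {}
    manifest.setdefault("stages", {})
    manifest["config_sha"] = sha
    manifest["config"] = dict(config)
    manifest["seed"] = config["seed"]
    manifest["version"] = __version__

    for stage in STAGES:
        func, deps = _STAGE_FUNCS[stage]
        if not config["stages"].get(stage, False):
            continue
        for dep in deps:
            _require(manifest, rundir, stage, dep)
        if _stage_cached(manifest, rundir, stage, sha):
            continue
        outputs = func(config, rundir)
        manifest["stages"][stage] = {"config_sha": sha, "outputs": outputs}
        _write_manifest(rundir, manifest)
    _write_manifest(rundir, manifest)
    return rundir
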