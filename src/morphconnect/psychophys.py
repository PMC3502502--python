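"""Stevens power-law psychophysics: exponent fitting and stimulus regressors.

Perceived magnitude grows as a power of stimulus intensity.  Facial-age
difference ratings are modelled as ``k * |a_target^p - a_start^p|`` (age
exponent ~0.3: early-life aging carries far more visible change per year),
and perceived gender along a morph continuum follows a symmetric S-curve
whose per-half power exponent (~3) pulls perception above the linear
transition — observers categorise gender early.  Stimulus regressors are the
unsigned first derivatives of these perceived trajectories, frame-binned and
scaled to a relative maximum of 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .stimuli import AGE_MAX, AGE_MIN, MorphSchedule, RatingDataset, Regressor

__all__ = [
    "PsychophysFit",
    "fit_stevens_exponent",
    "perceived_gender_level",
    "fit_gender_exponent",
    "build_age_regressor",
    "build_gender_regressor",
    "build_task_regressor",
    "build_run_regressors",
    "trichotomize_raters",
]


@dataclass(frozen=True)
class PsychophysFit:
    """Result of a power-law fit: exponent, scale, residual SSE, n records."""

    exponent: float
    scale: float
    sse: float
    n: int

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ValueError("fitted exponent must be positive")
        if self.sse < 0:
            raise ValueError("sse must be nonnegative")


def _age_sse(p: float, start: np.ndarray, target: np.ndarray, rating: np.ndarray) -> tuple[float, float]:
    """SSE of the Stevens age model at exponent ``p``; scale solved in closed form."""
    x = np.abs(target ** p - start ** p)
    sxx = float(x @ x)
    if sxx == 0.0:
        return float(rating @ rating), 0.0
    k = float(x @ rating) / sxx
    resid = rating - k * x
    return float(resid @ resid), k


def fit_stevens_exponent(
    ratings: RatingDataset,
    p_grid: np.ndarray | None = None,
    refine: bool = True,
) -> PsychophysFit:
    """Least-squares fit of the Stevens age-difference exponent.

    Minimises ``sum (rating - k*|a_t^p - a_s^p|)^2`` over ``p`` in ``p_grid``,
    with the scale ``k`` solved in closed form per candidate, then refines the
    best grid point by bounded scalar minimisation between its neighbours.

    Parameters
    ----------
    ratings : RatingDataset
        At least 10 records with nonnegative ratings, not all zero.
    p_grid : array, optional
        Candidate exponents (default: 120 points on [0.05, 2.0]).
    """
    if len(ratings) < 10:
        raise ValueError("need at least 10 rating records")
    rec = ratings.records
    rating = rec["rating"].to_numpy(float)
    if not np.any(rating > 0):
        raise ValueError("degenerate fit: all ratings are zero")
    start = rec["start_age"].to_numpy(float)
    target = rec["target_age"].to_numpy(float)

    if p_grid is None:
        p_grid = np.linspace(0.05, 2.0, 120)
    p_grid = np.asarray(p_grid, float)
    if p_grid.min() <= 0:
        raise ValueError("exponent candidates must be positive")

    sses = np.array([_age_sse(p, start, target, rating)[0] for p in p_grid])
    i = int(np.argmin(sses))
    p_best = float(p_grid[i])
    if refine and p_grid.size > 1:
        lo = float(p_grid[max(i - 1, 0)])
        hi = float(p_grid[min(i + 1, p_grid.size - 1)])
        if lo < hi:
            res = minimize_scalar(
                lambda p: _age_sse(p, start, target, rating)[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-9},
            )
            p_best = float(res.x)
    sse, k = _age_sse(p_best, start, target, rating)
    return PsychophysFit(exponent=p_best, scale=k, sse=sse, n=rating.size)


def perceived_gender_level(position: np.ndarray | float, gamma: float = 3.0) -> np.ndarray:
    """Perceived gender level along the morph continuum.

    ``position`` is the physical morph coordinate in [0, 1] (0.5 = peak
    androgyny).  With ``u = 2*position - 1`` the perceived level is
    ``0.5 * (1 + sign(u) * |u|^(1/gamma))`` — a symmetric S-curve above the
    diagonal for gamma > 1, reflecting apperceptive gender categorisation.
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    u = 2.0 * np.asarray(position, dtype=float) - 1.0
    return 0.5 * (1.0 + np.sign(u) * np.abs(u) ** (1.0 / gamma))


def fit_gender_exponent(
    positions: np.ndarray,
    ratings: np.ndarray,
    gamma_grid: np.ndarray | None = None,
    refine: bool = True,
) -> PsychophysFit:
    """Fit the per-half power exponent of the perceived-gender S-curve.

    ``positions`` are morph coordinates in [0, 1]; ``ratings`` are perceived
    gender levels on a scale with maximum 1.  Grid search over ``gamma_grid``
    (default 80 points on [1, 5]) with bounded local refinement.
    """
    positions = np.asarray(positions, float)
    ratings = np.asarray(ratings, float)
    if positions.shape != ratings.shape:
        raise ValueError("positions and ratings must align")
    if positions.size < 10:
        raise ValueError("need at least 10 gender ratings")

    if gamma_grid is None:
        gamma_grid = np.linspace(1.0, 5.0, 80)
    gamma_grid = np.asarray(gamma_grid, float)

    def sse(g: float) -> float:
        resid = ratings - perceived_gender_level(positions, g)
        return float(resid @ resid)

    sses = np.array([sse(g) for g in gamma_grid])
    i = int(np.argmin(sses))
    g_best = float(gamma_grid[i])
    if refine and gamma_grid.size > 1:
        lo = float(gamma_grid[max(i - 1, 0)])
        hi = float(gamma_grid[min(i + 1, gamma_grid.size - 1)])
        if lo < hi:
            res = minimize_scalar(sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-9})
            g_best = float(res.x)
    return PsychophysFit(exponent=g_best, scale=1.0, sse=sse(g_best), n=positions.size)


# ---------------------------------------------------------------------------
# regressor construction
# ---------------------------------------------------------------------------

def _frame_pair_times(schedule: MorphSchedule) -> tuple[np.ndarray, np.ndarray]:
    t = schedule.frame_times()
    return t, t + 1.0 / schedule.fps


def build_age_regressor(schedule: MorphSchedule, p: float = 0.3, normalize: bool = True) -> Regressor:
    """Unsigned first derivative of Stevens-transformed facial age.

    Frame ``i`` carries ``|a(t_{i+1})^p - a(t_i)^p|``; the trailing still
    contributes zero.  For p < 1 this up-weights early morph periods and
    younger absolute ages.
    """
    if p <= 0:
        raise ValueError("exponent must be positive")
    t0, t1 = _frame_pair_times(schedule)
    a0 = schedule.age_at(np.minimum(t0, schedule.duration_s))
    a1 = schedule.age_at(np.minimum(t1, schedule.duration_s))
    vals = np.abs(a1 ** p - a0 ** p)
    vals[t0 >= schedule.duration_s] = 0.0
    reg = Regressor("age", vals, fps=schedule.fps)
    return reg.normalize() if normalize else reg


def build_gender_regressor(schedule: MorphSchedule, gamma: float = 3.0, normalize: bool = True) -> Regressor:
    """Unsigned first derivative of the perceived gender level.

    Peak androgyny mid-morph is the effective stimulus: the discrete
    derivative of the S-curve peaks at the central frame pair.  Morphs
    without a gender transition yield an all-zero regressor.
    """
    t0, t1 = _frame_pair_times(schedule)
    if not schedule.has_gender_transition:
        reg = Regressor("gender", np.zeros(schedule.n_frames), fps=schedule.fps, normalized=False)
        return reg.normalize() if normalize else reg
    p0 = perceived_gender_level(schedule.morph_position(t0), gamma)
    p1 = perceived_gender_level(schedule.morph_position(np.minimum(t1, schedule.duration_s)), gamma)
    vals = np.abs(p1 - p0)
    vals[t0 >= schedule.duration_s] = 0.0
    reg = Regressor("gender", vals, fps=schedule.fps)
    return reg.normalize() if normalize else reg


def build_task_regressor(schedule: MorphSchedule, anticipation_s: float = 5.0) -> Regressor:
    """Unit impulse at the anticipated key press (nuisance-only)."""
    vals = np.zeros(schedule.n_frames)
    idx = int(round(anticipation_s * schedule.fps))
    vals[min(idx, schedule.n_frames - 1)] = 1.0
    return Regressor("task", vals, fps=schedule.fps, normalized=True)


def build_run_regressors(
    schedules: Sequence[MorphSchedule],
    p_age: float = 0.3,
    gamma: float = 3.0,
    anticipation_s: float = 5.0,
) -> dict[str, Regressor]:
    """Concatenate per-morph regressors over a run and max-normalise each.

    Normalisation is applied once across the whole run, so relative stimulus
    strength between morphs is preserved.
    """
    parts: dict[str, list[np.ndarray]] = {"age": [], "gender": [], "task": []}
    fps = schedules[0].fps
    for s in schedules:
        if s.fps != fps:
            raise ValueError("all schedules in a run must share one frame rate")
        parts["age"].append(build_age_regressor(s, p_age, normalize=False).values)
        parts["gender"].append(build_gender_regressor(s, gamma, normalize=False).values)
        parts["task"].append(build_task_regressor(s, anticipation_s).values)
    return {
        name: Regressor(name, np.concatenate(chunks), fps=fps).normalize()
        for name, chunks in parts.items()
    }


def trichotomize_raters(
    per_subject_mean_errors: Mapping[object, float] | Sequence[float] | Iterable[tuple[object, float]],
) -> dict[str, list]:
    """Split raters into high/average/low accuracy by quintile cutoffs.

    The lowest-error quintile (``ceil(n/5)`` subjects) is the high-accuracy
    group, the highest-error quintile the low-accuracy group, the remainder
    average.  Ties spanning a cutoff are resolved by a stable sort on subject
    id.
    """
    if isinstance(per_subject_mean_errors, Mapping):
        items = list(per_subject_mean_errors.items())
    else:
        seq = list(per_subject_mean_errors)
        if seq and isinstance(seq[0], tuple) and len(seq[0]) == 2:
            items = seq
        else:
            items = list(enumerate(seq))
    n = len(items)
    if n < 5:
        raise ValueError("need at least 5 subjects to trichotomize")
    ids = [sid for sid, _ in items]
    errors = np.array([float(e) for _, e in items])
    order = np.lexsort((np.argsort(np.argsort([str(s) for s in ids], kind="stable")), errors))
    q = int(np.ceil(n / 5))
    high = [ids[i] for i in order[:q]]
    low = [ids[i] for i in order[n - q:]]
    average = [ids[i] for i in order[q: n - q]]
    return {"high": high, "average": average, "low": low}
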