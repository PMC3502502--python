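"""Vertex-wise spatial cross-correlation of activation and connectivity.

The central question: does the spatial profile of a structural connection
between two cortical regions predict the activation profile at its endpoint?
Activation likelihood (|log10 p| from the group analysis — higher means more
likely active) is rank-correlated with the log-transformed connectivity
score log10(cs/ns) across the vertices of a cluster, using Spearman's rho;
p-values come from the t approximation (or exact permutation at small n)
and are Bonferroni-corrected for the number of tests performed.  Directed
seed->target results are first-class: the profile seeded in A and evaluated
on B is correlated with B's activation, and vice versa.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import VertexStatMap
from .tractsim import ConnectivityProfile

__all__ = [
    "InsufficientDataError",
    "UndefinedCorrelationError",
    "CrossCorrResult",
    "SpatialCorrelation",
    "spatial_crosscorr",
    "binned_profile",
    "crosscorr_matrix",
]


class InsufficientDataError(ValueError):
    """Fewer than 3 common vertices: no correlation can be computed."""


class UndefinedCorrelationError(ValueError):
    """One of the series is constant, so ranks carry no information."""


@dataclass
class CrossCorrResult:
    """Spearman rho between activation and connectivity on one vertex set."""

    seed: str
    target: str
    rho: float
    p_raw: float
    p_bonferroni: float
    n_vertices: int
    n_tests: int
    method: str = "t"
    binned: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.rho) and not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho must lie in [-1, 1]")
        if self.n_vertices < 3:
            raise ValueError("need at least 3 vertices")

    def significant(self, alpha: float = 0.05, positive_only: bool = True) -> bool:
        if not np.isfinite(self.rho):
            return False
        ok = self.p_bonferroni < alpha
        return bool(ok and (self.rho > 0 if positive_only else True))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "seed": self.seed,
                    "target": self.target,
                    "rho": self.rho,
                    "p_raw": self.p_raw,
                    "p_bonferroni": self.p_bonferroni,
                    "n_vertices": self.n_vertices,
                    "n_tests": self.n_tests,
                    "method": self.method,
                }
            ]
        )


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks on ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise UndefinedCorrelationError("constant series: Spearman rho undefined")
    return float(rx @ ry) / denom


def _p_t_approx(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _p_permutation(x: np.ndarray, y: np.ndarray, rho_obs: float, rng: np.random.Generator | None) -> float:
    n = x.size
    if n <= 8:  # full enumeration is cheap
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_spearman_rho(x[list(perm)], y)) >= abs(rho_obs) - 1e-12:
                count += 1
        return count / total
    rng = rng or np.random.default_rng(0)
    n_perm = 10_000
    count = 1
    for _ in range(n_perm):
        if abs(_spearman_rho(x[rng.permutation(n)], y)) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / (n_perm + 1)


def _extract_pair(activation, connectivity) -> tuple[np.ndarray, np.ndarray]:
    """Align activation and connectivity values on the common vertex set."""
    act = activation.values if isinstance(activation, VertexStatMap) else np.asarray(activation, float)
    if isinstance(connectivity, ConnectivityProfile):
        keep = connectivity.included_vertices
        if act.size != connectivity.cs.size:
            raise ValueError("activation map and connectivity profile must share a vertex set")
        return act[keep], connectivity.score[keep]
    conn = np.asarray(connectivity, float)
    if act.size != conn.size:
        raise ValueError("activation and connectivity must align")
    keep = np.isfinite(act) & np.isfinite(conn)
    return act[keep], conn[keep]


def spatial_crosscorr(
    activation: VertexStatMap | np.ndarray,
    connectivity: ConnectivityProfile | np.ndarray,
    n_tests: int = 1,
    method: str = "auto",
    seed: str = "seed",
    target: str = "target",
    n_bins: int | None = None,
    rng: np.random.Generator | None = None,
) -> CrossCorrResult:
    """Spearman correlation between |log10 p| activation and log10(cs/ns).

    Vertices excluded by the connectivity profile (cs = 0 after smoothing)
    are removed from both series.  ``method``: ``"t"`` (t approximation),
    ``"permutation"``, or ``"auto"`` (exact permutation when n <= 10).
    """
    act, conn = _extract_pair(activation, connectivity)
    n = act.size
    if n < 3:
        raise InsufficientDataError(f"only {n} common vertices (need >= 3)")
    rho = _spearman_rho(act, conn)
    if method == "auto":
        method = "permutation" if n <= 10 else "t"
    if method == "t":
        p_raw = _p_t_approx(rho, n)
    elif method == "permutation":
        p_raw = _p_permutation(conn, act, rho, rng)
    else:
        raise ValueError(f"unknown method '{method}'")
    binned = binned_profile(act, conn, n_bins) if n_bins else None
    return CrossCorrResult(
        seed=seed,
        target=target,
        rho=rho,
        p_raw=p_raw,
        p_bonferroni=min(p_raw * n_tests, 1.0),
        n_vertices=n,
        n_tests=n_tests,
        method=method,
        binned=binned,
    )


class SpatialCorrelation:
    """Model object pairing an activation map with a connectivity profile."""

    def __init__(
        self,
        activation: VertexStatMap | np.ndarray,
        connectivity: ConnectivityProfile | np.ndarray,
        n_tests: int = 1,
        seed: str = "seed",
        target: str = "target",
    ):
        self.activation = activation
        self.connectivity = connectivity
        self.n_tests = n_tests
        self.seed = seed
        self.target = target

    def fit(self, method: str = "auto", n_bins: int | None = 10) -> CrossCorrResult:
        return spatial_crosscorr(
            self.activation,
            self.connectivity,
            n_tests=self.n_tests,
            method=method,
            seed=self.seed,
            target=self.target,
            n_bins=n_bins,
        )


def binned_profile(
    activation: np.ndarray | VertexStatMap,
    connectivity: np.ndarray | ConnectivityProfile,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Equal-count bins over the connectivity score: mean +- SEM activation.

    Display companion to the vertex-wise correlation (the rho itself is
    always computed on raw vertices).
    """
    act, conn = _extract_pair(activation, connectivity)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    n = act.size
    order = np.argsort(conn, kind="stable")
    edges = np.array_split(order, min(n_bins, n))
    rows = []
    for b, idx in enumerate(edges):
        vals = act[idx]
        rows.append(
            {
                "bin": b,
                "n": idx.size,
                "score_mean": float(conn[idx].mean()),
                "activation_mean": float(vals.mean()),
                "activation_sem": float(vals.std(ddof=1) / np.sqrt(idx.size)) if idx.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def crosscorr_matrix(
    activations: dict[str, VertexStatMap | np.ndarray],
    profiles: dict[tuple[str, str], ConnectivityProfile],
    method: str = "auto",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All directed seed->target correlations, Bonferroni over all tests.

    The profile seeded in A and evaluated on B's surface is correlated with
    B's activation map; with k clusters and all profiles available this
    yields k*(k-1) directed results.  Pairs with too few usable vertices or
    a constant series are reported with NaN rho and counted as
    non-significant (they still enter the Bonferroni divisor since the test
    was attempted).
    """
    n_tests = len(profiles)
    rows = []
    for (seed, target), profile in profiles.items():
        if target not in activations:
            raise KeyError(f"no activation map for target cluster '{target}'")
        try:
            res = spatial_crosscorr(
                activations[target], profile, n_tests=n_tests, method=method, seed=seed, target=target
            )
            rows.append(
                {
                    "seed": seed,
                    "target": target,
                    "rho": res.rho,
                    "p_raw": res.p_raw,
                    "p_bonferroni": res.p_bonferroni,
                    "n_vertices": res.n_vertices,
                    "significant": res.significant(alpha),
                }
            )
        except (InsufficientDataError, UndefinedCorrelationError):
            rows.append(
                {
                    "seed": seed,
                    "target": target,
                    "rho": np.nan,
                    "p_raw": np.nan,
                    "p_bonferroni": np.nan,
                    "n_vertices": int(profile.included_vertices.size),
                    "significant": False,
                }
            )
    return pd.DataFrame(rows, columns=["seed", "target", "rho", "p_raw", "p_bonferroni", "n_vertices", "significant"])
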