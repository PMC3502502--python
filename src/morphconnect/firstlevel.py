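"""First-level BOLD analysis: HRF convolution, design matrices, vertex GLMs.

Stimulus functions binned at the video frame rate are convolved with a gamma
hemodynamic response function, downsampled to the TR grid, and augmented
with temporal derivatives, spike confounds and an intercept.  The
:class:`VertexGLM` model fits ordinary least squares per vertex (optionally
after AR(1) prewhitening) and produces contrast-of-parameter estimates
(COPEs) with their variances (VARCOPEs), convertible to percent-BOLD signal
change via the peak-to-peak height of the effective regressor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

__all__ = [
    "HRFKernel",
    "gamma_hrf",
    "dct_highpass_basis",
    "highpass_filter",
    "DesignMatrix",
    "make_design",
    "VertexGLM",
    "VertexGLMResults",
    "cope_to_percent_bold",
    "normalize_response_magnitudes",
]


@dataclass(frozen=True)
class HRFKernel:
    """Gamma HRF sampled at ``dt_s``; nonnegative, unit sum."""

    values: np.ndarray
    dt_s: float
    lag_s: float
    sd_s: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if np.any(v < 0):
            raise ValueError("HRF values must be nonnegative")
        if not np.isclose(v.sum(), 1.0):
            raise ValueError("HRF must be normalised to unit sum")
        object.__setattr__(self, "values", v)

    def mode_s(self) -> float:
        """Peak latency of the underlying gamma density (seconds)."""
        shape = (self.lag_s / self.sd_s) ** 2
        scale = self.sd_s ** 2 / self.lag_s
        return max(shape - 1.0, 0.0) * scale


def gamma_hrf(lag_s: float = 6.0, sd_s: float = 3.0, dt_s: float = 1.0 / 24.0, truncate_s: float = 32.0) -> HRFKernel:
    """Gamma HRF parameterised by mean lag and SD.

    Shape ``(lag/sd)^2`` and scale ``sd^2/lag`` give a gamma density with the
    requested mean and standard deviation; it is sampled at ``dt_s``,
    truncated at ``truncate_s`` and renormalised to unit sum so convolution
    preserves regressor scale.
    """
    if lag_s <= 0 or sd_s <= 0 or dt_s <= 0:
        raise ValueError("lag, sd and dt must be positive")
    shape = (lag_s / sd_s) ** 2
    scale = sd_s ** 2 / lag_s
    t = np.arange(0.0, truncate_s, dt_s)
    vals = gamma_dist.pdf(t, a=shape, scale=scale)
    vals = vals / vals.sum()
    return HRFKernel(values=vals, dt_s=dt_s, lag_s=lag_s, sd_s=sd_s)


def dct_highpass_basis(n: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """DCT basis of drift terms with periods longer than ``cutoff_s``.

    Returns an ``(n, K)`` orthonormal matrix (DC excluded); empty when the
    run is shorter than half the cutoff period.
    """
    duration = n * tr_s
    k_max = int(np.floor(2.0 * duration / cutoff_s))
    t = np.arange(n)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n)) for k in range(1, k_max + 1)]
    if not cols:
        return np.zeros((n, 0))
    basis = np.column_stack(cols)
    basis /= np.linalg.norm(basis, axis=0, keepdims=True)
    return basis


def highpass_filter(data: np.ndarray, tr_s: float, cutoff_s: float = 100.0) -> np.ndarray:
    """Remove slow drifts by projecting out the DCT basis below cutoff."""
    data = np.asarray(data, float)
    basis = dct_highpass_basis(data.shape[0], tr_s, cutoff_s)
    if basis.shape[1] == 0:
        return data.copy()
    return data - basis @ (basis.T @ data)


@dataclass
class DesignMatrix:
    """TR-sampled design with named columns.

    ``task_columns`` are the HRF-convolved stimulus functions (contrasts are
    formed on these), ``derivative_columns`` their temporal derivatives,
    ``confound_columns`` spike indicators plus the intercept.
    """

    frame: pd.DataFrame
    tr_s: float
    task_columns: list[str]
    derivative_columns: list[str] = field(default_factory=list)
    confound_columns: list[str] = field(default_factory=list)
    highpass_s: float | None = None

    def __post_init__(self) -> None:
        names = list(self.frame.columns)
        if len(set(names)) != len(names):
            raise ValueError("design column names must be unique")
        for c in self.task_columns:
            if not np.any(self.frame[c].to_numpy() != 0):
                raise ValueError(f"task column '{c}' is all zero")

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(float)

    @property
    def n_volumes(self) -> int:
        return len(self.frame)

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(float)

    def contrast_vector(self, name: str) -> np.ndarray:
        """Unit contrast selecting one task column (derivatives excluded)."""
        c = np.zeros(self.frame.shape[1])
        c[list(self.frame.columns).index(name)] = 1.0
        return c

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def make_design(
    regressors,
    hrf: HRFKernel,
    tr_s: float = 2.4,
    n_volumes: int = 350,
    highpass_s: float | None = 100.0,
    confound_spikes: list[int] | None = None,
    add_derivatives: bool = True,
) -> DesignMatrix:
    """Build the TR-grid design from frame-rate regressors.

    Each regressor is convolved with the HRF at its native frame rate,
    sampled at volume onsets, and (optionally) paired with its first
    temporal derivative.  High-pass filtering (DCT projection at
    ``highpass_s``) applies to task and derivative columns, not to spike
    confounds or the intercept.
    """
    if hasattr(regressors, "items"):
        regressors = list(regressors.values())
    duration = n_volumes * tr_s
    cols: dict[str, np.ndarray] = {}
    task_names: list[str] = []
    deriv_names: list[str] = []
    for reg in regressors:
        expected = int(round(duration * reg.fps))
        if reg.n_frames != expected:
            raise ValueError(
                f"regressor '{reg.name}' covers {reg.n_frames} frames; run of "
                f"{duration:g} s at {reg.fps:g} fps needs {expected}"
            )
        if not np.isclose(hrf.dt_s * reg.fps, 1.0):
            kernel = gamma_hrf(hrf.lag_s, hrf.sd_s, dt_s=1.0 / reg.fps)
        else:
            kernel = hrf
        fine = np.convolve(reg.values, kernel.values)[: reg.n_frames]
        idx = np.minimum((np.arange(n_volumes) * tr_s * reg.fps).round().astype(int), reg.n_frames - 1)
        col = fine[idx]
        cols[reg.name] = col
        task_names.append(reg.name)
        if add_derivatives:
            cols[f"{reg.name}_deriv"] = np.gradient(col, tr_s)
            deriv_names.append(f"{reg.name}_deriv")

    if highpass_s is not None:
        model = np.column_stack([cols[c] for c in task_names + deriv_names])
        filtered = highpass_filter(model, tr_s, highpass_s)
        for j, c in enumerate(task_names + deriv_names):
            cols[c] = filtered[:, j]

    confound_names: list[str] = []
    for f in sorted(set(confound_spikes or [])):
        if not 0 <= f < n_volumes:
            raise ValueError(f"spike frame {f} outside run")
        spike = np.zeros(n_volumes)
        spike[f] = 1.0
        cols[f"spike_{f}"] = spike
        confound_names.append(f"spike_{f}")
    cols["intercept"] = np.ones(n_volumes)
    confound_names.append("intercept")

    return DesignMatrix(
        frame=pd.DataFrame(cols),
        tr_s=tr_s,
        task_columns=task_names,
        derivative_columns=deriv_names,
        confound_columns=confound_names,
        highpass_s=highpass_s,
    )


def _name_collinear(X: np.ndarray, names: list[str]) -> list[str]:
    kept: list[int] = []
    flagged: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(j)
        else:
            flagged.append(names[j])
    return flagged


class VertexGLM:
    """Mass-univariate GLM: one ordinary-least-squares fit per vertex.

    Parameters
    ----------
    endog : (T, V) array
        BOLD series per vertex (a.u.).
    design : DesignMatrix
        Shared design; rows must match ``endog``.
    """

    def __init__(self, endog: np.ndarray, design: DesignMatrix):
        endog = np.asarray(endog, float)
        if endog.ndim == 1:
            endog = endog[:, None]
        if endog.shape[0] != design.n_volumes:
            raise ValueError("endog rows must match design rows")
        X = design.matrix
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            bad = _name_collinear(X, list(design.frame.columns))
            raise ValueError(f"design is rank deficient; collinear columns: {bad}")
        self.endog = endog
        self.design = design

    def fit(
        self,
        contrasts: dict[str, np.ndarray] | None = None,
        prewhiten: bool = False,
    ) -> "VertexGLMResults":
        """Fit OLS per vertex; with ``prewhiten`` an AR(1) two-pass fit.

        Prewhitening estimates the lag-1 residual autocorrelation per vertex
        from a first OLS pass, transforms data and design, and refits.
        """
        X = self.design.matrix
        Y = self.endog
        if contrasts is None:
            contrasts = {
                name: self.design.contrast_vector(name) for name in self.design.task_columns
            }
        if prewhiten:
            beta0 = np.linalg.lstsq(X, Y, rcond=None)[0]
            resid0 = Y - X @ beta0
            num = np.sum(resid0[1:] * resid0[:-1], axis=0)
            den = np.sum(resid0 ** 2, axis=0)
            rho = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
            rho = np.clip(rho, -0.95, 0.95)
            V = Y.shape[1]
            params = np.empty((X.shape[1], V))
            copes = {k: np.empty(V) for k in contrasts}
            varcopes = {k: np.empty(V) for k in contrasts}
            resid = np.empty_like(Y)
            dof = Y.shape[0] - 1 - X.shape[1]
            for v in range(V):
                r = rho[v]
                Xw = X[1:] - r * X[:-1]
                yw = Y[1:, v] - r * Y[:-1, v]
                b, cov, rs = _ols_cov(Xw, yw[:, None])
                params[:, v] = b[:, 0]
                sigma2 = rs[0] / max(dof, 1)
                for k, c in contrasts.items():
                    copes[k][v] = c @ b[:, 0]
                    varcopes[k][v] = sigma2 * (c @ cov @ c)
                resid[:, v] = Y[:, v] - X @ b[:, 0]
            ar1 = rho
        else:
            b, cov, rs = _ols_cov(X, Y)
            params = b
            dof = Y.shape[0] - X.shape[1]
            sigma2 = rs / max(dof, 1)
            copes = {}
            varcopes = {}
            for k, c in contrasts.items():
                copes[k] = c @ b
                varcopes[k] = sigma2 * (c @ cov @ c)
            resid = Y - X @ b
            ar1 = np.zeros(Y.shape[1])
        return VertexGLMResults(
            model=self,
            params=params,
            copes=copes,
            varcopes=varcopes,
            dof=int(dof),
            resid=resid,
            ar1=ar1,
        )


def _ols_cov(X: np.ndarray, Y: np.ndarray):
    """OLS estimates, (X'X)^-1 and residual sums of squares."""
    xtx_inv = np.linalg.pinv(X.T @ X)
    b = xtx_inv @ X.T @ Y
    resid = Y - X @ b
    return b, xtx_inv, np.sum(resid ** 2, axis=0)


@dataclass
class VertexGLMResults:
    """Per-vertex betas and per-contrast COPE/VARCOPE/t maps."""

    model: VertexGLM
    params: np.ndarray
    copes: dict[str, np.ndarray]
    varcopes: dict[str, np.ndarray]
    dof: int
    resid: np.ndarray
    ar1: np.ndarray

    def tstat(self, contrast: str) -> np.ndarray:
        cope = self.copes[contrast]
        varcope = self.varcopes[contrast]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(varcope > 0, cope / np.sqrt(np.maximum(varcope, 1e-300)), 0.0)
            t = np.where((varcope <= 0) & (cope != 0), np.sign(cope) * np.inf, t)
        return t

    def summary(self, contrast: str | None = None) -> pd.DataFrame:
        """Per-contrast table of mean COPE, mean VARCOPE and peak |t|."""
        rows = []
        keys = [contrast] if contrast else list(self.copes)
        for k in keys:
            t = self.tstat(k)
            finite = t[np.isfinite(t)]
            rows.append(
                {
                    "contrast": k,
                    "mean_cope": float(np.mean(self.copes[k])),
                    "mean_varcope": float(np.mean(self.varcopes[k])),
                    "peak_abs_t": float(np.max(np.abs(finite))) if finite.size else np.inf,
                    "dof": self.dof,
                }
            )
        return pd.DataFrame(rows)


def cope_to_percent_bold(
    cope: np.ndarray | float,
    effective_regressor: np.ndarray,
    y_mean_over_time: np.ndarray | float,
) -> np.ndarray | float:
    """Scale a COPE to mean percent BOLD signal change.

    ``100 * cope * peak_to_peak(effective convolved regressor) / mean(Y)``.
    """
    ptp = float(np.ptp(np.asarray(effective_regressor, float)))
    return 100.0 * np.asarray(cope, float) * ptp / np.asarray(y_mean_over_time, float)


def normalize_response_magnitudes(cluster_means) -> np.ndarray | dict:
    """Divide cluster-mean responses by the within-condition minimum.

    Accepts a 1-D array of means for one condition, or a mapping
    condition -> means; the minimum of each condition maps to 1.0.
    """
    if hasattr(cluster_means, "items"):
        return {k: normalize_response_magnitudes(v) for k, v in cluster_means.items()}
    arr = np.asarray(cluster_means, float)
    m = arr.min()
    if m <= 0:
        raise ValueError("cluster means must be positive to normalise")
    return arr / m
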