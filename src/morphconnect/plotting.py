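"""Display helpers: coupling profiles, flow fields, cluster stat maps."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_binned_profile", "plot_flow_field", "plot_regressor"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_binned_profile(result, ax=None):
    """Mean +- SEM activation per connectivity-score bin for one pair."""
    if result.binned is None:
        raise ValueError("result carries no binned profile (fit with n_bins set)")
    ax = _get_ax(ax)
    b = result.binned
    ax.errorbar(b["score_mean"], b["activation_mean"], yerr=b["activation_sem"],
                fmt="o-", capsize=3)
    ax.set_xlabel("connectivity score log10(cs/ns)")
    ax.set_ylabel("activation |log10 p|")
    ax.set_title(f"{result.seed} -> {result.target}: rho = {result.rho:.2f}")
    return ax


def plot_flow_field(field, step: int = 4, ax=None):
    """Quiver display of a dense optical-flow field."""
    ax = _get_ax(ax)
    h, w = field.shape
    yy, xx = np.mgrid[0:h:step, 0:w:step]
    ax.quiver(xx, yy, field.u[::step, ::step], -field.v[::step, ::step],
              angles="xy", scale_units="xy")
    ax.set_aspect("equal")
    ax.invert_yaxis()
    return ax


def plot_regressor(regressor, ax=None):
    """Time course of a stimulus regressor."""
    ax = _get_ax(ax)
    ax.plot(regressor.times(), regressor.values, lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"{regressor.name} (a.u.)")
    return ax
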