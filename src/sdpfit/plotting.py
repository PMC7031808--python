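"""Plot helpers: fitted curves and volume-probability profiles.

matplotlib is imported lazily so the fitting stack stays usable without it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_fit", "plot_profiles"]


def plot_fit(result, path=None):
    """Data and fitted model curves for every contrast of an ensemble fit.

    ``result`` is an :class:`~sdpfit.fitting.EnsembleFitResult` attached to
    its :class:`~sdpfit.fitting.JointSDPModel`.  Returns the figure; saves
    to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    model = result.model
    if model is None:
        raise ValueError("result is not attached to a JointSDPModel")
    params = result.param_dict()
    n = len(model.datasets)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.0), squeeze=False)
    for ax, ds in zip(axes[0], model.datasets):
        dsw = ds.windowed()
        q, I_model = model.predict(params, ds)
        ax.errorbar(dsw.q, dsw.I, yerr=dsw.sigma, fmt=".", ms=2, lw=0.5,
                    alpha=0.5, label="data")
        ax.plot(q, I_model, "-", lw=1.2, label="fit")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_title(ds.label(), fontsize=9)
        ax.set_xlabel(r"q [$\mathrm{\AA}^{-1}$]")
    axes[0, 0].set_ylabel("I(q) [arb.]")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_profiles(model, z_max=40.0, path=None):
    """Volume-probability profiles of an :class:`~sdpfit.bilayer.SDPModel`."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    from .bilayer import volume_probability

    z = np.linspace(-z_max, z_max, 801)
    prof = volume_probability(model, z)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for name, arr in prof.components.items():
        ax.plot(z, arr, lw=1.0, label=name)
    ax.plot(z, np.clip(prof.water, 0, None), "k--", lw=1.0, label="water")
    ax.set_xlabel(r"z [$\mathrm{\AA}$]")
    ax.set_ylabel("volume probability")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
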