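"""Quick-look plots for decoded tracks and activity budgets."""

from __future__ import annotations

import numpy as np

from .states import STATE_NAMES

STATE_COLORS = {
    "ActiveWater": "tab:red",
    "ActiveLand": "tab:blue",
    "InactiveWater": "tab:gray",
    "InactiveLand": "tab:green",
    "Nesting": "tab:orange",
}


def plot_decoded_track(decoded, ax=None):
    """Feature time series of one track coloured by decoded state.

    ``decoded`` is a frame for a single burst with ``window_start``,
    the two log10 features, ``immersed`` and ``state_name``.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(3, 1, sharex=True, figsize=(10, 6))
    t = decoded["window_start"]
    for name in STATE_NAMES:
        m = decoded["state_name"] == name
        if not m.any():
            continue
        c = STATE_COLORS[name]
        ax[0].scatter(t[m], decoded.loc[m, "var_pitch_log10"], s=4, color=c, label=name)
        ax[1].scatter(t[m], decoded.loc[m, "mean_odba_log10"], s=4, color=c)
        ax[2].scatter(t[m], decoded.loc[m, "immersed"], s=4, color=c)
    ax[0].set_ylabel("log10 var pitch")
    ax[1].set_ylabel("log10 mean ODBA")
    ax[2].set_ylabel("immersed")
    ax[0].legend(markerscale=3, fontsize=8)
    return ax


def plot_deployment_budget(budget, ax=None):
    """Stacked per-individual whole-deployment activity budget."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    inds = budget["individual_id"]
    bottom = np.zeros(len(budget))
    for name in STATE_NAMES:
        vals = budget[f"prop_{name}"].to_numpy(float)
        ax.bar(inds, vals, bottom=bottom, color=STATE_COLORS[name], label=name)
        bottom += vals
    ax.set_ylabel("proportion of deployment")
    ax.legend(fontsize=8)
    ax.tick_params(axis="x", rotation=45)
    return ax
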