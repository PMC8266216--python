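"""Quick-look plots of firing fields and place-map tilings.

matplotlib is imported lazily so the numerical pipeline has no hard
plotting dependency at import time.
"""

from __future__ import annotations

import math

import numpy as np

from .environment import Environment

__all__ = ["plot_fields", "plot_centers"]


def plot_fields(fields, env: Environment, n_cols: int = 10, cmap: str = "viridis"):
    """Grid of rate-map heatmaps (one block per cell), normalized per cell."""
    import matplotlib.pyplot as plt

    values = [f.values if hasattr(f, "values") else np.asarray(f) for f in fields]
    n = len(values)
    n_rows = math.ceil(n / n_cols)
    fig, axes = plt.subplots(
        n_rows, n_cols, figsize=(1.2 * n_cols, 1.2 * n_rows), squeeze=False
    )
    for ax in axes.ravel():
        ax.set_axis_off()
    for i, v in enumerate(values):
        ax = axes[i // n_cols][i % n_cols]
        vmax = v.max() if v.max() > 0 else 1.0
        ax.imshow(env.to_grid(v / vmax), origin="lower", cmap=cmap)
    fig.tight_layout()
    return fig


def plot_centers(centers_cm: np.ndarray, env: Environment):
    """Scatter of fitted place-field centers in the box."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4 * env.height_cm / env.width_cm))
    centers = np.atleast_2d(centers_cm)
    ax.plot(centers[:, 0], centers[:, 1], "o", ms=5)
    ax.set_xlim(0, env.width_cm)
    ax.set_ylim(0, env.height_cm)
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    ax.set_aspect("equal")
    return fig
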