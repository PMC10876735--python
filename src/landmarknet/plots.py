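"""Bland-Altman panel grid (7 landmarks x 3 spatial components)."""

from __future__ import annotations

import numpy as np

from .evaluation import bland_altman
from .io import N_LANDMARKS


def bland_altman_grid(predictions: dict, annotations: dict, path) -> None:
    """Write a 7x3 grid of Bland-Altman panels to ``path``.

    Rows are landmarks 1-7, columns the z/y/x components in mm.  Each
    panel shows difference vs mean, the bias line, the 95% limits of
    agreement (dashed) and the proportional-bias regression line.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    subjects = sorted(predictions)
    pred = np.stack([np.asarray(predictions[s], dtype=float) for s in subjects])
    ref = np.stack([np.asarray(annotations[s], dtype=float) for s in subjects])

    fig, axes = plt.subplots(N_LANDMARKS, 3, figsize=(11, 18), sharex=False)
    for j in range(N_LANDMARKS):
        for d, comp in enumerate(("z", "y", "x")):
            ax = axes[j, d]
            a, b = pred[:, j, d], ref[:, j, d]
            res = bland_altman(a, b)
            mean, diff = (a + b) / 2.0, a - b
            ax.scatter(mean, diff, s=8, color="k")
            ax.axhline(res["bias"], color="0.4", lw=1)
            ax.axhline(res["upper_limit"], color="0.4", lw=1, ls="--")
            ax.axhline(res["lower_limit"], color="0.4", lw=1, ls="--")
            if np.ptp(mean) > 0:
                xs = np.linspace(mean.min(), mean.max(), 2)
                centred = xs - mean.mean()
                ax.plot(xs, res["bias"] + res["slope"] * centred, color="tab:blue",
                        lw=1)
            ax.set_title(f"L{j + 1} {comp} (SD {res['sd']:.1f} mm)", fontsize=8)
            if d == 0:
                ax.set_ylabel("diff (mm)", fontsize=7)
    fig.suptitle("Bland-Altman: predicted vs annotated landmark positions")
    fig.tight_layout(rect=(0, 0, 1, 0.98))
    fig.savefig(path, dpi=120)
    plt.close(fig)
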