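"""Small plotting helpers for DVHs and setting-vs-metric trends."""

from __future__ import annotations

import numpy as np

from .eval3d import DVH


def plot_dvh(dvhs: dict[str, DVH], prescription: float | None = None, ax=None):
    """Cumulative DVH curves (exact voxel samples) for named structures."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, h in dvhs.items():
        vol = 100.0 * (np.arange(1, h.n_voxels + 1)) / h.n_voxels
        ax.step(h.samples, vol, where="post", label=name)
    if prescription:
        ax.axvline(prescription, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("dose [Gy(RBE)]")
    ax.set_ylabel("volume [%]")
    ax.set_ylim(0, 102)
    ax.legend(fontsize=8)
    return ax


def plot_metric_trend(metrics, metric: str, stage: str = "3d_nominal", ax=None):
    """Median organ-dose trend across setup-uncertainty settings."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = metrics[(metrics.metric == metric) & (metrics.stage == stage)]
    med = sub.groupby("setting_mm")["value"].median().sort_index(ascending=False)
    ax.plot([f"{s:g} mm" for s in med.index], med.values, "o-")
    ax.set_ylabel(metric)
    ax.set_title(stage)
    return ax
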