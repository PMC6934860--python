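"""Small rendering helpers: kinetics curves and pseudo-color frames."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .containers import TimeLapseStack
from .quantification import KineticSeries


def plot_kinetics(series: list[KineticSeries], ax=None):
    """Mean-fluorescence-vs-time curves, one line per subject."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for s in series:
        label = s.subject or s.culture_mode
        ax.plot(s.times_h, s.mean_fluorescence, marker="o", ms=3, label=label)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("mean green fluorescence (a.u.)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def pseudocolor_frame(stack: TimeLapseStack, frame_index: int = -1, ax=None,
                      cmap: str = "viridis"):
    """Heat-map rendering of one green-channel frame (uptake pattern)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    frame = stack.green[frame_index]
    im = ax.imshow(frame, cmap=cmap,
                   vmax=np.percentile(frame, 99.5) or 1.0)
    ax.set_axis_off()
    t = stack.times_h[frame_index]
    ax.set_title(f"t = {t:.1f} h", fontsize=9)
    plt.colorbar(im, ax=ax, fraction=0.046, label="pixel intensity (a.u.)")
    return ax
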