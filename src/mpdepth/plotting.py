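"""Small plotting helpers (matplotlib)."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd


def plot_depth_curves(
    model_profiles: dict,
    measured: Optional[pd.DataFrame] = None,
    ax=None,
):
    """In-focus fluorescence fraction versus focal depth.

    ``model_profiles`` maps a label (e.g. "l = 200 µm") to a
    :class:`~mpdepth.optics.DepthProfile`; ``measured`` is an optional ECR
    profile table with columns ``depth_um`` and ``mean_ecr`` plotted as
    points over the model curves.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, prof in model_profiles.items():
        ax.plot(prof.depths_um, 100.0 * prof.contrast, label=label)
    if measured is not None:
        ax.plot(
            measured["depth_um"],
            100.0 * np.asarray(measured["mean_ecr"]),
            "o",
            color="k",
            label="measured ECR",
        )
    ax.axhline(50.0, color="gray", ls=":", lw=0.8)
    ax.set_xlabel("focal depth below surface (µm)")
    ax.set_ylabel("fluorescence from focal plane (%)")
    ax.set_ylim(0, 105)
    ax.legend(frameon=False)
    return ax
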