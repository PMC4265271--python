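"""Debug plotting of genotyping plots (theta vs R) and reachability profiles."""

from __future__ import annotations

import numpy as np

from .calling import ClusterModel
from .cluster_core import ReachabilityProfile
from .panel import IntensityPanel


def plot_assay(
    panel: IntensityPanel,
    marker: str,
    model: ClusterModel | None = None,
    ax=None,
    out=None,
):
    """Scatter one assay's points, optionally with fitted cluster centers."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    theta, r, _ = panel.marker_points(marker)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(theta, r, s=8, alpha=0.5, c="grey")
    if model is not None and marker in model:
        for c in model.markers[marker]:
            p95 = float(np.percentile(r, 95)) or 1.0
            ax.scatter([c.center_theta], [c.center_r * p95],
                       marker="x", s=60, c="red" if c.null else "black")
            ax.annotate(c.call_label, (c.center_theta, c.center_r * p95))
    ax.set_xlabel("theta")
    ax.set_ylabel("R")
    ax.set_title(marker)
    if out:
        ax.figure.savefig(out, dpi=120)
    return ax


def dump_reachability(profile: ReachabilityProfile, path) -> None:
    """Write a reachability profile as TSV for external plotting."""
    with open(path, "w") as fh:
        fh.write("position\tpoint\treachability\tcore_distance\n")
        for pos, idx in enumerate(profile.order):
            fh.write(
                f"{pos}\t{idx}\t{profile.reachability[idx]:.6f}"
                f"\t{profile.core_distance[idx]:.6f}\n"
            )
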