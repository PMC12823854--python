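"""Overlap of the final network map with canonical brain networks.

For each canonical network label, the statistic is the ratio of final-map
voxels inside that network to the network's total voxel count; networks
with a ratio >= 10% are classified as involved.  Voxels of the final map
not covered by any atlas label are reported as an unassigned count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LabelAtlas

__all__ = ["OverlapProfile", "overlap_profile", "plot_profile"]


@dataclass
class OverlapProfile:
    """Per-network overlap table plus atlas-coverage bookkeeping.

    ``table`` columns: label, name, n_network_voxels, n_overlap_voxels,
    proportion, significant.
    """

    table: pd.DataFrame
    unassigned_voxels: int
    significance_fraction: float

    def significant_networks(self) -> list:
        return list(self.table.loc[self.table["significant"], "name"])

    def to_records(self) -> list:
        return self.table.to_dict(orient="records")


def overlap_profile(final_mask: np.ndarray, atlas: LabelAtlas,
                    significance_fraction: float = 0.10) -> OverlapProfile:
    """Quantify overlap of *final_mask* with every atlas network.

    The >= 10% classification is inclusive.  Errors on grid-shape
    mismatch and on empty atlas labels (named in the message).
    """
    final_mask = np.asarray(final_mask).astype(bool)
    if final_mask.shape != atlas.labels.shape:
        raise ValueError("final mask and atlas are on different grids")
    rows = []
    for label in atlas.label_ids:
        net = atlas.labels == label
        n_net = int(net.sum())
        if n_net == 0:
            raise ValueError(f"atlas label {label} ({atlas.names[label]}) is empty")
        n_overlap = int((net & final_mask).sum())
        prop = n_overlap / n_net
        rows.append({"label": label, "name": atlas.names[label],
                     "n_network_voxels": n_net, "n_overlap_voxels": n_overlap,
                     "proportion": prop,
                     "significant": bool(prop >= significance_fraction)})
    unassigned = int((final_mask & (atlas.labels == 0)).sum())
    return OverlapProfile(table=pd.DataFrame(rows), unassigned_voxels=unassigned,
                          significance_fraction=float(significance_fraction))


def plot_profile(profile: OverlapProfile, path) -> None:
    """Polar plot of overlap proportions (involved networks highlighted)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = profile.table
    theta = np.linspace(0, 2 * np.pi, len(table), endpoint=False)
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    colors = ["tab:blue" if s else "tab:orange" for s in table["significant"]]
    ax.bar(theta, table["proportion"] * 100, width=2 * np.pi / len(table) * 0.8,
           color=colors, alpha=0.7)
    ax.set_xticks(theta)
    ax.set_xticklabels(table["name"], fontsize=7)
    ax.set_title("Canonical network overlap (%)", fontsize=10)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
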