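"""Plotting helpers: component scatter maps and ranked-map heatmaps.

These are convenience visualizations; nothing downstream depends on them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .effects import PHENOTYPES


def pc_scatter(result, colony_wells, profiles, phenotype, components=(0, 1), ax=None):
    """Scatter colonies on two components, colored by well phenotype frequency."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    prof = profiles.set_index("well_id")
    c = prof.loc[np.asarray(colony_wells), f"f_{phenotype}"].to_numpy(float)
    i, j = components
    sc = ax.scatter(
        result.colony_scores[:, i], result.colony_scores[:, j],
        c=c, s=4, cmap="viridis",
    )
    ax.set_xlabel(f"PC{i + 1}")
    ax.set_ylabel(f"PC{j + 1}")
    ax.figure.colorbar(sc, ax=ax, label=f"f({phenotype})")
    return ax


def ranked_map_heatmap(report: pd.DataFrame, ax=None):
    """Heatmap of the composition report (phenotype x category/level)."""
    import matplotlib.pyplot as plt

    pivot = report.pivot_table(
        index="phenotype", columns=["category", "level"], values="percent"
    ).reindex(list(PHENOTYPES))
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="magma")
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    ax.set_xticks(
        range(pivot.shape[1]),
        [f"{c}\n{l}" for c, l in pivot.columns], fontsize=6, rotation=90,
    )
    ax.figure.colorbar(im, ax=ax, label="% of top wells")
    return ax
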