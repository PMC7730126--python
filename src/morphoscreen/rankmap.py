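"""Ranked frequency maps: condition composition of top-ranked wells.

Wells are ranked by the frequency of a phenotype; the top fraction
(default 5%) is selected and the microenvironmental levels of the selected
wells are tallied per factor category as percentages.  An optional variant
averages replicate wells per condition before ranking.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .effects import PHENOTYPES
from .glm import FACTORS

__all__ = ["rank_wells", "top_fraction_map", "composition_report", "RankedMap"]


class RankedMap(dict):
    """phenotype + per-category level percentages of the selected wells."""


def rank_wells(
    profiles: pd.DataFrame, phenotype: str, average_replicates: bool = False
) -> pd.DataFrame:
    """Wells (or conditions) ordered by descending phenotype frequency.

    Ties break by colony count (descending) then by well id (ascending), so
    the order is a deterministic total order.  With ``average_replicates``
    the frequency is first averaged over each condition's replicate wells
    and every well of a condition inherits the averaged rank key.
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    if len(profiles) == 0:
        raise ValueError("empty profile set")
    col = f"f_{phenotype}"
    df = profiles.copy()
    if average_replicates:
        df["_key"] = df.groupby("condition_id")[col].transform("mean")
    else:
        df["_key"] = df[col]
    df = df.sort_values(
        ["_key", "n_colonies", "well_id"], ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_key")
    return df.reset_index(drop=True)


def top_fraction_map(
    ranked: pd.DataFrame,
    design: pd.DataFrame,
    phenotype: str,
    top_fraction: float = 0.05,
) -> RankedMap:
    """Factor-level composition of the top-ranked wells.

    Selects ceil(top_fraction * N) wells, joins them to the design table and
    reports, for each factor category, the percentage of selected wells at
    each level (all observed levels listed; percentages per category sum to
    100).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    n_sel = math.ceil(top_fraction * len(ranked))
    sel = ranked.head(n_sel)
    merged = sel.merge(design[["well_id", *[f for f in FACTORS
                                            if f not in sel.columns]]],
                       on="well_id", how="left", validate="one_to_one")
    for f in FACTORS:
        if merged[f].isna().any():
            orphan = merged.loc[merged[f].isna(), "well_id"].iloc[0]
            raise KeyError(f"well {orphan!r} missing from the design table")
    composition = {}
    for f in FACTORS:
        levels = sorted(design[f].dropna().unique(), key=str)
        counts = merged[f].value_counts()
        composition[f] = {
            lv: 100.0 * counts.get(lv, 0) / n_sel for lv in levels
        }
    return RankedMap(
        phenotype=phenotype,
        wells=list(sel["well_id"]),
        n_selected=n_sel,
        composition=composition,
    )


def composition_report(maps: dict[str, RankedMap]) -> pd.DataFrame:
    """Tidy long-format table over all phenotype maps."""
    rows = []
    for ph in PHENOTYPES:
        if ph not in maps:
            raise KeyError(f"missing ranked map for phenotype {ph!r}")
        m = maps[ph]
        for category, levels in m["composition"].items():
            for lv, pct in levels.items():
                rows.append(
                    {"phenotype": ph, "category": category, "level": lv,
                     "percent": pct, "n_wells": m["n_selected"]}
                )
    return pd.DataFrame(rows)
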