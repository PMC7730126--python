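import numpy as np
import pandas as pd
import pytest

from morphoscreen import features as feat
from morphoscreen.classify import build_training_set, classify_plate, train_iterative
from morphoscreen.design import Condition, PlateLayout, default_design
from morphoscreen.effects import ColonyCountParams, simulate_profiles
from morphoscreen.render import WellImageParams, generate_plate
from morphoscreen.segmentation import match_to_truth, segment_well

#: one fixed seed per synthetic data set used across the suite
FULL_PLATE_SEED = 1
MINI_PLATE_SEED = 3


@pytest.fixture(scope="session")
def default_layout():
    levels, layout = default_design(seed=0)
    return levels, layout


@pytest.fixture(scope="session")
def full_profiles(default_layout):
    """Counts-only simulation of the default 384-well plate (planted model)."""
    _, layout = default_layout
    return simulate_profiles(layout, seed=FULL_PLATE_SEED)


def mini_conditions():
    """Eight conditions spanning the four planted phenotype optima."""
    return [
        Condition("C000", 2.0, "low", "blank", "EGF+"),   # polarized
        Condition("C001", 4.0, "high", "L", "EGF+"),
        Condition("C002", 2.0, "low", "F", "EGF+"),       # non-polarized
        Condition("C003", 4.0, "high", "LCF", "EGF+"),
        Condition("C004", 0.5, "low", "blank", "EGF+"),   # spread
        Condition("C005", 0.5, "high", "C", "EGF+"),
        Condition("C006", 8.0, "low", "blank", "EGF+"),   # inverted
        Condition("C007", 2.0, "high", "LC", "EGF-"),
    ]


def mini_layout(replicates=2):
    conds = mini_conditions()
    wells = [
        (f"{chr(ord('A') + r)}{i + 1}", c.condition_id, r)
        for r in range(replicates)
        for i, c in enumerate(conds)
    ]
    return PlateLayout(wells, {c.condition_id: c for c in conds})


@pytest.fixture(scope="session")
def mini_plate():
    """Image-based mini plate: rendered, segmented, measured and labelled."""
    layout = mini_layout()
    params = WellImageParams(
        size_px=640, counts=ColonyCountParams(mean=45, dispersion=13.0)
    )
    images, truth = generate_plate(layout, seed=MINI_PLATE_SEED, params=params)
    results = [segment_well(images[w]) for w in layout.well_ids()]
    table = feat.feature_table(results, images)
    matched = pd.concat(
        [match_to_truth(r, truth) for r in results], ignore_index=True
    ).dropna(subset=["matched_colony_id"])
    labelled = table.merge(
        matched[["well_id", "matched_colony_id", "phenotype"]],
        left_on=["well_id", "colony_id"],
        right_on=["well_id", "matched_colony_id"],
    )
    return {
        "layout": layout,
        "params": params,
        "images": images,
        "truth": truth,
        "results": results,
        "table": table,
        "labelled": labelled,
    }


@pytest.fixture(scope="session")
def sampled_default_plate():
    """Image plate over a stride-sample of the default design.

    Keeps the default plate's planted composition (inverted-dominated) at
    desk scale: every 11th condition, duplicated wells, 30 colonies/well.
    """
    from morphoscreen.design import PlateLayout, enumerate_conditions, FactorLevels

    # odd stride so the fastest-varying factor (EGF) keeps both levels
    conds = enumerate_conditions(FactorLevels())[::5]
    wells = [(f"W{i:03d}", c.condition_id, 0) for i, c in enumerate(conds)]
    layout = PlateLayout(wells, {c.condition_id: c for c in conds})
    params = WellImageParams(
        size_px=512, counts=ColonyCountParams(mean=25.0, dispersion=13.0)
    )
    images, truth = generate_plate(layout, seed=21, params=params)
    results = [segment_well(images[w]) for w in layout.well_ids()]
    table = feat.feature_table(results, images)
    # ground-truth per-well frequencies (the generator's realized mixtures)
    rows = []
    for well_id, cid, _ in layout.wells:
        grp = truth[truth["well_id"] == well_id]
        row = {"well_id": well_id, "condition_id": cid,
               "n_colonies": len(grp)}
        for ph in ("polarized", "non_polarized", "spread", "inverted"):
            row[f"f_{ph}"] = (grp["phenotype"] == ph).mean() if len(grp) \
                else np.nan
        rows.append(row)
    profiles = pd.DataFrame(rows)
    return {"layout": layout, "images": images, "truth": truth,
            "results": results, "table": table, "profiles": profiles}


@pytest.fixture(scope="session")
def mini_classifier(mini_plate):
    """Forest trained on the mini plate's ground-truth labels."""
    lab = mini_plate["labelled"]
    split = build_training_set(lab, lab["phenotype"], seed=0)
    forest, itlog = train_iterative(split, seed=0)
    summary = classify_plate(forest, lab, truth_labels=lab["phenotype"])
    return {"forest": forest, "log": itlog, "summary": summary}
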