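"""Full-factorial microenvironment screen design.

The screen crosses four categories of microenvironmental control:

* **MP** — matrix mechanical properties: nominal shear modulus in kPa, each
  level paired with the PEG polymer content (% w/v) that produces it;
* **DG** — matrix degradability: which MMP-substrate crosslinker is used
  ("high" ↔ GPQG↓IWGQ, "low" ↔ VPMS↓MRGG);
* **EC** — grafted ECM proteins: every subset of a base protein set
  (laminin ``L``, collagen IV ``C``, fibronectin ``F``), including the empty
  "blank" control;
* **SF** — soluble factor: EGF present (10 ng/ml) or absent.

Under the defaults this yields 4 x 2 x 2^3 x 2 = 128 conditions, dispensed in
triplicate into a 384-well plate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorLevels",
    "Condition",
    "PlateLayout",
    "DesignError",
    "enumerate_conditions",
    "gel_precursor_combinations",
    "assign_wells",
    "write_design_table",
    "read_design_table",
    "ECM_LETTER_ORDER",
    "BLANK_ECM",
]

#: canonical ECM letter order so subset labels read "L", "C", "F", "LC",
#: "LF", "CF", "LCF" (matching figure-legend codes), never "CL" or "FCL".
ECM_LETTER_ORDER = "LCF"
BLANK_ECM = "blank"


class DesignError(ValueError):
    """Invalid factor levels or plate parameters."""


def _ecm_label(subset: frozenset[str]) -> str:
    if not subset:
        return BLANK_ECM
    return "".join(c for c in ECM_LETTER_ORDER if c in subset) + "".join(
        sorted(c for c in subset if c not in ECM_LETTER_ORDER)
    )


@dataclass(frozen=True)
class FactorLevels:
    """Levels of the four screen factors.

    ``stiffness_kPa`` is the ordered list of nominal stiffnesses;
    ``polymer_pct`` carries the paired PEG content as metadata (same length).
    ``ecm_base`` is the base protein set; the EC factor is its full power set.
    """

    stiffness_kPa: tuple[float, ...] = (0.5, 2.0, 4.0, 8.0)
    polymer_pct: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0)
    degradability: tuple[str, ...] = ("high", "low")
    ecm_base: tuple[str, ...] = ("L", "C", "F")
    soluble_factor: tuple[str, ...] = ("EGF+", "EGF-")
    replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("stiffness_kPa", "degradability", "soluble_factor"):
            levels = getattr(self, name)
            if len(levels) == 0:
                raise DesignError(f"factor {name!r} has no levels")
            if len(set(levels)) != len(levels):
                raise DesignError(f"factor {name!r} has duplicate levels")
        if len(set(self.ecm_base)) != len(self.ecm_base):
            raise DesignError("ecm_base has duplicate proteins")
        if len(self.polymer_pct) != len(self.stiffness_kPa):
            raise DesignError("polymer_pct must pair 1:1 with stiffness_kPa")
        if self.replicates < 1:
            raise DesignError("replicates must be >= 1")

    @property
    def ecm_levels(self) -> tuple[str, ...]:
        """All 2^k ECM subset labels, blank first, then by size and letter order."""
        subsets = [
            frozenset(c)
            for r in range(len(self.ecm_base) + 1)
            for c in itertools.combinations(self.ecm_base, r)
        ]
        return tuple(_ecm_label(s) for s in subsets)

    def polymer_for(self, stiffness: float) -> float:
        return self.polymer_pct[self.stiffness_kPa.index(stiffness)]


@dataclass(frozen=True)
class Condition:
    """One microenvironmental combination (MP, DG, EC, SF)."""

    condition_id: str
    mp: float
    dg: str
    ec: str
    sf: str


@dataclass
class PlateLayout:
    """Assignment of conditions to wells.

    ``wells`` is an ordered list of ``(well_id, condition_id, replicate_index)``;
    ``conditions`` maps condition_id to the :class:`Condition`.
    """

    wells: list[tuple[str, str, int]]
    conditions: dict[str, Condition] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.wells)

    def well_ids(self) -> list[str]:
        return [w for w, _, _ in self.wells]

    def condition_of(self, well_id: str) -> Condition:
        for w, cid, _ in self.wells:
            if w == well_id:
                return self.conditions[cid]
        raise KeyError(well_id)


def enumerate_conditions(levels: FactorLevels) -> list[Condition]:
    """Cartesian product MP x DG x EC-subsets x SF in deterministic order.

    MP varies slowest and SF fastest, so condition ids are stable across runs
    with identical levels.
    """
    out: list[Condition] = []
    for i, (mp, dg, ec, sf) in enumerate(
        itertools.product(
            levels.stiffness_kPa, levels.degradability, levels.ecm_levels,
            levels.soluble_factor,
        )
    ):
        out.append(Condition(f"C{i:03d}", mp, dg, ec, sf))
    return out


def gel_precursor_combinations(levels: FactorLevels) -> list[tuple[float, str]]:
    """The (MP, DG) pairs mixed as hydrogel precursors (8 under defaults)."""
    return list(itertools.product(levels.stiffness_kPa, levels.degradability))


def _plate_well_names(n: int) -> list[str]:
    """Row/column well names (A1..P24 for n <= 384, extending rows if needed)."""
    rows = [chr(ord("A") + i) for i in range(26)]
    ncol = 24 if n > 96 else 12
    names = [f"{r}{c}" for r in rows for c in range(1, ncol + 1)]
    if n > len(names):
        names = [f"W{i:04d}" for i in range(n)]
    return names[:n]


def assign_wells(
    conditions: list[Condition], replicates: int = 3, seed: int = 0
) -> PlateLayout:
    """Assign each condition to ``replicates`` wells in seeded-shuffled order.

    The plate carries no positional effects in this pipeline, but the well
    order is still randomized so that downstream analyses cannot accidentally
    exploit enumeration order.
    """
    if replicates < 1:
        raise DesignError("replicates must be >= 1")
    pairs = [(c.condition_id, r) for c in conditions for r in range(replicates)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    names = _plate_well_names(len(pairs))
    wells = [(names[i], *pairs[j]) for i, j in enumerate(order)]
    return PlateLayout(wells=wells, conditions={c.condition_id: c for c in conditions})


def layout_frame(layout: PlateLayout, levels: FactorLevels | None = None) -> pd.DataFrame:
    """Design table with one row per well and the factor levels spelled out."""
    rows = []
    for well_id, cid, rep in layout.wells:
        c = layout.conditions[cid]
        rows.append(
            {
                "well_id": well_id,
                "condition_id": cid,
                "replicate": rep,
                "stiffness_kPa": c.mp,
                "polymer_pct": levels.polymer_for(c.mp) if levels else np.nan,
                "degradability": c.dg,
                "ecm": c.ec,
                "egf": c.sf,
            }
        )
    return pd.DataFrame(rows)


def write_design_table(
    layout: PlateLayout, path, levels: FactorLevels | None = None
) -> None:
    layout_frame(layout, levels).to_csv(path, index=False)


def read_design_table(path) -> PlateLayout:
    """Read a design table back into an identical :class:`PlateLayout`."""
    df = pd.read_csv(path, dtype={"ecm": str})
    conditions = {}
    wells = []
    for row in df.itertuples(index=False):
        cond = Condition(
            row.condition_id, float(row.stiffness_kPa), str(row.degradability),
            str(row.ecm), str(row.egf),
        )
        prev = conditions.setdefault(row.condition_id, cond)
        if prev != cond:
            raise DesignError(f"inconsistent rows for condition {row.condition_id}")
        wells.append((row.well_id, row.condition_id, int(row.replicate)))
    return PlateLayout(wells=wells, conditions=conditions)


def default_design(seed: int = 0) -> tuple[FactorLevels, PlateLayout]:
    """The default 128-condition, 384-well triplicate design."""
    levels = FactorLevels()
    conditions = enumerate_conditions(levels)
    return levels, assign_wells(conditions, levels.replicates, seed=seed)
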