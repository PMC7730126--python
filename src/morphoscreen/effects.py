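"""Condition-dependent phenotype mixture model for the synthetic screen.

Each colony in a well adopts one of four phenotypes — ``polarized`` (round,
central actin belt), ``non_polarized`` (round, unpolarized cytoskeleton),
``spread`` (elongated, diffuse actin) and ``inverted`` (actin concentrated at
the colony edge).  The probability of each phenotype under a given
microenvironmental condition is a softmax over additive per-factor logits:

    p(condition) = softmax[(baseline + sum of factor effects) / temperature]

The planted default effects encode the qualitative biology the screen is
built to detect:

* absence of EGF, or 8 kPa stiffness, drives wells toward ~pure inverted;
* intermediate stiffness (2-4 kPa) with EGF permits polarized colonies,
  with non-polarized slightly favored at 2 kPa;
* any fibronectin-containing ECM combination shifts polarized colonies to
  non-polarized;
* the softest matrix (0.5 kPa) favors the spread phenotype;
* matrix degradability leaves the *mean* composition untouched but controls
  within-well mixing: non-degradable wells collapse toward a single dominant
  phenotype, degradable wells stay close to the condition mixture.  This is
  modelled by drawing each well's mixture from a Dirichlet centred on the
  condition probabilities whose concentration is keyed to degradability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import Condition, FactorLevels, PlateLayout, layout_frame

__all__ = [
    "PHENOTYPES",
    "PhenotypeEffectModel",
    "ColonyCountParams",
    "condition_phenotype_probs",
    "sample_colony_count",
    "sample_well_mixture",
    "simulate_profiles",
    "ConfigurationError",
]

#: canonical phenotype order used for every 4-vector in the package
PHENOTYPES = ("polarized", "non_polarized", "spread", "inverted")


class ConfigurationError(KeyError):
    """A condition refers to a level the effect model does not cover."""


def _zero4() -> np.ndarray:
    return np.zeros(4)


def _default_factor_effects() -> dict[tuple[str, object], np.ndarray]:
    # order: polarized, non_polarized, spread, inverted
    eff: dict[tuple[str, object], np.ndarray] = {
        ("mp", 0.5): np.array([-2.0, -2.0, 2.5, 0.0]),
        ("mp", 2.0): np.array([2.5, 2.3, 0.0, 0.0]),
        ("mp", 4.0): np.array([2.5, 1.9, 0.0, 0.0]),
        ("mp", 8.0): np.array([0.0, 0.0, 0.0, 4.0]),
        ("dg", "high"): _zero4(),
        ("dg", "low"): _zero4(),
        ("sf", "EGF+"): _zero4(),
        ("sf", "EGF-"): np.array([0.0, 0.0, 0.0, 7.0]),
    }
    fibro = np.array([-2.5, 2.5, 0.0, 0.0])
    for ec in ("blank", "L", "C", "F", "LC", "LF", "CF", "LCF"):
        eff[("ec", ec)] = fibro.copy() if "F" in ec else _zero4()
    return eff


@dataclass
class PhenotypeEffectModel:
    """Planted ground-truth mapping from condition to phenotype mixture."""

    baseline_logits: np.ndarray = field(default_factory=_zero4)
    factor_effects: dict[tuple[str, object], np.ndarray] = field(
        default_factory=_default_factor_effects
    )
    #: softmax temperature per degradability level (> 0); 1.0 = neutral
    mixing_temperature: dict[str, float] = field(
        default_factory=lambda: {"high": 1.0, "low": 1.0}
    )
    #: Dirichlet concentration per degradability level; higher = wells closer
    #: to the condition mixture (degradable), lower = near-pure wells
    mixing_concentration: dict[str, float] = field(
        default_factory=lambda: {"high": 80.0, "low": 2.0}
    )

    def effect(self, factor: str, level) -> np.ndarray:
        try:
            return self.factor_effects[(factor, level)]
        except KeyError as err:
            raise ConfigurationError(
                f"effect model has no entry for factor {factor!r} level {level!r}"
            ) from err

    def to_json(self, path) -> None:
        payload = {
            "phenotypes": list(PHENOTYPES),
            "baseline_logits": list(map(float, self.baseline_logits)),
            "factor_effects": [
                {"factor": f, "level": lv, "logits": list(map(float, v))}
                for (f, lv), v in self.factor_effects.items()
            ],
            "mixing_temperature": self.mixing_temperature,
            "mixing_concentration": self.mixing_concentration,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PhenotypeEffectModel":
        with open(path) as fh:
            payload = json.load(fh)
        eff = {
            (e["factor"], e["level"] if e["factor"] != "mp" else float(e["level"])):
                np.asarray(e["logits"], float)
            for e in payload["factor_effects"]
        }
        return cls(
            baseline_logits=np.asarray(payload["baseline_logits"], float),
            factor_effects=eff,
            mixing_temperature=payload["mixing_temperature"],
            mixing_concentration=payload["mixing_concentration"],
        )


def condition_phenotype_probs(
    model: PhenotypeEffectModel, condition: Condition
) -> np.ndarray:
    """Phenotype mixture for a condition: temperature-scaled softmax of logits."""
    logits = np.asarray(model.baseline_logits, float).copy()
    for factor, level in (
        ("mp", condition.mp), ("dg", condition.dg),
        ("ec", condition.ec), ("sf", condition.sf),
    ):
        logits = logits + model.effect(factor, level)
    temp = model.mixing_temperature.get(condition.dg, 1.0)
    if temp <= 0:
        raise ConfigurationError("mixing temperature must be positive")
    z = logits / temp
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


@dataclass(frozen=True)
class ColonyCountParams:
    """Negative-binomial per-well colony count.

    Defaults give median 159 and sd ~47 colonies per well.  ``dispersion`` is
    the NB shape k (variance = mean + mean^2/k); ``dispersion = inf`` (or
    ``sd == 0``) degenerates to a constant count of round(mean).
    """

    mean: float = 163.0
    dispersion: float = 13.0

    def distribution(self):
        k = self.dispersion
        if not np.isfinite(k):
            return None
        return stats.nbinom(k, k / (k + self.mean))


def sample_colony_count(
    rng: np.random.Generator, params: ColonyCountParams = ColonyCountParams()
) -> int:
    dist = params.distribution()
    if dist is None:
        return int(round(params.mean))
    return int(dist.rvs(random_state=rng))


def sample_well_mixture(
    model: PhenotypeEffectModel, condition: Condition, rng: np.random.Generator
) -> np.ndarray:
    """Draw the well-specific mixture: Dirichlet centred on the condition probs.

    With concentration c, the well mixture has mean equal to the condition
    probabilities for every c, so degradability modulates heterogeneity
    without shifting average composition.  ``c = inf`` returns the condition
    probabilities exactly.
    """
    p = condition_phenotype_probs(model, condition)
    c = model.mixing_concentration.get(condition.dg, np.inf)
    if not np.isfinite(c):
        return p
    alpha = np.maximum(c * p, 1e-9)
    return rng.dirichlet(alpha)


def simulate_profiles(
    layout: PlateLayout,
    model: PhenotypeEffectModel | None = None,
    seed: int = 0,
    count_params: ColonyCountParams = ColonyCountParams(),
) -> pd.DataFrame:
    """Counts-only simulation of per-well phenotype profiles (no images).

    For each well: draw the colony count, draw the well mixture, then draw
    per-phenotype counts multinomially.  Returns one row per well with the
    condition levels, ``n_colonies``, per-phenotype counts ``n_<phenotype>``
    and frequencies ``f_<phenotype>``.  This is the fast path used for
    plate-scale statistical analyses; :func:`morphoscreen.render.generate_plate`
    produces the same structure with images attached.
    """
    model = model or PhenotypeEffectModel()
    ss = np.random.SeedSequence(seed)
    rows = []
    for child, (well_id, cid, rep) in zip(ss.spawn(len(layout.wells)), layout.wells):
        rng = np.random.default_rng(child)
        cond = layout.conditions[cid]
        n = sample_colony_count(rng, count_params)
        mix = sample_well_mixture(model, cond, rng)
        counts = rng.multinomial(n, mix) if n > 0 else np.zeros(4, int)
        row = {
            "well_id": well_id, "condition_id": cid, "replicate": rep,
            "stiffness_kPa": cond.mp, "degradability": cond.dg,
            "ecm": cond.ec, "egf": cond.sf, "n_colonies": n,
        }
        for ph, c in zip(PHENOTYPES, counts):
            row[f"n_{ph}"] = int(c)
        for ph, c in zip(PHENOTYPES, counts):
            row[f"f_{ph}"] = c / n if n > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def expected_within_well_entropy(
    model: PhenotypeEffectModel,
    condition: Condition,
    rng: np.random.Generator,
    n_draws: int = 200,
) -> float:
    """Monte-Carlo expected Shannon entropy (nats) of the well mixture."""
    h = 0.0
    for _ in range(n_draws):
        mix = sample_well_mixture(model, condition, rng)
        m = mix[mix > 0]
        h += float(-(m * np.log(m)).sum())
    return h / n_draws
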