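"""Random-forest phenotype classification and per-well frequency profiles.

The training protocol mirrors interactive high-content classification: at
least 30 labelled examples per class seed the training set, the model is
validated on batches of at least 10 held-out examples, and iteration stops
once a cumulative minimum of correctly classified validation examples is
reached (each validated batch is folded into the training set, emulating an
annotator confirming machine suggestions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix

from .design import PlateLayout
from .effects import PHENOTYPES
from .features import FEATURE_NAMES

log = logging.getLogger(__name__)

__all__ = [
    "TrainingProtocol",
    "TrainingSplit",
    "ProtocolError",
    "ClassificationSummary",
    "build_training_set",
    "train_iterative",
    "classify_plate",
    "well_profiles",
    "class_fractions",
]


class ProtocolError(ValueError):
    """Labelled data cannot satisfy the training protocol."""


@dataclass(frozen=True)
class TrainingProtocol:
    min_train_per_class: int = 30
    min_validation: int = 10
    min_correct: int = 15
    max_iterations: int = 20

    def __post_init__(self) -> None:
        if min(self.min_train_per_class, self.min_validation,
               self.max_iterations) < 1 or self.min_correct < 0:
            raise ProtocolError("protocol sizes must be positive")


@dataclass
class TrainingSplit:
    X_train: np.ndarray
    y_train: np.ndarray
    X_pool: np.ndarray      # held-out validation pool
    y_pool: np.ndarray
    feature_names: tuple[str, ...]


@dataclass
class IterationLog:
    accuracies: list[float] = field(default_factory=list)
    cumulative_correct: int = 0
    converged: bool = False


@dataclass
class ClassificationSummary:
    predictions: pd.DataFrame          # well_id, colony_id, predicted_phenotype
    class_counts: dict[str, int]
    class_fractions: dict[str, float]
    total_colonies: int
    confusion: np.ndarray | None = None


def build_training_set(
    features: pd.DataFrame,
    labels: pd.Series,
    protocol: TrainingProtocol = TrainingProtocol(),
    seed: int = 0,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> TrainingSplit:
    """Stratified seeded split into a training set and a validation pool.

    Takes ``min_train_per_class`` examples per class for training; everything
    else goes to the validation pool, which must hold at least
    ``min_validation`` examples.
    """
    labels = pd.Series(np.asarray(labels), index=features.index)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    pool_idx: list[int] = []
    for cls, group in labels.groupby(labels):
        need = protocol.min_train_per_class
        if len(group) < need:
            raise ProtocolError(
                f"class {cls!r} has {len(group)} labelled examples; "
                f"protocol needs at least {need} for training"
            )
        perm = rng.permutation(group.index.to_numpy())
        train_idx.extend(perm[:need])
        pool_idx.extend(perm[need:])
    if len(pool_idx) < protocol.min_validation:
        raise ProtocolError(
            f"validation pool has {len(pool_idx)} examples; "
            f"protocol needs at least {protocol.min_validation}"
        )
    rng.shuffle(pool_idx)
    X = features.loc[:, list(feature_names)].to_numpy(float)
    loc = {ix: i for i, ix in enumerate(features.index)}
    tr = [loc[i] for i in train_idx]
    po = [loc[i] for i in pool_idx]
    return TrainingSplit(
        X[tr], labels.loc[train_idx].to_numpy(),
        X[po], labels.loc[pool_idx].to_numpy(),
        tuple(feature_names),
    )


def _new_forest(seed: int) -> RandomForestClassifier:
    # 100 trees, sqrt(p) features per split
    return RandomForestClassifier(
        n_estimators=100, max_features="sqrt", random_state=seed, n_jobs=1
    )


def train_iterative(
    split: TrainingSplit,
    protocol: TrainingProtocol = TrainingProtocol(),
    seed: int = 0,
) -> tuple[RandomForestClassifier, IterationLog]:
    """Fit-validate loop until enough validation examples are correct.

    Each iteration fits a fresh forest, validates on the next
    ``min_validation`` pool examples (recycling the pool if exhausted), adds
    them to the training set, and accumulates the number of correct
    predictions.  Terminates once ``min_correct`` cumulative correct
    classifications are reached, or after ``max_iterations`` with a warning.
    """
    X_tr, y_tr = split.X_train.copy(), split.y_train.copy()
    pool_X, pool_y = split.X_pool, split.y_pool
    logrec = IterationLog()
    model = _new_forest(seed)
    cursor = 0
    for it in range(protocol.max_iterations):
        model = _new_forest(seed + it)
        model.fit(X_tr, y_tr)
        if logrec.cumulative_correct >= protocol.min_correct:
            logrec.converged = True
            break
        if cursor + protocol.min_validation > len(pool_y):
            cursor = 0
        batch = slice(cursor, cursor + protocol.min_validation)
        cursor += protocol.min_validation
        Xb, yb = pool_X[batch], pool_y[batch]
        if len(yb) == 0:
            break
        pred = model.predict(Xb)
        correct = int((pred == yb).sum())
        logrec.accuracies.append(correct / len(yb))
        logrec.cumulative_correct += correct
        X_tr = np.vstack([X_tr, Xb])
        y_tr = np.concatenate([y_tr, yb])
        if logrec.cumulative_correct >= protocol.min_correct:
            model = _new_forest(seed + it + 1)
            model.fit(X_tr, y_tr)
            logrec.converged = True
            break
    if not logrec.converged:
        log.warning(
            "training did not reach %d cumulative correct within %d iterations",
            protocol.min_correct, protocol.max_iterations,
        )
    return model, logrec


def classify_plate(
    model: RandomForestClassifier,
    features: pd.DataFrame,
    truth_labels: pd.Series | None = None,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> ClassificationSummary:
    """Predict a phenotype for every colony in the feature table."""
    missing = [c for c in feature_names if c not in features.columns]
    if missing:
        raise KeyError(f"feature table lacks manifest columns: {missing[:5]}")
    X = features.loc[:, list(feature_names)].to_numpy(float)
    pred = model.predict(X)
    proba = model.predict_proba(X).max(axis=1)
    predictions = pd.DataFrame(
        {
            "well_id": features["well_id"].to_numpy(),
            "colony_id": features["colony_id"].to_numpy(),
            "predicted_phenotype": pred,
            "confidence": proba,
        }
    )
    total = len(predictions)
    counts = {ph: int((pred == ph).sum()) for ph in PHENOTYPES}
    fractions = class_fractions(counts, total)
    conf = None
    if truth_labels is not None:
        conf = confusion_matrix(
            np.asarray(truth_labels), pred, labels=list(PHENOTYPES)
        )
    return ClassificationSummary(predictions, counts, fractions, total, conf)


def class_fractions(counts: dict[str, int], total: int) -> dict[str, float]:
    """Per-class percentage of the total segmented colony count."""
    if total <= 0:
        return {k: float("nan") for k in counts}
    return {k: 100.0 * v / total for k, v in counts.items()}


def well_profiles(
    predictions: pd.DataFrame, layout: PlateLayout
) -> pd.DataFrame:
    """Per-well phenotype frequency profiles from colony predictions.

    Wells with zero colonies get NaN frequencies and ``empty = True``.
    Raises on predictions whose well is absent from the layout.
    """
    known = set(layout.well_ids())
    orphans = set(predictions["well_id"]) - known
    if orphans:
        raise KeyError(f"predictions reference unknown wells: {sorted(orphans)[:5]}")
    rows = []
    by_well = dict(tuple(predictions.groupby("well_id")))
    for well_id, cid, _rep in layout.wells:
        grp = by_well.get(well_id)
        n = 0 if grp is None else len(grp)
        row = {"well_id": well_id, "condition_id": cid, "n_colonies": n,
               "is_empty": n == 0}
        for ph in PHENOTYPES:
            row[f"f_{ph}"] = (
                (grp["predicted_phenotype"] == ph).sum() / n if n else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
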