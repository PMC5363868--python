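"""Three-class random-forest classification with leave-one-out CV.

Each subject is predicted by a forest trained on all remaining subjects; the
fold count therefore equals the subject count and every subject is predicted
exactly once. Per-fold random substreams derived from the master seed make
the whole procedure deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix


@dataclass(frozen=True)
class ClassifierConfig:
    n_trees: int = 500
    features_per_split: str | int | float = "sqrt"
    seed: int = 0
    nested_selection: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("need at least one tree")


@dataclass
class ClassifierResult:
    accuracy_percent: float
    confusion: np.ndarray  # n_classes x n_classes, rows = true label
    class_order: list[str]
    per_fold_predictions: list[tuple[str, str, str]]  # (subject_id, true, predicted)
    config: ClassifierConfig

    def to_dict(self) -> dict:
        return {
            "accuracy_percent": self.accuracy_percent,
            "confusion": self.confusion.tolist(),
            "class_order": self.class_order,
            "per_fold_predictions": [list(t) for t in self.per_fold_predictions],
            "config": {"n_trees": self.config.n_trees,
                       "features_per_split": self.config.features_per_split,
                       "seed": self.config.seed,
                       "nested_selection": self.config.nested_selection},
        }


def baseline_accuracy(n_classes: int) -> float:
    """Expected accuracy (percent) of a uniform random guesser."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    return 100.0 / n_classes


def loocv_rf(features: np.ndarray, labels: Sequence[str],
             cfg: ClassifierConfig = ClassifierConfig(),
             subject_ids: Sequence[str] | None = None,
             selector: Callable[[np.ndarray, np.ndarray], Sequence[int]] | None = None,
             ) -> ClassifierResult:
    """Leave-one-out random-forest classification.

    ``selector``, used when ``cfg.nested_selection`` is true, maps a training
    fold (features, labels) to the column indices to keep, re-running feature
    selection inside every fold for leakage-free estimates. Without it the
    feature matrix is used as passed (selection on the full sample, if any,
    has then happened upstream).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = features.shape[0]
    if features.ndim != 2 or features.shape[1] < 1:
        raise ValueError("empty feature set; run feature selection first "
                         "(stats.select_features) and pass its columns")
    if n != len(labels):
        raise ValueError("features and labels must align")
    class_order = sorted(set(labels))
    if subject_ids is None:
        subject_ids = [f"subject_{i:03d}" for i in range(n)]
    if cfg.nested_selection and selector is None:
        raise ValueError("nested_selection=True requires a selector callable")

    fold_seeds = [int(c.generate_state(1)[0] % (2 ** 31))
                  for c in np.random.SeedSequence(cfg.seed).spawn(n)]
    predictions = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        x_train, y_train = features[mask], labels[mask]
        x_test = features[i:i + 1]
        if cfg.nested_selection:
            cols = list(selector(x_train, y_train))
            if not cols:
                cols = list(range(features.shape[1]))  # degenerate fold: keep all
            x_train, x_test = x_train[:, cols], x_test[:, cols]
        forest = RandomForestClassifier(n_estimators=cfg.n_trees,
                                        max_features=cfg.features_per_split,
                                        random_state=fold_seeds[i])
        forest.fit(x_train, y_train)
        predictions.append(str(forest.predict(x_test)[0]))

    conf = confusion_matrix(labels, predictions, labels=class_order)
    accuracy = 100.0 * np.trace(conf) / n
    folds = [(str(sid), str(t), p)
             for sid, t, p in zip(subject_ids, labels, predictions)]
    return ClassifierResult(float(accuracy), conf, class_order, folds, cfg)
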