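"""Downstream evaluation in the latent space.

The encoder is judged by what a classical classifier can do with its latents:
fit on training-fold latents, score accuracy and macro-F1 on the held-out
fold.  Random Forest with 15 trees is the reference classifier; K-NN, a
decision tree and gradient boosting are available for the classifier
comparison.  A PCA baseline (components covering ≥95% cumulative variance on
the concatenated training matrix, then the same RF) provides the
no-encoder arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .losses import LossWeights
from .omics_data import FoldSplit, MultiOmicsDataset, preprocess_fold

CLASSIFIERS = ("RF", "KNN", "DT", "GBC")


def _make_classifier(name: str, seed: int):
    if name == "RF":
        return RandomForestClassifier(n_estimators=15, random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier()
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if name == "GBC":
        return GradientBoostingClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def metric_accuracy(y_true, y_pred) -> float:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return float(np.mean(y_true == y_pred))


def metric_macro_f1(y_true, y_pred, classes=None) -> float:
    """Unweighted mean of per-class F1.

    A class with no true and no predicted instances contributes F1 = 0 — the
    conservative convention, so the macro average never benefits from a class
    the fold simply lacks (only relevant when ``classes`` is given explicitly).
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    f1s = []
    for c in classes:
        tp = np.sum((y_true == c) & (y_pred == c))
        fp = np.sum((y_true != c) & (y_pred == c))
        fn = np.sum((y_true == c) & (y_pred != c))
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom > 0 else 0.0)
    return float(np.mean(f1s))


@dataclass
class ClassificationReport:
    classifier: str
    accuracy: float
    macro_f1: float
    confusion: np.ndarray = field(repr=False, default=None)
    n_test: int = 0

    def as_row(self) -> dict:
        d = asdict(self)
        d.pop("confusion")
        return d


def classify_latent(z_train, y_train, z_test, y_test, classifier: str = "RF",
                    seed: int = 0) -> ClassificationReport:
    """Fit the chosen classifier on training latents only; score the test fold."""
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training labels contain a single class")
    clf = _make_classifier(classifier, seed)
    clf.fit(np.asarray(z_train), y_train)
    y_pred = clf.predict(np.asarray(z_test))
    classes = np.unique(np.concatenate([np.asarray(y_test), y_train]))
    return ClassificationReport(
        classifier=classifier,
        accuracy=metric_accuracy(y_test, y_pred),
        macro_f1=metric_macro_f1(y_test, y_pred, classes=classes),
        confusion=confusion_matrix(y_test, y_pred, labels=classes),
        n_test=len(y_pred),
    )


def compare_classifiers(z_train, y_train, z_test, y_test, seed: int = 0,
                        classifiers=CLASSIFIERS) -> pd.DataFrame:
    """One row per classifier, in the fixed declaration order."""
    rows = [classify_latent(z_train, y_train, z_test, y_test, c, seed).as_row()
            for c in classifiers]
    return pd.DataFrame(rows)


def pca_baseline(dataset: MultiOmicsDataset, fold: FoldSplit,
                 variance_threshold: float = 0.95, seed: int = 0,
                 classifier: str = "RF") -> ClassificationReport:
    """PCA (fit on the training fold) at a cumulative-variance threshold + RF."""
    if not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance_threshold must lie in (0, 1]")
    processed, _, _ = preprocess_fold(dataset, fold)
    X = np.column_stack([np.asarray(m.values, dtype=float)
                         for m in processed.modalities])
    X_train, X_test = X[fold.train_indices], X[fold.test_indices]
    pca = PCA(random_state=seed)
    pca.fit(X_train)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    n_comp = min(n_comp, len(cum))
    z_train = pca.transform(X_train)[:, :n_comp]
    z_test = pca.transform(X_test)[:, :n_comp]
    rep = classify_latent(z_train, dataset.labels[fold.train_indices],
                          z_test, dataset.labels[fold.test_indices],
                          classifier=classifier, seed=seed)
    rep.classifier = f"PCA({n_comp})+{classifier}"
    return rep


def all_modality_combinations(names) -> list[tuple[str, ...]]:
    return [combo for r in range(1, len(names) + 1)
            for combo in combinations(names, r)]


def modality_combination_experiment(dataset: MultiOmicsDataset, combos, config,
                                    weights: LossWeights | None = None,
                                    encoder_config=None, seeds=(0,),
                                    ) -> pd.DataFrame:
    """Train one encoder per modality subset and score RF latents per seed.

    ``combos="all"`` evaluates every nonempty subset.  Returns one row per
    (combination, seed) with the fold fixed per seed so subsets are compared
    on identical splits.
    """
    from dataclasses import asdict as _asdict

    from .omics_data import make_folds
    from .training import TrainConfig, encode_fold, train

    weights = weights or LossWeights()
    if combos == "all":
        combos = all_modality_combinations(dataset.modality_names())
    rows = []
    for seed in seeds:
        fold = make_folds(dataset, k=5, repeats=1, seed=seed)[0]
        for combo in combos:
            sub = dataset.subset_modalities(list(combo))
            run_cfg = TrainConfig(**{**_asdict(config), "seed": seed})
            state = train(sub, fold, run_cfg, weights, encoder_config)
            rep = classify_latent(
                encode_fold(state, fold.train_indices),
                sub.labels[fold.train_indices],
                encode_fold(state, fold.test_indices),
                sub.labels[fold.test_indices],
                classifier="RF", seed=seed)
            rows.append({"combination": "+".join(combo), "n_modalities": len(combo),
                         "seed": seed, "accuracy": rep.accuracy,
                         "macro_f1": rep.macro_f1})
    return pd.DataFrame(rows)
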