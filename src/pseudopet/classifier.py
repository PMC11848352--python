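"""Multi-branch MLP ensemble and its cross-validation harness.

One small MLP per (modality, tissue-segment) feature vector; each branch
returns class probabilities, the branches of one modality are averaged,
and with several modalities the modality scores are averaged again —
which, with a full branch grid, equals the flat mean over all branches.
Branches standardize features (z-score fit on training folds only) and are
seeded for determinism.

The cross-validation harness splits at the subject level so no subject can
appear on both sides of a fold, and — when a view requires a synthesized
functional volume — trains the synthesis model on that fold's training
subjects only before generating test-subject views.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, StandardScaler

from .features import pair_feature_table
from .phantoms import VolumePair

__all__ = [
    "BranchConfig",
    "EnsemblePrediction",
    "train_branch",
    "predict_ensemble",
    "cross_validate",
]

SEGMENTS = ("GM", "WM", "CSF")

DEFAULT_TASKS = {
    "NC/MCI/AD": ("NC", "MCI", "AD"),
    "NC/MCI": ("NC", "MCI"),
    "MCI/AD": ("MCI", "AD"),
    "NC/AD": ("NC", "AD"),
}


def _l1_normalize_rows(X):
    """Per-subject global-signal normalization: each feature vector becomes
    its regional fractions (L1), removing inter-subject scale differences —
    the usual normalization before comparing regional uptake/volume."""
    X = np.asarray(X, dtype=np.float64)
    norms = np.abs(X).sum(axis=1, keepdims=True)
    return X / np.maximum(norms, 1e-12)


@dataclass(frozen=True)
class BranchConfig:
    """One MLP branch: a single hidden layer over per-subject-normalized,
    z-scored features.  ``lbfgs`` converges reliably at the cohort sizes
    this package targets (tens of training subjects)."""

    hidden: int = 64
    alpha: float = 0.1
    solver: str = "lbfgs"
    max_iter: int = 1000
    normalize_features: bool = True
    early_stopping: bool = False
    seed: int = 0


@dataclass(frozen=True)
class EnsemblePrediction:
    branch_probs: dict  # (modality, segment) -> probability vector
    probs: np.ndarray  # averaged probability vector
    classes: tuple
    predicted_class: str


def train_branch(features: np.ndarray, labels, config: BranchConfig) -> Pipeline:
    """Fit one branch on an (n_subjects, n_features) matrix."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    steps = []
    if config.normalize_features:
        steps.append(("fractions", FunctionTransformer(_l1_normalize_rows)))
    steps += [
        ("scale", StandardScaler()),
        (
            "mlp",
            MLPClassifier(
                hidden_layer_sizes=(config.hidden,),
                alpha=config.alpha,
                solver=config.solver,
                max_iter=config.max_iter,
                early_stopping=config.early_stopping,
                random_state=config.seed,
            ),
        ),
    ]
    clf = Pipeline(steps)
    clf.fit(np.asarray(features, dtype=np.float64), labels)
    return clf


def _check_probs(p: np.ndarray) -> None:
    if np.any(p < -1e-9) or abs(float(p.sum()) - 1.0) > 1e-9:
        raise AssertionError("probability vector must be nonnegative and sum to 1")


def predict_ensemble(branches: dict, features: dict) -> EnsemblePrediction:
    """Average branch probabilities for one subject.

    ``branches`` and ``features`` must share exactly the same
    (modality, segment) keys; branch class orders must agree.
    """
    if not branches:
        raise ValueError("branch set is empty")
    missing = sorted(set(branches) - set(features))
    extra = sorted(set(features) - set(branches))
    if missing or extra:
        raise ValueError(
            f"feature keys do not match branches; missing={missing}, extra={extra}"
        )
    classes = None
    probs = []
    branch_probs = {}
    for key in sorted(branches):
        model = branches[key]
        vec = np.asarray(features[key].values, dtype=np.float64)[None, :]
        p = model.predict_proba(vec)[0]
        # clip tiny negative float noise, renormalize exactly
        p = np.clip(p, 0.0, None)
        p = p / p.sum()
        _check_probs(p)
        cls = tuple(model.classes_)
        if classes is None:
            classes = cls
        elif cls != classes:
            raise ValueError(f"branch class order mismatch: {cls} vs {classes}")
        branch_probs[key] = p
        probs.append(p)
    final = np.mean(probs, axis=0)
    _check_probs(final)
    return EnsemblePrediction(
        branch_probs=branch_probs,
        probs=final,
        classes=classes,
        predicted_class=classes[int(np.argmax(final))],
    )


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    table: pd.DataFrame
    accuracies: dict = field(default_factory=dict)  # (task, view) -> accuracy


def _base_volumes(pair: VolumePair) -> dict:
    return {"structural": pair.structural, "functional": pair.functional}


def cross_validate(
    dataset: list[VolumePair],
    k: int = 5,
    tasks: dict | None = None,
    views: list[tuple] | None = None,
    seed: int = 0,
    branch_config: BranchConfig | None = None,
    fold_synthesizer: Callable | None = None,
) -> CVResult:
    """Subject-level k-fold evaluation of task x view combinations.

    ``views`` are tuples of modality names; names beyond
    ``structural``/``functional`` (e.g. ``functional_synth_two_way``) must
    be produced by ``fold_synthesizer(train_pairs)``, which returns a
    callable ``pair -> {name: volume}`` trained only on that fold's
    training subjects.  Per task and view the result table reports
    accuracy plus per-class precision/recall/F1.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    tasks = dict(tasks) if tasks else dict(DEFAULT_TASKS)
    views = list(views) if views else [("structural",), ("functional",)]
    branch_config = branch_config or BranchConfig()

    synth_names = sorted(
        {m for view in views for m in view}
        - {"structural", "functional"}
    )
    if synth_names and fold_synthesizer is None:
        raise ValueError(
            f"views reference synthesized modalities {synth_names} but no "
            "fold_synthesizer was given"
        )

    # one shared region list so feature vectors align across subjects
    regions = tuple(
        int(r)
        for r in np.unique(
            np.concatenate([np.unique(p.atlas[p.atlas != 0]) for p in dataset])
        )
    )

    rows = []
    accuracies = {}
    for task_name, task_classes in tasks.items():
        subset = [p for p in dataset if p.class_label in task_classes]
        labels = np.array([p.class_label for p in subset])
        for c in task_classes:
            if int((labels == c).sum()) < k:
                raise ValueError(
                    f"task {task_name}: class {c} has fewer than k={k} subjects"
                )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        fold_preds = {view: [] for view in views}
        fold_truth = []
        for train_idx, test_idx in skf.split(np.zeros(len(subset)), labels):
            train_pairs = [subset[i] for i in train_idx]
            test_pairs = [subset[i] for i in test_idx]
            train_ids = {p.subject_id for p in train_pairs}
            test_ids = {p.subject_id for p in test_pairs}
            if train_ids & test_ids:
                raise AssertionError("fold hygiene violated: shared subject ids")

            synth_fn = None
            if synth_names:
                synth_fn = fold_synthesizer(train_pairs)

            def volumes_for(pair):
                vols = _base_volumes(pair)
                if synth_fn is not None:
                    vols.update(synth_fn(pair))
                return vols

            feats_train = [
                pair_feature_table(
                    volumes_for(p), p.atlas, p.segment_masks, p.subject_id,
                    regions=regions,
                )
                for p in train_pairs
            ]
            feats_test = [
                pair_feature_table(
                    volumes_for(p), p.atlas, p.segment_masks, p.subject_id,
                    regions=regions,
                )
                for p in test_pairs
            ]
            y_train = [p.class_label for p in train_pairs]
            fold_truth.extend(p.class_label for p in test_pairs)

            for view in views:
                keys = [(m, s) for m in view for s in SEGMENTS]
                branches = {
                    key: train_branch(
                        np.stack([f[key].values for f in feats_train]),
                        y_train,
                        branch_config,
                    )
                    for key in keys
                }
                for f in feats_test:
                    pred = predict_ensemble(
                        branches, {key: f[key] for key in keys}
                    )
                    fold_preds[view].append(pred.predicted_class)

        truth = np.array(fold_truth)
        for view in views:
            pred = np.array(fold_preds[view])
            acc = float(accuracy_score(truth, pred))
            prec, rec, f1, _ = precision_recall_fscore_support(
                truth, pred, labels=list(task_classes), zero_division=0
            )
            accuracies[(task_name, view)] = acc
            for i, c in enumerate(task_classes):
                rows.append(
                    {
                        "task": task_name,
                        "view": "+".join(view),
                        "class": c,
                        "precision": float(prec[i]),
                        "recall": float(rec[i]),
                        "f1": float(f1[i]),
                        "accuracy": acc,
                    }
                )
    return CVResult(table=pd.DataFrame(rows), accuracies=accuracies)
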