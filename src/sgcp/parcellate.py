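"""Stage II: supervised voxel classification on frozen embeddings.

A small MLP with sigmoid output is fitted by cross-entropy on pooled
(embedding, label) pairs from the training regions; the held-out region's
voxels are then scored, thresholded at 0.5 (no tuning on test folds), and
the positive set is compared to ground truth by Dice. Leave-one-region-out
cross-validation reuses the same frozen embeddings in every fold — only the
classifier is retrained.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .graphdata import RegionGraph, dice_score

__all__ = [
    "ClassifierConfig",
    "ParcellationResult",
    "train_classifier",
    "predict_labels",
    "leave_one_region_out",
    "extract_region",
    "evaluate_report",
]


@dataclasses.dataclass
class ClassifierConfig:
    """Voxel-classifier hyperparameters.

    ``n_layers`` counts all layers including the output (2 = one hidden
    layer, the headline setting; 3 adds a second hidden layer). ``balanced``
    oversamples the minority class to equal frequency; off by default —
    plain cross-entropy on the ~40/60 inside/outside split.
    """

    n_layers: int = 2
    hidden_dim: int = 64
    epochs: int = 300
    learning_rate: float = 1e-3
    seed: int = 0
    decision_threshold: float = 0.5
    balanced: bool = False
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must lie in (0, 1)")


@dataclasses.dataclass
class ParcellationResult:
    """Predicted voxel labels for one region, plus Dice when truth is known."""

    region_id: str
    predicted_labels: np.ndarray
    scores: np.ndarray
    dice: float | None = None
    coords: np.ndarray | None = None

    @property
    def predicted_region(self) -> set[int]:
        return set(np.flatnonzero(self.predicted_labels).tolist())


@dataclasses.dataclass
class _FittedClassifier:
    mlp: MLPClassifier
    scaler: StandardScaler | None

    def scores(self, embeddings: np.ndarray) -> np.ndarray:
        X = np.asarray(embeddings, float)
        if X.shape[1] != self.mlp.n_features_in_ and self.scaler is None:
            raise ValueError(
                f"embedding dim {X.shape[1]} != classifier input {self.mlp.n_features_in_}"
            )
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return self.mlp.predict_proba(X)[:, 1]


def train_classifier(
    embeddings: np.ndarray, labels: np.ndarray, config: ClassifierConfig
) -> _FittedClassifier:
    """Fit the voxel MLP on pooled training-region embeddings.

    The embeddings are frozen inputs — nothing here back-propagates into the
    encoder. Reproducible from ``config.seed``.
    """
    X = np.asarray(embeddings, float)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("embeddings and labels must have matching first dimension")
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class; cannot fit a classifier")
    if config.balanced:
        rng = np.random.default_rng(config.seed)
        n1, n0 = int((y == 1).sum()), int((y == 0).sum())
        minority = 1 if n1 < n0 else 0
        extra = abs(n0 - n1)
        pool = np.flatnonzero(y == minority)
        take = rng.choice(pool, size=extra, replace=True)
        X = np.concatenate([X, X[take]], axis=0)
        y = np.concatenate([y, y[take]])
    scaler = None
    if config.standardize:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    mlp = MLPClassifier(
        hidden_layer_sizes=(config.hidden_dim,) * (config.n_layers - 1),
        activation="relu",
        solver="adam",
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        mlp.fit(X, y)
    return _FittedClassifier(mlp=mlp, scaler=scaler)


def predict_labels(
    classifier: _FittedClassifier, embeddings: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Binary labels (score >= threshold) and the raw sigmoid scores."""
    scores = classifier.scores(embeddings)
    return (scores >= threshold).astype(np.int64), scores


def leave_one_region_out(
    dataset: list[RegionGraph],
    embeddings: list[np.ndarray],
    config: ClassifierConfig,
) -> tuple[list[ParcellationResult], float]:
    """Region-level cross-validation on frozen embeddings.

    For each labelled region: train the classifier on every *other* labelled
    region's pooled (embedding, label) pairs, predict the held-out region's
    voxels, and score the positive set against ground truth by Dice. Regions
    without labels are excluded with a warning. Returns the per-region
    results and the cross-region mean Dice.
    """
    if len(dataset) != len(embeddings):
        raise ValueError("dataset and embeddings length mismatch")
    usable = []
    for g, h in zip(dataset, embeddings):
        if g.labels is None:
            warnings.warn(f"region {g.region_id} has no labels; excluded from CV")
            continue
        if h.shape[0] != g.n_nodes:
            raise ValueError(f"embedding rows != voxels for region {g.region_id}")
        usable.append((g, h))
    if len(usable) < 2:
        raise ValueError("leave-one-region-out needs >= 2 labelled regions")

    results = []
    for k, (g_test, h_test) in enumerate(usable):
        X_tr = np.concatenate([h for j, (_, h) in enumerate(usable) if j != k], axis=0)
        y_tr = np.concatenate(
            [g.labels for j, (g, _) in enumerate(usable) if j != k], axis=0
        )
        clf = train_classifier(X_tr, y_tr, config)
        pred, scores = predict_labels(clf, h_test, config.decision_threshold)
        truth = set(np.flatnonzero(g_test.labels).tolist())
        predicted = set(np.flatnonzero(pred).tolist())
        d = dice_score(predicted, truth) if (predicted or truth) else None
        results.append(
            ParcellationResult(
                region_id=g_test.region_id,
                predicted_labels=pred,
                scores=scores,
                dice=d,
                coords=g_test.coords,
            )
        )
    mean_dice = float(np.mean([r.dice for r in results if r.dice is not None]))
    return results, mean_dice


def _lattice_components(positive: np.ndarray, coords: np.ndarray) -> list[set[int]]:
    """6-connected components of the positive voxel set on its lattice."""
    from scipy import ndimage

    pitch = []
    for ax in range(3):
        u = np.unique(coords[:, ax])
        d = np.diff(u)
        pitch.append(d[d > 0].min() if (d > 0).any() else 1.0)
    ijk = np.round((coords - coords.min(axis=0)) / np.asarray(pitch)).astype(int)
    shape = tuple(ijk.max(axis=0) + 1)
    vol = np.zeros(shape, dtype=bool)
    pos_idx = np.flatnonzero(positive)
    vol[tuple(ijk[pos_idx].T)] = True
    lab, n = ndimage.label(vol, structure=ndimage.generate_binary_structure(3, 1))
    comps: dict[int, set[int]] = {}
    for v in pos_idx:
        c = int(lab[tuple(ijk[v])])
        comps.setdefault(c, set()).add(int(v))
    return sorted(comps.values(), key=len, reverse=True)


def extract_region(result: ParcellationResult, postprocess: bool = False) -> set[int]:
    """The parcellated voxel set: positives verbatim, or (opt-in) only their
    largest 6-connected lattice component."""
    positive = np.asarray(result.predicted_labels) == 1
    if not postprocess or not positive.any():
        return set(np.flatnonzero(positive).tolist())
    if result.coords is None:
        raise ValueError("postprocessing requires voxel coordinates")
    return _lattice_components(positive, np.asarray(result.coords))[0]


def evaluate_report(
    results: list[ParcellationResult], path: str | None = None
) -> pd.DataFrame:
    """Per-region Dice table with a trailing mean row; optionally written as TSV."""
    if not results:
        raise ValueError("no results to report")
    rows = [
        {
            "region_id": r.region_id,
            "n_voxels": len(r.predicted_labels),
            "n_predicted": int(np.sum(r.predicted_labels)),
            "dice": r.dice,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    dices = df["dice"].dropna()
    mean_row = {
        "region_id": "mean",
        "n_voxels": int(df["n_voxels"].sum()),
        "n_predicted": int(df["n_predicted"].sum()),
        "dice": float(dices.mean()) if len(dices) else None,
    }
    df = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
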