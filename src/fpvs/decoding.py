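"""Per-frequency multivariate decoding of condition from epoch spectra.

For each integer frequency from 1 to 47 Hz, the 64 scalp-channel
baseline-corrected amplitudes of every one-second epoch form the feature
vector.  One repetition draws a stratified 60/40 train/test split, fits a
scaler (unit variance) and a 20-component PCA on the training rows only,
selects a ridge penalty for regularised logistic regression by three-fold
cross-validation inside the training set (10 log-spaced values from 1e-3 to
1e3), trains one binary classifier per condition pair, and predicts the
held-out 40% by majority vote (ties broken toward the lowest class index).
The procedure is repeated over independent splits and summarised by the
median test accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler

from .recording import SCALP
from .spectral import AmplitudeSpectrum


@dataclass(frozen=True)
class DecodingParams:
    train_fraction: float = 0.6
    inner_folds: int = 3
    pca_components: int = 20
    penalty_grid: tuple[float, ...] = tuple(np.logspace(-3, 3, 10))
    repeats: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.pca_components < 1 or self.pca_components > 64:
            raise ValueError("pca_components must lie in 1..64")
        if any(c <= 0 for c in self.penalty_grid):
            raise ValueError("penalty grid must be strictly positive")


@dataclass
class DecodingResult:
    frequency: float
    accuracies: np.ndarray      # one test accuracy per repetition
    n_conditions: int

    @property
    def median_accuracy(self) -> float:
        return float(np.median(self.accuracies))

    @property
    def chance_level(self) -> float:
        return 1.0 / self.n_conditions


def feature_table(
    spectra: list[AmplitudeSpectrum], frequency: float
) -> tuple[np.ndarray, np.ndarray]:
    """Epochs x 64 scalp amplitudes at one 1 Hz bin, with condition labels.

    Each spectrum must be a baseline-corrected 1 Hz-resolution epoch
    spectrum; the class label is its ``condition`` attribute, set by
    :func:`fpvs.spectral.epoch_spectra` from the parent segment.
    """
    if not spectra:
        raise ValueError("no epoch spectra given")
    first = spectra[0]
    if first.df != 1.0:
        raise ValueError("feature extraction expects 1 Hz epoch spectra")
    max_f = first.n_bins - 2  # exclude the Nyquist bin
    if not (1 <= frequency <= min(47, max_f)) or frequency != int(frequency):
        raise ValueError(
            f"frequency must be an integer in [1, {min(47, max_f)}], got {frequency}"
        )
    bin_idx = int(frequency)
    scalp = [i for i, role in enumerate(first.channel_roles) if role == SCALP]
    rows, labels = [], []
    for spec in spectra:
        if not spec.baseline_corrected:
            raise ValueError("epoch spectra must be baseline-corrected")
        rows.append(spec.amps[scalp, bin_idx])
        labels.append(getattr(spec, "condition", ""))
    return np.asarray(rows), np.asarray(labels)


def _fit_transformers(X: np.ndarray, n_components: int):
    scaler = StandardScaler().fit(X)
    n_comp = min(n_components, X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full").fit(scaler.transform(X))
    return scaler, pca


def _fit_ovo(X: np.ndarray, y: np.ndarray, classes: np.ndarray, c_value: float):
    """One ridge-penalised logistic model per class pair."""
    models = []
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            mask = (y == classes[i]) | (y == classes[j])
            # default penalty is ridge (L2); C is the inverse penalty strength
            clf = LogisticRegression(C=c_value, max_iter=1000)
            clf.fit(X[mask], y[mask])
            models.append((i, j, clf))
    return models


def _predict_ovo(models, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    votes = np.zeros((X.shape[0], len(classes)), dtype=int)
    for i, j, clf in models:
        pred = clf.predict(X)
        votes[:, i] += pred == classes[i]
        votes[:, j] += pred == classes[j]
    # argmax returns the first maximum: ties break toward the lowest index
    return classes[np.argmax(votes, axis=1)]


def _ovo_accuracy(models, X: np.ndarray, y: np.ndarray, classes: np.ndarray) -> float:
    return float(np.mean(_predict_ovo(models, X, classes) == y))


def _select_penalty(
    X: np.ndarray, y: np.ndarray, classes: np.ndarray, params: DecodingParams,
    seed: int,
) -> float:
    """Inner 3-fold CV over the penalty grid; transformers refit per fold."""
    cv = StratifiedKFold(n_splits=params.inner_folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(params.penalty_grid))
    for train_idx, val_idx in cv.split(X, y):
        scaler, pca = _fit_transformers(X[train_idx], params.pca_components)
        X_tr = pca.transform(scaler.transform(X[train_idx]))
        X_val = pca.transform(scaler.transform(X[val_idx]))
        for k, c_value in enumerate(params.penalty_grid):
            models = _fit_ovo(X_tr, y[train_idx], classes, c_value)
            scores[k] += _ovo_accuracy(models, X_val, y[val_idx], classes)
    return params.penalty_grid[int(np.argmax(scores))]


def classify_once(
    features: np.ndarray, labels: np.ndarray, params: DecodingParams, split_seed: int
) -> float:
    """One stratified 60/40 split -> penalty selection -> test accuracy."""
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("classification requires at least 2 classes")
    X_tr, X_te, y_tr, y_te = train_test_split(
        features,
        labels,
        train_size=params.train_fraction,
        stratify=labels,
        random_state=split_seed % (2**32 - 1),
    )
    if len(np.unique(y_tr)) < len(classes) or len(np.unique(y_te)) < len(classes):
        raise ValueError("a class is absent from one side of the split")
    best_c = _select_penalty(X_tr, y_tr, classes, params, seed=split_seed % (2**31 - 1))
    scaler, pca = _fit_transformers(X_tr, params.pca_components)
    models = _fit_ovo(pca.transform(scaler.transform(X_tr)), y_tr, classes, best_c)
    return _ovo_accuracy(models, pca.transform(scaler.transform(X_te)), y_te, classes)


def decode_frequency(
    features: np.ndarray,
    labels: np.ndarray,
    params: DecodingParams,
    frequency: float,
) -> DecodingResult:
    """Repeated random-split decoding of one frequency bin."""
    seeds = np.random.SeedSequence(
        (params.master_seed, int(frequency))
    ).generate_state(params.repeats)
    accuracies = np.array(
        [classify_once(features, labels, params, int(s)) for s in seeds]
    )
    return DecodingResult(
        frequency=frequency,
        accuracies=accuracies,
        n_conditions=len(np.unique(labels)),
    )


def decode_sweep(
    spectra: list[AmplitudeSpectrum],
    params: DecodingParams,
    frequencies: tuple[int, ...] = tuple(range(1, 48)),
) -> list[DecodingResult]:
    """Per-frequency decoding results over the requested 1 Hz bins."""
    results = []
    for frequency in frequencies:
        features, labels = feature_table(spectra, frequency)
        results.append(decode_frequency(features, labels, params, frequency))
    return results
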