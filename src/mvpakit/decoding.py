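"""Time-resolved classification.

One classifier is trained per timepoint under seeded stratified k-fold
cross-validation; standardization and dimensionality reduction are re-fit on
the training rows of every fold. Multimodal fusion concatenates unit-variance
channel blocks of trial-matched epochs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import sklearn
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import RidgeClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import collapse as clps
from .containers import EpochsSet, PAIR_ID_NONE
from .dimreduction import (
    ReducerSpec,
    apply_standardizer,
    fit_standardizer,
    pca_reduce,
    univariate_select_channels,
)

__all__ = [
    "ClassifierSpec",
    "PipelineConfig",
    "AccuracyCurve",
    "make_classifier",
    "timepoint_decode",
    "decode_timecourse",
    "fuse_modalities",
]


@dataclass
class ClassifierSpec:
    """Decoder choice and its (deliberately plain) parameters.

    ``lda``: SVD solver, no priors, no shrinkage. ``ridge``: regression on
    +/-1 targets with the stochastic-average-gradient solver, alpha = 1,
    decision at the sign of the output (ties -> class 0). ``svm_sigmoid``:
    sigmoid-kernel SVC with shrinking and no class weights.
    """

    kind: str = "lda"  # {lda, ridge, svm_sigmoid}
    tolerance: float = 1e-4
    ridge_alpha: float = 1.0
    ridge_solver: str = "sag"
    lda_solver: str = "svd"
    svm_shrinking: bool = True
    svm_gamma: str | float = "scale"
    svm_coef0: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("lda", "ridge", "svm_sigmoid"):
            raise ValueError("kind must be one of {'lda', 'ridge', 'svm_sigmoid'}")
        if self.ridge_alpha <= 0:
            raise ValueError("ridge_alpha must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def make_classifier(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator described by ``spec``."""
    spec.validate()
    if spec.kind == "lda":
        return LinearDiscriminantAnalysis(
            solver=spec.lda_solver, priors=None, shrinkage=None, tol=spec.tolerance
        )
    if spec.kind == "ridge":
        # regression on {-1, +1} targets; predict = sign, ties -> class 0
        return RidgeClassifier(
            alpha=spec.ridge_alpha,
            solver=spec.ridge_solver,
            tol=spec.tolerance,
            random_state=spec.seed,
        )
    return SVC(
        kernel="sigmoid",
        tol=spec.tolerance,
        shrinking=spec.svm_shrinking,
        gamma=spec.svm_gamma,
        coef0=spec.svm_coef0,
        class_weight=None,
        random_state=spec.seed,
    )


@dataclass
class PipelineConfig:
    """A complete, hashable description of one decoding variant."""

    collapse: clps.CollapseConfig = field(default_factory=clps.CollapseConfig)
    reducer: ReducerSpec = field(default_factory=ReducerSpec)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    cv_folds: int = 10
    chance_level: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.collapse, dict):
            self.collapse = clps.CollapseConfig(**self.collapse)
        if isinstance(self.reducer, dict):
            self.reducer = ReducerSpec(**self.reducer)
        if isinstance(self.classifier, dict):
            self.classifier = ClassifierSpec(**self.classifier)

    def validate(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        self.collapse.validate()
        self.reducer.validate()
        self.classifier.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class AccuracyCurve:
    """Per-subject decoding accuracy over time."""

    subject_id: str
    times: np.ndarray
    accuracy: np.ndarray
    per_fold: np.ndarray  # folds x timepoints
    config_hash: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        self.per_fold = np.asarray(self.per_fold, dtype=float)
        if self.accuracy.min() < 0 or self.accuracy.max() > 1:
            raise ValueError("accuracy must lie in [0, 1]")
        if np.abs(self.per_fold.mean(axis=0) - self.accuracy).max() > 1e-12:
            raise ValueError("accuracy must equal the fold mean")


def _stratified_splits(
    y: np.ndarray, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros((len(y), 1)), y))
    for _, test_idx in splits:
        if len(np.unique(y[test_idx])) < 2:
            raise RuntimeError("stratification produced a fold missing a class")
    return splits


def _lda_svd_predict(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, tol: float
) -> np.ndarray:
    """Binary LDA with the SVD solver (no priors given, no shrinkage).

    Same algorithm as scikit-learn's ``solver='svd'`` path, specialised to
    two classes for the per-timepoint hot loop: whiten the within-class
    scatter through an SVD with tolerance-based rank truncation, then score
    classes by the Gaussian discriminant in the whitened space. Prediction
    equality with scikit-learn is asserted in the test suite.
    """
    n, _ = Xtr.shape
    classes = np.array([0, 1])
    means = np.stack([Xtr[ytr == c].mean(axis=0) for c in classes])
    priors = np.array([(ytr == c).mean() for c in classes])
    xbar = priors @ means
    Xc = Xtr - means[ytr]
    std = Xc.std(axis=0)
    std[std == 0] = 1.0
    fac = 1.0 / (n - 2)
    X1 = np.sqrt(fac) * (Xc / std)
    # within-class whitening via the feature-space Gram eigendecomposition
    w, V = np.linalg.eigh(X1.T @ X1)
    S = np.sqrt(np.maximum(w[::-1], 0.0))
    Vt = V[:, ::-1].T
    rank = int((S > tol).sum())
    if rank == 0:
        return np.full(len(Xte), classes[np.argmax(priors)])
    scalings = (Vt[:rank] / std).T / S[:rank]
    # between-class step: for two classes both weighted centred means are
    # parallel, so the between-class scatter is rank one and its leading
    # direction is the whitened mean difference
    d = (means[1] - means[0]) @ scalings
    norm = np.sqrt((d**2).sum())
    if norm == 0:
        return np.full(len(Xte), classes[np.argmax(priors)])
    W = scalings @ (d / norm)[:, None]
    m = (means - xbar) @ W  # class means in the discriminant space
    T = (Xte - xbar) @ W
    scores = T @ m.T - 0.5 * (m**2).sum(axis=1) + np.log(priors)
    return classes[np.argmax(scores, axis=1)]


def _fit_score_fold(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    reducer: ReducerSpec,
    clf_spec: ClassifierSpec,
) -> float:
    params = fit_standardizer(X[train_idx])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-SD features are legitimate here
        Xtr = apply_standardizer(params, X[train_idx])
        Xte = apply_standardizer(params, X[test_idx])
    if reducer.method == "pca":
        Xtr, Xte, _ = pca_reduce(Xtr, Xte, reducer.pca_var_threshold)
    if clf_spec.kind == "lda":
        pred = _lda_svd_predict(Xtr, y[train_idx], Xte, clf_spec.tolerance)
        return float(np.mean(pred == y[test_idx]))
    clf = make_classifier(clf_spec)
    clf.fit(Xtr, y[train_idx])
    return float(np.mean(clf.predict(Xte) == y[test_idx]))


def timepoint_decode(
    X: np.ndarray, y: np.ndarray, config: PipelineConfig
) -> np.ndarray:
    """Cross-validated accuracies for one timepoint's feature matrix.

    Returns the ``config.cv_folds`` held-out fold accuracies. Within each
    fold, standardization and (optionally) PCA are fit on the training rows
    only, then the configured classifier is trained and scored.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    splits = _stratified_splits(y, config.cv_folds, config.seed)
    with sklearn.config_context(assume_finite=True):
        return np.array(
            [
                _fit_score_fold(X, y, tr, te, config.reducer, config.classifier)
                for tr, te in splits
            ]
        )


def condition_epochs(E: EpochsSet, config: PipelineConfig) -> EpochsSet:
    """Apply the pipeline's conditioning: baseline, flagging, balancing,
    time collapse, pseudo-trial averaging — in that order."""
    cc = config.collapse
    cc.validate(E.sfreq)
    out = clps.baseline_correct(E, cc.baseline_interval)
    if cc.zscore_threshold is not None:
        out, _ = clps.flag_bad_epochs(out, cc.zscore_threshold)
    out = clps.balance_epochs(out, seed=cc.seed)
    out = clps.apply_time_collapse(out, cc)
    if cc.avg_group_size > 1:
        out = clps.average_trials(out, cc.avg_group_size, seed=cc.seed)
    return out


def decode_timecourse(
    E: EpochsSet, config: PipelineConfig, precollapsed: bool = False
) -> AccuracyCurve:
    """Full per-subject decoding curve for one pipeline variant.

    Conditions the epochs per ``config.collapse`` (skipped when
    ``precollapsed``), resolves the univariate channel mask if requested,
    then runs :func:`timepoint_decode` at every timepoint. Deterministic
    given ``config.seed``.
    """
    config.validate()
    out = E if precollapsed else condition_epochs(E, config)

    reducer = config.reducer
    if reducer.method == "univariate":
        mask = univariate_select_channels(out, reducer)
        if not mask.any():
            warnings.warn("empty channel selection; falling back to all channels")
            mask = np.ones(out.n_channels, dtype=bool)
        out = out.select_channels(mask)
        fold_reducer = replace(reducer, method="none")
    else:
        fold_reducer = reducer

    y = out.labels
    splits = _stratified_splits(y, config.cv_folds, config.seed)
    per_fold = np.empty((config.cv_folds, out.n_times))
    data = out.data
    with sklearn.config_context(assume_finite=True):
        for t in range(out.n_times):
            X = data[:, :, t]
            for k, (tr, te) in enumerate(splits):
                per_fold[k, t] = _fit_score_fold(
                    X, y, tr, te, fold_reducer, config.classifier
                )
    return AccuracyCurve(
        subject_id=out.subject_id,
        times=out.times,
        accuracy=per_fold.mean(axis=0),
        per_fold=per_fold,
        config_hash=config.config_hash(),
    )


def fuse_modalities(E_meg: EpochsSet, E_eeg: EpochsSet, seed: int = 0) -> EpochsSet:
    """Concatenate trial-matched, unit-variance channel blocks of two modalities.

    Trials are matched across modalities by ``(pair_id, label)``, class
    counts equalised, every channel scaled to unit whole-epoch variance, and
    the channel axes concatenated into a ``fused`` set.
    """
    if E_meg.n_times != E_eeg.n_times or np.abs(E_meg.times - E_eeg.times).max() > 1e-9:
        raise ValueError("time grids differ; resample before fusing")
    keys_meg = {
        (p, l): i
        for i, (p, l) in enumerate(zip(E_meg.pair_ids, E_meg.labels))
        if p != PAIR_ID_NONE
    }
    keys_eeg = {
        (p, l): i
        for i, (p, l) in enumerate(zip(E_eeg.pair_ids, E_eeg.labels))
        if p != PAIR_ID_NONE
    }
    common = sorted(set(keys_meg) & set(keys_eeg))
    if not common:
        raise ValueError("no common (pair_id, label) trials across modalities")
    meg = E_meg.select_trials([keys_meg[k] for k in common])
    eeg = E_eeg.select_trials([keys_eeg[k] for k in common])
    # equalise class counts with a shared, seeded selection
    rng = np.random.default_rng(seed)
    n0, n1 = meg.class_counts()
    if n0 != n1:
        minority = min(n0, n1)
        keep = []
        for lab in (0, 1):
            idx = np.flatnonzero(meg.labels == lab)
            if len(idx) > minority:
                idx = np.sort(rng.choice(idx, size=minority, replace=False))
            keep.append(idx)
        keep = np.sort(np.concatenate(keep))
        meg, eeg = meg.select_trials(keep), eeg.select_trials(keep)

    def unit_variance(data: np.ndarray) -> np.ndarray:
        sd = data.std(axis=(0, 2), keepdims=True)
        sd[sd == 0] = 1.0
        return data / sd

    data = np.concatenate([unit_variance(meg.data), unit_variance(eeg.data)], axis=1)
    return EpochsSet(
        data=data,
        labels=meg.labels,
        pair_ids=meg.pair_ids,
        times=meg.times,
        sfreq=meg.sfreq,
        channel_ids=list(meg.channel_ids) + list(eeg.channel_ids),
        modality="fused",
        subject_id=meg.subject_id,
    )
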