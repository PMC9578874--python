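"""Two-layer stacked ensemble fusing facial and voice features.

Layer 1 holds five base learners: logistic regression, a CART decision
tree and a linear SVM on the five facial features (blinks, ABT, ABTI,
PERCLOS, FOM), plus an LSTM and a CNN on the MFCC matrix of the paired
audio clip. Layer 2 is a logistic regression trained on the base
learners' stratified out-of-fold probabilities, so the meta-learner never
sees a probability produced by a model that was trained on that sample.

The ensemble is exposed statsmodels-style: :class:`FVStackingModel` is
built from data, ``fit()`` returns a :class:`StackingResults` carrying the
fitted learners, the fold bookkeeping, the meta coefficients and
``summary()``/``predict()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from . import metrics as _metrics
from .errors import InvalidArgumentError, InvalidDataError, InvalidSpecError
from .features import FacialFeatureVector, facial_features
from .mfcc import MfccConfig, mfcc
from .nn import Conv2D, Dense, Flatten, LSTMClassifier, MaxPool2D, ReLU, Sequential

logger = logging.getLogger(__name__)

BASE_LEARNER_NAMES = ("lr", "cart", "linear_svm", "lstm", "cnn")
FACIAL_FEATURE_NAMES = FacialFeatureVector.FIELD_NAMES


@dataclass(frozen=True)
class BaseLearnerSpec:
    name: Literal["lr", "cart", "linear_svm", "lstm", "cnn"]
    modality: Literal["facial", "voice"] = None  # type: ignore[assignment]
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in BASE_LEARNER_NAMES:
            raise InvalidSpecError(f"unknown base learner {self.name!r}")
        expected = "facial" if self.name in ("lr", "cart", "linear_svm") else "voice"
        if self.modality is None:
            object.__setattr__(self, "modality", expected)
        elif self.modality != expected:
            raise InvalidSpecError(
                f"{self.name} is a {expected} learner, got modality={self.modality!r}"
            )


DEFAULT_BASE_SPECS = tuple(BaseLearnerSpec(name) for name in BASE_LEARNER_NAMES)


@dataclass(frozen=True)
class ClipSample:
    facial: np.ndarray  # the 5 facial features
    voice: np.ndarray  # MFCC coefficients x frames
    label: int | None
    clip_id: str = ""


def _check_binary_labels(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise InvalidDataError("labels must contain both classes")


# ---------------------------------------------------------------------------
# Base learners (uniform fit/predict_proba API; probability of fatigue)


class _SkFacialLearner:
    """Facial learner backed by a scikit-learn classifier."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_SkFacialLearner":
        _check_binary_labels(y)
        self.estimator.fit(x, y)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(x)[:, 1]


class _LinearSvmLearner:
    """Linear SVM with a logistic link fitted on the training margins."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.svm = LinearSVC(C=C, random_state=seed)
        self.platt = LogisticRegression()

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_LinearSvmLearner":
        _check_binary_labels(y)
        self.svm.fit(x, y)
        margins = self.svm.decision_function(x).reshape(-1, 1)
        self.platt.fit(margins, y)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        margins = self.svm.decision_function(x).reshape(-1, 1)
        return self.platt.predict_proba(margins)[:, 1]


class _VoiceCnnLearner:
    """CNN over the MFCC matrix treated as a 1-channel image.

    Three conv+pool blocks, one dense layer, sigmoid output.
    """

    def __init__(self, seed: int = 0, epochs: int = 4, lr: float = 1e-3,
                 batch_size: int = 32, filters: tuple[int, int, int] = (8, 16, 32)):
        self.seed = seed
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.filters = filters
        self.net: Sequential | None = None

    def _build(self, rows: int, cols: int) -> Sequential:
        rng = np.random.default_rng(self.seed)
        layers = []
        in_ch = 1
        for f in self.filters:
            layers += [Conv2D(in_ch, f, 3, rng), ReLU(), MaxPool2D(2)]
            rows, cols = rows // 2, cols // 2
            in_ch = f
        layers += [Flatten(), Dense(rows * cols * in_ch, 32, rng), ReLU(),
                   Dense(32, 1, rng)]
        return Sequential(layers)

    def fit(self, v: np.ndarray, y: np.ndarray) -> "_VoiceCnnLearner":
        _check_binary_labels(y)
        self.net = self._build(v.shape[1], v.shape[2])
        self.net.fit(v[..., None], y, epochs=self.epochs, batch_size=self.batch_size,
                     lr=self.lr, seed=self.seed)
        return self

    def predict_proba(self, v: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(v[..., None])


class _VoiceLstmLearner:
    """LSTM over the MFCC frame sequence; final hidden state -> sigmoid.

    The frame axis is subsampled with a fixed stride before the
    recurrence to keep backprop-through-time cheap.
    """

    def __init__(self, seed: int = 0, hidden_size: int = 32, epochs: int = 8,
                 lr: float = 3e-3, batch_size: int = 64, time_stride: int = 4):
        self.seed = seed
        self.hidden_size = hidden_size
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.time_stride = time_stride
        self.net: LSTMClassifier | None = None

    def _sequences(self, v: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(v[:, :, :: self.time_stride].transpose(0, 2, 1))

    def fit(self, v: np.ndarray, y: np.ndarray) -> "_VoiceLstmLearner":
        _check_binary_labels(y)
        x = self._sequences(v)
        self.net = LSTMClassifier(n_features=x.shape[2], hidden_size=self.hidden_size,
                                  seed=self.seed)
        self.net.fit(x, y, epochs=self.epochs, batch_size=self.batch_size,
                     lr=self.lr, seed=self.seed)
        return self

    def predict_proba(self, v: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._sequences(v))


def make_base_learner(spec: BaseLearnerSpec, seed: int = 0):
    """Instantiate an unfitted base learner for a spec."""
    seed = int(seed) % (2**31)  # keep derived seeds inside sklearn's range
    hp = dict(spec.hyperparameters)
    if spec.name == "lr":
        return _SkFacialLearner(LogisticRegression(max_iter=1000, **hp))
    if spec.name == "cart":
        hp.setdefault("criterion", "gini")
        return _SkFacialLearner(DecisionTreeClassifier(random_state=seed, **hp))
    if spec.name == "linear_svm":
        return _LinearSvmLearner(C=hp.pop("C", 1.0), seed=seed)
    if spec.name == "cnn":
        return _VoiceCnnLearner(seed=seed, **hp)
    if spec.name == "lstm":
        return _VoiceLstmLearner(seed=seed, **hp)
    raise InvalidSpecError(spec.name)


def fit_base(
    spec: BaseLearnerSpec,
    facial: np.ndarray,
    voice: np.ndarray | None,
    labels: np.ndarray,
    seed: int = 0,
):
    """Fit a single base learner on its modality's (already scaled) inputs."""
    learner = make_base_learner(spec, seed)
    y = np.asarray(labels).reshape(-1)
    if spec.modality == "facial":
        return learner.fit(np.asarray(facial, dtype=float), y)
    if voice is None:
        raise InvalidSpecError(f"{spec.name} requires voice (MFCC) input")
    return learner.fit(np.asarray(voice, dtype=np.float32), y)


# ---------------------------------------------------------------------------
# Scalers


@dataclass
class _Standardizer:
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray, axis) -> "_Standardizer":
        mean = x.mean(axis=axis, keepdims=True)
        sd = x.std(axis=axis, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(mean=mean, sd=sd)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


# ---------------------------------------------------------------------------
# The Model / Results pair


def corpus_to_arrays(
    clips: Iterable, mfcc_config: MfccConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Facial matrix (n, 5), voice tensor (n, coeffs, frames), labels, ids
    from a sequence of synthetic (or equivalently structured) clips."""
    mfcc_config = mfcc_config or MfccConfig()
    facial_rows, voice_mats, labels, ids = [], [], [], []
    for clip in clips:
        fv = facial_features(clip.eye_queue, clip.mouth_queue)
        facial_rows.append(fv.as_array())
        voice_mats.append(mfcc(clip.audio, mfcc_config).coefficients)
        labels.append(clip.label)
        ids.append(clip.clip_id)
    return (
        np.asarray(facial_rows, dtype=float),
        np.asarray(voice_mats, dtype=np.float32),
        np.asarray(labels, dtype=int),
        ids,
    )


class FVStackingModel:
    """Two-layer stacking ensemble built from paired facial/voice data.

    Parameters
    ----------
    facial : (n, 5) array of clip-level facial features.
    voice : (n, coeffs, frames) MFCC tensor.
    labels : (n,) binary labels, 1 = fatigued.
    base_specs : the five base-learner specs (defaults to LR, CART,
        linear SVM, LSTM, CNN).
    """

    def __init__(
        self,
        facial: np.ndarray,
        voice: np.ndarray,
        labels: np.ndarray,
        clip_ids: Sequence[str] | None = None,
        base_specs: Sequence[BaseLearnerSpec] = DEFAULT_BASE_SPECS,
    ):
        self.facial = np.asarray(facial, dtype=float)
        self.voice = np.asarray(voice, dtype=np.float32)
        self.labels = np.asarray(labels, dtype=int).reshape(-1)
        n = self.labels.size
        if self.facial.shape != (n, 5):
            raise InvalidArgumentError(
                f"facial must be (n, 5); got {self.facial.shape} for n={n}"
            )
        if self.voice.ndim != 3 or self.voice.shape[0] != n:
            raise InvalidArgumentError("voice must be (n, coeffs, frames)")
        if not np.isin(self.labels, (0, 1)).all():
            raise InvalidArgumentError("labels must be binary 0/1")
        _check_binary_labels(self.labels)
        self.clip_ids = list(clip_ids) if clip_ids is not None else [
            f"clip{i:05d}" for i in range(n)
        ]
        self.base_specs = tuple(base_specs)
        if len(self.base_specs) != 5:
            raise InvalidSpecError("the ensemble uses exactly five base learners")

    @classmethod
    def from_corpus(cls, clips: Iterable, mfcc_config: MfccConfig | None = None,
                    **kwargs) -> "FVStackingModel":
        facial, voice, labels, ids = corpus_to_arrays(clips, mfcc_config)
        return cls(facial, voice, labels, clip_ids=ids, **kwargs)

    @classmethod
    def from_dataframe(cls, features: pd.DataFrame, voice: np.ndarray,
                       label_col: str = "label", **kwargs) -> "FVStackingModel":
        facial = features[list(FACIAL_FEATURE_NAMES)].to_numpy(dtype=float)
        ids = (features["clip_id"].tolist() if "clip_id" in features
               else None)
        return cls(facial, voice, features[label_col].to_numpy(), clip_ids=ids,
                   **kwargs)

    # -- fitting ----------------------------------------------------------

    def _make_folds(self, k_folds: int, seed: int) -> np.ndarray:
        """Stratified fold assignment; refolds (new seed) if a training
        side ever degenerates to one class, erroring after 5 attempts."""
        y = self.labels
        for attempt in range(5):
            skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                                  random_state=seed + attempt)
            fold_of = np.empty(y.size, dtype=int)
            ok = True
            for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(y.size), y)):
                fold_of[test_idx] = fold
                if np.unique(y[train_idx]).size < 2:
                    ok = False
            if ok:
                if attempt:
                    logger.warning("refolded %d time(s) to avoid a single-class fold",
                                   attempt)
                return fold_of
        raise InvalidDataError("could not build folds with both classes after 5 attempts")

    def fit(self, k_folds: int = 5, seed: int = 0,
            folds: np.ndarray | None = None) -> "StackingResults":
        """Out-of-fold stacking fit.

        Each base learner is trained once per fold on the complementary
        folds to score the held-out fold, building the leak-free (n, 5)
        meta-feature matrix; the meta logistic regression is fitted on it,
        and the base learners are refitted on all data for deployment.
        ``folds`` overrides the stratified assignment with an explicit
        per-sample fold index.
        """
        y = self.labels
        n = y.size
        if folds is not None:
            fold_of = np.asarray(folds, dtype=int).reshape(-1)
            if fold_of.size != n:
                raise InvalidArgumentError("folds must assign every sample")
            k_folds = int(fold_of.max()) + 1
        else:
            if n < 2 * k_folds:
                raise InvalidDataError(f"need n >= 2*k_folds samples (n={n}, k={k_folds})")
            fold_of = self._make_folds(k_folds, seed)

        facial_scaler = _Standardizer.fit(self.facial, axis=0)
        voice_scaler = _Standardizer.fit(self.voice, axis=(0, 2))
        xf = facial_scaler.transform(self.facial)
        xv = voice_scaler.transform(self.voice).astype(np.float32)

        oof = np.full((n, 5), np.nan)
        fold_train_indices: dict[int, np.ndarray] = {}
        for fold in range(k_folds):
            test_mask = fold_of == fold
            train_idx = np.flatnonzero(~test_mask)
            test_idx = np.flatnonzero(test_mask)
            fold_train_indices[fold] = train_idx
            # Fold-local scaling would be stricter still, but the scaler is
            # a fixed affine map; global statistics keep deployment simple.
            for j, spec in enumerate(self.base_specs):
                learner = make_base_learner(spec, seed=seed * 31 + fold)
                if spec.modality == "facial":
                    learner.fit(xf[train_idx], y[train_idx])
                    oof[test_idx, j] = learner.predict_proba(xf[test_idx])
                else:
                    learner.fit(xv[train_idx], y[train_idx])
                    oof[test_idx, j] = learner.predict_proba(xv[test_idx])

        meta = LogisticRegression(max_iter=1000)
        meta.fit(oof, y)

        deployed = []
        for spec in self.base_specs:
            learner = make_base_learner(spec, seed=seed)
            if spec.modality == "facial":
                learner.fit(xf, y)
            else:
                learner.fit(xv, y)
            deployed.append(learner)

        return StackingResults(
            model=self,
            base_learners=tuple(deployed),
            meta=meta,
            oof_probs=oof,
            fold_of=fold_of,
            fold_train_indices=fold_train_indices,
            facial_scaler=facial_scaler,
            voice_scaler=voice_scaler,
            k_folds=k_folds,
            seed=seed,
        )


@dataclass
class StackingResults:
    """Fitted two-layer ensemble plus its training bookkeeping."""

    model: FVStackingModel
    base_learners: tuple
    meta: LogisticRegression
    oof_probs: np.ndarray
    fold_of: np.ndarray
    fold_train_indices: dict
    facial_scaler: _Standardizer
    voice_scaler: _Standardizer
    k_folds: int
    seed: int

    @property
    def meta_coefficients(self) -> np.ndarray:
        return self.meta.coef_.reshape(-1)

    @property
    def meta_intercept(self) -> float:
        return float(self.meta.intercept_[0])

    def base_probabilities(self, facial: np.ndarray, voice: np.ndarray) -> np.ndarray:
        facial = np.atleast_2d(np.asarray(facial, dtype=float))
        voice = np.asarray(voice, dtype=np.float32)
        if voice.ndim == 2:
            voice = voice[None]
        xf = self.facial_scaler.transform(facial)
        xv = self.voice_scaler.transform(voice).astype(np.float32)
        cols = []
        for spec, learner in zip(self.model.base_specs, self.base_learners):
            cols.append(learner.predict_proba(xf if spec.modality == "facial" else xv))
        return np.column_stack(cols)

    def predict_proba(self, facial: np.ndarray, voice: np.ndarray) -> np.ndarray:
        return self.meta.predict_proba(self.base_probabilities(facial, voice))[:, 1]

    def predict(self, facial: np.ndarray, voice: np.ndarray,
                threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
        """(probability, hard label) at the given decision threshold."""
        probs = self.predict_proba(facial, voice)
        return probs, (probs >= threshold).astype(int)

    def meta_probability_from_base(self, base_probs: np.ndarray) -> np.ndarray:
        """Meta probability for externally supplied base probabilities."""
        return self.meta.predict_proba(np.atleast_2d(base_probs))[:, 1]

    def verify_no_leakage(self) -> bool:
        """Every sample's out-of-fold probability must come from learners
        trained without that sample."""
        for i, fold in enumerate(self.fold_of):
            if i in self.fold_train_indices[int(fold)]:
                raise AssertionError(f"sample {i} leaked into its own fold-{fold} training set")
        if np.isnan(self.oof_probs).any():
            raise AssertionError("some samples never received an out-of-fold probability")
        return True

    def oof_base_accuracies(self) -> dict[str, float]:
        y = self.model.labels
        return {
            spec.name: float(np.mean((self.oof_probs[:, j] >= 0.5).astype(int) == y))
            for j, spec in enumerate(self.model.base_specs)
        }

    def summary(self) -> str:
        lines = [
            "FV-Stacking results",
            "===================",
            f"n samples: {self.model.labels.size}   folds: {self.k_folds}   seed: {self.seed}",
            "",
            "Base learners (out-of-fold accuracy / meta weight):",
        ]
        coefs = self.meta_coefficients
        for j, (spec, acc) in enumerate(self.oof_base_accuracies().items()):
            lines.append(f"  {spec:<11} {acc:6.3f}   {coefs[j]:+8.3f}")
        lines.append(f"  intercept   {'':>6}   {self.meta_intercept:+8.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Feature-subset baseline harness


def _baseline_classifier(name: str, seed: int):
    if name == "lr":
        return LogisticRegression(max_iter=1000)
    if name == "svm":
        return _LinearSvmLearner(seed=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    raise InvalidArgumentError(f"unknown baseline classifier {name!r}")


def baseline_compare(
    facial: np.ndarray,
    labels: np.ndarray,
    feature_subsets: Sequence[Sequence[str]],
    classifiers: Sequence[str] = ("lr", "svm", "knn"),
    seed: int = 0,
    test_size: float = 0.25,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Evaluate facial-feature-subset baselines on one shared split.

    Each row is a (subset, classifier) pair with held-out recall,
    precision, accuracy, f1 and AUC. ``split`` may supply explicit
    (train_idx, test_idx) so external rows (e.g. the stacked model) can be
    scored on the identical held-out set.
    """
    facial = np.asarray(facial, dtype=float)
    y = np.asarray(labels).reshape(-1)
    _check_binary_labels(y)
    for subset in feature_subsets:
        if len(subset) == 0:
            raise InvalidArgumentError("feature subsets must be nonempty")
        for name in subset:
            if name not in FACIAL_FEATURE_NAMES:
                raise InvalidArgumentError(f"unknown facial feature {name!r}")
    if split is None:
        train_idx, test_idx = train_test_split(
            np.arange(y.size), test_size=test_size, random_state=seed, stratify=y
        )
    else:
        train_idx, test_idx = split

    scaler = _Standardizer.fit(facial[train_idx], axis=0)
    xtr_full = scaler.transform(facial[train_idx])
    xte_full = scaler.transform(facial[test_idx])

    rows = []
    for subset in feature_subsets:
        cols = [FACIAL_FEATURE_NAMES.index(name) for name in subset]
        for clf_name in classifiers:
            clf = _baseline_classifier(clf_name, seed)
            if isinstance(clf, _LinearSvmLearner):
                clf.fit(xtr_full[:, cols], y[train_idx])
                probs = clf.predict_proba(xte_full[:, cols])
            else:
                clf.fit(xtr_full[:, cols], y[train_idx])
                probs = clf.predict_proba(xte_full[:, cols])[:, 1]
            preds = (probs >= 0.5).astype(int)
            m = _metrics.classification_metrics(
                _metrics.confusion(y[test_idx], preds)
            )
            auc = _metrics.roc_auc(y[test_idx], probs).auc
            rows.append(
                {
                    "subset": "+".join(subset),
                    "classifier": clf_name,
                    "recall": m["recall"],
                    "precision": m["precision"],
                    "accuracy": m["accuracy"],
                    "f1": m["f1"],
                    "auc": auc,
                }
            )
    return pd.DataFrame(rows)


DEFAULT_FEATURE_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("perclos", "blinks"),
    ("abt", "perclos", "blinks"),
    ("perclos", "fom"),
    ("blinks", "abt", "abti", "perclos", "fom"),
)
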