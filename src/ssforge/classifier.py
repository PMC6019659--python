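"""SVM combiner over the three candidate probabilities.

Training uses scikit-learn (RBF-kernel SVC with 5-fold grid search over C and
gamma after per-feature min-max scaling). The fitted machine is frozen into
plain arrays — support vectors, dual coefficients, intercept, kernel width —
and prediction evaluates the RBF decision function from those arrays, so a
model saved to JSON reproduces its predictions bit-identically after loading.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .errors import ContractError, ParseError, SchemaVersionError

MODEL_SCHEMA_VERSION = 1

POSITIVE, NEGATIVE = "positive", "negative"

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass
class TrainingSet:
    """Feature triples (p_geom, p_rmsd, p_delta_s) with positive/negative labels."""

    features: np.ndarray  # (n, 3)
    labels: np.ndarray    # (n,) of {"positive", "negative"}

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.features.ndim != 2 or self.features.shape[1] != 3:
            raise ContractError("features must be (n, 3) triples")
        if len(self.features) != len(self.labels):
            raise ContractError("features and labels must have equal length")


@dataclass
class TrainConfig:
    seed: int = 42
    n_folds: int = 5
    c_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID


@dataclass
class ClassifierModel:
    """Frozen RBF-SVM: everything needed for deterministic prediction."""

    support_vectors: np.ndarray   # scaled, (m, 3)
    dual_coef: np.ndarray         # (m,), signed alpha_i * y_i
    intercept: float
    gamma: float
    C: float
    scale_min: np.ndarray         # per-feature min of the training data
    scale_range: np.ndarray       # per-feature (max - min), zeros replaced by 1
    metadata: dict = field(default_factory=dict)

    def _scale(self, triples: np.ndarray) -> np.ndarray:
        x = (np.asarray(triples, dtype=float) - self.scale_min) / self.scale_range
        if np.any((x < -1e-9) | (x > 1 + 1e-9)):
            warnings.warn("feature outside the training range; clipping to [0, 1]",
                          stacklevel=3)
            x = np.clip(x, 0.0, 1.0)
        return x

    def decision_values(self, triples: np.ndarray) -> np.ndarray:
        """Signed margins; positive means the positive (disulfide) class."""
        x = self._scale(np.atleast_2d(triples))
        if not np.all(np.isfinite(x)):
            raise ContractError("feature triple must be finite")
        sq = ((x[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * sq) @ self.dual_coef + self.intercept

    def predict_one(self, triple) -> tuple[str, float]:
        margin = float(self.decision_values(np.asarray(triple))[0])
        return (POSITIVE if margin > 0 else NEGATIVE), margin


def train(ts: TrainingSet, config: TrainConfig | None = None) -> ClassifierModel:
    """Fit the RBF-SVM with reproducible 5-fold hyperparameter search.

    Requires at least 5 examples of each class. The min-max scaling constants
    are estimated on the training data and stored in the model.
    """
    config = config or TrainConfig()
    y = np.where(ts.labels == POSITIVE, 1, -1)
    classes, counts = np.unique(ts.labels, return_counts=True)
    if len(classes) < 2:
        raise ContractError("training set must contain both classes")
    if counts.min() < config.n_folds:
        raise ContractError(
            f"need >= {config.n_folds} examples per class, got {dict(zip(classes, counts))}"
        )
    lo = ts.features.min(axis=0)
    rng_ = ts.features.max(axis=0) - lo
    rng_[rng_ == 0] = 1.0
    x = (ts.features - lo) / rng_

    cv = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    search = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": list(config.c_grid), "gamma": list(config.gamma_grid)},
        cv=cv, scoring="accuracy",
    )
    search.fit(x, y)
    svc: SVC = search.best_estimator_
    n_pos = int((y == 1).sum())
    model = ClassifierModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        gamma=float(svc._gamma),
        C=float(svc.C),
        scale_min=lo,
        scale_range=rng_,
        metadata={
            "n": int(len(y)),
            "n_positive": n_pos,
            "n_negative": int(len(y) - n_pos),
            "cv_accuracy": float(search.best_score_),
            "seed": config.seed,
        },
    )
    return model


def cross_val_accuracy(ts: TrainingSet, config: TrainConfig | None = None) -> float:
    """Unbiased k-fold CV accuracy with hyperparameter search nested inside.

    The inner grid search selects (C, gamma) on each training split only, so
    the outer estimate is not inflated by selection — on label-shuffled data
    it stays at chance level.
    """
    from sklearn.model_selection import cross_val_score

    config = config or TrainConfig()
    y = np.where(ts.labels == POSITIVE, 1, -1)
    lo = ts.features.min(axis=0)
    rng_ = ts.features.max(axis=0) - lo
    rng_[rng_ == 0] = 1.0
    x = (ts.features - lo) / rng_
    inner = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    outer = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                            random_state=config.seed + 1)
    search = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": list(config.c_grid), "gamma": list(config.gamma_grid)},
        cv=inner, scoring="accuracy",
    )
    return float(cross_val_score(search, x, y, cv=outer, scoring="accuracy").mean())


def training_accuracy(model: ClassifierModel, ts: TrainingSet) -> float:
    margins = model.decision_values(ts.features)
    pred = np.where(margins > 0, POSITIVE, NEGATIVE)
    return float((pred == ts.labels).mean())


# ---------------------------------------------------------------------------
# persistence


def save_model(model: ClassifierModel, path) -> None:
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "kernel": "rbf",
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
        "gamma": model.gamma,
        "C": model.C,
        "scale_min": model.scale_min.tolist(),
        "scale_range": model.scale_range.tolist(),
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> ClassifierModel:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"corrupt model file {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"model schema version {version!r} not supported (expected {MODEL_SCHEMA_VERSION})"
        )
    return ClassifierModel(
        support_vectors=np.asarray(payload["support_vectors"]),
        dual_coef=np.asarray(payload["dual_coef"]),
        intercept=payload["intercept"],
        gamma=payload["gamma"],
        C=payload["C"],
        scale_min=np.asarray(payload["scale_min"]),
        scale_range=np.asarray(payload["scale_range"]),
        metadata=payload["metadata"],
    )


# ---------------------------------------------------------------------------
# training-set construction from a corpus


def build_training_set(corpus, library, rng: np.random.Generator,
                       scoring_config=None) -> TrainingSet:
    """Positives: native disulfides scored by the pipeline; negatives: an
    equal number of random non-disulfide pairs from the same structures."""
    from .scoring import ScoringConfig, score_pair
    from .structure_io import detect_native_disulfides, make_pair

    scoring_config = scoring_config or ScoringConfig()
    feats, labels = [], []
    for st in corpus:
        natives = detect_native_disulfides(st)
        native_keys = {frozenset((p.res_a, p.res_b)) for p in natives}
        keys = [r.key for r in st.residues()]
        for pair in natives:
            rec = score_pair(st, pair, library, scoring_config)
            feats.append(rec.scores.as_features())
            labels.append(POSITIVE)
        # sample as many negatives as positives from this structure
        n_needed, attempts = len(natives), 0
        while n_needed > 0 and attempts < 200:
            attempts += 1
            i, j = rng.choice(len(keys), size=2, replace=False)
            if frozenset((keys[i], keys[j])) in native_keys:
                continue
            pair = make_pair(st, keys[i], keys[j])
            try:
                rec = score_pair(st, pair, library, scoring_config)
            except Exception:
                continue
            feats.append(rec.scores.as_features())
            labels.append(NEGATIVE)
            n_needed -= 1
    return TrainingSet(np.asarray(feats), np.asarray(labels, dtype=object))
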