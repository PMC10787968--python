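"""Movement-intention classifiers on stacked RMS samples.

Three decoders are compared: logistic regression and an RBF support-vector
machine, each preceded by PCA keeping components that explain >= 95% of the
training variance and tuned by 5-fold cross-validated grid search
(C, and gamma for the SVM, log-spaced over 1e-4..1e4); and a fully
connected neural network (hidden 1000/500 with batch normalization, ReLU
and 20% dropout, softmax output) trained with label-smoothing cross
entropy (p = 0.9), Adam and a one-cycle schedule with early stopping.

The module follows a model/results split: :class:`MovementDecoder` holds
the data and configuration; ``fit()`` returns :class:`DecoderResults`,
which predicts, evaluates and summarizes.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from ._mlp import MLPNet, MLPSpec, TrainLog, train_mlp
from .simulate import CLASSES

# sklearn 1.9 deprecates SVC(probability=True); Platt-calibrated
# probabilities are still the behaviour we want for the online decoder
warnings.filterwarnings(
    "ignore", message="The `probability` parameter", category=FutureWarning
)

_MODEL_KINDS = ("lr", "svm", "mlp")
_FORMAT_VERSION = 1


@dataclass(frozen=True)
class GridSearchSpec:
    """Log-spaced hyperparameter grid with 5-fold cross-validation."""

    c_grid: tuple = tuple(np.logspace(-4, 4, 9))
    gamma_grid: tuple = tuple(np.logspace(-4, 4, 9))
    folds: int = 5

    def __post_init__(self):
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.folds < 2:
            raise ValueError("need at least 2 CV folds")


def hard_labels(probs: np.ndarray) -> np.ndarray:
    """Argmax with ties broken toward the lowest class index (Rest first)."""
    return np.argmax(probs, axis=1)


class MovementDecoder:
    """Classifier specification bound to training samples.

    Parameters
    ----------
    X : (n_samples, n_features) normalized stacked RMS samples.
    y : class indices into ``classes``.
    kind : 'lr', 'svm' or 'mlp'.
    classes : class labels; defaults to the labels present in ``y``
        mapped through the canonical 13-class list.
    """

    def __init__(self, X, y, kind="mlp", classes=None,
                 grid_spec: GridSearchSpec | None = None,
                 mlp_spec: MLPSpec | None = None):
        kind = kind.lower()
        if kind not in _MODEL_KINDS:
            raise ValueError(f"unknown model kind {kind!r}; choose from {_MODEL_KINDS}")
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.int64)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        present = np.unique(self.y)
        if present.size < 2:
            raise ValueError("training data must contain at least two classes")
        self.kind = kind
        self.classes = tuple(classes) if classes is not None else tuple(
            CLASSES[i] for i in present
        )
        self.class_indices = present
        self.grid_spec = grid_spec or GridSearchSpec()
        self.mlp_spec = mlp_spec or MLPSpec()

    def fit(self, seed: int = 0) -> "DecoderResults":
        if self.kind == "mlp":
            return self._fit_mlp(seed)
        return self._fit_linear(seed)

    # --- PCA + grid-searched sklearn estimators ------------------------
    def _fit_linear(self, seed: int) -> "DecoderResults":
        spec = self.grid_spec
        if self.X.shape[0] < spec.folds:
            raise ValueError("fewer samples than CV folds")
        pca = PCA(n_components=0.95, svd_solver="full", random_state=seed)
        Z = pca.fit_transform(self.X)
        # map original labels to 0..K-1 for the estimator
        remap = {c: i for i, c in enumerate(self.class_indices)}
        y = np.array([remap[v] for v in self.y])
        cv = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=seed)

        if self.kind == "lr":
            grid = [{"C": float(c)} for c in spec.c_grid]
            make = lambda p, prob: LogisticRegression(
                C=p["C"], max_iter=2000, random_state=seed
            )
        else:
            grid = [
                {"C": float(c), "gamma": float(g)}
                for c in spec.c_grid for g in spec.gamma_grid
            ]
            # probability calibration (Platt) only on the final refit: the
            # grid is scored on hard accuracy, which does not need it
            make = lambda p, prob: SVC(
                C=p["C"], gamma=p["gamma"], kernel="rbf", probability=prob,
                random_state=seed,
            )

        scores = []
        for p in grid:
            s = cross_val_score(make(p, False), Z, y, cv=cv, n_jobs=None)
            scores.append(float(s.mean()))
        # best mean CV accuracy; ties -> smallest C, then smallest gamma
        order = sorted(
            range(len(grid)),
            key=lambda i: (-scores[i], grid[i]["C"], grid[i].get("gamma", 0.0)),
        )
        best = grid[order[0]]
        est = make(best, True).fit(Z, y)
        return DecoderResults(
            model=self, kind=self.kind, pca=pca, estimator=est,
            best_params=best, cv_scores=dict(zip(map(str, grid), scores)),
            seed=seed,
        )

    # --- neural network -------------------------------------------------
    def _fit_mlp(self, seed: int) -> "DecoderResults":
        remap = {c: i for i, c in enumerate(self.class_indices)}
        y = np.array([remap[v] for v in self.y])
        net, log = train_mlp(self.X, y, len(self.classes), self.mlp_spec, seed=seed)
        return DecoderResults(model=self, kind="mlp", net=net, train_log=log, seed=seed)


@dataclass
class DecoderResults:
    """Fitted decoder: prediction, evaluation, persistence, summary."""

    model: MovementDecoder
    kind: str
    seed: int
    pca: PCA | None = None
    estimator: object | None = None
    net: MLPNet | None = None
    train_log: TrainLog | None = None
    best_params: dict = field(default_factory=dict)
    cv_scores: dict = field(default_factory=dict)

    @property
    def classes(self) -> tuple:
        return self.model.classes

    @property
    def class_indices(self) -> np.ndarray:
        return self.model.class_indices

    def predict_proba(self, X) -> np.ndarray:
        """Per-sample class probabilities over the training class set."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.model.X.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape} does not match training "
                f"dimension {self.model.X.shape[1]}"
            )
        if self.kind == "mlp":
            return self.net.predict_proba(X)
        return self.estimator.predict_proba(self.pca.transform(X))

    def predict(self, X) -> np.ndarray:
        """Hard labels as indices into the *global* class list."""
        local = hard_labels(self.predict_proba(X))
        return self.class_indices[local]

    def evaluate(self, X, y_true, schedule=None, **kw):
        from .metrics import evaluate_predictions

        return evaluate_predictions(self.predict(X), np.asarray(y_true), schedule, **kw)

    def summary(self) -> str:
        lines = [
            "Movement decoder results",
            "=" * 32,
            f"model kind       : {self.kind.upper()}",
            f"classes          : {len(self.classes)}",
            f"training samples : {self.model.X.shape[0]}",
            f"feature dim      : {self.model.X.shape[1]}",
            f"seed             : {self.seed}",
        ]
        if self.kind in ("lr", "svm"):
            lines.append(f"PCA components   : {self.pca.n_components_} "
                         f"({self.pca.explained_variance_ratio_.sum():.3f} var)")
            lines.append(f"best hyperparams : {self.best_params}")
        else:
            n = self.net.n_parameters
            lines.append(f"parameters       : {n}")
            if self.train_log and self.train_log.val_loss:
                lines.append(f"best epoch       : {self.train_log.best_epoch}"
                             f" (val loss {min(self.train_log.val_loss):.4f})")
        return "\n".join(lines)

    # --- persistence ----------------------------------------------------
    def save(self, path) -> None:
        """Write a self-contained ``.npz`` bundle (JSON meta + arrays)."""
        meta = {
            "format_version": _FORMAT_VERSION,
            "kind": self.kind,
            "classes": list(self.classes),
            "class_indices": self.class_indices.tolist(),
            "n_features": int(self.model.X.shape[1]),
            "seed": self.seed,
            "best_params": {k: float(v) for k, v in self.best_params.items()},
        }
        arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        if self.kind == "mlp":
            arrays.update(self.net.state_arrays())
        else:
            buf = _io.BytesIO()
            joblib.dump({"pca": self.pca, "estimator": self.estimator}, buf)
            arrays["sklearn_payload"] = np.frombuffer(buf.getvalue(), dtype=np.uint8)
        np.savez(path, **arrays)


def load_model(path) -> DecoderResults:
    """Load a bundle written by :meth:`DecoderResults.save`."""
    import zipfile

    try:
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
        meta = json.loads(bytes(arrays.pop("meta")).decode())
        if meta.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {meta.get('format_version')}")
    except (KeyError, json.JSONDecodeError, OSError, ValueError, zipfile.BadZipFile) as e:
        raise ValueError(f"corrupt or incompatible model file {path}: {e}") from e

    kind = meta["kind"]
    n_feat = meta["n_features"]
    idx = np.asarray(meta["class_indices"], dtype=np.int64)
    # rebuild a minimal model shell carrying dims and classes
    shell = MovementDecoder.__new__(MovementDecoder)
    shell.kind = kind
    shell.classes = tuple(meta["classes"])
    shell.class_indices = idx
    shell.X = np.empty((0, n_feat))
    shell.y = np.empty(0, dtype=np.int64)

    res = DecoderResults(model=shell, kind=kind, seed=meta["seed"],
                         best_params=meta.get("best_params", {}))
    if kind == "mlp":
        net = MLPNet(n_feat, len(shell.classes), MLPSpec(), seed=0)
        net.load_state_arrays(arrays)
        res.net = net
    else:
        payload = joblib.load(_io.BytesIO(bytes(arrays["sklearn_payload"])))
        res.pca, res.estimator = payload["pca"], payload["estimator"]
    return res


# --- functional wrappers ------------------------------------------------

def fit_linear(X, y, kind="lr", grid_spec=None, seed=0) -> DecoderResults:
    """PCA + grid-searched LR or SVM, refit on all training data."""
    return MovementDecoder(X, y, kind=kind, grid_spec=grid_spec).fit(seed)


def fit_mlp(X, y, mlp_spec=None, seed=0) -> DecoderResults:
    """The neural network under the full training recipe."""
    return MovementDecoder(X, y, kind="mlp", mlp_spec=mlp_spec).fit(seed)


def predict_proba(results: DecoderResults, X) -> np.ndarray:
    return results.predict_proba(X)


def export_model(results: DecoderResults, path) -> None:
    results.save(path)
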