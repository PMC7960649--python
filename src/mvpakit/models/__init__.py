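"""Declarative model specifications and the classical / deep backends.

Two backends share one contract: every trained model produces a per-example,
per-class score matrix, and the categorical decision is winner-take-all over
those scores.  The classical backend offers a linear SVM (one-vs-rest over
binary machines) and SMLR (sparse multinomial logistic regression, authored
here); the deep backend is a numpy sequential-network engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .deep import BuildError, LayerSpec, SequentialNet, build_network, leaky_relu
from .smlr import SMLRResult, smlr_fit, smlr_objective, softmax_scores

__all__ = [
    "ModelSpec",
    "LayerSpec",
    "TrainedModel",
    "BuildError",
    "build_model",
    "train",
    "predict_scores",
    "classify_wta",
    "save_model",
    "load_model",
    "smlr_fit",
    "smlr_objective",
    "softmax_scores",
    "SMLRResult",
    "SequentialNet",
    "leaky_relu",
]

CLASSICAL_ALGORITHMS = ("svm", "smlr")
BACKENDS = ("classical", "deep")


@dataclass
class ModelSpec:
    """Declarative classifier description.

    For ``backend="classical"``: ``algorithm`` is "svm" (linear kernel,
    C defaulting to 1) or "smlr" (lambda, max_iter, tol).  For
    ``backend="deep"``: an ordered ``layers`` list plus ``optimizer``
    (sgd: lr/momentum/nesterov, or adam: lr) and ``training``
    (epochs, batch_size, seed) settings.
    """

    backend: str = "classical"
    algorithm: str = "smlr"
    hyperparams: dict = field(default_factory=dict)
    layers: list[LayerSpec] = field(default_factory=list)
    optimizer: dict = field(default_factory=lambda: {"kind": "sgd"})
    training: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}; choose from {BACKENDS}")
        if self.backend == "classical" and self.algorithm not in CLASSICAL_ALGORITHMS:
            raise ValueError(
                f"unknown classical algorithm {self.algorithm!r}; "
                f"choose from {CLASSICAL_ALGORITHMS}"
            )
        if self.backend == "deep" and not self.layers:
            raise ValueError("deep backend requires a non-empty layer list")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        backend = d.pop("backend", "classical")
        if backend == "deep":
            layers = [LayerSpec.from_dict(ls) for ls in d.pop("layers", [])]
            return cls(
                backend="deep",
                layers=layers,
                optimizer=d.pop("optimizer", {"kind": "sgd"}),
                training=d.pop("training", {}),
            )
        algorithm = d.pop("algorithm", "smlr")
        return cls(backend="classical", algorithm=algorithm, hyperparams=d)


@dataclass
class TrainedModel:
    """A trained realization of a :class:`ModelSpec`."""

    kind: str  # "svm" | "smlr" | "deep"
    impl: object
    n_classes: int
    input_shape: tuple
    history: dict | None = None
    converged: bool = True


class _SVMOvR:
    """Linear-kernel SVM, multiclass by one-vs-rest over binary machines.

    Per-class scores are the binary machines' decision values (distances to
    their hyperplanes, unnormalized).
    """

    def __init__(self, C: float = 1.0):
        self.C = float(C)
        self.kernel = "linear"

    def fit(self, X, y, n_classes):
        from sklearn.svm import SVC

        self.machines = []
        for c in range(n_classes):
            clf = SVC(kernel="linear", C=self.C)
            clf.fit(X, (np.asarray(y) == c).astype(int))
            self.machines.append(clf)
        return self

    def decision_values(self, X):
        return np.column_stack([m.decision_function(X) for m in self.machines])

    def weight_tables(self):
        W = np.vstack([m.coef_.ravel() for m in self.machines])
        b = np.array([m.intercept_[0] for m in self.machines])
        return W, b


class _LinearScorer:
    """Reloaded linear model: decision values X @ W.T + b (used after load)."""

    def __init__(self, W, b):
        self.W, self.b = W, b

    def decision_values(self, X):
        return np.asarray(X, dtype=float) @ self.W.T + self.b


def _flatten2d(X):
    X = np.asarray(X, dtype=float)
    return X.reshape(X.shape[0], -1)


def build_model(spec: ModelSpec, input_shape, n_classes: int):
    """Instantiate an untrained model for the given example shape and class count.

    Classical models consume flattened 2-D data (flattening is applied
    internally when needed); deep models consume full-rank examples and the
    layer chain is shape-checked here, naming the offending layer on error.
    """
    input_shape = tuple(input_shape)
    n_classes = int(n_classes)
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if spec.backend == "classical":
        if spec.algorithm == "svm":
            return ("svm", _SVMOvR(C=spec.hyperparams.get("C", 1.0)), input_shape, n_classes)
        hp = spec.hyperparams
        cfg = {
            "lam": hp.get("lambda", hp.get("lam", 0.1)),
            "max_iter": hp.get("max_iter", 2000),
            "tol": hp.get("tol", 1e-9),
        }
        return ("smlr", cfg, input_shape, n_classes)
    tr = spec.training
    net = build_network(
        spec.layers,
        input_shape,
        n_classes,
        optimizer=spec.optimizer,
        epochs=tr.get("epochs", 50),
        batch_size=tr.get("batch_size", 32),
        seed=tr.get("seed", 0),
    )
    return ("deep", net, input_shape, n_classes)


def train(model, X, y, X_val=None, y_val=None, seed: int | None = None) -> TrainedModel:
    """Train an untrained model (from :func:`build_model`) on integer labels 0..K-1."""
    kind, impl, input_shape, n_classes = model
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class; nothing to learn")
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError(f"labels must be integers in 0..{n_classes - 1}")
    if X.shape[1:] != input_shape:
        raise ValueError(f"X feature shape {X.shape[1:]} != model input shape {input_shape}")
    if kind == "svm":
        impl.fit(_flatten2d(X), y, n_classes)
        return TrainedModel("svm", impl, n_classes, input_shape)
    if kind == "smlr":
        res = smlr_fit(_flatten2d(X), y, lam=impl["lam"],
                       max_iter=impl["max_iter"], tol=impl["tol"])
        return TrainedModel("smlr", res, n_classes, input_shape, converged=res.converged)
    if seed is not None:
        impl.seed = int(seed)
        impl.build()  # re-initialize with the per-iteration seed
    Xv = _coerce_val(X_val)
    impl.fit(X, y, Xv, None if y_val is None else np.asarray(y_val, dtype=int))
    return TrainedModel("deep", impl, n_classes, input_shape, history=impl.history)


def _coerce_val(X_val):
    if X_val is None:
        return None
    X_val = np.asarray(X_val, dtype=float)
    return X_val if len(X_val) else None


def predict_scores(tm: TrainedModel, X) -> np.ndarray:
    """Per-example per-class scores, shape (n, K).

    Deep and SMLR scores are softmax probabilities (rows sum to 1); SVM
    scores are the one-vs-rest decision values, deliberately unnormalized.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1:] != tm.input_shape:
        raise ValueError(
            f"X feature shape {X.shape[1:]} != model input shape {tm.input_shape}"
        )
    if tm.kind == "svm":
        return tm.impl.decision_values(_flatten2d(X))
    if tm.kind == "smlr":
        return softmax_scores(tm.impl.W, _flatten2d(X))
    return tm.impl.predict_scores(X)


def classify_wta(scores: np.ndarray) -> np.ndarray:
    """Winner-take-all decision: argmax per row, ties broken toward the
    lowest class index."""
    scores = np.asarray(scores)
    if scores.size == 0 or scores.ndim != 2:
        raise ValueError("scores must be a non-empty (n, K) matrix")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite values")
    return scores.argmax(axis=1)


# ---------------------------------------------------------------------------
# Serialization: one .npz per model (architecture/metadata JSON + weights)
# ---------------------------------------------------------------------------


def save_model(tm: TrainedModel, path: str | Path) -> Path:
    path = Path(path)
    meta = {
        "kind": tm.kind,
        "n_classes": tm.n_classes,
        "input_shape": list(tm.input_shape),
    }
    arrays: dict[str, np.ndarray] = {}
    if tm.kind == "svm":
        W, b = tm.impl.weight_tables()
        arrays = {"W": W, "b": b}
        meta["C"] = tm.impl.C
    elif tm.kind == "smlr":
        arrays = {"W": tm.impl.W}
        meta["objective"] = tm.impl.objective
        meta["converged"] = bool(tm.impl.converged)
    else:
        net: SequentialNet = tm.impl
        arrays = net.weight_arrays()
        meta["layers"] = [
            {"kind": ls.kind, "params": ls.params, "activation": ls.activation}
            for ls in net.layer_specs
        ]
        meta["optimizer"] = net.optimizer_spec
        meta["training"] = {
            "epochs": net.epochs,
            "batch_size": net.batch_size,
            "seed": net.seed,
        }
    np.savez(path, _meta=np.array(json.dumps(meta)), **arrays)
    return path


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["_meta"]))
        arrays = {k: npz[k] for k in npz.files if k != "_meta"}
    kind = meta["kind"]
    input_shape = tuple(meta["input_shape"])
    K = meta["n_classes"]
    if kind == "svm":
        return TrainedModel("svm", _LinearScorer(arrays["W"], arrays["b"]), K, input_shape)
    if kind == "smlr":
        res = SMLRResult(W=arrays["W"], objective=meta["objective"], n_iter=0,
                         converged=meta["converged"])
        return TrainedModel("smlr", res, K, input_shape, converged=res.converged)
    layers = [
        LayerSpec(kind=d["kind"], params=d["params"], activation=d["activation"])
        for d in meta["layers"]
    ]
    tr = meta["training"]
    net = build_network(layers, input_shape, K, optimizer=meta["optimizer"],
                        epochs=tr["epochs"], batch_size=tr["batch_size"], seed=tr["seed"])
    net.set_weight_arrays(arrays)
    return TrainedModel("deep", net, K, input_shape)
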