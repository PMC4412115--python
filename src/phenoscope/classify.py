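"""Phenotype classifier: one-hidden-layer network, RPROP + GA training.

A small feed-forward network (hue-histogram + brightness inputs, one sigmoid
hidden layer, three sigmoid outputs with one-hot targets) is trained by
resilient backpropagation (iRPROP-, sign-based per-weight step adaptation).
Whenever the training misclassification rate stalls — relative change below
1% over a window of epochs — a genetic-algorithm phase perturbs the weights
(population seeded from the current network, elitism preserves the best
individual) and RPROP resumes from the best individual found.  Training
stops when the misclassification rate reaches the target (0 by default).

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``predict_proba``, ``get_params`` / ``set_params``) and composes with
sklearn model selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_is_fitted

from .features import FeatureConfig
from .imgen import CLASS_LABELS

__all__ = [
    "PhenotypeNetClassifier",
    "TrainConfig",
    "train",
    "save_model",
    "load_model",
    "FingerprintMismatchError",
]

_FORMAT = "phenoscope-net"
_VERSION = 1


class FingerprintMismatchError(ValueError):
    """Feature convention of the model differs from the extractor's."""


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule parameters (see module docstring for the schedule).

    ``stall_threshold`` is the relative change in misclassification rate over
    ``stall_window`` epochs below which the GA engages; ``target_error`` is
    the training misclassification rate at which training stops.
    """

    hidden_size: int = 10
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta_init: float = 0.1
    delta_max: float = 50.0
    delta_min: float = 1e-6
    stall_threshold: float = 0.01
    stall_window: int = 20
    ga_population: int = 30
    ga_sigma: float = 0.2
    ga_elites: int = 2
    ga_generations: int = 25
    target_error: float = 0.0
    max_rounds: int = 2000
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_error < 1:
            raise ValueError("target_error must lie in [0, 1)")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class PhenotypeNetClassifier(ClassifierMixin, BaseEstimator):
    """One-hidden-layer sigmoid network trained by RPROP with a GA fallback.

    Parameters mirror :class:`TrainConfig`.  Fitted attributes:

    - ``classes_`` : class labels in prediction order (ties in the output
      activations resolve to the earliest class).
    - ``coef_hidden_``, ``intercept_hidden_``, ``coef_output_``,
      ``intercept_output_`` : layer weights.
    - ``n_epochs_`` : RPROP epochs run; ``converged_`` : whether the target
      error was reached; ``history_`` : per-epoch log (epoch, phase,
      train_error).
    - ``feature_fingerprint_`` : feature convention the model was trained
      under, if a ``feature_config`` was supplied.
    """

    def __init__(
        self,
        hidden_size: int = 10,
        eta_plus: float = 1.2,
        eta_minus: float = 0.5,
        delta_init: float = 0.1,
        delta_max: float = 50.0,
        delta_min: float = 1e-6,
        stall_threshold: float = 0.01,
        stall_window: int = 20,
        ga_population: int = 30,
        ga_sigma: float = 0.2,
        ga_elites: int = 2,
        ga_generations: int = 25,
        target_error: float = 0.0,
        max_rounds: int = 2000,
        feature_config: FeatureConfig | None = None,
        random_state: int | None = None,
    ):
        self.hidden_size = hidden_size
        self.eta_plus = eta_plus
        self.eta_minus = eta_minus
        self.delta_init = delta_init
        self.delta_max = delta_max
        self.delta_min = delta_min
        self.stall_threshold = stall_threshold
        self.stall_window = stall_window
        self.ga_population = ga_population
        self.ga_sigma = ga_sigma
        self.ga_elites = ga_elites
        self.ga_generations = ga_generations
        self.target_error = target_error
        self.max_rounds = max_rounds
        self.feature_config = feature_config
        self.random_state = random_state

    # ---------------------------------------------------------------- fit

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if not 0 <= self.target_error < 1:
            raise ValueError("target_error must lie in [0, 1)")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")

        present = set(np.unique(y).tolist())
        if present <= set(CLASS_LABELS):
            missing = [c for c in CLASS_LABELS if c not in present]
            if missing:
                raise ValueError(f"classes absent from the training labels: {missing}")
            self.classes_ = np.array(CLASS_LABELS, dtype=object)
        else:
            if len(present) < 2:
                raise ValueError("training needs at least two classes")
            self.classes_ = np.unique(y)

        if self.feature_config is not None:
            if X.shape[1] != self.feature_config.n_features:
                raise ValueError(
                    f"X has {X.shape[1]} features but the feature config "
                    f"defines {self.feature_config.n_features}"
                )
            self.feature_fingerprint_ = self.feature_config.fingerprint()

        self.n_features_in_ = X.shape[1]
        class_index = {c: i for i, c in enumerate(self.classes_)}
        targets = np.zeros((len(y), len(self.classes_)))
        targets[np.arange(len(y)), [class_index[v] for v in y]] = 1.0

        rng = np.random.default_rng(self.random_state)
        shapes = [
            (self.n_features_in_, self.hidden_size),
            (self.hidden_size,),
            (self.hidden_size, len(self.classes_)),
            (len(self.classes_),),
        ]
        wvec = rng.uniform(-0.5, 0.5, size=sum(int(np.prod(s)) for s in shapes))
        self._shapes = shapes

        history: list[tuple[int, str, float]] = []
        err_trace: list[float] = []
        delta = np.full_like(wvec, self.delta_init)
        prev_grad = np.zeros_like(wvec)
        cooldown = 0  # epochs since the last GA phase

        epoch = 0
        err = self._error_rate(wvec, X, targets)
        while epoch < self.max_rounds:
            grad = self._gradient(wvec, X, targets)
            sign = np.sign(prev_grad) * np.sign(grad)
            delta = np.where(
                sign > 0,
                np.minimum(delta * self.eta_plus, self.delta_max),
                np.where(sign < 0, np.maximum(delta * self.eta_minus, self.delta_min), delta),
            )
            grad = np.where(sign < 0, 0.0, grad)  # iRPROP-: forget flipped gradients
            wvec = wvec - np.sign(grad) * delta
            prev_grad = grad

            epoch += 1
            cooldown += 1
            err = self._error_rate(wvec, X, targets)
            err_trace.append(err)
            history.append((epoch, "rprop", err))
            if err <= self.target_error:
                break
            if (
                cooldown >= self.stall_window
                and len(err_trace) > self.stall_window
                and self._stalled(err_trace)
            ):
                wvec, err = self._ga_phase(wvec, X, targets, rng)
                err_trace.append(err)
                history.append((epoch, "ga", err))
                delta = np.full_like(wvec, self.delta_init)
                prev_grad = np.zeros_like(wvec)
                cooldown = 0
                if err <= self.target_error:
                    break

        self._set_weights(wvec)
        self.n_epochs_ = epoch
        self.train_error_ = err
        self.converged_ = err <= self.target_error
        self.history_ = pd.DataFrame(history, columns=["epoch", "phase", "train_error"])
        if not self.converged_:
            warnings.warn(
                f"training stopped at misclassification rate {err:.4f} "
                f"after {epoch} epochs without reaching the target",
                ConvergenceWarning,
            )
        return self

    def _stalled(self, err_trace: list[float]) -> bool:
        prev = err_trace[-1 - self.stall_window]
        cur = err_trace[-1]
        return abs(prev - cur) < self.stall_threshold * max(prev, 1e-12)

    # --------------------------------------------------------- network math

    def _unpack(self, wvec: np.ndarray):
        out, pos = [], 0
        for s in self._shapes:
            n = int(np.prod(s))
            out.append(wvec[pos : pos + n].reshape(s))
            pos += n
        return out

    def _set_weights(self, wvec: np.ndarray) -> None:
        w1, b1, w2, b2 = self._unpack(wvec)
        self.coef_hidden_ = w1
        self.intercept_hidden_ = b1
        self.coef_output_ = w2
        self.intercept_output_ = b2

    def _forward(self, wvec: np.ndarray, X: np.ndarray):
        w1, b1, w2, b2 = self._unpack(wvec)
        hidden = _sigmoid(X @ w1 + b1)
        return hidden, _sigmoid(hidden @ w2 + b2)

    def _error_rate(self, wvec, X, targets) -> float:
        _, out = self._forward(wvec, X)
        return float(np.mean(np.argmax(out, axis=1) != np.argmax(targets, axis=1)))

    def _gradient(self, wvec, X, targets) -> np.ndarray:
        w1, b1, w2, b2 = self._unpack(wvec)
        hidden = _sigmoid(X @ w1 + b1)
        out = _sigmoid(hidden @ w2 + b2)
        # sum-of-squares loss, sigmoid activations
        d_out = (out - targets) * out * (1.0 - out)
        d_hidden = (d_out @ w2.T) * hidden * (1.0 - hidden)
        return np.concatenate(
            [
                (X.T @ d_hidden).ravel(),
                d_hidden.sum(axis=0),
                (hidden.T @ d_out).ravel(),
                d_out.sum(axis=0),
            ]
        )

    def _ga_phase(self, wvec, X, targets, rng):
        """Evolve a weight population seeded from the current network.

        Fitness is the training misclassification rate (sum-of-squares error
        breaks ties); elitism guarantees the returned individual is never
        worse than the entering one.
        """

        def fitness(v):
            _, out = self._forward(v, X)
            err = np.mean(np.argmax(out, axis=1) != np.argmax(targets, axis=1))
            return err, float(np.sum((out - targets) ** 2))

        pop = [wvec] + [
            wvec + rng.normal(0.0, self.ga_sigma, size=wvec.shape)
            for _ in range(self.ga_population - 1)
        ]
        scores = [fitness(v) for v in pop]
        for _ in range(self.ga_generations):
            order = np.argsort([s[0] * 1e6 + s[1] for s in scores])
            pop = [pop[i] for i in order]
            scores = [scores[i] for i in order]
            parents = pop[: max(2, self.ga_population // 2)]
            children = []
            for _ in range(self.ga_population - self.ga_elites):
                i, j = rng.choice(len(parents), size=2, replace=False)
                cross = rng.random(wvec.shape) < 0.5
                child = np.where(cross, parents[i], parents[j])
                child = child + rng.normal(0.0, self.ga_sigma, size=wvec.shape)
                children.append(child)
            pop = pop[: self.ga_elites] + children
            scores = scores[: self.ga_elites] + [fitness(v) for v in children]
        best = int(np.argmin([s[0] * 1e6 + s[1] for s in scores]))
        return pop[best], scores[best][0]

    # ------------------------------------------------------------- predict

    def predict_proba(self, X):
        """Output activations of the three output units (not normalized —
        sigmoid outputs, as used for the argmax decision)."""
        check_is_fitted(self, "coef_hidden_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects {self.n_features_in_}"
            )
        hidden = _sigmoid(X @ self.coef_hidden_ + self.intercept_hidden_)
        return _sigmoid(hidden @ self.coef_output_ + self.intercept_output_)

    def predict(self, X):
        act = self.predict_proba(X)
        return self.classes_[np.argmax(act, axis=1)]

    def check_fingerprint(self, config: FeatureConfig) -> None:
        """Raise unless the model was trained under ``config``'s conventions."""
        check_is_fitted(self, "coef_hidden_")
        fp = getattr(self, "feature_fingerprint_", None)
        if fp is not None and fp != config.fingerprint():
            raise FingerprintMismatchError(
                f"model feature fingerprint {fp} does not match the "
                f"extractor configuration {config.fingerprint()}"
            )


def train(
    X,
    y,
    config: TrainConfig | None = None,
    feature_config: FeatureConfig | None = None,
) -> tuple[PhenotypeNetClassifier, pd.DataFrame]:
    """Train a phenotype network; returns the fitted model and training log."""
    cfg = config or TrainConfig()
    kwargs = asdict(cfg)
    seed = kwargs.pop("seed")
    model = PhenotypeNetClassifier(
        random_state=seed, feature_config=feature_config, **kwargs
    )
    model.fit(X, y)
    return model, model.history_


# ------------------------------------------------------------------ storage


def save_model(model: PhenotypeNetClassifier, path: str | Path) -> None:
    """Serialize a trained model to versioned JSON."""
    check_is_fitted(model, "coef_hidden_")
    doc = {
        "format": _FORMAT,
        "version": _VERSION,
        "params": {
            k: v for k, v in model.get_params().items() if k != "feature_config"
        },
        "feature_fingerprint": getattr(model, "feature_fingerprint_", None),
        "classes": [str(c) for c in model.classes_],
        "n_features_in": int(model.n_features_in_),
        "weights": {
            "coef_hidden": model.coef_hidden_.tolist(),
            "intercept_hidden": model.intercept_hidden_.tolist(),
            "coef_output": model.coef_output_.tolist(),
            "intercept_output": model.intercept_output_.tolist(),
        },
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> PhenotypeNetClassifier:
    """Load a model saved by :func:`save_model`; predictions round-trip
    bit-for-bit."""
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"{path}: not a valid model file ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != _FORMAT:
        raise ValueError(f"{path}: not a {_FORMAT} model file")
    if doc.get("version") != _VERSION:
        raise ValueError(
            f"{path}: unsupported model version {doc.get('version')!r}"
        )
    model = PhenotypeNetClassifier(**doc["params"])
    model.classes_ = np.array(doc["classes"], dtype=object)
    model.n_features_in_ = int(doc["n_features_in"])
    w = doc["weights"]
    model.coef_hidden_ = np.asarray(w["coef_hidden"], float)
    model.intercept_hidden_ = np.asarray(w["intercept_hidden"], float)
    model.coef_output_ = np.asarray(w["coef_output"], float)
    model.intercept_output_ = np.asarray(w["intercept_output"], float)
    if model.coef_hidden_.shape != (model.n_features_in_, model.hidden_size):
        raise ValueError(f"{path}: weight shapes inconsistent with architecture")
    if doc.get("feature_fingerprint") is not None:
        model.feature_fingerprint_ = doc["feature_fingerprint"]
    return model
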