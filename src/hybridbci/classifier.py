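"""One-hidden-layer log-sigmoid network trained with Levenberg–Marquardt.

The classifier maps a 54-value PSD feature vector (min–max scaled to [0, 1]
per feature, with scaling parameters fitted on the training split only) to
k class activations:

    z_k = sigma(b_k + sum_j w_kj * sigma(b_j + sum_i w_ji * x*_i))

Training minimizes the mean squared error against one-hot targets with a
damped Gauss–Newton (Levenberg–Marquardt) update

    dw = (J'J + lambda I)^-1 J' e

where J is the analytic Jacobian of the per-sample output errors.  The
damping factor is divided by 10 after an accepted step and multiplied by 10
after a rejected one.  A validation split provides early stopping: training
halts once validation MSE has risen for `patience` consecutive epochs, and
the weights from the best-validation epoch are returned.  The hidden-layer
size is selected by sweeping 4–20 neurons and keeping the model with the
lowest validation MSE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationParams",
    "ANNModel",
    "TrainingConfig",
    "TrainingHistory",
    "LabelledDataset",
    "fit_normalization",
    "apply_normalization",
    "forward",
    "train_lm",
    "select_architecture",
    "predict_class",
    "early_stop_epoch",
    "save_model",
    "load_model",
]


def _sigmoid(a: np.ndarray) -> np.ndarray:
    # numerically safe log-sigmoid
    out = np.empty_like(a, dtype=float)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


# --------------------------------------------------------------------------
# Normalization (min–max feature scaling)
# --------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    """Per-feature minima/maxima fitted on training data only."""

    x_min: np.ndarray
    x_max: np.ndarray

    def __post_init__(self) -> None:
        self.x_min = np.asarray(self.x_min, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        if self.x_min.shape != self.x_max.shape:
            raise ValueError("x_min and x_max shapes differ")
        if np.any(self.x_max < self.x_min):
            raise ValueError("x_max must be >= x_min component-wise")

    @property
    def constant_features(self) -> np.ndarray:
        """Boolean mask of features with zero training range."""
        return self.x_max == self.x_min


def fit_normalization(training_features: np.ndarray) -> NormalizationParams:
    X = np.asarray(training_features, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a 2-D feature matrix with at least 2 rows")
    return NormalizationParams(X.min(axis=0), X.max(axis=0))


def apply_normalization(features: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """x* = (x - x_min) / (x_max - x_min), clipped to [0, 1].

    Features that were constant in training map to 0.5 (no information).
    """
    X = np.asarray(features, dtype=float)
    if X.shape[-1] != params.x_min.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[-1]} does not match fitted "
            f"{params.x_min.shape[0]}")
    span = params.x_max - params.x_min
    safe = np.where(span > 0, span, 1.0)
    out = np.clip((X - params.x_min) / safe, 0.0, 1.0)
    const = params.constant_features
    if np.any(const):
        out[..., const] = 0.5
    return out


# --------------------------------------------------------------------------
# Model
# --------------------------------------------------------------------------

@dataclass
class ANNModel:
    """Weights/biases of the one-hidden-layer log-sigmoid network."""

    W_hidden: np.ndarray          # (m, n)
    b_hidden: np.ndarray          # (m,)
    W_out: np.ndarray             # (k, m)
    b_out: np.ndarray             # (k,)
    norm: NormalizationParams
    class_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W_hidden = np.asarray(self.W_hidden, dtype=float)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float)
        self.W_out = np.asarray(self.W_out, dtype=float)
        self.b_out = np.asarray(self.b_out, dtype=float)
        m, n = self.W_hidden.shape
        k = self.W_out.shape[0]
        if self.b_hidden.shape != (m,) or self.W_out.shape != (k, m) \
                or self.b_out.shape != (k,):
            raise ValueError("inconsistent model dimensions")
        if len(self.class_names) != k:
            raise ValueError("class_names length must equal output count")

    @property
    def n_inputs(self) -> int:
        return self.W_hidden.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W_hidden.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.W_out.shape[0]


def forward(model: ANNModel, x_star: np.ndarray) -> np.ndarray:
    """Output activations z for scaled input(s); all strictly in (0, 1)."""
    for W in (model.W_hidden, model.b_hidden, model.W_out, model.b_out):
        if not np.all(np.isfinite(W)):
            raise ValueError("model contains non-finite weights")
    X = np.atleast_2d(np.asarray(x_star, dtype=float))
    y = _sigmoid(X @ model.W_hidden.T + model.b_hidden)
    z = _sigmoid(y @ model.W_out.T + model.b_out)
    return z[0] if np.asarray(x_star).ndim == 1 else z


def predict_class(model: ANNModel, raw_features: np.ndarray) -> str | list[str]:
    """Normalize, run the forward pass and return the argmax class.

    Ties are broken toward the lowest class index.
    """
    X = np.asarray(raw_features, dtype=float)
    z = forward(model, apply_normalization(X, model.norm))
    if X.ndim == 1:
        return model.class_names[int(np.argmax(z))]
    return [model.class_names[int(i)] for i in np.argmax(z, axis=1)]


# --------------------------------------------------------------------------
# Datasets
# --------------------------------------------------------------------------

@dataclass
class LabelledDataset:
    """Feature rows with class labels and a one-hot target encoding."""

    features: np.ndarray
    labels: np.ndarray                 # array of str
    class_names: list[str] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels disagree in length")
        if self.class_names is None:
            self.class_names = sorted(set(self.labels.tolist()))
        if len(self.class_names) < 2:
            raise ValueError("need at least 2 classes")

    @property
    def one_hot(self) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.class_names)}
        T = np.zeros((len(self.labels), len(self.class_names)))
        for r, lab in enumerate(self.labels):
            T[r, idx[lab]] = 1.0
        return T

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_column: str = "label",
                   drop: tuple[str, ...] = ("window_index", "session"),
                   class_names: list[str] | None = None) -> "LabelledDataset":
        cols = [c for c in df.columns if c != label_column and c not in drop]
        return cls(df[cols].to_numpy(float), df[label_column].to_numpy(),
                   class_names)

    def subset(self, idx: np.ndarray) -> "LabelledDataset":
        return LabelledDataset(self.features[idx], self.labels[idx],
                               self.class_names)


def split_dataset(dataset: LabelledDataset, seed: int = 0,
                  sessions: np.ndarray | None = None,
                  fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)):
    """Train/validation/test split.

    With ``sessions`` given (one id per row), whole sessions are assigned to
    splits per class (session-blocked, the default protocol elsewhere in the
    package) so overlapping windows from one session never leak across
    splits.  Otherwise a stratified random split over rows is used.
    """
    rng = np.random.default_rng(seed)
    n = len(dataset.features)
    assign = np.empty(n, dtype=int)
    if sessions is not None:
        sessions = np.asarray(sessions)
        for cls_name in dataset.class_names:
            mask = dataset.labels == cls_name
            ids = np.unique(sessions[mask])
            ids = ids[rng.permutation(len(ids))]
            bounds = (np.cumsum(fractions) * len(ids)).round().astype(int)
            groups = np.split(ids, bounds[:-1])
            for g, sess_ids in enumerate(groups):
                assign[mask & np.isin(sessions, sess_ids)] = g
    else:
        for cls_name in dataset.class_names:
            idx = np.flatnonzero(dataset.labels == cls_name)
            idx = idx[rng.permutation(len(idx))]
            bounds = (np.cumsum(fractions) * len(idx)).round().astype(int)
            for g, part in enumerate(np.split(idx, bounds[:-1])):
                assign[part] = g
    return tuple(dataset.subset(np.flatnonzero(assign == g)) for g in range(3))


# --------------------------------------------------------------------------
# Levenberg–Marquardt training
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingConfig:
    max_epochs: int = 50
    lm_lambda_init: float = 1e-3
    lm_lambda_up: float = 10.0
    lm_lambda_down: float = 10.0
    patience: int = 3
    hidden_sweep: tuple[int, int] = (4, 20)   # inclusive
    seed: int = 0
    max_rejects: int = 12     # lambda escalations per epoch before giving up

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainingHistory:
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stop_epoch: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_mse) + 1),
            "train_mse": self.train_mse,
            "validation_mse": self.val_mse,
        })


def early_stop_epoch(val_mse: list[float], patience: int) -> tuple[int, int]:
    """(stop_epoch, best_epoch), 1-based, under the consecutive-rise rule.

    Training stops after the first epoch ending a run of ``patience``
    consecutive validation-MSE increases; the returned weights are those of
    the epoch with the minimum validation MSE seen so far.
    """
    rises = 0
    for e in range(1, len(val_mse)):
        rises = rises + 1 if val_mse[e] > val_mse[e - 1] else 0
        if rises >= patience:
            stop = e + 1
            return stop, int(np.argmin(val_mse[:stop])) + 1
    return len(val_mse), int(np.argmin(val_mse)) + 1 if val_mse else 0


def _init_model(n: int, m: int, k: int, norm: NormalizationParams,
                class_names: list[str], rng: np.random.Generator) -> ANNModel:
    # uniform [-0.5, 0.5] scaled by 1/sqrt(fan-in)
    return ANNModel(
        W_hidden=rng.uniform(-0.5, 0.5, (m, n)) / np.sqrt(n),
        b_hidden=rng.uniform(-0.5, 0.5, m) / np.sqrt(n),
        W_out=rng.uniform(-0.5, 0.5, (k, m)) / np.sqrt(m),
        b_out=rng.uniform(-0.5, 0.5, k) / np.sqrt(m),
        norm=norm, class_names=list(class_names))


def _pack(model: ANNModel) -> np.ndarray:
    return np.concatenate([model.W_hidden.ravel(), model.b_hidden,
                           model.W_out.ravel(), model.b_out])


def _unpack(w: np.ndarray, model: ANNModel) -> None:
    m, n = model.W_hidden.shape
    k = model.W_out.shape[0]
    o = 0
    model.W_hidden = w[o:o + m * n].reshape(m, n); o += m * n
    model.b_hidden = w[o:o + m].copy(); o += m
    model.W_out = w[o:o + k * m].reshape(k, m); o += k * m
    model.b_out = w[o:o + k].copy()


def _forward_jacobian(w: np.ndarray, X: np.ndarray, m: int, k: int):
    """Outputs z (S, k) and Jacobian J (S*k, P) of z w.r.t. the packed
    parameters, computed analytically and vectorized over samples."""
    S, n = X.shape
    W1 = w[:m * n].reshape(m, n)
    b1 = w[m * n:m * n + m]
    W2 = w[m * n + m:m * n + m + k * m].reshape(k, m)
    b2 = w[m * n + m + k * m:]
    Y = _sigmoid(X @ W1.T + b1)            # (S, m)
    Z = _sigmoid(Y @ W2.T + b2)            # (S, k)
    dZ = Z * (1 - Z)                        # sigma'(a2)
    dY = Y * (1 - Y)                        # sigma'(a1)
    P = m * n + m + k * m + k
    J = np.zeros((S, k, P))
    # dz_c/dW1_{j,i} = dZ_c * W2_{c,j} * dY_j * x_i
    G = dZ[:, :, None] * W2[None, :, :] * dY[:, None, :]       # (S, k, m)
    J[:, :, :m * n] = (G[:, :, :, None] * X[:, None, None, :]).reshape(S, k, m * n)
    J[:, :, m * n:m * n + m] = G
    # dz_c/dW2_{c,j} = dZ_c * Y_j (zero for other output rows)
    block = np.zeros((S, k, k, m))
    for c in range(k):
        block[:, c, c, :] = dZ[:, c, None] * Y
    J[:, :, m * n + m:m * n + m + k * m] = block.reshape(S, k, k * m)
    # dz_c/db2_c = dZ_c
    for c in range(k):
        J[:, c, m * n + m + k * m + c] = dZ[:, c]
    return Z, J.reshape(S * k, P)


def _mse(w: np.ndarray, X: np.ndarray, T: np.ndarray, m: int, k: int) -> float:
    n = X.shape[1]
    W1 = w[:m * n].reshape(m, n)
    b1 = w[m * n:m * n + m]
    W2 = w[m * n + m:m * n + m + k * m].reshape(k, m)
    b2 = w[m * n + m + k * m:]
    Z = _sigmoid(_sigmoid(X @ W1.T + b1) @ W2.T + b2)
    return float(np.mean((Z - T) ** 2))


def lm_step(w: np.ndarray, X: np.ndarray, T: np.ndarray, m: int, k: int,
            lam: float) -> np.ndarray:
    """One proposed damped Gauss–Newton update dw = (J'J + lam I)^-1 J'e."""
    Z, J = _forward_jacobian(w, X, m, k)
    e = (Z - T).ravel()
    A = J.T @ J + lam * np.eye(J.shape[1])
    g = J.T @ e
    try:
        dw = np.linalg.solve(A, g)
    except np.linalg.LinAlgError:
        dw = np.linalg.lstsq(A, g, rcond=None)[0]
    return w - dw


def train_lm(train: LabelledDataset, val: LabelledDataset,
             config: TrainingConfig = TrainingConfig(),
             m: int = 8) -> tuple[ANNModel, TrainingHistory]:
    """Train one network of ``m`` hidden neurons with LM + early stopping.

    One epoch is one accepted LM step (the damping factor is escalated on
    rejection until a step lowers the training MSE or the retry budget is
    exhausted).  Weights from the minimum-validation-MSE epoch are returned.
    """
    if set(train.class_names) != set(val.class_names):
        raise ValueError("train and validation class sets differ")
    norm = fit_normalization(train.features)
    Xtr = apply_normalization(train.features, norm)
    Xva = apply_normalization(val.features, norm)
    Ttr, Tva = train.one_hot, val.one_hot
    n, k = Xtr.shape[1], Ttr.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, m]))
    model = _init_model(n, m, k, norm, train.class_names, rng)
    w = _pack(model)
    lam = config.lm_lambda_init
    history = TrainingHistory()
    best_w, best_val = w.copy(), np.inf
    cost = _mse(w, Xtr, Ttr, m, k)
    rises = 0
    for epoch in range(1, config.max_epochs + 1):
        accepted = False
        for _ in range(config.max_rejects):
            w_new = lm_step(w, Xtr, Ttr, m, k, lam)
            if not np.all(np.isfinite(w_new)):
                raise FloatingPointError("non-finite weights during LM update")
            new_cost = _mse(w_new, Xtr, Ttr, m, k)
            if new_cost < cost:
                w, cost = w_new, new_cost
                lam = max(lam / config.lm_lambda_down, 1e-12)
                accepted = True
                break
            lam *= config.lm_lambda_up
        if not accepted:
            break   # damping exhausted: converged
        val_cost = _mse(w, Xva, Tva, m, k)
        history.train_mse.append(cost)
        history.val_mse.append(val_cost)
        if val_cost < best_val:
            best_val, best_w = val_cost, w.copy()
        rises = rises + 1 if (epoch > 1 and val_cost > history.val_mse[-2]) else 0
        if rises >= config.patience:
            break
    history.stop_epoch = len(history.train_mse)
    history.best_epoch = int(np.argmin(history.val_mse)) + 1 if history.val_mse else 0
    _unpack(best_w, model)
    model.meta = {"hidden": m, "seed": config.seed,
                  "stop_epoch": history.stop_epoch,
                  "best_epoch": history.best_epoch,
                  "best_val_mse": best_val}
    return model, history


def select_architecture(train: LabelledDataset, val: LabelledDataset,
                        config: TrainingConfig = TrainingConfig()
                        ) -> tuple[ANNModel, pd.DataFrame]:
    """Sweep hidden sizes (default 4–20), keep the lowest validation MSE.

    Ties break toward the smallest network.  Returns the winning model and
    the full sweep table (hidden, epochs, train/validation MSE).
    """
    lo, hi = config.hidden_sweep
    rows, best = [], None
    for m in range(lo, hi + 1):
        model, hist = train_lm(train, val, config, m)
        val_mse = model.meta["best_val_mse"]
        rows.append({"hidden": m, "epochs": hist.stop_epoch,
                     "train_mse": hist.train_mse[hist.best_epoch - 1]
                     if hist.train_mse else np.nan,
                     "validation_mse": val_mse})
        if best is None or val_mse < best[0]:
            best = (val_mse, model)
    return best[1], pd.DataFrame(rows)


def evaluate_accuracy(model: ANNModel, dataset: LabelledDataset) -> float:
    """Fraction of rows whose argmax prediction matches the label."""
    pred = predict_class(model, dataset.features)
    return float(np.mean(np.asarray(pred) == dataset.labels))


# --------------------------------------------------------------------------
# Serialization (structured text)
# --------------------------------------------------------------------------

def save_model(model: ANNModel, path: str | Path) -> None:
    payload = {
        "format": "hybridbci-ann-v1",
        "n": model.n_inputs, "m": model.n_hidden, "k": model.n_outputs,
        "class_names": model.class_names,
        "x_min": model.norm.x_min.tolist(),
        "x_max": model.norm.x_max.tolist(),
        "W_hidden": model.W_hidden.tolist(),
        "b_hidden": model.b_hidden.tolist(),
        "W_out": model.W_out.tolist(),
        "b_out": model.b_out.tolist(),
        "meta": model.meta,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> ANNModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "hybridbci-ann-v1":
        raise ValueError(f"{path}: not a hybridbci ANN model file")
    return ANNModel(
        W_hidden=np.array(payload["W_hidden"]),
        b_hidden=np.array(payload["b_hidden"]),
        W_out=np.array(payload["W_out"]),
        b_out=np.array(payload["b_out"]),
        norm=NormalizationParams(np.array(payload["x_min"]),
                                 np.array(payload["x_max"])),
        class_names=list(payload["class_names"]),
        meta=dict(payload.get("meta", {})),
    )
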